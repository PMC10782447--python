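"""Numba-compiled inner loops: pair listing, pair potentials, descriptors.

Everything here operates on plain float64/int64 arrays; object-level wrapping
(species lookup, configuration validation, unit handling) lives in the public
modules.  All energies are kJ/mol, lengths nm, forces kJ/(mol nm).

Sign conventions: kernels that return ``f`` arrays return *forces* (-dE/dx)
except the descriptor contraction, which returns the raw gradient of the
contracted scalar so the caller picks the sign.
"""

import math

import numpy as np
from numba import njit

SQRT_PI = math.sqrt(math.pi)


@njit(cache=True, fastmath=False)
def _mic(dx, dy, dz, bx, by, bz):
    dx -= bx * math.floor(dx / bx + 0.5)
    dy -= by * math.floor(dy / by + 0.5)
    dz -= bz * math.floor(dz / bz + 0.5)
    return dx, dy, dz


@njit(cache=True)
def build_pairs(pos, box, cutoff):
    """All unordered pairs (i<j) with minimum-image distance < cutoff. O(N^2)."""
    n = pos.shape[0]
    c2 = cutoff * cutoff
    bx, by, bz = box[0], box[1], box[2]
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy, dz = _mic(pos[j, 0] - pos[i, 0], pos[j, 1] - pos[i, 1],
                              pos[j, 2] - pos[i, 2], bx, by, bz)
            if dx * dx + dy * dy + dz * dz < c2:
                count += 1
    pi = np.empty(count, np.int64)
    pj = np.empty(count, np.int64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy, dz = _mic(pos[j, 0] - pos[i, 0], pos[j, 1] - pos[i, 1],
                              pos[j, 2] - pos[i, 2], bx, by, bz)
            if dx * dx + dy * dy + dz * dz < c2:
                pi[k] = i
                pj[k] = j
                k += 1
    return pi, pj


@njit(cache=True)
def max_displacement(pos, ref, box):
    """Largest minimum-image displacement between two coordinate sets."""
    n = pos.shape[0]
    best = 0.0
    for i in range(n):
        dx, dy, dz = _mic(pos[i, 0] - ref[i, 0], pos[i, 1] - ref[i, 1],
                          pos[i, 2] - ref[i, 2], box[0], box[1], box[2])
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > best:
            best = d2
    return math.sqrt(best)


@njit(cache=True)
def lj_pair(pos, box, pi, pj, sidx, sig, eps, rcut, shift, forces):
    """12-6 LJ over a pair list; adds forces in place, returns (energy, r_min).

    ``shift`` truncates-and-shifts the energy to zero at rcut.  ``r_min`` lets
    the caller detect hard-core overlaps without exceptions inside numba.
    """
    e = 0.0
    rmin = 1e30
    c2 = rcut * rcut
    for p in range(pi.shape[0]):
        i = pi[p]
        j = pj[p]
        dx, dy, dz = _mic(pos[j, 0] - pos[i, 0], pos[j, 1] - pos[i, 1],
                          pos[j, 2] - pos[i, 2], box[0], box[1], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= c2:
            continue
        r = math.sqrt(r2)
        if r < rmin:
            rmin = r
        if r2 < 1e-8:      # hard overlap: caller raises via rmin
            continue
        epsij = eps[sidx[i], sidx[j]]
        if epsij == 0.0:
            continue
        s = sig[sidx[i], sidx[j]]
        sr2 = (s * s) / r2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        e += 4.0 * epsij * (sr12 - sr6)
        if shift:
            sc2 = (s * s) / c2
            sc6 = sc2 * sc2 * sc2
            e -= 4.0 * epsij * (sc6 * sc6 - sc6)
        # f = -dU/dr ; fr = f/r along r_ij (j relative to i)
        fr = 24.0 * epsij * (2.0 * sr12 - sr6) / r2
        forces[i, 0] -= fr * dx
        forces[i, 1] -= fr * dy
        forces[i, 2] -= fr * dz
        forces[j, 0] += fr * dx
        forces[j, 1] += fr * dy
        forces[j, 2] += fr * dz
    return e, rmin


@njit(cache=True)
def wolf_pair(pos, box, pi, pj, q, ke_eff, alpha, rcut, dsf, forces):
    """Wolf-summed Coulomb over a pair list (damped-shifted force by default).

    DSF: U = ke'*qq*[erfc(ar)/r - erfc(aRc)/Rc + fs*(r-Rc)],
    F(r) = ke'*qq*[erfc(ar)/r^2 + (2a/sqrt(pi)) e^{-a^2 r^2}/r - fs];
    both vanish at Rc.  Energy-shift variant drops the fs terms.
    The per-charge self term is handled by the caller (constant, no force).
    """
    e = 0.0
    c2 = rcut * rcut
    erfc_rc = math.erfc(alpha * rcut)
    e_shift = erfc_rc / rcut
    f_shift = erfc_rc / c2 + (2.0 * alpha / SQRT_PI) * math.exp(-alpha * alpha * c2) / rcut
    for p in range(pi.shape[0]):
        i = pi[p]
        j = pj[p]
        qq = q[i] * q[j]
        if qq == 0.0:
            continue
        dx, dy, dz = _mic(pos[j, 0] - pos[i, 0], pos[j, 1] - pos[i, 1],
                          pos[j, 2] - pos[i, 2], box[0], box[1], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= c2 or r2 < 1e-8:
            continue
        r = math.sqrt(r2)
        erfc_r = math.erfc(alpha * r)
        gauss = (2.0 * alpha / SQRT_PI) * math.exp(-alpha * alpha * r2)
        u = erfc_r / r - e_shift
        fmag = erfc_r / r2 + gauss / r
        if dsf:
            u += f_shift * (r - rcut)
            fmag -= f_shift
        e += ke_eff * qq * u
        fr = ke_eff * qq * fmag / r
        forces[i, 0] -= fr * dx
        forces[i, 1] -= fr * dy
        forces[i, 2] -= fr * dz
        forces[j, 0] += fr * dx
        forces[j, 1] += fr * dy
        forces[j, 2] += fr * dz
    return e


@njit(cache=True)
def gaussian_pair(pos, box, pi, pj, sidx, amp, r0, width, rcut, forces):
    """Sum-of-Gaussians pair extras with a smooth (1-(r/rc)^2)^2 envelope.

    ``amp``, ``r0``, ``width`` are (S, S, T) stacks of per-species-pair terms
    (amp == 0 marks unused slots).  Used by the synthetic oracle.
    """
    e = 0.0
    c2 = rcut * rcut
    nt = amp.shape[2]
    for p in range(pi.shape[0]):
        i = pi[p]
        j = pj[p]
        a = sidx[i]
        b = sidx[j]
        dx, dy, dz = _mic(pos[j, 0] - pos[i, 0], pos[j, 1] - pos[i, 1],
                          pos[j, 2] - pos[i, 2], box[0], box[1], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= c2 or r2 < 1e-8:
            continue
        r = math.sqrt(r2)
        u = r / rcut
        env = (1.0 - u * u)
        fc = env * env
        dfc = -4.0 * u * env / rcut
        for t in range(nt):
            A = amp[a, b, t]
            if A == 0.0:
                continue
            w = width[a, b, t]
            g = math.exp(-(r - r0[a, b, t]) ** 2 / (2.0 * w * w))
            dg = -(r - r0[a, b, t]) / (w * w) * g
            e += A * g * fc
            dudr = A * (dg * fc + g * dfc)
            fr = -dudr / r
            forces[i, 0] -= fr * dx
            forces[i, 1] -= fr * dy
            forces[i, 2] -= fr * dz
            forces[j, 0] += fr * dx
            forces[j, 1] += fr * dy
            forces[j, 2] += fr * dz
    return e


@njit(cache=True)
def _csr_neighbors(pos, box, pi, pj, keep, rc):
    """CSR neighbor structure restricted to ``keep`` particles within rc.

    Returns (offsets, nbr index, nbr displacement vectors, nbr distances).
    Displacements point from the center to the neighbor.
    """
    n = pos.shape[0]
    c2 = rc * rc
    counts = np.zeros(n + 1, np.int64)
    for p in range(pi.shape[0]):
        i = pi[p]
        j = pj[p]
        if not (keep[i] and keep[j]):
            continue
        dx, dy, dz = _mic(pos[j, 0] - pos[i, 0], pos[j, 1] - pos[i, 1],
                          pos[j, 2] - pos[i, 2], box[0], box[1], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if 1e-8 <= r2 < c2:
            counts[i + 1] += 1
            counts[j + 1] += 1
    offsets = np.cumsum(counts)
    total = offsets[n]
    nbr = np.empty(total, np.int64)
    vec = np.empty((total, 3), np.float64)
    dist = np.empty(total, np.float64)
    cursor = offsets[:-1].copy()
    for p in range(pi.shape[0]):
        i = pi[p]
        j = pj[p]
        if not (keep[i] and keep[j]):
            continue
        dx, dy, dz = _mic(pos[j, 0] - pos[i, 0], pos[j, 1] - pos[i, 1],
                          pos[j, 2] - pos[i, 2], box[0], box[1], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if 1e-8 <= r2 < c2:
            r = math.sqrt(r2)
            k = cursor[i]
            nbr[k] = j
            vec[k, 0] = dx
            vec[k, 1] = dy
            vec[k, 2] = dz
            dist[k] = r
            cursor[i] += 1
            k = cursor[j]
            nbr[k] = i
            vec[k, 0] = -dx
            vec[k, 1] = -dy
            vec[k, 2] = -dz
            dist[k] = r
            cursor[j] += 1
    return offsets, nbr, vec, dist


@njit(cache=True)
def three_body_angular(pos, box, pi, pj, sidx, target_sp, lam, rc, forces):
    """Stillinger-Weber-like angular term among one species.

    E = lam * sum_i sum_{j<k in N(i)} (cos t_jik + 1/3)^2 fc(rij) fc(rik),
    with all of i, j, k of species ``target_sp``.  Adds forces in place.
    """
    n = pos.shape[0]
    keep = np.zeros(n, np.bool_)
    for i in range(n):
        keep[i] = sidx[i] == target_sp
    offs, nbr, vec, dist = _csr_neighbors(pos, box, pi, pj, keep, rc)
    e = 0.0
    for i in range(n):
        if not keep[i]:
            continue
        for a in range(offs[i], offs[i + 1]):
            j = nbr[a]
            rij = dist[a]
            uj = rij / rc
            envj = 1.0 - uj * uj
            fcj = envj * envj
            dfcj = -4.0 * uj * envj / rc
            for b in range(a + 1, offs[i + 1]):
                k = nbr[b]
                rik = dist[b]
                uk = rik / rc
                envk = 1.0 - uk * uk
                fck = envk * envk
                dfck = -4.0 * uk * envk / rc
                dot = (vec[a, 0] * vec[b, 0] + vec[a, 1] * vec[b, 1]
                       + vec[a, 2] * vec[b, 2])
                cost = dot / (rij * rik)
                h = cost + 1.0 / 3.0
                e += lam * h * h * fcj * fck
                # dE/dcos
                dcos = lam * 2.0 * h * fcj * fck
                # dE/drij, dE/drik (envelope parts)
                drj = lam * h * h * dfcj * fck
                drk = lam * h * h * fcj * dfck
                for x in range(3):
                    # grad of cos wrt r_j and r_k (r_i gets minus the sum)
                    gcj = vec[b, x] / (rij * rik) - cost * vec[a, x] / (rij * rij)
                    gck = vec[a, x] / (rij * rik) - cost * vec[b, x] / (rik * rik)
                    gj = dcos * gcj + drj * vec[a, x] / rij
                    gk = dcos * gck + drk * vec[b, x] / rik
                    forces[j, x] -= gj
                    forces[k, x] -= gk
                    forces[i, x] += gj + gk
    return e


# ---------------------------------------------------------------------------
# Atomic-environment descriptors (radial Gaussians + angular invariants)
# ---------------------------------------------------------------------------

def descriptors(pos, box, pi, pj, svoc, visible, rc, mu, wrad,
                zeta, lamb, eta, pair_channel, n_rad_feat,
                mode, g_in, r_in):
    """Descriptor wrapper that builds the CSR neighbor structure on the fly.

    Hot paths (MD, training) build the CSR once per configuration and call
    :func:`desc_core` directly.
    """
    offs, nbr, vec, dist = _csr_neighbors(pos, box, pi, pj, visible, rc)
    return desc_core(offs, nbr, vec, dist, svoc, rc, mu, wrad, zeta, lamb,
                     eta, pair_channel, n_rad_feat, mode, g_in, r_in)


@njit(cache=True)
def desc_core(offs, nbr, vec, dist, svoc, rc, mu, wrad,
              zeta, lamb, eta, pair_channel, n_rad_feat,
              mode, g_in, r_in):
    """Environment descriptors for every ML-visible particle, with optional
    Jacobian contractions computed in the same pass.

    Layout per atom: for each neighbor-species channel s, ``n_rad`` radial
    features  G[s,m] = sum_j exp(-(r-mu_m)^2/(2 w^2)) fc(r); then for each
    unordered species-pair channel c and angular basis z,
    A[c,z] = sum_{j<k} 2^{1-zeta} (1+lambda cos t)^zeta
             exp(-eta (rij^2+rik^2)) fc(rij) fc(rik).

    mode 0: descriptors only.
    mode 1: also return grad = d/dx ( sum_{i,f} g_in[i,f] * d[i,f] )  (N,3).
    mode 2: also return v[i,f] = sum_{a,x} r_in[a,x] * dd[i,f]/dx[a,x]  (N,F).

    svoc: per-particle vocabulary index (-1 = not visible / unknown).
    """
    n = offs.shape[0] - 1
    n_rad = mu.shape[0]
    n_z = zeta.shape[0]
    n_pc = 0
    ns = pair_channel.shape[0]
    for a in range(ns):
        for b in range(a, ns):
            n_pc += 1
    nfeat = n_rad_feat + n_pc * n_z
    d = np.zeros((n if mode == 0 else 1, nfeat), np.float64)
    grad = np.zeros((n, 3), np.float64)
    vout = np.zeros((n, nfeat) if mode == 2 else (1, 1), np.float64)

    dmu = mu[1] - mu[0]
    window = 7.5 * wrad          # beyond this the Gaussian is < 1e-12
    inv_2w2 = 1.0 / (2.0 * wrad * wrad)
    # Gaussian grid recurrence: phi_{m+1} = phi_m * t_m * cA, t_{m+1} = t_m*cB
    # (2 exps per neighbor instead of one per basis function)
    rec_a = math.exp(-dmu * dmu * inv_2w2)
    rec_b = math.exp(-2.0 * dmu * dmu * inv_2w2)
    scale_z = np.empty(n_z)
    int_z = np.empty(n_z, np.int64)
    for z in range(n_z):
        scale_z[z] = 2.0 ** (1.0 - zeta[z])
        int_z[z] = np.int64(zeta[z]) if zeta[z] == np.floor(zeta[z]) else -1
    for i in range(n):
        if svoc[i] < 0:
            continue
        nn = offs[i + 1] - offs[i]
        if nn == 0:
            continue
        # ---- radial ----
        for a in range(offs[i], offs[i + 1]):
            j = nbr[a]
            r = dist[a]
            u = r / rc
            env = 1.0 - u * u
            fc = env * env
            dfc = -4.0 * u * env / rc
            ch = svoc[j]
            base = ch * n_rad
            m_lo = int(math.ceil((r - window - mu[0]) / dmu))
            m_hi = int(math.floor((r + window - mu[0]) / dmu))
            if m_lo < 0:
                m_lo = 0
            if m_hi > n_rad - 1:
                m_hi = n_rad - 1
            dr = r - mu[m_lo]
            phi = math.exp(-dr * dr * inv_2w2)
            t = math.exp(2.0 * dr * dmu * inv_2w2)
            for m in range(m_lo, m_hi + 1):
                val = phi * fc
                phi_m = phi
                dr_m = dr
                phi *= t * rec_a
                t *= rec_b
                dr -= dmu
                if val < 1e-12:
                    continue
                f = base + m
                if mode == 0:
                    d[i, f] += val
                else:
                    dval = (-dr_m / (wrad * wrad)) * phi_m * fc + phi_m * dfc
                    if mode == 1:
                        c = g_in[i, f] * dval / r
                        grad[j, 0] += c * vec[a, 0]
                        grad[j, 1] += c * vec[a, 1]
                        grad[j, 2] += c * vec[a, 2]
                        grad[i, 0] -= c * vec[a, 0]
                        grad[i, 1] -= c * vec[a, 1]
                        grad[i, 2] -= c * vec[a, 2]
                    else:
                        c = dval / r
                        acc = (r_in[j, 0] - r_in[i, 0]) * c * vec[a, 0] \
                            + (r_in[j, 1] - r_in[i, 1]) * c * vec[a, 1] \
                            + (r_in[j, 2] - r_in[i, 2]) * c * vec[a, 2]
                        vout[i, f] += acc
        # ---- angular ----
        for a in range(offs[i], offs[i + 1]):
            j = nbr[a]
            rij = dist[a]
            uj = rij / rc
            envj = 1.0 - uj * uj
            fcj = envj * envj
            dfcj = -4.0 * uj * envj / rc
            for b in range(a + 1, offs[i + 1]):
                k = nbr[b]
                rik = dist[b]
                uk = rik / rc
                envk = 1.0 - uk * uk
                fck = envk * envk
                dfck = -4.0 * uk * envk / rc
                dot = (vec[a, 0] * vec[b, 0] + vec[a, 1] * vec[b, 1]
                       + vec[a, 2] * vec[b, 2])
                cost = dot / (rij * rik)
                rad = math.exp(-eta * (rij * rij + rik * rik))
                pref = rad * fcj * fck
                if pref < 1e-12:
                    continue
                ch = pair_channel[svoc[j], svoc[k]]
                base = n_rad_feat + ch * n_z
                for z in range(n_z):
                    zt = zeta[z]
                    lm = lamb[z]
                    core = 1.0 + lm * cost
                    if core <= 0.0:
                        continue
                    scale = scale_z[z]
                    if int_z[z] >= 0:
                        powz = 1.0
                        for _ in range(int_z[z]):
                            powz *= core
                    else:
                        powz = core ** zt
                    val = scale * powz * pref
                    f = base + z
                    if mode == 0:
                        d[i, f] += val
                        continue
                    # derivative pieces
                    dval_dcos = scale * zt * (powz / core) * lm * pref
                    dval_drj = scale * powz * rad * (fck * dfcj
                                                     - 2.0 * eta * rij * fcj * fck)
                    dval_drk = scale * powz * rad * (fcj * dfck
                                                     - 2.0 * eta * rik * fcj * fck)
                    if mode == 1:
                        gg = g_in[i, f]
                        for x in range(3):
                            gcj = vec[b, x] / (rij * rik) - cost * vec[a, x] / (rij * rij)
                            gck = vec[a, x] / (rij * rik) - cost * vec[b, x] / (rik * rik)
                            gj = gg * (dval_dcos * gcj + dval_drj * vec[a, x] / rij)
                            gk = gg * (dval_dcos * gck + dval_drk * vec[b, x] / rik)
                            grad[j, x] += gj
                            grad[k, x] += gk
                            grad[i, x] -= gj + gk
                    else:
                        acc = 0.0
                        for x in range(3):
                            gcj = vec[b, x] / (rij * rik) - cost * vec[a, x] / (rij * rij)
                            gck = vec[a, x] / (rij * rik) - cost * vec[b, x] / (rik * rik)
                            gj = dval_dcos * gcj + dval_drj * vec[a, x] / rij
                            gk = dval_dcos * gck + dval_drk * vec[b, x] / rik
                            acc += (r_in[j, x] - r_in[i, x]) * gj
                            acc += (r_in[k, x] - r_in[i, x]) * gk
                        vout[i, f] += acc
    return d, grad, vout


# ---------------------------------------------------------------------------
# Integrator inner loops
# ---------------------------------------------------------------------------

@njit(cache=True)
def baoab_first(pos, vel, forces, masses, mob, dt, c1, c2, sigv, noise,
                box, images, zero_com):
    """B(half) A(half) O A(half) of the BAOAB splitting, with wrapping.

    ``zero_com`` projects the mass-weighted centre-of-mass component out of
    the thermostat noise so net momentum of the mobile set stays exactly
    zero (consistent with the 3N-3 degree-of-freedom convention).
    """
    n = pos.shape[0]
    for i in range(n):
        if not mob[i]:
            continue
        im = 1.0 / masses[i]
        for x in range(3):
            vel[i, x] += 0.5 * dt * forces[i, x] * im
            pos[i, x] += 0.5 * dt * vel[i, x]
    if c2 != 0.0:
        bx = by = bz = 0.0
        if zero_com:
            mtot = 0.0
            for i in range(n):
                if not mob[i]:
                    continue
                bx += masses[i] * sigv[i] * noise[i, 0]
                by += masses[i] * sigv[i] * noise[i, 1]
                bz += masses[i] * sigv[i] * noise[i, 2]
                mtot += masses[i]
            bx /= mtot
            by /= mtot
            bz /= mtot
        for i in range(n):
            if not mob[i]:
                continue
            vel[i, 0] = c1 * vel[i, 0] + c2 * (sigv[i] * noise[i, 0] - bx)
            vel[i, 1] = c1 * vel[i, 1] + c2 * (sigv[i] * noise[i, 1] - by)
            vel[i, 2] = c1 * vel[i, 2] + c2 * (sigv[i] * noise[i, 2] - bz)
    for i in range(n):
        if not mob[i]:
            continue
        for x in range(3):
            p = pos[i, x] + 0.5 * dt * vel[i, x]
            s = math.floor(p / box[x])
            if s != 0.0:
                p -= s * box[x]
                images[i, x] += np.int64(s)
            pos[i, x] = p


@njit(cache=True)
def kick(vel, forces, masses, mob, half_dt):
    """Final half-kick (B) of the step."""
    n = vel.shape[0]
    for i in range(n):
        if not mob[i]:
            continue
        im = 1.0 / masses[i]
        for x in range(3):
            vel[i, x] += half_dt * forces[i, x] * im
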