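"""Built-in physics validation: gradient checks, Madelung limit, thermostat.

These checks are the package's own invariant suite (exposed via the
``disolv validate`` CLI): analytic forces vs central finite differences,
the Wolf/DSF electrostatics against an independent direct lattice sum for
rock salt, and Langevin thermostat statistics.
"""

from __future__ import annotations

import numpy as np

from .correction import CorrectionModel, DescriptorConfig
from .md import MDConfig, ZeroForceField, run_md
from .prior import PriorConfig, PriorForceField, build_neighbor_list
from .system import ParticleSystem, SpeciesParams, make_system
from .units import KB, KE_COULOMB


def finite_difference_forces(energy_fn, positions: np.ndarray,
                             h: float = 1e-5) -> np.ndarray:
    """Central finite differences of a scalar energy function."""
    f = np.zeros_like(positions)
    for i in range(positions.shape[0]):
        for x in range(3):
            p = positions.copy()
            p[i, x] += h
            ep = energy_fn(p)
            p[i, x] -= 2 * h
            em = energy_fn(p)
            f[i, x] = -(ep - em) / (2 * h)
    return f


def max_relative_force_error(analytic: np.ndarray, numeric: np.ndarray) -> float:
    scale = max(float(np.max(np.abs(numeric))), 1e-10)
    return float(np.max(np.abs(analytic - numeric)) / scale)


def rocksalt_system(n_cells: int = 6, nn_dist: float = 0.282) -> ParticleSystem:
    """Cubic NaCl rock-salt lattice, ``n_cells`` conventional cells per edge."""
    a = 2.0 * nn_dist
    pos, sp = [], []
    basis = [((0, 0, 0), "Na"), ((0.5, 0.5, 0), "Na"), ((0.5, 0, 0.5), "Na"),
             ((0, 0.5, 0.5), "Na"), ((0.5, 0, 0), "Cl"), ((0, 0.5, 0), "Cl"),
             ((0, 0, 0.5), "Cl"), ((0.5, 0.5, 0.5), "Cl")]
    for i in range(n_cells):
        for j in range(n_cells):
            for k in range(n_cells):
                for (fx, fy, fz), s in basis:
                    pos.append([(i + fx) * a, (j + fy) * a, (k + fz) * a])
                    sp.append(s)
    box = np.full(3, n_cells * a)
    return make_system(np.array(pos), sp, box)


def madelung_direct_sum(n_shells: int = 12) -> float:
    """Independent Madelung constant for rock salt by Evjen's method.

    Direct lattice sum over an expanding cube with fractional weights for
    boundary sites (faces 1/2, edges 1/4, corners 1/8), which keeps every
    partial sum charge-neutral and convergent.  Returns the (positive)
    constant ~1.7476 in units of e^2/(4 pi eps0 d).
    """
    n = n_shells
    total = 0.0
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            for k in range(-n, n + 1):
                if i == j == k == 0:
                    continue
                w = 1.0
                for c in (i, j, k):
                    if abs(c) == n:
                        w *= 0.5
                q = (-1.0) ** ((i + j + k) % 2)
                total += w * q / np.sqrt(i * i + j * j + k * k)
    return -total


def wolf_madelung_energy_per_pair(n_cells: int = 7, nn_dist: float = 0.282,
                                  alpha_rc: float = 3.0) -> float:
    """DSF Wolf energy per NaCl ion pair on the rock-salt lattice, in units
    of k_e/d (so the Madelung limit is -1.7476)."""
    system = rocksalt_system(n_cells, nn_dist)
    r_cut = min(6.5 * nn_dist, 0.5 * float(np.min(system.box)) * 0.999)
    cfg = PriorConfig(r_cut_lj=0.1, r_cut_coul=r_cut, epsilon_r=1.0,
                      alpha=alpha_rc / r_cut)
    params = SpeciesParams()
    for s in ("Na", "Cl"):
        params.table[s]["epsilon"] = 0.0   # electrostatics only
    ff = PriorForceField(system, params, cfg)
    nl = build_neighbor_list(system, ff.cutoff)
    e, _ = ff.compute(system.positions, (nl.i, nl.j))
    n_pairs = len(system) // 2
    return (e / n_pairs) / (KE_COULOMB / nn_dist)


def random_ionic_configurations(n_configs: int, n_ions: int = 8,
                                box_edge: float = 3.0, seed: int = 0,
                                min_dist: float = 0.22) -> list:
    """Small random Na/Cl boxes for gradient checks (no hard overlaps)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_configs):
        pos = []
        while len(pos) < n_ions:
            trial = rng.random(3) * box_edge
            ok = True
            for p in pos:
                d = trial - p
                d -= box_edge * np.floor(d / box_edge + 0.5)
                if np.dot(d, d) < min_dist ** 2:
                    ok = False
                    break
            if ok:
                pos.append(trial)
        sp = ["Na" if k % 2 == 0 else "Cl" for k in range(n_ions)]
        out.append(make_system(np.array(pos), sp, np.full(3, box_edge)))
    return out


def prior_gradient_check(n_configs: int = 10, seed: int = 0) -> float:
    """Worst relative deviation of analytic prior forces vs finite differences."""
    worst = 0.0
    cfg = PriorConfig(r_cut_lj=0.9, r_cut_coul=1.2)
    for system in random_ionic_configurations(n_configs, seed=seed):
        ff = PriorForceField(system, config=cfg)
        nl = build_neighbor_list(system, ff.cutoff)
        pairs = (nl.i, nl.j)
        _, f = ff.compute(system.positions, pairs)
        fd = finite_difference_forces(lambda p: ff.compute(p, pairs)[0],
                                      system.positions)
        worst = max(worst, max_relative_force_error(f, fd))
    return worst


def correction_gradient_check(n_configs: int = 10, seed: int = 0,
                              hidden: int = 8) -> float:
    """Worst relative deviation of correction forces vs finite differences."""
    model = CorrectionModel(["Na", "Cl"],
                            DescriptorConfig(n_radial=16), hidden=hidden, seed=seed)
    rng = np.random.default_rng(seed + 1)
    for s in model.species:  # randomize so gradients are nontrivial
        for k, arr in model.params[s].items():
            arr += 0.3 * rng.standard_normal(arr.shape)
    worst = 0.0
    for system in random_ionic_configurations(n_configs, seed=seed):
        pairs = model._pairs(system)
        _, f = model.energy_forces(system, pairs=pairs)
        fd = finite_difference_forces(
            lambda p: model.energy_forces(system.with_positions(p))[0],
            system.positions)
        worst = max(worst, max_relative_force_error(f, fd))
    return worst


def thermostat_temperature(n_steps: int = 20000, seed: int = 0) -> float:
    """Time-mean kinetic temperature of interacting ions under the thermostat."""
    from .synthetic import FixtureSpec, make_ionic_box, make_oracle
    spec = FixtureSpec(concentration=1.0, box=(3.0, 3.0, 3.0), seed=seed)
    system = make_ionic_box(spec)
    oracle = make_oracle(system, "ssip")
    cfg = MDConfig(n_steps=n_steps, save_every=0.05, seed=seed, equilibration=2.0)
    traj = run_md(system, oracle, cfg)
    return float(np.mean(traj.log["temperature"][1:]))


def free_particle_diffusion_ratio(seed: int = 0, n_particles: int = 512,
                                  t_total: float = 40.0) -> float:
    """Measured Langevin free diffusion over the k_B*T*tau/m prediction."""
    from .analysis import self_diffusion_einstein
    rng = np.random.default_rng(seed)
    box = np.full(3, 50.0)
    pos = rng.random((n_particles, 3)) * box
    system = make_system(pos, ["Na"] * n_particles, box)
    cfg = MDConfig(n_steps=int(t_total / 0.001), save_every=0.1, seed=seed)
    traj = run_md(system, ZeroForceField(), cfg)
    res = self_diffusion_einstein(traj, "Na", fit_window=(0.2, 0.8))
    d_pred = KB * cfg.temperature * cfg.tau / system.masses[0]
    return res.D / d_pred


def run_validation(seed: int = 0) -> dict:
    report = {}
    g = prior_gradient_check(5, seed)
    report["prior_gradients"] = {"pass": g < 1e-6, "detail": f"max rel err {g:.2e}"}
    g = correction_gradient_check(5, seed)
    report["correction_gradients"] = {"pass": g < 1e-5, "detail": f"max rel err {g:.2e}"}
    m = wolf_madelung_energy_per_pair()
    ref = -madelung_direct_sum()
    report["wolf_madelung"] = {
        "pass": abs(m - ref) / abs(ref) < 0.01,
        "detail": f"DSF {m:.4f} vs lattice sum {ref:.4f}"}
    t = thermostat_temperature(10000, seed)
    report["thermostat"] = {"pass": abs(t - 300.0) < 6.0,
                            "detail": f"mean T {t:.1f} K"}
    return report
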