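"""Structural and dynamical observables for implicit-solvent trajectories.

Implements the standard ion-atmosphere battery: radial distribution
functions and coordination numbers, cylindrical normalized density profiles
(NDPs) with block averaging, 3D occupancy grids, first-shell occupancy and
residence times with short-gap filtering, and Einstein-relation
self-diffusion from exactly unwrapped coordinates.

Conventions worth noting (all tested):

* RDF estimator: ordered-pair histogram with minimum image, shell-volume
  normalization ``4 pi r^2 dr`` and ideal density ``(N_B - delta_AB)/V``.
* NDP normalization: species count inside the analyzed cylinder divided by
  the cylinder volume (box-mean convention), so the profile tends to 1 in
  bulk for a homogeneous far field.
* Residence events: maximal occupied intervals after closing vacancy gaps
  of duration <= the tolerance (equality closes; a run of k vacant samples
  counts as a k-stride vacancy); an event's duration is the time between
  its first and last occupied frame, with single-frame events assigned one
  frame stride.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .md import Trajectory
from .units import NM2_PER_PS_TO_M2_PER_S


def _minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.floor(d / box + 0.5)


# ---------------------------------------------------------------------------
# RDF and coordination numbers
# ---------------------------------------------------------------------------

@dataclass
class RDFResult:
    r: np.ndarray                  # bin centers (nm)
    g: np.ndarray
    bin_width: float
    n_frames: int
    n_a: int
    n_b: int
    rho: float                     # ideal-gas density used for normalization
    pair: tuple = ("", "")

    def first_peak(self) -> tuple:
        """(r, g) at the global maximum."""
        k = int(np.argmax(self.g))
        return float(self.r[k]), float(self.g[k])

    def first_minimum_after_peak(self) -> float:
        k = int(np.argmax(self.g))
        rest = self.g[k:]
        dips = np.flatnonzero((rest[1:-1] <= rest[:-2]) & (rest[1:-1] <= rest[2:]))
        if len(dips) == 0:
            return float(self.r[-1])
        return float(self.r[k + 1 + dips[0]])


def radial_distribution(traj: Trajectory, species_a: str, species_b: str,
                        bin_width: float = 0.01, r_max: float = None) -> RDFResult:
    """Pair-histogram g(r) with minimum-image distances."""
    box = traj.box
    half = 0.5 * float(np.min(box))
    if r_max is None:
        r_max = half - bin_width
    if r_max > half + 1e-12:
        raise ValueError(f"r_max {r_max} exceeds half the smallest box edge")
    ia = np.flatnonzero(traj.species == species_a)
    ib = np.flatnonzero(traj.species == species_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError(f"empty species selection {species_a!r}/{species_b!r}")
    same = species_a == species_b
    n_bins = int(np.floor(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    hist = np.zeros(n_bins)
    for frame in traj.positions:
        d = frame[ib][None, :, :] - frame[ia][:, None, :]
        d = _minimum_image(d, box)
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        if same:
            np.fill_diagonal(r, np.inf)
        hist += np.histogram(r.ravel(), bins=edges)[0]
    volume = float(np.prod(box))
    rho = (len(ib) - (1 if same else 0)) / volume
    shell = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = len(traj) * len(ia) * rho * shell
    g = hist / ideal
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFResult(r=centers, g=g, bin_width=bin_width, n_frames=len(traj),
                     n_a=len(ia), n_b=len(ib), rho=rho,
                     pair=(species_a, species_b))


def coordination_number(rdf: RDFResult, rho: float = None) -> np.ndarray:
    """n(r) = 4 pi rho int_0^r g(s) s^2 ds on the RDF's bins (trapezoid)."""
    rho = rdf.rho if rho is None else rho
    integrand = 4.0 * np.pi * rho * rdf.g * rdf.r ** 2
    return cumulative_trapezoid(integrand, rdf.r, initial=0.0)


# ---------------------------------------------------------------------------
# Cylindrical normalized density profiles
# ---------------------------------------------------------------------------

@dataclass
class NDPResult:
    r: np.ndarray                   # cylindrical bin centers (nm)
    ndp: np.ndarray                 # normalized density, mean over blocks
    block_ndp: np.ndarray           # (n_blocks, n_bins)
    std: np.ndarray                 # std over block means
    species: str = ""
    axis_point: tuple = (0.0, 0.0)


def cylindrical_ndp(traj: Trajectory, axis_point, species: str,
                    bin_width: float = 0.02, r_max: float = None,
                    block_ps: float = None) -> NDPResult:
    """Cylindrically averaged density around a z-aligned axis, normalized to
    the species' mean density inside the analyzed cylinder.

    ``axis_point`` is (x, y) of the axis (e.g. the scaffold's center of
    mass); ``block_ps`` sets the block-averaging length (default: 10 blocks).
    """
    box = traj.box
    if r_max is None:
        r_max = 0.5 * float(min(box[0], box[1])) - bin_width
    sel = np.flatnonzero(traj.species == species)
    if len(sel) == 0:
        raise ValueError(f"no particles of species {species!r}")
    n_bins = int(np.floor(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    axis = np.asarray(axis_point, float)[:2]

    times = traj.times
    span = times[-1] - times[0] if len(times) > 1 else 0.0
    if block_ps is None:
        block_ps = span / 10.0 if span > 0 else 1.0
    if span > 0 and block_ps > span + 1e-9:
        raise ValueError("block length exceeds the trajectory span")
    n_blocks = max(1, int(np.floor((span + 1e-12) / block_ps))) if span > 0 else 1
    frames_per_block = len(traj) // n_blocks

    lz = float(box[2])
    shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2) * lz
    cyl_volume = np.pi * r_max ** 2 * lz

    block_profiles = []
    for b in range(n_blocks):
        frames = traj.positions[b * frames_per_block:(b + 1) * frames_per_block]
        hist = np.zeros(n_bins)
        inside = 0
        for frame in frames:
            d = frame[sel][:, :2] - axis
            d = _minimum_image(d, box[:2])
            r = np.sqrt(np.einsum("ij,ij->i", d, d))
            hist += np.histogram(r, bins=edges)[0]
            inside += int(np.sum(r < r_max))
        rho_ref = inside / (len(frames) * cyl_volume) if inside else np.nan
        dens = hist / (len(frames) * shell)
        block_profiles.append(dens / rho_ref if np.isfinite(rho_ref) else dens * 0)
    block_profiles = np.array(block_profiles)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return NDPResult(r=centers, ndp=block_profiles.mean(axis=0),
                     block_ndp=block_profiles,
                     std=block_profiles.std(axis=0), species=species,
                     axis_point=tuple(axis))


# ---------------------------------------------------------------------------
# 3D occupancy grids
# ---------------------------------------------------------------------------

@dataclass
class OccupancyGrid:
    origin: np.ndarray
    spacing: float
    values: np.ndarray              # (nx, ny, nz) probabilities

    def save_text(self, path):
        """Simple volumetric text format: header + flat voxel list."""
        with open(path, "w") as fh:
            nx, ny, nz = self.values.shape
            fh.write(f"# disolv occupancy grid v1\n")
            fh.write(f"origin {self.origin[0]} {self.origin[1]} {self.origin[2]}\n")
            fh.write(f"spacing {self.spacing}\n")
            fh.write(f"shape {nx} {ny} {nz}\n")
            np.savetxt(fh, self.values.ravel()[None].T)


def occupancy_grid_3d(traj: Trajectory, species: str,
                      spacing: float = 0.05) -> OccupancyGrid:
    """Voxel occupation probability, normalized over the trajectory and the
    species' particle count: the values sum to exactly 1."""
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    box = traj.box
    sel = np.flatnonzero(traj.species == species)
    if len(sel) == 0:
        raise ValueError(f"no particles of species {species!r}")
    shape = np.maximum(1, np.ceil(box / spacing - 1e-9).astype(int))
    counts = np.zeros(shape)
    for frame in traj.positions:
        p = frame[sel]
        p = p - box * np.floor(p / box)
        idx = np.minimum((p / spacing).astype(int), shape - 1)
        np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1)
    return OccupancyGrid(origin=np.zeros(3), spacing=spacing,
                         values=counts / (len(traj) * len(sel)))


# ---------------------------------------------------------------------------
# First-shell occupancy and residence times
# ---------------------------------------------------------------------------

@dataclass
class ResidenceStats:
    group: str
    shell_cutoff: float
    gap_tolerance: float
    mean_occupancy: float
    occupancy_std: float
    mean_residence: float           # ps
    residence_std: float
    n_events: int


def _events_from_series(occ: np.ndarray, times: np.ndarray, gap_tol: float,
                        dt: float) -> list:
    """Maximal occupied intervals after closing gaps of duration <= gap_tol.

    A run of k vacant samples between occupied ones represents a vacancy of
    duration k*dt (= t_next - t_prev - dt); it is closed when that duration
    is at most the tolerance, equality included.  An event's duration is the
    time between its first and last occupied frame, with single-frame events
    assigned one frame stride.
    """
    idx = np.flatnonzero(occ)
    if len(idx) == 0:
        return []
    events = []
    start = prev = idx[0]
    for k in idx[1:]:
        if times[k] - times[prev] - dt <= gap_tol + 1e-12:
            prev = k
        else:
            events.append((start, prev))
            start = prev = k
    events.append((start, prev))
    return [max(times[b] - times[a], dt) for a, b in events]


def shell_occupancy_residence(traj: Trajectory, site_groups: dict,
                              shell_cutoffs: dict, gap_tolerance: float = 1.0,
                              species: str = "Na") -> dict:
    """Per-group occupancy statistics and gap-filtered residence times.

    ``site_groups`` maps group name -> static site positions (M, 3) or
    particle indices into the trajectory's template; an ion occupies a
    group's shell when it is within the group's cutoff of *any* site.
    """
    times = traj.times
    if len(times) < 2:
        raise ValueError("need at least 2 frames")
    dt = float(times[1] - times[0])
    if dt > gap_tolerance + 1e-12:
        raise ValueError("frame stride must not exceed the gap tolerance")
    box = traj.box
    half = 0.5 * float(np.min(box))
    ions = np.flatnonzero(traj.species == species)
    out = {}
    for name, sites in site_groups.items():
        cutoff = float(shell_cutoffs[name])
        if cutoff >= half:
            raise ValueError(f"cutoff {cutoff} >= half box for group {name!r}")
        sites = np.asarray(sites)
        if sites.ndim == 1:  # particle indices
            site_pos = traj.positions[:, sites.astype(int), :]
        else:
            site_pos = np.broadcast_to(sites, (len(traj),) + sites.shape)
        occ = np.zeros((len(traj), len(ions)), bool)
        for f in range(len(traj)):
            d = traj.positions[f][ions][:, None, :] - site_pos[f][None, :, :]
            d = _minimum_image(d, box)
            r2 = np.einsum("ijk,ijk->ij", d, d)
            occ[f] = np.min(r2, axis=1) < cutoff * cutoff
        counts = occ.sum(axis=1)
        durations = []
        for i in range(len(ions)):
            durations.extend(_events_from_series(occ[:, i], times, gap_tolerance, dt))
        durations = np.array(durations)
        out[name] = ResidenceStats(
            group=name, shell_cutoff=cutoff, gap_tolerance=gap_tolerance,
            mean_occupancy=float(counts.mean()),
            occupancy_std=float(counts.std()),
            mean_residence=float(durations.mean()) if len(durations) else 0.0,
            residence_std=float(durations.std()) if len(durations) else 0.0,
            n_events=int(len(durations)))
    return out


# ---------------------------------------------------------------------------
# Einstein-relation self-diffusion
# ---------------------------------------------------------------------------

@dataclass
class DiffusionResult:
    D: float                        # nm^2/ps
    D_si: float                     # m^2/s
    fit_window: tuple               # (t_lo, t_hi) ps
    msd_times: np.ndarray
    msd: np.ndarray
    exponent: float                 # log-log slope over the window
    diffusive: bool                 # exponent close to 1


def self_diffusion_einstein(traj: Trajectory, species: str,
                            fit_window: tuple = (0.1, 0.5),
                            n_lags: int = 100) -> DiffusionResult:
    """D from the Einstein relation, MSD averaged over ions and time origins.

    ``fit_window`` is a fraction pair of the MSD span (default 10-50 %,
    avoiding the ballistic start and poorly averaged tail).  The log-log
    exponent over the window is reported; an exponent far from 1 flags a
    non-diffusive regime (e.g. purely ballistic motion).
    """
    if traj.images is None:
        raise ValueError("trajectory has no image counters: cannot unwrap")
    sel = np.flatnonzero(traj.species == species)
    if len(sel) == 0:
        raise ValueError(f"no particles of species {species!r}")
    pos = traj.unwrapped_positions()[:, sel, :]
    times = traj.times
    n = len(times)
    if n < 5:
        raise ValueError("trajectory too short for MSD analysis")
    max_lag = n - 1
    lags = np.unique(np.linspace(1, max_lag, min(n_lags, max_lag)).astype(int))
    msd = np.empty(len(lags))
    for k, lag in enumerate(lags):
        disp = pos[lag:] - pos[:-lag]
        msd[k] = np.mean(np.einsum("fij,fij->fi", disp, disp))
    tau = times[lags] - times[0]

    t_lo = fit_window[0] * tau[-1]
    t_hi = fit_window[1] * tau[-1]
    w = (tau >= t_lo) & (tau <= t_hi)
    if w.sum() < 2:
        raise ValueError("fit window contains fewer than 2 MSD points")
    slope, _ = np.polyfit(tau[w], msd[w], 1)
    log_slope, _ = np.polyfit(np.log(tau[w]), np.log(np.maximum(msd[w], 1e-300)), 1)
    d = slope / 6.0
    return DiffusionResult(D=float(d), D_si=float(d * NM2_PER_PS_TO_M2_PER_S),
                           fit_window=(float(t_lo), float(t_hi)),
                           msd_times=tau, msd=msd, exponent=float(log_slope),
                           diffusive=bool(abs(log_slope - 1.0) < 0.3))


# ---------------------------------------------------------------------------
# Block averaging
# ---------------------------------------------------------------------------

def block_average(series, block_length: int) -> tuple:
    """(mean of block means, population std over block means).

    The series is partitioned into complete blocks of ``block_length``
    samples; any remainder is discarded.
    """
    series = np.asarray(series, float)
    n_blocks = len(series) // block_length
    if n_blocks < 2:
        raise ValueError("need at least 2 complete blocks")
    trimmed = series[:n_blocks * block_length].reshape(n_blocks, block_length)
    means = trimmed.mean(axis=1)
    return float(means.mean()), float(means.std())
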