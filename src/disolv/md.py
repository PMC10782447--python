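"""Implicit-solvent Langevin MD: velocity Verlet with a BAOAB thermostat.

Protocol defaults follow the implicit-solvent simulation setup: 1 fs
timestep, 300 K, Langevin coupling time 0.1 ps (friction gamma = 1/tau),
periodic boundaries, frames saved every 1 ps.  With the thermostat off the
integrator is plain (symplectic) velocity Verlet — the BAOAB splitting
reduces to it exactly in the gamma -> 0 limit.

Frozen particles (``mobile=False``, e.g. the rigid DNA scaffold) keep their
coordinates bit-identical across all frames and carry zero velocity; they
still exert and receive forces (bookkeeping only).

Unwrapping for diffusion analysis is exact: the engine maintains per-particle
integer image counters rather than relying on post-hoc heuristics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .system import OverlapError, ParticleSystem
from .units import KB


@dataclass
class MDConfig:
    """Integration settings (times in ps, temperature in K)."""

    dt: float = 0.001               # 1 fs
    temperature: float = 300.0
    tau: float = 0.1                # Langevin coupling time; gamma = 1/tau
    n_steps: int = 1000
    save_every: float = 1.0         # ps between saved frames
    seed: int = 0
    thermostat: bool = True         # False => NVE velocity Verlet
    variant: str = "baoab"          # "baoab" | "kick" (impulse Langevin)
    skin: float = 0.2               # neighbor-list skin (nm)
    save_velocities: bool = False
    save_forces: bool = False
    equilibration: float = 0.0      # ps discarded before the first saved frame

    def __post_init__(self):
        if self.dt <= 0 or self.tau <= 0:
            raise ValueError("dt and tau must be positive")
        if self.variant not in ("baoab", "kick"):
            raise ValueError(f"unknown Langevin variant {self.variant!r}")
        if self.save_every < self.dt:
            raise ValueError("save_every must be >= dt")

    @property
    def save_stride(self) -> int:
        return max(1, int(round(self.save_every / self.dt)))


@dataclass
class Trajectory:
    """Time-ordered frames plus static species metadata and a scalar log."""

    positions: np.ndarray          # (F, N, 3) wrapped coordinates
    images: np.ndarray             # (F, N, 3) integer image counters
    times: np.ndarray              # (F,) ps, strictly increasing
    template: ParticleSystem       # species/charges/masses/box/masks
    velocities: np.ndarray = None  # (F, N, 3) optional
    forces: np.ndarray = None      # (F, N, 3) optional
    log: dict = field(default_factory=dict)   # step/time/e_pot/e_kin/temperature

    def __len__(self) -> int:
        return len(self.times)

    @property
    def box(self) -> np.ndarray:
        return self.template.box

    @property
    def species(self) -> np.ndarray:
        return self.template.species

    def frame(self, k: int) -> ParticleSystem:
        return self.template.with_positions(self.positions[k])

    def unwrapped_positions(self) -> np.ndarray:
        """(F, N, 3) continuous coordinates suitable for MSD analysis."""
        return self.positions + self.images * self.template.box


class CompositeForceField:
    """Sum of force-field components sharing one master pair list."""

    def __init__(self, *components):
        if not components:
            raise ValueError("need at least one force-field component")
        self.components = list(components)

    @property
    def cutoff(self) -> float:
        return max(c.cutoff for c in self.components)

    def compute(self, positions, pairs):
        e_tot = 0.0
        f_tot = np.zeros_like(positions)
        for c in self.components:
            e, f = c.compute(positions, pairs)
            e_tot += e
            f_tot += f
        return e_tot, f_tot


class ZeroForceField:
    """Free particles (used for thermostat diagnostics)."""

    cutoff = 0.3

    def compute(self, positions, pairs):
        return 0.0, np.zeros_like(positions)


def n_degrees_of_freedom(n_mobile: int) -> int:
    """3N - 3 (net-momentum removal), with the single-particle case pinned to 3."""
    if n_mobile < 1:
        raise ValueError("no mobile particles")
    return 3 if n_mobile == 1 else 3 * n_mobile - 3


def instantaneous_temperature(system: ParticleSystem, velocities: np.ndarray) -> float:
    """2*KE / (k_B * N_dof) over mobile particles only."""
    mob = system.mobile
    ke = 0.5 * np.sum(system.masses[mob, None] * velocities[mob] ** 2)
    return 2.0 * ke / (KB * n_degrees_of_freedom(int(mob.sum())))


def init_velocities(system: ParticleSystem, temperature: float, seed: int = 0) -> np.ndarray:
    """Maxwell-Boltzmann draw for mobile particles; net momentum removed."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = np.random.default_rng(seed)
    n = len(system)
    v = np.zeros((n, 3))
    mob = system.mobile
    sigma = np.sqrt(KB * temperature / system.masses[mob])
    v[mob] = rng.standard_normal((int(mob.sum()), 3)) * sigma[:, None]
    # remove centre-of-mass momentum of the mobile subset
    m = system.masses[mob][:, None]
    v[mob] -= np.sum(m * v[mob], axis=0) / np.sum(m)
    return v


class _Integrator:
    """One-system MD state: positions, velocities, images, pair list."""

    def __init__(self, system: ParticleSystem, forcefield, cfg: MDConfig,
                 velocities: np.ndarray = None):
        self.cfg = cfg
        self.ff = forcefield
        self.system = system.copy()
        self.box = system.box.copy()
        self.mob = system.mobile.copy()
        if velocities is None:
            if not cfg.thermostat:
                raise ValueError("NVE runs require explicit initial velocities")
            velocities = init_velocities(system, cfg.temperature, cfg.seed)
        self.vel = np.asarray(velocities, float).copy()
        self.vel[~self.mob] = 0.0
        self.pos = system.positions.copy()
        self.images = np.zeros((len(system), 3), dtype=np.int64)
        self.rng = np.random.default_rng(cfg.seed + 1)
        self.masses = system.masses[:, None]
        self.m_flat = np.ascontiguousarray(system.masses)
        gamma = (1.0 / cfg.tau) if cfg.thermostat else 0.0
        self.c1 = np.exp(-gamma * cfg.dt)
        self.c2 = np.sqrt(max(0.0, 1.0 - self.c1 ** 2))
        self.sig_v = np.sqrt(KB * cfg.temperature / system.masses)[:, None]
        self.sigv_flat = np.ascontiguousarray(self.sig_v[:, 0])
        self._zero_noise = np.zeros((len(system), 3))
        self._build_pairs()
        self.e_pot, self.forces = self.ff.compute(self.pos, self.pairs)

    def _build_pairs(self):
        cutoff = self.ff.cutoff + self.cfg.skin
        half = 0.5 * float(np.min(self.box))
        if cutoff > half:
            raise ValueError(f"cutoff+skin {cutoff:.3f} nm exceeds half box {half:.3f} nm")
        self.pairs = _kernels.build_pairs(self.pos, self.box, cutoff)
        self._ref_pos = self.pos.copy()

    def _maybe_rebuild(self):
        if _kernels.max_displacement(self.pos, self._ref_pos, self.box) > 0.5 * self.cfg.skin:
            self._build_pairs()

    def _wrap(self):
        mob = self.mob
        shift = np.floor(self.pos[mob] / self.box)
        self.pos[mob] -= shift * self.box
        self.images[mob] += shift.astype(np.int64)

    def _ou_update(self):
        noise = self.rng.standard_normal(self.vel.shape)
        add = self.sig_v * noise
        m = self.masses[self.mob]
        add[self.mob] -= np.sum(m * add[self.mob], axis=0) / np.sum(m)
        self.vel[self.mob] = (self.c1 * self.vel[self.mob]
                              + self.c2 * add[self.mob])

    def step(self):
        dt = self.cfg.dt
        mob = self.mob
        if self.cfg.variant == "baoab" or not self.cfg.thermostat:
            noise = (self.rng.standard_normal((len(self.pos), 3))
                     if self.cfg.thermostat else self._zero_noise)
            _kernels.baoab_first(self.pos, self.vel, self.forces, self.m_flat,
                                 mob, dt, self.c1, self.c2, self.sigv_flat,
                                 noise, self.box, self.images, True)
            self._maybe_rebuild()
            self.e_pot, self.forces = self.ff.compute(self.pos, self.pairs)
            if not np.all(np.isfinite(self.forces)):
                raise FloatingPointError("non-finite force encountered")
            _kernels.kick(self.vel, self.forces, self.m_flat, mob, 0.5 * dt)
        else:  # impulse ("kick") variant: velocity Verlet + end-of-step OU kick
            inv_m = 1.0 / self.masses
            self.vel[mob] += 0.5 * dt * (self.forces * inv_m)[mob]
            self.pos[mob] += dt * self.vel[mob]
            self._wrap()
            self._maybe_rebuild()
            self.e_pot, self.forces = self.ff.compute(self.pos, self.pairs)
            if not np.all(np.isfinite(self.forces)):
                raise FloatingPointError("non-finite force encountered")
            self.vel[mob] += 0.5 * dt * (self.forces * inv_m)[mob]
            self._ou_update()

    def kinetic_energy(self) -> float:
        return float(0.5 * np.sum(self.masses[self.mob] * self.vel[self.mob] ** 2))


def langevin_step(system: ParticleSystem, velocities: np.ndarray, forcefield,
                  cfg: MDConfig) -> tuple:
    """Single BAOAB update; returns (new system, new velocities, forces)."""
    it = _Integrator(system, forcefield, cfg, velocities)
    it.step()
    return system.with_positions(it.pos), it.vel, it.forces


def run_md(system: ParticleSystem, forcefield, cfg: MDConfig,
           velocities: np.ndarray = None) -> Trajectory:
    """Run MD and collect frames every ``cfg.save_every`` ps.

    The initial state (after optional equilibration) is frame 0; a request of
    0 steps therefore yields exactly the initial frame.  Fully reproducible
    for a fixed seed.
    """
    it = _Integrator(system, forcefield, cfg, velocities)
    n_equil = int(round(cfg.equilibration / cfg.dt))
    for k in range(n_equil):
        try:
            it.step()
        except FloatingPointError as err:
            raise FloatingPointError(f"{err} at equilibration step {k}") from None

    frames, imgs, times = [], [], []
    vels, frcs = [], []
    log = {k: [] for k in ("step", "time", "e_pot", "e_kin", "temperature")}

    def _save(step_idx: int):
        frames.append(it.pos.copy())
        imgs.append(it.images.copy())
        times.append(step_idx * cfg.dt)
        if cfg.save_velocities:
            vels.append(it.vel.copy())
        if cfg.save_forces:
            frcs.append(it.forces.copy())
        e_kin = it.kinetic_energy()
        log["step"].append(step_idx)
        log["time"].append(step_idx * cfg.dt)
        log["e_pot"].append(it.e_pot)
        log["e_kin"].append(e_kin)
        log["temperature"].append(instantaneous_temperature(it.system.with_positions(it.pos), it.vel)
                                  if it.mob.any() else 0.0)

    _save(0)
    stride = cfg.save_stride
    for k in range(1, cfg.n_steps + 1):
        try:
            it.step()
        except FloatingPointError as err:
            raise FloatingPointError(f"{err} at step {k}") from None
        except OverlapError as err:
            raise OverlapError(f"{err} at step {k}") from None
        if k % stride == 0:
            _save(k)

    template = it.system.with_positions(frames[0])
    return Trajectory(
        positions=np.array(frames), images=np.array(imgs), times=np.array(times),
        template=template,
        velocities=np.array(vels) if cfg.save_velocities else None,
        forces=np.array(frcs) if cfg.save_forces else None,
        log={k: np.array(v) for k, v in log.items()},
    )
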