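"""Particle systems, species parameters, and periodic-box geometry.

The central container is :class:`ParticleSystem`: positions, species labels,
charges, masses, an orthorhombic periodic box, plus two boolean masks that
encode the physics of the implicit-solvent model:

* ``mobile`` — frozen scaffold sites (the rigid DNA) are ``False`` and never
  move during MD;
* ``ml_visible`` — auxiliary zero-charge phosphate oxygens are ``False``:
  they interact through the Lennard-Jones prior but are invisible to the
  learned correction potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import N_AVOGADRO, NM3_TO_L


class InvalidBoxError(ValueError):
    """Raised for non-positive box edges or cutoffs exceeding half the box."""


class OverlapError(RuntimeError):
    """Raised when two particles come closer than the hard-core floor."""


class UnknownSpeciesError(KeyError):
    """Raised when a species label has no parameters / is not present."""


def _as_box(box) -> np.ndarray:
    box = np.asarray(box, dtype=float)
    if box.shape == ():
        box = np.full(3, float(box))
    if box.shape != (3,):
        raise InvalidBoxError(f"box must be a 3-vector of edge lengths, got shape {box.shape}")
    if not np.all(box > 0):
        raise InvalidBoxError(f"box edges must be positive, got {box}")
    return box


def minimum_image_displacement(r_i, r_j, box) -> np.ndarray:
    """Displacement ``r_j - r_i`` mapped into the half-open cube [-L/2, L/2).

    Works on single positions or (N, 3) arrays (broadcast).  Antisymmetric up
    to the boundary convention: components exactly at ±L/2 map to -L/2.
    """
    box = _as_box(box)
    d = np.asarray(r_j, dtype=float) - np.asarray(r_i, dtype=float)
    d -= box * np.floor(d / box + 0.5)
    return d


@dataclass
class ParticleSystem:
    """Snapshot of particle coordinates and static per-particle metadata."""

    positions: np.ndarray            # (N, 3) nm
    species: np.ndarray              # (N,) str labels, e.g. "Na", "Cl", "PH"
    charges: np.ndarray              # (N,) e
    masses: np.ndarray               # (N,) g/mol
    box: np.ndarray                  # (3,) nm, orthorhombic
    mobile: np.ndarray = None        # (N,) bool; False = frozen scaffold
    ml_visible: np.ndarray = None    # (N,) bool; False = hidden from the correction

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.species = np.asarray(self.species, dtype=object)
        self.charges = np.asarray(self.charges, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.box = _as_box(self.box)
        if self.mobile is None:
            self.mobile = np.ones(n, dtype=bool)
        self.mobile = np.asarray(self.mobile, dtype=bool)
        if self.ml_visible is None:
            self.ml_visible = np.ones(n, dtype=bool)
        self.ml_visible = np.asarray(self.ml_visible, dtype=bool)
        for name in ("species", "charges", "masses", "mobile", "ml_visible"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} has length {arr.shape}, expected ({n},)")

    # -- basic queries -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def indices_of(self, species: str) -> np.ndarray:
        return np.flatnonzero(self.species == species)

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            positions=self.positions.copy(),
            species=self.species.copy(),
            charges=self.charges.copy(),
            masses=self.masses.copy(),
            box=self.box.copy(),
            mobile=self.mobile.copy(),
            ml_visible=self.ml_visible.copy(),
        )

    def with_positions(self, positions: np.ndarray) -> "ParticleSystem":
        out = self.copy()
        out.positions = np.ascontiguousarray(positions, dtype=float).reshape(-1, 3)
        if len(out.positions) != len(self):
            raise ValueError("position array changes particle count")
        return out


def wrap_positions(system: ParticleSystem) -> ParticleSystem:
    """Return a copy with all coordinates wrapped into [0, L) per axis.

    Minimum-image pair distances are unchanged (pure lattice translation per
    particle).  Idempotent.
    """
    pos = system.positions - system.box * np.floor(system.positions / system.box)
    # floating subtlety: x = -1e-18 wraps to exactly L; fold such points to 0
    pos = np.where(pos >= system.box, pos - system.box, pos)
    return system.with_positions(pos)


def ionic_concentration(system: ParticleSystem, species: str) -> float:
    """Molar concentration (mol/L) of one species in the periodic box."""
    idx = system.indices_of(species)
    if len(idx) == 0 and species not in set(system.species.tolist()):
        raise UnknownSpeciesError(f"species {species!r} not present in system")
    volume_l = system.volume * NM3_TO_L
    return len(idx) / (N_AVOGADRO * volume_l)


# ---------------------------------------------------------------------------
# Species parameters and Lorentz-Berthelot mixing
# ---------------------------------------------------------------------------

#: Shipped per-species defaults: placeholder values assembled from common
#: monovalent-ion parameter sets (no optimized implicit-solvent LJ table is
#: publicly available), expected to be overridden from a force-field config
#: for production work.
DEFAULT_SPECIES = {
    #           sigma(nm)  eps(kJ/mol)  charge(e)  mass(g/mol)
    "Na": dict(sigma=0.2160, epsilon=1.4754, charge=+1.0, mass=22.990),
    "Cl": dict(sigma=0.4830, epsilon=0.0535, charge=-1.0, mass=35.453),
    # auxiliary phosphate oxygen: LJ-only site, charge fixed at 0
    "OX": dict(sigma=0.3166, epsilon=0.6502, charge=0.0, mass=15.999),
    # CG DNA site kinds (reconstruction; see cgmap)
    "PH": dict(sigma=0.4000, epsilon=0.8000, charge=-1.0, mass=94.970),
    "SU1": dict(sigma=0.3800, epsilon=0.5000, charge=0.0, mass=43.045),
    "SU2": dict(sigma=0.3800, epsilon=0.5000, charge=0.0, mass=57.057),
    "BA1": dict(sigma=0.3500, epsilon=0.5000, charge=0.0, mass=40.024),
    "BA2": dict(sigma=0.3500, epsilon=0.5000, charge=0.0, mass=40.0),
    "BA3": dict(sigma=0.3500, epsilon=0.5000, charge=0.0, mass=40.0),
}


@dataclass
class SpeciesParams:
    """Per-species LJ parameters with Lorentz-Berthelot cross terms.

    ``pair_overrides`` maps frozenset-like sorted tuples ``(a, b)`` to
    ``(sigma, epsilon)`` and takes precedence over mixing — the published
    pair table being unavailable, explicit overrides are first-class.
    """

    table: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SPECIES.items()})
    pair_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, p in self.table.items():
            if p["sigma"] <= 0:
                raise ValueError(f"sigma must be > 0 for species {name}")
            if p["epsilon"] < 0:
                raise ValueError(f"epsilon must be >= 0 for species {name}")
        self.pair_overrides = {tuple(sorted(k)): tuple(v) for k, v in self.pair_overrides.items()}

    def get(self, species: str) -> dict:
        try:
            return self.table[species]
        except KeyError:
            raise UnknownSpeciesError(f"no parameters for species {species!r}") from None

    def pair(self, a: str, b: str) -> tuple:
        """(sigma, epsilon) for the a-b pair: override if present, else LB."""
        key = tuple(sorted((a, b)))
        if key in self.pair_overrides:
            return self.pair_overrides[key]
        pa, pb = self.get(a), self.get(b)
        return (0.5 * (pa["sigma"] + pb["sigma"]),
                float(np.sqrt(pa["epsilon"] * pb["epsilon"])))

    def pair_matrices(self, species_order: list) -> tuple:
        """Dense (S, S) sigma and epsilon matrices for a species ordering."""
        s = len(species_order)
        sig = np.zeros((s, s))
        eps = np.zeros((s, s))
        for i, a in enumerate(species_order):
            for j, b in enumerate(species_order):
                sig[i, j], eps[i, j] = self.pair(a, b)
        return sig, eps


def make_system(positions, species, box, params: SpeciesParams = None,
                mobile=None, ml_visible=None, charges=None) -> ParticleSystem:
    """Convenience constructor filling charges/masses from a parameter table."""
    params = params or SpeciesParams()
    species = np.asarray(species, dtype=object)
    masses = np.array([params.get(s)["mass"] for s in species])
    if charges is None:
        charges = np.array([params.get(s)["charge"] for s in species])
    return ParticleSystem(positions=np.asarray(positions, float), species=species,
                          charges=np.asarray(charges, float), masses=masses,
                          box=box, mobile=mobile, ml_visible=ml_visible)
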