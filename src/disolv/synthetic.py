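"""Synthetic reference data: an analytic oracle force field and fixtures.

The all-atom explicit-solvent database that the implicit-solvent model is
meant to be trained on cannot be regenerated on a desk machine, so this
module replaces it with an analytic *oracle*: the physics prior (optionally
with "true" LJ parameters that differ from the model prior's) plus smooth
extra terms — per-species-pair sums of Gaussians and an optional angular
3-body term.  Because the oracle decomposes exactly as

    F_oracle = F_prior_true + F_extra,

delta-learning targets are known in closed form, which turns the otherwise
unreproducible reference pipeline into a controlled force-recovery test bed.

The shipped ``"ssip"`` preset shapes the Na-Cl extra term so that the pair
PMF develops a split solvent-separated feature with minima near 0.46 and
0.50 nm, mimicking the SSIP doublet seen in explicit-solvent NaCl data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .cgmap import (AllAtomStructure, CGScaffold, UnsupportedTerminusError,
                    default_templates)
from .md import MDConfig, run_md
from .prior import PriorConfig, PriorForceField, build_neighbor_list
from .system import ParticleSystem, SpeciesParams, make_system
from .training import LabeledConfiguration
from .units import N_AVOGADRO, NM3_TO_L

# ---------------------------------------------------------------------------
# Oracle force field
# ---------------------------------------------------------------------------


def oracle_true_params() -> SpeciesParams:
    """'True' ion LJ table of the oracle (deliberately off the model prior's)."""
    p = SpeciesParams()
    p.table["Na"] = dict(sigma=0.2250, epsilon=1.2000, charge=+1.0, mass=22.990)
    p.table["Cl"] = dict(sigma=0.4700, epsilon=0.0800, charge=-1.0, mass=35.453)
    return p


#: Gaussian extra terms (amplitude kJ/mol, center nm, width nm) per pair.
#: The Na-Cl wells at 0.46/0.50 nm create the SSIP doublet; their depths are
#: calibrated (outer well deeper) so that both features survive ionic
#: screening and remain resolved in g(r) at 1.0 mol/L, not only in the bare
#: pair potential.
SSIP_EXTRAS = {
    ("Na", "Cl"): [(-0.8, 0.38, 0.025), (-2.2, 0.46, 0.014), (-2.8, 0.50, 0.014)],
    ("Na", "Na"): [(-1.0, 0.37, 0.030)],
    ("Cl", "Cl"): [(-0.6, 0.52, 0.040)],
}


class OracleForceField:
    """Prior + analytic extra terms with an exact force decomposition."""

    def __init__(self, system: ParticleSystem, true_params: SpeciesParams = None,
                 prior_cfg: PriorConfig = None, extra_gaussians: dict = None,
                 r_cut_extra: float = 0.8, three_body: tuple = None):
        self.prior = PriorForceField(system, true_params or oracle_true_params(),
                                     prior_cfg)
        self.r_cut_extra = float(r_cut_extra)
        self.extra_gaussians = {tuple(k): [tuple(t) for t in v]
                                for k, v in (extra_gaussians or {}).items()}
        self.three_body = three_body        # (species, lambda kJ/mol, r3 nm) or None
        order = self.prior.species_order
        s = len(order)
        n_t = max([len(v) for v in self.extra_gaussians.values()] or [1])
        self._amp = np.zeros((s, s, n_t))
        self._r0 = np.ones((s, s, n_t))
        self._w = np.ones((s, s, n_t))
        lookup = {sp: k for k, sp in enumerate(order)}
        for (a, b), terms in self.extra_gaussians.items():
            if a not in lookup or b not in lookup:
                continue
            ia, ib = lookup[a], lookup[b]
            for t, (amp, r0, w) in enumerate(terms):
                for x, y in ((ia, ib), (ib, ia)):
                    self._amp[x, y, t] = amp
                    self._r0[x, y, t] = r0
                    self._w[x, y, t] = w
        self._tb_species = lookup.get(three_body[0], -1) if three_body else -1

    @property
    def cutoff(self) -> float:
        c = max(self.prior.cutoff, self.r_cut_extra)
        if self.three_body:
            c = max(c, self.three_body[2])
        return c

    def compute_extra(self, positions: np.ndarray, pairs: tuple) -> tuple:
        pi, pj = pairs
        forces = np.zeros_like(positions)
        e = _kernels.gaussian_pair(positions, self.prior.box, pi, pj,
                                   self.prior.sidx, self._amp, self._r0, self._w,
                                   self.r_cut_extra, forces)
        if self.three_body and self._tb_species >= 0:
            _, lam, r3 = self.three_body
            e += _kernels.three_body_angular(positions, self.prior.box, pi, pj,
                                             self.prior.sidx, self._tb_species,
                                             lam, r3, forces)
        return e, forces

    def compute(self, positions: np.ndarray, pairs: tuple) -> tuple:
        e1, f1 = self.prior.compute(positions, pairs)
        e2, f2 = self.compute_extra(positions, pairs)
        return e1 + e2, f1 + f2

    def extra_forces(self, system: ParticleSystem) -> np.ndarray:
        """Closed-form extra-term forces (the exact delta-learning target
        when the model prior shares the oracle's LJ table)."""
        nl = build_neighbor_list(system, self.cutoff)
        return self.compute_extra(system.positions, (nl.i, nl.j))[1]

    def forces(self, system: ParticleSystem) -> np.ndarray:
        nl = build_neighbor_list(system, self.cutoff)
        return self.compute(system.positions, (nl.i, nl.j))[1]

    def export_parameters(self) -> dict:
        """Full oracle parameterization, for dataset provenance files."""
        return {
            "true_lj": {s: dict(self.prior.params.table[s])
                        for s in self.prior.species_order
                        if s in self.prior.params.table},
            "prior_config": {
                "r_cut_lj": self.prior.config.r_cut_lj,
                "r_cut_coul": self.prior.config.r_cut_coul,
                "epsilon_r": self.prior.config.epsilon_r,
                "alpha": self.prior.config.alpha,
                "wolf_variant": self.prior.config.wolf_variant,
            },
            "extra_gaussians": {"-".join(k): [list(t) for t in v]
                                for k, v in self.extra_gaussians.items()},
            "r_cut_extra": self.r_cut_extra,
            "three_body": list(self.three_body) if self.three_body else None,
        }


def make_oracle(system: ParticleSystem, preset: str = "ssip",
                prior_cfg: PriorConfig = None) -> OracleForceField:
    """Shipped oracle presets: "ssip" (pair extras) and "ssip-3body"."""
    if preset == "ssip":
        return OracleForceField(system, prior_cfg=prior_cfg,
                                extra_gaussians=SSIP_EXTRAS)
    if preset == "ssip-3body":
        return OracleForceField(system, prior_cfg=prior_cfg,
                                extra_gaussians=SSIP_EXTRAS,
                                three_body=("Na", 2.0, 0.5))
    raise ValueError(f"unknown oracle preset {preset!r}")


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """Reproducible description of a synthetic labeled-data fixture.

    Defaults mirror the emulated reference protocol: concentrations in
    0.15-2.0 mol/L, configurations sampled every 1 ps at 300 K.  The number
    of configurations is desk-scaled (the emulated database has 8e4-3e5).
    """

    concentration: float = 1.0       # mol/L
    box: tuple = (4.2, 4.2, 4.2)     # nm
    seed: int = 0
    stride_ps: float = 1.0
    n_configs: int = 2000
    equilibration_ps: float = 10.0
    temperature: float = 300.0
    min_dist: float = 0.25           # packing floor, nm

    def ion_pairs(self) -> int:
        volume_l = float(np.prod(self.box)) * NM3_TO_L
        return int(round(self.concentration * N_AVOGADRO * volume_l))


class PackingError(RuntimeError):
    pass


def make_ionic_box(spec: FixtureSpec, scaffold: CGScaffold = None,
                   params: SpeciesParams = None) -> ParticleSystem:
    """Seeded rejection-sampled NaCl box, optionally around a frozen scaffold.

    Equal Na/Cl counts from the requested concentration; if the scaffold
    carries net charge -Q, Q extra Na counterions restore electroneutrality.
    """
    params = params or SpeciesParams()
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, float)
    n_pairs = spec.ion_pairs()
    n_counter = 0
    placed, species = [], []
    mobile, mlvis = [], []
    if scaffold is not None:
        center = 0.5 * box - np.mean(scaffold.positions, axis=0)
        center[2] = 0.0
        for k in range(len(scaffold)):
            placed.append(scaffold.positions[k] + center)
            species.append(scaffold.kinds[k])
            mobile.append(False)
            mlvis.append(bool(scaffold.ml_visible[k]))
        n_counter = int(round(-scaffold.net_charge))
        if n_counter < 0:
            raise ValueError("scaffold with positive net charge is unsupported")
    n_na, n_cl = n_pairs + n_counter, n_pairs

    coords = np.array(placed).reshape(-1, 3)
    min2 = spec.min_dist ** 2
    for sp, count in (("Na", n_na), ("Cl", n_cl)):
        for _ in range(count):
            for attempt in range(20000):
                trial = rng.random(3) * box
                if len(coords):
                    d = coords - trial
                    d -= box * np.floor(d / box + 0.5)
                    if np.min(np.einsum("ij,ij->i", d, d)) < min2:
                        continue
                coords = np.vstack([coords, trial])
                species.append(sp)
                mobile.append(True)
                mlvis.append(True)
                break
            else:
                raise PackingError(
                    f"could not place {sp} ion {_ + 1}/{count} after 20000 attempts")

    if scaffold is not None:
        sys_charges = np.concatenate([
            scaffold.charges,
            np.array([params.get(s)["charge"] for s in species[len(scaffold):]])])
        masses = np.concatenate([
            scaffold.masses,
            np.array([params.get(s)["mass"] for s in species[len(scaffold):]])])
        return ParticleSystem(positions=coords, species=np.array(species, dtype=object),
                              charges=sys_charges, masses=masses, box=box,
                              mobile=np.array(mobile), ml_visible=np.array(mlvis))
    return make_system(coords, species, box, params,
                       mobile=np.array(mobile), ml_visible=np.array(mlvis))


def generate_labeled_dataset(spec: FixtureSpec, oracle_preset: str = "ssip",
                             system: ParticleSystem = None,
                             oracle: OracleForceField = None,
                             scaffold: CGScaffold = None) -> list:
    """Run Langevin MD under the oracle and label sampled configurations.

    Configurations are saved every ``stride_ps`` after discarding the
    equilibration span; stored forces are the oracle's own re-evaluation at
    the stored coordinates (so a round-trip re-evaluation is bitwise equal).
    Returns a list of :class:`LabeledConfiguration`.
    """
    if spec.n_configs == 0:
        return []
    if system is None:
        system = make_ionic_box(spec, scaffold=scaffold)
    if oracle is None:
        oracle = make_oracle(system, oracle_preset)
    stride_steps = max(1, int(round(spec.stride_ps / 0.001)))
    cfg = MDConfig(dt=0.001, temperature=spec.temperature, tau=0.1,
                   n_steps=spec.n_configs * stride_steps,
                   save_every=spec.stride_ps, seed=spec.seed,
                   equilibration=spec.equilibration_ps)
    traj = run_md(system, oracle, cfg)
    configs = []
    meta = {"concentration": spec.concentration, "source": "oracle",
            "preset": oracle_preset}
    for k in range(1, len(traj)):
        snap = traj.frame(k)
        nl = build_neighbor_list(snap, oracle.cutoff)
        _, f = oracle.compute(snap.positions, (nl.i, nl.j))
        configs.append(LabeledConfiguration(system=snap, forces=f, index=k - 1,
                                            metadata=dict(meta, time_ps=traj.times[k])))
    return configs


# ---------------------------------------------------------------------------
# Scaffolds: helical polyion and idealized B-DNA
# ---------------------------------------------------------------------------

def make_helical_polyion(n_per_strand: int, pitch: float = 3.4,
                         radius: float = 0.9, box=None,
                         strand_offset_deg: float = 144.0) -> CGScaffold:
    """Frozen double-helical arrangement of -1 e sites, z-periodic.

    Stands in for the rigid DNA: two strands of ``n_per_strand`` sites each,
    z-spacing ``pitch / n_per_strand`` so the helix is commensurate with a
    box of z-edge equal to the pitch.
    """
    if box is not None and pitch > np.asarray(box, float)[2] + 1e-12:
        raise ValueError("pitch exceeds the box z-edge")
    dz = pitch / n_per_strand
    pos, kinds = [], []
    for strand in range(2):
        phase = math.radians(strand_offset_deg) * strand
        for k in range(n_per_strand):
            z = k * dz
            phi = 2.0 * math.pi * z / pitch + phase
            pos.append([radius * math.cos(phi), radius * math.sin(phi), z])
            kinds.append("PH")
    n = len(pos)
    return CGScaffold(positions=np.array(pos), kinds=np.array(kinds, dtype=object),
                      charges=np.full(n, -1.0), masses=np.full(n, 94.97),
                      ml_visible=np.ones(n, bool))


_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

# idealized cylindrical placement per CG group: (radius nm, angular offset deg,
# z offset nm).  Synthetic geometry: deterministic and helically plausible,
# not crystallographic.
_GROUP_LAYOUT = {
    0: (0.91, -28.0, -0.05),
    1: (0.82, -10.0, 0.03),
    2: (0.70, 4.0, -0.02),
    3: (0.52, 14.0, 0.00),
    4: (0.38, 22.0, 0.02),
    5: (0.22, 30.0, -0.01),
}


def build_ideal_bdna(sequence: str, periodic: bool = True, rise: float = 0.34,
                     twist_deg: float = 36.0) -> AllAtomStructure:
    """Idealized periodic B-form duplex for a given strand-A sequence.

    Geometry is a synthetic idealization: atoms are placed on helical arcs
    (backbone outside, base fragments stepping toward the axis) with the
    canonical 0.34 nm rise and 36 deg twist, so that a 10-bp duplex spans
    exactly one pitch.  Atom names/elements/counts follow the internal
    nucleotide templates exactly; only internal (phosphorylated) residues
    are supported, which requires ``periodic=True``.
    """
    sequence = sequence.upper()
    if not sequence or any(c not in _COMPLEMENT for c in sequence):
        raise ValueError(f"invalid DNA sequence {sequence!r}")
    if not periodic:
        raise UnsupportedTerminusError(
            "only periodic (all-internal) duplexes are supported: terminal "
            "residue templates are not shipped")
    templates = default_templates()
    names, elements, res_names, res_ids, chain_ids, coords = [], [], [], [], [], []

    def _place(res: str, bp_index: int, strand: int, res_id: int):
        t = templates[res]
        phi0 = math.radians(twist_deg) * bp_index + (math.radians(144.0) if strand else 0.0)
        z0 = rise * bp_index
        sign = 1.0 if strand == 0 else -1.0
        group_counter = {}
        for aname, elem, g in t.atoms:
            i_in_g = group_counter.get(g, 0)
            group_counter[g] = i_in_g + 1
            r_g, dphi_g, dz_g = _GROUP_LAYOUT[g]
            r = r_g + 0.02 * ((i_in_g % 3) - 1)
            phi = phi0 + sign * math.radians(dphi_g + 6.0 * i_in_g)
            z = z0 + sign * (dz_g + 0.015 * ((i_in_g % 2) - 0.5))
            coords.append([r * math.cos(phi), r * math.sin(phi), z])
            names.append(aname)
            elements.append(elem)
            res_names.append(res)
            res_ids.append(res_id)
            chain_ids.append("A" if strand == 0 else "B")

    n = len(sequence)
    for k, base in enumerate(sequence):
        _place("D" + base, k, 0, k + 1)
    for k, base in enumerate(sequence):
        # strand B runs antiparallel: its residue paired with A's k-th base
        _place("D" + _COMPLEMENT[base], k, 1, n - k)

    return AllAtomStructure(atom_names=np.array(names, dtype=object),
                            elements=np.array(elements, dtype=object),
                            res_names=np.array(res_names, dtype=object),
                            res_ids=np.array(res_ids, int),
                            chain_ids=np.array(chain_ids, dtype=object),
                            coords=np.array(coords))


def reverse_complement(sequence: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(sequence.upper()))
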