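"""Desk-scale study protocols: the end-to-end experiments of the toolkit.

These routines bundle the package's standard numerical experiments — the
oracle NaCl study (generate labeled data, delta-train the correction,
closure-test the structure), the integrator diagnostics, and the exact
counting checks — so that scripts and tests run the same protocol from a
single seed.

Problem sizes are desk-scale by design: 64 ions, ~1900 labeled
configurations (80/20 split), and closure MD runs of a few hundred ps,
against the emulated reference protocol's tens of thousands of
configurations and tens of ns.  docs/methods.md discusses what these scales
do and do not demonstrate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import radial_distribution, self_diffusion_einstein
from .cgmap import add_auxiliary_oxygens, count_atoms, map_to_cg
from .correction import CorrectionForceField, CorrectionModel, DescriptorConfig
from .md import CompositeForceField, MDConfig, ZeroForceField, init_velocities, run_md
from .prior import PriorForceField
from .synthetic import FixtureSpec, build_ideal_bdna, generate_labeled_dataset, \
    make_ionic_box, make_oracle
from .system import make_system
from .training import (TrainingOptions, correction_force_rmse,
                       make_delta_dataset, prior_baseline_rmse, split_dataset,
                       train_model)
from .units import KB, N_AVOGADRO, NM3_TO_L

#: study conditions for the oracle NaCl benchmark
STUDY_CONCENTRATION = 1.0          # mol/L
STUDY_N_PAIRS = 32                 # 64 ions total
STUDY_N_CONFIGS = 1900             # ~1520 train / ~380 val after 80/20
STUDY_STRIDE_PS = 1.0
STUDY_EQUILIBRATION_PS = 10.0
CLOSURE_T_PS = 500.0               # per closure replica
CLOSURE_REPLICAS = 3               # independent replicas per force field
CLOSURE_SAVE_PS = 0.1


def study_box_edge(n_pairs: int = STUDY_N_PAIRS,
                   concentration: float = STUDY_CONCENTRATION) -> float:
    """Cubic edge (nm) holding ``n_pairs`` NaCl pairs at a concentration."""
    volume = n_pairs / (concentration * N_AVOGADRO * NM3_TO_L)
    return float(volume ** (1.0 / 3.0))


def study_fixture(seed: int, concentration: float = STUDY_CONCENTRATION,
                  n_configs: int = STUDY_N_CONFIGS) -> FixtureSpec:
    edge = study_box_edge(STUDY_N_PAIRS, concentration)
    return FixtureSpec(concentration=concentration, box=(edge, edge, edge),
                       seed=seed, stride_ps=STUDY_STRIDE_PS,
                       n_configs=n_configs,
                       equilibration_ps=STUDY_EQUILIBRATION_PS)


def study_training_options(seed: int) -> TrainingOptions:
    return TrainingOptions(epochs=100, batch_size=32, learning_rate=3e-3,
                           lr_schedule="cosine", seed=seed, patience=0)


@dataclass
class NaClStudy:
    """Everything produced by the oracle NaCl delta-learning study."""

    spec: FixtureSpec
    system: object
    oracle: object
    dataset: object
    model: CorrectionModel
    history: dict
    val_rmse: float
    baseline_rmse: float

    @property
    def rmse_ratio(self) -> float:
        return self.val_rmse / self.baseline_rmse


def run_nacl_study(seed: int, n_configs: int = STUDY_N_CONFIGS) -> NaClStudy:
    """Generate the oracle dataset, split 80/20, and train the correction."""
    spec = study_fixture(seed, n_configs=n_configs)
    system = make_ionic_box(spec)
    oracle = make_oracle(system, "ssip")
    configs = generate_labeled_dataset(spec, system=system, oracle=oracle)
    dataset = split_dataset(make_delta_dataset(configs), seed=seed)
    model = CorrectionModel(["Na", "Cl"], DescriptorConfig(), hidden=32,
                            seed=seed)
    result = train_model(model, dataset, study_training_options(seed))
    return NaClStudy(spec=spec, system=system, oracle=oracle, dataset=dataset,
                     model=model, history=result.history,
                     val_rmse=correction_force_rmse(model, dataset, "val"),
                     baseline_rmse=prior_baseline_rmse(dataset, "val"))


# ---------------------------------------------------------------------------
# Structural closure
# ---------------------------------------------------------------------------

def detect_ssip_doublet(rdf, window=(0.42, 0.54), smooth: int = 3) -> list:
    """Positions of local maxima of g(r) inside the SSIP window.

    A light boxcar smoothing (``smooth`` bins) suppresses single-bin noise
    before extrema detection.
    """
    g = np.convolve(rdf.g, np.ones(smooth) / smooth, mode="same")
    r = rdf.r
    peaks = []
    for k in range(1, len(g) - 1):
        if window[0] <= r[k] <= window[1] and g[k] > g[k - 1] and g[k] >= g[k + 1]:
            peaks.append(float(r[k]))
    return peaks


@dataclass
class ClosureResult:
    rdf_oracle: object
    rdf_model: object
    max_abs_dg: float
    peak_offset_bins: int
    oracle_ssip_peaks: list
    model_ssip_peaks: list


def run_closure(study: NaClStudy, seed: int, t_ps: float = CLOSURE_T_PS,
                n_replicas: int = CLOSURE_REPLICAS) -> ClosureResult:
    """MD under the oracle vs under prior+trained correction; compare RDFs.

    Each force field is sampled with ``n_replicas`` independent replicas
    (fresh velocities and thermostat streams) whose RDFs are averaged: at 64
    ions the ion-association number is a slow collective variable, and
    replica averaging suppresses its run-to-run scatter far more effectively
    than one long trajectory.
    """
    n_steps = int(round(t_ps / 0.001))
    ff = CompositeForceField(PriorForceField(study.system),
                             CorrectionForceField(study.model, study.system))

    def _mean_rdf(field, seed0):
        gs = None
        for k in range(n_replicas):
            cfg = MDConfig(n_steps=n_steps, save_every=CLOSURE_SAVE_PS,
                           seed=seed0 + 1000 * k, equilibration=20.0)
            traj = run_md(study.system, field, cfg)
            g = radial_distribution(traj, "Na", "Cl", bin_width=0.01)
            gs = g.g if gs is None else gs + g.g
        g.g = gs / n_replicas
        return g

    g_o = _mean_rdf(study.oracle, seed + 101)
    g_m = _mean_rdf(ff, seed + 202)
    peak_o = int(np.argmax(g_o.g))
    peak_m = int(np.argmax(g_m.g))
    return ClosureResult(
        rdf_oracle=g_o, rdf_model=g_m,
        max_abs_dg=float(np.max(np.abs(g_o.g - g_m.g))),
        peak_offset_bins=abs(peak_o - peak_m),
        oracle_ssip_peaks=detect_ssip_doublet(g_o),
        model_ssip_peaks=detect_ssip_doublet(g_m))


# ---------------------------------------------------------------------------
# Transferability
# ---------------------------------------------------------------------------

def run_transferability(study: NaClStudy, seed: int,
                        concentrations=(0.5, 2.0), n_configs: int = 150) -> dict:
    """Evaluate the trained model's force RMSE at other concentrations.

    Mirrors the train-at-one-concentration / test-at-others protocol; the
    deliverable is the reported degradation, not a numerical target.
    """
    out = {}
    for c in concentrations:
        spec = study_fixture(seed + int(100 * c), concentration=c,
                             n_configs=n_configs)
        system = make_ionic_box(spec)
        oracle = make_oracle(system, "ssip")
        configs = generate_labeled_dataset(spec, system=system, oracle=oracle)
        ds = make_delta_dataset(configs)
        ds.train_idx = np.arange(0)
        ds.val_idx = np.arange(len(ds))
        out[c] = {
            "rmse": correction_force_rmse(study.model, ds, "val"),
            "baseline": prior_baseline_rmse(ds, "val"),
        }
        out[c]["ratio"] = out[c]["rmse"] / out[c]["baseline"]
    return out


# ---------------------------------------------------------------------------
# Integrator diagnostics
# ---------------------------------------------------------------------------

def nve_energy_drift(seed: int, n_steps: int = 10_000) -> float:
    """|dE|/|E| for a 64-ion NVE run under the prior after equilibration."""
    spec = study_fixture(seed, n_configs=0)
    system = make_ionic_box(spec)
    ff = PriorForceField(system)
    warm = run_md(system, ff, MDConfig(n_steps=2000, save_every=2.0, seed=seed))
    s_eq = warm.frame(-1)
    v = init_velocities(s_eq, 300.0, seed + 1)
    traj = run_md(s_eq, ff, MDConfig(n_steps=n_steps, save_every=0.05,
                                     thermostat=False, seed=seed),
                  velocities=v)
    e = traj.log["e_pot"] + traj.log["e_kin"]
    return float(np.max(np.abs(e - e[0])) / abs(e[0]))


def nvt_mean_temperature(seed: int, t_ps: float = 100.0) -> float:
    """Time-mean kinetic temperature of a thermostatted 200-ion prior run."""
    edge = study_box_edge(100)
    spec = FixtureSpec(concentration=STUDY_CONCENTRATION,
                       box=(edge, edge, edge), seed=seed)
    system = make_ionic_box(spec)
    cfg = MDConfig(n_steps=int(t_ps / 0.001), save_every=0.1, seed=seed,
                   equilibration=5.0)
    traj = run_md(system, PriorForceField(system), cfg)
    return float(np.mean(traj.log["temperature"]))


def langevin_free_diffusion_ratio(seed: int, n_particles: int = 512,
                                  t_ps: float = 40.0) -> float:
    """Free-particle Langevin diffusion over the k_B*T*tau/m prediction."""
    rng = np.random.default_rng(seed)
    box = np.full(3, 50.0)
    system = make_system(rng.random((n_particles, 3)) * box,
                         ["Na"] * n_particles, box)
    cfg = MDConfig(n_steps=int(t_ps / 0.001), save_every=0.1, seed=seed)
    traj = run_md(system, ZeroForceField(), cfg)
    res = self_diffusion_einstein(traj, "Na", fit_window=(0.2, 0.8))
    d_pred = KB * cfg.temperature * cfg.tau / system.masses[0]
    return float(res.D / d_pred)


# ---------------------------------------------------------------------------
# Exact counting checks
# ---------------------------------------------------------------------------

def dna_counting_checks(sequence: str = "CTCTCGAGAG") -> dict:
    """Atom and CG-site counts of the periodic duplex."""
    structure = build_ideal_bdna(sequence, periodic=True)
    scaffold = map_to_cg(structure)
    full = add_auxiliary_oxygens(scaffold, structure)
    return {
        "n_atoms": count_atoms(structure),
        "n_ml_visible_sites": scaffold.n_ml_visible,
        "n_auxiliary_oxygens": len(full) - len(scaffold),
        "net_scaffold_charge": scaffold.net_charge,
    }
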