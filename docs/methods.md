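# Methods

`disolv` implements a deep-implicit-solvation (DIS) workflow for ionic
solutions around rigid DNA: water is coarse-grained away and its mean-field
effect on the ions is carried by a two-part potential of mean force (PMF),

    U = U_prior + U_corr,

where `U_prior` is fixed physics (excluded volume + screened electrostatics)
and `U_corr` is a local, trainable many-body correction fitted to reference
ion forces by delta learning.  This note records the model, its parameters,
the numerical choices, and what the synthetic test bed does and does not
demonstrate.

## Units

Internal units are nm, kJ/mol, ps, g/mol and elementary charge; with these,
1 (g/mol)(nm/ps)^2 = 1 kJ/mol, so no conversion factors appear in the
dynamics.  Angstrom and SI diffusion units appear only at I/O boundaries.

## The physics prior

* **Dispersion/excluded volume** — 12-6 Lennard-Jones, cutoff 0.9 nm,
  energy-shifted to zero at the cutoff (a `lj_shift=False` flag restores
  plain truncation).  Cross-species parameters follow Lorentz–Berthelot
  mixing unless an explicit pair override is configured; the shipped
  per-species table is a placeholder assembled from common monovalent-ion
  parameter sets and is expected to be overridden for production use.
* **Electrostatics** — Coulomb interaction under the Wolf summation with a
  relative dielectric constant of 95 (the measured dielectric constant of
  TIP3P water, standing in for the coarse-grained solvent), cutoff 1.2 nm.
  The default variant is damped-shifted-force (DSF): pair energy and force
  both vanish continuously at the cutoff, so MD sees no cutoff impulse.
  The damping parameter defaults to alpha = 2.0 nm^-1; at alpha*Rc = 2.4-3
  and Rc >= 6 nearest-neighbor distances the DSF energy of rock-salt NaCl
  matches the exact Madelung energy to well under 1 % (verified in the test
  suite against an Evjen neutralized-shell lattice sum).  Neither the exact
  Wolf variant nor alpha is fixed by the emulated protocol, so both are
  configuration, not constants.
* Auxiliary phosphate oxygens carry charge exactly 0 and interact through
  LJ only; a hard-core floor of 1e-4 nm raises an error instead of
  returning infinities, because labeled data should never contain overlaps.

## The correction potential

A strictly local invariant-descriptor model replaces the equivariant
network of large-scale DIS implementations while preserving its contract:
cutoff-limited locality, force training, delta learning on the prior, and
exclusion of ML-invisible sites.

* **Descriptors** (cutoff 0.9 nm, smooth envelope `(1-(r/rc)^2)^2` with
  value and slope zero at the cutoff):
  * radial: per neighbor species, 64 Gaussians on a uniform grid in r with
    width equal to the grid spacing (~0.014 nm).  The high radial
    resolution is deliberate: the solvent-separated Na-Cl doublet at
    0.46/0.50 nm is only 0.04 nm wide, and a correction built from ~8
    coarse basis functions cannot represent it.
  * angular: per unordered neighbor-species pair, four 3-body invariants
    `2^(1-z) (1 + l cos t)^z exp(-eta(rij^2+rik^2)) fc(rij) fc(rik)` with
    (z, l) in {(1,±1), (4,±1)} and eta = 2/rc^2.  A pair-only mode exists
    for ablation.
* **Head** — per-species: standardized features feed one tanh hidden layer
  (32 units) *plus a linear skip term*.  The skip term can represent any
  pair-additive correction exactly (it is a radial-basis expansion of a
  pair potential), which is where most of an ionic solvation PMF lives;
  the hidden layer adds many-body flexibility.  With `hidden=0` the model
  is purely linear and force matching becomes ordinary least squares,
  solved in closed form by `fit_linear_model`.
* Forces are exact analytic gradients (chain rule through descriptors);
  energy-force consistency is enforced by finite-difference tests at
  rel. error < 1e-5.  Particles with `ml_visible=False` neither appear in
  any descriptor nor receive correction forces.

## Training

Targets are force residuals `dF = F_ref - F_prior` on the mobile,
ML-visible subset, with the prior evaluated at exactly the MD cutoffs.  The
loss is the mean squared force deviation over configurations, ions and
Cartesian components (a `reduction="sum"` flag preserves the plain summed
form; the mean makes the scale independent of dataset size).  Datasets are
split 80/20 with a seeded permutation.  Optimization is Adam (default
pytorch-style hyperparameters) over whole-configuration mini-batches of 32,
100 epochs, with a cosine learning-rate decay from 3e-3; the returned model
carries the best-validation-loss parameters.  Early stopping is available
but off by default (with a cosine schedule the final epochs are the
fine-tuning phase).  Everything is reproducible from the seeds (data order,
initialization, optimizer state).

Two safeguards protect MD stability in regions the training data never
visits: descriptor channels with zero variance over the training set are
*pruned* (their head weights zeroed — they receive no force-matching
gradient, so randomly initialized weights would otherwise survive training
and fire arbitrarily when such a channel first activates during MD, e.g.
deep in the repulsive core), and the feature scale is floored at 1e-3 of
the largest per-species feature standard deviation so rarely-active
channels are not amplified thousandsfold by standardization.

## MD engine

Langevin dynamics by BAOAB splitting: half-kick, half-drift, exact
Ornstein-Uhlenbeck velocity update with `exp(-dt/tau)` decay and matching
noise variance, half-drift, half-kick.  Defaults: 1 fs timestep, 300 K,
coupling time 0.1 ps, frames saved every 1 ps.  BAOAB reduces exactly to
velocity Verlet as the friction vanishes, which is also the thermostat-off
(NVE) path; an impulse-style "kick" variant is retained behind a flag.
The thermostat acts only on mobile particles, and the mass-weighted
center-of-mass component of the noise is projected out each step, so the
net momentum of the mobile set stays exactly zero and the kinetic
temperature convention `T = 2 KE / (k_B (3N-3))` is unbiased even for
small N.  Frozen scaffolds are never touched: their coordinates are
bit-identical across frames.  Neighbor lists use a 0.2 nm skin with
displacement-triggered rebuilds; correctness is guaranteed by a superset
property and verified against brute-force enumeration.  Unwrapping for
diffusion uses integer image counters maintained during integration.

## CG DNA mapping

Each nucleotide maps to six CG sites at the centers of mass of fixed atom
groups: phosphate (P, OP1, OP2, O5'), two sugar fragments, and three base
fragments.  The exact published six-site partition is not reprinted
anywhere accessible, so the shipped partition is a reconstruction in the
same spirit, stored as editable template data (YAML-exportable), not code.
Internal (phosphorylated) residues only: this is what makes the counts of
a periodic duplex well defined — the 10-bp CTCTCGAGAG duplex has exactly
634 atoms and 120 ML-visible CG sites, plus 40 auxiliary oxygens.  CG
charges default to -1 e on the phosphate site and 0 elsewhere.  The
built-in B-form builder places atoms on helical arcs with the canonical
0.34 nm rise and 36 degree twist; its geometry is an idealized synthetic
construction (correct atom names, counts, connectivity ordering and
helical topology; not crystallographic coordinates).

## Synthetic reference data (what the oracle is and is not)

The emulated all-atom database cannot be regenerated on a desk machine, so
reference forces come from an analytic *oracle*: the prior with a "true"
LJ table deliberately different from the model prior's, plus per-pair sums
of Gaussians under a smooth cutoff, plus an optional Stillinger-Weber-like
3-body term among cations.  Because `F_oracle = F_prior_true + F_extra`
exactly, delta targets are known in closed form and the whole pipeline
becomes a controlled force-recovery experiment.

The `"ssip"` preset places Gaussian wells on the Na-Cl pair at 0.46 and
0.50 nm so that the pair PMF has two local minima there, mimicking the
solvent-separated ion-pair doublet of explicit-solvent NaCl; well depths
and widths were calibrated once so that the doublet is actually resolved
in the oracle's own g(r) at 1.0 mol/L (a doublet that only exists in the
bare pair potential but is washed out by ionic screening would make the
preset useless as a structural target).  The default preset is pair-only;
`"ssip-3body"` adds the angular term and is exercised in the unit tests.

What passing on this test bed shows: that the estimator chain —
force matching on deltas, the descriptor model, the integrator, and the
analysis operators — recovers a known many-body PMF and its equilibrium
structure at matched conditions.  What it does not show: transferability
of any shipped parameters to real electrolytes, water-mediated dynamics
(the oracle has no hydrodynamic memory), or accuracy of the idealized DNA
geometry.

## Desk-scale study conditions

The standard study (shared by the acceptance tests and
`scripts/acceptance.py`) uses 64 ions (32 NaCl pairs) at 1.0 mol/L in a
~3.76 nm cubic box; 1900 labeled configurations sampled every 1 ps after
10 ps equilibration (vs 8e4-3e5 configurations in the emulated database);
training as above; and a structural-closure comparison of 3 independent
replicas x 500 ps per force field (frames every 0.1 ps), whose RDFs are
averaged.  Replica averaging matters: at 64 ions the ion-association
number is a slow collective variable, so single few-hundred-ps
trajectories show run-to-run RDF scatter at the first peak comparable to
the closure tolerance itself, while averages over independent replicas
(fresh velocities and noise streams) suppress it well below that level.
Transferability is probed by evaluating the 1.0 mol/L model on
150-configuration datasets at 0.5 and 2.0 mol/L.

## Numerical conventions worth knowing

* Minimum image uses the half-open interval [-L/2, L/2); cutoffs must not
  exceed half the smallest box edge (enforced at construction).
* RDF: ordered-pair histogram, ideal density `(N_B - delta_AB)/V`, default
  bin 0.01 nm.  Coordination numbers by trapezoid on the RDF bins.
* Cylindrical NDPs normalize by the species' mean density inside the
  analyzed cylinder (box-mean convention; the bulk-plateau alternative
  differs only by a constant factor when the far field is homogeneous).
* Occupancy grids: 0.05 nm voxels, counts normalized by frames x
  particles so the grid sums to exactly 1.
* Residence times: an event is a maximal occupied interval after closing
  vacancy gaps of duration <= 1 ps (equality closes; k vacant samples
  count as a k-stride vacancy); single-frame events get one frame stride.
  Both the mean and the standard deviation of event durations are
  reported, since summary conventions differ between studies.
* Einstein diffusion: MSD over ions and time origins, least-squares slope
  on the 10-50 % window of the span by default; the log-log exponent over
  the window is reported and flags non-diffusive (e.g. ballistic) regimes.
* Wolf self-term and LJ energy shifts are constants: they matter for NVE
  bookkeeping, never for forces.

## Known limitations

* The correction model predicts scalar atomic energies from invariants;
  it cannot express properties requiring equivariant outputs.
* One environment per particle (no message passing): interactions beyond
  0.9 nm are carried entirely by the prior.
* Orthorhombic boxes, NVT/NVE only; no barostat.
* DNA is rigid by design; flexible scaffolds and sequence transferability
  are out of scope.
* The Adam path does not reach the closed-form optimum of rank-deficient
  linear problems in finite time; use `fit_linear_model` for pure linear
  heads.
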