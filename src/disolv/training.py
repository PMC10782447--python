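"""Delta-learning: datasets of reference ion forces and force matching.

The correction potential is trained on force residuals
``dF = F_ref - F_prior`` evaluated on the mobile, ML-visible subset of each
labeled configuration, with the prior evaluated at exactly the coordinates
and cutoffs MD will use.  The loss is the force-matching objective

    L = (1/N_ifk) sum_i sum_j sum_k (F_model,ijk - dF_ijk)^2

over configurations i, ions j and Cartesian directions k, with a
``reduction="sum"`` flag preserving the plain summed form.  Optimization is
mini-batch Adam where a batch is a set of whole configurations (all ions of
a configuration share an environment and are evaluated together); the model
returned carries the best-validation-loss parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correction import CorrectionModel
from .prior import PriorConfig, PriorForceField, build_neighbor_list
from .system import OverlapError, ParticleSystem, SpeciesParams


@dataclass
class LabeledConfiguration:
    """A system snapshot plus reference forces on the mobile ML-visible ions.

    ``forces`` is (N, 3); only rows of the target subset (mobile and
    ML-visible) are meaningful and must be finite.
    """

    system: ParticleSystem
    forces: np.ndarray
    index: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.forces = np.asarray(self.forces, float).reshape(len(self.system), 3)
        if not np.all(np.isfinite(self.forces[self.target_mask])):
            raise ValueError(f"non-finite reference forces in configuration {self.index}")

    @property
    def target_mask(self) -> np.ndarray:
        return self.system.mobile & self.system.ml_visible


@dataclass
class DeltaDataset:
    """Configurations with delta-force targets and a train/val partition."""

    configs: list
    delta_forces: list                  # per config (N, 3), zero off-target
    train_idx: np.ndarray = None
    val_idx: np.ndarray = None
    split_seed: int = None

    def __len__(self) -> int:
        return len(self.configs)

    @property
    def is_split(self) -> bool:
        return self.train_idx is not None

    def subset_indices(self, subset: str) -> np.ndarray:
        if subset == "all":
            return np.arange(len(self))
        if not self.is_split:
            raise ValueError("dataset has not been split")
        return {"train": self.train_idx, "val": self.val_idx}[subset]

    @staticmethod
    def concat(datasets: list) -> "DeltaDataset":
        """Pooled multi-concentration dataset (metadata retained per config)."""
        configs, deltas = [], []
        for ds in datasets:
            configs.extend(ds.configs)
            deltas.extend(ds.delta_forces)
        return DeltaDataset(configs=configs, delta_forces=deltas)


def make_delta_dataset(configs, params: SpeciesParams = None,
                       prior_cfg: PriorConfig = None) -> DeltaDataset:
    """Subtract prior forces from reference forces on the target subset."""
    deltas = []
    ff = None
    for c in configs:
        try:
            ff = PriorForceField(c.system, params, prior_cfg)
            nl = build_neighbor_list(c.system, ff.cutoff)
            _, f_prior = ff.compute(c.system.positions, (nl.i, nl.j))
        except OverlapError as err:
            raise OverlapError(f"configuration {c.index}: {err}") from None
        mask = c.target_mask
        d = np.zeros_like(c.forces)
        d[mask] = c.forces[mask] - f_prior[mask]
        deltas.append(d)
    return DeltaDataset(configs=list(configs), delta_forces=deltas)


def split_dataset(dataset: DeltaDataset, fraction: float = 0.8,
                  seed: int = 0) -> DeltaDataset:
    """Random reproducible train/validation partition (default 80/20)."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 configurations to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = min(n - 1, max(1, int(round(fraction * n))))
    dataset.train_idx = np.sort(perm[:n_train])
    dataset.val_idx = np.sort(perm[n_train:])
    dataset.split_seed = seed
    return dataset


def force_matching_loss(predicted: np.ndarray, target: np.ndarray,
                        reduction: str = "mean") -> float:
    """Squared force deviation, averaged (default) or summed over i, j, k."""
    predicted = np.asarray(predicted, float)
    target = np.asarray(target, float)
    if predicted.shape != target.shape:
        raise ValueError(f"shape mismatch {predicted.shape} vs {target.shape}")
    sq = (predicted - target) ** 2
    return float(sq.sum() if reduction == "sum" else sq.mean())


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

@dataclass
class TrainingOptions:
    epochs: int = 150
    batch_size: int = 16            # configurations per Adam step
    learning_rate: float = 3e-3
    lr_schedule: str = "cosine"     # "cosine" (decay to ~0) | "constant"
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0
    patience: int = 25              # early stopping on validation loss
    reduction: str = "mean"
    standardize_features: bool = True


@dataclass
class TrainingResult:
    model: CorrectionModel
    history: dict                   # epoch, train_loss, val_loss
    best_epoch: int
    best_val_loss: float
    aborted: bool = False


class _ConfigCache:
    """Per-configuration precomputation reused across epochs."""

    def __init__(self, model: CorrectionModel, config: LabeledConfiguration,
                 delta: np.ndarray):
        self.system = config.system
        self.pairs = model._pairs(config.system)
        self.svoc = model.species_index(config.system)
        self.csr = model._csr(config.system, self.pairs)
        self.d = model._kernel(config.system, self.pairs, mode=0,
                               csr=self.csr, svoc=self.svoc)[0]
        self.mask = config.target_mask
        self.n_comp = 3 * int(self.mask.sum())
        self.delta = delta


def _model_forces_cached(model: CorrectionModel, cc: _ConfigCache):
    e_at, g, cache = model._forward(cc.d, cc.svoc)
    _, grad, _ = model._kernel(cc.system, cc.pairs, mode=1, g=g,
                               csr=cc.csr, svoc=cc.svoc)
    return -grad, cache


def _param_grads(model: CorrectionModel, cc: _ConfigCache, cache: dict,
                 dldf: np.ndarray) -> dict:
    """Analytic dL/dtheta given dL/dF for one configuration."""
    _, _, v = model._kernel(cc.system, cc.pairs, mode=2, R=dldf,
                            csr=cc.csr, svoc=cc.svoc)
    grads = {}
    for s, (rows, dstd, h, hp) in cache.items():
        q = -v[rows] / model.feat_scale[s]     # dL/d g_std per atom
        p = model.params[s]
        if model.hidden > 0:
            smat = q @ p["W1"].T               # (atoms, H)
            hpp = -2.0 * h * hp
            grads[s] = {
                "W1": p["w2"][:, None] * (hp.T @ q + (smat * hpp).T @ dstd),
                "b1": np.sum(smat * p["w2"] * hpp, axis=0),
                "w2": np.sum(hp * smat, axis=0),
                "b2": np.zeros(1),
                "w": q.sum(axis=0),
            }
        else:
            grads[s] = {"w": q.sum(axis=0), "b": np.zeros(1)}
    return grads


def _flat_grads(model: CorrectionModel, grads_acc: dict) -> np.ndarray:
    parts = []
    for s in model.species:
        for k in sorted(model.params[s]):
            if s in grads_acc:
                parts.append(grads_acc[s][k].ravel())
            else:
                parts.append(np.zeros(model.params[s][k].size))
    return np.concatenate(parts)


def _epoch_loss(model: CorrectionModel, caches: list, idx, reduction: str) -> float:
    total, count = 0.0, 0
    for k in idx:
        cc = caches[k]
        f_model, _ = _model_forces_cached(model, cc)
        r = f_model[cc.mask] - cc.delta[cc.mask]
        total += float(np.sum(r * r))
        count += cc.n_comp
    return total if reduction == "sum" else total / max(count, 1)


def train_model(model: CorrectionModel, data: DeltaDataset,
                opts: TrainingOptions = None) -> TrainingResult:
    """Force-matching optimization with Adam; returns best-validation model.

    Fully reproducible for fixed seeds (data order, init, optimizer state).
    Divergence (non-finite loss) aborts, reporting the last finite state.
    """
    opts = opts or TrainingOptions()
    if not data.is_split:
        raise ValueError("dataset must be split before training")
    train_idx = list(data.subset_indices("train"))
    val_idx = list(data.subset_indices("val"))
    if not train_idx:
        raise ValueError("empty training partition")

    caches = [_ConfigCache(model, c, d) for c, d in zip(data.configs, data.delta_forces)]

    if opts.standardize_features:
        # Standardize per species over the training set.  Two safeguards for
        # regions the data never visits: features with (near-)zero variance
        # are pruned (their head weights zeroed — they receive no gradient,
        # so random init would otherwise survive and fire out-of-distribution
        # during MD), and the scale is floored at 1e-3 of the largest feature
        # std so that rarely-active features are not amplified thousandsfold.
        mean, scale = {}, {}
        for si, s in enumerate(model.species):
            rows = [caches[k].d[caches[k].svoc == si] for k in train_idx]
            stacked = np.concatenate([r for r in rows if len(r)], axis=0) \
                if any(len(r) for r in rows) else np.zeros((1, model.n_feat))
            mean[s] = stacked.mean(axis=0)
            raw_std = stacked.std(axis=0)
            dead = raw_std <= 1e-12
            mean[s][dead] = 0.0
            if model.hidden > 0:
                model.params[s]["W1"][:, dead] = 0.0
            model.params[s]["w"][dead] = 0.0
            floor = 1e-3 * max(float(raw_std.max()), 1e-12)
            scale[s] = np.maximum(raw_std, floor)
        model.set_feature_scaling(mean, scale)

    rng = np.random.default_rng(opts.seed)
    theta = model.get_flat()
    m_adam = np.zeros_like(theta)
    v_adam = np.zeros_like(theta)
    t_adam = 0

    history = {"epoch": [], "train_loss": [], "val_loss": []}
    val0 = _epoch_loss(model, caches, val_idx, opts.reduction)
    best_val, best_theta, best_epoch = val0, theta.copy(), 0
    history["epoch"].append(0)
    history["train_loss"].append(_epoch_loss(model, caches, train_idx, opts.reduction))
    history["val_loss"].append(val0)

    aborted = False
    since_best = 0
    for epoch in range(1, opts.epochs + 1):
        if opts.lr_schedule == "cosine":
            lr = opts.learning_rate * 0.5 * (
                1.0 + np.cos(np.pi * (epoch - 1) / max(opts.epochs - 1, 1)))
        else:
            lr = opts.learning_rate
        order = rng.permutation(len(train_idx))
        run_sq, run_comp = 0.0, 0
        for start in range(0, len(order), opts.batch_size):
            batch = [train_idx[k] for k in order[start:start + opts.batch_size]]
            grads_flat = np.zeros_like(theta)
            n_comp = sum(caches[k].n_comp for k in batch)
            norm = 1.0 if opts.reduction == "sum" else 1.0 / max(n_comp, 1)
            for k in batch:
                cc = caches[k]
                f_model, cache = _model_forces_cached(model, cc)
                resid = f_model[cc.mask] - cc.delta[cc.mask]
                run_sq += float(np.sum(resid * resid))
                run_comp += cc.n_comp
                dldf = np.zeros_like(f_model)
                dldf[cc.mask] = 2.0 * norm * resid
                grads_flat += _flat_grads(model, _param_grads(model, cc, cache, dldf))
            t_adam += 1
            m_adam = opts.beta1 * m_adam + (1 - opts.beta1) * grads_flat
            v_adam = opts.beta2 * v_adam + (1 - opts.beta2) * grads_flat ** 2
            mhat = m_adam / (1 - opts.beta1 ** t_adam)
            vhat = v_adam / (1 - opts.beta2 ** t_adam)
            theta = theta - lr * mhat / (np.sqrt(vhat) + opts.adam_eps)
            model.set_flat(theta)

        # running training loss (evaluated as the epoch progressed)
        train_loss = run_sq if opts.reduction == "sum" else run_sq / max(run_comp, 1)
        val_loss = _epoch_loss(model, caches, val_idx, opts.reduction) if val_idx else train_loss
        if not np.isfinite(train_loss):
            aborted = True
            break
        history["epoch"].append(epoch)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val, best_theta, best_epoch = val_loss, theta.copy(), epoch
            since_best = 0
        else:
            since_best += 1
            if opts.patience and since_best >= opts.patience:
                break

    model.set_flat(best_theta)
    model.metadata.update({
        "seed": opts.seed, "epochs_run": int(history["epoch"][-1]),
        "best_epoch": int(best_epoch), "best_val_loss": float(best_val),
        "reduction": opts.reduction,
    })
    return TrainingResult(model=model, history={k: np.array(v) for k, v in history.items()},
                          best_epoch=best_epoch, best_val_loss=float(best_val),
                          aborted=aborted)


def fit_linear_model(model: CorrectionModel, data: DeltaDataset,
                     subset: str = "train", rcond: float = 1e-10) -> float:
    """Closed-form force matching for linear (``hidden=0``) models.

    For a linear-in-parameters head the force-matching problem is ordinary
    least squares; this assembles the normal equations from the analytic
    descriptor Jacobians and solves them with a pseudo-inverse (minimum-norm
    in rank-deficient directions, e.g. basis functions at unsampled radii).
    Returns the root-mean-square force residual on the chosen subset.
    """
    if model.hidden != 0:
        raise ValueError("closed-form fit requires a linear model (hidden=0)")
    idx = data.subset_indices(subset)
    caches = [_ConfigCache(model, data.configs[k], data.delta_forces[k])
              for k in idx]
    n_p = model.n_feat * len(model.species)
    gram = np.zeros((n_p, n_p))
    rhs = np.zeros(n_p)
    total_sq, total_n = 0.0, 0
    for cc in caches:
        cols = []
        g = np.zeros((len(cc.svoc), model.n_feat))
        for si, s in enumerate(model.species):
            rows = cc.svoc == si
            for f in range(model.n_feat):
                g[:] = 0.0
                g[rows, f] = 1.0 / model.feat_scale[s][f]
                _, grad, _ = model._kernel(cc.system, cc.pairs, mode=1, g=g,
                                           csr=cc.csr, svoc=cc.svoc)
                cols.append(-grad[cc.mask].ravel())
        b_mat = np.array(cols).T
        target = cc.delta[cc.mask].ravel()
        gram += b_mat.T @ b_mat
        rhs += b_mat.T @ target
        total_n += target.size
    w = np.linalg.pinv(gram, rcond=rcond, hermitian=True) @ rhs
    pos = 0
    for s in model.species:
        model.params[s]["w"][:] = w[pos:pos + model.n_feat]
        pos += model.n_feat
    for cc in caches:
        f_model, _ = _model_forces_cached(model, cc)
        r = f_model[cc.mask] - cc.delta[cc.mask]
        total_sq += float(np.sum(r * r))
    return float(np.sqrt(total_sq / max(total_n, 1)))


# ---------------------------------------------------------------------------
# Evaluation helpers
# ---------------------------------------------------------------------------

def correction_force_rmse(model: CorrectionModel, data: DeltaDataset,
                          subset: str = "val") -> float:
    """RMSE of (prior + correction) vs reference forces on the target subset.

    Because targets are deltas, this equals the RMSE of the correction's
    forces against the delta targets.
    """
    idx = data.subset_indices(subset)
    total, count = 0.0, 0
    for k in idx:
        c = data.configs[k]
        f_model = model.forces(c.system)
        mask = c.target_mask
        r = f_model[mask] - data.delta_forces[k][mask]
        total += float(np.sum(r * r))
        count += r.size
    return float(np.sqrt(total / max(count, 1)))


def prior_baseline_rmse(data: DeltaDataset, subset: str = "val") -> float:
    """RMSE of the prior alone vs reference forces (= RMS of delta targets)."""
    idx = data.subset_indices(subset)
    total, count = 0.0, 0
    for k in idx:
        mask = data.configs[k].target_mask
        d = data.delta_forces[k][mask]
        total += float(np.sum(d * d))
        count += d.size
    return float(np.sqrt(total / max(count, 1)))
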