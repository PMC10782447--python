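"""Trainable local many-body correction potential.

This is the learned half of the delta-learning split: a strictly local,
cutoff-limited model that maps each ML-visible particle's atomic environment
to an atomic energy, trained so that the *forces* of prior + correction match
reference ion forces.  The architecture is an invariant-descriptor model:

* per-neighbor-species radial features — Gaussians on a grid in r, under a
  smooth polynomial cutoff envelope ``(1-(r/rc)^2)^2`` (value and first
  derivative vanish at the cutoff, so MD forces are continuous);
* optional 3-body angular invariants ``2^(1-z) (1+l*cos t)^z
  exp(-eta(rij^2+rik^2)) fc(rij) fc(rik)`` per unordered species pair;
* a small per-species feed-forward head (one tanh hidden layer, or a linear
  map with ``hidden=0``) from standardized features to the atomic energy.

Forces are exact analytic gradients of the total energy (chain rule through
the descriptors), and particles with ``ml_visible=False`` neither appear in
any descriptor nor receive a correction force.

Only scalar invariance (not equivariance) is required since the model
predicts energies; rotation/translation/permutation invariance is inherited
from the descriptors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import _kernels
from .system import ParticleSystem, UnknownSpeciesError


class VocabularyError(UnknownSpeciesError):
    """An ML-visible species is missing from the model's vocabulary."""


@dataclass
class DescriptorConfig:
    """Atomic-environment descriptor hyperparameters.

    ``n_radial`` defaults to 64 Gaussians on [0, r_cut]: the radial
    resolution (~0.014 nm) is chosen to resolve solvent-separated ion-pair
    structure at the 0.04 nm scale.  These values are engineering choices of
    this package, not published ones.
    """

    r_cut: float = 0.9
    n_radial: int = 64
    basis: str = "gaussian"
    width_factor: float = 1.0           # basis width = width_factor * grid spacing
    include_angular: bool = True
    angular_zeta: tuple = ((1.0, 1.0), (1.0, -1.0), (4.0, 1.0), (4.0, -1.0))
    angular_eta: float = None           # default 2 / r_cut^2

    def __post_init__(self):
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")
        if self.n_radial < 2:
            raise ValueError("need at least 2 radial basis functions")
        if self.basis != "gaussian":
            raise ValueError(f"unknown radial basis {self.basis!r}")
        if self.angular_eta is None:
            self.angular_eta = 2.0 / self.r_cut ** 2

    @property
    def mu(self) -> np.ndarray:
        return np.linspace(0.0, self.r_cut, self.n_radial)

    @property
    def width(self) -> float:
        return self.width_factor * (self.r_cut / (self.n_radial - 1))

    def n_features(self, n_species: int) -> int:
        n = n_species * self.n_radial
        if self.include_angular:
            n += (n_species * (n_species + 1) // 2) * len(self.angular_zeta)
        return n

    def to_dict(self) -> dict:
        d = asdict(self)
        d["angular_zeta"] = [list(p) for p in self.angular_zeta]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DescriptorConfig":
        d = dict(d)
        d["angular_zeta"] = tuple(tuple(p) for p in d["angular_zeta"])
        return cls(**d)


def _pair_channel_matrix(n_species: int) -> np.ndarray:
    ch = np.zeros((n_species, n_species), dtype=np.int64)
    c = 0
    for a in range(n_species):
        for b in range(a, n_species):
            ch[a, b] = ch[b, a] = c
            c += 1
    return ch


class CorrectionModel:
    """Per-species descriptor -> atomic-energy model with analytic forces."""

    FORMAT_VERSION = 1

    def __init__(self, species: list, descriptor: DescriptorConfig = None,
                 hidden: int = 32, seed: int = 0, metadata: dict = None):
        self.species = list(species)
        self.descriptor = descriptor or DescriptorConfig()
        self.hidden = int(hidden)
        self.metadata = dict(metadata or {})
        self.n_feat = self.descriptor.n_features(len(self.species))
        self._pair_channel = _pair_channel_matrix(len(self.species))
        zl = np.asarray(self.descriptor.angular_zeta, dtype=float)
        if self.descriptor.include_angular and len(zl):
            self._zeta = np.ascontiguousarray(zl[:, 0])
            self._lamb = np.ascontiguousarray(zl[:, 1])
        else:
            self._zeta = np.zeros(0)
            self._lamb = np.zeros(0)
        self._mu = self.descriptor.mu
        self.params = {}
        self.feat_mean = {s: np.zeros(self.n_feat) for s in self.species}
        self.feat_scale = {s: np.ones(self.n_feat) for s in self.species}
        self.init_parameters(seed)

    # -- parameters --------------------------------------------------------

    def init_parameters(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.params = {}
        for s in self.species:
            if self.hidden > 0:
                # tanh hidden layer plus a linear skip term: the skip can
                # represent pair-additive corrections exactly, the hidden
                # layer adds many-body flexibility
                self.params[s] = {
                    "W1": rng.standard_normal((self.hidden, self.n_feat)) / np.sqrt(self.n_feat),
                    "b1": np.zeros(self.hidden),
                    "w2": 0.1 * rng.standard_normal(self.hidden) / np.sqrt(self.hidden),
                    "b2": np.zeros(1),
                    "w": np.zeros(self.n_feat),
                }
            else:
                self.params[s] = {"w": np.zeros(self.n_feat), "b": np.zeros(1)}

    def zero_parameters(self):
        for blocks in self.params.values():
            for arr in blocks.values():
                arr[:] = 0.0

    def get_flat(self) -> np.ndarray:
        return np.concatenate([self.params[s][k].ravel()
                               for s in self.species for k in sorted(self.params[s])])

    def set_flat(self, vec: np.ndarray):
        pos = 0
        for s in self.species:
            for k in sorted(self.params[s]):
                arr = self.params[s][k]
                arr[...] = vec[pos:pos + arr.size].reshape(arr.shape)
                pos += arr.size
        if pos != vec.size:
            raise ValueError("flat parameter vector has wrong length")

    def set_feature_scaling(self, mean: dict, scale: dict):
        for s in self.species:
            self.feat_mean[s] = np.asarray(mean[s], float).copy()
            sc = np.asarray(scale[s], float).copy()
            sc[sc <= 0] = 1.0
            self.feat_scale[s] = sc

    # -- descriptors -------------------------------------------------------

    def species_index(self, system: ParticleSystem) -> np.ndarray:
        lookup = {s: k for k, s in enumerate(self.species)}
        out = np.full(len(system), -1, dtype=np.int64)
        for i, (sp, vis) in enumerate(zip(system.species, system.ml_visible)):
            if not vis:
                continue
            if sp not in lookup:
                raise VocabularyError(
                    f"ML-visible species {sp!r} not in model vocabulary {self.species}")
            out[i] = lookup[sp]
        return out

    def _pairs(self, system: ParticleSystem):
        pi, pj = _kernels.build_pairs(system.positions, system.box,
                                      self.descriptor.r_cut)
        return pi, pj

    def _csr(self, system: ParticleSystem, pairs):
        """Per-configuration neighbor structure (cacheable: positions fixed)."""
        return _kernels._csr_neighbors(system.positions, system.box,
                                       pairs[0], pairs[1],
                                       np.ascontiguousarray(system.ml_visible),
                                       self.descriptor.r_cut)

    def _kernel(self, system: ParticleSystem, pairs, mode: int,
                g: np.ndarray = None, R: np.ndarray = None, csr=None,
                svoc=None):
        n = len(system)
        if svoc is None:
            svoc = self.species_index(system)
        if csr is None:
            csr = self._csr(system, pairs)
        empty = np.zeros((n, 1)) if g is None else g
        emptyR = np.zeros((n, 3)) if R is None else R
        d = self.descriptor
        return _kernels.desc_core(
            csr[0], csr[1], csr[2], csr[3], svoc,
            d.r_cut, self._mu, d.width, self._zeta, self._lamb, d.angular_eta,
            self._pair_channel, len(self.species) * d.n_radial,
            mode, np.ascontiguousarray(empty, float), np.ascontiguousarray(emptyR, float))

    def descriptor_matrix(self, system: ParticleSystem, pairs=None) -> np.ndarray:
        """(N, n_feat) raw descriptors; zero rows for non-ML-visible particles."""
        pairs = pairs if pairs is not None else self._pairs(system)
        d, _, _ = self._kernel(system, pairs, mode=0)
        return d

    def environment_descriptor(self, system: ParticleSystem, i: int) -> np.ndarray:
        """Feature vector of particle ``i`` (must be ML-visible)."""
        if not (0 <= i < len(system)):
            raise IndexError(f"particle index {i} out of range")
        if not system.ml_visible[i]:
            raise ValueError(f"particle {i} is not ML-visible")
        return self.descriptor_matrix(system)[i]

    # -- network forward/backward ------------------------------------------

    def _forward(self, d: np.ndarray, svoc: np.ndarray):
        """Atomic energies and dE/d(descriptor) for every visible particle."""
        n = len(svoc)
        e_at = np.zeros(n)
        g = np.zeros((n, self.n_feat))
        cache = {}
        for k, s in enumerate(self.species):
            rows = np.flatnonzero(svoc == k)
            if len(rows) == 0:
                continue
            dstd = (d[rows] - self.feat_mean[s]) / self.feat_scale[s]
            p = self.params[s]
            if self.hidden > 0:
                a = dstd @ p["W1"].T + p["b1"]
                h = np.tanh(a)
                e_at[rows] = h @ p["w2"] + p["b2"][0] + dstd @ p["w"]
                hp = 1.0 - h * h
                g[rows] = ((hp * p["w2"]) @ p["W1"] + p["w"]) / self.feat_scale[s]
                cache[s] = (rows, dstd, h, hp)
            else:
                e_at[rows] = dstd @ p["w"] + p["b"][0]
                g[rows] = p["w"] / self.feat_scale[s]
                cache[s] = (rows, dstd, None, None)
        return e_at, g, cache

    # -- public evaluation --------------------------------------------------

    def energy_forces(self, system: ParticleSystem, pairs=None) -> tuple:
        """(energy, forces): E = sum of atomic energies, F = -grad E."""
        pairs = pairs if pairs is not None else self._pairs(system)
        return self._energy_forces_raw(system.positions, system.box, pairs,
                                       self.species_index(system),
                                       np.ascontiguousarray(system.ml_visible))

    def _energy_forces_raw(self, positions, box, pairs, svoc, visible) -> tuple:
        """Array-level evaluation (hot path for MD: no system copies)."""
        dcfg = self.descriptor
        csr = _kernels._csr_neighbors(positions, box, pairs[0], pairs[1],
                                      visible, dcfg.r_cut)
        n = len(positions)
        n_rad_feat = len(self.species) * dcfg.n_radial
        empty = np.zeros((1, 1))
        emptyR = np.zeros((1, 3))
        d, _, _ = _kernels.desc_core(csr[0], csr[1], csr[2], csr[3], svoc,
                                     dcfg.r_cut, self._mu, dcfg.width,
                                     self._zeta, self._lamb, dcfg.angular_eta,
                                     self._pair_channel, n_rad_feat, 0,
                                     empty, emptyR)
        e_at, g, _ = self._forward(d, svoc)
        _, grad, _ = _kernels.desc_core(csr[0], csr[1], csr[2], csr[3], svoc,
                                        dcfg.r_cut, self._mu, dcfg.width,
                                        self._zeta, self._lamb, dcfg.angular_eta,
                                        self._pair_channel, n_rad_feat, 1,
                                        g, emptyR)
        return float(np.sum(e_at[svoc >= 0])), -grad

    def energy(self, system: ParticleSystem) -> float:
        return self.energy_forces(system)[0]

    def forces(self, system: ParticleSystem) -> np.ndarray:
        return self.energy_forces(system)[1]

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "disolv-correction-model",
            "version": self.FORMAT_VERSION,
            "species": self.species,
            "descriptor": self.descriptor.to_dict(),
            "hidden": self.hidden,
            "params": {s: {k: v.tolist() for k, v in blk.items()}
                       for s, blk in self.params.items()},
            "feat_mean": {s: v.tolist() for s, v in self.feat_mean.items()},
            "feat_scale": {s: v.tolist() for s, v in self.feat_scale.items()},
            "metadata": self.metadata,
        }

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "CorrectionModel":
        if d.get("format") != "disolv-correction-model":
            raise ValueError("not a correction-model file")
        if d["version"] > cls.FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {d['version']}")
        model = cls(d["species"], DescriptorConfig.from_dict(d["descriptor"]),
                    hidden=d["hidden"], metadata=d.get("metadata", {}))
        for s, blk in d["params"].items():
            for k, v in blk.items():
                model.params[s][k] = np.asarray(v, float).reshape(model.params[s][k].shape)
        model.set_feature_scaling({s: np.asarray(v) for s, v in d["feat_mean"].items()},
                                  {s: np.asarray(v) for s, v in d["feat_scale"].items()})
        return model

    @classmethod
    def load(cls, path) -> "CorrectionModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


class CorrectionForceField:
    """Adapter giving a trained model the force-field interface used by MD."""

    def __init__(self, model: CorrectionModel, system: ParticleSystem):
        self.model = model
        self.svoc = model.species_index(system)  # fails fast on vocabulary gaps
        self.visible = np.ascontiguousarray(system.ml_visible)
        self.box = system.box.copy()

    @property
    def cutoff(self) -> float:
        return self.model.descriptor.r_cut

    def compute(self, positions: np.ndarray, pairs: tuple) -> tuple:
        return self.model._energy_forces_raw(positions, self.box, pairs,
                                             self.svoc, self.visible)


def model_energy(system: ParticleSystem, model: CorrectionModel) -> float:
    return model.energy(system)


def model_forces(system: ParticleSystem, model: CorrectionModel) -> np.ndarray:
    return model.forces(system)
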