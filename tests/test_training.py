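import numpy as np
import pytest

from disolv.correction import CorrectionModel, DescriptorConfig
from disolv.prior import PriorForceField, build_neighbor_list
from disolv.synthetic import (FixtureSpec, generate_labeled_dataset,
                              make_ionic_box, make_oracle, oracle_true_params)
from disolv.system import make_system
from disolv.training import (DeltaDataset, LabeledConfiguration,
                             TrainingOptions, force_matching_loss,
                             make_delta_dataset, split_dataset, train_model,
                             correction_force_rmse, prior_baseline_rmse,
                             _ConfigCache, _flat_grads, _model_forces_cached,
                             _param_grads)


def _tiny_dataset(n_configs=6, seed=0):
    spec = FixtureSpec(concentration=1.0, box=(3.0, 3.0, 3.0), seed=seed,
                       n_configs=n_configs, stride_ps=0.2, equilibration_ps=1.0)
    return generate_labeled_dataset(spec)


class TestDeltaDataset:
    def test_zero_delta_when_reference_equals_prior(self):
        system = make_ionic_box(FixtureSpec(box=(3.0, 3.0, 3.0), seed=1))
        ff = PriorForceField(system)
        nl = build_neighbor_list(system, ff.cutoff)
        _, f = ff.compute(system.positions, (nl.i, nl.j))
        config = LabeledConfiguration(system=system, forces=f)
        ds = make_delta_dataset([config])
        np.testing.assert_allclose(ds.delta_forces[0], 0.0, atol=1e-12)

    def test_single_pair_hand_subtraction(self):
        system = make_system([[1, 1, 1], [1.5, 1, 1]], ["Na", "Cl"], (4, 4, 4))
        f_ref = np.array([[1.0, 2.0, 3.0], [-1.0, -2.0, -3.0]])
        ds = make_delta_dataset([LabeledConfiguration(system=system, forces=f_ref)])
        ff = PriorForceField(system)
        nl = build_neighbor_list(system, ff.cutoff)
        _, f_prior = ff.compute(system.positions, (nl.i, nl.j))
        np.testing.assert_allclose(ds.delta_forces[0], f_ref - f_prior, atol=1e-13)

    def test_oracle_delta_equals_extra_term_in_closed_form(self):
        """When the model prior shares the oracle's LJ table, the delta
        targets are exactly the oracle's extra Gaussian forces."""
        configs = _tiny_dataset(4)
        true_params = oracle_true_params()
        ds = make_delta_dataset(configs, params=true_params)
        for c, delta in zip(configs, ds.delta_forces):
            f_extra = make_oracle(c.system, "ssip").extra_forces(c.system)
            np.testing.assert_allclose(delta[c.target_mask],
                                       f_extra[c.target_mask], atol=1e-9)


class TestSplit:
    def _dataset(self, n):
        system = make_system([[1, 1, 1]], ["Na"], (3, 3, 3))
        cfgs = [LabeledConfiguration(system=system, forces=np.zeros((1, 3)),
                                     index=k) for k in range(n)]
        return DeltaDataset(configs=cfgs, delta_forces=[np.zeros((1, 3))] * n)

    def test_ten_configs_gives_8_2(self):
        ds = split_dataset(self._dataset(10), 0.8, seed=3)
        assert len(ds.train_idx) == 8 and len(ds.val_idx) == 2
        assert set(ds.train_idx) | set(ds.val_idx) == set(range(10))
        assert set(ds.train_idx) & set(ds.val_idx) == set()

    def test_same_seed_same_partition(self):
        a = split_dataset(self._dataset(20), seed=7)
        b = split_dataset(self._dataset(20), seed=7)
        np.testing.assert_array_equal(a.train_idx, b.train_idx)

    def test_validation_frequency_is_uniform(self):
        # each of 5 configs lands in the single validation slot with
        # empirical frequency 0.2 +- 0.01 over many independent splits
        counts = np.zeros(5)
        n_draws = 100_000
        ds = self._dataset(5)
        for seed in range(n_draws):
            split_dataset(ds, seed=seed)
            counts[ds.val_idx[0]] += 1
        np.testing.assert_allclose(counts / n_draws, 0.2, atol=0.01)

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            split_dataset(self._dataset(5), fraction=1.0)


class TestLoss:
    def test_exact_match_is_zero(self):
        x = np.arange(24.0).reshape(2, 4, 3)
        assert force_matching_loss(x, x) == 0.0

    def test_constant_offset_gives_c_squared(self):
        x = np.zeros((2, 4, 3))
        assert force_matching_loss(x + 1.7, x) == pytest.approx(1.7 ** 2)

    def test_matches_triple_loop(self, rng):
        a = rng.normal(size=(2, 3, 3))
        b = rng.normal(size=(2, 3, 3))
        total = 0.0
        for i in range(2):
            for j in range(3):
                for k in range(3):
                    total += (a[i, j, k] - b[i, j, k]) ** 2
        assert force_matching_loss(a, b) == pytest.approx(total / 18)
        assert force_matching_loss(a, b, reduction="sum") == pytest.approx(total)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            force_matching_loss(np.zeros((2, 3)), np.zeros((3, 2)))


class TestParameterGradients:
    def test_analytic_loss_gradient_matches_finite_differences(self):
        configs = _tiny_dataset(2)
        ds = make_delta_dataset(configs)
        model = CorrectionModel(["Na", "Cl"], DescriptorConfig(n_radial=8),
                                hidden=6, seed=3)
        rng = np.random.default_rng(0)
        for s in model.species:
            for arr in model.params[s].values():
                arr += 0.2 * rng.standard_normal(arr.shape)
        cc = _ConfigCache(model, ds.configs[0], ds.delta_forces[0])

        def loss_at(theta):
            model.set_flat(theta)
            f, _ = _model_forces_cached(model, cc)
            r = f[cc.mask] - cc.delta[cc.mask]
            return float(np.sum(r * r)) / cc.n_comp

        theta0 = model.get_flat()
        f, cache = _model_forces_cached(model, cc)
        dldf = np.zeros_like(f)
        dldf[cc.mask] = 2.0 / cc.n_comp * (f[cc.mask] - cc.delta[cc.mask])
        grad = _flat_grads(model, _param_grads(model, cc, cache, dldf))
        idx = rng.choice(len(theta0), size=25, replace=False)
        h = 1e-6
        for k in idx:
            tp = theta0.copy(); tp[k] += h
            tm = theta0.copy(); tm[k] -= h
            fd = (loss_at(tp) - loss_at(tm)) / (2 * h)
            assert grad[k] == pytest.approx(fd, rel=1e-3, abs=1e-8)
        model.set_flat(theta0)


class TestTrainModel:
    def test_zero_targets_zero_init_stays_zero(self):
        configs = _tiny_dataset(4)
        ds = DeltaDataset(configs=configs,
                          delta_forces=[np.zeros_like(c.forces) for c in configs])
        split_dataset(ds, seed=0)
        model = CorrectionModel(["Na", "Cl"], DescriptorConfig(n_radial=8),
                                hidden=0, seed=0)  # linear head, zero init
        res = train_model(model, ds, TrainingOptions(epochs=3, seed=0,
                                                     standardize_features=False))
        assert res.history["train_loss"][0] == 0.0
        np.testing.assert_array_equal(model.get_flat(), 0.0)

    def test_linear_targets_recovered_by_closed_form_fit(self):
        """Targets generated by a known linear-in-parameters model are
        recovered by the closed-form linear fit; the solution is checked
        against an independently assembled least-squares oracle."""
        from disolv.training import fit_linear_model
        configs = _tiny_dataset(8, seed=4)
        gen = CorrectionModel(["Na", "Cl"], DescriptorConfig(n_radial=8),
                              hidden=0, seed=1)
        rng = np.random.default_rng(2)
        for s in gen.species:
            gen.params[s]["w"] += rng.standard_normal(gen.n_feat)
        deltas = [gen.forces(c.system) for c in configs]
        ds = DeltaDataset(configs=configs, delta_forces=deltas)
        split_dataset(ds, seed=0)
        model = CorrectionModel(["Na", "Cl"], DescriptorConfig(n_radial=8),
                                hidden=0, seed=5)
        resid = fit_linear_model(model, ds, subset="train")
        scale = np.sqrt(np.mean(np.concatenate(
            [d[c.target_mask].ravel() for c, d in zip(configs, deltas)]) ** 2))
        # generating forces recovered on the training set
        assert resid / scale < 1e-3
        for k in ds.train_idx:
            mask = configs[k].target_mask
            err = np.max(np.abs(model.forces(configs[k].system)[mask]
                                - deltas[k][mask]))
            assert err / scale < 1e-3
        # oracle: probe unit parameters, stack the design matrix, lstsq
        probe = CorrectionModel(["Na", "Cl"], DescriptorConfig(n_radial=8),
                                hidden=0, seed=0)
        cols = []
        for s in probe.species:
            for f in range(probe.n_feat):
                probe.zero_parameters()
                probe.params[s]["w"][f] = 1.0
                cols.append(np.concatenate(
                    [probe.forces(configs[k].system)[configs[k].target_mask].ravel()
                     for k in ds.train_idx]))
        a_mat = np.array(cols).T
        b_vec = np.concatenate([deltas[k][configs[k].target_mask].ravel()
                                for k in ds.train_idx])
        w_star, *_ = np.linalg.lstsq(a_mat, b_vec, rcond=1e-10)
        # both routes must predict the same forces (min-norm solutions)
        pred_oracle = a_mat @ w_star
        w_fit = np.concatenate([model.params[s]["w"] for s in model.species])
        pred_fit = a_mat @ w_fit
        np.testing.assert_allclose(pred_fit, pred_oracle, atol=1e-4 * scale)

    def test_reproducible_for_fixed_seed(self):
        configs = _tiny_dataset(6)
        ds = split_dataset(make_delta_dataset(configs), seed=1)
        results = []
        for _ in range(2):
            model = CorrectionModel(["Na", "Cl"], DescriptorConfig(n_radial=8),
                                    hidden=4, seed=2)
            train_model(model, ds, TrainingOptions(epochs=3, seed=9))
            results.append(model.get_flat())
        np.testing.assert_array_equal(results[0], results[1])

    def test_requires_split(self):
        configs = _tiny_dataset(4)
        ds = make_delta_dataset(configs)
        model = CorrectionModel(["Na", "Cl"], DescriptorConfig(n_radial=8))
        with pytest.raises(ValueError):
            train_model(model, ds)


def test_loss_permutation_invariance(rng):
    a = rng.normal(size=(4, 5, 3))
    b = rng.normal(size=(4, 5, 3))
    perm = rng.permutation(4)
    assert force_matching_loss(a, b) == pytest.approx(
        force_matching_loss(a[perm], b[perm]))
    ion_perm = rng.permutation(5)
    assert force_matching_loss(a, b) == pytest.approx(
        force_matching_loss(a[:, ion_perm], b[:, ion_perm]))
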