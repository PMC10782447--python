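import json

import numpy as np
import pytest

from disolv.correction import (CorrectionModel, DescriptorConfig,
                               VocabularyError)
from disolv.system import make_system
from disolv.validate import (finite_difference_forces,
                             max_relative_force_error,
                             random_ionic_configurations)


def _model(hidden=8, n_radial=12, include_angular=True, seed=0):
    return CorrectionModel(["Na", "Cl"],
                           DescriptorConfig(n_radial=n_radial,
                                            include_angular=include_angular),
                           hidden=hidden, seed=seed)


def _randomized_model(seed=0, **kw):
    model = _model(seed=seed, **kw)
    rng = np.random.default_rng(seed + 100)
    for s in model.species:
        for arr in model.params[s].values():
            arr += 0.3 * rng.standard_normal(arr.shape)
    return model


def _rotate(positions, seed=3):
    from scipy.spatial.transform import Rotation
    r = Rotation.random(random_state=seed).as_matrix()
    return positions @ r.T


class TestDescriptors:
    def test_isolated_particle_has_zero_features(self):
        model = _model()
        system = make_system([[1, 1, 1], [4, 4, 4]], ["Na", "Cl"], (10, 10, 10))
        np.testing.assert_array_equal(model.environment_descriptor(system, 0), 0.0)

    def test_mirror_image_environments_identical(self):
        model = _model()
        pos = np.array([[2.0, 2.0, 2.0], [2.5, 2.0, 2.0], [2.2, 2.4, 2.0]])
        mirrored = pos.copy()
        mirrored[:, 0] = 4.0 - mirrored[:, 0]  # reflection plane x = 2
        a = make_system(pos, ["Na", "Cl", "Cl"], (8, 8, 8))
        b = make_system(mirrored, ["Na", "Cl", "Cl"], (8, 8, 8))
        np.testing.assert_allclose(model.environment_descriptor(a, 0),
                                   model.environment_descriptor(b, 0),
                                   atol=1e-12)

    def test_features_continuous_across_cutoff(self):
        model = _model()
        rc = model.descriptor.r_cut
        vals = []
        for delta in (-1e-2, -1e-4, -1e-6, 1e-6, 1e-2):
            system = make_system([[1, 1, 1], [1 + rc + delta, 1, 1]],
                                 ["Na", "Cl"], (8, 8, 8))
            vals.append(model.environment_descriptor(system, 0))
        # outside the cutoff features equal the isolated-particle value (zero)
        np.testing.assert_array_equal(vals[-1], 0.0)
        np.testing.assert_array_equal(vals[-2], 0.0)
        # approaching from inside, features tend continuously to zero
        assert np.max(np.abs(vals[2])) < np.max(np.abs(vals[1])) < np.max(np.abs(vals[0]))
        assert np.max(np.abs(vals[2])) < 1e-10

    def test_ml_invisible_particles_absent_from_descriptors(self):
        model = _model()
        base = make_system([[1, 1, 1], [1.4, 1, 1]], ["Na", "Cl"], (8, 8, 8))
        with_aux = make_system([[1, 1, 1], [1.4, 1, 1], [1.2, 1.2, 1]],
                               ["Na", "Cl", "Cl"], (8, 8, 8),
                               ml_visible=[True, True, False])
        np.testing.assert_allclose(model.environment_descriptor(base, 0),
                                   model.environment_descriptor(with_aux, 0),
                                   atol=1e-14)

    def test_not_visible_center_rejected(self):
        model = _model()
        system = make_system([[1, 1, 1], [1.4, 1, 1]], ["Na", "Cl"], (8, 8, 8),
                             ml_visible=[False, True])
        with pytest.raises(ValueError):
            model.environment_descriptor(system, 0)
        with pytest.raises(IndexError):
            model.environment_descriptor(system, 5)


class TestModelEnergy:
    def test_zero_parameters_zero_energy_everywhere(self, small_nacl_system):
        model = _model()
        model.zero_parameters()
        assert model.energy(small_nacl_system) == 0.0
        np.testing.assert_array_equal(model.forces(small_nacl_system), 0.0)

    def test_rotation_invariance(self, rng):
        model = _randomized_model()
        pos = 10.0 + rng.random((8, 3))  # compact cluster inside a large box
        system = make_system(pos, ["Na", "Cl"] * 4, (20, 20, 20))
        center = pos.mean(axis=0)
        rotated = system.with_positions(_rotate(pos - center) + center)
        assert model.energy(rotated) == pytest.approx(model.energy(system),
                                                      rel=1e-10)

    def test_three_particle_toy_matches_hand_composition(self):
        """Independent re-evaluation: descriptors -> standardization ->
        tanh network, composed by hand outside the library code path."""
        model = _randomized_model(seed=5, n_radial=6, include_angular=False)
        pos = np.array([[1.0, 1.0, 1.0], [1.5, 1.0, 1.0], [1.0, 1.6, 1.0]])
        system = make_system(pos, ["Na", "Cl", "Na"], (8, 8, 8))
        dcfg = model.descriptor
        mu, w, rc = dcfg.mu, dcfg.width, dcfg.r_cut
        vocab = {"Na": 0, "Cl": 1}

        def fc(r):
            return (1 - (r / rc) ** 2) ** 2 if r < rc else 0.0

        e_hand = 0.0
        for i in range(3):
            feats = np.zeros(model.n_feat)
            for j in range(3):
                if i == j:
                    continue
                r = np.linalg.norm(pos[j] - pos[i])
                if r >= rc:
                    continue
                ch = vocab[system.species[j]]
                for m in range(dcfg.n_radial):
                    feats[ch * dcfg.n_radial + m] += (
                        np.exp(-(r - mu[m]) ** 2 / (2 * w * w)) * fc(r))
            s = system.species[i]
            dstd = (feats - model.feat_mean[s]) / model.feat_scale[s]
            p = model.params[s]
            h = np.tanh(p["W1"] @ dstd + p["b1"])
            e_hand += p["w2"] @ h + p["b2"][0] + p["w"] @ dstd
        assert model.energy(system) == pytest.approx(e_hand, rel=1e-10)

    def test_unknown_visible_species_is_vocabulary_error(self):
        model = _model()
        system = make_system([[1, 1, 1]], ["PH"], (4, 4, 4))
        with pytest.raises(VocabularyError):
            model.energy(system)


class TestModelForces:
    def test_forces_match_finite_differences(self):
        worst = 0.0
        model = _randomized_model(seed=2)
        for system in random_ionic_configurations(3, n_ions=10, seed=11):
            _, f = model.energy_forces(system)
            fd = finite_difference_forces(
                lambda p: model.energy(system.with_positions(p)),
                system.positions)
            worst = max(worst, max_relative_force_error(f, fd))
        assert worst < 1e-5

    def test_forces_sum_to_zero(self, small_nacl_system):
        model = _randomized_model(seed=4)
        f = model.forces(small_nacl_system)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-8)

    def test_invisible_particles_get_zero_force(self):
        model = _randomized_model()
        system = make_system([[1, 1, 1], [1.4, 1, 1], [1.2, 1.2, 1]],
                             ["Na", "Cl", "Cl"], (8, 8, 8),
                             ml_visible=[True, True, False])
        f = model.forces(system)
        np.testing.assert_array_equal(f[2], 0.0)

    def test_locality_beyond_cutoff(self):
        model = _randomized_model()
        rc = model.descriptor.r_cut
        pos = np.array([[1, 1, 1], [1.3, 1, 1], [1 + 2 * rc, 1, 1]])
        system = make_system(pos, ["Na", "Cl", "Cl"], (10, 10, 10))
        d0 = model.descriptor_matrix(system)[0]
        moved = pos.copy()
        moved[2] += 0.1
        d0_moved = model.descriptor_matrix(system.with_positions(moved))[0]
        np.testing.assert_array_equal(d0, d0_moved)


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path, small_nacl_system):
        model = _randomized_model(seed=9)
        model.metadata["note"] = "fixture"
        path = tmp_path / "model.json"
        model.save(path)
        loaded = CorrectionModel.load(path)
        for s in model.species:
            for k in model.params[s]:
                np.testing.assert_array_equal(model.params[s][k],
                                              loaded.params[s][k])
            np.testing.assert_array_equal(model.feat_scale[s], loaded.feat_scale[s])
        assert loaded.energy(small_nacl_system) == model.energy(small_nacl_system)

    def test_rejects_foreign_files(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"format": "something-else"}))
        with pytest.raises(ValueError):
            CorrectionModel.load(path)


def test_determinism_given_fixed_parameters(small_nacl_system):
    model = _randomized_model(seed=1)
    e1, f1 = model.energy_forces(small_nacl_system)
    e2, f2 = model.energy_forces(small_nacl_system)
    assert e1 == e2
    np.testing.assert_array_equal(f1, f2)
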