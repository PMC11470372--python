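"""Searchlight geometry, neural RDMs, and RSA regression."""

import numpy as np
import pandas as pd
import pytest

from emorsa import synthdata as sd
from emorsa.rdm import as_rdm, lower_triangle
from emorsa.searchlight import (
    build_searchlights,
    neural_rdm,
    rsa_regress,
    run_searchlight,
    sphere_offsets,
)
from emorsa.volumes import BetaVolumeSet

AFFINE3 = np.diag([3.0, 3.0, 3.0, 1.0])


class TestSphereGeometry:
    def test_interior_center_has_seven_members_on_3mm_grid(self):
        """Radius 4 mm on an isotropic 3-mm grid keeps the center and its six
        face neighbors; edge diagonals sit at sqrt(18) ~ 4.24 mm and are out.
        Verified against exhaustive offset enumeration."""
        offsets = sphere_offsets(AFFINE3, 4.0)
        oracle = [
            (dx, dy, dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if 3.0 * np.sqrt(dx * dx + dy * dy + dz * dz) <= 4.0
        ]
        assert len(offsets) == len(oracle) == 7
        mask = np.ones((5, 5, 5), dtype=bool)
        lights, dropped = build_searchlights(mask, AFFINE3, 4.0)
        interior = next(sl for sl in lights if sl.center == (2, 2, 2))
        assert len(interior.members) == 7
        assert not dropped

    def test_tiny_radius_gives_singletons(self):
        mask = np.ones((3, 3, 3), dtype=bool)
        lights, _ = build_searchlights(mask, AFFINE3, 1.0, min_voxels=1)
        assert all(len(sl.members) == 1 for sl in lights)

    def test_corner_center_clipped_by_boundary(self):
        mask = np.ones((5, 5, 5), dtype=bool)
        lights, _ = build_searchlights(mask, AFFINE3, 4.0)
        corner = next(sl for sl in lights if sl.center == (0, 0, 0))
        interior = next(sl for sl in lights if sl.center == (2, 2, 2))
        assert len(corner.members) < len(interior.members)

    def test_membership_symmetry_on_full_cube(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        lights, _ = build_searchlights(mask, AFFINE3, 4.5, min_voxels=1)
        members = {sl.center: {tuple(m) for m in sl.members} for sl in lights}
        for u, mem in members.items():
            for v in mem:
                assert u in members[v]

    def test_anisotropic_voxels_respected(self):
        # 3.3 x 3.3 x 3 mm voxels: only the z neighbors fall within 3.2 mm
        affine = np.diag([3.3, 3.3, 3.0, 1.0])
        offsets = sphere_offsets(affine, 3.2)
        assert sorted(map(tuple, offsets)) == [(-0, -0, -1), (0, 0, 0), (0, 0, 1)] or len(offsets) == 3

    def test_bad_radius_and_empty_mask(self):
        with pytest.raises(ValueError):
            sphere_offsets(AFFINE3, 0.0)
        with pytest.raises(ValueError):
            build_searchlights(np.zeros((2, 2, 2), bool), AFFINE3, 4.0)


class TestNeuralRdm:
    def test_identical_mean_patterns_give_zero_entry(self):
        rngl = np.random.default_rng(0)
        data = np.zeros((4, 3, 3, 3))
        pattern = rngl.normal(0, 1, 27).reshape(3, 3, 3)
        data[0] = data[1] = pattern  # emotion a, twice
        data[2] = data[3] = -pattern + 0.5
        trials = pd.DataFrame({"trial_type": ["a", "a", "b", "b"]})
        bv = BetaVolumeSet(data=data, mask=np.ones((3, 3, 3), bool), affine=AFFINE3, trials=trials)
        lights, _ = build_searchlights(bv.mask, AFFINE3, 6.1, min_voxels=3)
        sl = next(s for s in lights if s.center == (1, 1, 1))
        d = neural_rdm(bv, trials["trial_type"], sl)
        assert d.loc["a", "a"] == 0
        assert d.loc["a", "b"] == pytest.approx(2.0, abs=1e-10)

    def test_planted_world_round_trip(self, world):
        """Noiseless planted betas: the RDM of a sphere matching the signal
        region equals the subject RDM."""
        srdm = sd.sample_subject_rdm(world, 4)
        bv = sd.gen_beta_volumes(world, srdm, trials_per_emotion=2, subject_id=4)
        lights, _ = build_searchlights(bv.mask, world.affine, 6.001)
        sl = next(s for s in lights if s.center == (5, 5, 5))
        assert len(sl.members) == len(world.signal_region)
        d = neural_rdm(bv, bv.trials["trial_type"], sl)
        assert np.abs(d.to_numpy() - srdm.to_numpy()).max() < 0.05

    def test_label_permutation_equivariance(self, world):
        srdm = sd.sample_subject_rdm(world, 2)
        bv = sd.gen_beta_volumes(world, srdm, trials_per_emotion=2, subject_id=2)
        lights, _ = build_searchlights(bv.mask, world.affine, 4.0)
        sl = lights[len(lights) // 2]
        labels = bv.trials["trial_type"].to_numpy()
        d1 = neural_rdm(bv, labels, sl)
        # present the same trials with emotion names swapped consistently
        swap = {e: e for e in srdm.index}
        swap["angry"], swap["happy"] = "happy", "angry"
        d2 = neural_rdm(bv, [swap[l] for l in labels], sl)
        assert d1.loc["angry", "sad"] == pytest.approx(d2.loc["happy", "sad"])

    def test_small_sphere_rejected(self, world):
        srdm = sd.sample_subject_rdm(world, 0)
        bv = sd.gen_beta_volumes(world, srdm, trials_per_emotion=2)
        from emorsa.searchlight import Searchlight

        tiny = Searchlight(center=(0, 0, 0), members=np.array([[0, 0, 0]]), radius_mm=1.0)
        with pytest.raises(ValueError, match="3 voxels"):
            neural_rdm(bv, bv.trials["trial_type"], tiny)


class TestRsaRegress:
    def _random_rdm(self, rng, n=7):
        x = rng.normal(0, 1, (n, n))
        x = np.abs(x + x.T)
        np.fill_diagonal(x, 0)
        return as_rdm(x)

    def test_identity_model_hits_fisher_clip(self, rng):
        d = self._random_rdm(rng)
        coef = rsa_regress(d, [d])
        assert coef[0] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_single_model_equals_fisher_of_pearson(self, rng):
        neural, model = self._random_rdm(rng), self._random_rdm(rng)
        coef = rsa_regress(neural, [model])
        r = np.corrcoef(lower_triangle(neural), lower_triangle(model))[0, 1]
        assert coef[0] == pytest.approx(np.arctanh(r), abs=1e-10)

    def test_orthogonal_second_model_gets_zero_weight(self, rng):
        m1, m2 = self._random_rdm(rng), self._random_rdm(rng)
        # orthogonalize m2's triangle against m1's
        t1 = lower_triangle(m1)
        t2 = lower_triangle(m2)
        t1c, t2c = t1 - t1.mean(), t2 - t2.mean()
        t2o = t2c - (t2c @ t1c) / (t1c @ t1c) * t1c
        vals = np.zeros((7, 7))
        il = np.tril_indices(7, -1)
        vals[il] = t2o
        vals = vals + vals.T
        m2o = as_rdm(vals - vals.min() * (1 - np.eye(7)))
        neural = m2o  # built purely from model 2
        coef = rsa_regress(neural, [m1, m2o])
        assert abs(coef[0]) < 1e-8

    def test_collinear_models_rejected(self, rng):
        m = self._random_rdm(rng)
        with pytest.raises(ValueError, match="collinear"):
            rsa_regress(self._random_rdm(rng), [m, m])

    def test_zero_variance_neural_rejected(self, rng):
        flat = as_rdm(np.ones((4, 4)) - np.eye(4))
        with pytest.raises(ValueError, match="variance"):
            rsa_regress(flat, [self._random_rdm(rng, 4)])


class TestRunSearchlight:
    def test_planted_signal_peaks_inside_region(self, world):
        noisy = sd.PlantedWorld(
            seed=world.seed,
            idiosyncrasy_sd=0.1,
            noise_sd=2.0,
            signal_region=world.signal_region,
            grid_shape=world.grid_shape,
        )
        model = noisy.target_rdm
        maps = []
        for s in range(5):
            srdm = sd.sample_subject_rdm(noisy, s)
            bv = sd.gen_beta_volumes(noisy, srdm, trials_per_emotion=8, subject_id=s)
            res = run_searchlight(bv, bv.trials["trial_type"], [model])
            maps.append(np.nan_to_num(res.coef_maps_[0]))
        mean_map = np.mean(maps, axis=0)
        reg = world.signal_region
        region_mask = np.zeros(world.grid_shape, bool)
        region_mask[reg[:, 0], reg[:, 1], reg[:, 2]] = True
        assert mean_map[region_mask].mean() > mean_map[~region_mask].mean() + 0.2
        assert region_mask[np.unravel_index(np.argmax(mean_map), mean_map.shape)]

    def test_pure_noise_map_centered_on_zero(self, rng):
        data = rng.normal(0, 1, (14, 8, 8, 8))
        trials = pd.DataFrame({"trial_type": list(sd.EMOTIONS) * 2})
        bv = BetaVolumeSet(data=data, mask=np.ones((8, 8, 8), bool), affine=AFFINE3, trials=trials)
        res = run_searchlight(bv, trials["trial_type"], [sd.default_target_rdm()])
        vals = res.coef_maps_[0][res.valid_mask_]
        # spheres overlap (~7 voxels), so discount the effective sample size
        se = vals.std() / np.sqrt(len(vals) / 7)
        assert abs(vals.mean()) < 3 * se

    def test_output_grid_matches_input(self, world):
        srdm = sd.sample_subject_rdm(world, 0)
        bv = sd.gen_beta_volumes(world, srdm, trials_per_emotion=2)
        res = run_searchlight(bv, bv.trials["trial_type"], [world.target_rdm])
        assert res.coef_maps_.shape[1:] == bv.grid_shape
        assert np.array_equal(res.affine_, bv.affine)
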