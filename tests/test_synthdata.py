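"""Synthetic-data generators: design enumerations, planted structure, determinism."""

import numpy as np
import pandas as pd
import pytest

from emorsa import synthdata as sd
from emorsa.behavior import confusion_to_dissimilarity, correlate_upper_triangles
from emorsa.concept import rdm_from_ratings
from emorsa.rdm import as_rdm, lower_triangle, pearson_distance
from emorsa.singletrial import canonical_hrf, trial_regressor


class TestRatingDesign:
    def test_default_design_has_280_records(self, spec):
        design = sd.gen_rating_design(spec, seed=1)
        assert len(design) == 280
        # one record per (emotion block, word)
        assert design.groupby(["emotion", "word"]).size().eq(1).all()

    def test_single_emotion_single_word(self):
        spec = sd.DesignSpec(n_emotions=1, n_words=1)
        assert len(sd.gen_rating_design(spec, seed=0)) == 1

    def test_seeded_determinism(self, spec):
        a = sd.gen_rating_design(spec, seed=5)
        b = sd.gen_rating_design(spec, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_count_formula_holds_for_any_spec(self):
        spec = sd.DesignSpec(n_emotions=3, n_words=11)
        assert len(sd.gen_rating_design(spec, seed=2)) == 33


class TestSessionDesign:
    def test_default_session_has_114_records(self, spec):
        des = sd.gen_session_design(spec, "face", seed=3)
        assert len(des) == 114
        assert des["catch"].sum() == 2

    def test_no_catch_gives_112(self, spec):
        spec112 = sd.DesignSpec(catch_per_session=0)
        assert len(sd.gen_session_design(spec112, "voice", seed=3)) == 112

    def test_onsets_non_overlapping_and_increasing(self, spec):
        des = sd.gen_session_design(spec, "voice", seed=9)
        onset = des["onset"].to_numpy()
        dur = des["duration"].to_numpy()
        assert np.all(np.diff(onset) > 0)
        assert np.all(onset[1:] >= onset[:-1] + dur[:-1] - 1e-9)

    def test_each_block_presents_all_seven_emotions(self, spec):
        des = sd.gen_session_design(spec, "face", seed=11)
        real = des.loc[~des["catch"]]
        for _, block in real.groupby("block"):
            assert sorted(block["trial_type"].unique()) == sorted(sd.EMOTIONS)


class TestSubjectRatings:
    def test_noiseless_ratings_recover_target_rdm(self):
        """With no jitter/noise and a fine rating scale, the empirical
        Pearson-distance RDM of the generated ratings matches the target."""
        w = sd.PlantedWorld(seed=3, idiosyncrasy_sd=0.0, noise_sd=0.0)
        r = sd.gen_subject_ratings(w, 0, rating_max=1000, loc=500.0, scale=120.0)
        d = rdm_from_ratings(r).to_numpy()
        assert np.abs(d - w.target_rdm.to_numpy()).max() < 0.05

    def test_zero_rdm_gives_perfectly_correlated_rows(self):
        w = sd.PlantedWorld(
            target_rdm=as_rdm(np.zeros((7, 7)), sd.EMOTIONS),
            idiosyncrasy_sd=0.0,
            noise_sd=0.0,
            seed=1,
        )
        r = sd.gen_subject_ratings(w, 0, rating_max=1000, loc=500.0, scale=120.0)
        d = rdm_from_ratings(r).to_numpy()
        assert np.abs(d).max() < 0.01

    def test_determinism_and_scale_bounds(self):
        w = sd.PlantedWorld(seed=4, noise_sd=1.0)
        a = sd.gen_subject_ratings(w, 2)
        b = sd.gen_subject_ratings(w, 2)
        pd.testing.assert_frame_equal(a, b)
        assert a.to_numpy().min() >= 1 and a.to_numpy().max() <= 7
        assert a.shape == (7, 40)

    def test_non_psd_target_rejected(self):
        d = np.full((7, 7), 1.9)
        np.fill_diagonal(d, 0.0)
        with pytest.raises(ValueError, match="positive semidefinite"):
            sd.PlantedWorld(target_rdm=as_rdm(d, sd.EMOTIONS))


class TestConfusions:
    def test_zero_temperature_limit_is_diagonal(self):
        cm = sd.gen_confusions(sd.default_target_rdm(), 1e-3, 100, seed=0)
        assert np.all(np.diag(cm.to_numpy()) == 100)

    def test_constant_dissimilarity_gives_uniform_offdiag(self):
        d = np.full((7, 7), 0.8)
        np.fill_diagonal(d, 0.0)
        cm = sd.gen_confusions(as_rdm(d, sd.EMOTIONS), 1.0, 70_000, seed=1).to_numpy()
        off = cm[~np.eye(7, dtype=bool)].astype(float)
        assert off.std() / off.mean() < 0.05

    def test_planted_monotone_link_yields_positive_correlation(self):
        """Large-n confusion counts transformed to dissimilarity correlate
        positively with the conceptual RDM that generated them."""
        rdm = sd.default_target_rdm()
        cm = sd.gen_confusions(rdm, 0.5, 5000, seed=2)
        r, df, _ = correlate_upper_triangles(confusion_to_dissimilarity(cm), rdm)
        assert df == 19
        assert r > 0.5

    def test_temperature_must_be_positive(self):
        with pytest.raises(ValueError):
            sd.gen_confusions(sd.default_target_rdm(), 0.0, 10, seed=0)

    def test_row_sums_equal_trials(self):
        cm = sd.gen_confusions(sd.default_target_rdm(), 1.0, 57, seed=3)
        assert (cm.sum(axis=1) == 57).all()


class TestBetaVolumes:
    def test_noiseless_region_rdm_matches_subject_rdm(self, world):
        srdm = sd.sample_subject_rdm(world, 1)
        bv = sd.gen_beta_volumes(world, srdm, trials_per_emotion=3, subject_id=1)
        lab = bv.trials["trial_type"].to_numpy()
        reg = world.signal_region
        means = np.stack([bv.data[lab == e].mean(0) for e in srdm.index])
        pats = means[:, reg[:, 0], reg[:, 1], reg[:, 2]]
        d = pearson_distance(pats, list(srdm.index)).to_numpy()
        assert np.abs(d - srdm.to_numpy()).max() < 0.05

    def test_zero_rdm_whole_grid_gives_identical_means(self):
        grid = (4, 4, 4)
        region = np.array([(x, y, z) for x in range(4) for y in range(4) for z in range(4)])
        w = sd.PlantedWorld(
            target_rdm=as_rdm(np.zeros((7, 7)), sd.EMOTIONS),
            idiosyncrasy_sd=0.0,
            noise_sd=0.0,
            signal_region=region,
            grid_shape=grid,
            seed=5,
        )
        srdm = sd.sample_subject_rdm(w, 0)
        bv = sd.gen_beta_volumes(w, srdm, trials_per_emotion=2)
        lab = bv.trials["trial_type"].to_numpy()
        means = np.stack([bv.data[lab == e].mean(0) for e in srdm.index])
        centered = means - means.mean(axis=(1, 2, 3), keepdims=True)
        scaled = centered / centered.std(axis=(1, 2, 3), keepdims=True)
        assert np.abs(scaled - scaled[0]).max() < 1e-8

    def test_determinism_and_small_region_error(self, world):
        srdm = sd.sample_subject_rdm(world, 0)
        a = sd.gen_beta_volumes(world, srdm, 2, subject_id=0)
        b = sd.gen_beta_volumes(world, srdm, 2, subject_id=0)
        assert np.array_equal(a.data, b.data)
        tiny = sd.PlantedWorld(seed=1, signal_region=np.array([[0, 0, 0], [0, 0, 1]]))
        with pytest.raises(ValueError, match="at least 3"):
            sd.gen_beta_volumes(tiny, srdm, 2)


class TestBoldAndTone:
    def test_zero_amplitudes_zero_noise_gives_zeros(self):
        ev = pd.DataFrame({"onset": [5.0], "duration": [12.0], "trial_type": ["a"]})
        hrf = canonical_hrf(0.1)
        bold = sd.gen_bold(ev, [0.0], hrf, tr=1.6, noise_sd=0.0, seed=0)
        assert np.all(bold == 0)

    def test_single_trial_equals_convolved_boxcar(self):
        ev = pd.DataFrame({"onset": [8.0], "duration": [12.0], "trial_type": ["a"]})
        tr = 1.6
        hrf = canonical_hrf(tr / 16)
        bold = sd.gen_bold(ev, [1.0], hrf, tr=tr, noise_sd=0.0, seed=0, n_scans=60)
        expected = trial_regressor(8.0, 12.0, 60, tr, hrf)
        assert np.allclose(bold[:, 0, 0, 0], expected)

    def test_invalid_tr_rejected(self):
        ev = pd.DataFrame({"onset": [0.0], "duration": [1.0], "trial_type": ["a"]})
        with pytest.raises(ValueError):
            sd.gen_bold(ev, [1.0], canonical_hrf(0.1), tr=0.0, noise_sd=0.0, seed=0)

    def test_tone_length_period_and_zero_crossings(self):
        wave = sd.gen_tone(220.0, 22050.0, 1.0)
        assert len(wave) == 22050
        crossings = int(np.sum(np.diff(np.sign(wave)) != 0))
        assert abs(crossings - 2 * 220) <= 2

    def test_tone_nyquist_violation(self):
        with pytest.raises(ValueError):
            sd.gen_tone(11025.0, 22050.0, 1.0)
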