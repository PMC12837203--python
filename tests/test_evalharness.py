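"""Inference averaging, grouped CV, t-tests, EAW, ablation wiring."""

import numpy as np
import pytest
from scipy import stats as sstats

from eedcl.evalharness import (EAWResult, MetricsReport, _fwhm, _splits,
                               ablate, eaw, model_gflops, paired_ttest,
                               sliding_predict)
from eedcl.model import EEDModel, VARIANTS, desk_config
from eedcl.types import Recording, Segment

from conftest import labelled_segments


class TestSlidingPredict:
    def test_probability_averaging_arithmetic(self):
        # two windows with probs (0.6, 0.4) and (0.2, 0.8) average to
        # (0.4, 0.6) -> class 1; verified through a stub model
        class Stub:
            def eval(self):
                return self

            def __call__(self, x):
                from eedcl.nn import Tensor
                return Tensor(np.array([[0.6, 0.4], [0.2, 0.8]]))

        rec = Recording(samples=np.random.default_rng(0)
                        .normal(size=(2, 768)), fs=128.0)
        from eedcl.preprocess import PreprocessConfig
        probs, label = sliding_predict(rec, Stub(),
                                       PreprocessConfig(low_hz=4.0,
                                                        high_hz=40.0),
                                       preprocessed=True)
        assert label == 1
        np.testing.assert_allclose(probs.mean(axis=0), [0.4, 0.6])

    def test_single_window_identity(self, rng):
        model = EEDModel(desk_config(n_channels=4, n_classes=2), 0).eval()
        rec = Recording(samples=rng.normal(size=(4, 256)), fs=64.0)
        from eedcl.preprocess import PreprocessConfig
        probs, label = sliding_predict(
            rec, model, PreprocessConfig(low_hz=4.0, high_hz=28.0))
        assert probs.shape[0] == 1
        assert label == int(np.argmax(probs[0]))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_too_short_recording_rejected(self, rng):
        model = EEDModel(desk_config(n_channels=4, n_classes=2), 0)
        rec = Recording(samples=rng.normal(size=(4, 100)), fs=64.0)
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            sliding_predict(rec, model, preprocessed=True)


class TestGroupedSplits:
    def test_kfold_never_splits_a_trial(self):
        segs = labelled_segments(n_per_class=10, n_subjects=3)
        trial_of = np.array([s.trial_id for s in segs])
        for tr, te in _splits(segs, "kfold5", seed=0):
            assert not (set(trial_of[tr]) & set(trial_of[te]))

    def test_kfold_test_sets_cover_dataset_disjointly(self):
        segs = labelled_segments(n_per_class=10, n_subjects=3)
        seen = []
        for _, te in _splits(segs, "kfold5", seed=1):
            seen.extend(te.tolist())
        assert sorted(seen) == list(range(len(segs)))

    def test_loso_one_subject_per_fold(self):
        segs = labelled_segments(n_per_class=4, n_subjects=4)
        subj = np.array([s.subject_id for s in segs])
        folds = list(_splits(segs, "loso", seed=0))
        assert len(folds) == 4
        for tr, te in folds:
            assert len(set(subj[te])) == 1
            assert set(subj[te]).isdisjoint(subj[tr])

    def test_loso_single_subject_rejected(self):
        segs = labelled_segments(n_per_class=4, n_subjects=1)
        with pytest.raises(ValueError):
            list(_splits(segs, "loso", seed=0))


class TestCrossvalidate:
    def test_report_fields_and_fold_count(self):
        from eedcl.evalharness import crossvalidate

        segs = labelled_segments(n_per_class=10, n_subjects=2, n_channels=4,
                                 window=256)
        report = crossvalidate(
            segs, lambda s: EEDModel(desk_config(n_channels=4,
                                                 n_classes=2), s),
            scheme="kfold5", seed=0,
            train_fn=lambda model, train_segs: model.eval())
        assert len(report.per_fold_accuracy) == 5
        assert 0.0 <= report.accuracy <= 100.0
        assert 0.0 <= report.macro_f1 <= 100.0
        assert report.scheme == "kfold5"
        assert report.accuracy_sd >= 0.0


class TestPairedTTest:
    def test_identical_lists_p_one(self):
        assert paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_constant_nonzero_difference_policy(self):
        # zero-variance nonzero differences: documented limit p = 0
        assert paired_ttest([2.0, 3.0, 4.0], [1.0, 2.0, 3.0]) == 0.0

    def test_three_pair_closed_form(self):
        """t = d̄ / (s_d/√n) against the textbook formula and scipy."""
        a = np.array([84.0, 79.0, 91.0])
        b = np.array([80.0, 78.0, 86.0])
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        expected = 2 * sstats.t.sf(abs(t), df=2)
        assert paired_ttest(a, b) == pytest.approx(expected, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0], [2.0])
        with pytest.raises(ValueError):
            paired_ttest([1.0, 2.0], [1.0, 2.0, 3.0])


class TestEAW:
    def test_delta_attention_one_token(self):
        a = np.zeros((1, 5, 5))
        a[:, :, 2] = 1.0
        res = eaw([a], hop_ms=10.0)
        assert res.eaw_tokens == pytest.approx(1.0)
        assert res.eaw_ms == pytest.approx(10.0)

    def test_uniform_attention_full_width(self):
        a = np.full((1, 4, 8), 1 / 8)
        res = eaw([a], hop_ms=5.0)
        assert res.eaw_tokens == pytest.approx(8.0)
        assert res.eaw_ms == pytest.approx(40.0)

    def test_gaussian_profile_fwhm(self):
        idx = np.arange(101)
        profile = np.exp(-((idx - 50) ** 2) / (2 * 2.0 ** 2))
        width = _fwhm(profile / profile.sum())
        assert width == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 2.0,
                                      rel=0.05)

    def test_provenance_flag_present(self):
        res = eaw([np.full((1, 2, 4), 0.25)], hop_ms=1.0)
        assert isinstance(res, EAWResult)
        assert "operationalization" in res.provenance

    def test_missing_records_rejected(self):
        with pytest.raises(ValueError):
            eaw([], hop_ms=1.0)


class TestAnalyticCompute:
    def test_msa_core_exceeds_mgla_core_from_32_tokens(self):
        from eedcl.encoder import mgla_core_macs, msa_core_macs

        gaps = []
        for n in (32, 64, 128, 256):
            gap = msa_core_macs(n, 64) - mgla_core_macs(n, 64)
            assert gap > 0
            gaps.append(gap)
        assert gaps == sorted(gaps)      # quadratic gap grows with n

    def test_full_model_gap_grows_with_tokens(self):
        from dataclasses import replace

        base = desk_config(n_channels=8, n_classes=2)
        gaps = []
        for tokens in (64, 128, 256):
            enc = replace(base.encoder, window_samples=tokens * 32,
                          pool_factor=16, patch_len=2)
            cfg_mgla = replace(base, encoder=enc)
            cfg_msa = replace(base, encoder=enc, variant="msa_cgb")
            gaps.append(model_gflops(cfg_msa) - model_gflops(cfg_mgla))
            assert gaps[-1] > 0
        assert gaps == sorted(gaps)


class TestAblationWiring:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_variant_structure(self, variant, rng):
        from dataclasses import replace

        cfg = replace(desk_config(n_channels=4, n_classes=2),
                      variant=variant)
        model = EEDModel(cfg, 0)
        if variant == "no_hcmft":
            assert all(layer.mgb is None for layer in model.layers)
        else:
            assert all(layer.mgb is not None for layer in model.layers)
        if variant == "no_te":
            assert model.head.encoder_layers == []
        else:
            assert len(model.head.encoder_layers) >= 1
        if variant == "no_adip":
            assert all(stage.medium.cfg.mode == "dip"
                       for stage in model.adip_stages)
        if variant == "no_dscsfe":
            from eedcl.encoder import BaselineSfe
            assert isinstance(model.encoder, BaselineSfe)
        if variant == "msa_cgb":
            assert all(layer.cgb.attention == "msa"
                       for layer in model.layers)
        # every variant still runs end to end
        probs = model.eval()(rng.normal(size=(2, 4, 256))
                             .astype(np.float32)).data
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_unknown_variant_rejected(self):
        from dataclasses import replace

        with pytest.raises(ValueError):
            replace(desk_config(), variant="mystery")
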