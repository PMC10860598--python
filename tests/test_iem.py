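"""Encoding-model estimation, inversion, recentering, cross-validation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dsriem.basis import ChannelBasis, channel_response, ideal_channel_matrix
from dsriem.iem import (
    RankDeficiencyError,
    crossval_reconstruct_timecourse,
    estimate_weights,
    invert_model,
    preprocess,
    recenter_reconstruction,
)
from dsriem.stats import reconstruction_slope
from dsriem.synth import SynthConfig, simulate_subject

from test_synth import single_dim_config


class TestEstimateWeights:
    def test_self_encoding_gives_identity(self, loc_basis):
        c1 = ideal_channel_matrix(loc_basis, np.linspace(0, 359, 20))
        w = estimate_weights(c1, c1)
        assert np.allclose(w, np.eye(9), atol=1e-10)

    def test_recovers_true_weights_noise_free(self, loc_basis, rng):
        w_true = rng.normal(size=(25, 9))
        c1 = ideal_channel_matrix(loc_basis, rng.uniform(0, 360, 50))
        w = estimate_weights(w_true @ c1, c1)
        # independent generic least-squares oracle
        w_ref = np.linalg.lstsq(c1.T, (w_true @ c1).T, rcond=None)[0].T
        assert np.allclose(w, w_true, atol=1e-8)
        assert np.allclose(w, w_ref, atol=1e-10)

    def test_single_repeated_feature_raises(self, loc_basis):
        c1 = ideal_channel_matrix(loc_basis, np.full(30, 100.0))
        b1 = np.random.default_rng(0).normal(size=(12, 30))
        with pytest.raises(RankDeficiencyError, match="singular"):
            estimate_weights(b1, c1)

    def test_too_few_trials_raises(self, loc_basis):
        c1 = ideal_channel_matrix(loc_basis, [0.0, 40.0])
        with pytest.raises(RankDeficiencyError):
            estimate_weights(np.zeros((5, 2)), c1)


class TestInvertModel:
    def test_identity_model_returns_data(self, rng):
        b2 = rng.normal(size=(9, 14))
        assert np.allclose(invert_model(np.eye(9), b2), b2)

    def test_pseudo_inverse_round_trip(self, rng):
        w = rng.normal(size=(40, 6))
        c2 = rng.uniform(0, 1, size=(6, 17))
        # independent oracle: numpy pinv
        assert np.allclose(invert_model(w, w @ c2), c2, atol=1e-9)
        assert np.allclose(
            invert_model(w, w @ c2), np.linalg.pinv(w) @ (w @ c2), atol=1e-9
        )

    def test_underdetermined_raises(self, rng):
        with pytest.raises(RankDeficiencyError, match="underdetermined"):
            invert_model(rng.normal(size=(5, 9)), rng.normal(size=(5, 3)))


class TestRecenterReconstruction:
    def test_on_grid_peak_moves_to_zero_position(self, loc_basis):
        label = loc_basis.centers[7]
        col = channel_response(loc_basis, label)[:, None]
        out = recenter_reconstruction(col, [label], loc_basis)
        assert np.argmax(out[:, 0]) == loc_basis.zero_position

    @given(st.lists(st.floats(0, 359.9), min_size=1, max_size=8))
    def test_per_trial_value_multiset_preserved(self, labels):
        basis = ChannelBasis.location()
        rng = np.random.default_rng(1)
        values = rng.normal(size=(9, len(labels)))
        out = recenter_reconstruction(values, labels, basis)
        assert np.allclose(np.sort(out, axis=0), np.sort(values, axis=0))
        assert np.allclose(out.sum(axis=0), values.sum(axis=0))

    def test_zero_vector_unchanged(self, ori_basis):
        out = recenter_reconstruction(np.zeros(6), [40.0], ori_basis)
        assert np.allclose(out, 0.0)

    def test_nonfinite_label_raises(self, loc_basis):
        with pytest.raises(ValueError):
            recenter_reconstruction(np.zeros((9, 1)), [np.inf], loc_basis)


class TestPreprocess:
    def test_zscore_normalizes_each_voxel_per_run(self, small_design):
        ds = simulate_subject(small_design, SynthConfig(n_voxels=12, noise_sd=1.0), seed=0)
        z = preprocess(ds)
        for r in range(z.n_runs):
            ts = np.moveaxis(z.data[r], 1, 2).reshape(12, -1)
            assert np.allclose(ts.mean(axis=1), 0.0, atol=1e-10)
            assert np.allclose(ts.std(axis=1), 1.0, atol=1e-10)

    def test_detrend_removes_linear_drift(self, small_design):
        ds = simulate_subject(small_design, SynthConfig(n_voxels=12, noise_sd=0.5), seed=0)
        data = ds.data.copy()
        # linear drift along the within-run acquisition ordering (trial-major)
        ramp = np.linspace(-3, 3, 12 * ds.trials_per_run)
        data += ramp.reshape(ds.trials_per_run, 12).T[None, None]
        drifted = type(ds)(data=data, design=ds.design, truth=ds.truth)
        clean = preprocess(drifted, detrend_order=1, zscore=False)
        ref = preprocess(ds, detrend_order=1, zscore=False)
        assert np.allclose(clean.data, ref.data, atol=1e-8)

    def test_bad_detrend_order_raises(self, small_design):
        ds = simulate_subject(small_design, SynthConfig(n_voxels=12), seed=0)
        with pytest.raises(ValueError):
            preprocess(ds, detrend_order=5)


class TestCrossvalReconstruct:
    def test_noise_free_recovery_matches_ideal_curve(self, small_design, loc_basis):
        """Linear-encoding fidelity: single-item, noise-free data reproduce
        the generating channel response exactly."""
        ds = simulate_subject(small_design, single_dim_config(), seed=5)
        rec = crossval_reconstruct_timecourse(ds, "location", test_item="pmi", trs=[10])
        ideal = channel_response(loc_basis, loc_basis.centers[loc_basis.zero_position])
        assert np.abs(rec.curve(10) - ideal).max() < 1e-6
        assert reconstruction_slope(rec.curve(10), loc_basis) > 0

    def test_fold_excludes_held_out_run(self, small_design):
        """Scaling one run's data scales only that run's reconstructions
        (training for its fold saw none of it); by linearity of the
        inversion this verifies leave-one-run-out exactness."""
        ds = simulate_subject(small_design, single_dim_config(), seed=6)
        base = crossval_reconstruct_timecourse(ds, "location", test_item="pmi", trs=[10])
        data = ds.data.copy()
        data[4] *= 5.0
        scaled_ds = type(ds)(data=data, design=ds.design, truth=ds.truth)
        scaled = crossval_reconstruct_timecourse(
            scaled_ds, "location", test_item="pmi", trs=[10]
        )
        tpr = ds.trials_per_run
        sl = slice(4 * tpr, 5 * tpr)
        assert np.allclose(scaled.per_trial[10][:, sl], 5 * base.per_trial[10][:, sl])

    def test_every_trial_reconstructed_once(self, small_design):
        ds = simulate_subject(small_design, single_dim_config(noise_sd=0.5), seed=7)
        rec = crossval_reconstruct_timecourse(ds, "location", test_item="pmi", trs=[3, 10])
        for tr in (3, 10):
            vals = rec.per_trial[tr]
            assert vals.shape == (9, small_design.n_trials)
            assert np.all(np.isfinite(vals))

    def test_rank_deficient_fold_names_run_and_tr(self, small_design):
        ds = simulate_subject(small_design, single_dim_config(noise_sd=0.5), seed=8)
        constant_labels = np.full(small_design.n_trials, 60.0)
        with pytest.raises(RankDeficiencyError, match=r"run 0 held out, TR 10"):
            crossval_reconstruct_timecourse(
                ds, "location", test_item="pmi", trs=[10],
                train_labels_override=constant_labels,
            )

    def test_two_runs_required(self, small_design):
        ds = simulate_subject(small_design, single_dim_config(noise_sd=0.5), seed=9)
        one_run = type(ds)(
            data=ds.data[:1],
            design=type(small_design)(
                trials=small_design.trials[small_design.trials["run"] == 0]
            ),
            truth=ds.truth,
        )
        with pytest.raises(ValueError, match="2 runs"):
            crossval_reconstruct_timecourse(one_run, "location", trs=[10])

    def test_export_frame_schema(self, small_design):
        ds = simulate_subject(small_design, single_dim_config(noise_sd=0.5), seed=10)
        rec = crossval_reconstruct_timecourse(ds, "location", test_item="pmi", trs=[10])
        frame = rec.to_frame(subject=0, roi="EVC")
        assert list(frame.columns) == [
            "subject", "roi", "feature_dim", "item", "tr",
            "channel_offset_deg", "response",
        ]
        assert len(frame) == 9
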