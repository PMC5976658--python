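import numpy as np
import pandas as pd
import pytest

from emgsyn import EMGDataset, compute_vaf, fit_space_by_time
from emgsyn.decomposition import SpaceByTimeModel, match_components
from emgsyn.synthetic_data import make_ground_truth, synthesize_dataset


def _dataset_from_trials(trials):
    labels = pd.DataFrame(
        {"trial_id": range(len(trials)), "movement_id": range(len(trials))}
    )
    return EMGDataset(trials=np.asarray(trials, dtype=float), labels=labels)


class TestFit:
    def test_parameter_recovery_noiseless(self, design):
        truth = make_ground_truth(2, 2, T=20, M=10, seed=1, emg_noise_sd=0.0)
        ds = synthesize_dataset(truth, design, reps_per_movement=1, seed=2)
        fit = fit_space_by_time(ds.emg, 2, 2, restarts=8, max_iter=800,
                                tol=1e-10, seed=3)
        _, _, corr_t = match_components(truth.temporal_synergies, fit.model.W_t, axis=1)
        _, _, corr_s = match_components(truth.spatial_synergies, fit.model.W_s, axis=0)
        assert np.all(corr_t >= 0.95)
        assert np.all(corr_s >= 0.95)
        assert fit.vaf >= 0.999

    def test_rank1_identical_trials_vaf_one(self):
        rng = np.random.default_rng(4)
        base = np.outer(rng.uniform(size=6), rng.uniform(size=4))
        trials = np.stack([2.0 * base, 0.5 * base, base])
        fit = fit_space_by_time(_dataset_from_trials(trials), 1, 1,
                                restarts=4, max_iter=500, tol=1e-12, seed=5)
        assert fit.vaf == pytest.approx(1.0, abs=1e-6)

    def test_objective_monotone(self, small_dataset):
        fit = fit_space_by_time(small_dataset.emg, 2, 2, restarts=1,
                                max_iter=60, seed=6)
        trace = fit.objective_trace
        assert np.all(np.diff(trace) <= 1e-9 * np.maximum(trace[:-1], 1.0))

    def test_factors_non_negative_and_normalized(self, small_dataset):
        fit = fit_space_by_time(small_dataset.emg, 2, 2, restarts=2,
                                max_iter=80, seed=7)
        m = fit.model
        assert np.all(m.W_t >= 0) and np.all(m.W_s >= 0) and np.all(m.A >= 0)
        np.testing.assert_allclose(np.linalg.norm(m.W_t, axis=0), 1.0, rtol=1e-8)
        np.testing.assert_allclose(np.linalg.norm(m.W_s, axis=1), 1.0, rtol=1e-8)

    def test_best_of_restarts(self, small_dataset):
        # restart seeds are spawned from the master seed by counter, so a
        # single-restart run reproduces the first restart of a multi run
        single = fit_space_by_time(small_dataset.emg, 2, 2, restarts=1,
                                   max_iter=50, seed=0).model.objective
        multi = fit_space_by_time(small_dataset.emg, 2, 2, restarts=4,
                                  max_iter=50, seed=0).model.objective
        assert multi <= single + 1e-12

    def test_deterministic(self, small_dataset):
        a = fit_space_by_time(small_dataset.emg, 2, 2, restarts=2, max_iter=40, seed=9)
        b = fit_space_by_time(small_dataset.emg, 2, 2, restarts=2, max_iter=40, seed=9)
        np.testing.assert_array_equal(a.model.W_t, b.model.W_t)
        np.testing.assert_array_equal(a.model.A, b.model.A)

    def test_invalid_data_rejected(self):
        trials = np.ones((3, 4, 2))
        trials[0, 0, 0] = -1.0
        with pytest.raises(ValueError):
            fit_space_by_time(_dataset_from_trials(np.abs(trials) * np.nan), 1, 1)
        with pytest.raises(ValueError):
            fit_space_by_time(_dataset_from_trials(trials), 1, 1)

    def test_bad_shape_args_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            fit_space_by_time(small_dataset.emg, 0, 1)
        with pytest.raises(ValueError):
            fit_space_by_time(small_dataset.emg, 1, 99)

    def test_rank1_oracle_equivalence(self):
        # exhaustive alternating NNLS oracle on a single trial, many restarts
        rng = np.random.default_rng(11)
        trial = rng.uniform(size=(5, 4))
        from scipy.optimize import nnls

        best = np.inf
        for r in range(30):
            rr = np.random.default_rng(100 + r)
            w = rr.uniform(size=5)
            for _ in range(200):
                h = np.array([nnls(w[:, None], trial[:, j])[0][0] for j in range(4)])
                if np.all(h == 0):
                    break
                w = np.array([nnls(h[:, None], trial[i, :])[0][0] for i in range(5)])
            best = min(best, np.sum((trial - np.outer(w, h)) ** 2))
        fit = fit_space_by_time(_dataset_from_trials(trial[None]), 1, 1,
                                restarts=10, max_iter=800, tol=1e-13, seed=12)
        assert fit.model.objective == pytest.approx(best, rel=1e-4, abs=1e-10)


class TestVAF:
    def _hand_model(self):
        W_t = np.array([[1.0], [0.0]])
        W_s = np.array([[1.0, 0.0]])
        A = np.array([[[2.0]], [[1.0]]])
        return SpaceByTimeModel(W_t=W_t, W_s=W_s, A=A)

    def test_exact_reconstruction_is_one(self):
        model = self._hand_model()
        data = _dataset_from_trials(model.reconstruct())
        assert compute_vaf(model, data) == pytest.approx(1.0)

    def test_mean_reconstruction_is_zero(self):
        trials = np.array([[[1.0, 2.0], [3.0, 4.0]], [[5.0, 2.0], [1.0, 0.0]]])
        mean = trials.mean(axis=0)
        # model that reconstructs exactly the mean trial for every trial:
        # error term equals the variance term by definition
        class MeanModel(SpaceByTimeModel):
            def reconstruct(self):
                return np.stack([mean, mean])

        model = MeanModel(W_t=np.eye(2), W_s=np.eye(2), A=np.zeros((2, 2, 2)))
        assert compute_vaf(model, _dataset_from_trials(trials)) == pytest.approx(0.0)

    def test_hand_computed_fixture(self):
        # 2 trials of 2x2 matrices, hand-built model; independent arithmetic
        trials = np.array([[[2.0, 0.0], [0.0, 0.0]], [[1.0, 1.0], [0.0, 0.0]]])
        model = self._hand_model()  # reconstructs [[2,0],[0,0]] and [[1,0],[0,0]]
        recon = model.reconstruct()
        err = ((trials - recon) ** 2).sum()  # = 1.0 (the stray 1 at (0,1))
        mean = trials.mean(axis=0)
        var = ((trials - mean) ** 2).sum()  # = 2*(0.25+0.25) = 1.0
        expected = 1.0 - err / var
        assert err == 1.0 and var == 1.0
        assert compute_vaf(model, _dataset_from_trials(trials)) == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        model = self._hand_model()
        trials = np.ones((2, 2, 2))
        with pytest.raises(ValueError, match="variance"):
            compute_vaf(model, _dataset_from_trials(trials))

    def test_scale_invariance(self, small_dataset):
        # rescaling a synergy and inversely rescaling its coefficients
        # leaves reconstruction and VAF unchanged
        fit = fit_space_by_time(small_dataset.emg, 2, 2, restarts=1,
                                max_iter=60, seed=13)
        m = fit.model
        scaled = SpaceByTimeModel(
            W_t=m.W_t * np.array([2.0, 0.5]),
            W_s=m.W_s.copy(),
            A=m.A / np.array([2.0, 0.5])[None, :, None],
        )
        assert compute_vaf(scaled, small_dataset.emg) == pytest.approx(
            compute_vaf(m, small_dataset.emg), rel=1e-10
        )
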