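import numpy as np
import pytest

from emgsyn import compute_vaf
from emgsyn.decomposition import SpaceByTimeModel
from emgsyn.synthetic_data import (
    make_ground_truth,
    make_subject_variant,
    mean_gain_matrix,
    sample_trial_coefficients,
    synthesize_dataset,
)


class TestMakeGroundTruth:
    def test_bump_peaks_strictly_increasing(self):
        truth = make_ground_truth(4, 5, T=50, M=30, seed=1)
        peaks = truth.temporal_synergies.argmax(axis=0)
        assert np.all(np.diff(peaks) > 0)
        assert truth.temporal_synergies.shape == (50, 4)
        assert truth.spatial_synergies.shape == (5, 30)

    def test_non_negative(self):
        truth = make_ground_truth(3, 4, seed=2)
        assert np.all(truth.temporal_synergies >= 0)
        assert np.all(truth.spatial_synergies >= 0)
        for gains in truth.temporal_gains + truth.spatial_gains:
            assert all(g > 0 for g in gains.values())

    def test_deterministic(self):
        a = make_ground_truth(3, 3, seed=42)
        b = make_ground_truth(3, 3, seed=42)
        np.testing.assert_array_equal(a.temporal_synergies, b.temporal_synergies)
        np.testing.assert_array_equal(a.spatial_synergies, b.spatial_synergies)
        assert a.temporal_gains == b.temporal_gains

    def test_infeasible_shapes_rejected(self):
        with pytest.raises(ValueError):
            make_ground_truth(10, 3, T=15)  # T < 2K
        with pytest.raises(ValueError):
            make_ground_truth(2, 10, M=5)  # M < N
        with pytest.raises(ValueError):
            make_ground_truth(0, 1)

    def test_default_tuning_structure(self):
        truth = make_ground_truth(4, 6, seed=3)
        assert truth.temporal_tuning[0] == "start_target"
        assert truth.temporal_tuning[-1] == "end_target"
        assert all(p == "direction" for p in truth.temporal_tuning[1:-1])

    def test_gain_gap_configurable(self, design):
        truth = make_ground_truth(2, 2, seed=4, min_gain_gap=0.5)
        for gains in truth.temporal_gains:
            values = sorted(gains.values())
            assert min(np.diff(values)) >= 0.5 - 1e-12


class TestSampleCoefficients:
    def test_sigma_zero_equals_means(self, design):
        truth = make_ground_truth(2, 2, seed=5, coefficient_noise_sigma=0.0)
        movement = design.movement_record(10)
        A = sample_trial_coefficients(truth, movement, rng=0)
        np.testing.assert_allclose(A, mean_gain_matrix(truth, movement))

    def test_lognormal_moments(self, design):
        # Monte-Carlo: mean of log a_ij within 3 SE of log mean gain
        sigma = 0.2
        truth = make_ground_truth(2, 2, seed=6, coefficient_noise_sigma=sigma)
        movement = design.movement_record(1)
        rng = np.random.default_rng(99)
        n = 10_000
        draws = np.stack(
            [sample_trial_coefficients(truth, movement, rng) for _ in range(n)]
        )
        log_mean = np.log(draws).mean(axis=0)
        se = sigma / np.sqrt(n)
        expected = np.log(mean_gain_matrix(truth, movement))
        assert np.all(np.abs(log_mean - expected) < 3 * se)

    def test_end_target_tuning_isolated(self, design):
        # two movements sharing every tuned parameter except end target:
        # T7->T1 and T7->T4 (same start, direction US, same end bar)
        truth = make_ground_truth(
            2, 2, seed=7, coefficient_noise_sigma=0.0,
            temporal_tuning=("start_target", "end_target"),
            spatial_tuning=("start_height", "start_bar"),
        )
        table = design.parameter_table
        rec_a = table[(table.start_target == 7) & (table.end_target == 1)].iloc[0].to_dict()
        rec_b = table[(table.start_target == 7) & (table.end_target == 4)].iloc[0].to_dict()
        A_a = sample_trial_coefficients(truth, rec_a, rng=0)
        A_b = sample_trial_coefficients(truth, rec_b, rng=0)
        # only the end-target-tuned temporal synergy (row 1) changes
        np.testing.assert_allclose(A_a[0], A_b[0])
        assert np.all(A_a[1] != A_b[1])


class TestSynthesizeDataset:
    def test_trial_count_full_protocol(self, design):
        truth = make_ground_truth(2, 2, T=10, M=4, seed=8)
        ds = synthesize_dataset(truth, design, reps_per_movement=30, seed=9)
        assert ds.emg.L == 2160

    def test_non_negative(self, small_dataset):
        assert np.all(small_dataset.emg.trials >= 0)

    def test_noiseless_trials_exactly_factorizable(self, small_truth, design):
        # with zero EMG noise every trial lies exactly in the planted
        # model's span: least-squares coefficients reconstruct it to
        # floating precision
        truth = small_truth
        ds = synthesize_dataset(truth, design, reps_per_movement=1, seed=3)
        Wt, Ws = truth.temporal_synergies, truth.spatial_synergies
        G = np.kron(Ws.T, Wt)  # maps vec(A) -> vec(trial)
        recon_err = []
        for trial in ds.emg.trials:
            coeff, *_ = np.linalg.lstsq(G, trial.ravel(order="F"), rcond=None)
            A_l = coeff.reshape((truth.K, truth.N), order="F")
            recon_err.append(np.sum((Wt @ A_l @ Ws - trial) ** 2))
        assert max(recon_err) < 1e-18

    def test_planted_model_vaf_one(self, design):
        truth = make_ground_truth(2, 2, T=12, M=6, seed=11, emg_noise_sd=0.0)
        ds = synthesize_dataset(truth, design, reps_per_movement=1, seed=13)
        Wt, Ws = truth.temporal_synergies, truth.spatial_synergies
        G = np.kron(Ws.T, Wt)
        A = np.stack([
            np.linalg.lstsq(G, trial.ravel(order="F"), rcond=None)[0]
            .reshape((truth.K, truth.N), order="F")
            for trial in ds.emg.trials
        ])
        model = SpaceByTimeModel(W_t=Wt, W_s=Ws, A=A)
        assert compute_vaf(model, ds.emg) == pytest.approx(1.0, abs=1e-9)

    def test_determinism(self, design):
        truth = make_ground_truth(2, 2, T=10, M=4, seed=1)
        a = synthesize_dataset(truth, design, reps_per_movement=1, seed=5)
        b = synthesize_dataset(truth, design, reps_per_movement=1, seed=5)
        np.testing.assert_array_equal(a.emg.trials, b.emg.trials)
        assert a.emg.labels.equals(b.emg.labels)

    def test_labels_aligned(self, small_dataset, design):
        labels = small_dataset.emg.labels
        assert list(labels["trial_id"]) == list(range(small_dataset.emg.L))
        # every movement appears reps times
        assert (labels["movement_id"].value_counts() == 2).all()

    def test_reps_validated(self, small_truth, design):
        with pytest.raises(ValueError):
            synthesize_dataset(small_truth, design, reps_per_movement=0, seed=1)

    def test_raw_traces_attached(self, design):
        truth = make_ground_truth(2, 2, T=10, M=3, seed=2)
        ds = synthesize_dataset(
            truth, design, reps_per_movement=1, seed=2,
            raw_traces=True, sampling_rate=500.0,
        )
        assert ds.raw_traces is not None and len(ds.raw_traces) == 72
        trace = ds.raw_traces[0]
        assert trace["emg"].shape[1] == 3
        assert trace["speed"].max() > 0
        assert abs(trace["emg"].mean()) < 0.05  # zero-mean carrier


def test_subject_variant_keeps_tuning(design):
    truth = make_ground_truth(3, 3, seed=30)
    variant = make_subject_variant(truth, seed=31)
    assert variant.temporal_tuning == truth.temporal_tuning
    assert variant.spatial_tuning == truth.spatial_tuning
    assert variant.spatial_gains == truth.spatial_gains
    np.testing.assert_array_equal(
        variant.temporal_synergies, truth.temporal_synergies
    )
    assert not np.allclose(variant.spatial_synergies, truth.spatial_synergies)
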