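import numpy as np
import pytest

from vitalwatch.agrnn import (
    AutoencoderModel,
    DetectorConfig,
    DetectorModel,
    Genome,
    RNNModel,
    TrainingError,
    agrnn_fit,
    autoencoder_fit,
    detect,
    ga_optimize,
    reconstruction_loss,
    rnn_forward,
    rnn_gradients,
    rnn_train,
    window_labels,
)
from vitalwatch.frames import ValidationError
from vitalwatch.synthgen import (
    AnomalySpec,
    ChannelSpec,
    LabelledStream,
    generate_baseline,
    inject_anomalies,
)

TINY = DetectorConfig(
    window=8,
    stride=4,
    xcorr_pairs=(),
    ae_epochs=150,
    ga_population=4,
    ga_generations=2,
    ga_rnn_epochs=5,
    rnn_hidden=4,
    rnn_epochs=30,
    detrend_process_var=1e-6,
)


def tiny_stream(n=1200, seed=0):
    specs = [
        ChannelSpec("heart_rate", 74.0, 1.5, ar_coefficient=0.6),
        ChannelSpec("spo2", 98.0, 0.4, ar_coefficient=0.5),
    ]
    frame = generate_baseline(specs, n, seed=seed)
    return LabelledStream(frame, np.zeros(n, dtype=int), [])


def linear_ae(enc, dec):
    enc = np.asarray(enc, dtype=float)
    dec = np.asarray(dec, dtype=float)
    return AutoencoderModel(enc, np.zeros(enc.shape[1]), dec, np.zeros(dec.shape[1]),
                            activation="linear")


class TestReconstructionLoss:
    def test_perfect_reconstruction_is_zero(self):
        ae = linear_ae([[1.0], [0.0]], [[1.0, 0.0]])
        batch = np.array([[3.0, 0.0]])
        assert reconstruction_loss(batch, ae) == pytest.approx(0.0)

    def test_single_sample_hand_example(self):
        # target [1, 2] reconstructed as [0, 0] -> squared norm 5
        ae = linear_ae(np.zeros((2, 1)), np.zeros((1, 2)))
        assert reconstruction_loss(np.array([[1.0, 2.0]]), ae) == pytest.approx(5.0)

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(0)
        ae = linear_ae(rng.normal(size=(3, 2)), rng.normal(size=(2, 3)))
        batch = rng.normal(size=(6, 3))
        assert reconstruction_loss(batch, ae) == pytest.approx(
            reconstruction_loss(batch[::-1], ae)
        )

    def test_empty_batch_rejected(self):
        ae = linear_ae(np.zeros((2, 1)), np.zeros((1, 2)))
        with pytest.raises(ValidationError):
            reconstruction_loss(np.empty((0, 2)), ae)


class TestAutoencoderFit:
    def test_linear_ae_recovers_low_rank_structure(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 2)) @ rng.normal(size=(2, 6))
        _, curve = autoencoder_fit(X, bottleneck=3, epochs=2000, seed=1,
                                   activation="linear")
        assert curve[-1] < 1e-4

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValidationError):
            autoencoder_fit(np.zeros((4, 3)), bottleneck=1, epochs=0)

    def test_training_reduces_the_loss(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 5))
        _, curve = autoencoder_fit(X, bottleneck=2, epochs=200, seed=0)
        assert curve[-1] <= curve[0]

    def test_seeded_initialisation_is_reproducible(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4))
        a, _ = autoencoder_fit(X, bottleneck=2, epochs=10, seed=5)
        b, _ = autoencoder_fit(X, bottleneck=2, epochs=10, seed=5)
        np.testing.assert_array_equal(a.enc_weight, b.enc_weight)


class TestGeneticAlgorithm:
    def test_finds_all_ones_mask_for_bit_count_fitness(self):
        best, _ = ga_optimize(
            lambda g: float(sum(g.feature_mask)),
            population=20, generations=30, seed=0, n_bits=5, vary_scalars=False,
        )
        assert all(best.feature_mask)

    def test_no_variation_leaves_identical_population_unchanged(self):
        genome = Genome((True, False, True), 0.98, 1.0)
        best, history = ga_optimize(
            lambda g: 1.0,
            population=4, generations=5,
            crossover_rate=0.0, mutation_rate=0.0, seed=0,
            init_population=[genome] * 4,
        )
        assert best.feature_mask == genome.feature_mask
        assert history.best_fitness == [1.0] * 5

    def test_best_fitness_history_is_nondecreasing_under_elitism(self):
        rng_table = np.random.default_rng(9).normal(size=256)

        def fitness(g):
            return float(rng_table[int(sum(b << i for i, b in enumerate(g.feature_mask)))])

        _, history = ga_optimize(fitness, population=10, generations=25, seed=2, n_bits=8)
        assert np.all(np.diff(history.best_fitness) >= 0)

    def test_non_finite_fitness_genomes_are_discarded(self):
        def fitness(g):
            return float("nan") if g.feature_mask[0] else float(sum(g.feature_mask))

        best, _ = ga_optimize(fitness, population=20, generations=20, seed=1,
                              n_bits=4, vary_scalars=False)
        assert not best.feature_mask[0]

    def test_all_non_finite_raises(self):
        with pytest.raises(TrainingError):
            ga_optimize(lambda g: float("inf") * 0, population=4, generations=2,
                        seed=0, n_bits=3)

    def test_genome_invariants(self):
        with pytest.raises(ValidationError):
            Genome((False, False))
        with pytest.raises(ValidationError):
            Genome((True,), threshold_quantile=0.4)
        with pytest.raises(ValidationError):
            Genome((True,), rnn_hidden_scale=0.0)


class TestRecurrentNet:
    def scalar_model(self):
        return RNNModel([[1.0]], [[0.5]], [[2.0]])

    def test_scalar_worked_example(self):
        hidden, outputs = rnn_forward(np.array([[1.0], [0.0]]), self.scalar_model())
        np.testing.assert_allclose(hidden.ravel(), [0.7616, 0.3634], atol=1e-4)
        np.testing.assert_allclose(outputs.ravel(), [1.5232, 0.7268], atol=1e-4)

    def test_zero_weights_give_zero_outputs(self):
        model = RNNModel(np.zeros((2, 3)), np.zeros((2, 2)), np.zeros((3, 2)))
        _, outputs = rnn_forward(np.ones((4, 3)), model)
        np.testing.assert_array_equal(outputs, np.zeros((4, 3)))

    def test_zero_recurrence_is_memoryless(self):
        model = RNNModel([[0.8]], [[0.0]], [[1.0]])
        _, out_a = rnn_forward(np.array([[5.0], [1.0]]), model)
        _, out_b = rnn_forward(np.array([[-3.0], [1.0]]), model)
        assert out_a[1, 0] == pytest.approx(out_b[1, 0])

    def test_bptt_gradient_matches_finite_differences(self):
        model = RNNModel([[0.7]], [[0.3]], [[1.1]])
        seq = np.array([[0.5], [0.2], [-0.3], [0.8]])
        _, grads = rnn_gradients(seq, model)
        eps = 1e-6
        for name in ("input_map", "recurrence", "readout"):
            kwargs = {
                "input_map": model.input_map.copy(),
                "recurrence": model.recurrence.copy(),
                "readout": model.readout.copy(),
            }
            kwargs[name] = kwargs[name] + eps
            lp, _ = rnn_gradients(seq, RNNModel(**kwargs))
            kwargs[name] = kwargs[name] - 2 * eps
            lm, _ = rnn_gradients(seq, RNNModel(**kwargs))
            numeric = (lp - lm) / (2 * eps)
            assert abs(numeric - grads[name][0, 0]) / (abs(numeric) + 1e-12) < 1e-5

    def test_constant_sequence_is_learned_to_low_loss(self):
        seq = np.full((60, 1), 3.0)
        _, curve = rnn_train(seq, hidden=4, epochs=400, learning_rate=0.02, seed=0)
        assert curve[-1] < 1e-3

    def test_zero_learning_rate_leaves_weights_unchanged(self):
        rng = np.random.default_rng(0)
        seq = rng.normal(size=(20, 2))
        a, _ = rnn_train(seq, hidden=3, epochs=5, learning_rate=0.0, seed=4)
        b, _ = rnn_train(seq, hidden=3, epochs=1, learning_rate=0.0, seed=4)
        np.testing.assert_array_equal(a.input_map, b.input_map)

    def test_training_reduces_loss(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 8 * np.pi, 200)
        seq = np.sin(t)[:, None]
        _, curve = rnn_train(seq, hidden=6, epochs=150, seed=0)
        assert curve[-1] <= curve[0]

    def test_spectral_radius_is_reported(self):
        model = RNNModel([[1.0]], [[1.5]], [[1.0]])
        assert model.spectral_radius == pytest.approx(1.5)


class TestDetectorPipeline:
    def test_same_seed_gives_identical_serialized_models(self, tmp_path):
        stream = tiny_stream()
        a = agrnn_fit(stream, TINY, seed=3)
        b = agrnn_fit(stream, TINY, seed=3)
        a.to_json(tmp_path / "a.json")
        b.to_json(tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_model_round_trips_through_json(self, tmp_path):
        model = agrnn_fit(tiny_stream(), TINY, seed=1)
        model.to_json(tmp_path / "m.json")
        back = DetectorModel.from_json(tmp_path / "m.json")
        assert back.score_threshold == model.score_threshold
        np.testing.assert_array_equal(back.rnn.input_map, model.rnn.input_map)
        rep_a = detect(tiny_stream(seed=8).frame, model)
        rep_b = detect(tiny_stream(seed=8).frame, back)
        np.testing.assert_array_equal(rep_a.scores, rep_b.scores)

    def test_threshold_is_the_stated_quantile_of_calibration_scores(self):
        model = agrnn_fit(tiny_stream(), TINY, seed=2)
        expected = np.quantile(model.calibration_scores, model.genome.threshold_quantile)
        assert model.score_threshold == pytest.approx(expected, abs=1e-9)

    def test_training_with_labelled_anomalies_rejected(self):
        stream = tiny_stream()
        stream.labels[5] = 1
        with pytest.raises(ValidationError):
            agrnn_fit(stream, TINY, seed=0)

    def test_flagged_fraction_on_training_stream_matches_quantile(self):
        stream = tiny_stream()
        model = agrnn_fit(stream, TINY, seed=4)
        report = detect(stream.frame, model)
        expected = 1.0 - model.genome.threshold_quantile
        assert abs(report.flagged_fraction - expected) <= 0.03

    def test_large_spike_on_training_stream_is_flagged(self):
        stream = tiny_stream()
        model = agrnn_fit(stream, TINY, seed=5)
        spiked = inject_anomalies(
            stream.frame, [AnomalySpec("spike", "heart_rate", 600, 1, 10 * 1.5)]
        )
        report = detect(spiked.frame, model)
        truth = window_labels(spiked.labels, report.window_spans)
        assert report.flags[truth == 1].any()

    def test_schema_mismatch_lists_missing_channels(self):
        model = agrnn_fit(tiny_stream(), TINY, seed=6)
        other = generate_baseline(
            [ChannelSpec("heart_rate", 74.0, 1.5, ar_coefficient=0.6)], 600, seed=0
        )
        with pytest.raises(ValidationError, match="spo2"):
            detect(other, model)

    def test_detection_report_exports_csv(self, tmp_path):
        stream = tiny_stream()
        model = agrnn_fit(stream, TINY, seed=7)
        report = detect(stream.frame, model)
        report.to_csv(tmp_path / "r.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "r.csv")
        assert list(df.columns) == [
            "window_start", "window_end", "score", "flag", "contributing_channel"
        ]
        assert len(df) == len(report.window_spans)
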