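"""Classifier training, HMM estimation, smoothing and event evaluation."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from sklearn.metrics import balanced_accuracy_score

import epikit as ek

from conftest import make_session


def brute_force_posteriors(obs, A, B, pi):
    """Exhaustive path-sum marginals: the oracle for forward-backward."""
    n = len(obs)
    post = np.zeros((n, 2))
    for path in itertools.product((0, 1), repeat=n):
        p = pi[path[0]] * B[path[0], obs[0]]
        for t in range(1, n):
            p *= A[path[t - 1], path[t]] * B[path[t], obs[t]]
        for t in range(n):
            post[t, path[t]] += p
    return post / post.sum(axis=1, keepdims=True)


class TestForwardBackward:
    def test_single_obs_perfect_emission(self):
        hmm = ek.HmmParameters(A=np.eye(2), B=np.eye(2), pi=[0.5, 0.5])
        gamma = ek.forward_backward(np.array([1]), hmm)
        assert gamma[0, 1] == pytest.approx(1.0)

    def test_uninformative_model_gives_uniform(self):
        """Uniform A and B: the prior washes out after the first step."""
        hmm = ek.HmmParameters(
            A=np.full((2, 2), 0.5), B=np.full((2, 2), 0.5), pi=[0.3, 0.7]
        )
        gamma = ek.forward_backward(np.array([0, 1, 1, 0, 1]), hmm)
        assert np.allclose(gamma[0], [0.3, 0.7])  # uninformative obs: gamma_1 = pi
        assert np.allclose(gamma[1:], 0.5)

    def test_matches_brute_force_enumeration(self):
        """All sequences up to length 8 against exhaustive path summation."""
        rng = np.random.default_rng(42)
        for _ in range(3):
            A = rng.dirichlet((2.0, 2.0), size=2)
            B = rng.dirichlet((2.0, 2.0), size=2)
            pi = rng.dirichlet((2.0, 2.0))
            hmm = ek.HmmParameters(A=A, B=B, pi=pi)
            for n in range(1, 9):
                for obs in itertools.product((0, 1), repeat=n):
                    got = ek.forward_backward(np.array(obs), hmm)
                    want = brute_force_posteriors(obs, A, B, pi)
                    assert np.abs(got - want).max() < 1e-10

    def test_long_sequence_stays_normalized(self):
        rng = np.random.default_rng(0)
        obs = rng.integers(0, 2, 1_000_000)
        hmm = ek.HmmParameters(
            A=[[0.999, 0.001], [0.05, 0.95]],
            B=[[0.98, 0.02], [0.1, 0.9]],
            pi=[0.99, 0.01],
        )
        gamma = ek.forward_backward(obs, hmm)
        assert np.all(np.isfinite(gamma))
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-12)

    def test_identity_emissions_reproduce_observations(self):
        """With B = I the smoothed labels equal the raw classifier labels."""
        hmm = ek.HmmParameters(
            A=[[0.9, 0.1], [0.2, 0.8]], B=np.eye(2), pi=[0.5, 0.5]
        )
        obs = np.array([0, 0, 1, 1, 0, 1, 0, 0])
        gamma = ek.forward_backward(obs, hmm)
        assert np.array_equal((gamma[:, 1] >= 0.5).astype(int), obs)

    def test_invalid_observation_rejected(self):
        hmm = ek.HmmParameters(A=np.eye(2), B=np.eye(2), pi=[0.5, 0.5])
        with pytest.raises(ValueError):
            ek.forward_backward(np.array([0, 2]), hmm)


class TestEstimateHmm:
    def test_transition_counts_without_smoothing(self):
        seqs = [np.array([0, 0, 1, 0, 0, 1, 0])]  # no ictal->ictal transition
        hmm = ek.estimate_hmm(seqs, seqs, smoothing=0.0)
        assert hmm.A[1, 1] == 0.0

    def test_perfect_predictions_give_identity_emissions(self):
        seqs = [np.array([0, 1, 0, 1, 1, 0])]
        hmm = ek.estimate_hmm(seqs, seqs, smoothing=0.0)
        assert np.array_equal(hmm.B, np.eye(2))

    def test_parameter_recovery_from_simulated_chain(self):
        """A and B recovered within 0.01 from a 1e5-step two-state chain."""
        rng = np.random.default_rng(7)
        A = np.array([[0.95, 0.05], [0.3, 0.7]])
        B = np.array([[0.9, 0.1], [0.2, 0.8]])
        n = 100_000
        states = np.empty(n, dtype=int)
        states[0] = 0
        u = rng.random(n)
        for t in range(1, n):
            states[t] = int(u[t] < A[states[t - 1], 1])
        obs = (rng.random(n) < B[states, 1]).astype(int)
        hmm = ek.estimate_hmm([states], [obs], smoothing=1.0)
        assert np.abs(hmm.A - A).max() < 0.01
        assert np.abs(hmm.B - B).max() < 0.01

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ek.estimate_hmm([], [])


class TestTrainClassifier:
    def test_separable_library_high_balanced_accuracy(self, training_library):
        _, cv_pred = ek.train_classifier(training_library, seed=0)
        y = training_library.all_labels()
        assert balanced_accuracy_score(y, cv_pred) >= 0.95

    def test_shuffled_labels_give_chance_accuracy(self, training_library):
        import copy

        lib = copy.copy(training_library)
        rng = np.random.default_rng(0)
        lib.chunk_labels = [rng.permutation(l) for l in training_library.chunk_labels]
        lib.feature_matrix = training_library.feature_matrix
        _, cv_pred = ek.train_classifier(lib, seed=0)
        y = lib.all_labels()
        assert 0.4 <= balanced_accuracy_score(y, cv_pred) <= 0.6

    def test_same_seed_reproduces_predictions(self, training_library):
        _, p1 = ek.train_classifier(training_library, seed=3)
        _, p2 = ek.train_classifier(training_library, seed=3)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        rec, _ = make_session(100, duration_s=600.0, n_seizures=0)
        lib = ek.build_library(
            [("a", rec, ek.AnnotationSet())], include_seizure_free=("a",)
        )
        with pytest.raises(ValueError, match="both"):
            ek.train_classifier(lib)


class TestDetectAndEvaluate:
    def test_negative_control_no_events(self, trained_detector):
        model, hmm = trained_detector
        rec, _ = make_session(900, duration_s=600.0, n_seizures=0)
        res = ek.detect(rec, model, hmm)
        metrics = ek.evaluate(res, ek.AnnotationSet(), rec.duration_s)
        assert res.events == []
        assert metrics.false_positives_per_day == 0.0
        assert metrics.false_negative_rate is None  # no true seizures

    def test_event_boundaries_on_chunk_grid(self, trained_detector):
        model, hmm = trained_detector
        rec, _ = make_session(901, duration_s=600.0)
        res = ek.detect(rec, model, hmm)
        assert res.events
        for s, e in res.events:
            assert s % model.chunk_s == 0 and e % model.chunk_s == 0

    def test_every_detected_event_accounted_for(self, trained_detector):
        model, hmm = trained_detector
        rec, ann = make_session(902, duration_s=600.0)
        res = ek.detect(rec, model, hmm)
        m = ek.evaluate(res, ann, rec.duration_s)
        overlapping = sum(
            1 for d in res.events
            if any(d[0] < e and d[1] > s for s, e in ann.ictal_intervals())
        )
        assert overlapping + m.n_false_positive_events == len(res.events)

    def test_fs_mismatch_rejected(self, trained_detector):
        model, hmm = trained_detector
        rec = ek.EcogRecording(samples=np.zeros(1000) + 1e-9, fs=512.0)
        rec.samples[0] = 1.0
        with pytest.raises(ValueError, match="fs"):
            ek.detect(rec, model, hmm)

    def test_perfect_detections_score_perfectly(self):
        truth = ek.AnnotationSet(
            intervals=[(10.0, 30.0, ek.ICTAL), (100.0, 130.0, ek.ICTAL)]
        )
        m = ek.evaluate(truth.ictal_intervals(), truth, 3600.0)
        assert m.sensitivity == 1.0
        assert m.false_negative_rate == 0.0
        assert m.false_positives_per_day == 0.0

    def test_one_missed_in_300(self):
        truth = ek.AnnotationSet(
            intervals=[(i * 100.0, i * 100.0 + 30.0, ek.ICTAL) for i in range(300)]
        )
        detections = truth.ictal_intervals()[:-1]
        m = ek.evaluate(detections, truth, 300 * 100.0)
        assert m.false_negative_rate == pytest.approx(1 / 300)

    def test_metrics_match_quadratic_overlap_oracle(self, trained_detector):
        model, hmm = trained_detector
        rec, ann = make_session(903, duration_s=600.0)
        res = ek.detect(rec, model, hmm)
        m = ek.evaluate(res, ann, rec.duration_s)
        true_events = ann.ictal_intervals()
        detected = 0
        for t in true_events:
            hit = False
            for d in res.events:
                if max(t[0], d[0]) < min(t[1], d[1]):
                    hit = True
            detected += hit
        fp = 0
        for d in res.events:
            hit = False
            for t in true_events:
                if max(t[0], d[0]) < min(t[1], d[1]):
                    hit = True
            fp += not hit
        assert m.n_detected_true == detected
        assert m.n_false_positive_events == fp


class TestReviewRoundTrip:
    @pytest.fixture()
    def result(self, trained_detector):
        model, hmm = trained_detector
        rec, _ = make_session(904, duration_s=600.0)
        return ek.detect(rec, model, hmm)

    def test_accept_all_reproduces_events(self, result, tmp_path):
        path = tmp_path / "review.csv"
        ek.export_for_review(result, path)
        back = ek.import_review(path)
        assert back.provenance == "verified"
        assert [(s, e) for s, e, _ in back.intervals] == result.events

    def test_rejected_row_absent(self, result, tmp_path):
        import pandas as pd

        path = tmp_path / "review.csv"
        ek.export_for_review(result, path)
        df = pd.read_csv(path)
        df.loc[0, "accept"] = "no"
        df.to_csv(path, index=False)
        back = ek.import_review(path)
        assert len(back.intervals) == len(result.events) - 1

    def test_boundary_override_preserved(self, result, tmp_path):
        import pandas as pd

        path = tmp_path / "review.csv"
        ek.export_for_review(result, path)
        df = pd.read_csv(path)
        df.loc[0, "new_start_s"] = 12.3  # human override off the 5-s grid
        df.to_csv(path, index=False)
        back = ek.import_review(path)
        assert back.intervals[0][0] == 12.3

    def test_malformed_edit_reports_line(self, result, tmp_path):
        import pandas as pd

        path = tmp_path / "review.csv"
        ek.export_for_review(result, path)
        df = pd.read_csv(path)
        df.loc[1, "accept"] = "maybe"
        df.to_csv(path, index=False)
        with pytest.raises(ek.ReviewFormatError, match="line 3"):
            ek.import_review(path)
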