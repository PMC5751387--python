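import numpy as np
import pytest

from adaptref.evaluation import (
    cca_ssvep_classify,
    confusion_metrics,
    idx_metric,
    max_canonical_corr,
    recognition_timing,
    tune_and_classify,
)


def labels_from_cm(cm):
    y_true, y_pred = [], []
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            y_true += [i] * int(cm[i, j])
            y_pred += [j] * int(cm[i, j])
    return np.array(y_true), np.array(y_pred)


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics(np.diag([5, 7, 3]))
        assert m.acc == 1.0 and m.kappa == pytest.approx(1.0)
        assert np.all(m.pnm == 1.0) and m.fpr_max == 0.0
        assert idx_metric(m) == pytest.approx(0.0)

    def test_fully_wrong_two_class(self):
        m = confusion_metrics([[0, 10], [10, 0]])
        assert m.pnm == pytest.approx([-1.0, -1.0])
        assert m.acc == 0.0

    def test_hand_worked_example(self):
        m = confusion_metrics([[8, 2], [3, 7]])
        assert m.acc == pytest.approx(0.75)
        assert m.pnm[0] == pytest.approx(11 / 21)

    def test_worthless_symmetric_classifier_idx(self):
        m = confusion_metrics([[5, 5], [5, 5]])
        assert m.kappa == pytest.approx(0.0)
        assert m.acc == pytest.approx(0.5)
        assert idx_metric(m) == pytest.approx(0.775)  # FPR_max = 0.5 here

    def test_idx_direct_substitution(self):
        from dataclasses import replace

        # component values substituted directly into the weighted loss
        m = confusion_metrics([[5, 5], [5, 5]])
        m = replace(m, kappa=0.0, fpr_max=1.0, pnm_min=0.0)
        assert idx_metric(m) == pytest.approx(0.925)

    def test_idx_improves_with_each_component(self):
        base = confusion_metrics([[8, 2], [3, 7]])
        base.idx = idx_metric(base)
        better = confusion_metrics([[9, 1], [3, 7]])
        assert idx_metric(better) < base.idx

    def test_against_sklearn_on_random_matrices(self, rng):
        from sklearn.metrics import (
            accuracy_score,
            cohen_kappa_score,
            f1_score,
            recall_score,
        )

        for _ in range(300):
            k = int(rng.integers(2, 5))
            cm = rng.integers(0, 12, size=(k, k)).astype(float)
            if cm.sum() == 0 or np.any(cm.sum(axis=1) == 0):
                continue
            m = confusion_metrics(cm)
            yt, yp = labels_from_cm(cm)
            assert m.acc == pytest.approx(accuracy_score(yt, yp), abs=1e-10)
            assert m.tpr == pytest.approx(
                recall_score(yt, yp, labels=range(k), average=None,
                             zero_division=0), abs=1e-10
            )
            assert m.f1 == pytest.approx(
                f1_score(yt, yp, labels=range(k), average=None, zero_division=0),
                abs=1e-10,
            )
            if len(set(yt) | set(yp)) > 1:
                assert m.kappa == pytest.approx(
                    cohen_kappa_score(yt, yp), abs=1e-10
                )

    def test_pnm_brute_force(self, rng):
        for _ in range(500):
            k = int(rng.integers(2, 6))
            cm = rng.integers(0, 20, size=(k, k)).astype(float)
            if cm.sum() == 0:
                continue
            m = confusion_metrics(cm)
            for i in range(k):
                row = cm[i].sum()
                col = cm[:, i].sum()
                if row + col == 0:
                    continue
                fn = row - cm[i, i]
                fp = col - cm[i, i]
                expect = ((cm[i, i] - fn) + (cm[i, i] - fp)) / (row + col)
                assert m.pnm[i] == pytest.approx(expect, abs=1e-10)
                assert -1.0 - 1e-12 <= m.pnm[i] <= 1.0 + 1e-12

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(np.zeros((2, 2)))


class TestTuneAndClassify:
    def test_separable_clouds_perfect_and_smallest_c(self, rng):
        X0 = rng.standard_normal((60, 3)) + 8
        X1 = rng.standard_normal((60, 3)) - 8
        X = np.vstack([X0, X1])
        y = np.array([0] * 60 + [1] * 60)
        Xt = np.vstack([rng.standard_normal((20, 3)) + 8,
                        rng.standard_normal((20, 3)) - 8])
        yt = np.array([0] * 20 + [1] * 20)
        pred, c, table = tune_and_classify(X, y, Xt, seed=0)
        assert np.mean(pred == yt) == 1.0
        assert c == 0.01  # all C tie at Idx 0; smallest wins
        assert set(table) == {0.01, 0.05, 0.1, 1.0, 5.0, 10.0}

    def test_deterministic_choice(self, rng):
        X = rng.standard_normal((80, 4))
        y = (X[:, 0] + rng.standard_normal(80) > 0).astype(int)
        _, c1, _ = tune_and_classify(X, y, X[:5], seed=9)
        _, c2, _ = tune_and_classify(X, y, X[:5], seed=9)
        assert c1 == c2

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((20, 2))
        with pytest.raises(ValueError, match="2 classes"):
            tune_and_classify(X, np.zeros(20), X)


class TestCcaSsvep:
    def test_noiseless_sinusoid_recognized(self):
        fs = 250.0
        t = np.arange(int(2 * fs)) / fs
        ep = np.vstack([np.sin(2 * np.pi * 10 * t), np.cos(2 * np.pi * 10 * t)])
        pred, corrs = cca_ssvep_classify(ep, [8.0, 10.0, 12.0], fs)
        assert pred == 10.0
        assert corrs[1] == pytest.approx(1.0, abs=1e-6)

    def test_harmonic_does_not_change_prediction(self, rng):
        fs = 250.0
        t = np.arange(int(2 * fs)) / fs
        base = np.sin(2 * np.pi * 9.4 * t) + 0.2 * rng.standard_normal(t.size)
        with_h = base + 0.5 * np.sin(2 * np.pi * 18.8 * t)
        cands = np.arange(8.0, 15.81, 0.2)
        p1, _ = cca_ssvep_classify(base[None, :], cands, fs)
        p2, _ = cca_ssvep_classify(with_h[None, :], cands, fs)
        assert p1 == pytest.approx(9.4) and p2 == pytest.approx(9.4)

    def test_scale_and_offset_invariance(self, rng):
        fs = 250.0
        t = np.arange(int(1.5 * fs)) / fs
        ep = np.vstack([
            np.sin(2 * np.pi * 12 * t) + 0.3 * rng.standard_normal(t.size),
            np.sin(2 * np.pi * 12 * t + 0.4) + 0.3 * rng.standard_normal(t.size),
        ])
        _, c1 = cca_ssvep_classify(ep, [10.0, 12.0, 14.0], fs)
        _, c2 = cca_ssvep_classify(5 * ep + 100.0, [10.0, 12.0, 14.0], fs)
        assert c1 == pytest.approx(c2, abs=1e-9)

    def test_noisy_epochs_mostly_recognized(self, rng):
        fs, dur = 250.0, 3.0
        t = np.arange(int(dur * fs)) / fs
        cands = np.round(np.arange(8.0, 15.81, 0.2), 1)
        hits = 0
        n_ep = 25
        for i in range(n_ep):
            f = float(rng.choice(cands))
            sig = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            ep = np.vstack([
                sig + rng.standard_normal(t.size),      # ~0 dB per channel
                0.8 * sig + rng.standard_normal(t.size),
                0.9 * sig + rng.standard_normal(t.size),
            ])
            pred, _ = cca_ssvep_classify(ep, cands, fs)
            hits += np.isclose(pred, f)
        assert hits / n_ep >= 0.9

    def test_max_canonical_corr_bounds(self, rng):
        X = rng.standard_normal((100, 3))
        r = max_canonical_corr(X, X @ rng.standard_normal((3, 2)))
        assert r == pytest.approx(1.0, abs=1e-9)
        r2 = max_canonical_corr(X, rng.standard_normal((100, 2)))
        assert 0.0 <= r2 <= 1.0


class TestRecognitionTiming:
    def test_always_planning_stream(self):
        fs = 400.0
        res = recognition_timing(np.ones(600), fs)
        assert not res.failed
        # persistence completes 35 samples (87.5 ms) after the interval start
        assert res.latency_ms == pytest.approx(-1500.0 + 87.5)
        assert res.run_min_ms == pytest.approx(1500.0)
        assert res.run_max_ms == pytest.approx(1500.0)

    def test_short_burst_fails_cycle(self):
        fs = 400.0
        stream = np.zeros(600)
        stream[100:120] = 1  # 50 ms burst, below the 88 ms rule
        res = recognition_timing(stream, fs)
        assert res.failed and res.latency_ms is None

    def test_alternating_runs(self):
        fs = 400.0
        block = [1] * 40 + [0] * 40  # 100 ms planning / 100 ms rest
        stream = np.array(block * 7 + [1] * 40)
        res = recognition_timing(stream, fs)
        assert not res.failed
        assert res.run_max_ms == pytest.approx(100.0)
        assert res.run_min_ms == pytest.approx(100.0)
        assert res.latency_ms == pytest.approx(-1500.0 + 87.5)

    def test_latency_of_delayed_onset(self):
        fs = 400.0
        stream = np.zeros(600)
        stream[200:] = 1
        res = recognition_timing(stream, fs)
        assert res.latency_ms == pytest.approx(-1500.0 + (200 + 35) * 2.5)
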