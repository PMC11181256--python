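import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_auc

from eustex.evaluation import (
    ConfusionCounts,
    ReaderResult,
    compare_accuracy_chi2,
    confusion_from_cv,
    confusion_metrics,
    delong_paired,
    reader_table,
    roc_auc,
    round_half_up,
)

# Reader-study counts (six endoscopists, 59 GISTs / 61 non-GISTs) and the
# classifier's per-combination counts, with their published percentages.
READER_ROWS = [
    ("Experienced 1", 38, 46, 64.41, 75.41, 70.00),
    ("Experienced 2", 39, 46, 66.10, 75.41, 70.83),
    ("Experienced 3", 40, 43, 67.80, 70.49, 69.17),
    ("Junior 1", 40, 42, 67.80, 68.85, 68.33),
    ("Junior 2", 37, 46, 62.71, 75.41, 69.17),
    ("Junior 3", 38, 44, 64.41, 72.13, 68.33),
]
SVM_ROWS = [
    ("GLCM48", 43, 48, 72.88, 78.69, 75.83),
    ("GLCM48_PLUS_GLOBAL3", 44, 46, 74.58, 75.41, 75.00),
    ("GGCM15", 48, 50, 81.36, 81.97, 81.67),
]
N_POS, N_NEG = 59, 61


def counts(tp, tn):
    return ConfusionCounts(tp=tp, tn=tn, fp=N_NEG - tn, fn=N_POS - tp)


class TestConfusionMetrics:
    @pytest.mark.parametrize("row", READER_ROWS + SVM_ROWS, ids=lambda r: r[0])
    def test_reproduces_published_cells(self, row):
        _, tp, tn, sens, spec, acc = row
        got = confusion_metrics(counts(tp, tn))
        assert tuple(round_half_up(v) for v in got) == (sens, spec, acc)

    def test_perfect_classifier(self):
        assert confusion_metrics(ConfusionCounts(10, 12, 0, 0)) == (100, 100, 100)

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts(tp=0, tn=5, fp=2, fn=0))

    def test_from_cv_result(self):
        from eustex.classification import CVResult

        res = CVResult(
            lesion_ids=("a", "b", "c", "d"),
            true_labels=np.array([1, 1, 0, 0]),
            predicted_labels=np.array([1, 0, 0, 1]),
            scores=np.array([1.0, -0.5, -1.0, 0.2]),
        )
        c = confusion_from_cv(res)
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)


class TestRocAuc:
    def test_perfect_separation(self):
        s = roc_auc((np.array([2.0, 3.0, 0.0, 1.0]), np.array([1, 1, 0, 0])))
        assert s.auc == 1.0

    def test_all_ties_give_half(self):
        s = roc_auc((np.ones(8), np.array([1, 1, 1, 1, 0, 0, 0, 0])))
        assert s.auc == 0.5

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        pos=st.lists(st.integers(-5, 5), min_size=1, max_size=8),
        neg=st.lists(st.integers(-5, 5), min_size=1, max_size=8),
    )
    def test_matches_exhaustive_pair_counting(self, pos, neg):
        scores = np.array(pos + neg, dtype=float)
        labels = np.array([1] * len(pos) + [0] * len(neg))
        assert roc_auc((scores, labels)).auc == pytest.approx(
            brute_auc(np.array(pos), np.array(neg))
        )

    def test_curve_shape_and_ci(self, rng):
        scores = rng.normal(size=40) + np.r_[np.ones(20), np.zeros(20)]
        labels = np.r_[np.ones(20), np.zeros(20)].astype(int)
        s = roc_auc((scores, labels))
        assert tuple(s.curve[0]) == (0.0, 0.0) and tuple(s.curve[-1]) == (1.0, 1.0)
        assert np.all(np.diff(s.curve[:, 0]) >= 0) and np.all(np.diff(s.curve[:, 1]) >= 0)
        assert s.ci95[0] <= s.auc <= s.ci95[1]
        assert s.variance > 0

    def test_invariant_to_monotone_score_transform(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        a = roc_auc((scores, labels))
        b = roc_auc((np.exp(scores * 2.0), labels))
        assert a.auc == pytest.approx(b.auc)
        np.testing.assert_allclose(a.curve, b.curve)

    def test_variance_shrinks_with_n(self, rng):
        variances = []
        for n in (50, 200, 800):
            scores = np.r_[rng.normal(1.0, 1.0, n), rng.normal(0.0, 1.0, n)]
            labels = np.r_[np.ones(n), np.zeros(n)].astype(int)
            variances.append(roc_auc((scores, labels)).variance)
        assert variances[0] > variances[1] > variances[2]

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc((np.ones(4), np.ones(4, dtype=int)))


class TestDelongPaired:
    def test_self_comparison_is_null(self, rng):
        scores = rng.normal(size=30)
        labels = np.r_[np.ones(15), np.zeros(15)].astype(int)
        res = delong_paired(scores, scores, labels)
        assert res.auc_a == res.auc_b
        assert res.z == 0.0 and res.p_value == 1.0

    def test_detects_large_auc_difference(self, rng):
        n = 60
        labels = np.r_[np.ones(n), np.zeros(n)].astype(int)
        good = np.r_[rng.normal(2.5, 1, n), rng.normal(0, 1, n)]
        bad = rng.normal(size=2 * n)  # uninformative
        res = delong_paired(good, bad, labels)
        assert res.auc_a > res.auc_b
        assert res.p_value < 0.01

    def test_degenerate_zero_variance_raises(self):
        labels = np.array([1, 1, 0, 0])
        a = np.array([2.0, 2.0, 1.0, 1.0])  # AUC 1, zero variance
        b = np.array([1.0, 1.0, 2.0, 2.0])  # AUC 0, zero variance
        with pytest.raises(ValueError, match="zero variance"):
            delong_paired(a, b, labels)

    def test_misaligned_inputs_raise(self):
        with pytest.raises(ValueError, match="paired"):
            delong_paired(np.ones(4), np.ones(5), np.array([1, 0, 1, 0]))


class TestChiSquare:
    def test_identical_proportions_null(self):
        chi2, p = compare_accuracy_chi2(50, 100, 50, 100)
        assert chi2 == 0.0 and p == 1.0

    def test_equals_squared_two_proportion_z(self):
        ca, na, cb, nb = 98, 120, 84, 120
        chi2, _ = compare_accuracy_chi2(ca, na, cb, nb)
        p_pool = (ca + cb) / (na + nb)
        z = (ca / na - cb / nb) / np.sqrt(p_pool * (1 - p_pool) * (1 / na + 1 / nb))
        assert chi2 == pytest.approx(z**2, rel=1e-12)

    def test_continuity_correction_flag(self):
        chi2_raw, _ = compare_accuracy_chi2(98, 120, 84, 120)
        chi2_corr, _ = compare_accuracy_chi2(98, 120, 84, 120, correction=True)
        assert chi2_corr < chi2_raw


class TestReaderTable:
    def readers(self):
        return [
            ReaderResult(name, tp, tn, N_POS, N_NEG)
            for name, tp, tn, *_ in READER_ROWS
        ]

    def test_reproduces_published_reader_means(self):
        df = reader_table(self.readers())
        mean = df[df.reader_id == "mean"].iloc[0]
        assert round_half_up(mean.sensitivity) == 65.54
        assert round_half_up(mean.specificity) == 72.95
        assert round_half_up(mean.accuracy) == 69.31

    def test_single_reader_mean_is_itself(self):
        df = reader_table([ReaderResult("solo", 38, 46, N_POS, N_NEG)])
        assert len(df) == 2
        assert df.iloc[0].sensitivity == df.iloc[1].sensitivity

    def test_inconsistent_totals_raise(self):
        readers = self.readers()
        readers.append(ReaderResult("odd", 10, 10, 20, 20))
        with pytest.raises(ValueError, match="inconsistent"):
            reader_table(readers)

    def test_counts_exceeding_totals_raise(self):
        with pytest.raises(ValueError):
            ReaderResult("bad", 60, 40, N_POS, N_NEG)


def test_round_half_up_ties():
    assert round_half_up(69.305) == 69.31
    assert round_half_up(2.675) == 2.68  # decimal-exact half-up, not banker's
    assert round_half_up(-1.005) == -1.01
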