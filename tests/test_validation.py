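"""Agreement metrics (Cohen's kappa vs direct formula and sklearn oracle),
progenitor k-mer mapping, and the full report."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from ploidbin.clustering import BinningState
from ploidbin.fragmentation import Fragment, FragmentSet, chunk_assembly
from ploidbin.io import AssemblyRecord
from ploidbin.validation import (agreement_stats, align_bins, cohens_kappa,
                                 fragment_truth_labels, full_report,
                                 progenitor_map)


def _fragments(n, length=100):
    frs = [Fragment(f"s::{i * length}-{(i + 1) * length}", "s", i * length,
                    (i + 1) * length) for i in range(n)]
    return FragmentSet(frs, length, 1)


class TestCohensKappa:
    def test_identical_labelings(self):
        labels = np.array([0, 1, 0, 1, 1])
        weights = np.full(5, 10.0)
        assert cohens_kappa(labels, labels, weights) == pytest.approx(1.0)

    def test_confusion_example(self):
        # bp-weighted confusion [[45,5],[5,45]] with equal fragment sizes:
        # p_o = 0.90, p_e = 0.50, kappa = 0.8
        labels_a = np.array([0] * 50 + [1] * 50)
        labels_b = labels_a.copy()
        labels_b[:5] = 1
        labels_b[50:55] = 0
        weights = np.ones(100)
        assert cohens_kappa(labels_a, labels_b, weights) == pytest.approx(0.8)

    def test_independent_labelings_near_zero(self):
        rng = np.random.default_rng(0)
        base = np.array([0] * 50 + [1] * 50)
        weights = np.ones(100)
        kappas = []
        for _ in range(20):
            kappas.append(cohens_kappa(base, rng.permutation(base), weights,
                                       align=False))
        assert abs(np.mean(kappas)) < 0.05

    def test_matches_sklearn_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, 200)
        b = rng.integers(0, 3, 200)
        w = rng.integers(1, 10, 200).astype(float)
        ours = cohens_kappa(a, b, w, align=False, n_a=3, n_b=3)
        oracle = cohen_kappa_score(a, b, sample_weight=w)
        assert ours == pytest.approx(oracle, abs=1e-9)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 2, 100)
        b = rng.integers(0, 2, 100)
        w = np.ones(100)
        assert cohens_kappa(a, b, w) == pytest.approx(cohens_kappa(b, a, w))

    def test_invariant_under_bin_relabeling(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, 100)
        b = rng.integers(0, 2, 100)
        w = np.ones(100)
        assert cohens_kappa(1 - a, b, w) == pytest.approx(cohens_kappa(a, b, w))

    def test_ambiguous_handling(self):
        a = np.array([0, 0, 1, 1, -1, -1])
        b = np.array([0, 0, 1, 1, 0, 1])
        w = np.ones(6)
        assert cohens_kappa(a, b, w, include_ambiguous=False) == pytest.approx(1.0)
        assert cohens_kappa(a, b, w, include_ambiguous=True) < 1.0

    def test_all_dropped_is_undefined(self):
        a = np.array([-1, -1])
        b = np.array([0, 1])
        assert np.isnan(cohens_kappa(a, b, np.ones(2), include_ambiguous=False))


class TestAlignBins:
    def test_permuted_labels_recovered(self):
        ref = np.array([0, 0, 1, 1, 2, 2])
        pred = np.array([2, 2, 0, 0, 1, 1])  # bin k maps to ref (k+1) % 3
        mapping = align_bins(pred, ref, np.ones(6), 3, 3)
        assert mapping.tolist() == [1, 2, 0]

    def test_agreement_stats_on_perfect_recovery(self):
        ref = np.array([0, 0, 1, 1])
        stats = agreement_stats(1 - ref, ref, np.ones(4) * 25, 2, 2)
        assert stats["accuracy"] == pytest.approx(1.0)
        assert stats["agreement_fraction"] == pytest.approx(1.0)
        for b in range(2):
            assert stats["per_bin"][b]["f1"] == pytest.approx(1.0)

    def test_agreement_fraction_equals_confusion_trace(self):
        rng = np.random.default_rng(4)
        ref = rng.integers(0, 2, 50)
        pred = rng.integers(-1, 2, 50)
        w = rng.integers(1, 5, 50).astype(float)
        stats = agreement_stats(pred, ref, w, 2, 2)
        aligned = stats["aligned_labels"]
        direct = sum(wi for a, r, wi in zip(aligned, ref, w) if a == r and a >= 0)
        assert stats["agreement_fraction"] == pytest.approx(direct / w.sum())


class TestFragmentTruthLabels:
    def test_majority_bp_rule(self):
        fragments = _fragments(2, length=100)
        truth = [("s", 0, 60, 0), ("s", 60, 200, 1)]
        labels = fragment_truth_labels(fragments, truth)
        assert labels.tolist() == [0, 1]  # fragment 0 is 60 bp label-0, 40 bp label-1

    def test_uncovered_fragment_ambiguous(self):
        fragments = _fragments(2, length=100)
        labels = fragment_truth_labels(fragments, [("s", 0, 100, 1)])
        assert labels.tolist() == [1, -1]


class TestProgenitorMap:
    def _progenitors(self):
        rng = np.random.default_rng(5)
        p1 = "".join(rng.choice(list("ACGT"), size=4000))
        p2 = "".join(rng.choice(list("ACGT"), size=4000))
        return [AssemblyRecord("p1", p1)], [AssemblyRecord("p2", p2)]

    def test_concatenation_maps_back_to_source(self):
        prog1, prog2 = self._progenitors()
        poly = [AssemblyRecord("c1", prog1[0].sequence),
                AssemblyRecord("c2", prog2[0].sequence)]
        fragments = chunk_assembly(poly, fragment_length=1000, min_length=1)
        bins = progenitor_map(fragments, poly, [prog1, prog2], k=21, ratio_threshold=2)
        expected = np.array([0] * 4 + [1] * 4)
        assert np.array_equal(bins.labels, expected)

    def test_foreign_fragment_is_ambiguous(self):
        prog1, prog2 = self._progenitors()
        rng = np.random.default_rng(99)
        foreign = "".join(rng.choice(list("ACGT"), size=1000))
        poly = [AssemblyRecord("c1", foreign)]
        fragments = chunk_assembly(poly, fragment_length=1000, min_length=1)
        bins = progenitor_map(fragments, poly, [prog1, prog2], k=21)
        assert bins.labels[0] == -1

    def test_requires_two_progenitors(self):
        prog1, _ = self._progenitors()
        poly = [AssemblyRecord("c1", prog1[0].sequence)]
        fragments = chunk_assembly(poly, fragment_length=1000, min_length=1)
        with pytest.raises(ValueError):
            progenitor_map(fragments, poly, [prog1])


class TestFullReport:
    def test_perfect_recovery_metrics(self):
        fragments = _fragments(8)
        ref = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=np.int32)
        bins = BinningState(1 - ref, 2, fragments.lengths)
        rng = np.random.default_rng(0)
        emb = np.vstack([rng.normal(0, 0.1, (4, 2)), rng.normal(5, 0.1, (4, 2))])
        report = full_report(bins, ref, fragments, embedding=emb)
        assert report.accuracy == pytest.approx(1.0)
        assert report.kappa_unambiguous == pytest.approx(1.0)
        assert report.homogeneity == pytest.approx(1.0)
        assert report.completeness == pytest.approx(1.0)
        assert (report.per_bin["f1"] == 1.0).all()
        assert report.silhouette is not None

    def test_confusion_sums_to_total_bp(self):
        fragments = _fragments(6)
        ref = np.array([0, 0, 1, 1, -1, 1], dtype=np.int32)
        bins = BinningState(np.array([0, 1, 1, 1, 0, -1], dtype=np.int32), 2,
                            fragments.lengths)
        report = full_report(bins, ref, fragments)
        assert report.confusion.to_numpy().sum() == pytest.approx(fragments.lengths.sum())
        assert "embedding absent" in report.notes[0]
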