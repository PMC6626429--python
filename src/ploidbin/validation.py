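"""Agreement metrics and reference-progenitor validation.

Two labelings of the same fragments (e.g. the unsupervised bins versus bins
derived from candidate progenitor genomes, or versus simulation truth) are
compared after aligning bin identities by a bp-maximizing one-to-one
matching.  All headline metrics are bp-weighted — what matters is how much
*sequence* agrees, not how many fragments.  Reference labels can be produced
without an aligner by exact k-mer sharing against progenitor genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn import metrics as skmetrics

from .clustering import AMBIGUOUS, BinningState
from .fragmentation import FragmentSet
from .io import AssemblyRecord
from .kmers import encode_sequence, window_codes

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Truth labels and bin alignment
# ---------------------------------------------------------------------------

def fragment_truth_labels(fragments: FragmentSet,
                          truth_intervals: Sequence[tuple[str, int, int, int]],
                          ) -> np.ndarray:
    """Majority-bp truth label per fragment from labeled intervals.

    ``truth_intervals`` are (scaffold, start, end, label) with 0-based
    half-open coordinates, e.g. from a simulator truth BED.  A fragment
    straddling an interval boundary gets the label covering most of its bp.
    """
    by_scaffold: dict[str, list[tuple[int, int, int]]] = {}
    for scaffold, start, end, label in truth_intervals:
        by_scaffold.setdefault(scaffold, []).append((start, end, label))
    labels = np.full(len(fragments), AMBIGUOUS, dtype=np.int32)
    for i, frag in enumerate(fragments.fragments):
        votes: dict[int, int] = {}
        for start, end, label in by_scaffold.get(frag.scaffold_id, ()):
            overlap = min(end, frag.end) - max(start, frag.start)
            if overlap > 0:
                votes[label] = votes.get(label, 0) + overlap
        if votes:
            labels[i] = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    return labels


def confusion_bp(labels_a: np.ndarray, labels_b: np.ndarray, weights: np.ndarray,
                 n_a: int, n_b: int, include_ambiguous: bool = False) -> np.ndarray:
    """bp-weighted confusion matrix; with ``include_ambiguous`` the last
    row/column holds the ambiguous category."""
    size_a = n_a + (1 if include_ambiguous else 0)
    size_b = n_b + (1 if include_ambiguous else 0)
    out = np.zeros((size_a, size_b), dtype=np.float64)
    for a, b, w in zip(labels_a, labels_b, weights):
        ia = int(a) if a != AMBIGUOUS else n_a
        ib = int(b) if b != AMBIGUOUS else n_b
        if not include_ambiguous and (a == AMBIGUOUS or b == AMBIGUOUS):
            continue
        out[ia, ib] += w
    return out


def align_bins(labels_pred: np.ndarray, labels_ref: np.ndarray,
               weights: np.ndarray, n_pred: int, n_ref: int) -> np.ndarray:
    """bp-maximizing one-to-one matching of predicted bins onto reference bins.

    Returns ``mapping`` with ``mapping[pred_bin] = ref_bin`` (or -1 for
    unmatched predicted bins when n_pred > n_ref).
    """
    conf = confusion_bp(labels_pred, labels_ref, weights, n_pred, n_ref)
    rows, cols = linear_sum_assignment(-conf)
    mapping = np.full(n_pred, -1, dtype=np.int64)
    mapping[rows] = cols
    return mapping


def remap_labels(labels: np.ndarray, mapping: np.ndarray) -> np.ndarray:
    out = labels.copy()
    labeled = labels >= 0
    out[labeled] = mapping[labels[labeled]]
    return out


# ---------------------------------------------------------------------------
# Agreement metrics
# ---------------------------------------------------------------------------

def cohens_kappa(labels_a: np.ndarray, labels_b: np.ndarray, weights: np.ndarray,
                 include_ambiguous: bool = False, n_a: int | None = None,
                 n_b: int | None = None, align: bool = True) -> float:
    """bp-weighted Cohen's kappa between two labelings.

    Bins are first aligned by the bp-maximizing one-to-one matching (the two
    labelings carry arbitrary bin identities).  ``include_ambiguous`` treats
    "ambiguous" as an extra category; otherwise fragments ambiguous in either
    labeling are dropped.  Returns NaN when nothing remains to compare.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    weights = np.asarray(weights, dtype=np.float64)
    n_a = int(labels_a[labels_a >= 0].max()) + 1 if n_a is None and (labels_a >= 0).any() else (n_a or 1)
    n_b = int(labels_b[labels_b >= 0].max()) + 1 if n_b is None and (labels_b >= 0).any() else (n_b or 1)
    if align:
        mapping = align_bins(labels_a, labels_b, weights, n_a, n_b)
        # unmatched predicted bins stay as distinct (always-disagreeing) categories
        spare = iter(range(n_b, n_b + n_a))
        mapping = np.array([m if m >= 0 else next(spare) for m in mapping])
        labels_a = remap_labels(labels_a, mapping)
        n_cat = max(n_a, n_b)
    else:
        n_cat = max(n_a, n_b)
    conf = confusion_bp(labels_a, labels_b, weights, n_cat, n_cat,
                        include_ambiguous=include_ambiguous)
    total = conf.sum()
    if total == 0:
        log.warning("no comparable fragments; kappa undefined")
        return float("nan")
    p_o = np.trace(conf) / total
    p_e = float((conf.sum(axis=1) / total) @ (conf.sum(axis=0) / total))
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def agreement_stats(labels_pred: np.ndarray, labels_ref: np.ndarray,
                    weights: np.ndarray, n_pred: int, n_ref: int) -> dict:
    """Coverage, accuracy and per-bin precision/recall/F1/Jaccard, bp-weighted.

    Predicted bins are aligned onto reference bins first.  ``accuracy`` is
    over bp classified by both labelings; ``agreement_fraction`` is agreeing
    bp over total bp (ambiguity counts against it); ``classified_fraction``
    is the bp fraction the prediction classified at all.
    """
    weights = np.asarray(weights, dtype=np.float64)
    mapping = align_bins(labels_pred, labels_ref, weights, n_pred, n_ref)
    aligned = remap_labels(labels_pred, mapping)
    both = (aligned >= 0) & (labels_ref >= 0)
    agree = both & (aligned == labels_ref)
    total = weights.sum()
    both_bp = weights[both].sum()
    per_bin = {}
    for b in range(n_ref):
        pred_b = (aligned == b)
        ref_b = (labels_ref == b)
        tp = weights[pred_b & ref_b].sum()
        fp = weights[pred_b & ~ref_b].sum()
        fn = weights[~pred_b & ref_b].sum()
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        union = tp + fp + fn
        per_bin[b] = {
            "precision": float(precision), "recall": float(recall),
            "f1": float(f1), "jaccard": float(tp / union) if union else 0.0,
        }
    return {
        "mapping": mapping,
        "aligned_labels": aligned,
        "classified_fraction": float(weights[labels_pred >= 0].sum() / total) if total else 0.0,
        "accuracy": float(weights[agree].sum() / both_bp) if both_bp else float("nan"),
        "agreement_fraction": float(weights[agree].sum() / total) if total else 0.0,
        "per_bin": per_bin,
    }


# ---------------------------------------------------------------------------
# Progenitor mapping
# ---------------------------------------------------------------------------

def progenitor_map(fragments: FragmentSet, assembly: Sequence[AssemblyRecord],
                   progenitors: Sequence[Sequence[AssemblyRecord]], k: int = 21,
                   ratio_threshold: float = 2.0) -> BinningState:
    """Bin fragments by exact k-mer sharing with candidate progenitor genomes.

    Each fragment's windows are matched against every progenitor's canonical
    k-mer set; the fragment goes to the progenitor with the most shared
    windows iff that count exceeds the runner-up by ``ratio_threshold``
    (zero runner-up clamped to 1), else it is ambiguous.
    """
    if len(progenitors) < 2:
        raise ValueError("need at least 2 progenitor genomes")
    prog_sets = []
    for prog in progenitors:
        chunks = []
        for rec in prog:
            packed, valid = window_codes(encode_sequence(rec.sequence), k)
            chunks.append(packed[valid])
        prog_sets.append(np.unique(np.concatenate(chunks)) if chunks else
                         np.empty(0, dtype=np.uint64))
    seqs = {rec.scaffold_id: encode_sequence(rec.sequence) for rec in assembly}
    scores = np.zeros((len(fragments), len(progenitors)), dtype=np.float64)
    for i, frag in enumerate(fragments.fragments):
        packed, valid = window_codes(seqs[frag.scaffold_id][frag.start:frag.end], k)
        packed = packed[valid]
        for p, codes in enumerate(prog_sets):
            if codes.size and packed.size:
                pos = np.searchsorted(codes, packed)
                inside = pos < codes.size
                scores[i, p] = np.count_nonzero(codes[pos[inside]] == packed[inside])
    order = np.argsort(scores, axis=1)
    best_bin = order[:, -1]
    best = scores[np.arange(len(fragments)), best_bin]
    second = scores[np.arange(len(fragments)), order[:, -2]]
    labels = np.full(len(fragments), AMBIGUOUS, dtype=np.int32)
    confident = (best > 0) & (best / np.maximum(second, 1.0) >= ratio_threshold)
    labels[confident] = best_bin[confident]
    return BinningState(labels, len(progenitors), fragments.lengths)


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    confusion: pd.DataFrame
    kappa_unambiguous: float
    kappa_all: float
    agreement_fraction: float
    classified_fraction: float
    accuracy: float
    per_bin: pd.DataFrame
    silhouette: float | None = None
    calinski_harabasz: float | None = None
    homogeneity: float | None = None
    completeness: float | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "kappa_unambiguous": self.kappa_unambiguous,
            "kappa_all": self.kappa_all,
            "agreement_fraction": self.agreement_fraction,
            "classified_fraction": self.classified_fraction,
            "accuracy": self.accuracy,
            "silhouette": self.silhouette,
            "calinski_harabasz": self.calinski_harabasz,
            "homogeneity": self.homogeneity,
            "completeness": self.completeness,
            "per_bin": self.per_bin.to_dict(orient="index"),
            "notes": self.notes,
        }
        return out

    def write(self, prefix) -> None:
        from .io import write_json

        self.confusion.to_csv(f"{prefix}.confusion.tsv", sep="\t")
        self.per_bin.to_csv(f"{prefix}.per_bin.tsv", sep="\t")
        write_json(self.to_dict(), f"{prefix}.json")


def full_report(bins: BinningState, reference_labels: np.ndarray,
                fragments: FragmentSet, n_ref: int | None = None,
                embedding: np.ndarray | None = None) -> ValidationReport:
    """All agreement and clustering metrics against a reference labeling.

    Confusion and agreement are bp-weighted after bin alignment; clustering
    scores (silhouette, Calinski-Harabasz) are computed on the embedding of
    classified fragments when one is supplied, and homogeneity/completeness
    against the reference on fragments classified by both.
    """
    weights = bins.fragment_lengths.astype(np.float64)
    reference_labels = np.asarray(reference_labels, dtype=np.int32)
    n_ref = n_ref or (int(reference_labels.max()) + 1 if (reference_labels >= 0).any() else 1)
    stats = agreement_stats(bins.labels, reference_labels, weights, bins.n_bins, n_ref)
    aligned = stats["aligned_labels"]
    conf = confusion_bp(aligned, reference_labels, weights,
                        max(bins.n_bins, n_ref), n_ref, include_ambiguous=True)
    row_names = [f"pred_{b}" for b in range(max(bins.n_bins, n_ref))] + ["pred_ambiguous"]
    col_names = [f"ref_{b}" for b in range(n_ref)] + ["ref_ambiguous"]
    confusion = pd.DataFrame(conf, index=row_names, columns=col_names)
    notes: list[str] = []
    kappa_un = cohens_kappa(bins.labels, reference_labels, weights,
                            include_ambiguous=False, n_a=bins.n_bins, n_b=n_ref)
    kappa_all = cohens_kappa(bins.labels, reference_labels, weights,
                             include_ambiguous=True, n_a=bins.n_bins, n_b=n_ref)
    per_bin = pd.DataFrame(stats["per_bin"]).T
    silhouette = calinski = homogeneity = completeness = None
    both = (bins.labels >= 0) & (reference_labels >= 0)
    if both.sum() > 2:
        homogeneity = float(skmetrics.homogeneity_score(reference_labels[both],
                                                        bins.labels[both]))
        completeness = float(skmetrics.completeness_score(reference_labels[both],
                                                          bins.labels[both]))
    if embedding is not None:
        classified = bins.labels >= 0
        if len(np.unique(bins.labels[classified])) >= 2:
            silhouette = float(skmetrics.silhouette_score(embedding[classified],
                                                          bins.labels[classified]))
            calinski = float(skmetrics.calinski_harabasz_score(embedding[classified],
                                                               bins.labels[classified]))
    else:
        notes.append("embedding absent; clustering scores omitted")
    return ValidationReport(
        confusion=confusion,
        kappa_unambiguous=kappa_un,
        kappa_all=kappa_all,
        agreement_fraction=stats["agreement_fraction"],
        classified_fraction=stats["classified_fraction"],
        accuracy=stats["accuracy"],
        per_bin=per_bin,
        silhouette=silhouette,
        calinski_harabasz=calinski,
        homogeneity=homogeneity,
        completeness=completeness,
        notes=notes,
    )
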