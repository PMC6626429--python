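"""Iterative differential-feature signal amplification.

Given an initial partition, features (k-mers or annotated repeats) that are
far more frequent in one bin than in any other are the bin's *differential*
features.  Every fragment is then scored by the total occurrences of each
bin's differential features, and assigned to the best-scoring bin when that
score dominates the runner-up by a ratio threshold — otherwise it is left
ambiguous.  Alternating identification and recruitment amplifies the
subgenome signal: each round recruits previously ambiguous fragments, which
in turn sharpen the next round's differential features, until the bin sizes
(in bp) stop changing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .clustering import AMBIGUOUS, BinningState

log = logging.getLogger(__name__)


@dataclass
class DifferentialFeatureSet:
    """Per-bin differential feature (column) indices with per-bin counts."""

    feature_indices: dict[int, np.ndarray]  # bin -> column indices
    bin_counts: np.ndarray                  # n_bins x n_features totals
    fold_threshold: float
    min_own_count: int

    @property
    def n_features(self) -> int:
        return sum(idx.size for idx in self.feature_indices.values())

    def columns(self, b: int) -> np.ndarray:
        return self.feature_indices.get(b, np.empty(0, dtype=np.int64))


def bin_feature_counts(matrix: sparse.spmatrix, labels: np.ndarray,
                       n_bins: int) -> np.ndarray:
    """Total count of each feature within each bin (n_bins x n_features)."""
    counts = np.zeros((n_bins, matrix.shape[1]), dtype=np.float64)
    for b in range(n_bins):
        members = np.flatnonzero(labels == b)
        if members.size:
            counts[b] = np.asarray(matrix[members].sum(axis=0)).ravel()
    return counts


def find_differential_features(matrix: sparse.spmatrix, labels: np.ndarray,
                               n_bins: int, fold_threshold: float = 20.0,
                               min_own_count: int = 10) -> DifferentialFeatureSet:
    """Features frequent in one bin but not in the others.

    A feature belongs to bin b when its count there is at least
    ``min_own_count`` and at least ``fold_threshold`` times the largest count
    in any other bin (zero denominators clamped to 1), so each feature
    belongs to at most one bin.
    """
    nonempty = [b for b in range(n_bins) if (labels == b).any()]
    if len(nonempty) < 2:
        raise ValueError("need at least 2 non-empty bins to find differential features")
    counts = bin_feature_counts(matrix, labels, n_bins)
    order = np.argsort(counts, axis=0)
    owner = order[-1]
    best = counts[owner, np.arange(counts.shape[1])]
    second = counts[order[-2], np.arange(counts.shape[1])]
    qualifies = (best >= min_own_count) & (best / np.maximum(second, 1.0) >= fold_threshold)
    feature_indices: dict[int, np.ndarray] = {}
    for b in range(n_bins):
        feature_indices[b] = np.flatnonzero(qualifies & (owner == b))
        if feature_indices[b].size == 0 and b in nonempty:
            log.warning("bin %d yielded no differential features", b)
    return DifferentialFeatureSet(feature_indices, counts, fold_threshold, min_own_count)


def differential_scores(matrix: sparse.spmatrix,
                        diff: DifferentialFeatureSet) -> np.ndarray:
    """S[i, b]: total occurrences in fragment i of bin b's differential features."""
    n_bins = diff.bin_counts.shape[0]
    scores = np.zeros((matrix.shape[0], n_bins), dtype=np.float64)
    for b in range(n_bins):
        cols = diff.columns(b)
        if cols.size:
            scores[:, b] = np.asarray(matrix[:, cols].sum(axis=1)).ravel()
    return scores


def recruit(matrix: sparse.spmatrix, diff: DifferentialFeatureSet,
            ratio_threshold: float = 3.0) -> np.ndarray:
    """Assign every fragment by its differential-feature scores.

    A fragment goes to the bin with the largest score iff that score exceeds
    the runner-up by ``ratio_threshold`` (zero runner-up clamped to 1);
    otherwise it is ambiguous.  Previously labeled fragments are re-evaluated
    under the same rule, so reassignment is possible.
    """
    scores = differential_scores(matrix, diff)
    order = np.argsort(scores, axis=1)
    best_bin = order[:, -1]
    best = scores[np.arange(scores.shape[0]), best_bin]
    second = scores[np.arange(scores.shape[0]), order[:, -2]]
    labels = np.full(scores.shape[0], AMBIGUOUS, dtype=np.int32)
    confident = (best > 0) & (best / np.maximum(second, 1.0) >= ratio_threshold)
    labels[confident] = best_bin[confident]
    return labels


def amplify_until_convergence(matrix: sparse.spmatrix, initial: BinningState,
                              fold_threshold: float = 20.0, min_own_count: int = 10,
                              ratio_threshold: float = 3.0, max_iter: int = 10,
                              tol_fraction: float = 1e-3,
                              freeze_initial: bool = False) -> BinningState:
    """Alternate differential-feature discovery and recruitment to a fixed size.

    Stops when every bin's bp changes by less than ``tol_fraction``
    (relative) between iterations, when the label state repeats without
    meeting the tolerance (oscillation), or at ``max_iter``.  The per-
    iteration bin_bp history is retained so any iteration's bins can be
    inspected afterwards.
    """
    state = initial.with_labels(initial.labels)
    if max_iter <= 0:
        return state
    labels = state.labels.copy()
    lengths = state.fragment_lengths
    seen: set[bytes] = {labels.tobytes()}
    prev_bp = state.bin_bp.astype(np.float64)
    for iteration in range(1, max_iter + 1):
        try:
            diff = find_differential_features(matrix, labels, state.n_bins,
                                              fold_threshold, min_own_count)
        except ValueError:
            log.warning("amplification stopped: fewer than 2 non-empty bins")
            break
        if diff.n_features == 0:
            log.warning("amplification stopped: no bin yields differential "
                        "features at fold >= %g", fold_threshold)
            break
        new_labels = recruit(matrix, diff, ratio_threshold)
        if freeze_initial:
            frozen = initial.labels >= 0
            new_labels[frozen] = initial.labels[frozen]
        labels = new_labels
        state.labels = labels
        state.iteration = iteration
        bp = state.bin_bp.astype(np.float64)
        state.history.append(state.bin_bp)
        converged = bool(np.all(np.abs(bp - prev_bp) < tol_fraction * np.maximum(prev_bp, 1.0)))
        if converged:
            log.info("amplification converged at iteration %d", iteration)
            break
        key = labels.tobytes()
        if key in seen:
            log.warning("amplification oscillates without meeting tolerance; "
                        "stopping at iteration %d", iteration)
            break
        seen.add(key)
        prev_bp = bp
    return state
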