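"""Subgenome binning from annotated repeat elements.

Instead of raw k-mers, fragments can be binned by their content of annotated
repeat consensus models (RepeatMasker-style annotations).  A prior k-mer
binning supplies labels from which *informative* repeats are ranked by a
chi-squared statistic of their per-fragment counts against the labels, and
*differential* repeats are those several-fold more frequent in one subgenome
than the others.  The per-bin intersection (top-N informative, differential)
drives a PCA -> k-NN -> spectral clustering -> amplification pipeline that
mirrors the k-mer path with repeat-specific thresholds.  Finally, repeat
subclasses over- or under-represented among the informative differential
repeats are scored by a one-vs-rest chi-squared against the genome-wide
subclass composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.feature_selection import chi2 as sk_chi2

from .amplify import amplify_until_convergence, bin_feature_counts
from .clustering import AMBIGUOUS, BinningState, cluster, embed, knn_graph, spectral_embed
from .fragmentation import FragmentSet
from .io import RepeatFeature

log = logging.getLogger(__name__)


@dataclass
class RepeatMatrix:
    """Sparse fragments x repeat-consensus count matrix (midpoint assignment)."""

    fragment_ids: list[str]
    consensus_ids: list[str]
    counts: sparse.csr_matrix
    n_skipped: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def build_repeat_matrix(fragments: FragmentSet,
                        features: Sequence[RepeatFeature]) -> RepeatMatrix:
    """Count annotated repeat instances per fragment.

    Each instance is assigned to the single fragment containing its midpoint
    (avoiding double counting at fragment boundaries); instances on unknown
    scaffolds or in excluded sequence are skipped with a warning.
    """
    by_scaffold = fragments.by_scaffold()
    frag_list = fragments.fragments
    consensus_ids = sorted({f.consensus_id for f in features})
    col_of = {cid: j for j, cid in enumerate(consensus_ids)}
    starts = {sid: np.array([frag_list[i].start for i in idxs]) for sid, idxs in by_scaffold.items()}
    rows, cols = [], []
    n_skipped = 0
    unknown: set[str] = set()
    for feat in features:
        idxs = by_scaffold.get(feat.scaffold_id)
        if idxs is None:
            unknown.add(feat.scaffold_id)
            n_skipped += 1
            continue
        mid = feat.midpoint
        pos = int(np.searchsorted(starts[feat.scaffold_id], mid, side="right")) - 1
        if pos < 0:
            n_skipped += 1
            continue
        frag = frag_list[idxs[pos]]
        if not (frag.start <= mid < frag.end):
            n_skipped += 1  # midpoint falls in excluded sequence
            continue
        rows.append(idxs[pos])
        cols.append(col_of[feat.consensus_id])
    if unknown:
        log.warning("skipped features on %d unknown scaffolds", len(unknown))
    if n_skipped:
        log.info("%d repeat instances not assignable to any fragment", n_skipped)
    mat = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(frag_list), len(consensus_ids)), dtype=np.float64,
    ).tocsr()
    return RepeatMatrix(fragments.fragment_ids, consensus_ids, mat, n_skipped)


@dataclass
class InformativeRepeatReport:
    """Chi-squared informativeness and differential assignment per consensus."""

    consensus_ids: list[str]
    chi_squared: np.ndarray                  # per consensus, vs subgenome labels
    differential: dict[int, np.ndarray]      # bin -> column indices (fold rule)
    selected: dict[int, np.ndarray]          # bin -> top-N informative ∩ differential
    discovery_fold: float
    top_n_per_bin: int

    @property
    def selected_columns(self) -> np.ndarray:
        cols = [idx for idx in self.selected.values() if idx.size]
        return np.sort(np.concatenate(cols)) if cols else np.empty(0, dtype=np.int64)

    @property
    def selected_ids(self) -> list[str]:
        return [self.consensus_ids[j] for j in self.selected_columns]

    def to_frame(self) -> pd.DataFrame:
        owner = np.full(len(self.consensus_ids), AMBIGUOUS, dtype=int)
        chosen = np.zeros(len(self.consensus_ids), dtype=bool)
        for b, idx in self.differential.items():
            owner[idx] = b
        chosen[self.selected_columns] = True
        return pd.DataFrame({
            "consensus_id": self.consensus_ids,
            "chi_squared": self.chi_squared,
            "differential_bin": owner,
            "selected": chosen,
        })


def select_informative_differential_repeats(
        repeat_matrix: RepeatMatrix, labels: np.ndarray, n_bins: int,
        discovery_fold: float = 5.0, top_n_per_bin: int = 150,
        min_own_count: int = 1) -> InformativeRepeatReport:
    """Rank repeats by chi-squared vs labels and intersect with the fold rule.

    ``labels`` come from a prior k-mer binning.  A consensus is differential
    for bin b when its total count there is at least ``discovery_fold`` times
    the largest count in any other bin (zero denominators clamped to 1); the
    selection takes the ``top_n_per_bin`` highest-chi-squared differential
    repeats of each bin (all of them, with a warning, when fewer qualify).
    """
    labeled = labels >= 0
    if labeled.sum() == 0:
        raise ValueError("no labeled fragments; run the k-mer binning first")
    X = repeat_matrix.counts[np.flatnonzero(labeled)]
    y = labels[labeled]
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 non-empty bins in the prior labeling")
    with np.errstate(invalid="ignore", divide="ignore"):
        chi_vals, _ = sk_chi2(X, y)
    chi_vals = np.nan_to_num(chi_vals, nan=0.0)

    counts = bin_feature_counts(repeat_matrix.counts, labels, n_bins)
    order = np.argsort(counts, axis=0)
    owner = order[-1]
    best = counts[owner, np.arange(counts.shape[1])]
    second = counts[order[-2], np.arange(counts.shape[1])]
    qualifies = (best >= min_own_count) & (best / np.maximum(second, 1.0) >= discovery_fold)
    differential = {b: np.flatnonzero(qualifies & (owner == b)) for b in range(n_bins)}

    selected: dict[int, np.ndarray] = {}
    for b, idx in differential.items():
        if idx.size == 0:
            selected[b] = idx
            continue
        if idx.size < top_n_per_bin:
            log.warning("bin %d has only %d qualifying repeats (< top_n=%d); taking all",
                        b, idx.size, top_n_per_bin)
            take = idx.size
        else:
            take = top_n_per_bin
        ranked = idx[np.argsort(chi_vals[idx])[::-1]]
        selected[b] = np.sort(ranked[:take])
    return InformativeRepeatReport(repeat_matrix.consensus_ids, chi_vals,
                                   differential, selected, discovery_fold,
                                   top_n_per_bin)


def bin_by_repeats(repeat_matrix: RepeatMatrix, selected_columns: np.ndarray,
                   fragments: FragmentSet, n_bins: int, seed: int = 42,
                   n_neighbors: int = 20, d: int | None = None,
                   amplify_fold: float = 8.0, reassign_ratio: float = 3.0,
                   min_own_count: int = 3, max_trials: int = 10,
                   tol_fraction: float = 1e-3) -> BinningState:
    """Cluster fragments on the selected repeat columns and amplify.

    Feature-selects the repeat matrix, embeds with PCA, builds the k-NN
    graph, spectrally clusters, then runs signal amplification on the full
    repeat matrix with repeat-specific thresholds (discovery fold 8,
    reassignment ratio 3) until bin sizes converge over successive trials.
    """
    selected_columns = np.asarray(selected_columns, dtype=np.int64)
    if selected_columns.size == 0:
        raise ValueError("no selected repeats to bin on")
    sub = repeat_matrix.counts[:, np.sort(selected_columns)]
    d = n_bins + 1 if d is None else d
    emb = embed(sub, d=min(d, max(2, sub.shape[1] - 1)), method="pca", seed=seed)
    n_neighbors = min(n_neighbors, emb.coords.shape[0] - 1)
    adj = knn_graph(emb.coords, n_neighbors=n_neighbors)
    spec, isolated = spectral_embed(adj, d_spec=n_bins)
    zero_signal = np.asarray(sub.sum(axis=1)).ravel() == 0
    initial = cluster(spec, n_bins, fragments, method="spectral_kmeans", seed=seed,
                      zero_signal=zero_signal, isolated=isolated)
    return amplify_until_convergence(
        repeat_matrix.counts, initial, fold_threshold=amplify_fold,
        min_own_count=min_own_count, ratio_threshold=reassign_ratio,
        max_iter=max_trials, tol_fraction=tol_fraction,
    )


def subclass_enrichment(report: InformativeRepeatReport,
                        features: Sequence[RepeatFeature]) -> pd.DataFrame:
    """Chi-squared enrichment of repeat subclasses among selected repeats.

    Observed: the subclass composition of the selected informative
    differential repeats.  Expected: genome-wide subclass proportions (over
    distinct consensus models) scaled to the selection size.  Each subclass
    gets a one-vs-rest two-cell chi-squared, ranked descending; subclasses
    with an expected cell below 1 are flagged as unstable estimates.
    """
    subclass_of: dict[str, str] = {}
    for f in features:
        subclass_of.setdefault(f.consensus_id, f.subclass or "unknown")
    missing = [cid for cid in report.selected_ids if cid not in subclass_of]
    if missing:
        raise ValueError(f"selected repeats without a subclass: {missing[:5]}")
    genome = pd.Series([subclass_of[c] for c in subclass_of]).value_counts()
    null_prop = genome / genome.sum()
    observed = pd.Series([subclass_of[c] for c in report.selected_ids]).value_counts()
    n_sel = int(observed.sum())
    rows = []
    for subclass in null_prop.index:
        obs = float(observed.get(subclass, 0))
        exp = float(null_prop[subclass] * n_sel)
        exp_rest = float(n_sel - exp)
        if exp == 0 or exp_rest == 0:
            stat, unstable = 0.0, True
        else:
            stat = (obs - exp) ** 2 / exp + ((n_sel - obs) - exp_rest) ** 2 / exp_rest
            unstable = min(exp, exp_rest) < 1.0
        rows.append({"subclass": subclass, "observed": obs, "expected": exp,
                     "chi_squared": stat, "unstable": unstable})
    out = pd.DataFrame(rows).sort_values("chi_squared", ascending=False)
    return out.reset_index(drop=True)
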