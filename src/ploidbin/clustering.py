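"""Embedding and graph clustering of the fragment x k-mer matrix.

The sparse count matrix is projected to a few dimensions with kernel PCA
under a cosine kernel (cosine compares repeat *profiles* and ignores overall
repeat density, so a repeat-rich and a repeat-poor fragment of the same
subgenome land together).  A k-nearest-neighbour graph is built in the
embedded space — an edge is a proxy for a shared repeat-k-mer profile — and
cut along regions of low edge density via spectral clustering: k-means on
the eigenvectors of the symmetric normalized graph Laplacian.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.linalg import eigh
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA, KernelPCA
from sklearn.mixture import BayesianGaussianMixture
from sklearn.neighbors import kneighbors_graph

from .fragmentation import AMBIGUOUS, FragmentSet
from .kmers import RepeatKmerMatrix

log = logging.getLogger(__name__)


@dataclass
class BinningState:
    """Per-fragment subgenome labels (AMBIGUOUS = -1) with bp bookkeeping."""

    labels: np.ndarray            # int32, length n_fragments
    n_bins: int
    fragment_lengths: np.ndarray  # int64, aligned with labels
    iteration: int = 0
    history: list[np.ndarray] = field(default_factory=list)  # per-iteration bin_bp

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        self.fragment_lengths = np.asarray(self.fragment_lengths, dtype=np.int64)
        if self.labels.shape != self.fragment_lengths.shape:
            raise ValueError("labels and fragment_lengths must align")
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")
        if not self.history:
            self.history = [self.bin_bp]

    @property
    def label_names(self) -> list[str]:
        return [f"subgenome_{b}" for b in range(self.n_bins)]

    @property
    def bin_bp(self) -> np.ndarray:
        out = np.zeros(self.n_bins, dtype=np.int64)
        labeled = self.labels >= 0
        np.add.at(out, self.labels[labeled], self.fragment_lengths[labeled])
        return out

    @property
    def ambiguous_bp(self) -> int:
        return int(self.fragment_lengths[self.labels == AMBIGUOUS].sum())

    @property
    def total_bp(self) -> int:
        return int(self.fragment_lengths.sum())

    @property
    def classified_fraction_bp(self) -> float:
        total = self.total_bp
        return float(self.bin_bp.sum() / total) if total else 0.0

    def with_labels(self, labels: np.ndarray, iteration: int | None = None) -> "BinningState":
        state = BinningState(labels.copy(), self.n_bins, self.fragment_lengths,
                             self.iteration if iteration is None else iteration,
                             history=[bp.copy() for bp in self.history])
        return state


@dataclass
class EmbeddingResult:
    coords: np.ndarray
    method: str
    d: int
    neighbor_graph: sparse.csr_matrix | None = None
    spectral_coords: np.ndarray | None = None
    isolated: np.ndarray | None = None


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Make each component's largest-magnitude entry positive (reproducible
    up to numerical ties)."""
    coords = coords.copy()
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] *= -1
    return coords


def embed(matrix: RepeatKmerMatrix | sparse.spmatrix | np.ndarray, d: int = 3,
          method: str = "kpca_cosine", seed: int = 42) -> EmbeddingResult:
    """Project fragment count rows to ``d`` dimensions.

    ``kpca_cosine`` is kernel PCA on the pairwise cosine-similarity kernel
    (zero-count rows have zero similarity to everything and collapse to a
    single point); ``pca`` is ordinary PCA on the densified counts, used for
    the much narrower repeat-annotation matrices.
    """
    X = matrix.counts if isinstance(matrix, RepeatKmerMatrix) else matrix
    if d < 2:
        raise ValueError("d must be >= 2")
    n_nonzero = int((np.asarray(np.abs(X).sum(axis=1)).ravel() > 0).sum())
    if n_nonzero < d + 1:
        raise ValueError(
            f"only {n_nonzero} fragments carry repeat k-mers but d={d}; "
            "lower k or min_count to increase repetitive signal"
        )
    if method == "kpca_cosine":
        model = KernelPCA(n_components=d, kernel="cosine", eigen_solver="dense",
                          random_state=seed)
        coords = model.fit_transform(X)
    elif method == "pca":
        dense = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
        model = PCA(n_components=d, svd_solver="full", random_state=seed)
        coords = model.fit_transform(dense)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return EmbeddingResult(_fix_signs(coords), method, d)


def knn_graph(coords: np.ndarray, n_neighbors: int = 20) -> sparse.csr_matrix:
    """Symmetrized binary Euclidean k-NN graph (an edge exists if either
    endpoint selected the other); no self-edges."""
    n = coords.shape[0]
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n fragments={n}")
    adj = kneighbors_graph(coords, n_neighbors=n_neighbors, mode="connectivity",
                           include_self=False)
    adj = ((adj + adj.T) > 0).astype(np.float64)
    adj.setdiag(0)
    adj.eliminate_zeros()
    return adj.tocsr()


def spectral_embed(adj: sparse.spmatrix, d_spec: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Laplacian eigenmaps of a neighbour graph.

    Returns ``(coords, isolated)``: eigenvectors of the symmetric normalized
    Laplacian for the ``d_spec`` smallest nontrivial eigenvalues (the single
    trivial leading eigenvector is dropped; extra connected components show
    up as further zero eigenvalues and indicator-like eigenvectors).
    Isolated nodes are excluded from the decomposition, flagged in
    ``isolated``, and given zero coordinates.
    """
    adj = sparse.csr_matrix(adj, dtype=np.float64)
    n = adj.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    deg = np.asarray(adj.sum(axis=1)).ravel()
    isolated = deg == 0
    keep = np.flatnonzero(~isolated)
    if keep.size == 0:
        raise ValueError("graph has no edges")
    sub = adj[keep][:, keep].toarray()
    dsub = sub.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(dsub)
    lap = np.eye(keep.size) - inv_sqrt[:, None] * sub * inv_sqrt[None, :]
    n_vec = min(d_spec + 1, keep.size)
    eigvals, eigvecs = eigh(lap, subset_by_index=(0, n_vec - 1))
    vecs = eigvecs[:, 1:n_vec]  # drop the trivial leading eigenvector
    if vecs.shape[1] < d_spec:
        vecs = np.pad(vecs, ((0, 0), (0, d_spec - vecs.shape[1])))
    coords = np.zeros((n, d_spec))
    coords[keep] = _fix_signs(vecs)
    return coords, isolated


def cluster(coords: np.ndarray, n_bins: int, fragments: FragmentSet,
            method: str = "spectral_kmeans", seed: int = 42,
            ambiguity_threshold: float = 0.95,
            zero_signal: np.ndarray | None = None,
            isolated: np.ndarray | None = None) -> BinningState:
    """Cut the embedded fragments into ``n_bins`` initial subgenome bins.

    ``spectral_kmeans`` runs k-means on spectral coordinates (every connected
    fragment is assigned; only zero-signal / isolated fragments are
    ambiguous).  ``bayesian_gmm`` fits a Bayesian Gaussian mixture and labels
    fragments whose maximum posterior responsibility falls below
    ``ambiguity_threshold`` as ambiguous.
    """
    n = coords.shape[0]
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds number of fragments={n}")
    skip = np.zeros(n, dtype=bool)
    if zero_signal is not None:
        skip |= np.asarray(zero_signal, dtype=bool)
    if isolated is not None:
        skip |= np.asarray(isolated, dtype=bool)
    eligible = np.flatnonzero(~skip)
    labels = np.full(n, AMBIGUOUS, dtype=np.int32)
    if eligible.size < n_bins:
        raise ValueError(
            f"only {eligible.size} fragments carry signal but n_bins={n_bins}")
    pts = coords[eligible]
    if np.unique(pts, axis=0).shape[0] < n_bins:
        log.warning("fewer distinct embedded points than bins; assigning all "
                    "fragments to one bin")
        labels[eligible] = 0
        return BinningState(labels, n_bins, fragments.lengths)
    if method == "spectral_kmeans":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km = KMeans(n_clusters=n_bins, n_init=10, random_state=seed)
            labels[eligible] = km.fit_predict(pts)
    elif method == "bayesian_gmm":
        gmm = BayesianGaussianMixture(n_components=n_bins, random_state=seed,
                                      max_iter=500, n_init=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            resp = gmm.fit(pts).predict_proba(pts)
        assign = resp.argmax(axis=1).astype(np.int32)
        confident = resp.max(axis=1) >= ambiguity_threshold
        labels[eligible[confident]] = assign[confident]
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return BinningState(labels, n_bins, fragments.lengths)
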