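"""End-to-end orchestration of the two-phase binning workflow.

Phase 1 (initial partitioning): fragment the assembly, select repeat k-mers
by genome-wide frequency, build the sparse count matrix, embed with kernel
PCA (cosine), link each fragment to its nearest neighbours, spectrally embed
the graph and cut it into subgenome bins.  Phase 2 (signal amplification):
iterate differential-k-mer discovery and recruitment until bin sizes
converge, then optionally propagate labels positionally along scaffolds.
A repeat-annotation variant of the pipeline consumes the k-mer labels.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import amplify as _amplify
from . import clustering as _clustering
from . import kmers as _kmers
from . import propagate as _propagate
from . import repeats as _repeats
from . import validation as _validation
from .fragmentation import FragmentSet, chunk_assembly
from .io import AssemblyRecord, RepeatFeature, write_labels_bed

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters; serialized next to every run's outputs."""

    k: int = 26
    min_count: int | None = None          # None -> scaled with genome size
    max_count: int | None = None
    subsample: int | None = None
    stranded: bool = False
    log1p: bool = False
    fragment_length: int = 250_000
    min_length: int = 2_500
    n_subgenomes: int = 2
    n_neighbors: int = 20
    dims: int | None = None               # None -> n_subgenomes + 1
    d_spec: int | None = None             # None -> n_subgenomes
    cluster_method: str = "spectral_kmeans"
    ambiguity_threshold: float = 0.95
    fold_threshold: float = 20.0
    min_own_count: int = 10
    ratio_threshold: float = 3.0
    max_iter: int = 10
    tol_fraction: float = 1e-3
    freeze_initial: bool = False
    propagate: bool = True
    window: int = 2
    min_margin: int = 1
    # repeat-annotation path
    discovery_fold: float = 5.0
    amplify_fold: float = 8.0
    reassign_ratio: float = 3.0
    top_n_per_bin: int = 150
    seed: int = 42

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class KmerPipelineResult:
    config: PipelineConfig
    fragments: FragmentSet
    matrix: _kmers.RepeatKmerMatrix
    diagnostics: _kmers.RepeatmerDiagnostics
    embedding: _clustering.EmbeddingResult
    initial_bins: _clustering.BinningState
    amplified_bins: _clustering.BinningState
    final_bins: _clustering.BinningState
    provenance: list[str]
    report: _validation.ValidationReport | None = None

    def summary(self) -> dict:
        return {
            "n_fragments": len(self.fragments),
            "n_kmers": len(self.matrix.vocab),
            "bin_bp": self.final_bins.bin_bp.tolist(),
            "ambiguous_bp": self.final_bins.ambiguous_bp,
            "classified_fraction_bp": self.final_bins.classified_fraction_bp,
            "iterations": self.amplified_bins.iteration,
        }


def run_kmer_pipeline(assembly: Sequence[AssemblyRecord], config: PipelineConfig,
                      out_dir: str | Path | None = None,
                      progenitors: Sequence[Sequence[AssemblyRecord]] | None = None,
                      ) -> KmerPipelineResult:
    """Execute chunk -> count -> select -> (subsample) -> matrix -> embed ->
    knn -> spectral -> cluster -> amplify -> (propagate) -> outputs.

    When progenitor genomes are supplied, a reference-based labeling is
    computed by exact k-mer sharing and a validation report appended.
    """
    total_bp = sum(rec.length for rec in assembly)
    log.info("assembly: %d scaffolds, %d bp", len(assembly), total_bp)

    fragments = chunk_assembly(assembly, config.fragment_length, config.min_length)
    log.info("fragmentation: %d fragments (excluded %d bp)",
             len(fragments), fragments.excluded_bp)

    table = _kmers.count_genome_kmers(assembly, config.k, stranded=config.stranded)
    min_count = config.min_count
    if min_count is None:
        min_count = _kmers.default_min_count(total_bp)
        log.info("min_count scaled to %d for %d bp", min_count, total_bp)
    vocab = _kmers.select_repeat_kmers(table, min_count, config.max_count)
    log.info("k-mer selection: %d of %d distinct %d-mers retained",
             len(vocab), len(table), config.k)
    if config.subsample is not None and config.subsample < len(vocab):
        vocab = _kmers.subsample_vocabulary(vocab, config.subsample, config.seed)
        log.info("vocabulary subsampled to %d k-mers", len(vocab))

    matrix = _kmers.build_matrix(fragments, assembly, vocab,
                                 stranded=config.stranded, log1p=config.log1p)
    diagnostics = _kmers.repeatmers_per_fragment_histogram(matrix)

    d = config.dims or config.n_subgenomes + 1
    embedding = _clustering.embed(matrix, d=d, seed=config.seed)
    n_neighbors = min(config.n_neighbors, len(fragments) - 1)
    embedding.neighbor_graph = _clustering.knn_graph(embedding.coords, n_neighbors)
    d_spec = config.d_spec or config.n_subgenomes
    embedding.spectral_coords, embedding.isolated = _clustering.spectral_embed(
        embedding.neighbor_graph, d_spec)
    zero_signal = matrix.row_sums == 0
    coords = (embedding.spectral_coords
              if config.cluster_method == "spectral_kmeans" else embedding.coords)
    initial = _clustering.cluster(
        coords, config.n_subgenomes, fragments, method=config.cluster_method,
        seed=config.seed, ambiguity_threshold=config.ambiguity_threshold,
        zero_signal=zero_signal, isolated=embedding.isolated)
    log.info("initial partition: bin_bp=%s ambiguous_bp=%d",
             initial.bin_bp.tolist(), initial.ambiguous_bp)

    amplified = _amplify.amplify_until_convergence(
        matrix.counts, initial, fold_threshold=config.fold_threshold,
        min_own_count=config.min_own_count, ratio_threshold=config.ratio_threshold,
        max_iter=config.max_iter, tol_fraction=config.tol_fraction,
        freeze_initial=config.freeze_initial)
    log.info("amplification: %d iterations, bin_bp=%s ambiguous_bp=%d",
             amplified.iteration, amplified.bin_bp.tolist(), amplified.ambiguous_bp)

    provenance = np.where(initial.labels >= 0, "clustered", "ambiguous")
    provenance = np.where((amplified.labels >= 0) &
                          (amplified.labels != initial.labels),
                          "amplified", provenance).astype(object)
    final = amplified
    if config.propagate:
        final, newly = _propagate.propagate(amplified, fragments,
                                            window=config.window,
                                            min_margin=config.min_margin)
        provenance[newly] = "propagated"
        log.info("propagation: %d fragments labeled positionally; ambiguous_bp=%d",
                 int(newly.sum()), final.ambiguous_bp)
    provenance[final.labels < 0] = "ambiguous"
    provenance = provenance.tolist()

    report = None
    if progenitors is not None:
        ref = _validation.progenitor_map(fragments, assembly, progenitors, k=config.k)
        report = _validation.full_report(final, ref.labels, fragments,
                                         n_ref=len(progenitors),
                                         embedding=embedding.coords)
        log.info("validation vs progenitors: kappa=%.4f agreement=%.4f",
                 report.kappa_unambiguous, report.agreement_fraction)

    result = KmerPipelineResult(config, fragments, matrix, diagnostics, embedding,
                                initial, amplified, final, provenance, report)
    if out_dir is not None:
        write_outputs(result, assembly, out_dir)
    return result


def write_outputs(result: KmerPipelineResult, assembly: Sequence[AssemblyRecord],
                  out_dir: str | Path) -> dict[str, Path]:
    """Write deterministic BED/TSV/JSON stage outputs for a run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "config": out_dir / "config.json",
        "fragments": out_dir / "fragments.bed",
        "labels": out_dir / "labels.bed",
        "embedding": out_dir / "embedding.tsv",
        "convergence": out_dir / "convergence.tsv",
        "summary": out_dir / "summary.json",
    }
    result.config.to_json(paths["config"])
    result.fragments.to_bed(paths["fragments"])
    write_labels_bed(result.final_bins, result.fragments, paths["labels"],
                     provenance=result.provenance)
    with open(paths["embedding"], "w") as fh:
        names = result.final_bins.label_names
        header = ["fragment_id"] + [f"dim_{j}" for j in range(result.embedding.d)] + ["label"]
        fh.write("\t".join(header) + "\n")
        for i, fid in enumerate(result.fragments.fragment_ids):
            label = result.final_bins.labels[i]
            name = names[label] if label >= 0 else "ambiguous"
            coords = "\t".join(f"{x:.6g}" for x in result.embedding.coords[i])
            fh.write(f"{fid}\t{coords}\t{name}\n")
    with open(paths["convergence"], "w") as fh:
        names = result.amplified_bins.label_names
        fh.write("iteration\t" + "\t".join(f"{n}_bp" for n in names) + "\tambiguous_bp\n")
        total = result.amplified_bins.total_bp
        for it, bp in enumerate(result.amplified_bins.history):
            fh.write(f"{it}\t" + "\t".join(str(int(x)) for x in bp)
                     + f"\t{total - int(bp.sum())}\n")
    with open(paths["summary"], "w") as fh:
        json.dump(result.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    if result.report is not None:
        result.report.write(out_dir / "validation")
    return paths


def run_repeat_pipeline(fragments: FragmentSet, features: Sequence[RepeatFeature],
                        kmer_labels: np.ndarray, config: PipelineConfig,
                        ) -> tuple[_clustering.BinningState, _repeats.InformativeRepeatReport]:
    """Bin fragments by annotated repeats, seeded by the k-mer labels.

    Builds the fragment x consensus matrix, selects informative differential
    repeats against the k-mer labels, then clusters and amplifies with
    repeat-specific thresholds.
    """
    if len(features) == 0:
        raise ValueError("repeat annotation is empty")
    rm = _repeats.build_repeat_matrix(fragments, features)
    report = _repeats.select_informative_differential_repeats(
        rm, kmer_labels, config.n_subgenomes,
        discovery_fold=config.discovery_fold, top_n_per_bin=config.top_n_per_bin)
    cols = report.selected_columns
    if cols.size == 0:
        raise ValueError("no informative differential repeats; check the annotation")
    bins = _repeats.bin_by_repeats(
        rm, cols, fragments, config.n_subgenomes, seed=config.seed,
        n_neighbors=config.n_neighbors, amplify_fold=config.amplify_fold,
        reassign_ratio=config.reassign_ratio, max_trials=config.max_iter,
        tol_fraction=config.tol_fraction)
    return bins, report
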