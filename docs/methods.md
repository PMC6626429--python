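# Methods

## Model and assumptions

ploidbin assumes that the subgenomes of an allopolyploid differ in the
copy number and sequence of their repetitive DNA: transposon and satellite
families that amplified in one progenitor after divergence leave k-mers
that are (a) frequent genome-wide and (b) largely private to one
subgenome. Fragments of the assembly are represented by their counts over
these repeat k-mers; fragments from the same subgenome then share repeat
*profiles* even when they carry different individual families, because
co-occurrence of families within fragments links them transitively through
the nearest-neighbour graph. The method makes no assumption about GC
content, coverage, gene content or overall sequence similarity — it only
requires that each subgenome carries enough private high-copy repeat
sequence for most fragments to contain some of it.

The number of subgenomes `m` is supplied by the user; the method does not
estimate it.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 26 | k-mer length (2–32; canonical, strand-collapsed) |
| `min_count` | genome_bp / 2.9e9 × 150, floor 3 | genome-wide frequency floor for a k-mer to count as repetitive |
| `fragment_length` | 250 kb | fragment size; 100 kb suits draft assemblies, 10 kb the bundled Mb-scale simulations |
| `min_length` | 2.5 kb | fragments below this carry too few repeat-mers and are excluded |
| `n_neighbors` | 20 | k-NN graph degree before symmetrization |
| `dims` / `d_spec` | m + 1 / m | kernel-PCA and spectral embedding dimensions |
| `fold_threshold` | 20 | differential-k-mer dominance fold (bin total vs best other bin, zero clamped to 1) |
| `min_own_count` | 10 | minimum bin total for a differential k-mer |
| `ratio_threshold` | 3 | best-vs-second score ratio for recruiting a fragment |
| `max_iter`, `tol_fraction` | 10, 1e-3 | amplification stopping rule (relative bp change per bin) |
| `window`, `min_margin` | 2, 1 bp | positional propagation: labeled flank count per side, required bp vote margin |
| repeat path: `discovery_fold`, `amplify_fold`, `reassign_ratio`, `top_n_per_bin` | 5, 8, 3, 150 | fold rules and informative-repeat selection for annotated-repeat binning |

Larger `k` increases specificity but lowers the number of repeat-mers per
fragment, so `min_count` should drop as `k` grows. The
`repeatmers_per_fragment_histogram` diagnostic flags a low-signal
configuration when the median row sum of the count matrix falls below 30
and recommends decreasing `k`, enlarging fragments or lowering
`min_count`.

## Numerical choices

- K-mers are 2-bit packed into `uint64` (so `k ≤ 32`); numeric code order
  equals lexicographic string order, making the vocabulary, column order
  and every downstream output deterministic. Windows containing N are
  skipped. Counting is exact hashing, not sketching.
- Counts enter the cosine kernel raw: cosine already normalizes magnitude,
  so repeat-rich and repeat-poor fragments of one subgenome are
  comparable. A `log1p` option exists for heavy-tailed vocabularies.
- Kernel PCA uses a dense eigensolver; eigenvector signs are fixed so each
  component's largest-magnitude entry is positive, making embeddings
  reproducible. Fragments with all-zero count rows have zero cosine
  similarity to everything, collapse to one embedded point, and are forced
  ambiguous rather than clustered.
- The k-NN graph is binary and symmetrized (an edge exists if either
  endpoint chose the other); isolated nodes are set aside as ambiguous
  before the Laplacian eigendecomposition. The spectral embedding drops
  the single trivial leading eigenvector; additional connected components
  appear as further zero eigenvalues with indicator-like eigenvectors
  (piecewise constant per component in any basis of the zero eigenspace).
- All vote/ratio rules clamp zero denominators to 1. The amplification
  loop re-evaluates previously labeled fragments each iteration
  (`freeze_initial` disables this), records per-iteration bin sizes, and
  stops on the bp tolerance, on `max_iter`, or when a label state repeats
  without meeting the tolerance (oscillation; both states are retained in
  the history). `max_iter = 0` is a no-op. When *no* bin yields
  differential features, the loop stops and keeps the current labels —
  recruiting against an empty feature set would erase the labeling.
- Degenerate clustering inputs (fewer distinct embedded points than bins)
  yield a single bin plus a warning instead of an error.
- Annotated repeats are assigned to the fragment containing their midpoint,
  so boundary-straddling instances are counted exactly once.
- Agreement metrics are bp-weighted throughout (the object of interest is
  sequence, not fragment count) and computed after a bp-maximizing
  one-to-one bin alignment (Hungarian assignment on the bp confusion
  matrix). Cohen's κ is reported both dropping ambiguous fragments and
  treating "ambiguous" as a category. Homogeneity/completeness and the
  silhouette/Calinski-Harabasz scores come from scikit-learn on classified
  fragments (fragment-weighted; fragments are near-uniform in length by
  construction).
- The subclass enrichment statistic is a one-vs-rest two-cell chi-squared
  per subclass — observed vs expected counts of selected consensus models
  in the subclass and its complement, with the null taken from the
  genome-wide subclass composition of distinct consensus models; expected
  cells below 1 are flagged unstable. This layout yields one statistic per
  subclass, the shape in which such scans are usually reported.
- One pipeline seed drives every stochastic stage (k-means and GMM
  initialization, vocabulary subsampling); equal config + seed gives
  byte-identical tabular outputs. Stage outputs are written per run but not
  content-hash cached: at the problem sizes this package targets a full
  re-run costs seconds and determinism makes caching redundant.

## The synthetic generator

`ploidbin.simulate` emulates exactly the premise the method exploits: each
subgenome is i.i.d. background sequence (default GC 0.40) carrying
`n_private_families` repeat families (default 20 × 50 copies × 500 bp)
private to it plus `n_shared_families` (default 10) common to all, with
private copies diverged from their consensus by per-copy substitutions
(default 0.02/site). Insertions replace background bp, so each subgenome's
truth bp equals `subgenome_length` exactly. Reciprocal equal-length
translocations (default 5 × 50 kb) swap segments between scaffolds of
different subgenomes; truth labels follow the sequence of origin, and
annotation entries fully inside a segment travel with it (straddling
instances are dropped as disrupted elements). Everything is reproducible
from one seed.

The default scenarios are the package's study conditions: `tobacco_like`
(2 × 2 Mb, a repeat-rich tetraploid), `wheat_like` (3 × 1.5 Mb, the
hexaploid analogue) and `low_repeat` (5 copies per family, a stress test
in which the barcode signal nearly vanishes — private-family k-mers fall
below the frequency filter, the low-signal diagnostic fires and recovery
collapses). Pipeline runs on these scenarios use k = 21, `min_count` 10
and 10 kb fragments, keeping the ratio of fragment size to genome size in
the regime the defaults target for Gb-scale assemblies.

What the generator does *not* model: homeologous background similarity
(backgrounds are independent across subgenomes; under any repeat-frequency
filter ≥ 3 this is indistinguishable from a shared diverged background,
because near-unique background k-mers never enter the vocabulary, but it
means the simulations cannot probe confusion from conserved single-copy
sequence), indels and truth-coordinate drift, transposon nesting and LTR
structure, target-site duplications, segmental duplications, and
assembly-error chimerism. Passing on these simulations therefore
demonstrates the machinery — selection, clustering, amplification,
propagation, scoring — under the method's own assumptions, not performance
on real assemblies, where repeat annotation quality, uneven fragment
lengths and shared repeat proliferation after hybridization all erode the
signal.

## Design choices where the design was open

- **Canonical k-mers** by default: repeats insert in both orientations, so
  stranded counting would split each family's signal arbitrarily; a
  `stranded` mode is provided.
- **Remainder fragments** (scaffold tails shorter than `fragment_length`)
  are kept when ≥ `min_length`: it maximizes classified sequence and the
  length floor already guards signal quality.
- **Positional propagation** is a windowed bp-weighted majority vote
  iterated to a fixed point, with newly labeled fragments voting in later
  sweeps and labeled fragments never overwritten. It is an optional
  post-processing stage; a tie between flanks leaves a fragment ambiguous.
- **Conflicted scaffolds** under the `unanimity` merge rule are reported,
  not split: discordance may indicate a mis-assembly, but breaking
  scaffolds is out of scope.
- **Progenitor mapping** counts exact shared canonical k-mers per
  progenitor with a best/second ratio of 2 — a deliberately simple,
  alignment-free reference labeling used for validation only.

## Limitations

- `k ≤ 32` (uint64 packing); genomes are held in memory (desk-scale, not
  >10 Gb); no disk-backed or probabilistic counting.
- The spectral stage uses dense eigendecomposition, appropriate up to a
  few thousand fragments per run.
- Subsampling the vocabulary (for very large repeat spaces) trades
  recall of differential k-mers for memory, as in the scaled-up setting
  it emulates.
- Very repeat-poor genomes (the `low_repeat` regime) are genuinely out of
  reach of the signal the method relies on; the diagnostic detects this
  but cannot fix it.
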