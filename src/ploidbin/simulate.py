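"""Synthetic allopolyploid genome generator with truth labels.

Emulates the biological premise behind repeat-k-mer subgenome binning: each
progenitor genome carries its own amplified transposon-like repeat families
(the subgenome-private barcode signal) on top of families common to all
subgenomes, and the allopolyploid is their concatenation, optionally
scrambled by reciprocal inter-subgenome translocations.  The output is a
FASTA assembly, a truth BED of sequence-of-origin labels and a GFF3 of every
inserted repeat instance — enough to exercise and score every pipeline
stage without external data.

Backgrounds are i.i.d. nucleotides at a configurable GC: background k-mers
(k >= 13) are then essentially unique genome-wide and never pass a repeat
frequency filter, so the only inter-subgenome k-mer signal is the one the
generator deliberately planted.  Repeat copies diverge from their family
consensus by per-copy substitutions only, which keeps all truth coordinates
exact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import AssemblyRecord, RepeatFeature, write_fasta, write_repeat_gff3

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_SUBCLASS_CYCLE = ("LTR/Gypsy", "LTR/Copia", "Simple", "unknown")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic allopolyploid.

    ``subgenome_length`` is the final bp per subgenome (repeat insertions
    replace background, they do not extend it).  Private families are
    inserted only into their home subgenome, with per-copy substitutions at
    ``mutation_rate_private``; shared families are inserted verbatim into
    every subgenome.  Reciprocal equal-length translocations swap segments
    between scaffolds of different subgenomes and are recorded in the truth
    labels.
    """

    n_subgenomes: int = 2
    subgenome_length: int = 2_000_000
    n_shared_families: int = 10
    n_private_families: int = 20
    family_length: int = 500
    copies_per_family: int = 50
    mutation_rate_private: float = 0.02
    background_gc: float = 0.40
    translocation_count: int = 5
    translocation_length: int = 50_000
    scaffold_length: int = 500_000
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_subgenomes < 1:
            raise ValueError("n_subgenomes must be >= 1")
        for name in ("subgenome_length", "family_length", "scaffold_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_shared_families", "n_private_families", "copies_per_family",
                     "translocation_count", "translocation_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.mutation_rate_private <= 1.0:
            raise ValueError("mutation_rate_private must be in [0, 1]")
        if not 0.0 <= self.background_gc <= 1.0:
            raise ValueError("background_gc must be in [0, 1]")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SimulationResult:
    assembly: list[AssemblyRecord]
    truth: list[tuple[str, int, int, int]]  # scaffold, start, end, origin subgenome
    features: list[RepeatFeature]
    config: SimulationConfig

    @property
    def truth_label_names(self) -> list[str]:
        return [f"subgenome_{s}" for s in range(self.config.n_subgenomes)]

    def truth_bp_per_subgenome(self) -> np.ndarray:
        out = np.zeros(self.config.n_subgenomes, dtype=np.int64)
        for _, start, end, label in self.truth:
            out[label] += end - start
        return out

    def write(self, out_dir) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out_dir / "genome.fasta",
            "truth": out_dir / "truth.bed",
            "gff3": out_dir / "repeats.gff3",
            "config": out_dir / "config.json",
        }
        write_fasta(self.assembly, paths["fasta"])
        with open(paths["truth"], "w") as fh:
            for scaffold, start, end, label in self.truth:
                fh.write(f"{scaffold}\t{start}\t{end}\tsubgenome_{label}\n")
        write_repeat_gff3(self.features, paths["gff3"])
        with open(paths["config"], "w") as fh:
            json.dump(dataclasses.asdict(self.config), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _random_seq_codes(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    return rng.choice(4, size=length, p=[at, gc / 2.0, gc / 2.0, at]).astype(np.uint8)


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    if rate == 0.0:
        return codes.copy()
    out = codes.copy()
    hit = np.flatnonzero(rng.random(codes.size) < rate)
    # substitute with one of the three other bases
    out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate the assembly, truth labels and repeat annotation.

    Fully reproducible under ``config.seed``; raises when the requested
    insertions exceed a scaffold's capacity.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_subgenomes
    n_scaf = max(1, config.subgenome_length // config.scaffold_length)
    scaf_lengths = [config.scaffold_length] * n_scaf
    remainder = config.subgenome_length - n_scaf * config.scaffold_length
    if remainder > 0:
        scaf_lengths.append(remainder)

    # family consensus sequences and metadata
    families: list[dict] = []
    for i in range(config.n_shared_families):
        families.append({
            "name": f"shared_f{i:03d}", "home": None,
            "consensus": _random_seq_codes(rng, config.family_length, config.background_gc),
        })
    for s in range(m):
        for i in range(config.n_private_families):
            families.append({
                "name": f"sg{s}_f{i:03d}", "home": s,
                "consensus": _random_seq_codes(rng, config.family_length, config.background_gc),
            })
    for j, fam in enumerate(families):
        fam["subclass"] = _SUBCLASS_CYCLE[j % len(_SUBCLASS_CYCLE)]

    sequences: dict[str, np.ndarray] = {}
    truth_arrays: dict[str, np.ndarray] = {}
    features_by_scaffold: dict[str, list[RepeatFeature]] = {}

    for s in range(m):
        scaffold_ids = [f"sg{s}_scaf{c}" for c in range(len(scaf_lengths))]
        # choose a scaffold for every copy of every family present in s
        copies: dict[int, list[tuple[dict, np.ndarray]]] = {c: [] for c in range(len(scaf_lengths))}
        for fam in families:
            if fam["home"] is not None and fam["home"] != s:
                continue
            for _ in range(config.copies_per_family):
                c = int(rng.integers(0, len(scaf_lengths)))
                if fam["home"] is None:
                    copy = fam["consensus"].copy()
                else:
                    copy = _mutate(rng, fam["consensus"], config.mutation_rate_private)
                copies[c].append((fam, copy))
        for c, scaffold_id in enumerate(scaffold_ids):
            scaf_len = scaf_lengths[c]
            inserts = copies[c]
            insert_bp = sum(copy.size for _, copy in inserts)
            if insert_bp > scaf_len:
                raise ValueError(
                    f"requested insertions ({insert_bp} bp) exceed capacity of "
                    f"{scaffold_id} ({scaf_len} bp)")
            bg_len = scaf_len - insert_bp
            background = _random_seq_codes(rng, bg_len, config.background_gc)
            offsets = np.sort(rng.integers(0, bg_len + 1, size=len(inserts)))
            order = rng.permutation(len(inserts))
            pieces: list[np.ndarray] = []
            feats: list[RepeatFeature] = []
            cursor_bg = 0
            cursor_out = 0
            for off, idx in zip(offsets, order):
                fam, copy = inserts[idx]
                pieces.append(background[cursor_bg:off])
                cursor_out += off - cursor_bg
                cursor_bg = off
                feats.append(RepeatFeature(scaffold_id, cursor_out,
                                           cursor_out + copy.size, fam["name"],
                                           fam["name"], fam["subclass"]))
                pieces.append(copy)
                cursor_out += copy.size
            pieces.append(background[cursor_bg:])
            seq = np.concatenate(pieces) if pieces else background
            assert seq.size == scaf_len
            sequences[scaffold_id] = seq
            truth_arrays[scaffold_id] = np.full(scaf_len, s, dtype=np.int8)
            features_by_scaffold[scaffold_id] = feats

    # reciprocal equal-length translocations between subgenomes
    if m >= 2 and config.translocation_count > 0:
        scaffold_of = {sid: int(sid.split("_")[0][2:]) for sid in sequences}
        all_ids = sorted(sequences)
        for _ in range(config.translocation_count):
            length = config.translocation_length
            s1, s2 = rng.choice(m, size=2, replace=False)
            cands1 = [sid for sid in all_ids
                      if scaffold_of[sid] == s1 and sequences[sid].size >= length]
            cands2 = [sid for sid in all_ids
                      if scaffold_of[sid] == s2 and sequences[sid].size >= length]
            if not cands1 or not cands2:
                log.warning("translocation skipped: no scaffold long enough")
                continue
            x = cands1[int(rng.integers(len(cands1)))]
            y = cands2[int(rng.integers(len(cands2)))]
            a = int(rng.integers(0, sequences[x].size - length + 1))
            b = int(rng.integers(0, sequences[y].size - length + 1))
            _swap_segments(sequences, truth_arrays, features_by_scaffold,
                           x, a, y, b, length)

    assembly = [AssemblyRecord(sid, "".join(_BASES[sequences[sid]]))
                for sid in sorted(sequences)]
    truth = []
    for sid in sorted(truth_arrays):
        arr = truth_arrays[sid]
        boundaries = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [arr.size]))
        for start, end in zip(starts, ends):
            truth.append((sid, int(start), int(end), int(arr[start])))
    features = sorted(
        (f for feats in features_by_scaffold.values() for f in feats),
        key=lambda f: (f.scaffold_id, f.start),
    )
    return SimulationResult(assembly, truth, features, config)


def _swap_segments(sequences, truth_arrays, features_by_scaffold,
                   x: str, a: int, y: str, b: int, length: int) -> None:
    """Swap [a, a+L) of scaffold x with [b, b+L) of scaffold y in place.

    Repeat instances fully inside a segment travel with it; instances
    straddling a junction are dropped (the element is disrupted).
    """
    seg_x = sequences[x][a : a + length].copy()
    sequences[x][a : a + length] = sequences[y][b : b + length]
    sequences[y][b : b + length] = seg_x
    lab_x = truth_arrays[x][a : a + length].copy()
    truth_arrays[x][a : a + length] = truth_arrays[y][b : b + length]
    truth_arrays[y][b : b + length] = lab_x

    def split(feats, start, end):
        inside, outside = [], []
        for f in feats:
            if f.start >= start and f.end <= end:
                inside.append(f)
            elif f.end <= start or f.start >= end:
                outside.append(f)
            # straddling features dropped
        return inside, outside

    in_x, out_x = split(features_by_scaffold[x], a, a + length)
    in_y, out_y = split(features_by_scaffold[y], b, b + length)
    moved_to_y = [RepeatFeature(y, f.start - a + b, f.end - a + b,
                                f.consensus_id, f.family, f.subclass) for f in in_x]
    moved_to_x = [RepeatFeature(x, f.start - b + a, f.end - b + a,
                                f.consensus_id, f.family, f.subclass) for f in in_y]
    features_by_scaffold[x] = out_x + moved_to_x
    features_by_scaffold[y] = out_y + moved_to_y


def default_scenarios() -> dict[str, SimulationConfig]:
    """Named study conditions used throughout the test suite.

    ``tobacco_like``: 2 subgenomes x 2 Mb, 20 private families x 50 copies x
    500 bp each, 5 translocations — a tetraploid with abundant private
    repeat signal.  ``wheat_like``: the 3-subgenome analogue at 1.5 Mb per
    subgenome.  ``low_repeat``: the tetraploid with only 5 copies per family,
    a stress test where the repeat barcode nearly vanishes.
    """
    tobacco = SimulationConfig()
    return {
        "tobacco_like": tobacco,
        "wheat_like": tobacco.replace(n_subgenomes=3, subgenome_length=1_500_000),
        "low_repeat": tobacco.replace(copies_per_family=5),
    }
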