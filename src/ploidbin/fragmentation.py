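"""Split scaffolds into near-uniform fragments and merge labels back.

The binning machinery works on fixed-length fragments rather than whole
scaffolds because repeat k-mer profiles are only comparable between
sequences of similar length.  Each scaffold of length L is tiled into
``ceil(L / fragment_length)`` non-overlapping candidate fragments (the last
being the remainder); fragments shorter than ``min_length`` are excluded and
reported, since very short sequences carry too few repeat k-mers for
confident classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .io import AssemblyRecord, fragment_header

log = logging.getLogger(__name__)

AMBIGUOUS = -1


@dataclass(frozen=True)
class Fragment:
    fragment_id: str
    scaffold_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FragmentSet:
    """Ordered, non-overlapping fragments tiling an assembly."""

    fragments: list[Fragment]
    fragment_length: int
    min_length: int
    excluded: list[tuple[str, int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([f.length for f in self.fragments], dtype=np.int64)

    @property
    def fragment_ids(self) -> list[str]:
        return [f.fragment_id for f in self.fragments]

    @property
    def excluded_bp(self) -> int:
        return sum(end - start for _, start, end in self.excluded)

    def by_scaffold(self) -> dict[str, list[int]]:
        """Fragment indices per scaffold, in coordinate order."""
        out: dict[str, list[int]] = {}
        for i, frag in enumerate(self.fragments):
            out.setdefault(frag.scaffold_id, []).append(i)
        for idxs in out.values():
            idxs.sort(key=lambda i: self.fragments[i].start)
        return out

    def sequences(self, assembly: Sequence[AssemblyRecord]) -> Iterator[str]:
        seqs = {rec.scaffold_id: rec.sequence for rec in assembly}
        for frag in self.fragments:
            yield seqs[frag.scaffold_id][frag.start : frag.end]

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for frag in self.fragments:
                fh.write(f"{frag.scaffold_id}\t{frag.start}\t{frag.end}\t{frag.fragment_id}\n")


def chunk_assembly(assembly: Sequence[AssemblyRecord], fragment_length: int = 250_000,
                   min_length: int = 2_500) -> FragmentSet:
    """Tile every scaffold into fragments of at most ``fragment_length`` bp.

    Remainder fragments (and whole short scaffolds) are kept when they are at
    least ``min_length`` bp, otherwise excluded and recorded so that total bp
    is conserved: retained + excluded = assembly bp.
    """
    if fragment_length <= 0:
        raise ValueError("fragment_length must be positive")
    if min_length < 0:
        raise ValueError("min_length must be non-negative")
    if min_length >= fragment_length:
        log.warning(
            "min_length %d >= fragment_length %d: full-length fragments would "
            "be the only survivors", min_length, fragment_length,
        )
    fragments: list[Fragment] = []
    excluded: list[tuple[str, int, int]] = []
    for rec in assembly:
        for start in range(0, rec.length, fragment_length):
            end = min(start + fragment_length, rec.length)
            if end - start >= min_length:
                fragments.append(
                    Fragment(fragment_header(rec.scaffold_id, start, end),
                             rec.scaffold_id, start, end)
                )
            else:
                excluded.append((rec.scaffold_id, start, end))
    if excluded:
        log.info("excluded %d fragments (< %d bp, %d bp total)",
                 len(excluded), min_length, sum(e - s for _, s, e in excluded))
    return FragmentSet(fragments, fragment_length, min_length, excluded)


@dataclass
class ScaffoldLabels:
    """Scaffold-level labels after merging fragment labels."""

    labels: dict[str, int]          # scaffold -> bin index or AMBIGUOUS
    conflicts: list[str]            # scaffolds with non-unanimous labels (unanimity rule)
    rule: str


def merge_labels_to_scaffolds(bins, fragments: FragmentSet,
                              rule: str = "majority_bp") -> ScaffoldLabels:
    """Merge fragment labels back to their scaffold of origin.

    ``majority_bp`` assigns the label holding the majority of labeled bp;
    ``unanimity`` only assigns when all labeled fragments agree and flags
    conflicted scaffolds (potential mis-assemblies) as ambiguous.
    """
    if rule not in ("majority_bp", "unanimity"):
        raise ValueError(f"unknown merge rule {rule!r}")
    votes: dict[str, dict[int, int]] = {}
    for i, frag in enumerate(fragments.fragments):
        label = int(bins.labels[i])
        if label == AMBIGUOUS:
            continue
        votes.setdefault(frag.scaffold_id, {}).setdefault(label, 0)
        votes[frag.scaffold_id][label] += frag.length
    labels: dict[str, int] = {}
    conflicts: list[str] = []
    for frag in fragments.fragments:  # preserves scaffold order, incl. all-ambiguous
        labels.setdefault(frag.scaffold_id, AMBIGUOUS)
    for scaffold, tally in votes.items():
        if rule == "majority_bp":
            labels[scaffold] = max(tally.items(), key=lambda kv: (kv[1], -kv[0]))[0]
        else:
            if len(tally) == 1:
                labels[scaffold] = next(iter(tally))
            else:
                conflicts.append(scaffold)
    if conflicts:
        log.warning("%d scaffolds carry conflicting labels under unanimity rule",
                    len(conflicts))
    return ScaffoldLabels(labels, conflicts, rule)
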