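"""Readers and writers for the on-disk formats the binning pipeline touches.

Everything here is plumbing: FASTA assemblies in, repeat annotations in
(GFF3 / BED / RepeatMasker ``.out``), per-bin FASTA and BED/TSV tracks out.
All in-memory coordinates are 0-based half-open (BED convention); conversion
from 1-based inclusive dialects happens here and only here.
"""

from __future__ import annotations

import gzip
import json
import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

# IUPAC ambiguity codes other than N; folded to N on read, with a warning.
_IUPAC_AMBIGUOUS = "RYSWKMBDHV"
_FOLD_TABLE = str.maketrans(_IUPAC_AMBIGUOUS, "N" * len(_IUPAC_AMBIGUOUS))
_VALID_CHARS = frozenset("ACGTN")


@dataclass(frozen=True)
class AssemblyRecord:
    """One scaffold of an assembly: uppercase DNA over {A,C,G,T,N}."""

    scaffold_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for scaffold {self.scaffold_id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RepeatFeature:
    """A single annotated repeat instance (0-based half-open coordinates)."""

    scaffold_id: str
    start: int
    end: int
    consensus_id: str
    family: str = ""
    subclass: str = "unknown"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start},{self.end}) for {self.consensus_id!r}"
            )
        if not self.consensus_id:
            raise ValueError("consensus_id must be non-empty")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _open_text(path: str | os.PathLike):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _clean_sequence(raw: str, scaffold_id: str) -> str:
    seq = raw.upper()
    folded = seq.translate(_FOLD_TABLE)
    if folded != seq:
        n_folded = sum(1 for a, b in zip(seq, folded) if a != b)
        log.warning(
            "scaffold %s: %d IUPAC ambiguity bases folded to N", scaffold_id, n_folded
        )
    bad = set(folded) - _VALID_CHARS
    if bad:
        raise ValueError(
            f"scaffold {scaffold_id!r} contains non-nucleotide characters: {sorted(bad)}"
        )
    return folded


def read_fasta(path: str | os.PathLike) -> list[AssemblyRecord]:
    """Read a (possibly gzipped) FASTA into a list of AssemblyRecord.

    Sequences are uppercased; IUPAC ambiguity codes other than N are folded
    to N with a warning; duplicate scaffold IDs are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[AssemblyRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate scaffold ID {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append(AssemblyRecord(rec.id, _clean_sequence(str(rec.seq), rec.id)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[AssemblyRecord], path: str | os.PathLike,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.scaffold_id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Repeat annotations
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            key, _, val = chunk.partition("=")
            attrs[key.strip()] = val.strip()
    return attrs


def _feature_from_gff3(line: str, lineno: int) -> RepeatFeature | None:
    if line.startswith("#") or not line.strip():
        return None
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 9:
        raise ValueError(f"line {lineno}: GFF3 record has {len(cols)} columns, expected 9")
    try:
        start = int(cols[3]) - 1  # 1-based inclusive on disk
        end = int(cols[4])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-integer coordinates") from exc
    attrs = _parse_gff3_attributes(cols[8])
    consensus = attrs.get("ID") or attrs.get("Name") or attrs.get("Target", "").split()[0:1]
    if isinstance(consensus, list):
        consensus = consensus[0] if consensus else ""
    if not consensus:
        raise ValueError(f"line {lineno}: no ID/Name/Target attribute for repeat")
    family = attrs.get("family", attrs.get("Name", consensus))
    subclass = attrs.get("subclass") or attrs.get("class") or "unknown"
    if end <= start:
        raise ValueError(f"line {lineno}: end <= start after normalization")
    return RepeatFeature(cols[0], start, end, consensus, family, subclass)


def _feature_from_bed(line: str, lineno: int) -> RepeatFeature | None:
    if line.startswith(("#", "track", "browser")) or not line.strip():
        return None
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 3:
        raise ValueError(f"line {lineno}: BED record has {len(cols)} columns, expected >= 3")
    try:
        start, end = int(cols[1]), int(cols[2])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-integer coordinates") from exc
    if end <= start:
        raise ValueError(f"line {lineno}: end <= start")
    name = cols[3] if len(cols) > 3 and cols[3] else f"feature_{lineno}"
    # name may carry consensus|family|subclass, pipe-separated
    parts = name.split("|")
    consensus = parts[0]
    family = parts[1] if len(parts) > 1 else consensus
    subclass = parts[2] if len(parts) > 2 else "unknown"
    return RepeatFeature(cols[0], start, end, consensus, family, subclass)


def _feature_from_rm_out(line: str, lineno: int) -> RepeatFeature | None:
    stripped = line.strip()
    if not stripped or stripped.startswith(("SW", "score", "*")):
        return None
    cols = stripped.split()
    if len(cols) < 11:
        raise ValueError(f"line {lineno}: RepeatMasker .out record has {len(cols)} fields")
    try:
        start = int(cols[5]) - 1
        end = int(cols[6])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-integer coordinates") from exc
    if end <= start:
        raise ValueError(f"line {lineno}: end <= start after normalization")
    consensus = cols[9]
    subclass = cols[10] if cols[10] else "unknown"
    return RepeatFeature(cols[4], start, end, consensus, consensus, subclass)


_DIALECTS = {
    "gff3": _feature_from_gff3,
    "bed": _feature_from_bed,
    "repeatmasker_out": _feature_from_rm_out,
}


def read_repeat_annotation(path: str | os.PathLike,
                           dialect: str = "gff3") -> list[RepeatFeature]:
    """Parse a repeat annotation; coordinates are normalized to 0-based half-open.

    ``dialect`` is one of ``gff3``, ``bed``, ``repeatmasker_out``.  GFF3 and
    RepeatMasker ``.out`` are 1-based inclusive on disk and are shifted here;
    BED is already half-open.  A record lacking a class/subclass attribute
    gets subclass ``"unknown"``.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    parse = _DIALECTS[dialect]
    features: list[RepeatFeature] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            feat = parse(line, lineno)
            if feat is not None:
                features.append(feat)
    return features


def write_repeat_gff3(features: Sequence[RepeatFeature], path: str | os.PathLike,
                      source: str = "ploidbin") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(features):
            attrs = f"ID={f.consensus_id}.{i};family={f.family};subclass={f.subclass}"
            fh.write(
                f"{f.scaffold_id}\t{source}\tdispersed_repeat\t{f.start + 1}\t{f.end}"
                f"\t.\t+\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Binned output
# ---------------------------------------------------------------------------

def fragment_header(scaffold_id: str, start: int, end: int) -> str:
    """Reversible fragment naming: ``scaffold::start-end``."""
    return f"{scaffold_id}::{start}-{end}"


def parse_fragment_header(header: str) -> tuple[str, int, int]:
    scaffold, _, coords = header.rpartition("::")
    start_s, _, end_s = coords.partition("-")
    return scaffold, int(start_s), int(end_s)


def write_bins_fasta(bins, fragments, assembly: Sequence[AssemblyRecord],
                     out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write one FASTA per bin (empty bins yield empty files).

    Headers encode ``scaffold::start-end`` so positions are recoverable.
    Returns a mapping of bin label to written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seqs = {rec.scaffold_id: rec.sequence for rec in assembly}
    for frag in fragments.fragments:
        if frag.scaffold_id not in seqs:
            raise ValueError(f"fragment references unknown scaffold {frag.scaffold_id!r}")
    paths: dict[str, Path] = {}
    handles = {}
    try:
        for b, name in enumerate(bins.label_names):
            paths[name] = out_dir / f"{name}.fasta"
            handles[b] = open(paths[name], "w")
        for frag, label in zip(fragments.fragments, bins.labels):
            if label < 0:
                continue
            seq = seqs[frag.scaffold_id][frag.start : frag.end]
            handles[label].write(f">{fragment_header(frag.scaffold_id, frag.start, frag.end)}\n")
            for i in range(0, len(seq), 80):
                handles[label].write(seq[i : i + 80] + "\n")
    finally:
        for fh in handles.values():
            fh.close()
    return paths


def write_labels_bed(bins, fragments, path: str | os.PathLike,
                     provenance: Sequence[str] | None = None) -> None:
    """BED of fragment labels; optional provenance column
    (``clustered|amplified|propagated``)."""
    with open(path, "w") as fh:
        for i, frag in enumerate(fragments.fragments):
            label = bins.labels[i]
            name = bins.label_names[label] if label >= 0 else "ambiguous"
            row = [frag.scaffold_id, str(frag.start), str(frag.end), name]
            if provenance is not None:
                row.append(provenance[i])
            fh.write("\t".join(row) + "\n")


def write_json(obj, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
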