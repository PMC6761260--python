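"""Readers and writers for the pipeline's standard formats.

FASTA goes through Bio.SeqIO; BED6 is validated line by line so errors can
name the offending line; genomic coordinates are BED-convention 0-based
half-open throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

log = logging.getLogger("mircomp")

RNA_ALPHABET = set("ACGUN")
DNA_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class GenomicInterval:
    scaffold: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str  # "+" or "-"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.scaffold}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_fasta(path, alphabet: str = "either") -> dict[str, str]:
    """Read FASTA into an ordered id->sequence map.

    Sequences are upper-cased; with ``alphabet="rna"`` T is normalized to U
    (and with ``"dna"`` U to T).  Duplicate ids and empty files are errors.
    """
    if alphabet not in ("rna", "dna", "either"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if alphabet == "rna":
            seq = seq.replace("T", "U")
        elif alphabet == "dna":
            seq = seq.replace("U", "T")
        if rec.id in out:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = seq
    if not out:
        raise FormatError(f"no FASTA records in {path}")
    return out


def write_fasta(records: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path) -> list[tuple[str, GenomicInterval]]:
    """Read BED6 as (name, interval) pairs, preserving file order."""
    out: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if s >= e:
                raise FormatError(
                    f"{path}:{lineno}: start ({s}) must be < end ({e})"
                )
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            out.append((name, GenomicInterval(chrom, s, e, strand)))
    return out


def write_bed(records: list[tuple[str, GenomicInterval]], path) -> None:
    with open(path, "w") as fh:
        for name, iv in records:
            fh.write(
                f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


@dataclass
class Alignment:
    """A per-gene multi-species alignment (gap character ``-``)."""

    sequences: dict[str, str]  # species -> aligned sequence (RNA)
    n_columns: int

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    def ungapped(self, species: str) -> str:
        return self.sequences[species].replace("-", "")

    def ungapped_length(self, species: str) -> int:
        return len(self.ungapped(species))

    @property
    def single_species(self) -> bool:
        return len(self.sequences) == 1


def read_alignment(path, tree_tips=None) -> Alignment:
    """Read an aligned FASTA (one gene, one sequence per species).

    All sequences must have the same aligned length.  Species not on the
    supplied tree-tip list are kept but logged as a warning.
    """
    seqs = read_fasta(path, alphabet="rna")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise FormatError(
            f"{path}: aligned sequences have unequal lengths {sorted(lengths)}"
        )
    if tree_tips is not None:
        unknown = [s for s in seqs if s not in tree_tips]
        if unknown:
            log.warning("%s: species not on tree: %s", path, ", ".join(unknown))
    aln = Alignment(sequences=seqs, n_columns=lengths.pop())
    if aln.single_species:
        log.info("%s: single-species alignment, no cross-species comparison", path)
    return aln


def ungapped_to_columns(aligned_seq: str) -> list[int]:
    """Map each ungapped offset to its 0-based alignment column."""
    return [i for i, c in enumerate(aligned_seq) if c != "-"]


def read_annotation(path) -> dict[str, set[str]]:
    """Read a two-column gene<TAB>GO_id table into gene -> set of terms."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected gene<TAB>GO_id")
            out.setdefault(parts[0], set()).add(parts[1])
    return out
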