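"""Reading and writing proteome length data.

The analysis is composition-blind (every bond shares one Δ), so a proteome
reduces to its protein length histogram.  FASTA files (one per organism,
filename stem = organism id, KEGG-style) are read with Biopython; histograms
round-trip through 2-column TSV tables with header ``length<TAB>count``.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .equilibrium import LengthDistribution
from .errors import DataFormatError

__all__ = [
    "ProteomeRecord",
    "read_fasta_lengths",
    "read_fasta_dir",
    "aggregate_records",
    "read_length_table",
    "write_length_table",
]

#: residue characters accepted without complaint (ambiguity codes count as residues)
_STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYXBZUO")


@dataclass
class ProteomeRecord:
    """One organism's protein length histogram."""

    organism_id: str
    distribution: LengthDistribution

    def __post_init__(self) -> None:
        if not self.organism_id:
            raise DataFormatError("organism_id must be nonempty")

    @property
    def n_proteins(self) -> float:
        return self.distribution.n_total


def _sequence_length(seq: str) -> int:
    """Residue count: whitespace and gaps removed, one terminal stop stripped."""
    s = "".join(seq.split()).replace("-", "")
    if s.endswith("*"):
        s = s[:-1]
    return len(s)


def read_fasta_lengths(path: str | Path) -> ProteomeRecord:
    """Histogram the record lengths of one FASTA file.

    The organism id is the filename stem.  Nonstandard residue characters are
    warned about but still counted — only lengths matter here.
    """
    path = Path(path)
    counts: dict[int, float] = {}
    odd_chars: set[str] = set()
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        body = "".join(seq.split()).replace("-", "").rstrip("*").upper()
        odd_chars |= set(body) - _STANDARD_RESIDUES
        L = _sequence_length(seq.upper())
        if L >= 1:
            counts[L] = counts.get(L, 0.0) + 1.0
            n += 1
    if n == 0:
        raise DataFormatError(f"no FASTA records with residues in {path}")
    if odd_chars:
        warnings.warn(
            f"{path.name}: nonstandard residue characters counted as residues: "
            f"{''.join(sorted(odd_chars))}"
        )
    return ProteomeRecord(path.stem, LengthDistribution(counts))


def read_fasta_dir(path: str | Path) -> list[ProteomeRecord]:
    """One record per FASTA file in a directory (KEGG-style layout)."""
    path = Path(path)
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in {".fa", ".faa", ".fasta"}
    )
    if not files:
        raise DataFormatError(f"no FASTA files found in {path}")
    return [read_fasta_lengths(p) for p in files]


def aggregate_records(records: list[ProteomeRecord]) -> ProteomeRecord:
    """Sum the histograms of several organisms into one pooled record."""
    if not records:
        raise DataFormatError("no records to aggregate")
    pooled = records[0].distribution
    for rec in records[1:]:
        pooled = pooled.merged(rec.distribution)
    return ProteomeRecord("pooled", pooled)


def read_length_table(path: str | Path) -> ProteomeRecord:
    """Read a ``length<TAB>count`` TSV into a record.

    Malformed rows and duplicated lengths raise :class:`DataFormatError`
    naming the offending line.
    """
    path = Path(path)
    counts: dict[int, float] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise DataFormatError(f"{path}: empty file") from None
        if [h.strip().lower() for h in header] != ["length", "count"]:
            raise DataFormatError(
                f"{path}: line 1: expected header 'length\\tcount', got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise DataFormatError(f"{path}: line {lineno}: expected 2 fields")
            try:
                L = int(row[0])
                c = int(row[1])
            except ValueError:
                raise DataFormatError(
                    f"{path}: line {lineno}: non-integer field in {row!r}"
                ) from None
            if L < 1 or c < 0:
                raise DataFormatError(
                    f"{path}: line {lineno}: length must be >= 1 and count >= 0"
                )
            if L in counts:
                raise DataFormatError(f"{path}: line {lineno}: duplicate length {L}")
            if c > 0:
                counts[L] = float(c)
    if not counts:
        raise DataFormatError(f"{path}: table has no nonzero counts")
    return ProteomeRecord(path.stem, LengthDistribution(counts))


def write_length_table(record: ProteomeRecord, path: str | Path) -> None:
    """Write a record as a ``length<TAB>count`` TSV (lengths ascending)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("length\tcount\n")
        for L in sorted(record.distribution.counts):
            fh.write(f"{L}\t{int(record.distribution.counts[L])}\n")
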