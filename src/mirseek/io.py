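"""Readers and writers for the formats the pipeline touches.

FASTA and FASTQ go through strict validating readers: FASTA via Biopython
with duplicate-id rejection, FASTQ via a 4-line Phred+33 reader that
reports the offending line number on malformed input (a contract plain
``SeqIO`` does not give). Count matrices are pandas DataFrames wrapped in
:class:`CountTable`, written as tab-delimited text with a header row.

Coordinates are 0-based half-open internally; serialised locus strings use
the 1-based inclusive ``scaffold:start:end`` convention common in small-RNA
catalogue tables.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .seq import normalize_dna, to_rna


@dataclass(frozen=True)
class RawRead:
    """A single sequenced small-RNA record (pre-cleaning)."""

    read_id: str
    sequence: str  # uppercase DNA
    quality: str  # Phred+33 string, same length as sequence

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quality)}"
            )


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path, *, rna: bool = False) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Sequences are uppercased; U→T by default (DNA-internal convention) or
    T→U when ``rna=True``. Duplicate ids raise ``ValueError``. An empty
    file yields an empty mapping.
    """
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise ValueError(f"duplicate FASTA id: {rec.id!r} in {path}")
            s = str(rec.seq)
            out[rec.id] = to_rna(s) if rna else normalize_dna(s)
    return out


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]], path) -> None:
    if isinstance(records, dict):
        records = records.items()
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def read_fastq(path) -> Iterator[RawRead]:
    """Stream 4-line Phred+33 FASTQ records, validating as we go.

    Malformed records raise ``ValueError`` naming the line number. An
    empty file is a valid empty stream.
    """
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise ValueError(f"{path}:{lineno}: FASTQ header must start with '@'")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise ValueError(f"{path}:{lineno}: truncated FASTQ record")
            lineno += 3
            if not plus.startswith("+"):
                raise ValueError(f"{path}:{lineno - 1}: expected '+' separator line")
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}:{lineno}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            yield RawRead(header[1:].split()[0], normalize_dna(seq), qual)


def write_fastq(reads: Iterable[RawRead], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


class LibrarySet(dict):
    """Mapping of library label → list of :class:`RawRead`, labels unique."""

    @classmethod
    def from_paths(cls, paths: dict[str, str]) -> "LibrarySet":
        return cls({label: list(read_fastq(p)) for label, p in paths.items()})


# ---------------------------------------------------------------------------
# Count tables


class CountTable:
    """Row (miRNA/tag id) × column (library) non-negative integer counts,
    with an optional real-valued TPM layer."""

    def __init__(self, counts: pd.DataFrame, tpm: pd.DataFrame | None = None):
        counts = counts.astype("int64")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        if tpm is not None and (
            list(tpm.index) != list(counts.index)
            or list(tpm.columns) != list(counts.columns)
        ):
            raise ValueError("TPM layer must share the count layer's axes")
        self.tpm = tpm

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    def __eq__(self, other):
        if not isinstance(other, CountTable):
            return NotImplemented
        if not self.counts.equals(other.counts):
            return False
        if (self.tpm is None) != (other.tpm is None):
            return False
        return self.tpm is None or self.tpm.round(6).equals(other.tpm.round(6))

    def write(self, path) -> None:
        df = self.counts.copy()
        if self.tpm is not None:
            tpm = self.tpm.add_suffix("_TPM").round(6)
            df = pd.concat([df, tpm], axis=1)
        df.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def read(cls, path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="id")
        tpm_cols = [c for c in df.columns if c.endswith("_TPM")]
        count_cols = [c for c in df.columns if not c.endswith("_TPM")]
        tpm = None
        if tpm_cols:
            tpm = df[tpm_cols].copy()
            tpm.columns = [c[: -len("_TPM")] for c in tpm_cols]
        return cls(df[count_cols], tpm)


def write_count_table(table: CountTable, path) -> None:
    table.write(path)


def read_annotation_map(path) -> dict[str, set[str]]:
    """Tab-delimited ``gene<TAB>term`` lines → gene → set of terms.

    Lines starting with '#' are skipped; malformed lines raise with the
    line number.
    """
    out: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'gene<TAB>term'")
            gene, terms = parts[0], parts[1]
            out.setdefault(gene, set()).update(t for t in terms.split(",") if t)
    return out


# ---------------------------------------------------------------------------
# Locus strings


def format_locus(scaffold: str, start: int, end: int) -> str:
    """0-based half-open → 1-based inclusive ``scaffold:start:end``."""
    return f"{scaffold}:{start + 1}:{end}"


def parse_locus(s: str) -> tuple[str, int, int]:
    """Inverse of :func:`format_locus`."""
    scaffold, start, end = s.rsplit(":", 2)
    return scaffold, int(start) - 1, int(end)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
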