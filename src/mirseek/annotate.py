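"""Unique-tag annotation: collapsing, genome mapping, ncRNA classing.

Clean tags are collapsed into unique sequences carrying per-library count
vectors, classified hierarchically against non-coding-RNA reference sets
(rRNA > tRNA > snRNA > snoRNA > repeat > mRNA degradation, first match by
exact substring wins — short tags are degradation fragments of their
source transcripts, so substring containment, not alignment, is the
natural test), and mapped to the genome on both strands allowing a small
number of substitutions.

Mapping is an exact Hamming-neighbourhood scan (vectorised over all
genome offsets), equivalent by construction to a brute-force
sliding-window comparison; no heuristic seeding, so hit lists are
complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seq import revcomp, normalize_dna

NCRNA_PRECEDENCE = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "mRNA")
UNANNOTATED = "unannotated"

_BASE_CODE = {b: i for i, b in enumerate("ACGTN")}


@dataclass(frozen=True)
class GenomeHit:
    scaffold: str
    start: int  # 0-based half-open
    end: int
    strand: str
    mismatches: int


@dataclass
class UniqueTag:
    """A distinct clean sequence with per-library counts."""

    sequence: str  # DNA, 18–32 nt
    counts: dict[str, int]
    annotation: str = UNANNOTATED
    hits: list[GenomeHit] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


def collapse_tags(tags_per_library: dict[str, list[str]]) -> list[UniqueTag]:
    """Collapse per-library clean tag lists into unique tags.

    One record per distinct sequence; count vectors (over all configured
    libraries) sum to the input multiplicities. Output sorted by
    descending total count, then sequence, for stable reporting.
    """
    libraries = list(tags_per_library)
    table: dict[str, dict[str, int]] = {}
    for lib, tags in tags_per_library.items():
        for t in tags:
            t = normalize_dna(t)
            row = table.setdefault(t, {l: 0 for l in libraries})
            row[lib] += 1
    out = [UniqueTag(seq, counts) for seq, counts in table.items()]
    out.sort(key=lambda u: (-u.total_count, u.sequence))
    return out


class GenomeIndex:
    """Pigeonhole seed-and-verify scanner, exact for ≤ k substitutions.

    A query with ≤ k mismatches against some window must match at least
    one of k+1 contiguous query chunks exactly (pigeonhole), so locating
    every exact chunk occurrence with ``str.find`` and verifying the full
    window by Hamming count yields precisely the brute-force hit list,
    at a fraction of the cost. Genome Ns count as mismatches (tags are
    N-free after cleaning).
    """

    def __init__(self, genome: dict[str, str]):
        self.sequences = {name: normalize_dna(seq) for name, seq in genome.items()}

    @staticmethod
    def _chunks(m: int, n_chunks: int) -> list[tuple[int, int]]:
        bounds = [round(i * m / n_chunks) for i in range(n_chunks + 1)]
        return list(zip(bounds, bounds[1:]))

    def scan(self, tag: str, max_mismatches: int) -> list[GenomeHit]:
        tag = normalize_dna(tag)
        m = len(tag)
        hits: list[GenomeHit] = []
        for name, seq in self.sequences.items():
            if len(seq) < m:
                continue
            for q, strand in ((tag, "+"), (revcomp(tag), "-")):
                seen: set[int] = set()
                for lo, hi in self._chunks(m, max_mismatches + 1):
                    chunk = q[lo:hi]
                    pos = seq.find(chunk)
                    while pos != -1:
                        start = pos - lo
                        if 0 <= start <= len(seq) - m and start not in seen:
                            seen.add(start)
                            window = seq[start : start + m]
                            mm = 0
                            for a, b in zip(window, q):
                                if a != b:
                                    mm += 1
                                    if mm > max_mismatches:
                                        break
                            if mm <= max_mismatches:
                                hits.append(GenomeHit(name, start, start + m,
                                                      strand, mm))
                        pos = seq.find(chunk, pos + 1)
        hits.sort(key=lambda h: (h.scaffold, h.start, h.strand))
        return hits


def map_to_genome(tag: str, genome: dict[str, str] | GenomeIndex,
                  max_mismatches: int = 2) -> list[GenomeHit]:
    """All gapless loci of ``tag`` on either strand with ≤ ``max_mismatches``
    substitutions; reverse-strand hits are matches of the tag's reverse
    complement, reported in forward coordinates."""
    if len(normalize_dna(tag)) < 18:
        raise ValueError("tags shorter than 18 nt are not mapped")
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    return index.scan(tag, max_mismatches)


def classify_tag(tag: str, reference_sets: dict[str, dict[str, str]],
                 precedence: tuple[str, ...] = NCRNA_PRECEDENCE) -> str:
    """First class in ``precedence`` whose reference set contains ``tag``
    as an exact substring; otherwise ``unannotated``."""
    tag = normalize_dna(tag)
    for cls in precedence:
        refs = reference_sets.get(cls)
        if not refs:
            continue
        for ref in refs.values():
            if tag in normalize_dna(ref):
                return cls
    return UNANNOTATED


def annotate_tags(tags: list[UniqueTag],
                  reference_sets: dict[str, dict[str, str]],
                  precedence: tuple[str, ...] = NCRNA_PRECEDENCE) -> None:
    """In-place hierarchical classification of unique tags."""
    # Concatenate each class's references with a separator for fast
    # substring membership; the separator cannot occur inside a tag.
    joined = {
        cls: "#".join(normalize_dna(r) for r in refs.values())
        for cls, refs in reference_sets.items()
    }
    for tag in tags:
        tag.annotation = UNANNOTATED
        for cls in precedence:
            if cls in joined and tag.sequence in joined[cls]:
                tag.annotation = cls
                break


@dataclass
class MappingStats:
    """Per-library mapped-tag statistics with self-consistent percentages."""

    library: str
    unique_mapped: int
    unique_total: int
    total_mapped: int
    total_reads: int

    @property
    def unique_pct(self) -> float:
        return round(self.unique_mapped / self.unique_total * 100, 2) \
            if self.unique_total else 0.0

    @property
    def total_pct(self) -> float:
        return round(self.total_mapped / self.total_reads * 100, 2) \
            if self.total_reads else 0.0

    def to_dict(self) -> dict:
        return {
            "library": self.library,
            "unique_mapped": self.unique_mapped,
            "unique_total": self.unique_total,
            "unique_pct": self.unique_pct,
            "total_mapped": self.total_mapped,
            "total_reads": self.total_reads,
            "total_pct": self.total_pct,
        }


def mapping_stats(tags: list[UniqueTag], libraries: list[str],
                  denominators: dict[str, int] | None = None) -> list[MappingStats]:
    """Tally mapped unique tags and mapped read totals per library.

    ``denominators`` optionally overrides the total-read base (clean reads
    vs high-quality reads); by default the per-library sum of unique-tag
    counts (i.e. clean reads) is used, and the choice is visible in the
    report's ``total_reads`` field.
    """
    out = []
    for lib in libraries:
        present = [t for t in tags if t.counts.get(lib, 0) > 0]
        mapped = [t for t in present if t.hits]
        total_reads = (denominators or {}).get(
            lib, sum(t.counts[lib] for t in present))
        out.append(MappingStats(
            library=lib,
            unique_mapped=len(mapped),
            unique_total=len(present),
            total_mapped=sum(t.counts[lib] for t in mapped),
            total_reads=total_reads,
        ))
    return out


def compare_libraries(tags: list[UniqueTag], lib_a: str, lib_b: str,
                      ) -> tuple[float, float, float]:
    """(shared %, specific-to-A %, specific-to-B %) over the union of tags
    present (count > 0) in either library. Sums to 100 up to rounding."""
    for lib in (lib_a, lib_b):
        if not any(lib in t.counts for t in tags):
            raise KeyError(f"unknown library label: {lib}")
    in_a = {t.sequence for t in tags if t.counts.get(lib_a, 0) > 0}
    in_b = {t.sequence for t in tags if t.counts.get(lib_b, 0) > 0}
    union = len(in_a | in_b)
    if union == 0:
        return 0.0, 0.0, 0.0
    shared = len(in_a & in_b) / union * 100
    only_a = len(in_a - in_b) / union * 100
    only_b = len(in_b - in_a) / union * 100
    return round(shared, 2), round(only_a, 2), round(only_b, 2)


def tags_to_table(tags: list[UniqueTag], libraries: list[str]) -> pd.DataFrame:
    from .io import format_locus

    rows = []
    for t in tags:
        row = {"sequence": t.sequence, "annotation": t.annotation}
        for lib in libraries:
            row[lib] = t.counts.get(lib, 0)
        row["hits"] = ";".join(
            f"{format_locus(h.scaffold, h.start, h.end)}:{h.strand}:{h.mismatches}"
            for h in t.hits)
        rows.append(row)
    return pd.DataFrame(rows)
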