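"""Read-cleaning cascade with per-category accounting.

Each high-quality read is assigned to exactly the first matching category
in a fixed order, so the categories partition the library and the clean
count is the high-quality count minus the five artifact categories:

    low-quality → 3'adapter_null → insert_null → 5'adapter_contaminant
    → smaller_than_18nt → polyA → clean

Rules, since raw small-RNA pipelines rarely publish theirs:

* low-quality: any base below the Phred threshold (default Q20) or any N;
* 3'-adapter: the longest prefix of the 3' adapter (≥ 6 nt, ≤ 1 mismatch)
  found in the read; no such match → ``3'adapter_null``; the insert is
  everything before the match;
* insert_null: empty insert, or an insert that is exactly the 5' adapter
  (adapter dimer);
* 5'-adapter contaminant: insert starts with the 5' adapter (first 10 nt,
  ≤ 1 mismatch) — a read-through ligation artifact;
* smaller_than_18nt: insert shorter than ``min_len`` after trimming;
* polyA: insert with ≥ 90% adenine.

Percentages in the report are computed against the high-quality count,
the convention used in published per-category accounting tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import RawRead
from . import simulate as _sim

CATEGORY_ORDER = (
    _sim.ADAPTER3_NULL,
    _sim.INSERT_NULL,
    _sim.ADAPTER5_CONTAM,
    _sim.TOO_SHORT,
    _sim.POLYA,
)


@dataclass
class CleaningReport:
    """Per-library cleaning tallies mirroring a cleaning-statistics table."""

    library: str
    total_reads: int = 0
    high_quality: int = 0
    category_counts: dict[str, int] = field(default_factory=dict)
    clean_reads: int = 0

    @classmethod
    def from_counts(cls, library: str, total_reads: int, high_quality: int,
                    category_counts: dict[str, int]) -> "CleaningReport":
        """Build a report from tallies; the clean count is derived from the
        partition identity clean = high_quality − Σ artifact categories."""
        counts = {c: int(category_counts.get(c, 0)) for c in CATEGORY_ORDER}
        if any(v < 0 for v in counts.values()) or high_quality < 0:
            raise ValueError("counts must be non-negative")
        clean = high_quality - sum(counts.values())
        return cls(library, total_reads, high_quality, counts, clean)

    def percentage(self, category: str) -> float:
        """count/high_quality × 100, rounded to 2 decimals."""
        if self.high_quality == 0:
            return 0.0
        if category == _sim.CLEAN:
            count = self.clean_reads
        else:
            count = self.category_counts[category]
        return round(count / self.high_quality * 100, 2)

    def to_dict(self) -> dict:
        d = {
            "library": self.library,
            "total_reads": self.total_reads,
            "high_quality": self.high_quality,
        }
        for c in CATEGORY_ORDER:
            d[c] = self.category_counts.get(c, 0)
            d[f"{c}_pct"] = self.percentage(c)
        d["clean_reads"] = self.clean_reads
        d["clean_reads_pct"] = self.percentage(_sim.CLEAN)
        return d


def _find_adapter3(seq: str, adapter3: str, min_prefix: int = 6,
                   max_mismatches: int = 1) -> int:
    """Position of the best 3'-adapter match, or -1.

    The longest prefix of ``adapter3`` (≥ ``min_prefix`` nt, ≤
    ``max_mismatches`` substitutions) is searched; among equal-length
    matches the leftmost wins, and longer prefixes beat shorter ones only
    at the same start (the start position defines the insert, so we take
    the leftmost start over all acceptable prefix lengths).
    """
    best = -1
    max_k = min(len(adapter3), len(seq))
    for i in range(len(seq) - min_prefix + 1):
        k = min(max_k, len(seq) - i)
        window = seq[i : i + k]
        mm = 0
        ok_len = 0
        for pos in range(k):
            if window[pos] != adapter3[pos]:
                mm += 1
                if mm > max_mismatches:
                    break
            ok_len = pos + 1
        if ok_len >= min_prefix and mm <= max_mismatches:
            return i
    return best


def _is_low_quality(read: RawRead, quality_threshold: int) -> bool:
    if "N" in read.sequence:
        return True
    floor = chr(quality_threshold + 33)
    return any(q < floor for q in read.quality)


def _starts_with_adapter5(insert: str, adapter5: str, probe: int = 10,
                          max_mismatches: int = 1) -> bool:
    k = min(probe, len(adapter5), len(insert))
    if k < probe:
        return False
    mm = sum(a != b for a, b in zip(insert[:k], adapter5[:k]))
    return mm <= max_mismatches


def classify_read(read: RawRead, adapter5: str, adapter3: str, *,
                  min_len: int = 18, max_len: int | None = None,
                  polyA_frac: float = 0.9, quality_threshold: int = 20,
                  ) -> tuple[str, str | None]:
    """Assign one read to its cleaning category.

    Returns ``(category, insert)`` where ``insert`` is the trimmed clean
    tag for category ``clean`` and ``None`` otherwise.
    """
    if _is_low_quality(read, quality_threshold):
        return _sim.LOW_QUALITY, None
    pos = _find_adapter3(read.sequence, adapter3)
    if pos < 0:
        return _sim.ADAPTER3_NULL, None
    insert = read.sequence[:pos]
    if not insert or insert == adapter5:
        return _sim.INSERT_NULL, None
    if _starts_with_adapter5(insert, adapter5):
        return _sim.ADAPTER5_CONTAM, None
    if len(insert) < min_len:
        return _sim.TOO_SHORT, None
    if insert.count("A") / len(insert) >= polyA_frac:
        return _sim.POLYA, None
    if max_len is not None and len(insert) > max_len:
        # over-long inserts are retained as clean unless a cap is configured
        return _sim.TOO_SHORT, None
    return _sim.CLEAN, insert


def clean_library(reads: Iterable[RawRead], adapter5: str, adapter3: str, *,
                  library: str = "library", min_len: int = 18,
                  max_len: int | None = None, polyA_frac: float = 0.9,
                  quality_threshold: int = 20,
                  ) -> tuple[list[str], CleaningReport]:
    """Run the cleaning cascade over a library.

    Returns the clean adapter-trimmed tags (one per surviving read, in
    input order) and the category-accounting report.
    """
    if not adapter5 or not adapter3:
        raise ValueError("adapters must be non-empty")
    if max_len is not None and min_len > max_len:
        raise ValueError("min_len must be ≤ max_len")
    counts = {c: 0 for c in CATEGORY_ORDER}
    total = high_quality = low_quality = 0
    tags: list[str] = []
    for read in reads:
        total += 1
        category, insert = classify_read(
            read, adapter5, adapter3, min_len=min_len, max_len=max_len,
            polyA_frac=polyA_frac, quality_threshold=quality_threshold)
        if category == _sim.LOW_QUALITY:
            low_quality += 1
            continue
        high_quality += 1
        if category == _sim.CLEAN:
            tags.append(insert)
        else:
            counts[category] += 1
    report = CleaningReport.from_counts(library, total, high_quality, counts)
    assert report.clean_reads == len(tags)
    return tags, report


def reports_to_table(reports: Sequence[CleaningReport]):
    import pandas as pd

    return pd.DataFrame([r.to_dict() for r in reports]).set_index("library")
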