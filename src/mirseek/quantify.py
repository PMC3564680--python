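"""Expression normalisation, fold changes and term enrichment.

Counts are normalised to transcripts per million clean reads:

    TPM = count / library_clean_total × 10⁶

exactly, with no pseudo-counts, so the TPM of a whole library sums to 10⁶
when computed over its complete tag set. Cross-library ratios use a
0.5-read pseudo-count, applied only when one of the two counts is zero,
so every ratio printed for nonzero pairs is the plain TPM ratio.

Term enrichment is the one-sided hypergeometric upper tail on a
user-supplied gene → term annotation map, with Benjamini–Hochberg
q-values reported alongside the raw p-values; the significance flag uses
raw p by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io import CountTable


def tpm(count: int | float, library_total: int) -> float:
    """Transcripts per million clean reads; exact formula."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / library_total * 1_000_000


def normalize_table(table: CountTable, library_totals: dict[str, int]) -> CountTable:
    """Attach a TPM layer computed against per-library clean-read totals."""
    missing = [l for l in table.libraries if l not in library_totals]
    if missing:
        raise KeyError(f"missing library totals: {missing}")
    tpm_df = table.counts.astype(float).copy()
    for lib in table.libraries:
        tpm_df[lib] = table.counts[lib] / library_totals[lib] * 1_000_000
    return CountTable(table.counts, tpm_df)


def fold_change(table: CountTable, mirna: str, lib_a: str, lib_b: str,
                library_totals: dict[str, int], pseudo: float = 0.5) -> float:
    """TPM ratio A/B for one miRNA.

    When either raw count is zero, a pseudo-count of ``pseudo`` raw reads
    (in TPM units of its own library) is added to both sides; a 0-vs-0
    comparison is defined as 1.0.
    """
    for lib in (lib_a, lib_b):
        if lib not in table.libraries:
            raise KeyError(f"unknown library: {lib}")
    ca = int(table.counts.loc[mirna, lib_a])
    cb = int(table.counts.loc[mirna, lib_b])
    if ca == 0 and cb == 0:
        return 1.0
    ta = tpm(ca, library_totals[lib_a])
    tb = tpm(cb, library_totals[lib_b])
    if ca == 0 or cb == 0:
        ta += pseudo / library_totals[lib_a] * 1_000_000
        tb += pseudo / library_totals[lib_b] * 1_000_000
    return ta / tb


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    population_size: int
    population_hits: int
    sample_size: int
    sample_hits: int
    p_value: float
    q_value: float
    significant: bool


def _bh_qvalues(pvals: list[float]) -> list[float]:
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [0.0] * n
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = n - rank_from_end
        prev = min(prev, pvals[idx] * n / rank)
        q[idx] = prev
    return q


def hypergeom_enrich(sample: set[str] | list[str], population: set[str] | list[str],
                     term_map: dict[str, set[str]], alpha: float = 0.05,
                     flag_on: str = "p") -> list[EnrichmentResult]:
    """Hypergeometric over-representation of annotation terms in ``sample``.

    ``term_map`` maps gene → set of terms; genes without annotations count
    toward sizes but toward no term. ``flag_on`` selects whether the
    significance flag thresholds the raw p-value (default, the common
    p<α convention) or the BH q-value (``"q"``).
    """
    sample = set(sample)
    population = set(population)
    stray = sample - population
    if stray:
        raise ValueError(f"sample genes absent from population: {sorted(stray)[:5]}")
    if not term_map:
        return []
    terms = sorted({t for g in population for t in term_map.get(g, ())})
    M, n = len(population), len(sample)
    rows = []
    for term in terms:
        members = {g for g in population if term in term_map.get(g, ())}
        K = len(members)
        k = len(sample & members)
        # P(X ≥ k) for X ~ Hypergeom(M, K, n)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        p = min(max(p, 0.0), 1.0)
        rows.append((term, K, k, p))
    qvals = _bh_qvalues([r[3] for r in rows])
    out = []
    for (term, K, k, p), q in zip(rows, qvals):
        flagged = (p if flag_on == "p" else q) < alpha
        out.append(EnrichmentResult(term, M, K, n, k, p, q, flagged))
    return out


def enrichment_to_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def top_expressed(table: CountTable, library: str, k: int = 10) -> pd.DataFrame:
    """Most abundant rows of one library (rank report)."""
    col = table.counts[library].sort_values(ascending=False).head(k)
    return col.to_frame(name=library)


def library_specific(table: CountTable, library: str) -> list[str]:
    """Rows with nonzero count only in ``library``."""
    counts = table.counts
    others = [c for c in counts.columns if c != library]
    mask = (counts[library] > 0) & (counts[others].sum(axis=1) == 0)
    return list(counts.index[mask])
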