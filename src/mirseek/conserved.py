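"""Conserved miRNA identification by weighted-mismatch matching.

Unannotated unique tags are compared to a mature-miRNA reference set
(miRBase-style ``>family-member`` headers). A tag is assigned to its
best-scoring reference when it is a near-perfect match: at most two
mismatches, a weighted alignment score ≤ 4.5 (non-wobble substitution
1.0, wobble-class substitution 0.5, gap 2.0 — the same weighting the
target-prediction rules use), and at most ``max_edits`` non-identical
aligned positions in total. All constraints apply conjunctively: the
total-edit budget is what "near perfectly matched" means (wobble-class
variants are merely charged half in the score, they still count as
edits), and without it a deeply sequenced background of random tags
would occasionally reach the score threshold through wobble-heavy
alignments. Ties on (score, mismatches) go to the lexicographically
smallest reference id, so assignment is deterministic.

A shared-6-mer prefilter skips hopeless references: an assignable pair
aligns ≥16 nt with at most two mismatch/gap breakpoints, whose longest
uninterrupted run is ≥ ⌈16/3⌉ = 6 nt, so any assignable tag shares an
exact 6-mer with its reference and the prefilter cannot change results —
a property the tests check against exhaustive scoring.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .annotate import UniqueTag
from .io import CountTable
from .scoring import align_stats
from .seq import normalize_dna

_FAMILY_RE = re.compile(r"(mir|miR)[-_]?(\d+)", re.IGNORECASE)


def family_of(reference_id: str) -> str:
    """Family label from a reference id, e.g. ``ath-miR156a`` → ``miR156``."""
    m = _FAMILY_RE.search(reference_id)
    if not m:
        return reference_id
    return f"miR{m.group(2)}"


@dataclass(frozen=True)
class MirnaAssignment:
    tag: str  # DNA
    reference_id: str
    family: str
    mismatches: int
    score: float
    counts: tuple[tuple[str, int], ...]  # per-library

    @property
    def count_dict(self) -> dict[str, int]:
        return dict(self.counts)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def assign_conserved(tags: list[UniqueTag], mature_refs: dict[str, str],
                     max_mm: int = 2, max_score: float = 4.5,
                     max_edits: int | None = None,
                     prefilter_k: int | None = 6,
                     ) -> tuple[list[MirnaAssignment], CountTable]:
    """Assign unannotated tags to mature miRNA references.

    Returns the assignments plus a count table (rows = assigned reference
    ids, columns = libraries, counts summed over assigned tags).
    ``max_edits`` (total non-identical positions, wobbles included)
    defaults to ``max_mm``.
    """
    if max_edits is None:
        max_edits = max_mm
    refs = {rid: normalize_dna(seq) for rid, seq in mature_refs.items()}
    ref_kmers = ({rid: _kmers(s, prefilter_k) for rid, s in refs.items()}
                 if prefilter_k else None)
    assignments: list[MirnaAssignment] = []
    for tag in tags:
        if tag.annotation not in ("unannotated", "miRNA"):
            continue
        seq = tag.sequence
        if not (18 <= len(seq) <= 26):
            continue
        tag_kmers = _kmers(seq, prefilter_k) if prefilter_k else None
        best = None
        for rid in sorted(refs):
            ref = refs[rid]
            if abs(len(ref) - len(seq)) > 2:
                continue
            if tag_kmers is not None and not (tag_kmers & ref_kmers[rid]):
                continue
            mm, edits, score = align_stats(seq, ref)
            if mm > max_mm or edits > max_edits or score > max_score:
                continue
            key = (score, mm, rid)
            if best is None or key < best:
                best = key
        if best is not None:
            score, mm, rid = best
            assignments.append(MirnaAssignment(
                tag=seq, reference_id=rid, family=family_of(rid),
                mismatches=mm, score=score,
                counts=tuple(sorted(tag.counts.items()))))
    libraries = sorted({lib for a in assignments for lib, _ in a.counts})
    if tags:
        all_libs = list(tags[0].counts)
        libraries = [l for l in all_libs if l in set(libraries)] or all_libs
    rows: dict[str, dict[str, int]] = {}
    for a in assignments:
        row = rows.setdefault(a.reference_id, {lib: 0 for lib in libraries})
        for lib, c in a.counts:
            if lib in row:
                row[lib] += c
    counts = pd.DataFrame(rows).T.reindex(columns=libraries).fillna(0).astype(int) \
        if rows else pd.DataFrame(columns=libraries, dtype=int)
    counts = counts.sort_index()
    return assignments, CountTable(counts)


def families(assignments: list[MirnaAssignment]) -> dict[str, set[str]]:
    """Family label → set of member reference ids among assignments."""
    out: dict[str, set[str]] = {}
    for a in assignments:
        out.setdefault(a.family, set()).add(a.reference_id)
    return out
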