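"""Weighted-mismatch scoring shared by conserved-miRNA matching and
novel-hairpin duplex evaluation.

A candidate tag is compared to a reference mature sequence by a global
alignment with free terminal gaps (miRNA length variants commonly differ
by a base or two at either end). Substitutions are weighted by whether
they preserve wobble pairing with a common target: transitions (A↔G,
C↔U) leave G:U pairing available and count 0.5; transversions count 1.0;
internal gaps are heaviest at 2.0. The returned mismatch count follows
the small-RNA annotation convention of counting only non-wobble
substitutions and gaps.
"""

from __future__ import annotations

from .seq import normalize_dna

WOBBLE_SUBS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

MATCH = 0.0
WOBBLE = 0.5
MISMATCH = 1.0
GAP = 2.0


def substitution_cost(a: str, b: str) -> float:
    if a == b:
        return MATCH
    if (a, b) in WOBBLE_SUBS:
        return WOBBLE
    return MISMATCH


def align_stats(tag: str, reference: str,
                max_len_diff: int = 2) -> tuple[int, int, float]:
    """Align ``tag`` to ``reference``; returns ``(mismatches, edits, score)``.

    ``score`` = 1.0 per non-wobble substitution + 0.5 per wobble-class
    substitution + 2.0 per internal gap position; terminal gaps of up to
    ``max_len_diff`` nt at each end are free. ``mismatches`` = non-wobble
    substitutions + internal gap positions (the convention under which a
    wobble-compatible variant is not a mismatch); ``edits`` additionally
    counts wobble-class substitutions, i.e. every non-identical aligned
    position. Ties in score break toward fewer mismatches, so the result
    is a deterministic function of the inputs.
    """
    a = normalize_dna(tag)
    b = normalize_dna(reference)
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if abs(len(a) - len(b)) > max_len_diff:
        raise ValueError(
            f"length difference {abs(len(a) - len(b))} exceeds {max_len_diff}")

    n, m = len(a), len(b)
    d = max_len_diff  # free terminal-gap length at each end

    def end_gap(k: int) -> tuple[float, int, int]:
        extra = max(0, k - d)
        return (GAP * extra, extra, extra)

    # cell = (score, mismatches, edits); terminal gaps of ≤ d nt are
    # free, any excess is charged as ordinary gap positions
    prev = [end_gap(j) for j in range(m + 1)]
    last_col = [prev[m]]
    for i in range(1, n + 1):
        cur = [(0.0, 0, 0)] * (m + 1)
        cur[0] = end_gap(i)
        for j in range(1, m + 1):
            c = substitution_cost(a[i - 1], b[j - 1])
            ds, dm, de = prev[j - 1]
            best = (ds + c, dm + (1 if c == MISMATCH else 0),
                    de + (1 if c > 0 else 0))
            us, um, ue = prev[j]
            if (us + GAP, um + 1, ue + 1) < best:
                best = (us + GAP, um + 1, ue + 1)
            ls, lm, le = cur[j - 1]
            if (ls + GAP, lm + 1, le + 1) < best:
                best = (ls + GAP, lm + 1, le + 1)
            cur[j] = best
        prev = cur
        last_col.append(cur[m])
    candidates = []
    for j, (s, mm, ed) in enumerate(prev):  # b suffix unaligned
        gs, gm, ge = end_gap(m - j)
        candidates.append((s + gs, mm + gm, ed + ge))
    for i, (s, mm, ed) in enumerate(last_col):  # a suffix unaligned
        gs, gm, ge = end_gap(n - i)
        candidates.append((s + gs, mm + gm, ed + ge))
    score, mm, edits = min(candidates)
    return mm, edits, score


def weighted_mismatch_score(tag: str, reference: str,
                            max_len_diff: int = 2) -> tuple[int, float]:
    """``(mismatches, score)`` of the end-free alignment; see
    :func:`align_stats` (wobble-class substitutions are not mismatches)."""
    mm, _, score = align_stats(tag, reference, max_len_diff)
    return mm, score
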