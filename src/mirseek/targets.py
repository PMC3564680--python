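"""Rule-based miRNA target prediction on transcript sets.

A candidate duplex between a miRNA (read 5'→3') and a transcript site
(antiparallel) is described per miRNA position as match, G:U wobble,
mismatch or gap, positions numbered 1..L from the miRNA 5' end. The
weighted score counts mismatches 1.0, wobbles 0.5 and gaps 2.0. A hit
must satisfy all six criteria:

  i    weighted score ≤ 4 over the whole duplex;
  ii   no run of ≥3 consecutive mismatch/gap positions anywhere;
  iii  no run of ≥2 consecutive mismatch/gap positions in positions 2–12;
  iv   positions 10–11 perfectly paired (the expected cleavage site —
       wobbles count toward the mismatch total, so they are not "no
       mismatch" and are disallowed here);
  v    weighted score ≤ 2.5 over positions 1–12;
  vi   duplex MFE ≥ 75% of the MFE of the miRNA bound to its perfect
       complement (same energy engine for both, so constants cancel).

The transcript scan evaluates the gapless antiparallel alignment at every
offset of every transcript — exhaustive, so the hit list needs no seeding
heuristic and equals a brute-force evaluation by construction. Gap states
are supported when scoring externally constructed alignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .fold import duplex_energy
from .seq import to_rna, revcomp_rna

MATCH, WOBBLE, MISMATCH, GAP = "match", "wobble", "mismatch", "gap"
STATE_WEIGHTS = {MATCH: 0.0, WOBBLE: 0.5, MISMATCH: 1.0, GAP: 2.0}

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLES = {("G", "U"), ("U", "G")}


def pair_state(mirna_base: str, target_base: str) -> str:
    """Duplex state of one antiparallel position (both bases 5'→3' of
    their own strands)."""
    key = (mirna_base, target_base)
    if key in _PAIRS:
        return MATCH
    if key in _WOBBLES:
        return WOBBLE
    return MISMATCH


@dataclass(frozen=True)
class DuplexAlignment:
    """Per-position duplex states indexed 1..L from the miRNA 5' end."""

    mirna: str  # RNA, 5'→3'
    site: str  # transcript site, RNA, 5'→3' on the transcript
    states: tuple[str, ...]

    def __post_init__(self):
        if len(self.states) < len(self.mirna):
            raise ValueError("states must cover every miRNA position")
        run = 0
        for s in self.states:
            run = run + 1 if s == GAP else 0
            if run > 2:
                raise ValueError("gap runs longer than 2 are not allowed")

    @classmethod
    def gapless(cls, mirna: str, site: str) -> "DuplexAlignment":
        """Antiparallel gapless alignment: miRNA position k (from 5') faces
        site position L−k (from the site 5' end)."""
        m = to_rna(mirna)
        s = to_rna(site)
        if len(m) != len(s):
            raise ValueError("gapless duplex needs equal lengths")
        states = tuple(pair_state(a, b) for a, b in zip(m, s[::-1]))
        return cls(m, s, states)


def score_duplex(alignment: DuplexAlignment) -> float:
    """Weighted mismatch score over all duplex positions."""
    return sum(STATE_WEIGHTS[s] for s in alignment.states)


def _has_run(states, bad: int, lo: int = 0, hi: int | None = None) -> bool:
    """Any run of ≥ ``bad`` consecutive mismatch/gap states in the
    (0-based, half-open) position range."""
    hi = len(states) if hi is None else hi
    run = 0
    for s in states[lo:hi]:
        run = run + 1 if s in (MISMATCH, GAP) else 0
        if run >= bad:
            return True
    return False


def check_criteria(alignment: DuplexAlignment, *, mfe_ratio: float | None = None,
                   max_score: float = 4.0, seed_max_score: float = 2.5,
                   min_mfe_ratio: float = 0.75) -> tuple[dict[str, bool], bool]:
    """Evaluate the six acceptance criteria; returns (verdicts, accept).

    ``mfe_ratio`` is duplex MFE / perfect-complement MFE; when None,
    criterion vi is computed from the alignment's own sequences with the
    default energy engine.
    """
    states = alignment.states
    if len(states) < 12:
        raise ValueError("criteria are ill-defined for duplexes shorter than 12")
    if mfe_ratio is None:
        mfe_ratio = compute_mfe_ratio(alignment.mirna, alignment.site)
    weights = [STATE_WEIGHTS[s] for s in states]
    verdicts = {
        "i": sum(weights) <= max_score,
        "ii": not _has_run(states, 3),
        "iii": not _has_run(states, 2, 1, 12),  # positions 2–12
        "iv": states[9] == MATCH and states[10] == MATCH,  # positions 10–11
        "v": sum(weights[:12]) <= seed_max_score,  # positions 1–12
        "vi": mfe_ratio >= min_mfe_ratio,
    }
    return verdicts, all(verdicts.values())


def compute_mfe_ratio(mirna: str, site: str, engine: str = "auto") -> float:
    """duplex MFE / perfect-complement MFE, clamped to [0, 1.5].

    Both energies come from the same engine; a perfect-complement site has
    ratio 1.0 by construction.
    """
    m = to_rna(mirna)
    e_duplex = duplex_energy(m, to_rna(site), engine)
    e_perfect = duplex_energy(m, revcomp_rna(m), engine)
    if e_perfect >= 0:
        return 0.0
    ratio = e_duplex / e_perfect
    return max(0.0, min(ratio, 1.5))


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    transcript_id: str
    start: int  # site on transcript, 0-based half-open
    end: int
    alignment: DuplexAlignment
    score: float
    verdicts: tuple[tuple[str, bool], ...]
    duplex_mfe: float
    perfect_mfe: float
    mfe_ratio: float


def scan_transcripts(mirnas: dict[str, str], transcripts: dict[str, str],
                     *, max_score: float = 4.0, seed_max_score: float = 2.5,
                     min_mfe_ratio: float = 0.75, engine: str = "auto",
                     ) -> list[TargetHit]:
    """All forward-strand sites passing the six criteria.

    Every offset of every transcript is evaluated with the gapless
    antiparallel alignment; hits are sorted by (transcript, position,
    score). The energy ratio (criterion vi) is only computed for sites
    passing the sequence criteria i–v, which does not change the result
    set (acceptance needs all six).
    """
    if not transcripts:
        raise ValueError("transcripts must be non-empty")
    hits: list[TargetHit] = []
    for mid in sorted(mirnas):
        m = to_rna(mirnas[mid])
        L = len(m)
        if L < 12:
            raise ValueError(f"miRNA {mid} shorter than 12 nt")
        e_perfect = duplex_energy(m, revcomp_rna(m), engine)
        for tid in sorted(transcripts):
            t = to_rna(transcripts[tid])
            for off in range(0, len(t) - L + 1):
                site = t[off : off + L]
                aln = DuplexAlignment.gapless(m, site)
                verdicts, ok = check_criteria(
                    aln, mfe_ratio=1.0, max_score=max_score,
                    seed_max_score=seed_max_score, min_mfe_ratio=min_mfe_ratio)
                if not all(v for k, v in verdicts.items() if k != "vi"):
                    continue
                e_duplex = duplex_energy(m, site, engine)
                ratio = max(0.0, min(e_duplex / e_perfect, 1.5)) \
                    if e_perfect < 0 else 0.0
                verdicts["vi"] = ratio >= min_mfe_ratio
                if not verdicts["vi"]:
                    continue
                hits.append(TargetHit(
                    mirna_id=mid, transcript_id=tid, start=off, end=off + L,
                    alignment=aln, score=score_duplex(aln),
                    verdicts=tuple(sorted(verdicts.items())),
                    duplex_mfe=e_duplex, perfect_mfe=e_perfect,
                    mfe_ratio=round(ratio, 4)))
    hits.sort(key=lambda h: (h.transcript_id, h.start, h.score, h.mirna_id))
    return hits


def hits_to_table(hits: list[TargetHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        row = {
            "mirna": h.mirna_id,
            "transcript": h.transcript_id,
            "site_start": h.start + 1,  # 1-based inclusive for output
            "site_end": h.end,
            "score": h.score,
            "mfe_ratio": h.mfe_ratio,
        }
        row.update({f"criterion_{k}": v for k, v in h.verdicts})
        rows.append(row)
    return pd.DataFrame(rows)
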