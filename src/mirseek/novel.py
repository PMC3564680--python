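"""Novel miRNA prediction from genome-mapped unannotated tags.

For every genome hit of a sufficiently abundant unannotated tag, a window
of ±``window_flank`` nt around the hit is extracted (reverse-complemented
for minus-strand hits so the tag reads 5'→3'), folded, and evaluated
against hairpin-duplex criteria:

(a) the folded precursor's free energy is at or below ``energy_max``;
(b) the tag lies wholly within one stem arm, with ≥16 of its bases paired
    and all partners on the same side (no loop-spanning reads);
(c) at most 4 tag bases unpaired and no asymmetric bulge > 2 nt within
    the tag region of the duplex;
(d) the weighted mismatch score of the tag against the reverse complement
    of its pairing-partner segment is ≤ ``score_max`` (wobbles 0.5);
(e) the tag's total read count is ≥ ``min_tag_count``.

Candidates from multiple hits of one tag are deduplicated by locus, and
different tags reaching the same locus merge with counts summed per arm;
the most abundant tag at the locus provides the mature sequence, a
partner-arm tag sitting at the 2-nt 3'-overhang duplex position is
reported as the miRNA*. Accepted candidates are numbered in locus order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotate import UniqueTag
from .fold import fold
from .io import format_locus
from .scoring import weighted_mismatch_score
from .seq import revcomp, to_rna, normalize_dna


@dataclass
class HairpinCandidate:
    name: str
    scaffold: str
    start: int  # precursor, 0-based half-open genome coordinates
    end: int
    strand: str
    structure: str
    energy: float
    mature_arm: str  # "5p" | "3p"
    mature: str  # RNA
    star: str | None
    counts_5p: dict[str, int] = field(default_factory=dict)
    counts_3p: dict[str, int] = field(default_factory=dict)
    score: float = 0.0
    truncated_window: bool = False

    @property
    def locus(self) -> str:
        return format_locus(self.scaffold, self.start, self.end)

    def total_count(self, arm: str) -> int:
        d = self.counts_5p if arm == "5p" else self.counts_3p
        return sum(d.values())


@dataclass
class _TagEvaluation:
    ok: bool
    reason: str = ""
    arm: str = ""
    duplex_score: float = 0.0
    partner_start: int = 0  # window coordinates
    partner_end: int = 0
    precursor_start: int = 0
    precursor_end: int = 0
    energy: float = 0.0
    structure: str = ""


def _evaluate_tag_in_window(window: str, tag_start: int, tag_end: int,
                            engine: str, energy_max: float, score_max: float,
                            ) -> _TagEvaluation:
    """Fold a window and test the hairpin-duplex criteria for the tag at
    [tag_start, tag_end) in window coordinates."""
    window_rna = to_rna(window)
    res = fold(window_rna, engine)
    partner = res.partner
    m = tag_end - tag_start
    paired_pos = [i for i in range(tag_start, tag_end) if i in partner]
    if len(paired_pos) < 16:
        return _TagEvaluation(False, "fewer than 16 tag bases paired")
    if m - len(paired_pos) > 4:
        return _TagEvaluation(False, "more than 4 unpaired tag bases")
    partners = [partner[i] for i in paired_pos]
    downstream = all(p >= tag_end for p in partners)
    upstream = all(p < tag_start for p in partners)
    if not (downstream or upstream):
        return _TagEvaluation(False, "tag spans the hairpin loop")
    arm = "5p" if downstream else "3p"
    # partners must run antiparallel without large asymmetric bulges
    for (i1, p1), (i2, p2) in zip(zip(paired_pos, partners),
                                  zip(paired_pos[1:], partners[1:])):
        if p2 >= p1:
            return _TagEvaluation(False, "non-nested pairing within tag")
        gap_tag = i2 - i1 - 1
        gap_partner = p1 - p2 - 1
        if abs(gap_tag - gap_partner) > 2:
            return _TagEvaluation(False, "asymmetric bulge > 2 nt in duplex")
    p_lo, p_hi = min(partners), max(partners) + 1
    partner_seq = window[p_lo:p_hi]
    # duplex agreement: the tag against the reverse complement of its
    # partner segment (a perfect stem gives score 0)
    try:
        _, duplex_score = weighted_mismatch_score(
            window[tag_start:tag_end], revcomp(partner_seq), max_len_diff=6)
    except ValueError:
        return _TagEvaluation(False, "partner segment length mismatch")
    if duplex_score > score_max:
        return _TagEvaluation(False, f"duplex score {duplex_score} > {score_max}")

    # precursor: walk the enclosing stem outward from the duplex, stopping
    # where the helix breaks into a multiloop (>8 nt jump on either side),
    # so distal coincidental pairs in the window do not inflate the locus
    lo = min(tag_start, p_lo)
    hi = max(tag_end, p_hi)
    enclosing = sorted((i, j) for i, j in res.pairs if i <= lo and j >= hi - 1)
    cur_i, cur_j = lo, hi - 1
    for i, j in reversed(enclosing):  # innermost first
        if cur_i - i > 8 or j - cur_j > 8:
            break
        cur_i, cur_j = i, j
    lo, hi = cur_i, cur_j + 1
    pre = fold(window_rna[lo:hi], engine)
    if pre.energy > energy_max:
        return _TagEvaluation(False, f"energy {pre.energy} > {energy_max}")
    return _TagEvaluation(True, arm=arm, duplex_score=duplex_score,
                          partner_start=p_lo, partner_end=p_hi,
                          precursor_start=lo, precursor_end=hi,
                          energy=pre.energy, structure=pre.structure)


def _star_matches(mature_gstart: int, mature_gend: int, cand_gstart: int,
                  cand_gend: int, partner_gstart: int, partner_gend: int) -> bool:
    """Does a partner-arm tag sit at the canonical miRNA* position
    (partner region of the mature, 2-nt 3' overhangs)?"""
    return (abs(cand_gstart - partner_gstart) <= 2
            and abs(cand_gend - partner_gend) <= 2)


def predict_novel(tags: list[UniqueTag], genome: dict[str, str],
                  window_flank: int = 150, energy_max: float = -18.0,
                  score_max: float = 5.0, min_tag_count: int = 5,
                  engine: str = "auto") -> list[HairpinCandidate]:
    """Predict hairpin (pre-miRNA) candidates from mapped unannotated tags.

    Returns accepted candidates named ``oeu_mir_N`` in (scaffold, start)
    locus order, one per precursor locus, with per-library 5p/3p counts.
    Overlapping precursor loci on a scaffold are merged regardless of
    strand — a hairpin is an inverted repeat, so a tag maps to both
    strands of its own precursor and both orientations describe the same
    locus. Each tag's counts enter a merged locus once.
    """
    genome = {k: normalize_dna(v) for k, v in genome.items()}
    entries: list[dict] = []
    for tag in tags:
        if tag.annotation != "unannotated":
            continue
        if tag.total_count < min_tag_count:
            continue
        for hit in tag.hits:
            seq = genome[hit.scaffold]
            w_lo = max(0, hit.start - window_flank)
            w_hi = min(len(seq), hit.end + window_flank)
            truncated = (w_lo > hit.start - window_flank
                         or w_hi < hit.end + window_flank)
            window = seq[w_lo:w_hi]
            if hit.strand == "+":
                t_lo, t_hi = hit.start - w_lo, hit.end - w_lo
            else:
                window = revcomp(window)
                t_lo = w_hi - hit.end
                t_hi = w_hi - hit.start
            ev = _evaluate_tag_in_window(window, t_lo, t_hi, engine,
                                         energy_max, score_max)
            if not ev.ok:
                continue
            if hit.strand == "+":
                pre = (w_lo + ev.precursor_start, w_lo + ev.precursor_end)
                partner_g = (w_lo + ev.partner_start, w_lo + ev.partner_end)
            else:
                pre = (w_hi - ev.precursor_end, w_hi - ev.precursor_start)
                partner_g = (w_hi - ev.partner_end, w_hi - ev.partner_start)
            entries.append(dict(
                tag=tag, arm=ev.arm, duplex_score=ev.duplex_score,
                energy=ev.energy, structure=ev.structure,
                scaffold=hit.scaffold, strand=hit.strand,
                pre_start=pre[0], pre_end=pre[1],
                tag_g=(hit.start, hit.end), partner_g=partner_g,
                truncated=truncated))

    # cluster entries by overlapping precursor intervals per scaffold
    entries.sort(key=lambda e: (e["scaffold"], e["pre_start"], e["pre_end"]))
    clusters: list[list[dict]] = []
    for e in entries:
        if (clusters and clusters[-1][0]["scaffold"] == e["scaffold"]
                and e["pre_start"] < max(x["pre_end"] for x in clusters[-1])):
            clusters[-1].append(e)
        else:
            clusters.append([e])

    candidates: list[HairpinCandidate] = []
    for cluster in clusters:
        rep = min(cluster, key=lambda e: (
            -e["tag"].total_count, e["energy"], e["strand"] != "+",
            e["pre_start"], e["tag"].sequence))
        cand = HairpinCandidate(
            name="", scaffold=rep["scaffold"], start=rep["pre_start"],
            end=rep["pre_end"], strand=rep["strand"],
            structure=rep["structure"], energy=rep["energy"],
            mature_arm=rep["arm"], mature=to_rna(rep["tag"].sequence),
            star=None, score=rep["duplex_score"],
            truncated_window=any(e["truncated"] for e in cluster))
        # one entry per distinct tag, preferring the representative strand
        by_tag: dict[str, dict] = {}
        for e in sorted(cluster, key=lambda e: e["strand"] != rep["strand"]):
            by_tag.setdefault(e["tag"].sequence, e)
        flip = {"5p": "3p", "3p": "5p"}
        for seq_, e in by_tag.items():
            arm = e["arm"] if e["strand"] == rep["strand"] else flip[e["arm"]]
            bucket = cand.counts_5p if arm == "5p" else cand.counts_3p
            for lib, c in e["tag"].counts.items():
                bucket[lib] = bucket.get(lib, 0) + c
            if seq_ != rep["tag"].sequence and arm != cand.mature_arm:
                if _star_matches(*rep["tag_g"], *e["tag_g"], *rep["partner_g"]):
                    cand.star = to_rna(seq_)
        candidates.append(cand)

    candidates.sort(key=lambda c: (c.scaffold, c.start, c.end, c.strand))
    for i, cand in enumerate(candidates, 1):
        cand.name = f"oeu_mir_{i}"
    return candidates


def arm_proportion(candidates: list[HairpinCandidate]) -> dict[str, int]:
    """Tally of mature-arm assignments, e.g. to report whether more
    matures derive from the 5' arm of their hairpins."""
    tally = {"5p": 0, "3p": 0}
    for c in candidates:
        tally[c.mature_arm] += 1
    return tally


def candidates_to_table(candidates: list[HairpinCandidate], libraries: list[str]):
    """Catalogue-style table: name, locus, strand, energy, 5p/3p sequences
    and per-library 5p/3p counts."""
    import pandas as pd

    rows = []
    for c in candidates:
        seq5 = c.mature if c.mature_arm == "5p" else (c.star or "-")
        seq3 = c.mature if c.mature_arm == "3p" else (c.star or "-")
        row = {
            "novel_id": c.name,
            "location": c.locus,
            "strand": c.strand,
            "energy": f"{c.energy:.2f}",
            "sequence_5p": seq5,
            "sequence_3p": seq3,
        }
        for lib in libraries:
            row[f"{lib}_5p"] = c.counts_5p.get(lib, 0) or "-"
            row[f"{lib}_3p"] = c.counts_3p.get(lib, 0) or "-"
        rows.append(row)
    return pd.DataFrame(rows)
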