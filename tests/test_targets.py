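"""Target-prediction duplex rules and transcript scanning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirseek.seq import revcomp_rna, to_rna
from mirseek.targets import (DuplexAlignment, GAP, MATCH, MISMATCH, WOBBLE,
                             check_criteria, compute_mfe_ratio, pair_state,
                             scan_transcripts, score_duplex)

MIRNA = "UGACAGAAGAGAGUGAGCACA"  # 21 nt
SITE = revcomp_rna(MIRNA)

rna21 = st.text(alphabet="ACGU", min_size=18, max_size=24)


def _site_with_mismatch(positions, wobble=False):
    """Perfect-complement site disrupted at the given miRNA positions
    (1-based from the miRNA 5' end)."""
    site = list(SITE)
    L = len(MIRNA)
    for pos in positions:
        idx = L - pos  # site index facing miRNA position `pos`
        m_base = MIRNA[pos - 1]
        if wobble:
            # G:U wobble: miRNA G faces U, miRNA U faces G
            repl = {"G": "U", "U": "G"}.get(m_base)
            if repl is None:
                raise ValueError("wobble needs G or U on the miRNA side")
        else:
            repl = {"A": "A", "C": "C", "G": "G", "U": "U"}[m_base]  # same base → mismatch
        site[idx] = repl
    return "".join(site)


class TestScoreDuplex:
    def test_perfect_complement_scores_zero(self):
        aln = DuplexAlignment.gapless(MIRNA, SITE)
        assert score_duplex(aln) == 0.0
        assert set(aln.states) == {MATCH}

    def test_two_wobbles_score_one(self):
        positions = [i + 1 for i, b in enumerate(MIRNA) if b in "GU"][:2]
        aln = DuplexAlignment.gapless(MIRNA, _site_with_mismatch(positions,
                                                                 wobble=True))
        assert score_duplex(aln) == 1.0

    @settings(derandomize=True, max_examples=40)
    @given(rna21)
    def test_score_equals_positionwise_recount(self, mirna):
        rng = np.random.default_rng(len(mirna))
        site = "".join(rng.choice(list("ACGU"), size=len(mirna)))
        aln = DuplexAlignment.gapless(mirna, site)
        weights = {MATCH: 0.0, WOBBLE: 0.5, MISMATCH: 1.0, GAP: 2.0}
        expected = 0.0
        for k in range(len(mirna)):
            expected += weights[pair_state(mirna[k], site[len(site) - 1 - k])]
        assert score_duplex(aln) == expected

    def test_gap_run_limit(self):
        states = (MATCH,) * 9 + (GAP, GAP, GAP) + (MATCH,) * 9
        with pytest.raises(ValueError, match="gap runs"):
            DuplexAlignment(MIRNA, SITE, states)


class TestCriteria:
    def _check(self, site, **kw):
        aln = DuplexAlignment.gapless(MIRNA, site)
        return check_criteria(aln, mfe_ratio=kw.pop("mfe_ratio", 1.0), **kw)

    def test_perfect_complement_accepted(self):
        verdicts, accept = self._check(SITE)
        assert accept and all(verdicts.values())

    def test_mismatch_at_position_ten_rejected(self):
        verdicts, accept = self._check(_site_with_mismatch([10]))
        assert not verdicts["iv"] and not accept

    def test_wobble_at_cleavage_site_rejected(self):
        pos = next(i + 1 for i, b in enumerate(MIRNA)
                   if b in "GU" and i + 1 in (10, 11))
        verdicts, _ = self._check(_site_with_mismatch([pos], wobble=True))
        assert not verdicts["iv"]

    def test_three_adjacent_mismatches_reject_ii(self):
        verdicts, _ = self._check(_site_with_mismatch([15, 16, 17]))
        assert not verdicts["ii"]

    def test_adjacent_mismatches_in_seed_reject_iii(self):
        verdicts, _ = self._check(_site_with_mismatch([4, 5]))
        assert not verdicts["iii"]
        # ...but adjacent mismatches outside 2–12 only hit ii's ≥3 rule
        verdicts, _ = self._check(_site_with_mismatch([15, 16]))
        assert verdicts["iii"] and verdicts["ii"]

    def test_seed_weighted_budget_v(self):
        verdicts, _ = self._check(_site_with_mismatch([2, 4, 6]))
        assert not verdicts["v"]  # 3.0 > 2.5 in positions 1–12

    def test_total_budget_i(self):
        verdicts, _ = self._check(_site_with_mismatch([2, 6, 14, 17, 20]))
        assert not verdicts["i"]  # 5.0 > 4

    def test_mfe_ratio_criterion_vi(self):
        _, accept = self._check(SITE, mfe_ratio=0.74)
        assert not accept
        verdicts, _ = self._check(SITE, mfe_ratio=0.76)
        assert verdicts["vi"]

    def test_short_duplex_rejected(self):
        aln = DuplexAlignment.gapless("ACGUACGUACG", revcomp_rna("ACGUACGUACG"))
        with pytest.raises(ValueError, match="shorter than 12"):
            check_criteria(aln, mfe_ratio=1.0)

    def test_tightening_never_adds_hits(self):
        rng = np.random.default_rng(61)
        sites = []
        for _ in range(200):
            n_mut = int(rng.integers(0, 4))
            pos = rng.choice(21, size=n_mut, replace=False) + 1
            sites.append(_site_with_mismatch(pos.tolist()))
        loose = {s for s in sites if self._check(s)[1]}
        strict = {s for s in sites
                  if self._check(s, max_score=2.0, seed_max_score=1.0)[1]}
        assert strict <= loose


class TestMfeRatio:
    def test_perfect_complement_ratio_is_one(self):
        assert compute_mfe_ratio(MIRNA, SITE) == pytest.approx(1.0)

    def test_disrupted_site_ratio_below_one(self):
        site = _site_with_mismatch([8, 9, 15])
        assert compute_mfe_ratio(MIRNA, site) < 1.0


class TestScan:
    def test_embedded_perfect_site_found(self):
        rng = np.random.default_rng(71)
        pad = lambda n: "".join(rng.choice(list("ACGU"), size=n))
        transcript = pad(60) + SITE + pad(60)
        hits = scan_transcripts({"m1": MIRNA}, {"t1": transcript})
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end) == (60, 60 + len(MIRNA))
        assert h.score == 0.0 and h.mfe_ratio == pytest.approx(1.0)

    def test_two_sites_two_hits(self):
        rng = np.random.default_rng(73)
        pad = lambda n: "".join(rng.choice(list("ACGU"), size=n))
        transcript = pad(30) + SITE + pad(40) + SITE + pad(30)
        hits = scan_transcripts({"m1": MIRNA}, {"t1": transcript})
        assert [h.start for h in hits] == [30, 30 + len(MIRNA) + 40 + 0]

    def test_empty_transcripts_rejected(self):
        with pytest.raises(ValueError):
            scan_transcripts({"m1": MIRNA}, {})

    def test_equals_brute_force_all_offsets(self):
        """Hit list equals an independent all-offsets evaluation with its
        own rule implementation."""
        rng = np.random.default_rng(79)
        transcript = "".join(rng.choice(list("ACGU"), size=600))
        # embed a near-perfect site so the scan has something to find
        site = list(SITE)
        site[3] = "A" if site[3] != "A" else "C"
        transcript = transcript[:200] + "".join(site) + transcript[221:]
        hits = scan_transcripts({"m1": MIRNA}, {"t1": transcript})
        got = {(h.start, h.end) for h in hits}

        expected = set()
        L = len(MIRNA)
        for off in range(len(transcript) - L + 1):
            s = transcript[off:off + L]
            states = []
            for k in range(L):
                a, b = MIRNA[k], s[L - 1 - k]
                if (a, b) in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}:
                    states.append("M")
                elif (a, b) in {("G", "U"), ("U", "G")}:
                    states.append("W")
                else:
                    states.append("X")
            w = sum({"M": 0, "W": 0.5, "X": 1.0}[x] for x in states)
            ok = (w <= 4
                  and "XXX" not in "".join(states)
                  and "XX" not in "".join(states[1:12])
                  and states[9] == "M" and states[10] == "M"
                  and sum({"M": 0, "W": 0.5, "X": 1.0}[x]
                          for x in states[:12]) <= 2.5)
            if ok:
                ratio = compute_mfe_ratio(MIRNA, s)
                ok = ratio >= 0.75
            if ok:
                expected.add((off, off + L))
        assert got == expected
        assert (200, 221) in got
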