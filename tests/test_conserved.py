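"""Weighted-mismatch scoring and conserved miRNA assignment."""

import itertools

import numpy as np
import pytest

from mirseek.annotate import UniqueTag
from mirseek.conserved import assign_conserved, families, family_of
from mirseek.scoring import align_stats, weighted_mismatch_score


def _oracle_score(a, b, d=2):
    """Independent exhaustive aligner: recursive minimisation over all
    monotone alignments with capped free terminal gaps."""
    WOB = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

    def sub(x, y):
        return 0.0 if x == y else (0.5 if (x, y) in WOB else 1.0)

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def go(i, j):
        # returns set of attainable (score, mm, edits) minima as min tuple
        if i == len(a) and j == len(b):
            return (0.0, 0, 0)
        best = None
        if i < len(a) and j < len(b):
            c = sub(a[i], b[j])
            s, m, e = go(i + 1, j + 1)
            cand = (s + c, m + (c == 1.0), e + (c > 0))
            best = cand if best is None else min(best, cand)
        if i < len(a):  # gap in b
            s, m, e = go(i + 1, j)
            free = j == 0 and i < d or j == len(b) and len(a) - i <= d
            cand = (s, m, e) if free else (s + 2.0, m + 1, e + 1)
            best = cand if best is None else min(best, cand)
        if j < len(b):  # gap in a
            s, m, e = go(i, j + 1)
            free = i == 0 and j < d or i == len(a) and len(b) - j <= d
            cand = (s, m, e) if free else (s + 2.0, m + 1, e + 1)
            best = cand if best is None else min(best, cand)
        return best

    s, m, e = go(0, 0)
    return m, e, s


class TestScoring:
    def test_identical(self):
        assert weighted_mismatch_score("ACGTACGTACGTACGTACGT",
                                       "ACGTACGTACGTACGTACGT") == (0, 0.0)

    def test_single_wobble_class_substitution(self):
        a = "ACGTACGTACGTACGTACGT"
        b = "ACGTACGTACATACGTACGT"  # G→A at one position (wobble class)
        mm, score = weighted_mismatch_score(a, b)
        assert (mm, score) == (0, 0.5)
        _, edits, _ = align_stats(a, b)
        assert edits == 1  # wobble still counts as an edit

    def test_transversion_is_full_mismatch(self):
        a = "ACGTACGTACGTACGTACGT"
        b = "ACGTACGTACCTACGTACGT"  # G→C
        assert weighted_mismatch_score(a, b) == (1, 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            weighted_mismatch_score("", "ACGT")

    def test_length_difference_capped(self):
        with pytest.raises(ValueError):
            weighted_mismatch_score("ACGTACGTACGTACGTACGTACG", "ACGT" * 5)

    def test_matches_exhaustive_oracle_on_fixture(self):
        """All pairs from a 20-sequence fixture equal the independent
        recursive aligner."""
        rng = np.random.default_rng(31)
        bases = "ACGT"
        seqs = ["".join(rng.choice(list(bases), size=int(rng.integers(18, 23))))
                for _ in range(12)]
        # include near-identical pairs, the regime that matters
        for i in range(8):
            mutant = list(seqs[i])
            for pos in rng.choice(len(mutant), size=int(rng.integers(1, 3)),
                                  replace=False):
                mutant[pos] = bases[int(rng.integers(0, 4))]
            seqs.append("".join(mutant))
        for a, b in itertools.combinations(seqs, 2):
            if abs(len(a) - len(b)) > 2:
                continue
            assert align_stats(a, b) == _oracle_score(a, b), (a, b)


class TestFamilies:
    @pytest.mark.parametrize("rid,family", [
        ("oeu_miR156a", "miR156"),
        ("ath-miR395b", "miR395"),
        ("ptc-MIR159c", "miR159"),
        ("sim_miR203b", "miR203"),
    ])
    def test_family_parsing(self, rid, family):
        assert family_of(rid) == family

    def test_family_grouping_counts_distinct_labels(self, sim, unique_tags):
        assignments, _ = assign_conserved(unique_tags, sim["known"])
        fams = families(assignments)
        assert len(fams) == len({a.family for a in assignments})


def _tag(seq, count=1, lib="UF"):
    return UniqueTag(seq, {lib: count})


class TestAssignment:
    def test_exact_match_assigned(self, sim):
        rid, mature = next(iter(sim["known"].items()))
        tags = [_tag(mature.replace("U", "T"))]
        assignments, table = assign_conserved(tags, sim["known"])
        assert len(assignments) == 1
        assert assignments[0].reference_id == rid
        assert assignments[0].mismatches == 0

    def test_three_substitutions_unassigned(self, sim):
        mature = next(iter(sim["known"].values())).replace("U", "T")
        mutant = list(mature)
        for pos, base in [(2, "C"), (8, "A"), (14, "G")]:
            mutant[pos] = base if mutant[pos] != base else \
                "ACGT"[("ACGT".index(base) + 2) % 4]
        assignments, _ = assign_conserved([_tag("".join(mutant))], sim["known"])
        # a triple mutant may retain ≤2 strict mismatches only through
        # wobble-class substitutions; the total-edit budget still bars it
        assert assignments == []

    def test_tie_breaks_to_smallest_reference_id(self):
        refs = {"zzz_miR1a": "ACGUACGUACGUACGUACGU",
                "aaa_miR1a": "ACGUACGUACGUACGUACGU"}
        assignments, _ = assign_conserved([_tag("ACGTACGTACGTACGTACGT")], refs)
        assert assignments[0].reference_id == "aaa_miR1a"

    def test_threshold_monotonicity(self, sim, unique_tags):
        base, _ = assign_conserved(unique_tags, sim["known"])
        base_set = {(a.tag, a.reference_id) for a in base}
        for max_mm, max_score in ((1, 4.5), (2, 0.5), (0, 0.0)):
            tighter, _ = assign_conserved(unique_tags, sim["known"],
                                          max_mm=max_mm, max_score=max_score)
            assert {(a.tag, a.reference_id) for a in tighter} <= base_set

    def test_prefilter_is_lossless(self, sim, unique_tags):
        with_filter, _ = assign_conserved(unique_tags, sim["known"],
                                          prefilter_k=6)
        exhaustive, _ = assign_conserved(unique_tags, sim["known"],
                                         prefilter_k=None)
        assert with_filter == exhaustive

    def test_deterministic_reruns(self, sim, unique_tags):
        a1, t1 = assign_conserved(unique_tags, sim["known"])
        a2, t2 = assign_conserved(unique_tags, sim["known"])
        assert a1 == a2 and t1 == t2

    def test_manifest_recall_and_precision(self, sim, unique_tags):
        """Every planted tag (exact or ≤2-substitution variant) is
        assigned to its source; nothing else is assigned."""
        manifest = sim["manifest"]
        truth = manifest.known_mirna_tags()
        assignments, table = assign_conserved(unique_tags, sim["known"])
        got = {a.tag: a.reference_id for a in assignments}
        observed_truth = {t: r for t, r in truth.items()
                          if any(u.sequence == t for u in unique_tags)}
        assert got == observed_truth
        # count table columns = libraries, rows = assigned references
        assert list(table.counts.columns) == list(manifest.libraries)
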