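"""Synthetic-data generator: determinism, conservation, planted truth."""

import io

import numpy as np
import pytest
from scipy import stats

from mirseek.fold import fold
from mirseek.io import write_fastq
from mirseek.simulate import (ALL_CATEGORIES, CLEAN, POLYA, SimulationConfig,
                              generate_contaminants, generate_genome,
                              generate_known_mirnas, generate_libraries)


def _fastq_bytes(reads):
    buf = io.StringIO()
    for r in reads:
        buf.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
    return buf.getvalue()


class TestConfigValidation:
    def test_fractions_over_one_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(category_fractions={"polyA": 0.7,
                                                 "insert_null": 0.5})

    def test_length_distribution_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(length_distribution={20: 0.5, 24: 0.4})

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_novel_loci=-1)


class TestGenome:
    def test_determinism(self):
        g1, l1 = generate_genome(7, 2, 5000, n_novel_loci=4)
        g2, l2 = generate_genome(7, 2, 5000, n_novel_loci=4)
        assert g1 == g2 and l1 == l2

    def test_overlapping_loci_rejected_with_ids(self):
        specs = [
            {"locus_id": "a", "scaffold": "scaffold_1", "start": 1000,
             "strand": "+", "mature_length": 22},
            {"locus_id": "b", "scaffold": "scaffold_1", "start": 1020,
             "strand": "+", "mature_length": 22},
        ]
        with pytest.raises(ValueError, match="overlapping.*b.*a"):
            generate_genome(1, 1, 5000, novel_locus_specs=specs)

    def test_locus_out_of_bounds_rejected(self):
        specs = [{"locus_id": "a", "scaffold": "scaffold_1", "start": 4990,
                  "strand": "+", "mature_length": 22}]
        with pytest.raises(ValueError, match="does not fit"):
            generate_genome(1, 1, 5000, novel_locus_specs=specs)

    def test_planted_hairpin_folds_with_mature_on_5p_arm(self):
        genome, loci = generate_genome(11, 1, 3000, n_novel_loci=1)
        locus = loci[0]
        window = genome[locus.scaffold][locus.start:locus.end]
        if locus.strand == "-":
            from mirseek.seq import revcomp
            window = revcomp(window)
        res = fold(window)
        mature_dna = locus.mature.replace("U", "T")
        pos = window.find(mature_dna)
        assert pos >= 0, "mature must sit on the precursor's 5' arm"
        paired = res.paired(pos, pos + len(mature_dna))
        assert len(paired) >= len(mature_dna) - 2
        # 5' arm: partners lie downstream of the mature
        assert all(res.partner[i] > pos + len(mature_dna) for i in paired)

    def test_mature_genome_coordinates_recorded(self):
        genome, loci = generate_genome(13, 1, 5000, n_novel_loci=2)
        from mirseek.seq import revcomp
        for locus in loci:
            segment = genome[locus.scaffold][locus.mature_start:locus.mature_end]
            expected = locus.mature.replace("U", "T")
            if locus.strand == "-":
                segment = revcomp(segment)
            assert segment == expected


class TestLibraries:
    def test_byte_identical_reruns(self, sim):
        cfg = sim["config"]
        libs2, _ = generate_libraries(cfg, sim["genome"], sim["known"],
                                      sim["contaminants"], sim["loci"])
        for lib in sim["libraries"]:
            assert _fastq_bytes(sim["libraries"][lib]) == _fastq_bytes(libs2[lib])

    def test_category_conservation(self, sim):
        man = sim["manifest"]
        n = sim["config"].n_reads_per_library
        for lib in man.libraries:
            assert sum(man.category_counts[lib].values()) == n
            assert len(man.read_categories[lib]) == n
            assert set(man.category_counts[lib]) == set(ALL_CATEGORIES)

    def test_all_artifacts_off_yields_all_clean(self):
        cfg = SimulationConfig(seed=5, n_reads_per_library=1000,
                               library_names=("UF",), category_fractions={},
                               n_known_mirnas=5, n_novel_loci=0,
                               n_contaminants_per_class=3)
        known = generate_known_mirnas(5, 5)
        cont = generate_contaminants(5, 3)
        genome, _ = generate_genome(5, 1, 2000)
        _, man = generate_libraries(cfg, genome, known, cont)
        counts = man.category_counts["UF"]
        assert counts[CLEAN] == 1000
        assert all(v == 0 for c, v in counts.items() if c != CLEAN)

    def test_polya_count_matches_fastq_rescan(self):
        cfg = SimulationConfig(seed=9, n_reads_per_library=10_000,
                               library_names=("UF",),
                               category_fractions={"polyA": 0.10},
                               n_known_mirnas=5, n_novel_loci=0,
                               n_contaminants_per_class=3)
        known = generate_known_mirnas(9, 5)
        cont = generate_contaminants(9, 3)
        genome, _ = generate_genome(9, 1, 2000)
        libs, man = generate_libraries(cfg, genome, known, cont)
        # independent re-scan of the emitted reads: locate the 3' adapter
        # start, take the insert, call poly-A at ≥90% adenine
        adapter = cfg.adapter3
        n_polya = 0
        for read in libs["UF"]:
            pos = read.sequence.find(adapter[:8])
            if pos <= 0:
                continue
            insert = read.sequence[:pos]
            if len(insert) >= 18 and insert.count("A") / len(insert) >= 0.9:
                n_polya += 1
        assert man.category_counts["UF"][POLYA] == n_polya

    def test_expression_ratio_recovered_within_binomial_error(self):
        ids = [f"sim_miR{200 + i}a" for i in range(10)]
        profile = {i: {"UF": 1.0, "RF": 1.0} for i in ids}
        profile[ids[0]] = {"UF": 10.0, "RF": 1.0}  # 10× more abundant in UF
        profile[ids[1]] = {"UF": 1.0, "RF": 10.0}  # counterweight keeps the
        # per-library weight totals equal, so selection probabilities stay
        # proportional to the configured weights
        known = generate_known_mirnas(21, 10)
        known = dict(zip(ids, known.values()))
        cfg = SimulationConfig(
            seed=21, n_reads_per_library=30_000, library_names=("UF", "RF"),
            category_fractions={}, n_known_mirnas=10, n_novel_loci=0,
            expression_profile=profile, mutant_fraction=0.0,
            valid_mix={"known": 0.5, "random": 0.5})
        genome, _ = generate_genome(21, 1, 2000)
        cont = generate_contaminants(21, 2)
        _, man = generate_libraries(cfg, genome, known, cont)
        uf = man.expression.loc[ids[0], "UF"]
        rf = man.expression.loc[ids[0], "RF"]
        ratio = uf / rf
        se = ratio * np.sqrt(1 / uf + 1 / rf)
        assert abs(ratio - 10) < 4 * se

    def test_length_distribution_chi2(self):
        dist = {20: 0.2, 22: 0.3, 24: 0.4, 28: 0.1}
        cfg = SimulationConfig(
            seed=17, n_reads_per_library=50_000, library_names=("UF",),
            category_fractions={}, length_distribution=dist,
            n_known_mirnas=0, n_novel_loci=0, n_contaminants_per_class=0,
            valid_mix={"random": 1.0})
        genome, _ = generate_genome(17, 1, 2000)
        libs, _ = generate_libraries(cfg, genome, {}, {})
        # realized insert lengths, re-derived from the emitted reads
        lengths = []
        for read in libs["UF"]:
            pos = read.sequence.find(cfg.adapter3[:8])
            lengths.append(pos)
        vals, counts = np.unique(lengths, return_counts=True)
        obs = dict(zip(vals.tolist(), counts.tolist()))
        f_obs = [obs.get(k, 0) for k in sorted(dist)]
        f_exp = [dist[k] * len(lengths) for k in sorted(dist)]
        p = stats.chisquare(f_obs, f_exp).pvalue
        assert p > 0.01
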