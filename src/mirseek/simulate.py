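"""Synthetic small-RNA-seq data with a planted ground truth.

The generator emulates a six-library small-RNA sequencing experiment of the
kind used to profile miRNAs in non-model plants: adapter-flanked 18–32 nt
inserts, a 24-nt modal length distribution, a read-cleaning artifact mix
(missing 3' adapter, empty insert, 5'-adapter read-through, too-short
inserts, poly-A runs, low-quality reads), planted conserved miRNAs with
library-specific abundances, planted novel hairpin loci embedded in a toy
genome, and non-coding-RNA contaminant fragments (rRNA/tRNA/snRNA/snoRNA/
repeat/mRNA degradation).

Reads are emitted as ``insert + 3'-adapter + random fill`` at a fixed read
length, matching how single-end small-RNA sequencing reads through the
insert into the 3' adapter; 5'-adapter contaminants additionally carry the
5' adapter at the read start (read-through ligation artifacts). Every read
carries exactly one ground-truth category label, and the manifest's
realized tallies are exact, so downstream category accounting can be
checked for equality rather than approximately.

All randomness flows through explicit integer seeds via
``numpy.random.default_rng``; the same configuration yields byte-identical
FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import RawRead, write_fasta, write_fastq, write_json
from .seq import revcomp, to_rna, normalize_dna
from .scoring import weighted_mismatch_score

BASES = np.array(list("ACGT"))

# Category labels follow the conventional cleaning-cascade accounting.
LOW_QUALITY = "low_quality"
ADAPTER3_NULL = "3'adapter_null"
INSERT_NULL = "insert_null"
ADAPTER5_CONTAM = "5'adapter_contaminants"
TOO_SHORT = "smaller_than_18nt"
POLYA = "polyA"
CLEAN = "clean"
ARTIFACT_CATEGORIES = (ADAPTER3_NULL, INSERT_NULL, ADAPTER5_CONTAM, TOO_SHORT, POLYA)
ALL_CATEGORIES = (LOW_QUALITY,) + ARTIFACT_CATEGORIES + (CLEAN,)

DEFAULT_LIBRARIES = ("UF", "RF", "NON", "JON", "NOFF", "JOFF")

# Canonical Illumina small-RNA adapters (configurable; any pair works).
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"

# Artifact rates: per-category fractions of the same order as deep
# small-RNA runs report (a few parts per thousand each).
DEFAULT_CATEGORY_FRACTIONS = {
    LOW_QUALITY: 0.0016,
    ADAPTER3_NULL: 0.0003,
    INSERT_NULL: 0.0004,
    ADAPTER5_CONTAM: 0.0030,
    TOO_SHORT: 0.0015,
    POLYA: 0.00005,
}

# 18–32 nt with the 24-nt mode typical of plant small-RNA libraries
# (24-mers are dominated by heterochromatic siRNAs, 21-mers by miRNAs).
DEFAULT_LENGTH_DISTRIBUTION = {
    18: 0.02, 19: 0.03, 20: 0.05, 21: 0.08, 22: 0.08, 23: 0.10, 24: 0.30,
    25: 0.08, 26: 0.05, 27: 0.04, 28: 0.04, 29: 0.04, 30: 0.03, 31: 0.03,
    32: 0.03,
}

CONTAMINANT_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "mRNA")
# rRNA fragments dominate the annotated fraction, then tRNA.
DEFAULT_CONTAMINANT_MIX = {
    "rRNA": 0.55, "tRNA": 0.25, "snRNA": 0.06, "snoRNA": 0.05,
    "repeat": 0.04, "mRNA": 0.05,
}

# Composition of valid (clean) inserts by true origin.
DEFAULT_VALID_MIX = {
    "known": 0.30,      # conserved miRNA reads
    "novel": 0.02,      # mature reads from planted hairpin loci
    "star": 0.003,      # miRNA* partner-strand reads from the same loci
    "contaminant": 0.35,
    "genomic": 0.05,    # random genome-derived degradation fragments
    "random": 0.272,
}


def _rand_dna(rng, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _contains_motif(seq: str, motif: str, max_mm: int = 1) -> bool:
    """True if any window of ``seq`` matches ``motif`` with ≤ max_mm subs."""
    k = len(motif)
    for i in range(len(seq) - k + 1):
        mm = sum(a != b for a, b in zip(seq[i : i + k], motif))
        if mm <= max_mm:
            return True
    return False


def _adapter_free(seq: str, adapter3: str, adapter5: str = "") -> bool:
    """True if ``seq`` cannot trigger adapter detection anywhere.

    Guards the first 5 nt of the 3' adapter (any 5-window within one
    mismatch could fire the trimmer, including windows that run past the
    insert into the genuine adapter) and, when given, the 10-nt 5'-adapter
    probe used by the read-through check.
    """
    if _contains_motif(seq, adapter3[:5], 1):
        return False
    if adapter5 and _contains_motif(seq, adapter5[:10], 1):
        return False
    return True


def _rand_insert(rng, length: int, adapter3: str, adapter5: str = "") -> str:
    """Random DNA insert guaranteed not to mimic an adapter."""
    while True:
        s = _rand_dna(rng, length)
        if _adapter_free(s, adapter3, adapter5):
            return s


@dataclass(frozen=True)
class NovelLocus:
    """A planted hairpin locus: inverted repeat with a mature miRNA on one
    stem arm and a 2-nt 3'-overhang miRNA* partner on the other."""

    locus_id: str
    scaffold: str
    start: int  # precursor, 0-based half-open, genome coordinates
    end: int
    strand: str
    arm: str  # arm carrying the mature sequence, "5p" or "3p"
    mature: str  # RNA, 5'→3'
    star: str  # RNA, 5'→3'
    mature_start: int  # genome coordinates of the mature sequence
    mature_end: int


@dataclass
class SimulationConfig:
    seed: int = 0
    n_reads_per_library: int = 100_000
    adapter5: str = DEFAULT_ADAPTER5
    adapter3: str = DEFAULT_ADAPTER3
    library_names: tuple[str, ...] = DEFAULT_LIBRARIES
    category_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_FRACTIONS))
    length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION))
    n_known_mirnas: int = 50
    n_novel_loci: int = 10
    n_contaminants_per_class: int = 20
    expression_profile: dict[str, dict[str, float]] | None = None
    valid_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VALID_MIX))
    contaminant_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTAMINANT_MIX))
    mutant_fraction: float = 0.10  # of known-miRNA reads carry 1–2 planted subs
    read_length: int = 49

    def __post_init__(self):
        if not self.adapter5 or not self.adapter3:
            raise ValueError("adapters must be non-empty")
        bad = [k for k in self.category_fractions
               if k not in (LOW_QUALITY,) + ARTIFACT_CATEGORIES]
        if bad:
            raise ValueError(f"unknown filter categories: {bad}")
        total = sum(self.category_fractions.values())
        if total > 1.0 + 1e-12:
            raise ValueError(
                f"category fractions sum to {total:.4f} > 1 "
                "(the remainder must be valid inserts)")
        if any(v < 0 for v in self.category_fractions.values()):
            raise ValueError("category fractions must be non-negative")
        ld = self.length_distribution
        if abs(sum(ld.values()) - 1.0) > 1e-9:
            raise ValueError("length_distribution must sum to 1")
        if any(not (18 <= k <= 32) for k in ld):
            raise ValueError("length_distribution keys must be in 18–32 nt")
        for name in ("n_reads_per_library", "n_known_mirnas", "n_novel_loci",
                     "n_contaminants_per_class"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")


class GroundTruthManifest:
    """Exact per-read/per-tag provenance of a simulated experiment."""

    def __init__(self, libraries):
        self.libraries = list(libraries)
        self.category_counts = {lib: {c: 0 for c in ALL_CATEGORIES}
                                for lib in self.libraries}
        self.read_categories: dict[str, list[str]] = {lib: [] for lib in self.libraries}
        self.tag_origins: dict[str, str] = {}  # DNA insert → origin label
        self.loci: list[NovelLocus] = []
        self.expression = pd.DataFrame()  # planted id × library realized counts

    def record(self, lib: str, category: str, insert: str | None, origin: str | None):
        self.category_counts[lib][category] += 1
        self.read_categories[lib].append(category)
        if insert and origin:
            prev = self.tag_origins.get(insert)
            # First writer wins; collisions across origins are astronomically
            # unlikely for ≥18-mers but must stay deterministic.
            if prev is None:
                self.tag_origins[insert] = origin

    def origin_of(self, tag: str) -> str | None:
        return self.tag_origins.get(normalize_dna(tag))

    def known_mirna_tags(self) -> dict[str, str]:
        """DNA tag → planted known-miRNA id (exact + mutant tags)."""
        out = {}
        for tag, origin in self.tag_origins.items():
            kind, _, ident = origin.partition(":")
            if kind in ("known", "known_mutant"):
                out[tag] = ident
        return out

    def to_dict(self) -> dict:
        return {
            "libraries": self.libraries,
            "category_counts": self.category_counts,
            "loci": [asdict(l) for l in self.loci],
            "expression": {k: v.to_dict() for k, v in self.expression.items()}
            if not self.expression.empty else {},
        }

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        write_json(self.to_dict(), outdir / "manifest.json")
        with open(outdir / "tag_origins.tsv", "w") as fh:
            fh.write("tag\torigin\n")
            for tag in sorted(self.tag_origins):
                fh.write(f"{tag}\t{self.tag_origins[tag]}\n")


# ---------------------------------------------------------------------------
# Reference-set generation


def generate_known_mirnas(seed: int, n: int, adapter3: str = DEFAULT_ADAPTER3,
                          adapter5: str = DEFAULT_ADAPTER5,
                          min_separation: float = 8.0) -> dict[str, str]:
    """``n`` mature miRNA references (RNA), grouped two per family.

    Sequences are 20–22 nt, mutually separated by a weighted-mismatch
    score ≥ ``min_separation`` so that planted ≤2-substitution variants
    cannot be attributed to the wrong reference.
    """
    rng = np.random.default_rng([seed, 101])
    refs: dict[str, str] = {}
    seqs: list[str] = []
    i = 0
    while len(refs) < n:
        length = int(rng.integers(20, 23))
        cand = _rand_insert(rng, length, adapter3, adapter5)
        if any(weighted_mismatch_score(cand, s)[1] < min_separation for s in seqs):
            continue
        family = 156 + i // 2  # two members (a, b) per family
        member = "ab"[i % 2]
        refs[f"sim_miR{family}{member}"] = to_rna(cand)
        seqs.append(cand)
        i += 1
    return refs


def generate_contaminants(seed: int, n_per_class: int,
                          adapter3: str = DEFAULT_ADAPTER3,
                          adapter5: str = DEFAULT_ADAPTER5) -> dict[str, dict[str, str]]:
    """Per-class reference sequences (DNA, 80–300 nt) for rRNA/tRNA/…"""
    rng = np.random.default_rng([seed, 202])
    out: dict[str, dict[str, str]] = {}
    for cls in CONTAMINANT_CLASSES:
        refs = {}
        for j in range(n_per_class):
            length = int(rng.integers(80, 301))
            refs[f"{cls}_{j + 1}"] = _rand_insert(rng, length, adapter3, adapter5)
        out[cls] = refs
    return out


# ---------------------------------------------------------------------------
# Genome generation


def _build_hairpin(rng, mature_dna: str, loop_len: int = 8):
    """Perfect inverted repeat carrying ``mature`` on the 5' arm.

    Layout: [pad_out(4) mature pad_in(4)] loop revcomp(same). The miRNA*
    of the mature under a 2-nt 3'-overhang duplex is the reverse
    complement of the window shifted 2 nt toward the precursor 5' end.
    """
    pad_out = _rand_dna(rng, 4)
    pad_in = _rand_dna(rng, 4)
    stem5 = pad_out + mature_dna + pad_in
    loop = "".join(np.array(list("ACT"))[rng.integers(0, 3, size=loop_len)])
    hairpin = stem5 + loop + revcomp(stem5)
    m_off = len(pad_out)  # mature offset within hairpin
    star_window = hairpin[m_off - 2 : m_off + len(mature_dna) - 2]
    star_dna = revcomp(star_window)
    return hairpin, m_off, star_dna


def generate_genome(seed: int, n_scaffolds: int = 1, scaffold_length: int = 100_000,
                    novel_locus_specs: list[dict] | None = None,
                    n_novel_loci: int | None = None,
                    adapter3: str = DEFAULT_ADAPTER3,
                    adapter5: str = DEFAULT_ADAPTER5,
                    ) -> tuple[dict[str, str], list[NovelLocus]]:
    """Random toy genome with planted hairpin loci.

    ``novel_locus_specs`` entries may fix ``locus_id``, ``scaffold``,
    ``start``, ``strand`` and ``mature_length``; unset loci are placed
    evenly with ≥500 nt spacing, alternating strands. Overlapping specs
    are rejected with the offending locus ids.
    """
    rng = np.random.default_rng([seed, 303])
    genome = {f"scaffold_{i + 1}": _rand_dna(rng, scaffold_length)
              for i in range(n_scaffolds)}
    if novel_locus_specs is None:
        n = n_novel_loci if n_novel_loci is not None else 0
        novel_locus_specs = []
        names = list(genome)
        per = -(-n // n_scaffolds) if n_scaffolds else 0
        for i in range(n):
            sc = names[i // per] if per else names[0]
            slot = i % per if per else 0
            start = 400 + slot * max(600, (scaffold_length - 800) // max(per, 1))
            novel_locus_specs.append({
                "locus_id": f"locus_{i + 1}", "scaffold": sc, "start": start,
                "strand": "+-"[i % 2],
                "mature_length": int(rng.integers(20, 25)),
            })

    loci: list[NovelLocus] = []
    occupied: dict[str, list[tuple[int, int, str]]] = {sc: [] for sc in genome}
    for spec in novel_locus_specs:
        lid = spec["locus_id"]
        sc = spec["scaffold"]
        if sc not in genome:
            raise ValueError(f"locus {lid}: unknown scaffold {sc}")
        mlen = int(spec.get("mature_length", 22))
        while True:
            mature_dna = _rand_insert(rng, mlen, adapter3, adapter5)
            hairpin, m_off, star_dna = _build_hairpin(rng, mature_dna)
            if _adapter_free(star_dna, adapter3, adapter5):
                break
        start = int(spec["start"])
        end = start + len(hairpin)
        strand = spec.get("strand", "+")
        if end > len(genome[sc]):
            raise ValueError(f"locus {lid} does not fit scaffold {sc}")
        clash = [pid for (s, e, pid) in occupied[sc] if s < end and start < e]
        if clash:
            raise ValueError(f"overlapping novel loci: {lid} vs {clash}")
        occupied[sc].append((start, end, lid))

        inserted = hairpin if strand == "+" else revcomp(hairpin)
        g = genome[sc]
        genome[sc] = g[:start] + inserted + g[end:]
        if strand == "+":
            m_start = start + m_off
        else:
            m_start = start + len(hairpin) - m_off - mlen
        loci.append(NovelLocus(
            locus_id=lid, scaffold=sc, start=start, end=end, strand=strand,
            arm="5p", mature=to_rna(mature_dna), star=to_rna(star_dna),
            mature_start=m_start, mature_end=m_start + mlen))
    return genome, loci


# ---------------------------------------------------------------------------
# Library generation


def default_expression_profile(ids, libraries, seed: int,
                               sigma: float = 1.0) -> dict[str, dict[str, float]]:
    """Log-normal per-miRNA, per-library relative abundances."""
    rng = np.random.default_rng([seed, 404])
    return {i: {lib: float(rng.lognormal(0.0, sigma)) for lib in libraries}
            for i in ids}


def _mutants_of(rng, seq_dna: str, adapter3: str, adapter5: str = "") -> list[str]:
    """One 1-sub and one 2-sub variant of a mature sequence."""
    out = []
    for n_mut in (1, 2):
        while True:
            s = list(seq_dna)
            for pos in rng.choice(len(s), size=n_mut, replace=False):
                choices = [b for b in "ACGT" if b != s[pos]]
                s[pos] = choices[int(rng.integers(0, 3))]
            cand = "".join(s)
            if _adapter_free(cand, adapter3, adapter5):
                out.append(cand)
                break
    return out


def generate_libraries(config: SimulationConfig, genome: dict[str, str],
                       known_mirnas: dict[str, str],
                       contaminants: dict[str, dict[str, str]],
                       loci: list[NovelLocus] | None = None,
                       ) -> tuple[dict[str, list[RawRead]], GroundTruthManifest]:
    """Simulate one FASTQ library per configured label.

    ``known_mirnas`` maps id → mature RNA; ``contaminants`` maps class →
    {id: DNA}. Planted hairpin loci contribute mature and miRNA* reads.
    Returns the libraries and an exact ground-truth manifest.
    """
    if not known_mirnas and config.valid_mix.get("known", 0) > 0:
        raise ValueError("known_mirnas must be non-empty")
    loci = loci or []
    libs = list(config.library_names)
    manifest = GroundTruthManifest(libs)
    manifest.loci = list(loci)

    mature_by_id = {i: normalize_dna(s) for i, s in known_mirnas.items()}
    known_ids = sorted(mature_by_id)
    novel_ids = [l.locus_id for l in loci]
    locus_by_id = {l.locus_id: l for l in loci}

    profile = config.expression_profile or default_expression_profile(
        known_ids + novel_ids, libs, config.seed)

    mut_rng = np.random.default_rng([config.seed, 505])
    mutants = {i: _mutants_of(mut_rng, mature_by_id[i], config.adapter3,
                              config.adapter5)
               for i in known_ids} if config.mutant_fraction > 0 else {}

    cat_names = [LOW_QUALITY, *ARTIFACT_CATEGORIES, "valid"]
    cat_probs = np.array([config.category_fractions.get(c, 0.0)
                          for c in (LOW_QUALITY,) + ARTIFACT_CATEGORIES])
    cat_probs = np.append(cat_probs, 1.0 - cat_probs.sum())

    mix_names = list(config.valid_mix)
    mix_probs = np.array([config.valid_mix[k] for k in mix_names], float)
    active = [(n, p) for n, p in zip(mix_names, mix_probs)
              if p > 0 and not (n == "known" and not known_ids)
              and not (n in ("novel", "star") and not novel_ids)
              and not (n == "contaminant" and not contaminants)
              and not (n == "genomic" and not genome)]
    if active:
        mix_names = [n for n, _ in active]
        mix_probs = np.array([p for _, p in active])
        mix_probs = mix_probs / mix_probs.sum()

    lengths = np.array(sorted(config.length_distribution))
    length_probs = np.array([config.length_distribution[k] for k in lengths])
    ctm_classes = [c for c in CONTAMINANT_CLASSES if c in contaminants]
    ctm_probs = np.array([config.contaminant_mix.get(c, 0.0) for c in ctm_classes])
    ctm_probs = ctm_probs / ctm_probs.sum() if ctm_probs.sum() else ctm_probs
    scaffolds = sorted(genome)

    expression = {i: {lib: 0 for lib in libs} for i in known_ids + novel_ids}
    libraries: dict[str, list[RawRead]] = {}

    for lib_idx, lib in enumerate(libs):
        rng = np.random.default_rng([config.seed, 606, lib_idx])
        n = config.n_reads_per_library
        categories = rng.choice(len(cat_names), size=n, p=cat_probs)
        known_w = np.array([profile[i][lib] for i in known_ids]) if known_ids else None
        if known_w is not None:
            known_w = known_w / known_w.sum()
        novel_w = np.array([profile[i][lib] for i in novel_ids]) if novel_ids else None
        if novel_w is not None:
            novel_w = novel_w / novel_w.sum()

        reads: list[RawRead] = []
        for ridx in range(n):
            cat = cat_names[categories[ridx]]
            length = int(lengths[rng.choice(len(lengths), p=length_probs)])
            insert = None
            origin = None
            label = cat
            low_quality = cat == LOW_QUALITY
            if cat in (LOW_QUALITY, "valid"):
                src = mix_names[rng.choice(len(mix_names), p=mix_probs)]
                if src == "known":
                    mid = known_ids[rng.choice(len(known_ids), p=known_w)]
                    if mutants and rng.random() < config.mutant_fraction:
                        insert = mutants[mid][int(rng.integers(0, len(mutants[mid])))]
                        origin = f"known_mutant:{mid}"
                    else:
                        insert = mature_by_id[mid]
                        origin = f"known:{mid}"
                    if not low_quality:
                        expression[mid][lib] += 1
                elif src == "novel":
                    lid = novel_ids[rng.choice(len(novel_ids), p=novel_w)]
                    insert = normalize_dna(locus_by_id[lid].mature)
                    origin = f"novel:{lid}"
                    if not low_quality:
                        expression[lid][lib] += 1
                elif src == "star":
                    lid = novel_ids[rng.choice(len(novel_ids), p=novel_w)]
                    insert = normalize_dna(locus_by_id[lid].star)
                    origin = f"novel_star:{lid}"
                elif src == "contaminant":
                    cls = ctm_classes[rng.choice(len(ctm_classes), p=ctm_probs)]
                    refs = contaminants[cls]
                    ref = refs[sorted(refs)[int(rng.integers(0, len(refs)))]]
                    L = min(length, len(ref))
                    off = int(rng.integers(0, len(ref) - L + 1))
                    insert = ref[off : off + L]
                    origin = f"contaminant:{cls}"
                elif src == "genomic":
                    sc = scaffolds[int(rng.integers(0, len(scaffolds)))]
                    g = genome[sc]
                    while True:
                        off = int(rng.integers(0, len(g) - length + 1))
                        insert = g[off : off + length]
                        if "N" not in insert and _adapter_free(
                                insert, config.adapter3, config.adapter5):
                            break
                    origin = "genomic"
                else:
                    insert = _rand_insert(rng, length, config.adapter3,
                                          config.adapter5)
                    origin = "random"
                label = LOW_QUALITY if low_quality else CLEAN
                read_seq = insert + config.adapter3
            elif cat == ADAPTER3_NULL:
                while True:
                    read_seq = _rand_dna(rng, config.read_length)
                    if _adapter_free(read_seq, config.adapter3):
                        break
            elif cat == INSERT_NULL:
                if rng.random() < 0.5:
                    read_seq = config.adapter3  # adapter dimer, empty insert
                else:
                    read_seq = config.adapter5 + config.adapter3
            elif cat == ADAPTER5_CONTAM:
                # cap so ≥6 nt of the 3' adapter stay within the read
                max5 = config.read_length - len(config.adapter5) - 6
                insert5 = _rand_insert(rng, min(length, max5), config.adapter3)
                read_seq = config.adapter5 + insert5 + config.adapter3
            elif cat == TOO_SHORT:
                short = _rand_insert(rng, int(rng.integers(1, 18)),
                                     config.adapter3, config.adapter5)
                read_seq = short + config.adapter3
            else:  # POLYA
                a = ["A"] * length
                n_non = int(rng.integers(0, max(1, length // 10)))  # keeps ≥90% A
                for pos in rng.choice(length, size=n_non, replace=False):
                    a[pos] = "CGT"[int(rng.integers(0, 3))]
                while not _adapter_free("".join(a), config.adapter3):
                    a = ["A"] * length
                read_seq = "".join(a) + config.adapter3

            # pad/trim to fixed read length with fill that cannot introduce
            # an earlier adapter match (fill sits after the genuine one)
            if len(read_seq) < config.read_length:
                read_seq = read_seq + _rand_dna(rng, config.read_length - len(read_seq))
            read_seq = read_seq[: config.read_length]

            qual = "I" * len(read_seq)
            if low_quality:
                pos = int(rng.integers(0, len(read_seq)))
                if rng.random() < 0.5:
                    qual = qual[:pos] + "#" + qual[pos + 1 :]
                else:
                    read_seq = read_seq[:pos] + "N" + read_seq[pos + 1 :]
            reads.append(RawRead(f"{lib}_{ridx + 1}", read_seq, qual))
            manifest.record(lib, label, insert if label == CLEAN else None, origin)
        libraries[lib] = reads

    manifest.expression = pd.DataFrame(expression).T.reindex(columns=libs).fillna(0).astype(int) \
        if expression else pd.DataFrame(columns=libs)
    return libraries, manifest


def simulate_to_dir(config: SimulationConfig, outdir) -> GroundTruthManifest:
    """Generate genome, references and libraries; write everything under
    ``outdir`` (FASTA/FASTQ/manifest)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, loci = generate_genome(
        config.seed, n_scaffolds=1, scaffold_length=100_000,
        n_novel_loci=config.n_novel_loci, adapter3=config.adapter3,
        adapter5=config.adapter5)
    known = generate_known_mirnas(config.seed, config.n_known_mirnas,
                                  config.adapter3, config.adapter5)
    contam = generate_contaminants(config.seed, config.n_contaminants_per_class,
                                   config.adapter3, config.adapter5)
    libraries, manifest = generate_libraries(config, genome, known, contam, loci)

    write_fasta(genome, outdir / "genome.fa")
    write_fasta(known, outdir / "known_mirnas.fa")
    for cls, refs in contam.items():
        write_fasta(refs, outdir / f"contaminant_{cls}.fa")
    for lib, reads in libraries.items():
        write_fastq(reads, outdir / f"{lib}.fastq")
    manifest.save(outdir)
    return manifest
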