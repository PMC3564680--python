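"""End-to-end orchestration: simulate/load → clean → annotate → conserved
→ novel → quantify (→ targets, enrichment), with per-stage reports and a
summary JSON. Reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotate as ann
from . import cleaning, conserved, novel, quantify
from . import targets as targets_mod
from .io import (CountTable, read_fasta, read_fastq, read_annotation_map,
                 write_json)
from .simulate import (SimulationConfig, DEFAULT_ADAPTER3,
                       DEFAULT_ADAPTER5)


@dataclass
class PipelineConfig:
    outdir: str = "mirseek_out"
    seed: int = 0
    # data sources: either simulate=True or explicit paths
    simulate: bool = True
    genome: str | None = None
    libraries: dict[str, str] = field(default_factory=dict)  # label → FASTQ
    mature_reference: str | None = None
    contaminant_references: dict[str, str] = field(default_factory=dict)
    transcripts: str | None = None
    annotations: str | None = None  # gene → term map for enrichment
    # stage parameters
    adapter5: str = DEFAULT_ADAPTER5
    adapter3: str = DEFAULT_ADAPTER3
    min_len: int = 18
    max_len: int | None = None
    quality_threshold: int = 20
    max_mismatches: int = 2
    conserved_max_score: float = 4.5
    window_flank: int = 150
    energy_max: float = -18.0
    novel_max_score: float = 5.0
    min_tag_count: int = 5
    n_reads_per_library: int = 20_000
    fold_engine: str = "auto"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def validate(self) -> None:
        if self.min_len < 15:
            raise ValueError("min_len must be ≥ 15")
        if not self.simulate:
            for p in filter(None, [self.genome, self.mature_reference,
                                   *self.libraries.values()]):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
            if self.genome is None or not self.libraries:
                raise ValueError("non-simulated runs need genome and libraries")


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; write per-stage tables under ``config.outdir`` and
    return (and write) a summary dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"parameters": {k: v for k, v in vars(config).items()
                                    if not isinstance(v, dict) or v}}

    # --- inputs
    if config.simulate:
        from .simulate import (generate_genome, generate_known_mirnas,
                               generate_contaminants, generate_libraries)
        sim = SimulationConfig(seed=config.seed,
                               n_reads_per_library=config.n_reads_per_library,
                               adapter5=config.adapter5, adapter3=config.adapter3)
        genome, loci = generate_genome(
            sim.seed, n_scaffolds=1, scaffold_length=100_000,
            n_novel_loci=sim.n_novel_loci, adapter3=sim.adapter3,
            adapter5=sim.adapter5)
        mature_refs = generate_known_mirnas(sim.seed, sim.n_known_mirnas,
                                            sim.adapter3, sim.adapter5)
        contaminants = generate_contaminants(
            sim.seed, sim.n_contaminants_per_class, sim.adapter3, sim.adapter5)
        libraries, manifest = generate_libraries(sim, genome, mature_refs,
                                                 contaminants, loci)
        summary["simulation"] = {"n_loci": len(loci),
                                 "libraries": list(libraries)}
    else:
        genome = read_fasta(config.genome)
        libraries = {label: list(read_fastq(path))
                     for label, path in config.libraries.items()}
        mature_refs = (read_fasta(config.mature_reference, rna=True)
                       if config.mature_reference else {})
        contaminants = {cls: read_fasta(path)
                        for cls, path in config.contaminant_references.items()}
        manifest = None

    lib_names = list(libraries)

    # --- cleaning
    tags_per_lib: dict[str, list[str]] = {}
    reports = []
    for lib, reads in libraries.items():
        tags, report = cleaning.clean_library(
            reads, config.adapter5, config.adapter3, library=lib,
            min_len=config.min_len, max_len=config.max_len,
            quality_threshold=config.quality_threshold)
        tags_per_lib[lib] = tags
        reports.append(report)
    cleaning.reports_to_table(reports).to_csv(outdir / "cleaning_report.tsv",
                                              sep="\t")
    clean_totals = {r.library: r.clean_reads for r in reports}
    summary["cleaning"] = {r.library: r.to_dict() for r in reports}

    # --- annotate
    unique_tags = ann.collapse_tags(tags_per_lib)
    ann.annotate_tags(unique_tags, contaminants)
    index = ann.GenomeIndex(genome)
    for tag in unique_tags:
        if tag.annotation == ann.UNANNOTATED:
            tag.hits = index.scan(tag.sequence, config.max_mismatches)
    stats = ann.mapping_stats(unique_tags, lib_names)
    summary["mapping"] = {s.library: s.to_dict() for s in stats}
    comparisons = {}
    for a, b in zip(lib_names, lib_names[1:]):
        comparisons[f"{a}_vs_{b}"] = ann.compare_libraries(unique_tags, a, b)
    summary["library_comparisons"] = comparisons
    ann.tags_to_table(unique_tags, lib_names).to_csv(
        outdir / "unique_tags.tsv", sep="\t", index=False)

    # --- conserved
    assignments, conserved_table = conserved.assign_conserved(
        unique_tags, mature_refs, max_mm=config.max_mismatches,
        max_score=config.conserved_max_score)
    conserved_table = quantify.normalize_table(conserved_table, clean_totals) \
        if not conserved_table.counts.empty else conserved_table
    conserved_table.write(outdir / "conserved_mirnas.tsv")
    summary["conserved"] = {
        "n_assigned_tags": len(assignments),
        "n_mirnas": int(conserved_table.counts.shape[0]),
        "n_families": len(conserved.families(assignments)),
    }

    # --- novel
    assigned_seqs = {a.tag for a in assignments}
    novel_input = [t for t in unique_tags if t.sequence not in assigned_seqs]
    candidates = novel.predict_novel(
        novel_input, genome, window_flank=config.window_flank,
        energy_max=config.energy_max, score_max=config.novel_max_score,
        min_tag_count=config.min_tag_count, engine=config.fold_engine)
    novel.candidates_to_table(candidates, lib_names).to_csv(
        outdir / "novel_mirnas.tsv", sep="\t", index=False)
    with open(outdir / "novel_structures.txt", "w") as fh:
        for c in candidates:
            fh.write(f">{c.name} {c.locus} {c.strand} {c.energy}\n"
                     f"{c.structure}\n")
    summary["novel"] = {
        "n_candidates": len(candidates),
        "arm_proportion": novel.arm_proportion(candidates),
    }

    # --- targets (optional)
    if config.transcripts:
        transcripts = read_fasta(config.transcripts, rna=True)
        mirna_set = {a.reference_id: mature_refs[a.reference_id]
                     for a in assignments}
        mirna_set.update({c.name: c.mature for c in candidates})
        hits = targets_mod.scan_transcripts(mirna_set, transcripts,
                                            engine=config.fold_engine)
        targets_mod.hits_to_table(hits).to_csv(outdir / "target_hits.tsv",
                                               sep="\t", index=False)
        summary["targets"] = {"n_hits": len(hits)}

        if config.annotations:
            term_map = read_annotation_map(config.annotations)
            population = set(transcripts)
            sample = {h.transcript_id for h in hits}
            enr = quantify.hypergeom_enrich(sample, population, term_map)
            quantify.enrichment_to_table(enr).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False)
            summary["enrichment"] = {
                "n_terms": len(enr),
                "n_significant": sum(r.significant for r in enr),
            }

    if manifest is not None:
        manifest.save(outdir)
    write_json(summary, outdir / "summary.json")
    return summary
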