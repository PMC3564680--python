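"""Shared fixtures: one small simulated two-library experiment, generated
once per session, with its ground-truth manifest."""

from __future__ import annotations

import pytest

from mirseek import annotate as ann
from mirseek.cleaning import clean_library
from mirseek.simulate import (SimulationConfig, generate_contaminants,
                              generate_genome, generate_known_mirnas,
                              generate_libraries)

SEED = 7


@pytest.fixture(scope="session")
def sim():
    """Genome with 5 planted hairpins, 20 known miRNAs, contaminants and
    two 4000-read libraries."""
    config = SimulationConfig(seed=SEED, n_reads_per_library=4000,
                              library_names=("UF", "RF"), n_known_mirnas=20,
                              n_novel_loci=5, n_contaminants_per_class=10)
    genome, loci = generate_genome(SEED, 1, 30_000, n_novel_loci=5)
    known = generate_known_mirnas(SEED, 20)
    contaminants = generate_contaminants(SEED, 10)
    libraries, manifest = generate_libraries(config, genome, known,
                                             contaminants, loci)
    return {
        "config": config,
        "genome": genome,
        "loci": loci,
        "known": known,
        "contaminants": contaminants,
        "libraries": libraries,
        "manifest": manifest,
    }


@pytest.fixture(scope="session")
def cleaned(sim):
    """Per-library clean tags and cleaning reports for the fixture data."""
    cfg = sim["config"]
    tags, reports = {}, {}
    for lib, reads in sim["libraries"].items():
        t, r = clean_library(reads, cfg.adapter5, cfg.adapter3, library=lib)
        tags[lib], reports[lib] = t, r
    return {"tags": tags, "reports": reports}


@pytest.fixture(scope="session")
def unique_tags(sim, cleaned):
    """Collapsed, classified and genome-mapped unique tags."""
    tags = ann.collapse_tags(cleaned["tags"])
    ann.annotate_tags(tags, sim["contaminants"])
    index = ann.GenomeIndex(sim["genome"])
    for tag in tags:
        if tag.annotation == ann.UNANNOTATED and tag.total_count >= 2:
            tag.hits = index.scan(tag.sequence, 2)
    return tags
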