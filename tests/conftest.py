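import numpy as np
import pytest
from hypothesis import settings

from circage import detect, quantify, simulate
from circage.genome_io import (
    GeneModel,
    GenomeSequence,
    PipelineConfig,
    Transcript,
    build_splice_index,
)

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pcfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def hand_genes() -> list[GeneModel]:
    """Two hand-built genes on a 3-kb toy chromosome.

    gA (+): five exons, CDS from mid-exon1 to mid-exon5.
    gB (-): three exons, non-coding.
    """
    gA = GeneModel(
        "gA",
        "chrT",
        "+",
        {
            "gA.t1": Transcript(
                "gA.t1",
                [(100, 200), (300, 400), (500, 600), (700, 800), (900, 1000)],
                [(150, 200), (300, 400), (500, 600), (700, 800), (900, 950)],
            )
        },
    )
    gB = GeneModel(
        "gB",
        "chrT",
        "-",
        {"gB.t1": Transcript("gB.t1", [(1500, 1600), (1700, 1800), (1900, 2000)])},
    )
    return [gA, gB]


@pytest.fixture(scope="session")
def hand_genome(hand_genes) -> GenomeSequence:
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
    return GenomeSequence(["chrT"], {"chrT": seq})


@pytest.fixture(scope="session")
def sim_small() -> simulate.SimDataset:
    """Error-free simulated dataset shared across detection/quantification
    tests (smaller linear depth than the study conditions, for speed)."""
    cfg = simulate.SimConfig(rng_seed=1, linear_mean=40.0)
    return simulate.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def sim_pipeline(sim_small, pcfg):
    """Catalog, templates and count matrix computed from ``sim_small``."""
    idx = build_splice_index(sim_small.genes)
    cands = detect.find_backsplice_candidates(sim_small.reads, sim_small.genome, idx, pcfg)
    catalog = detect.apply_catalog_cutoff(
        detect.dedup_and_merge(cands, sim_small.genes, pcfg), pcfg
    )
    templates = detect.build_junction_templates(
        catalog, sim_small.genes, sim_small.genome, pcfg
    )
    counts = quantify.count_junction_reads(
        sim_small.reads, templates, catalog, sim_small.libraries, pcfg
    )
    return {
        "splice_index": idx,
        "catalog": catalog,
        "templates": templates,
        "counts": counts,
    }
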