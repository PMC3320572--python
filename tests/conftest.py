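import numpy as np
import pytest

from sasrfuse.genemodel import Exon, Gene, GeneModel
from sasrfuse.simdata import SimConfig, simulate_dataset

BASES = "ACGT"


def random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def make_model(gene_specs, genome=None, seed=0):
    """Build a GeneModel from (gene_id, chrom, strand, [(start, end), ...]) tuples.

    Exon intervals are genomic; ranks follow transcription order.  A random
    genome is synthesized for any chromosome not supplied.
    """
    rng = np.random.default_rng(seed)
    genome = dict(genome or {})
    genes = []
    for gid, chrom, strand, ivals in gene_specs:
        need = max(e for _, e in ivals) + 10
        if chrom not in genome or len(genome[chrom]) < need:
            genome[chrom] = (genome.get(chrom, "") +
                             random_seq(rng, need - len(genome.get(chrom, ""))))
        ordered = sorted(ivals) if strand == "+" else sorted(ivals, reverse=True)
        exons = [Exon(exon_id=f"{gid}-{r + 1}", gene_id=gid, chrom=chrom,
                      start=s, end=e, strand=strand, rank=r + 1)
                 for r, (s, e) in enumerate(ordered)]
        genes.append(Gene(gene_id=gid, chrom=chrom, strand=strand, exons=exons))
    return GeneModel(genes, genome)


@pytest.fixture(scope="session")
def small_sim():
    """Small error-free simulated dataset with one fusion of each class."""
    config = SimConfig(seed=7, n_genes=12, n_fusions=3, n_fragments=600,
                       substitution_error_rate=0.0)
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def small_pipeline_result(small_sim):
    from sasrfuse.pipeline import run_fusion_pipeline

    return run_fusion_pipeline(small_sim.model, small_sim.read_pairs)
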