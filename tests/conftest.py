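"""Shared fixtures: a small synthetic world reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import exindnm as ed


@pytest.fixture(scope="session")
def small_config() -> ed.SimulationConfig:
    return ed.SimulationConfig(seed=11, n_genes=40)


@pytest.fixture(scope="session")
def small_world(small_config):
    """A compact simulated dataset: genome, annotation, gene models, windows,
    generating model and one draw of de novo mutations."""
    genome, annotation = ed.simulate_genome(small_config)
    genes, report = ed.build_gene_models(annotation)
    chrom_lengths = {c: genome.length(c) for c in genome.chrom_names}
    windows = ed.extract_windows(genes, chrom_lengths)
    true_model = ed.default_true_model(mean_rate=3e-7)
    dnms = ed.simulate_dnms(genome, annotation, small_config, true_model, genes=genes)
    return {
        "config": small_config,
        "genome": genome,
        "annotation": annotation,
        "genes": genes,
        "report": report,
        "chrom_lengths": chrom_lengths,
        "windows": windows,
        "true_model": true_model,
        "dnms": dnms,
    }


@pytest.fixture
def toy_annotation() -> pd.DataFrame:
    """Hand-built annotation: one 3-exon gene on two transcripts sharing the
    middle exon, plus a single-exon gene elsewhere."""
    rows = [
        # geneA: t1 has exons 1,2,3; t2 has exons 1b (overlapping exon1), 2
        ("chr1", "toy", "gene", 100, 1000, "+", ".", "geneA", ""),
        ("chr1", "toy", "exon", 100, 200, "+", ".", "geneA", "t1"),
        ("chr1", "toy", "exon", 400, 500, "+", ".", "geneA", "t1"),
        ("chr1", "toy", "exon", 800, 1000, "+", ".", "geneA", "t1"),
        ("chr1", "toy", "exon", 150, 250, "+", ".", "geneA", "t2"),
        ("chr1", "toy", "exon", 400, 500, "+", ".", "geneA", "t2"),
        # geneB: single exon
        ("chr1", "toy", "gene", 5000, 5300, "+", ".", "geneB", ""),
        ("chr1", "toy", "exon", 5000, 5300, "+", ".", "geneB", "t3"),
    ]
    return pd.DataFrame(rows, columns=["Chromosome", "Source", "Feature", "Start",
                                       "End", "Strand", "Frame", "gene_id",
                                       "transcript_id"])


def make_coding_gene(seq_exons, seq_introns, strand="+", offset=100, chrom="chr1"):
    """Assemble a GenomeSequence + GeneModel from explicit exon/intron strings.

    The CDS covers every exon; total exon length must be a codon multiple.
    Returns (genome, gene, annotation_free GeneModel exon intervals).
    """
    assert len(seq_introns) == len(seq_exons) - 1
    seq = "T" * offset
    exon_ivs = []
    for i, ex in enumerate(seq_exons):
        exon_ivs.append((len(seq), len(seq) + len(ex)))
        seq += ex
        if i < len(seq_introns):
            seq += seq_introns[i]
    seq += "T" * 50
    genome = ed.GenomeSequence({chrom: seq})
    order = exon_ivs if strand == "+" else exon_ivs[::-1]
    frames, cum = {}, 0
    for s, e in order:
        frames[(s, e)] = cum % 3
        cum += e - s
    gene = ed.GeneModel(
        gene_id="toy", chrom=chrom, strand=strand,
        meta_exons=exon_ivs[1:-1] if len(exon_ivs) > 2 else exon_ivs,
        meta_introns=[(exon_ivs[i][1], exon_ivs[i + 1][0])
                      for i in range(len(exon_ivs) - 1)][1:-1] if len(exon_ivs) > 3 else [],
        cds_intervals=exon_ivs,
        cds_frames=[frames[iv] for iv in exon_ivs],
    )
    return genome, gene


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1729)
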