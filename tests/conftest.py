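import numpy as np
import pytest

from pirnaflow import synthgen
from pirnaflow.core import AnnotatedGenome, CollapsedRead, FeatureInterval


@pytest.fixture(scope="session")
def forged_genome():
    """One default forged genome shared across the session (seed 7)."""
    return synthgen.build_genome(synthgen.GenomeSpec(seed=7))


@pytest.fixture()
def toy_genome():
    """A tiny hand-laid genome: one gene, one TE, one tRNA, one satellite.

    chrT layout (0-based):
      gene1 (+):  utr5 [50,80) | CDS [80,140) | intron [140,180) |
                  CDS [180,240) | utr3 [240,290)
      TE (+, LTR): [320,420)   tRNA (+): [450,500)   satellite: [520,580)
    """
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=650))
    feats = [
        FeatureInterval("chrT", 50, 80, "+", "five_prime_UTR",
                        {"ID": "g1.p1", "gene_id": "gene1"}),
        FeatureInterval("chrT", 80, 140, "+", "CDS",
                        {"ID": "g1.p2", "gene_id": "gene1"}),
        FeatureInterval("chrT", 140, 180, "+", "intron",
                        {"ID": "g1.p3", "gene_id": "gene1"}),
        FeatureInterval("chrT", 180, 240, "+", "CDS",
                        {"ID": "g1.p4", "gene_id": "gene1"}),
        FeatureInterval("chrT", 240, 290, "+", "three_prime_UTR",
                        {"ID": "g1.p5", "gene_id": "gene1"}),
        FeatureInterval("chrT", 320, 420, "+", "transposable_element",
                        {"ID": "te1.c1", "family": "te1", "class": "LTR"}),
        FeatureInterval("chrT", 450, 500, "+", "tRNA", {"ID": "trna1"}),
        FeatureInterval("chrT", 520, 580, "+", "satellite_DNA",
                        {"ID": "sat1", "family": "sat1"}),
    ]
    return AnnotatedGenome(contigs={"chrT": seq}, features=feats)


def make_read(genome, rid, contig, start, end, strand="+", counts=(5, 5)):
    """CollapsedRead whose sequence is an exact genomic (or revcomp) span."""
    from pirnaflow.core import revcomp

    seq = genome.contigs[contig][start:end]
    if strand == "-":
        seq = revcomp(seq)
    return CollapsedRead(id=rid, sequence=seq, counts=np.array(counts))


@pytest.fixture()
def read_factory():
    return make_read
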