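import random

import pytest
from hypothesis import settings

from xstart.genome_io import GeneModel, Genome

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


# default margins: long enough for every window placement (-20 needs the
# protospacer plus a 3-nt PAM beyond the start codon); upstream is G-free so
# bystander tests control their own window content
DEFAULT_UP = "TCTATTCAATCTATTCAATCTAT"
DEFAULT_DOWN = "TCAATTGATCCATTGATCCATTGATC"


def make_plus_gene(
    codons,
    upstream=DEFAULT_UP,
    downstream=DEFAULT_DOWN,
    contig="toy",
    gene_id="g1",
):
    """A plus-strand gene flanked by editable margins; codons include START
    and STOP."""
    cds = "".join(codons)
    seq = upstream + cds + downstream
    gene = GeneModel(
        gene_id, contig, len(upstream) + 1, len(upstream) + len(cds), "+", codons[0]
    )
    return Genome({contig: seq}), gene


def make_minus_gene(codons, upstream=DEFAULT_UP, downstream=DEFAULT_DOWN,
                    contig="toy", gene_id="g1"):
    """Same gene on the minus strand (the CDS reads 5'->3' as ``codons``)."""
    from xstart.genome_io import reverse_complement

    cds = "".join(codons)
    seq = downstream + reverse_complement(cds) + upstream
    gene = GeneModel(
        gene_id, contig, len(downstream) + 1, len(downstream) + len(cds), "-", codons[0]
    )
    return Genome({contig: seq}), gene


def random_codons(rng: random.Random, n: int, forbidden=()):
    """Interior codons avoiding start/stop codons and anything in
    ``forbidden`` (e.g. the four STOP-reachable codons)."""
    banned = {"ATG", "GTG", "TAA", "TAG", "TGA", *forbidden}
    pool = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in banned
    ]
    return [rng.choice(pool) for _ in range(n)]


@pytest.fixture
def rng():
    return random.Random(20240)
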