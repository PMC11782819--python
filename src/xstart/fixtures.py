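"""Deterministic synthetic fixtures with exact planted truths.

Builds toy bacterial genomes (a few kb, several single-segment CDS on both
strands) whose START-exclusion guide placements are known by construction,
plants spacer-similar decoy sites of chosen match lengths for the off-target
scanner, and writes audit VCFs with planted consequence-class compositions.

Truth tables are exact, not probabilistic: gene interiors avoid in-frame
start/stop codons, decoy flanks are forced to mismatch so a planted d-mer
cannot extend, and the whole genome is rebuilt from a fresh seed-derived
stream until no accidental spacer seed-match of length >= k exists outside
the planted loci.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .codon_logic import classify_codon_change, standard_table
from .genome_io import (
    GeneModel,
    Genome,
    Interval,
    reverse_complement,
    write_fasta,
    write_gff3,
)
from .offtarget import IDENTICAL, SEED, scan_spacer_matches
from .variant_audit import SNV

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture.

    ``decoy_lengths`` are contiguous match lengths (>= ``seed_match_k``, up
    to the spacer length) planted intergenically for the top guide of the
    first gene. ``variant_composition`` gives planted consequence-class
    counts for the audit VCF; ``n_other_transitions`` adds non-CBE-type
    (A->G) variants on top.
    """

    seed: int = 0
    contig: str = "chrSyn"
    gene_lengths: tuple = (30, 28, 32)  # codons, incl. START and STOP
    strands: tuple = ("+", "-", "+")
    start_codons: tuple = ("ATG", "ATG", "GTG")
    window: tuple = (-16, -17, -18, -19, -20)
    preferred_position: int = -19
    spacer_length: int = 20
    seed_match_k: int = 11
    decoy_lengths: tuple = (20, 11)
    variant_composition: dict = field(
        default_factory=lambda: {"silent": 3, "missense": 2, "nonsense": 1, "noncoding": 4}
    )
    n_other_transitions: int = 0
    margin: int = 80
    intergene: int = 70
    decoy_gap: int = 45

    def __post_init__(self) -> None:
        if not (
            len(self.gene_lengths) == len(self.strands) == len(self.start_codons)
        ):
            raise FixtureError("gene_lengths/strands/start_codons lengths differ")
        for sc in self.start_codons:
            if sc not in ("ATG", "GTG"):
                raise FixtureError(
                    "fixture truth arithmetic assumes ATG/GTG starts"
                )
        for d in self.decoy_lengths:
            if not self.seed_match_k <= d <= self.spacer_length:
                raise FixtureError(f"decoy length {d} outside [k, spacer_length]")
        if self.margin < self.spacer_length + 5:
            raise FixtureError("margin too small for guide placements")


@dataclass(frozen=True)
class TruthGuide:
    gene_id: str
    critical_position: int
    begin: int  # 0-based half-open protospacer interval
    end: int
    strand: str
    spacer: str
    pam: str


@dataclass(frozen=True)
class TruthHit:
    begin: int
    end: int
    strand: str
    match_length: int
    match_class: str


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    genome: Genome
    genes: list
    truth_guides: list
    truth_hits: list
    attempt: int


# interior codons guaranteeing each audit class is realizable
_CLASS_CODONS = ("CTG", "GCT", "CAG")  # silent / missense / nonsense capable


def _interior_codons(rng: random.Random, n: int, forbidden: frozenset) -> list:
    pool = [
        a + b + c
        for a in _BASES
        for b in _BASES
        for c in _BASES
        if a + b + c not in forbidden
    ]
    codons = [rng.choice(pool) for _ in range(n)]
    for slot, codon in enumerate(_CLASS_CODONS):
        if slot * 2 + 1 < n:
            codons[slot * 2 + 1] = codon
    return codons


def _gene_cassette(rng: random.Random, length: int, start_codon: str, forbidden: frozenset) -> str:
    if length < 5:
        raise FixtureError("gene must be at least 5 codons")
    return start_codon + "".join(_interior_codons(rng, length - 2, forbidden)) + "TAA"


def _expected_guides(
    spec: FixtureSpec, gene: GeneModel, seq: str
) -> list[TruthGuide]:
    """Placement arithmetic written out independently of the design module.

    The only valid single start-destroying edit for ATG and GTG is the
    position-3 G (position 1 of GTG would leave ATG); its noncoding-strand C
    shares the genomic coordinate of that G.
    """
    L = spec.spacer_length
    out = []
    for p in sorted(spec.window, key=lambda q: abs(q - spec.preferred_position)):
        if gene.strand == "+":
            g = (gene.start - 1) + 2
            begin = g + 1 + p
            end = begin + L
            strand = "-"
            spacer = reverse_complement(seq[begin:end])
            pam = reverse_complement(seq[begin - 3 : begin])
        else:
            g = (gene.end - 1) - 2
            begin = g - (p + L)
            end = begin + L
            strand = "+"
            spacer = seq[begin:end]
            pam = seq[end : end + 3]
        out.append(TruthGuide(gene.gene_id, p, begin, end, strand, spacer, pam))
    return out


def _assemble(spec: FixtureSpec, rng: random.Random):
    forbidden = frozenset(spec.start_codons) | frozenset({"TAA", "TAG", "TGA"})
    pieces: list[str] = []
    pos = 0

    def emit(s: str) -> int:
        nonlocal pos
        pieces.append(s)
        start = pos
        pos += len(s)
        return start

    emit("".join(rng.choice(_BASES) for _ in range(spec.margin)))
    genes: list[GeneModel] = []
    for idx, (ncod, strand, start_codon) in enumerate(
        zip(spec.gene_lengths, spec.strands, spec.start_codons)
    ):
        cds = _gene_cassette(rng, ncod, start_codon, forbidden)
        placed = cds if strand == "+" else reverse_complement(cds)
        at = emit(placed)
        genes.append(
            GeneModel(
                f"gene{idx:02d}", spec.contig, at + 1, at + len(placed), strand, start_codon
            )
        )
        emit("".join(rng.choice(_BASES) for _ in range(spec.intergene)))
    decoy_slots: list[tuple[int, int]] = []
    for d in spec.decoy_lengths:
        emit("".join(rng.choice(_BASES) for _ in range(spec.decoy_gap)))
        at = emit("N" * d)  # placeholder, overwritten below
        decoy_slots.append((at, d))
    emit("".join(rng.choice(_BASES) for _ in range(spec.margin)))
    seq = list("".join(pieces))

    truth_guides: list[TruthGuide] = []
    for gene in genes:
        truth_guides.extend(_expected_guides(spec, gene, "".join(seq)))

    # plant decoys from the top-ranked guide of the first gene
    top = next(t for t in truth_guides if t.gene_id == genes[0].gene_id)
    truth_hits: list[TruthHit] = []
    for at, d in decoy_slots:
        s0 = (spec.spacer_length - d) // 2
        sub = top.spacer[s0 : s0 + d]
        seq[at : at + d] = list(sub)
        if s0 > 0:
            want_not = top.spacer[s0 - 1]
            if seq[at - 1] == want_not:
                seq[at - 1] = _BASES[(_BASES.index(want_not) + 1) % 4]
        if s0 + d < spec.spacer_length:
            want_not = top.spacer[s0 + d]
            if seq[at + d] == want_not:
                seq[at + d] = _BASES[(_BASES.index(want_not) + 1) % 4]
        cls = IDENTICAL if d == spec.spacer_length else SEED
        truth_hits.append(TruthHit(at, at + d, "+", d, cls))
    return "".join(seq), genes, truth_guides, truth_hits


def _neighborhood(truths: list[TruthGuide], gene_id: str, contig: str) -> Interval:
    mine = [t for t in truths if t.gene_id == gene_id]
    return Interval(
        contig, min(t.begin for t in mine) - 3, max(t.end for t in mine) + 3
    )


def _clean(spec: FixtureSpec, genome: Genome, genes, truth_guides, truth_hits) -> bool:
    """No accidental seed matches anywhere; planted decoys found exactly."""
    tops = {g.gene_id: next(t for t in truth_guides if t.gene_id == g.gene_id) for g in genes}
    for gene in genes:
        mask = [_neighborhood(truth_guides, gene.gene_id, spec.contig)]
        hits = scan_spacer_matches(
            genome, tops[gene.gene_id].spacer, spec.seed_match_k, mask
        )
        if gene is genes[0]:
            got = sorted((h.interval.begin, h.interval.end, h.interval.strand, h.match_length)
                         for h in hits)
            want = sorted((t.begin, t.end, t.strand, t.match_length) for t in truth_hits)
            if got != want:
                return False
        elif hits:
            return False
    return True


def make_genome(spec: FixtureSpec, outdir: str | Path | None = None) -> FixtureBundle:
    """Build a fixture genome; byte-identical outputs for identical seeds.

    When ``outdir`` is given, writes genome.fasta, genes.gff3 and the truth
    tables (guides_truth.tsv, offtargets_truth.tsv) there.
    """
    bundle = None
    for attempt in range(50):
        rng = random.Random((spec.seed * 100003 + attempt) % 2**31)
        seq, genes, truth_guides, truth_hits = _assemble(spec, rng)
        genome = Genome({spec.contig: seq})
        if _clean(spec, genome, genes, truth_guides, truth_hits):
            bundle = FixtureBundle(spec, genome, genes, truth_guides, truth_hits, attempt)
            break
    if bundle is None:
        raise FixtureError("could not build a clean fixture in 50 attempts")
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(bundle.genome, outdir / "genome.fasta")
        write_gff3(bundle.genes, outdir / "genes.gff3")
        with open(outdir / "guides_truth.tsv", "w") as fh:
            fh.write(f"# fixture seed={spec.seed}\n")
            fh.write("gene_id\tcritical_position\tbegin\tend\tstrand\tspacer\tpam\n")
            for t in bundle.truth_guides:
                fh.write(
                    f"{t.gene_id}\t{t.critical_position}\t{t.begin}\t{t.end}\t"
                    f"{t.strand}\t{t.spacer}\t{t.pam}\n"
                )
        with open(outdir / "offtargets_truth.tsv", "w") as fh:
            fh.write(f"# fixture seed={spec.seed}\n")
            fh.write("begin\tend\tstrand\tmatch_length\tmatch_class\n")
            for h in bundle.truth_hits:
                fh.write(f"{h.begin}\t{h.end}\t{h.strand}\t{h.match_length}\t{h.match_class}\n")
    return bundle


def _cds_candidates(genome: Genome, genes, table):
    """All single CBE-type edits in interior codons, bucketed by consequence."""
    buckets: dict[str, list[SNV]] = {"silent": [], "missense": [], "nonsense": []}
    for gene in genes:
        cds = genome.fetch(gene.interval)
        seq = genome.contigs[gene.contig]
        for ci in range(2, gene.n_codons):  # skip START and terminal STOP
            codon = cds[(ci - 1) * 3 : ci * 3]
            for cp in (1, 2, 3):
                base = codon[cp - 1]
                if base == "C":
                    after = codon[: cp - 1] + "T" + codon[cp:]
                elif base == "G":
                    after = codon[: cp - 1] + "A" + codon[cp:]
                else:
                    continue
                cls = classify_codon_change(codon, after, table)
                if cls not in buckets:
                    continue
                coord = gene.codon_base_coord(ci, cp)
                ref = seq[coord]
                alt = "T" if ref == "C" else "A"
                buckets[cls].append(SNV(gene.contig, coord + 1, ref, alt))
    return buckets


def _intergenic_positions(spec: FixtureSpec, genome: Genome, genes, truth_hits, pad: int = 60):
    seq = genome.contigs[spec.contig]
    blocked = [(g.start - 1 - pad, g.end + pad) for g in genes]
    blocked += [(h.begin - pad, h.end + pad) for h in truth_hits]
    ok = []
    for pos in range(len(seq)):
        if any(b <= pos < e for b, e in blocked):
            continue
        ok.append(pos)
    return ok


def make_audit_vcf(
    spec: FixtureSpec, bundle: FixtureBundle, path: str | Path | None = None
) -> tuple[list[SNV], dict]:
    """Plant an audit variant set with a known consequence composition.

    Planted intergenic variants stay >= 60 bp away from genes and decoy
    sites so their attribution is ``deamination``. Returns the variants and
    the truth counts; raises when the composition is not realizable in the
    genome.
    """
    table = standard_table(start_set=frozenset(spec.start_codons))
    rng = random.Random((spec.seed * 100003 + 7919) % 2**31)
    genome, genes = bundle.genome, bundle.genes
    buckets = _cds_candidates(genome, genes, table)
    seq = genome.contigs[spec.contig]
    variants: list[SNV] = []
    truth: dict[str, int] = {}
    used: set[int] = set()

    for cls in ("silent", "missense", "nonsense"):
        want = spec.variant_composition.get(cls, 0)
        pool = [v for v in buckets[cls] if v.pos not in used]
        if len(pool) < want:
            raise FixtureError(
                f"composition unrealizable: {want} {cls} wanted, {len(pool)} sites"
            )
        chosen = rng.sample(pool, want)
        used.update(v.pos for v in chosen)
        variants.extend(chosen)
        truth[cls] = want

    free = _intergenic_positions(spec, genome, genes, bundle.truth_hits)
    want_nc = spec.variant_composition.get("noncoding", 0)
    cg = [p for p in free if seq[p] in "CG" and p + 1 not in used]
    if len(cg) < want_nc:
        raise FixtureError("composition unrealizable: not enough intergenic C/G")
    for p in rng.sample(cg, want_nc):
        ref = seq[p]
        variants.append(SNV(spec.contig, p + 1, ref, "T" if ref == "C" else "A"))
        used.add(p + 1)
    truth["noncoding"] = want_nc

    a_sites = [p for p in free if seq[p] == "A" and p + 1 not in used]
    if len(a_sites) < spec.n_other_transitions:
        raise FixtureError("composition unrealizable: not enough intergenic A")
    for p in rng.sample(a_sites, spec.n_other_transitions):
        variants.append(SNV(spec.contig, p + 1, "A", "G"))
    truth["noncoding"] = truth.get("noncoding", 0) + spec.n_other_transitions
    truth["other_transitions"] = spec.n_other_transitions

    variants.sort(key=lambda v: v.pos)
    if path is not None:
        write_vcf(variants, genome, path, seed=spec.seed)
    return variants, truth


def write_vcf(variants, genome: Genome, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=xstart-fixture\n")
        if seed is not None:
            fh.write(f"##fixture_seed={seed}\n")
        for name, seq in genome.contigs.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t50\tPASS\t.\n")
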