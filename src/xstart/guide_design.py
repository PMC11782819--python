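"""Guide enumeration for PAM-independent cytosine base editing.

Two design modes are implemented. START-exclusion (XSTART) places a guide on
the gene's noncoding strand so that the C pairing with a G of the START
codon (CAT/CAC, the reverse complement of ATG/GTG) sits in the deaminase
hot-spot window; a single C->T edit then abolishes translation initiation,
independent of any PAM when an SpRY effector is used. Premature-STOP (iSTOP)
mode is the conventional alternative: it scans the CDS for the four codons
(CAA, CAG, CGA on the coding strand; TGG via the noncoding strand) that a
single edit converts into a STOP codon.

Spacer positions follow the base-editing convention: the protospacer base
adjacent to the PAM is position -1 and the 5'-most base of a 20-nt spacer is
position -20. The hot spot lies at -16..-19 with -19 the most efficient
placement; -20 retains high activity and is included in the default window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .codon_logic import (
    CODING,
    NONCODING,
    CodonTable,
    SingleEdit,
    classify_codon_change,
    standard_table,
    start_elimination_edits,
    stop_introducible_codons,
)
from .genome_io import (
    DEFAULT_START_SET,
    GeneModel,
    Genome,
    Interval,
    reverse_complement,
)

PAM_LENGTH = 3

SPRY_FREE = "SpRY_free"
DCAS9_NGG = "dCas9_NGG"

NGG = "NGG"
NRN = "NRN"
NYN = "NYN"

_CLASS_RANK = {NGG: 0, NRN: 0, NYN: 1}


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class DesignConfig:
    """Tunable design parameters.

    ``window`` is the set of spacer positions eligible to hold the critical
    C (default -16..-20); ``preferred_position`` (default -19) anchors the
    ranking. ``pam_mode`` selects between the PAM-free SpRY regime (NRN
    softly preferred over NYN, nothing filtered) and a conventional
    dCas9-NGG filter. ``first_half_rule`` restricts premature-STOP designs
    to the first half of the CDS to avoid near-terminal truncations that may
    leave a functional protein.
    """

    spacer_length: int = 20
    window: frozenset = frozenset({-16, -17, -18, -19, -20})
    preferred_position: int = -19
    pam_mode: str = SPRY_FREE
    start_set: frozenset = DEFAULT_START_SET
    first_half_rule: bool = True
    seed_match_k: int = 11
    table_id: int = 11

    def __post_init__(self) -> None:
        if self.pam_mode not in (SPRY_FREE, DCAS9_NGG):
            raise DesignError(f"unknown pam_mode {self.pam_mode!r}")
        for p in self.window:
            if not (-self.spacer_length <= p <= -1):
                raise DesignError(f"window position {p} outside spacer")
        if self.preferred_position not in self.window:
            raise DesignError("preferred_position must lie in the window")

    def table(self) -> CodonTable:
        return standard_table(self.table_id, self.start_set)


def pam_class(pam: str, mode: str) -> tuple[str, bool]:
    """Classify a PAM triplet and decide whether the mode allows it.

    dCas9_NGG: allowed iff positions 2-3 are GG. SpRY_free: always allowed;
    class NRN when the middle base is a purine, NYN otherwise (a binding
    preference only, never a filter). A PAM containing N is disallowed in
    both modes.
    """
    pam = pam.upper()
    if len(pam) != PAM_LENGTH:
        raise DesignError(f"PAM must be a 3-mer, got {pam!r}")
    if set(pam) - set("ACGT"):
        return NYN, False
    if mode == DCAS9_NGG:
        if pam[1:] == "GG":
            return NGG, True
        return (NRN if pam[1] in "AG" else NYN), False
    return (NRN if pam[1] in "AG" else NYN), True


def place_protospacer(
    target: int, spacer_pos: int, strand: str, contig: str, length: int = 20
) -> tuple[Interval, Interval]:
    """Protospacer and PAM intervals placing ``target`` at ``spacer_pos``.

    ``target`` is the 0-based genomic coordinate of the base that must sit
    at spacer position ``spacer_pos`` on protospacer strand ``strand``; the
    PAM occupies the 3 nt immediately 3' of the protospacer on that strand.
    May return intervals with negative coordinates near the contig edge —
    callers drop those.
    """
    i = spacer_pos + length  # 0-based index from the spacer's 5' end
    if not 0 <= i < length:
        raise DesignError(f"spacer position {spacer_pos} outside spacer")
    if strand == "+":
        b = target - i
        return (
            Interval(contig, b, b + length, "+"),
            Interval(contig, b + length, b + length + PAM_LENGTH, "+"),
        )
    b = target - length + 1 + i
    return (
        Interval(contig, b, b + length, "-"),
        Interval(contig, b - PAM_LENGTH, b, "-"),
    )


def spacer_position_of(protospacer: Interval, coord: int) -> int:
    """Spacer position (-L..-1) of genomic ``coord`` inside a protospacer."""
    L = len(protospacer)
    if protospacer.strand == "+":
        p = coord - protospacer.begin - L
    else:
        p = protospacer.begin - 1 - coord
    if not -L <= p <= -1:
        raise DesignError(f"coordinate {coord} not inside {protospacer}")
    return p


def genomic_coord_at(protospacer: Interval, spacer_pos: int) -> int:
    """Inverse of :func:`spacer_position_of`."""
    L = len(protospacer)
    i = spacer_pos + L
    if protospacer.strand == "+":
        return protospacer.begin + i
    return protospacer.begin + L - 1 - i


@dataclass(frozen=True)
class IntendedEdit:
    """The designed deamination, as a plus-strand genomic substitution."""

    edit: SingleEdit
    genomic_pos: int  # 0-based
    ref_plus: str
    alt_plus: str


@dataclass(frozen=True)
class PredictedEdit:
    """A bystander C in the window, with its mapped consequence."""

    genomic_pos: int  # 0-based
    spacer_position: int
    ref_plus: str
    alt_plus: str
    context: str  # "CDS" or "five_prime_UTR/intergenic"
    consequence: str  # classify_codon_change class, or "noncoding"
    gene_id: str | None = None


@dataclass(frozen=True)
class GuideDesign:
    gene_id: str
    spacer: str
    protospacer: Interval
    pam: str
    pam_class: str
    critical_position: int
    intended_edit: IntendedEdit
    rank: int = 0
    bystanders: tuple = field(default=())

    def __post_init__(self) -> None:
        L = len(self.protospacer)
        if len(self.spacer) != L:
            raise DesignError("spacer length disagrees with protospacer interval")
        if self.spacer[self.critical_position + L] != "C":
            raise DesignError("critical position does not hold a C")


def _fits(genome: Genome, iv: Interval) -> bool:
    return 0 <= iv.begin and iv.end <= genome.length(iv.contig)


def _edit_on_plus(protospacer_strand: str) -> tuple[str, str]:
    """The C->T edit seen on the genomic plus strand."""
    return ("C", "T") if protospacer_strand == "+" else ("G", "A")


def _rank_and_sort(guides: list[GuideDesign], config: DesignConfig) -> list[GuideDesign]:
    """Total order: window distance from the preferred position, then PAM
    class (NRN/NGG before NYN), then 5'-most genomic coordinate."""
    key = lambda g: (
        abs(g.critical_position - config.preferred_position),
        _CLASS_RANK[g.pam_class],
        g.protospacer.begin,
        g.protospacer.strand,
        g.critical_position,
    )
    ordered = sorted(guides, key=key)
    return [replace(g, rank=i + 1) for i, g in enumerate(ordered)]


def _build_guide(
    genome: Genome,
    gene: GeneModel,
    edit: SingleEdit,
    target: int,
    proto_strand: str,
    spacer_pos: int,
    config: DesignConfig,
) -> GuideDesign | None:
    """Assemble one candidate placement, or None if it is invalid."""
    try:
        proto, pam_iv = place_protospacer(
            target, spacer_pos, proto_strand, gene.contig, config.spacer_length
        )
    except (DesignError, ValueError):
        return None
    if not (_fits(genome, proto) and _fits(genome, pam_iv)):
        return None
    spacer = genome.fetch(proto)
    pam = genome.fetch(pam_iv)
    if "N" in spacer or "N" in pam:
        return None
    cls, allowed = pam_class(pam, config.pam_mode)
    if not allowed:
        return None
    ref, alt = _edit_on_plus(proto_strand)
    return GuideDesign(
        gene_id=gene.gene_id,
        spacer=spacer,
        protospacer=proto,
        pam=pam,
        pam_class=cls,
        critical_position=spacer_pos,
        intended_edit=IntendedEdit(edit, target, ref, alt),
    )


def _joint_window_start_codon(
    gene: GeneModel, guide: GuideDesign, config: DesignConfig
) -> str:
    """First codon after applying every in-window edit of the start codon.

    The deaminase edits all window Cs with some probability, so a design is
    judged on the joint outcome of every editable start-codon G whose
    noncoding C lies in the window, not on the intended edit alone.
    """
    codon = list(gene.start_codon)
    for q in range(1, 4):
        if codon[q - 1] != "G":
            continue
        coord = gene.codon_base_coord(1, q)
        try:
            p = spacer_position_of(guide.protospacer, coord)
        except DesignError:
            continue
        if p in config.window or p == guide.critical_position:
            codon[q - 1] = "A"
    return "".join(codon)


def enumerate_xstart_guides(
    genome: Genome, gene: GeneModel, config: DesignConfig | None = None
) -> list[GuideDesign]:
    """Enumerate ranked START-exclusion guides for one gene.

    The protospacer strand is always the gene's noncoding strand; one
    candidate per valid start-destroying edit per window position. In
    SpRY_free mode nothing is PAM-filtered; in dCas9_NGG mode only NGG
    placements survive. A placement is dropped when the joint outcome of all
    in-window start-codon edits is still a legal start codon.
    """
    config = config or DesignConfig()
    table = config.table()
    if gene.start_codon not in table.start_set:
        raise DesignError(
            f"{gene.gene_id} start codon {gene.start_codon} not in start set"
        )
    proto_strand = "-" if gene.strand == "+" else "+"
    guides: list[GuideDesign] = []
    for edit in start_elimination_edits(gene.start_codon, table):
        target = gene.codon_base_coord(1, edit.codon_position)
        for p in sorted(config.window):
            g = _build_guide(genome, gene, edit, target, proto_strand, p, config)
            if g is None:
                continue
            if _joint_window_start_codon(gene, g, config) in table.start_set:
                continue
            guides.append(g)
    return _rank_and_sort(guides, config)


def _codon_single_edits(codon: str):
    for pos in range(3):
        if codon[pos] == "C":
            yield SingleEdit(pos + 1, CODING, codon, codon[:pos] + "T" + codon[pos + 1 :])
        if codon[pos] == "G":
            yield SingleEdit(pos + 1, NONCODING, codon, codon[:pos] + "A" + codon[pos + 1 :])


def enumerate_stop_guides(
    genome: Genome, gene: GeneModel, config: DesignConfig | None = None
) -> list[GuideDesign]:
    """Enumerate ranked premature-STOP guides for one gene.

    Scans the CDS for codons a single edit converts to STOP; with
    ``first_half_rule`` only codons in the first half of the CDS are used.
    The protospacer lies on whichever strand carries the editable C: the
    coding strand for C->T codons (CAA/CAG/CGA), the noncoding strand for
    TGG (a G->A on the coding strand).
    """
    config = config or DesignConfig()
    table = config.table()
    cds = genome.fetch(gene.interval)
    reachable = stop_introducible_codons(table)
    guides: list[GuideDesign] = []
    for ci in range(1, gene.n_codons + 1):
        if config.first_half_rule and 2 * ci > gene.n_codons:
            continue
        codon = cds[(ci - 1) * 3 : ci * 3]
        if codon not in reachable or codon in table.stop_set:
            continue
        for edit in _codon_single_edits(codon):
            if edit.after not in table.stop_set:
                continue
            proto_strand = (
                gene.strand
                if edit.edited_strand == CODING
                else ("-" if gene.strand == "+" else "+")
            )
            target = gene.codon_base_coord(ci, edit.codon_position)
            for p in sorted(config.window):
                g = _build_guide(genome, gene, edit, target, proto_strand, p, config)
                if g is not None:
                    guides.append(g)
    return _rank_and_sort(guides, config)


def codon_change_for_substitution(
    genome: Genome, gene: GeneModel, pos0: int, ref_plus: str, alt_plus: str
) -> tuple[str, str, int, int]:
    """Map a plus-strand substitution into a coding-strand codon change.

    Returns (before_codon, after_codon, codon_index, codon_position).
    """
    if gene.strand == "+":
        off = pos0 - (gene.start - 1)
        cref, calt = ref_plus, alt_plus
    else:
        off = (gene.end - 1) - pos0
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        cref, calt = comp[ref_plus], comp[alt_plus]
    if not 0 <= off < gene.end - gene.start + 1:
        raise DesignError(f"position {pos0} not inside {gene.gene_id}")
    ci, cp = off // 3 + 1, off % 3 + 1
    cds = genome.fetch(gene.interval)
    before = cds[(ci - 1) * 3 : ci * 3]
    if before[cp - 1] != cref:
        raise DesignError("reference base disagrees with extracted CDS")
    after = before[: cp - 1] + calt + before[cp:]
    return before, after, ci, cp


def predict_bystanders(
    guide: GuideDesign,
    genome: Genome,
    genes: Sequence[GeneModel],
    config: DesignConfig | None = None,
) -> list[PredictedEdit]:
    """Predict bystander edits: every window C other than the intended one.

    Each is mapped to a genomic coordinate and, when it falls in a CDS, to a
    consequence class via the affected codon; outside any CDS the context is
    reported as 5'-UTR/intergenic with consequence "noncoding".
    """
    config = config or DesignConfig()
    table = config.table()
    ref, alt = _edit_on_plus(guide.protospacer.strand)
    out: list[PredictedEdit] = []
    for p in sorted(config.window, reverse=True):
        if p == guide.critical_position:
            continue
        base = guide.spacer[p + len(guide.protospacer)]
        if base != "C":
            continue
        coord = genomic_coord_at(guide.protospacer, p)
        hit_gene = next(
            (
                g
                for g in genes
                if g.contig == guide.protospacer.contig and g.start - 1 <= coord < g.end
            ),
            None,
        )
        if hit_gene is None:
            out.append(
                PredictedEdit(coord, p, ref, alt, "five_prime_UTR/intergenic", "noncoding")
            )
            continue
        before, after, ci, _ = codon_change_for_substitution(
            genome, hit_gene, coord, ref, alt
        )
        consequence = classify_codon_change(before, after, table, is_first_codon=ci == 1)
        out.append(PredictedEdit(coord, p, ref, alt, "CDS", consequence, hit_gene.gene_id))
    return out


def shifted_ngg_note(genome: Genome, guide: GuideDesign, shift: int = 2) -> bool:
    """Informational only: is there an NGG within ``shift`` nt 3' of the PAM?

    A near-NGG motif next to a designed non-NGG PAM has been observed to
    rescue editing with a conventional dCas9 effector. This never alters
    filtering; callers may surface it as a note.
    """
    iv, strand = guide.protospacer, guide.protospacer.strand
    for off in range(1, shift + 1):
        if strand == "+":
            b = iv.end + off
            cand = Interval(iv.contig, b, b + PAM_LENGTH, "+")
        else:
            b = iv.begin - PAM_LENGTH - off
            if b < 0:
                continue
            cand = Interval(iv.contig, b, b + PAM_LENGTH, "-")
        if cand.end > genome.length(iv.contig):
            continue
        if genome.fetch(cand)[1:] == "GG":
            return True
    return False


def structure_warning_hook(guide: GuideDesign) -> None:
    """Placeholder for spacer secondary-structure/self-complementarity
    checks; intentionally a no-op."""
    return None


@dataclass(frozen=True)
class ReinitiationSite:
    """A downstream in-frame start-like codon (a reinitiation trap)."""

    genomic_pos: int  # 1-based coordinate of the codon's first base
    codon_index: int
    codon: str
    in_frame: bool = True


def scan_reinitiation(
    genome: Genome,
    gene: GeneModel,
    config: DesignConfig | None = None,
    horizon: int | None = None,
) -> list[ReinitiationSite]:
    """In-frame start-set codons downstream of codon 1.

    A downstream in-frame ATG/GTG can reinitiate translation after START
    exclusion and yield an N-terminally truncated but active protein, so
    such sites are flagged for multiplex (tandem-guide) designs. The scan
    horizon defaults to the first half of the CDS, sorted by proximity.
    """
    config = config or DesignConfig()
    cds = genome.fetch(gene.interval)
    if horizon is None:
        horizon = gene.n_codons // 2
    hits = []
    for ci in range(2, min(horizon, gene.n_codons) + 1):
        codon = cds[(ci - 1) * 3 : ci * 3]
        if codon in config.start_set:
            iv = gene.codon_interval(ci)
            first = iv.begin + 1 if gene.strand == "+" else iv.end
            hits.append(ReinitiationSite(first, ci, codon))
    return hits


def design_multiplex(
    genome: Genome, gene: GeneModel, config: DesignConfig | None = None
) -> list[list[GuideDesign]]:
    """Tandem designs: the top XSTART guide for the original START and for
    each downstream reinitiation site.

    Returns a single guide set (list of one guide per start-like codon)
    wrapped in a list, or an empty list with a warning when any member codon
    has no valid placement. With no downstream site this degenerates to the
    singleton standard design.
    """
    config = config or DesignConfig()
    targets: list[GeneModel] = [gene]
    for site in scan_reinitiation(genome, gene, config):
        off = (site.codon_index - 1) * 3
        if gene.strand == "+":
            sub = GeneModel(
                f"{gene.gene_id}@codon{site.codon_index}",
                gene.contig,
                gene.start + off,
                gene.end,
                "+",
                site.codon,
            )
        else:
            sub = GeneModel(
                f"{gene.gene_id}@codon{site.codon_index}",
                gene.contig,
                gene.start,
                gene.end - off,
                "-",
                site.codon,
            )
        targets.append(sub)
    guide_set: list[GuideDesign] = []
    for tgt in targets:
        guides = enumerate_xstart_guides(genome, tgt, config)
        if not guides:
            warnings.warn(
                f"no valid guide for {tgt.gene_id}; multiplex set not emitted",
                stacklevel=2,
            )
            return []
        guide_set.append(guides[0])
    return [guide_set]
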