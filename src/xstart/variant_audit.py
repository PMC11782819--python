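"""Whole-genome audit of base-edited strains from variant calls.

Classifies SNVs from a VCF into transition classes (C->T / G->A are the CBE
signature), genic context and codon-level consequence, and attributes each
variant to the intended design locus, to guide-dependent off-target binding
(proximity to a spacer-similar site), or to random deamination. Also
implements the screen statistics used to report editing efficiency:
edited colonies / screened colonies as a percent, replicate mean and sample
SD, and an unpaired two-tailed t test (Welch by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats as _stats

from pysam import VariantFile

from .codon_logic import CodonTable, classify_codon_change, standard_table
from .genome_io import GeneModel, Genome, Interval
from .guide_design import codon_change_for_substitution
from .offtarget import OffTargetHit

C_TO_T = "C_to_T"
G_TO_A = "G_to_A"
OTHER = "other"

INTENDED = "intended"
GUIDE_DEPENDENT = "guide_dependent"
DEAMINATION = "deamination"

NOCODING = "noncoding"

CONSEQUENCES = ("missense", "nonsense", "silent", NOCODING, "start_loss", "stop_loss")


class AuditError(ValueError):
    """Fatal audit inconsistency (e.g. VCF/FASTA coordinate drift)."""


@dataclass(frozen=True)
class SNV:
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str


@dataclass(frozen=True)
class AuditedVariant:
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    transition_class: str
    context: str  # "CDS" | "non_CDS"
    consequence: str
    attribution: str
    gene_id: str | None = None
    flank: str = ""  # +/- 3 bp reference context, descriptive only


@dataclass
class AuditSummary:
    """Aggregate counts; ``total`` excludes intended design edits."""

    total: int = 0
    total_including_intended: int = 0
    by_transition: dict = field(default_factory=dict)
    by_consequence: dict = field(default_factory=dict)
    by_attribution: dict = field(default_factory=dict)
    fraction_noncoding_or_silent: float = 0.0


def read_vcf(path: str | Path) -> list[SNV]:
    """Biallelic SNVs from a VCF; only PASS/'.' records are audited, indels
    are skipped with a warning, multi-allelic records yield one SNV per alt."""
    out: list[SNV] = []
    with VariantFile(str(path)) as vcf:
        for rec in vcf:
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                continue
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or alt == "*":
                    warnings.warn(
                        f"skipping non-SNV record at {rec.chrom}:{rec.pos}",
                        stacklevel=2,
                    )
                    continue
                out.append(SNV(rec.chrom, rec.pos, rec.ref.upper(), alt.upper()))
    return out


def transition_class(ref: str, alt: str) -> str:
    if (ref, alt) == ("C", "T"):
        return C_TO_T
    if (ref, alt) == ("G", "A"):
        return G_TO_A
    return OTHER


def _near(pos0: int, contig: str, hits: Sequence[OffTargetHit], w: int) -> bool:
    for h in hits:
        if h.interval.contig == contig and h.interval.begin - w <= pos0 < h.interval.end + w:
            return True
    return False


def classify_variants(
    variants: Iterable[SNV],
    genome: Genome,
    genes: Sequence[GeneModel],
    intended_mask: Iterable[Interval] = (),
    offtarget_hits: Sequence[OffTargetHit] = (),
    proximity_w: int = 50,
    table: CodonTable | None = None,
) -> tuple[list[AuditedVariant], AuditSummary]:
    """Classify and attribute SNVs; the summary excludes intended edits.

    A variant whose REF disagrees with the genome is fatal (coordinate
    drift between the VCF and the FASTA). Consequences are recomputed from
    the affected codon; variants outside every CDS are "noncoding".
    Attribution: ``intended`` inside the design mask, ``guide_dependent``
    within ``proximity_w`` bp of a spacer-similarity hit, else
    ``deamination``.
    """
    table = table or standard_table()
    mask = list(intended_mask)
    audited: list[AuditedVariant] = []
    for v in variants:
        seq = genome.contigs[v.contig]
        pos0 = v.pos - 1
        if not 0 <= pos0 < len(seq):
            raise AuditError(f"variant at {v.contig}:{v.pos} outside contig")
        if seq[pos0] != v.ref:
            raise AuditError(
                f"VCF REF {v.ref} disagrees with genome base {seq[pos0]} at "
                f"{v.contig}:{v.pos} — coordinate drift?"
            )
        gene = next(
            (g for g in genes if g.contig == v.contig and g.start - 1 <= pos0 < g.end),
            None,
        )
        if gene is None:
            context, consequence, gene_id = "non_CDS", NOCODING, None
        else:
            before, after, ci, _ = codon_change_for_substitution(
                genome, gene, pos0, v.ref, v.alt
            )
            context = "CDS"
            consequence = classify_codon_change(before, after, table, is_first_codon=ci == 1)
            gene_id = gene.gene_id
        if any(m.contig == v.contig and m.begin <= pos0 < m.end for m in mask):
            attribution = INTENDED
        elif _near(pos0, v.contig, offtarget_hits, proximity_w):
            attribution = GUIDE_DEPENDENT
        else:
            attribution = DEAMINATION
        flank = seq[max(0, pos0 - 3) : pos0 + 4]
        audited.append(
            AuditedVariant(
                v.contig,
                v.pos,
                v.ref,
                v.alt,
                transition_class(v.ref, v.alt),
                context,
                consequence,
                attribution,
                gene_id,
                flank,
            )
        )
    return audited, summarize(audited)


def summarize(audited: Sequence[AuditedVariant]) -> AuditSummary:
    s = AuditSummary()
    s.total_including_intended = len(audited)
    offtarget = [a for a in audited if a.attribution != INTENDED]
    s.total = len(offtarget)
    for a in offtarget:
        s.by_transition[a.transition_class] = s.by_transition.get(a.transition_class, 0) + 1
        s.by_consequence[a.consequence] = s.by_consequence.get(a.consequence, 0) + 1
    for a in audited:
        s.by_attribution[a.attribution] = s.by_attribution.get(a.attribution, 0) + 1
    if s.total:
        benign = sum(
            1 for a in offtarget if a.consequence in (NOCODING, "silent")
        )
        s.fraction_noncoding_or_silent = benign / s.total
    return s


def screen_efficiency(n_edited: int, n_total: int) -> float:
    """Editing efficiency: 100 * edited colonies / screened colonies,
    reported to two decimals."""
    if n_total < 1:
        raise ValueError("no colonies screened")
    if not 0 <= n_edited <= n_total:
        raise ValueError("edited colony count outside [0, total]")
    return round(100.0 * n_edited / n_total, 2)


def replicate_stats(percents: Sequence[float]) -> tuple[float, float]:
    """Mean and sample (n-1) SD of replicate efficiencies.

    A single replicate has undefined sample SD; by convention 0.0 is
    returned with a warning.
    """
    if len(percents) == 0:
        raise ValueError("no replicates")
    mean = sum(percents) / len(percents)
    if len(percents) == 1:
        warnings.warn("sample SD undefined for a single replicate; reporting 0",
                      stacklevel=2)
        return mean, 0.0
    var = sum((x - mean) ** 2 for x in percents) / (len(percents) - 1)
    return mean, math.sqrt(var)


def two_sample_t(
    group_a: Sequence[float], group_b: Sequence[float], equal_var: bool = False
) -> tuple[float, float]:
    """Unpaired two-tailed t test (Welch by default).

    Degenerate zero-variance groups with equal means give t = 0, p = 1.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 observations")
    with warnings.catch_warnings():
        # near-identical groups trip a scipy precision warning; the nan
        # fallback below handles the truly degenerate case
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = _stats.ttest_ind(group_a, group_b, equal_var=equal_var)
    if math.isnan(t):
        mean_a = sum(group_a) / len(group_a)
        mean_b = sum(group_b) / len(group_b)
        if mean_a == mean_b:
            return 0.0, 1.0
        return math.inf if mean_a > mean_b else -math.inf, 0.0
    return float(t), float(p)
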