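"""Genome-wide spacer-similarity scan (PAM-free, SpRY regime).

Off-target binding of a PAM-relaxed base editor is attributed to contiguous
exact sequence identity between the spacer and the genome: a full-length
duplicate, or a seed match of at least ``k`` consecutive bases (default 11,
the shortest match observed to drive off-target editing). Matching is exact;
mismatch-tolerant search is deliberately not implemented.

The scan indexes the spacer's (L - k + 1) k-mers, slides over both strands
of every contig, extends each k-mer hit to its maximal contiguous match, and
reports every maximal match once.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome_io import GeneModel, Genome, Interval, reverse_complement

IDENTICAL = "identical"
SEED = "seed"


@dataclass(frozen=True)
class OffTargetHit:
    spacer_id: str
    interval: Interval  # strand = genomic strand whose sequence matches the spacer
    match_length: int
    match_class: str
    gene_id: str = "intergenic"

    @property
    def strand(self) -> str:
        return self.interval.strand


def _maximal_matches(text: str, spacer: str, k: int) -> dict[tuple[int, int], int]:
    """Maximal contiguous matches (>= k) of ``spacer`` within ``text``.

    Returns {(begin, end): match_length} in ``text`` coordinates. Ns in the
    text never match (the spacer is N-free by construction).
    """
    L = len(spacer)
    seeds: dict[str, list[int]] = defaultdict(list)
    for i in range(L - k + 1):
        seeds[spacer[i : i + k]].append(i)
    found: dict[tuple[int, int], int] = {}
    n = len(text)
    for j in range(n - k + 1):
        offsets = seeds.get(text[j : j + k])
        if not offsets:
            continue
        for i in offsets:
            left = 0
            while j - left - 1 >= 0 and i - left - 1 >= 0 and text[j - left - 1] == spacer[i - left - 1]:
                left += 1
            right = 0
            while j + k + right < n and i + k + right < L and text[j + k + right] == spacer[i + k + right]:
                right += 1
            b, e = j - left, j + k + right
            found[(b, e)] = max(found.get((b, e), 0), e - b)
    return found


def scan_spacer_matches(
    genome: Genome,
    spacer: str,
    k: int = 11,
    mask: Iterable[Interval] = (),
    genes: Sequence[GeneModel] = (),
    spacer_id: str = "spacer",
) -> list[OffTargetHit]:
    """All genomic loci sharing a contiguous exact >= k-mer with the spacer.

    Both strands are scanned; hits overlapping any ``mask`` interval (e.g.
    the on-target protospacer) are suppressed. Hits are classed
    ``identical`` when the match spans the whole spacer, ``seed`` otherwise,
    annotated with any overlapping CDS, and returned in deterministic
    (contig, coordinate, strand) order.
    """
    spacer = spacer.upper()
    if not 1 <= k <= len(spacer):
        raise ValueError(f"k={k} outside 1..{len(spacer)}")
    mask = list(mask)
    hits: list[OffTargetHit] = []
    for contig, seq in genome.contigs.items():
        n = len(seq)
        for strand in ("+", "-"):
            text = seq if strand == "+" else reverse_complement(seq)
            for (b, e), mlen in _maximal_matches(text, spacer, k).items():
                if strand == "+":
                    iv = Interval(contig, b, e, "+")
                else:
                    iv = Interval(contig, n - e, n - b, "-")
                if any(iv.overlaps(m) for m in mask):
                    continue
                gene_id = next(
                    (
                        g.gene_id
                        for g in genes
                        if g.contig == contig and g.start - 1 < iv.end and iv.begin < g.end
                    ),
                    "intergenic",
                )
                cls = IDENTICAL if mlen == len(spacer) else SEED
                hits.append(OffTargetHit(spacer_id, iv, mlen, cls, gene_id))
    hits.sort(key=lambda h: (h.interval.contig, h.interval.begin, h.interval.strand))
    return hits
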