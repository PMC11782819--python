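"""Genetic-code reasoning for cytosine base editing.

A cytosine base editor (CBE) deaminates C to U, fixed as a C->T transition on
the edited strand. On the coding strand this reads as C->T; a C->T on the
noncoding (template) strand reads as G->A on the coding strand. This module
answers two questions that drive guide design:

* which codons can a single such edit convert into a STOP codon
  (premature-STOP / iSTOP mode), and
* which single noncoding-strand edits destroy a START codon without merely
  converting it into another legal start (START-exclusion / XSTART mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable

from Bio.Data import CodonTable as _BioCodonTable

from .genome_io import DEFAULT_START_SET

CODING = "coding"
NONCODING = "noncoding"

ALL_CODONS = ["".join(p) for p in product("ACGT", repeat=3)]


@dataclass(frozen=True)
class CodonTable:
    """Genetic code plus the start/stop codon sets used for design.

    ``code`` maps every one of the 64 codons to a one-letter amino acid or
    ``"*"`` for STOP. ``start_set`` defaults to {ATG, GTG} — the two starts
    targeted by START-exclusion designs — independent of the (much more
    permissive) initiation list of the underlying NCBI table.
    """

    code: dict
    start_set: frozenset
    stop_set: frozenset

    def __post_init__(self) -> None:
        if set(self.code) != set(ALL_CODONS):
            raise ValueError("codon table must cover all 64 codons")

    def amino_acid(self, codon: str) -> str:
        return self.code[codon]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_set

    def is_start(self, codon: str) -> bool:
        return codon in self.start_set


def standard_table(
    table_id: int = 11, start_set: Iterable[str] = DEFAULT_START_SET
) -> CodonTable:
    """Build a :class:`CodonTable` from an NCBI translation table.

    Default is table 11 (bacterial/archaeal/plastid); for the purposes of
    this package it is identical in codon assignments to the standard code.
    """
    bio = _BioCodonTable.unambiguous_dna_by_id[table_id]
    code = {c: bio.forward_table.get(c, "*") for c in ALL_CODONS}
    return CodonTable(
        code=code,
        start_set=frozenset(s.upper() for s in start_set),
        stop_set=frozenset(bio.stop_codons),
    )


@dataclass(frozen=True)
class SingleEdit:
    """One C->T deamination, in coding-strand codon representation.

    ``edited_strand == "coding"``: ``before`` has C at ``codon_position``
    (1-based within the codon) and ``after`` has T. ``edited_strand ==
    "noncoding"``: the deaminated C lies on the template strand, so on the
    coding strand ``before`` has G at ``codon_position`` and ``after`` has A.
    """

    codon_position: int
    edited_strand: str
    before: str
    after: str

    def __post_init__(self) -> None:
        if self.codon_position not in (1, 2, 3):
            raise ValueError("codon_position must be 1, 2 or 3")
        if self.edited_strand not in (CODING, NONCODING):
            raise ValueError(f"bad strand {self.edited_strand!r}")
        i = self.codon_position - 1
        want = ("C", "T") if self.edited_strand == CODING else ("G", "A")
        if (self.before[i], self.after[i]) != want:
            raise ValueError(f"inconsistent edit {self}")


def _single_edits(codon: str, strands: Iterable[str]):
    """All single C->T (coding) / G->A (noncoding C->T) edits of a codon."""
    for pos in range(3):
        base = codon[pos]
        if CODING in strands and base == "C":
            after = codon[:pos] + "T" + codon[pos + 1 :]
            yield SingleEdit(pos + 1, CODING, codon, after)
        if NONCODING in strands and base == "G":
            after = codon[:pos] + "A" + codon[pos + 1 :]
            yield SingleEdit(pos + 1, NONCODING, codon, after)


def stop_introducible_codons(
    table: CodonTable,
    strands: Iterable[str] = (CODING, NONCODING),
    multi_edit: bool = False,
) -> set[str]:
    """Codons convertible into a STOP codon by CBE editing.

    With single edits on both strands and the standard code this is the
    classic four-codon set {CAA, CAG, CGA, TGG}. ``multi_edit=True`` also
    allows several window edits applied jointly (useful for bystander
    analysis, e.g. TGG->TAA via two noncoding-strand edits) — which does not
    enlarge the set under the standard code, since reachability is already
    saturated by single edits.
    """
    strands = tuple(strands)
    if not strands or not set(strands) <= {CODING, NONCODING}:
        raise ValueError("strands must be a non-empty subset of coding/noncoding")
    out = set()
    for codon in ALL_CODONS:
        if codon in table.stop_set:
            continue
        if multi_edit:
            for mask in range(1, 8):
                cur = list(codon)
                ok = True
                for pos in range(3):
                    if not mask & (1 << pos):
                        continue
                    if CODING in strands and cur[pos] == "C":
                        cur[pos] = "T"
                    elif NONCODING in strands and cur[pos] == "G":
                        cur[pos] = "A"
                    else:
                        ok = False
                        break
                if ok and "".join(cur) in table.stop_set:
                    out.add(codon)
                    break
        else:
            if any(e.after in table.stop_set for e in _single_edits(codon, strands)):
                out.add(codon)
    return out


def start_elimination_edits(start_codon: str, table: CodonTable) -> list[SingleEdit]:
    """Single noncoding-strand edits that destroy a START codon.

    Every G of the start codon is a C on the noncoding strand and hence
    editable; an edit whose product is itself still in ``start_set`` (e.g.
    GTG -> ATG via the position-1 G) is excluded because translation would
    still initiate.
    """
    start_codon = start_codon.upper()
    if start_codon not in table.start_set:
        raise ValueError(
            f"{start_codon} is not in the start-codon set {sorted(table.start_set)}"
        )
    return [
        e
        for e in _single_edits(start_codon, (NONCODING,))
        if e.after not in table.start_set
    ]


# Consequence classes for a codon substitution.
SILENT = "silent"
MISSENSE = "missense"
NONSENSE = "nonsense"
START_LOSS = "start_loss"
STOP_LOSS = "stop_loss"


def classify_codon_change(
    before: str, after: str, table: CodonTable, is_first_codon: bool = False
) -> str:
    """Classify a codon substitution.

    ``start_loss`` applies only when the codon is a gene's first codon and
    the product leaves the start set — it takes precedence over silent and
    missense because the lesion acts on initiation, not protein identity.
    """
    before, after = before.upper(), after.upper()
    if before == after:
        raise ValueError("before and after codons are identical")
    if is_first_codon and table.is_start(before) and not table.is_start(after):
        return START_LOSS
    if table.is_stop(after) and not table.is_stop(before):
        return NONSENSE
    if table.is_stop(before) and not table.is_stop(after):
        return STOP_LOSS
    if table.amino_acid(before) == table.amino_acid(after):
        return SILENT
    return MISSENSE
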