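# Methods

## Design model

The package models a cytosine base editor (CBE) as a deterministic editor of
cytosines on the protospacer strand within a positional window of the
spacer. Positions are numbered −1 (PAM-adjacent) to −L (PAM-distal,
L = 20 by default). The hot-spot window defaults to {−16 … −20} with −19 the
preferred placement: −16…−19 is the classical deaminase hot spot, and −20 is
included because placements there retain near-maximal activity in practice.
Both the window and the preference are configuration fields, not constants.

**START exclusion (XSTART).** A gene's START codon (default legal set
{ATG, GTG}) is destroyed by a single C→T on the noncoding strand — the C
pairing with a codon G. `start_elimination_edits` enumerates those single
edits and discards any whose product is still a legal start (GTG's
position-1 edit yields ATG and is excluded). `enumerate_xstart_guides`
places each valid edit's C at each window position on the gene's noncoding
strand, drops placements that run off the contig or contain N, and — because
the deaminase edits *all* window Cs with some probability — validates each
placement on the joint outcome of every in-window start-codon G applied
together, not on the intended edit alone. For a GTG start this means the
position-1 G may be co-edited as a designed bystander (GTG→ATA) when both
Gs fall in the window; a placement whose joint outcome is still a start is
never emitted.

**Premature STOP (iSTOP).** The CDS is scanned for codons reachable into
{TAA, TAG, TGA} by one edit — {CAA, CAG, CGA} via a coding-strand C→T, TGG
via the noncoding strand. The set is computed by enumeration against the
genetic code (NCBI table id, default 11), not hard-coded. With the
first-half rule (default on) only codons with index ≤ ⌊n/2⌋ are used, to
avoid near-terminal truncations that can leave a functional product.

**PAM handling.** Two modes. `SpRY_free`: no filter; PAMs are classed NRN
(middle purine) or NYN and the class is a ranking tie-break only — NYN sites
are designable and are emitted. `dCas9_NGG`: a hard filter on N-G-G. PAMs
containing N are always disallowed. Guide ranking is a total order:
|position − preferred| ascending, then NRN/NGG before NYN, then the 5′-most
genomic coordinate; re-ranking a permuted list reproduces the same order.

**Bystanders and reinitiation.** Every window C other than the intended one
is reported with its genomic coordinate and consequence (via the affected
codon when inside a CDS, else "noncoding", context 5′-UTR/intergenic).
Downstream in-frame start-like codons within a horizon (default: the first
half of the CDS) are flagged as reinitiation traps; `design_multiplex`
emits one tandem set with the top guide per start-like codon, or no set
(with a warning) when any member codon has no valid placement.

## Off-target scan

Off-target attribution uses contiguous exact identity only: the scanner
indexes the spacer's (L−k+1) k-mers, slides across both strands of every
contig, extends each k-mer hit to its maximal contiguous match, and reports
each maximal match once with its length — `identical` when it spans the
whole spacer, `seed` otherwise. Default k = 11, the shortest contiguous
match observed to drive unintended editing. Mismatch-tolerant (Hamming)
search is deliberately out of scope: the model attributes off-target
binding to exact contiguous identity. Masks (e.g. the on-target
protospacer) suppress overlapping hits. Correctness is property-tested
against a quadratic brute-force oracle and for monotonicity in k and strand
symmetry.

## Variant audit

SNVs (PASS/unfiltered records only; indels skipped with a warning) are
checked base-by-base against the reference FASTA — a REF mismatch is fatal,
since it indicates coordinate drift. Each variant gets a transition class
(C→T, G→A, or other — the CBE signature is the first two), a consequence
recomputed from the affected codon on the coding strand (start_loss takes
precedence on first codons), and an attribution: `intended` inside the
design mask, `guide_dependent` within a proximity window (default 50 bp —
no principled value exists, so it is configuration-exposed) of a
spacer-similarity hit, else `deamination`. Summaries exclude intended edits
from the off-target total but report both totals. A ±3 bp reference context
string is carried per variant for descriptive use only; no deamination
motif model is fitted.

Screen statistics: efficiency = 100·edited/screened to two decimals;
replicate mean with sample (n−1) SD (a single replicate reports SD 0 with a
warning); an unpaired two-tailed t test, Welch by default (the safer choice
when only "unpaired, two-tailed" is specified; `equal_var=True` restores
the pooled Student form). Zero-variance groups with equal means return
p = 1.

## Synthetic fixtures

`fixtures.make_genome` emulates a small bacterial genome: ~0.8 kb by
default, three single-segment CDS (30/28/32 codons) on both strands with
ATG/ATG/GTG starts, random intergenic sequence, and intergenic decoy sites
planted from the first gene's top spacer (a full 20-mer and an interior
11-mer by default). Truth tables are exact by construction, not
probabilistic: gene interiors avoid in-frame start/stop codons (so
reinitiation scans are empty and guide counts are determined by geometry),
interior codons CTG/GCT/CAG are planted so silent/missense/nonsense audit
variants are always realizable, decoy flanks are forced to mismatch the
adjacent spacer base so a planted d-mer cannot extend, and the whole genome
is rebuilt from a fresh seed-derived stream until no accidental spacer
match ≥ k survives outside the planted loci (a ~2% event per spacer per
attempt; the loop is deterministic given the seed). `make_audit_vcf` plants
a consequence-class composition (default 3 silent + 2 missense + 1 nonsense
+ 4 noncoding) at sites chosen from enumerated candidates, keeping
intergenic variants ≥ 60 bp from genes and decoys so their attribution is
unambiguously `deamination`; optional A→G records exercise the non-CBE
transition flag.

What the fixtures do **not** emulate: realistic GC content or codon usage,
operon structure, repeated sequence families, sequencing noise, or the
biological off-target loads of real edited strains. Passing tests therefore
demonstrate geometric and combinatorial correctness of design, scanning and
classification — not wet-lab editing efficiency, which is an experimental
quantity.

## Numerical and design choices

- Internal coordinates are 0-based half-open; GFF3 and VCF I/O convert at
  the boundary. All spacer-position ↔ genomic-coordinate arithmetic lives
  in two inverse functions (`place_protospacer`, `spacer_position_of`),
  property-tested as a round trip.
- Genomes may contain N, but any candidate protospacer or PAM containing N
  is discarded (deamination on N is undefined), and N never matches in the
  off-target scan.
- The start-codon set is configurable; TTG and other rare bacterial starts
  are excluded by default because initiation-competence of edited
  near-cognate starts is uncertain — any member of the configured set is
  conservatively treated as "still a start".
- Only single-segment CDS are accepted (bacterial scope); a CDS whose first
  codon is outside the start set is excluded with a warning rather than an
  error, so one unusual annotation does not abort a genome-wide run.
- CLI precedence: built-in defaults, then the config file, then explicit
  command-line flags. Exit codes: 0 success (including empty result sets),
  1 usage error, 2 data inconsistency.
- In dCas9 mode an informational note for NGG motifs shifted ≤ 2 nt from a
  candidate PAM (observed to rescue editing at near-NGG sites) is exposed
  as a no-op hook; it never alters filtering. Secondary-structure and
  self-complementarity checks are likewise out of scope.

## Problem sizes

Test and acceptance runs use the default fixture (~0.8 kb genome, 3 genes,
10-variant audit sets) across 10–20 seeds, and property tests on random
genomes up to a few hundred bp against the quadratic oracle — sizes at
which the brute-force oracles are exact and instantaneous while exercising
every code path; the scanner itself is linear-time in genome length and
runs comfortably on full bacterial genomes.

## Known limitations

No on-target activity model (beyond the positional preference), no
expression/induction modelling, no Hamming-distance off-target search, no
read alignment or variant calling (the audit consumes VCF), and no
reproduction of strain-specific off-target counts, which depend on wet-lab
biology.
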