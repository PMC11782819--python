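# xstart

Guide design for PAM-independent cytosine base editing in bacteria:
inactivate any gene by **excluding its START codon** instead of hunting for a
premature-STOP site.

## The problem

A cytosine base editor (CBE) — a dead Cas protein fused to a cytidine
deaminase — converts C→T inside a narrow editing window without a
double-strand break. Used with wild-type SpCas9 it is doubly constrained:
the target must sit next to an NGG PAM, *and* a premature STOP codon can
only be created from four codons (CAA, CAG, CGA via a coding-strand C→T;
TGG via a C→T on the noncoding strand, read as G→A), which must also fall in
the editing window, preferably in the first half of the CDS. Many genes
simply have no usable site.

With a PAM-relaxed effector (dSpRY, which binds NRN ≳ NYN with no hard PAM
requirement), the constraint disappears: every START codon (ATG, GTG)
carries a G, whose partner C on the noncoding strand reads CAT/CAC. One
C→T edit there (ATG→ATA, GTG→GTA on the coding strand) abolishes
translation initiation — a one-for-all knockout design. `xstart` implements
this design method, plus the conventional premature-STOP mode, off-target
scanning by contiguous spacer identity, and a whole-genome variant audit
for edited strains.

Spacer positions are numbered from the PAM: the protospacer base adjacent
to the PAM is −1, the distal end of a 20-nt spacer is −20. The deaminase
hot spot spans −16…−19, −19 being the most efficient placement; −20
retains high activity and is in the default window.

## Worked example

```python
from xstart import (standard_table, stop_introducible_codons,
                    start_elimination_edits, screen_efficiency,
                    enumerate_xstart_guides)
from xstart.fixtures import FixtureSpec, make_genome

table = standard_table()
print(sorted(stop_introducible_codons(table)))
# ['CAA', 'CAG', 'CGA', 'TGG']        <- the only 4 premature-STOP sources
print(start_elimination_edits("ATG", table))
# [SingleEdit(codon_position=3, edited_strand='noncoding',
#             before='ATG', after='ATA')]

bundle = make_genome(FixtureSpec(seed=1))   # ~0.8 kb toy genome, 3 CDS
gene = bundle.genes[0]
guides = enumerate_xstart_guides(bundle.genome, gene)
print(len(guides), guides[0].critical_position, guides[0].pam, guides[0].pam_class)
# 5 -19 TAA NRN
print(screen_efficiency(10, 11), screen_efficiency(5, 11))
# 90.91 45.45
```

Five guides per ATG gene: one per window position, ranked by distance from
the preferred −19 placement, NRN PAMs before NYN (a soft preference — in
SpRY mode nothing is filtered). The efficiencies are the screen statistic
(100 × edited colonies / screened colonies) for 10/11 and 5/11 colonies.

The same workflow from a shell:

```
xstart fixture --seed 1 -o demo/
xstart design demo/genome.fasta demo/genes.gff3 -g gene00 -o demo/ --bed --fasta
xstart offtarget demo/genome.fasta demo/spacers.fasta --mask demo/guides.bed -o demo/hits.tsv
xstart audit demo/variants.vcf demo/genome.fasta demo/genes.gff3 \
       --guides demo/guides.tsv -O demo/
```

`design` writes `guides.tsv` (one row per guide with spacer, protospacer
span, PAM and class, critical position, intended edit and bystander
summary); `offtarget` reports every locus sharing a contiguous ≥ k-mer
(default k = 11) with a spacer; `audit` classifies VCF SNVs by transition
class, consequence (silent / missense / nonsense / noncoding / start_loss)
and attribution (intended / guide_dependent / deamination).

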