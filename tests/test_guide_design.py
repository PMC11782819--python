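"""Guide enumeration: geometry, ranking, PAM handling, bystanders."""

import random
from dataclasses import replace

import pytest

from xstart.genome_io import GeneModel, Genome, reverse_complement
from xstart.guide_design import (
    DesignConfig,
    DesignError,
    design_multiplex,
    enumerate_stop_guides,
    enumerate_xstart_guides,
    genomic_coord_at,
    pam_class,
    place_protospacer,
    predict_bystanders,
    scan_reinitiation,
    spacer_position_of,
    _rank_and_sort,
)

from conftest import make_minus_gene, make_plus_gene, random_codons

STOP_REACHABLE = ("CAA", "CAG", "CGA", "TGG")


def apply_intended_edit(genome: Genome, guide) -> Genome:
    e = guide.intended_edit
    seq = genome.contigs[guide.protospacer.contig]
    assert seq[e.genomic_pos] == e.ref_plus
    seq = seq[: e.genomic_pos] + e.alt_plus + seq[e.genomic_pos + 1 :]
    return Genome({guide.protospacer.contig: seq})


def first_codon_after_edit(genome, gene, guide) -> str:
    edited = apply_intended_edit(genome, guide)
    return edited.fetch(gene.codon_interval(1))


class TestPamClass:
    @pytest.mark.parametrize(
        "pam,mode,cls,allowed",
        [
            ("ATT", "SpRY_free", "NYN", True),
            ("AGG", "dCas9_NGG", "NGG", True),
            ("CCT", "dCas9_NGG", "NYN", False),
            ("CTC", "SpRY_free", "NYN", True),
            ("TCA", "SpRY_free", "NYN", True),
            ("AAT", "SpRY_free", "NRN", True),
            ("ANG", "SpRY_free", "NYN", False),
        ],
    )
    def test_examples(self, pam, mode, cls, allowed):
        assert pam_class(pam, mode) == (cls, allowed)

    def test_bad_length_rejected(self):
        with pytest.raises(DesignError):
            pam_class("AG", "SpRY_free")


class TestGeometry:
    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("p", [-1, -15, -19, -20])
    def test_spacer_position_round_trip(self, strand, p):
        proto, pam = place_protospacer(500, p, strand, "c")
        assert len(proto) == 20 and len(pam) == 3
        assert spacer_position_of(proto, 500) == p
        assert genomic_coord_at(proto, p) == 500

    def test_pam_abuts_protospacer_three_prime_end(self):
        proto, pam = place_protospacer(500, -19, "+", "c")
        assert pam.begin == proto.end
        proto, pam = place_protospacer(500, -19, "-", "c")
        assert pam.end == proto.begin


def atg_gene(n_interior=8, seed=7, **kw):
    rng = random.Random(seed)
    codons = ["ATG"] + random_codons(rng, n_interior, STOP_REACHABLE) + ["TAA"]
    return make_plus_gene(codons, **kw)


class TestXstartEnumeration:
    def test_atg_plus_gene_five_guides_top_at_minus_19(self):
        genome, gene = atg_gene()
        guides = enumerate_xstart_guides(genome, gene)
        assert len(guides) == 5
        assert guides[0].critical_position == -19
        assert [g.rank for g in guides] == [1, 2, 3, 4, 5]
        assert {g.critical_position for g in guides} == {-16, -17, -18, -19, -20}

    def test_protospacer_is_on_the_noncoding_strand(self):
        genome, gene = atg_gene()
        for g in enumerate_xstart_guides(genome, gene):
            assert g.protospacer.strand == "-"
        rng = random.Random(3)
        codons = ["ATG"] + random_codons(rng, 8, STOP_REACHABLE) + ["TAA"]
        genome_m, gene_m = make_minus_gene(codons)
        for g in enumerate_xstart_guides(genome_m, gene_m):
            assert g.protospacer.strand == "+"

    @pytest.mark.parametrize("builder", [make_plus_gene, make_minus_gene])
    def test_geometry_round_trip_and_start_loss(self, builder):
        rng = random.Random(11)
        codons = ["ATG"] + random_codons(rng, 8, STOP_REACHABLE) + ["TAA"]
        genome, gene = builder(codons)
        guides = enumerate_xstart_guides(genome, gene)
        assert len(guides) == 5
        for g in guides:
            # re-extracting the protospacer reproduces the spacer exactly
            assert genome.fetch(g.protospacer) == g.spacer
            assert g.spacer[g.critical_position + 20] == "C"
            # applying the intended edit removes the START codon
            after = first_codon_after_edit(genome, gene, g)
            assert after == "ATA"
            assert after not in DesignConfig().start_set

    def test_gtg_gene_never_emits_a_position_one_only_design(self):
        rng = random.Random(5)
        codons = ["GTG"] + random_codons(rng, 8, STOP_REACHABLE) + ["TAA"]
        genome, gene = make_plus_gene(codons)
        guides = enumerate_xstart_guides(genome, gene)
        assert guides, "GTG gene must still be designable via the position-3 G"
        table = DesignConfig().table()
        for g in guides:
            # the intended edit is always the position-3 G (GTG -> GTA);
            # jointly with any in-window position-1 edit the result is ATA
            assert g.intended_edit.edit.codon_position == 3
            after = first_codon_after_edit(genome, gene, g)
            assert after not in table.start_set

    def test_ngg_mode_filters_to_a_subset_of_spry(self):
        genome, gene = atg_gene()
        spry = enumerate_xstart_guides(genome, gene, DesignConfig(pam_mode="SpRY_free"))
        ngg = enumerate_xstart_guides(genome, gene, DesignConfig(pam_mode="dCas9_NGG"))
        key = lambda g: (g.protospacer.begin, g.protospacer.strand, g.critical_position)
        assert {key(g) for g in ngg} <= {key(g) for g in spry}
        assert all(g.pam_class == "NGG" for g in ngg)

    def test_ngg_mode_with_no_ngg_gives_empty_list(self):
        # upstream of all Cs/Gs on the plus strand -> no GG on the minus strand
        genome, gene = atg_gene(upstream="TATATTATATTATATTATATTATAT",
                                downstream="TTATTATTATTATTATTATTATTAT")
        # ensure the PAM region (3' of a minus-strand protospacer) has no NGG
        guides = enumerate_xstart_guides(
            genome, gene, DesignConfig(pam_mode="dCas9_NGG")
        )
        for g in guides:
            assert g.pam[1:] == "GG"

    def test_contig_edge_placements_dropped(self):
        # no upstream margin: a minus-strand protospacer + PAM cannot fit
        genome, gene = atg_gene(upstream="")
        assert enumerate_xstart_guides(genome, gene) == []

    def test_wrong_start_codon_rejected(self):
        genome, gene = atg_gene()
        bad = GeneModel(gene.gene_id, gene.contig, gene.start, gene.end, "+", "TTG")
        with pytest.raises(DesignError):
            enumerate_xstart_guides(genome, bad)

    def test_ranking_is_invariant_to_enumeration_order(self):
        genome, gene = atg_gene()
        guides = enumerate_xstart_guides(genome, gene)
        shuffled = list(guides)
        random.Random(0).shuffle(shuffled)
        rer = _rank_and_sort([replace(g, rank=0) for g in shuffled], DesignConfig())
        assert [g.protospacer for g in rer] == [g.protospacer for g in guides]


class TestStopEnumeration:
    def _gene_with(self, codon, at, n, seed=13):
        rng = random.Random(seed)
        interior = random_codons(rng, n - 2, STOP_REACHABLE)
        interior[at - 2] = codon  # 1-based codon index `at`
        return make_plus_gene(["ATG"] + interior + ["TAA"],
                              upstream="T" * 30, downstream="A" * 40)

    def test_first_half_rule(self):
        genome, gene = self._gene_with("CAG", at=5, n=30)
        assert enumerate_stop_guides(genome, gene)
        genome2, gene2 = self._gene_with("CAG", at=25, n=30)
        assert enumerate_stop_guides(genome2, gene2) == []
        # the same late codon is usable once the rule is lifted
        assert enumerate_stop_guides(
            genome2, gene2, DesignConfig(first_half_rule=False)
        )

    def test_tgg_designs_use_the_noncoding_strand(self):
        genome, gene = self._gene_with("TGG", at=5, n=30)
        guides = enumerate_stop_guides(genome, gene)
        assert guides
        for g in guides:
            assert g.intended_edit.edit.edited_strand == "noncoding"
            assert g.protospacer.strand == "-"
            assert g.intended_edit.edit.after in ("TGA", "TAG")

    def test_cag_designs_use_the_coding_strand(self):
        genome, gene = self._gene_with("CAG", at=5, n=30)
        guides = enumerate_stop_guides(genome, gene)
        assert all(g.protospacer.strand == "+" for g in guides)
        assert all(g.intended_edit.edit.after == "TAG" for g in guides)

    def test_no_reachable_codon_gives_empty_list(self):
        rng = random.Random(17)
        codons = ["ATG"] + random_codons(rng, 10, STOP_REACHABLE) + ["TAA"]
        genome, gene = make_plus_gene(codons)
        assert enumerate_stop_guides(genome, gene) == []

    def test_intended_edit_introduces_a_stop(self):
        genome, gene = self._gene_with("CAA", at=4, n=20)
        table = DesignConfig().table()
        for g in enumerate_stop_guides(genome, gene):
            edited = apply_intended_edit(genome, g)
            cds = edited.fetch(gene.interval)
            codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
            assert any(c in table.stop_set for c in codons[:-1])


class TestBystanders:
    def test_upstream_g_becomes_a_noncoding_bystander(self):
        # plus-strand G two bases 5' of the CDS = a C at spacer position -15
        # of the top (-19) guide's minus-strand protospacer
        up = "TATTCAATCTATTCAATCTAT" + "GA"  # position -2 relative to the START
        genome, gene = atg_gene(upstream=up)
        top = enumerate_xstart_guides(genome, gene)[0]
        bys = predict_bystanders(top, genome, [gene],
                                 DesignConfig(window=frozenset(range(-20, -14))))
        hit = [b for b in bys if b.spacer_position == -15]
        assert len(hit) == 1
        assert hit[0].context == "five_prime_UTR/intergenic"
        assert hit[0].consequence == "noncoding"
        assert hit[0].genomic_pos == gene.start - 1 - 2

    def test_window_with_only_the_intended_c_gives_no_bystanders(self):
        # the default upstream is G-free; codon 2 starts without G, so the
        # plus strand holds no window G other than the target
        codons = ["ATG", "ATT", "CTT", "AAT", "TAA"]
        genome, gene = make_plus_gene(codons)
        top = enumerate_xstart_guides(genome, gene)[0]
        assert predict_bystanders(top, genome, [gene]) == []

    def test_cds_bystander_is_classified_missense(self):
        # codon 2 = GCT; its G (plus strand) is a window C on the minus
        # strand; G->A gives ACT (Ala -> Thr)
        codons = ["ATG", "GCT", "CTT", "AAT", "TAA"]
        genome, gene = make_plus_gene(codons)
        top = enumerate_xstart_guides(genome, gene)[0]
        bys = predict_bystanders(top, genome, [gene])
        assert len(bys) == 1
        assert bys[0].context == "CDS"
        assert bys[0].consequence == "missense"
        assert bys[0].spacer_position == -20
        assert bys[0].gene_id == gene.gene_id


class TestReinitiation:
    def test_downstream_in_frame_atg_found(self):
        codons = ["ATG", "AAA", "ATG"] + ["AAT"] * 6 + ["TAA"]
        genome, gene = make_plus_gene(codons)
        hits = scan_reinitiation(genome, gene)
        assert [(h.codon_index, h.codon) for h in hits] == [(3, "ATG")]
        assert hits[0].in_frame

    def test_out_of_frame_atg_ignored(self):
        # AAT GAA: ATG straddles codons 2/3 but no in-frame start
        codons = ["ATG", "AAT", "GAA", "AAT", "CTT", "AAT", "CTT", "AAT", "CTT", "TAA"]
        genome, gene = make_plus_gene(codons)
        assert scan_reinitiation(genome, gene) == []

    def test_gtg_counts_as_start_like(self):
        codons = ["ATG", "AAA", "AAT", "GTG"] + ["AAT"] * 5 + ["TAA"]
        genome, gene = make_plus_gene(codons)
        hits = scan_reinitiation(genome, gene)
        assert [(h.codon_index, h.codon) for h in hits] == [(4, "GTG")]

    def test_horizon_defaults_to_first_half(self):
        codons = ["ATG"] + ["AAT"] * 6 + ["ATG"] + ["CTT"] * 3 + ["TAA"]
        genome, gene = make_plus_gene(codons)  # 12 codons, horizon 6
        assert scan_reinitiation(genome, gene) == []
        assert scan_reinitiation(genome, gene, horizon=12)[0].codon_index == 8


class TestMultiplex:
    def test_two_start_like_codons_give_one_set_of_two_guides(self):
        codons = ["ATG", "AAA", "ATG"] + ["AAT"] * 6 + ["TAA"]
        genome, gene = make_plus_gene(codons)
        sets = design_multiplex(genome, gene)
        assert len(sets) == 1
        (pair,) = sets
        assert len(pair) == 2
        # one guide per start-like codon, each destroying its own ATG
        positions = sorted(g.intended_edit.genomic_pos for g in pair)
        assert positions == sorted(
            [gene.codon_base_coord(1, 3), gene.codon_base_coord(3, 3)]
        )

    def test_no_downstream_hit_degenerates_to_the_standard_design(self):
        genome, gene = atg_gene()
        sets = design_multiplex(genome, gene)
        assert len(sets) == 1 and len(sets[0]) == 1
        top = enumerate_xstart_guides(genome, gene)[0]
        assert sets[0][0].protospacer == top.protospacer

    def test_unplaceable_member_emits_no_set_with_warning(self):
        # Ns around the downstream ATG invalidate every placement for it
        codons = ["ATG", "AAA", "ATG"] + ["AAT"] * 6 + ["TAA"]
        genome, gene = make_plus_gene(codons)
        seq = genome.contigs[gene.contig]
        ncoord = gene.codon_base_coord(3, 3) - 5
        seq = seq[:ncoord] + "N" + seq[ncoord + 1 :]
        broken = Genome({gene.contig: seq})
        with pytest.warns(UserWarning, match="multiplex"):
            assert design_multiplex(broken, gene) == []


class TestShiftedNggNote:
    def test_detects_ngg_just_beyond_the_pam(self):
        from xstart.guide_design import shifted_ngg_note

        # TGG one base 3' of the designed PAM on a minus-strand protospacer:
        # genome plus-strand CCA immediately 5' of the PAM interval
        genome, gene = atg_gene()
        top = enumerate_xstart_guides(genome, gene)[0]
        seq = list(genome.contigs["toy"])
        # candidate PAM shifted 1 nt further 3' on '-' spans plus-strand
        # [begin-4, begin-1); CC at its first two plus bases reads ...GG
        b = top.protospacer.begin
        seq[b - 4], seq[b - 3] = "C", "C"
        assert shifted_ngg_note(Genome({"toy": "".join(seq)}), top) is True
        seq[b - 4] = seq[b - 3] = seq[b - 5] = "T"
        assert shifted_ngg_note(Genome({"toy": "".join(seq)}), top) is False


class TestConfigValidation:
    def test_preferred_position_must_be_in_window(self):
        with pytest.raises(DesignError):
            DesignConfig(window=frozenset({-16, -17}), preferred_position=-19)

    def test_window_must_fit_the_spacer(self):
        with pytest.raises(DesignError):
            DesignConfig(window=frozenset({-25}), preferred_position=-25)

    def test_unknown_pam_mode_rejected(self):
        with pytest.raises(DesignError):
            DesignConfig(pam_mode="NG")
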