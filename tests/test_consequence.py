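"""Annotator: coordinate mapping, codon arithmetic, strand handling, HGVS."""

import pytest
from Bio.Data import CodonTable

from minkseg import (Category, TranscriptModel, UnsupportedVariantError,
                     ValidationError, VariantSite, annotate_best, annotate_snv,
                     load_transcripts)
from minkseg.consequence import revcomp, write_gff3
from minkseg.synthetic_data import (ToyTranscriptSpec, generate_transcript,
                                    genomic_of_cdna, snv_for_cdna_change)

STANDARD_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]


def translate_oracle(codon):
    """Independent codon lookup from the standard-table data (not Seq.translate)."""
    return "*" if codon in STANDARD_TABLE.stop_codons else STANDARD_TABLE.forward_table[codon]


class TestWorkedExamples:
    def test_minus_strand_g_to_a_gives_c478_arg160cys(self, copa_model):
        """Genomic G>A pairing with cDNA 478 of the minus-strand model is a
        C>T in cDNA space: codon 160 CGC->TGC, Arg->Cys missense."""
        v = snv_for_cdna_change(copa_model, 478, "T")
        assert (v.ref, v.alt) == ("G", "A")  # genomic alleles
        c = annotate_snv(v, copa_model)
        assert c.hgvs_c == "c.478C>T"
        assert c.hgvs_p == "p.Arg160Cys"
        assert c.category is Category.MISSENSE
        assert (c.codon_index, c.ref_codon, c.alt_codon) == (160, "CGC", "TGC")

    def test_donor_plus_one_after_cdna33_is_splice_donor(self, mitf_model):
        v = snv_for_cdna_change(mitf_model, 33, "A", offset=1)
        assert (v.ref, v.alt) == ("G", "A")  # canonical GT donor starts with G
        c = annotate_snv(v, mitf_model)
        assert c.hgvs_c == "c.33+1G>A"
        assert c.category is Category.SPLICE_DONOR
        assert (c.cdna.pos, c.cdna.offset) == (33, 1)


def _plus_toy(constraints, cds_length=30):
    spec = ToyTranscriptSpec(gene="TOY", strand="+", n_exons=1,
                             cds_length=cds_length,
                             required_codon_constraints=constraints)
    model, _ = generate_transcript(spec, seed=5)
    return model


def test_third_position_leucine_change_is_synonymous():
    model = _plus_toy(((3, "CTG"),))
    v = snv_for_cdna_change(model, 9, "A")  # CTG -> CTA
    c = annotate_snv(v, model)
    assert c.category is Category.SYNONYMOUS
    assert (c.ref_aa, c.alt_aa) == ("L", "L")


def test_cga_to_tga_is_stop_gained():
    model = _plus_toy(((4, "CGA"),))
    v = snv_for_cdna_change(model, 10, "T")  # CGA -> TGA
    c = annotate_snv(v, model)
    assert c.category is Category.STOP_GAINED
    assert c.hgvs_p == "p.Arg4Ter"


class TestCodonArithmetic:
    @pytest.mark.parametrize("cdna,expected", [
        (478, (160, 0)), (1, (1, 0)), (3, (1, 2)), (4, (2, 0)), (480, (160, 2)),
    ])
    def test_codon_of(self, copa_model, cdna, expected):
        assert copa_model.codon_of(cdna) == expected

    def test_out_of_range_rejected(self, copa_model):
        for bad in (0, copa_model.cds_len + 1):
            with pytest.raises(ValidationError):
                copa_model.codon_of(bad)


@pytest.mark.parametrize("model_fixture", ["copa_model", "mitf_model"])
def test_cdna_mapping_is_a_bijection_on_coding_positions(model_fixture, request):
    """Every coding cDNA position maps to a unique genomic base and back."""
    model = request.getfixturevalue(model_fixture)
    seen = set()
    for c in range(1, model.cds_len + 1):
        g = genomic_of_cdna(model, c)
        assert g not in seen
        seen.add(g)
        coord = model.cdna_position(g)
        assert (coord.kind, coord.pos, coord.offset) == ("coding", c, 0)


def test_intronic_offsets_donor_and_acceptor():
    spec = ToyTranscriptSpec(gene="X", strand="+", n_exons=2, cds_length=60,
                             exon_coding_lengths=(33, 27), intron_length=50)
    model, _ = generate_transcript(spec, seed=1)
    donor1 = model.cdna_position(genomic_of_cdna(model, 33) + 1)
    assert (donor1.kind, donor1.pos, donor1.offset) == ("intronic", 33, 1)
    acceptor1 = model.cdna_position(genomic_of_cdna(model, 34) - 1)
    assert (acceptor1.kind, acceptor1.pos, acceptor1.offset) == ("intronic", 34, -1)
    mid = model.cdna_position(genomic_of_cdna(model, 33) + 25)
    assert mid.kind == "intronic" and abs(mid.offset) > 2


def test_utr_and_intergenic_classification(mitf_model):
    utr_pos = mitf_model.exons[0][0]  # first exonic base is 5'UTR (12 bp UTR)
    assert mitf_model.cdna_position(utr_pos).kind == "utr"
    assert mitf_model.cdna_position(1).kind == "intergenic"  # in the flank
    v = VariantSite(mitf_model.contig, utr_pos, mitf_model.base_at(utr_pos),
                    "A" if mitf_model.base_at(utr_pos) != "A" else "C")
    assert annotate_snv(v, mitf_model).category is Category.UTR


def test_strand_symmetry_of_annotation():
    """The same construct annotated on + and on - (mirrored embedding, same
    seed) yields identical cDNA-space consequences for every coding SNV."""
    base = dict(gene="SYM", n_exons=2, cds_length=36, exon_coding_lengths=(15, 21),
                required_codon_constraints=((5, "CGA"),))
    plus, _ = generate_transcript(ToyTranscriptSpec(strand="+", **base), seed=9)
    minus, _ = generate_transcript(ToyTranscriptSpec(strand="-", **base), seed=9)
    assert plus.cds_sequence() == minus.cds_sequence()
    for c in range(1, plus.cds_len + 1):
        ref_cdna = plus.cds_sequence()[c - 1]
        for alt in "ACGT":
            if alt == ref_cdna:
                continue
            cons_p = annotate_snv(snv_for_cdna_change(plus, c, alt), plus)
            cons_m = annotate_snv(snv_for_cdna_change(minus, c, alt), minus)
            assert cons_p.category is cons_m.category
            assert cons_p.hgvs_c == cons_m.hgvs_c
            assert cons_p.hgvs_p == cons_m.hgvs_p


def test_reference_amino_acids_match_codon_table_oracle(copa_model):
    """Annotator ref_aa at every codon equals the standard-table lookup."""
    cds = copa_model.cds_sequence()
    for c in range(1, copa_model.cds_len - 3, 7):  # stride keeps it quick
        ref_cdna = cds[c - 1]
        alt = "A" if ref_cdna != "A" else "G"
        cons = annotate_snv(snv_for_cdna_change(copa_model, c, alt), copa_model)
        codon = cds[(cons.codon_index - 1) * 3:(cons.codon_index - 1) * 3 + 3]
        assert cons.ref_codon == codon
        assert cons.ref_aa == translate_oracle(codon)


def test_indel_and_off_contig_rejected(copa_model):
    with pytest.raises(UnsupportedVariantError):
        annotate_snv(VariantSite(copa_model.contig, 5, "AT", "A"), copa_model)
    with pytest.raises(ValidationError):
        annotate_snv(VariantSite("elsewhere", 5, "A", "G"), copa_model)


def test_ref_mismatch_detected(copa_model):
    g = genomic_of_cdna(copa_model, 10)
    wrong_ref = "A" if copa_model.base_at(g) != "A" else "C"
    alt = "G" if wrong_ref != "G" else "T"
    with pytest.raises(ValidationError, match="REF mismatch"):
        annotate_snv(VariantSite(copa_model.contig, g, wrong_ref, alt), copa_model)


def test_annotate_best_returns_intergenic_when_nothing_overlaps(copa_model):
    v = VariantSite("unrelated_contig", 50, "A", "G")
    assert annotate_best(v, [copa_model]).category is Category.INTERGENIC


def test_gff3_fasta_round_trip(tmp_path, copa_model, mitf_model):
    """write_gff3 + FASTA -> load_transcripts reproduces the models and
    their annotations."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    gff = tmp_path / "t.gff3"
    fa = tmp_path / "t.fa"
    write_gff3([copa_model, mitf_model], gff)
    SeqIO.write([SeqRecord(Seq(m.genomic_seq), id=m.contig, description="")
                 for m in (copa_model, mitf_model)], str(fa), "fasta")
    loaded = {m.gene: m for m in load_transcripts(gff, fa)}
    assert set(loaded) == {"COPA", "MITF"}
    for orig in (copa_model, mitf_model):
        got = loaded[orig.gene]
        assert got.exons == orig.exons
        assert (got.cds_start, got.cds_end, got.strand) == (
            orig.cds_start, orig.cds_end, orig.strand)
        assert got.cds_sequence() == orig.cds_sequence()
    v = snv_for_cdna_change(loaded["COPA"], 478, "T")
    assert annotate_snv(v, loaded["COPA"]).hgvs_p == "p.Arg160Cys"


def test_transcript_validation_rejects_malformed():
    with pytest.raises(ValidationError, match="strand"):
        TranscriptModel("g", "t", "c", "x", [(1, 10)], 1, 9, "A" * 10)
    with pytest.raises(ValidationError, match="exon"):
        TranscriptModel("g", "t", "c", "+", [(1, 10), (5, 20)], 1, 9, "A" * 20)
    m = TranscriptModel("g", "t", "c", "+", [(1, 12)], 1, 12, "ATGAAATTTTGA")
    m.validate()
    bad = TranscriptModel("g", "t", "c", "+", [(1, 12)], 1, 12, "TTGAAATTTTGA")
    with pytest.raises(ValidationError, match="ATG"):
        bad.validate()
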