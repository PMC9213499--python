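"""Generators: determinism, Hardy-Weinberg structure, constraint realisation."""

import json

import numpy as np
import pytest

from minkseg import (GT, CoatClass, FilterConfig, Role, TwoLocusGenotype,
                     ValidationError, annotate_snv, default_rules,
                     generate_cohort, generate_fixture_dir,
                     generate_genotyping_table, generate_transcript,
                     run_filter, write_vcf)
from minkseg.synthetic_data import (CausalSpec, CohortSpec, ToyTranscriptSpec,
                                    copa_like_spec, mitf_like_spec,
                                    snv_for_cdna_change)
from minkseg.consequence import write_gff3


class TestCohortGeneration:
    def test_same_seed_is_byte_identical(self, tmp_path):
        spec = CohortSpec(seed=5, n_background_variants=30)
        m1, _ = generate_cohort(spec)
        m2, _ = generate_cohort(CohortSpec(seed=5, n_background_variants=30))
        assert m1 == m2
        f1, f2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_vcf(m1, f1)
        write_vcf(m2, f2)
        assert f1.read_bytes() == f2.read_bytes()
        m3, _ = generate_cohort(CohortSpec(seed=6, n_background_variants=30))
        assert m1 != m3

    def test_causal_only_matrix_has_prescribed_genotypes(self):
        spec = CohortSpec(seed=1, n_cases=2, n_controls=3,
                          n_background_variants=0, missing_rate=0.5)
        m, samples = generate_cohort(spec)
        assert len(m.variants) == 1
        assert m.variants[0].pos == spec.causal.pos
        assert all(m.call(0, j).gt is GT.HOM_ALT for j in m.sample_indices(Role.CASE))
        # controls are hom-ref unless masked missing; never carriers
        for j in m.sample_indices(Role.CONTROL):
            assert m.call(0, j).gt in (GT.HOM_REF, GT.MISSING)

    def test_zero_alt_freq_background_is_all_hom_ref(self):
        spec = CohortSpec(seed=2, n_background_variants=50,
                          background_alt_freq=0.0, missing_rate=0.0)
        m, _ = generate_cohort(spec)
        bg = [i for i, v in enumerate(m.variants) if v.pos != spec.causal.pos]
        assert np.all(m.gts[bg][:, m.sample_indices(Role.CONTROL)] == GT.HOM_REF.value)
        assert np.all(m.gts[bg][:, m.sample_indices(Role.CASE)] == GT.HOM_REF.value)

    def test_background_genotypes_follow_hardy_weinberg_at_half(self):
        """Pooled background genotype frequencies at q=0.5 approach
        (1/4, 1/2, 1/4) within 4 sigma over 2000 draws."""
        spec = CohortSpec(seed=3, n_cases=1, n_controls=1,
                          n_background_variants=1000, background_alt_freq=0.5,
                          missing_rate=0.0)
        m, _ = generate_cohort(spec)
        bg = [i for i, v in enumerate(m.variants) if v.pos != spec.causal.pos]
        draws = m.gts[bg].ravel()
        n = draws.size
        assert n == 2000
        for state, p in ((GT.HOM_REF, 0.25), (GT.HET, 0.5), (GT.HOM_ALT, 0.25)):
            count = int(np.sum(draws == state.value))
            assert abs(count - n * p) < 4 * np.sqrt(n * p * (1 - p))

    def test_case_depth_floor_at_causal_site(self):
        spec = CohortSpec(seed=4, mean_depth=3.0, n_background_variants=0)
        for s in range(20):
            spec.seed = s
            m, _ = generate_cohort(spec)
            case = m.sample_indices(Role.CASE)
            assert all(m.call(0, j).depth >= spec.min_causal_case_depth for j in case)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValidationError):
            CohortSpec(n_cases=0)
        with pytest.raises(ValidationError):
            CohortSpec(background_alt_freq=1.5)
        with pytest.raises(ValidationError):
            CohortSpec(n_background_variants=100, region_length=50)


class TestTranscriptGeneration:
    def test_generated_models_pass_validation(self):
        for spec in (copa_like_spec(), mitf_like_spec()):
            model, record = generate_transcript(spec, seed=11)
            model.validate()  # ATG start, terminal stop, no internal stop
            assert str(record.seq) == model.genomic_seq

    def test_codon_constraint_realises_the_missense_example(self):
        model, _ = generate_transcript(copa_like_spec(), seed=21)
        cons = annotate_snv(snv_for_cdna_change(model, 478, "T"), model)
        assert (cons.hgvs_c, cons.hgvs_p) == ("c.478C>T", "p.Arg160Cys")

    def test_single_exon_transcript_has_no_splice_context(self):
        spec = ToyTranscriptSpec(gene="S", strand="+", n_exons=1, cds_length=30)
        model, _ = generate_transcript(spec, seed=2)
        before = model.exons[0][0] - 1
        after = model.exons[0][1] + 1
        assert model.cdna_position(before).kind == "intergenic"
        assert model.cdna_position(after).kind == "intergenic"

    def test_intron_boundaries_are_canonical_gt_ag(self):
        model, _ = generate_transcript(mitf_like_spec(), seed=13)
        (s1, e1), (s2, e2) = model.exons
        assert model.base_at(e1 + 1) + model.base_at(e1 + 2) == "GT"
        assert model.base_at(s2 - 2) + model.base_at(s2 - 1) == "AG"

    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        from Bio import SeqIO
        for run in ("x", "y"):
            model, record = generate_transcript(copa_like_spec(), seed=9)
            SeqIO.write([record], str(tmp_path / f"{run}.fa"), "fasta")
            write_gff3([model], tmp_path / f"{run}.gff3")
        assert (tmp_path / "x.fa").read_bytes() == (tmp_path / "y.fa").read_bytes()
        assert (tmp_path / "x.gff3").read_bytes() == (tmp_path / "y.gff3").read_bytes()

    def test_unsatisfiable_constraints_rejected(self):
        with pytest.raises(ValidationError, match="stop"):
            ToyTranscriptSpec(gene="B", cds_length=30,
                              required_codon_constraints=((5, "TAA"),))
        with pytest.raises(ValidationError, match="ATG"):
            ToyTranscriptSpec(gene="B", cds_length=30,
                              required_codon_constraints=((1, "CCC"),))
        with pytest.raises(ValidationError, match="outside"):
            ToyTranscriptSpec(gene="B", cds_length=30,
                              required_codon_constraints=((40, "CGC"),))


class TestGenotypingTables:
    def test_forced_cross_gives_single_row(self):
        rows = generate_genotyping_table(
            default_rules(),
            [((TwoLocusGenotype("T/T", "G/G"), TwoLocusGenotype("C/C", "G/G")), 10)],
            seed=1)
        assert len(rows) == 1
        row = rows[0]
        assert (row.phenotype_label, row.genotype_locus1, row.genotype_locus2,
                row.n_animals) == (CoatClass.WHITE_HAT.value, "C/T", "G/G", 10)
        assert row.group == "case"

    def test_empty_crosses(self):
        assert generate_genotyping_table(default_rules(), [], seed=1) == []

    def test_row_counts_sum_to_total_offspring(self):
        p = TwoLocusGenotype("C/T", "G/A")
        rows = generate_genotyping_table(default_rules(), [((p, p), 64)], seed=5)
        assert sum(r.n_animals for r in rows) == 64
        assert all(r.group in ("case", "control") for r in rows)


class TestFixtureDirectory:
    def test_end_to_end_recovery_from_files(self, tmp_path):
        """simulate -> read back -> run_filter recovers the planted missense
        variant as the top-ranked candidate."""
        from minkseg import load_transcripts, read_phenotype_table, read_vcf
        from minkseg.variant_io import phenotype_map_from_records

        manifest = generate_fixture_dir(tmp_path / "fx", seed=17)
        for name in manifest["files"] + ["manifest.json"]:
            assert (tmp_path / "fx" / name).exists()
        records = read_phenotype_table(tmp_path / "fx" / "phenotypes.tsv")
        matrix = read_vcf(tmp_path / "fx" / "cohort.vcf",
                          phenotype_map_from_records(records))
        transcripts = load_transcripts(tmp_path / "fx" / "transcripts.gff3",
                                       tmp_path / "fx" / "genome.fa")
        report = run_filter(matrix, FilterConfig(), transcripts, {"COPA"})
        top = report.ranked[0]
        assert str(top.variant) == manifest["causal_variant"]
        assert top.consequence.hgvs_p == "p.Arg160Cys"

    def test_unique_recovery_rate_matches_closed_form(self):
        """Frequency of 'planted variant is the only stage-1 survivor'
        agrees with the analytic expectation (1 - p_bg)^n_bg within 4 sigma
        over 50 seeds; the planted variant itself always survives."""
        from scipy import stats as sps

        spec0 = CohortSpec(seed=0)
        q = spec0.background_alt_freq
        p_dp = float(1 - sps.poisson.cdf(spec0.min_causal_case_depth - 1,
                                         spec0.mean_depth))
        p_case = (q ** 2) * (1 - spec0.missing_rate) * p_dp
        p_ctrl_ok = (1 - q) ** 2 * (1 - spec0.missing_rate) + spec0.missing_rate
        p_bg = p_case * p_ctrl_ok ** spec0.n_controls
        expected = (1 - p_bg) ** spec0.n_background_variants

        from minkseg import stage1_segregation

        unique = 0
        for seed in range(50):
            m, _ = generate_cohort(CohortSpec(seed=seed))
            passed = stage1_segregation(m, FilterConfig())
            assert any(v.pos == spec0.causal.pos for v in passed)
            unique += int(len(passed) == 1)
        sigma = np.sqrt(50 * expected * (1 - expected))
        assert abs(unique - 50 * expected) <= 4 * sigma
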