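# minkseg

Causal-variant discovery for Mendelian coat-colour traits, built around the
mink *Black crystal* (Cr) case study: a codominant COPA missense allele
whose interaction with the Hedlund-white MITF splice allele produces
completely white, dark-eyed, normally hearing double heterozygotes.

The package is aimed at people mapping fully penetrant Mendelian traits
from small case/control whole-genome cohorts (one or a few sequenced cases
against a panel of other phenotypes). It provides:

- **Segregation filtering** — the candidate funnel for a homozygous case:
  keep variants where every case is homozygous for the alternate allele
  with depth of coverage > 2 (DP ≥ 3) and no control is heterozygous or
  homozygous for it; restrict to coding exons and splice sites; rank by
  membership in a pigmentation-gene list and consequence severity.
- **Coding-consequence annotation** — a minimal strand-aware annotator
  mapping genomic SNVs to simplified HGVS c./p. notation against a
  GFF3+FASTA transcript model (e.g. genomic G>A on the minus strand →
  `c.478C>T`, codon CGC→TGC, `p.Arg160Cys`; a donor-site G>A →
  `c.33+1G>A`).
- **Association statistics** — allele-count 2×2 tables from genotyping
  count rows (two alleles per diploid animal), odds ratio with the
  Haldane–Anscombe 0.5 correction when a cell is zero, Wald confidence
  interval and two-sided p on ln(OR), with Fisher's exact test as a
  labelled alternative:

  OR = a·d / (b·c),  SE = √(1/a + 1/b + 1/c + 1/d),
  CI = exp(ln OR ± z·SE),  p = 2·(1 − Φ(|ln OR|/SE)).

- **Two-locus epistasis model** — the total genotype→phenotype map over
  COPA {C/C, C/T, T/T} × MITF {G/G, G/A, A/A} (standard, white hat,
  completely white, Hedlund white deaf, ventral spotting), concordance
  checking of observed genotyping tables, and seeded Mendelian cross
  simulation.
- **Synthetic data** — seed-reproducible cohorts (VCF 4.2 + phenotype
  table) with one planted causal variant and Hardy–Weinberg background
  variants, plus toy transcripts (GFF3 + FASTA) constrained to realise any
  required codon, so every stage is testable without downloads.

## Worked example

```python
from minkseg import annotate_snv, associate, build_allele_table
from minkseg.datasets import load_genotyping_counts
from minkseg.synthetic_data import (copa_like_spec, generate_transcript,
                                    snv_for_cdna_change)

rows = load_genotyping_counts()        # 17 Black-crystal cases, 34 controls
t = build_allele_table(rows, "T")
print(f"allele table: a={t.a} b={t.b} c={t.c} d={t.d}")
print(associate(rows, "T").formatted())

model, _ = generate_transcript(copa_like_spec(), seed=7)
v = snv_for_cdna_change(model, 478, "T")
c = annotate_snv(v, model)
print(f"{v} -> {c.hgvs_c} {c.hgvs_p} ({c.category.value})")
```

prints

```
allele table: a=21 b=13 c=0 d=68
p = 0.00023; OR = 218; 95% CI 12.45-3825.13
COPA_contig:165 G/A -> c.478C>T p.Arg160Cys (missense)
```

The allele table counts T alleles: the 17 cases carry 21 T and 13 C
alleles, the 34 control animals carry none, so the control cell is zero,
the 0.5 correction applies, and the corrected table gives OR ≈ 218 with a
wide but decisively positive confidence interval. The annotation line
shows the minus-strand bookkeeping: the genomic G>A is a C>T in cDNA
space, changing codon 160 from arginine to cysteine.

There is also a CLI mirroring the library:

```sh
minkseg simulate --seed 17 --out-dir fx         # VCF+GFF3+FASTA+TSV fixture set
minkseg filter --vcf fx/cohort.vcf --phenotypes fx/phenotypes.tsv \
    --gff3 fx/transcripts.gff3 --fasta fx/genome.fa \
    --gene-list fx/genes.txt --out-dir fx/out
minkseg annotate --vcf fx/cohort.vcf --gff3 fx/transcripts.gff3 \
    --fasta fx/genome.fa --out fx/consequences.tsv
minkseg associate --counts counts.tsv --allele T --out association.json
```

## Layout

- `src/minkseg/variant_io.py` — VCF/phenotype-table I/O, genotype matrix
- `src/minkseg/segregation_filter.py` — three-stage candidate funnel
- `src/minkseg/consequence.py` — transcript model, cDNA mapping, annotator
- `src/minkseg/association.py` — allele tables, Haldane/Wald, Fisher
- `src/minkseg/epistasis_model.py` — two-locus phenotype rules, crosses
- `src/minkseg/synthetic_data.py` — cohort/transcript/table generators
- `src/minkseg/datasets.py` — published genotyping counts
- `src/minkseg/cli.py` — `minkseg filter|annotate|associate|simulate`
- `docs/methods.md` — model, assumptions, numerical choices, limitations
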