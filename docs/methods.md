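# Methods

## Problem setting

A fully penetrant Mendelian coat-colour trait is mapped by sequencing one
(or a few) affected genomes and comparing them against a panel of animals
with other phenotypes. The affected animal is expected to be homozygous
for the causal allele; every unaffected animal must not carry it. The
package implements that segregation logic, the consequence annotation used
to shortlist protein-affecting candidates, the association statistics used
to confirm a candidate on a genotyped cohort, and a two-locus epistasis
model for the interaction between the mink COPA `Cr` allele and the MITF
Hedlund `h` allele.

## Segregation filter

Stage 1 keeps a biallelic site iff every case sample is homozygous for the
alternate allele with read depth ≥ `min_case_depth`, and no control sample
is heterozygous or homozygous-alternate. Choices that matter:

- `min_case_depth` defaults to 3: "depth of coverage greater than 2" read
  as a strict inequality (DP = 2 fails).
- "Homozygous" means homozygous for the **alternate** allele; a case that
  is homozygous-reference is not a candidate.
- Missing control genotypes do **not** exclude a site by default
  (`treat_missing_control_as="pass"`): the exclusion rule names observed
  het/hom genotypes. A strict mode is available for reanalysis.
- The depth requirement applies to cases only by default; whether the
  original analysis also required control depth is not determinable, so
  `min_control_depth` (default 0) exposes the stricter variant.
- With one case the rule reduces exactly to the single-genome design; with
  several cases it requires the genotype to be shared by all.

Stage 2 keeps sites inside a CDS exon or within `splice_window` (default 2,
the canonical GT/AG dinucleotides) intronic bases of an exon boundary.
Stage 3 ranks candidates by (gene ∈ user gene list) > severity
(stop > splice > missense > synonymous > non-coding) > input order; the
tie-break is stable so the ranking is deterministic.

The filter is vectorised over a dense genotype/depth matrix; the test
suite checks it against a naive per-sample double loop on random matrices,
and checks monotonicity (adding controls or raising the depth threshold
can only shrink the pass set).

## Consequence annotation

A transcript model is exon intervals (1-based, inclusive, genomic) plus
CDS bounds over an explicit genomic sequence. Coding positions are
numbered 1..CDS-length from the A of the start ATG in transcript
orientation; intronic positions are written `c.N+k` / `c.N−k` anchored to
the boundary on the nearer side of the intron (ties go to the donor side).
For minus-strand transcripts, genomic alleles are complemented into
transcript space before codon lookup — this is what reconciles a genomic
G/A with a cDNA C>T. Categories: missense, synonymous, stop_gained,
stop_lost, splice_donor/acceptor (|offset| ≤ 2), intronic, UTR (exonic
outside CDS; no c.−/c.* numbering), intergenic. Only SNVs are annotated;
indels are rejected explicitly with a typed error. The standard nuclear
genetic code is used, and REF alleles are checked against the supplied
sequence so inconsistent inputs fail loudly. Three-letter amino-acid codes
(`Arg`, `Cys`, `Ter`) are used in p. notation.

## Association statistics

Genotype count rows are collapsed into a 2×2 allele table: each diploid
animal contributes two allele observations to its group. When any cell is
zero (here: the risk allele is absent from every control) 0.5 is added to
all four cells (Haldane–Anscombe); tables without a zero cell are left
unmodified, since an unconditional correction would perturb non-degenerate
tables. Inference is Wald on ln(OR) with SE = √(Σ 1/cell).

Critical values are taken at two-decimal textbook precision by default
(1.96 for 95%): that is how such tables are conventionally analysed with
epidemiological calculators, and it reproduces published intervals digit
for digit; `z_precision=None` switches to the full normal quantile (the
two differ by < 0.01% on the interval bounds). Reporting rounds OR to 3
significant figures, CI bounds to 2 decimals and p to 2 significant
figures; full precision is kept internally. Fisher's exact test (two-sided,
sum of hypergeometric probabilities ≤ that of the observed table) is
provided as a labelled alternative and cross-checked in the tests against
direct enumeration over all tables with margins ≤ 15.

On the bundled genotyping counts (17 cases: 21 T / 13 C alleles; 34
controls: 0 T / 68 C) this yields OR = 218.19, 95% CI (12.45, 3825.13),
p = 0.00023. All 17 Black-crystal-phenotype animals — both the "white hat"
heterozygotes and the completely white animals — are counted as cases;
this is the only grouping under which the four statistics are mutually
consistent, and it is the grouping the package adopts.

## Two-locus epistasis model

The rule set is total over the 9 genotype combinations of COPA
{C/C, C/T, T/T} × MITF {G/G, G/A, A/A}. Observed classes: wild type →
standard; C/T,G/G → white hat; C/C,G/A → ventral spotting; C/C,A/A →
Hedlund white with impaired hearing; C/T,G/A (double heterozygote) and
T/T,— → completely white with dark eyes and normal hearing. The two
combinations never observed in the source cohort (C/T,A/A and T/T,A/A)
are extrapolated to completely white and carry an `extrapolated` flag so
reports can separate observed from conjectured classes. Hearing is a
categorical label on the class, not an audiometric model. Cr/Cr animals
are collapsed to completely white (their residual Himalayan-type pigmented
points are sparse and fade with maturation).

Cross simulation transmits one allele per locus per parent. Loci are
unlinked by default (recombination fraction 0.5, as for genes on different
chromosomes); smaller fractions model linkage by treating each parent's
genotype strings as haplotypes in written order. Genotype strings are
canonicalised (wild-type allele first) so `T/C` ≡ `C/T`.

## Synthetic data generator

`generate_cohort` emulates the downstream product of a germline-calling
pipeline on a small case/control cohort: a multi-sample genotype matrix
with one planted causal variant perfectly concordant with case status
(full penetrance), background variants with independent Hardy–Weinberg
genotypes (no linkage disequilibrium — the filter is site-wise, so LD adds
nothing testable), Poisson depths independent of genotype, and uniform
random missingness. Defaults are the study design: 1 case vs 8 controls,
200 background variants at alternate-allele frequency 0.2, mean depth 8×
(within the 5–40× coverage range typical of such cohorts), missingness
2% (a realistic germline-callset rate; the source data do not state one).
Case depth at the causal site is drawn from a Poisson truncated at the
filter threshold (≥ 3): the premise of the design is that the trait locus
was sequenced deeply enough in the case to be called at all. Control
calls at the causal site may still go missing.

What the generator does **not** emulate: read-level errors, genotype
likelihoods, LD and population structure, depth–genotype coupling,
multi-allelic background sites. Passing tests therefore demonstrate the
correctness of the filtering/annotation/statistics logic under the stated
model, not robustness to caller artefacts in real data.

`generate_transcript` builds a CDS satisfying ATG start, single terminal
stop, no internal stop and arbitrary `(codon_index, codon)` constraints,
embeds it in exons with GT..AG introns and UTRs, and (for minus-strand
specs) reverse-complements the whole embedding — so the worked annotation
examples (`c.478C>T`/`p.Arg160Cys` from a genomic G>A, `c.33+1G>A` at a
donor site) are realised by construction and verified by annotation, not
hard-coded. Identical spec + seed gives byte-identical FASTA/GFF3/VCF.

## Problem sizes used in the checks

The bundled statistics run on the published counts (51 animals). The
filter properties run on 20 cohorts of 201 variants × 9 samples, and
oracle comparisons on random 50×6 matrices; cross simulations use
n = 10,000 (headline check) and n = 2,000 per parent pair (all 81 pairs).
Fisher's exact enumeration covers all ≈ 18,000 tables with row margins
≤ 15. These sizes give 4σ statistical resolution on every stochastic
check while keeping the whole suite fast.

## Known limitations

- The annotator handles one transcript per gene and SNVs only; no
  c.−/c.* UTR numbering, no MNV/indel consequences, no damage scores.
- The published candidate-funnel sizes (tens of thousands of raw
  candidate variants reduced to hundreds in coding regions) depend on the
  real genomes and are not reproduced; the funnel's *structure* and its
  planted-variant recovery are what the synthetic checks establish.
- The Wald p-value is asymptotic; with a zero cell it depends on the
  continuity correction. Fisher's exact p for the same table is far
  smaller; the package reports whichever method is requested, labelled.
- Phenotype classes are discrete labels; penetrance, expressivity and
  maturation-dependent whitening are not modelled.
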