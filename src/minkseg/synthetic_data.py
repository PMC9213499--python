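"""Synthetic cohorts, toy transcripts and genotyping tables.

Everything the pipeline consumes can be generated here, self-contained and
seed-reproducible, with the statistical structure the analysis assumes:

* a genotype matrix with one planted causal variant perfectly concordant
  with case status (full penetrance, as expected for a Mendelian trait),
  background variants drawn per sample from Hardy–Weinberg proportions,
  Poisson read depths, and occasional missing calls;
* toy transcript models (GFF3 + FASTA) whose CDS satisfies arbitrary codon
  constraints, so worked annotation examples (a specific Arg codon at a
  specific residue, a donor-site break after a specific coding position)
  can be realised exactly;
* genotyping count tables produced by Mendelian crosses pushed through the
  two-locus phenotype rules.

Defaults mirror the study design the package re-implements: one sequenced
case against 8 controls at mean coverage ~8x. Case depth at the causal
site is floored at the filter threshold (the trait locus is, by premise,
observable in the sequenced case).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .association import GenotypeCountRow
from .consequence import TranscriptModel, revcomp, write_gff3
from .epistasis_model import (CoatClass, PhenotypeRuleSet, TwoLocusGenotype,
                              default_rules, simulate_cross)
from .errors import ValidationError
from .variant_io import (GT, GenotypeMatrix, Role, SampleRecord, VariantSite,
                         write_vcf)

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES
                      if a + b + c not in _STOPS)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass
class CausalSpec:
    """The planted variant: hom-alt in every case, hom-ref in every control."""

    contig: str = "chr1"
    pos: int = 500_000
    ref: str = "G"
    alt: str = "A"


@dataclass
class CohortSpec:
    """Study-shaped cohort: one case genome against a panel of controls."""

    n_cases: int = 1
    n_controls: int = 8
    n_background_variants: int = 200
    background_alt_freq: float = 0.2
    mean_depth: float = 8.0
    missing_rate: float = 0.02
    min_causal_case_depth: int = 3
    region_length: int = 1_000_000
    causal: CausalSpec = field(default_factory=CausalSpec)
    case_label: str = "Black crystal"
    control_label: str = "standard"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("need >= 1 case and >= 1 control")
        if not 0 <= self.background_alt_freq <= 1:
            raise ValidationError("background_alt_freq must be in [0,1]")
        if not 0 <= self.missing_rate <= 1:
            raise ValidationError("missing_rate must be in [0,1]")
        if self.mean_depth <= 0:
            raise ValidationError("mean_depth must be positive")
        if self.n_background_variants > self.region_length - 1:
            raise ValidationError("region too short for requested background variants")


def _truncated_poisson(rng: np.random.Generator, mean: float, floor: int, size: int) -> np.ndarray:
    """Poisson draws conditioned on >= floor (rejection sampling)."""
    out = rng.poisson(mean, size=size)
    while np.any(out < floor):
        low = out < floor
        out[low] = rng.poisson(mean, size=int(low.sum()))
    return out


def generate_cohort(
    spec: CohortSpec,
    contig_seq: str | None = None,
) -> tuple[GenotypeMatrix, list[SampleRecord]]:
    """Generate a genotype matrix with one planted causal variant.

    Background genotypes are independent across samples and sites (no LD),
    drawn from Hardy–Weinberg proportions at ``background_alt_freq``;
    depths are Poisson(``mean_depth``); calls are masked to missing with
    probability ``missing_rate`` except case calls at the causal site.

    When ``contig_seq`` is given, background REF alleles are read from it
    (so the VCF is consistent with a generated FASTA); otherwise they are
    random bases.
    """
    rng = np.random.default_rng(spec.seed)
    samples = (
        [SampleRecord(f"case_{i+1}", spec.case_label, Role.CASE)
         for i in range(spec.n_cases)]
        + [SampleRecord(f"control_{i+1}", spec.control_label, Role.CONTROL)
           for i in range(spec.n_controls)]
    )
    n_samples = len(samples)

    # background positions: without replacement, never colliding with the causal site
    candidates = rng.choice(spec.region_length, size=min(spec.region_length,
                            spec.n_background_variants + 1), replace=False) + 1
    positions = [int(p) for p in candidates if p != spec.causal.pos][: spec.n_background_variants]
    if len(positions) < spec.n_background_variants:
        raise ValidationError("could not place background variants without collision")

    sites: list[VariantSite] = []
    for p in positions:
        if contig_seq is not None:
            ref = contig_seq[p - 1].upper()
        else:
            ref = _BASES[rng.integers(4)]
        alt = _BASES[rng.integers(4)]
        while alt == ref:
            alt = _BASES[rng.integers(4)]
        sites.append(VariantSite(spec.causal.contig, p, ref, alt))
    causal_site = VariantSite(spec.causal.contig, spec.causal.pos,
                              spec.causal.ref, spec.causal.alt)

    n_bg = len(sites)
    q = spec.background_alt_freq
    bg_gts = rng.binomial(2, q, size=(n_bg, n_samples)).astype(np.int8)  # 0/1/2 = HW draw
    bg_dp = rng.poisson(spec.mean_depth, size=(n_bg, n_samples)).astype(np.int32)
    bg_missing = rng.random(size=(n_bg, n_samples)) < spec.missing_rate
    bg_gts[bg_missing] = GT.MISSING.value

    causal_gts = np.full(n_samples, GT.HOM_REF.value, dtype=np.int8)
    causal_gts[: spec.n_cases] = GT.HOM_ALT.value
    causal_dp = rng.poisson(spec.mean_depth, size=n_samples).astype(np.int32)
    causal_dp[: spec.n_cases] = _truncated_poisson(
        rng, spec.mean_depth, spec.min_causal_case_depth, spec.n_cases)
    causal_missing = rng.random(size=n_samples) < spec.missing_rate
    causal_missing[: spec.n_cases] = False  # the planted signal is always called in cases
    causal_gts[causal_missing] = GT.MISSING.value

    all_sites = sites + [causal_site]
    gts = np.vstack([bg_gts, causal_gts[None, :]])
    dps = np.vstack([bg_dp, causal_dp[None, :]])
    order = np.argsort([s.pos for s in all_sites], kind="stable")
    matrix = GenotypeMatrix([all_sites[i] for i in order], samples,
                            gts[order], dps[order])
    return matrix, samples


# ---------------------------------------------------------------------------
# toy transcript generation
# ---------------------------------------------------------------------------


@dataclass
class ToyTranscriptSpec:
    """Shape of a synthetic transcript whose CDS satisfies codon constraints."""

    gene: str
    strand: str = "+"
    n_exons: int = 1
    cds_length: int = 300
    required_codon_constraints: tuple[tuple[int, str], ...] = ()
    exon_coding_lengths: tuple[int, ...] | None = None  # split of cds_length
    intron_length: int = 60
    utr5_length: int = 12
    utr3_length: int = 12
    flank: int = 30
    contig: str | None = None

    def __post_init__(self) -> None:
        if self.cds_length % 3 != 0 or self.cds_length < 6:
            raise ValidationError("cds_length must be a multiple of 3, >= 6")
        if self.n_exons < 1:
            raise ValidationError("n_exons must be >= 1")
        if self.intron_length < 4 and self.n_exons > 1:
            raise ValidationError("introns must be >= 4 bp (GT..AG)")
        n_codons = self.cds_length // 3
        for idx, codon in self.required_codon_constraints:
            if not 1 <= idx <= n_codons:
                raise ValidationError(f"constrained codon {idx} outside 1..{n_codons}")
            if len(codon) != 3 or any(b not in _BASES for b in codon.upper()):
                raise ValidationError(f"bad codon constraint {codon!r}")
            if idx == 1 and codon.upper() != "ATG":
                raise ValidationError("codon 1 must be ATG")
            if idx == n_codons and codon.upper() not in _STOPS:
                raise ValidationError("terminal codon must be a stop")
            if idx not in (1, n_codons) and codon.upper() in _STOPS:
                raise ValidationError(f"internal codon {idx} may not be a stop")
        if self.exon_coding_lengths is not None:
            if len(self.exon_coding_lengths) != self.n_exons:
                raise ValidationError("exon_coding_lengths must have n_exons entries")
            if sum(self.exon_coding_lengths) != self.cds_length:
                raise ValidationError("exon_coding_lengths must sum to cds_length")
            if any(x < 1 for x in self.exon_coding_lengths):
                raise ValidationError("exon coding lengths must be positive")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(4, size=n))


def generate_transcript(spec: ToyTranscriptSpec, seed: int) -> tuple[TranscriptModel, SeqRecord]:
    """Generate a transcript model plus its genomic FASTA record.

    The CDS starts with ATG, ends with a single stop, contains no internal
    stop, and honours every required codon constraint; introns carry
    canonical GT..AG boundaries. Deterministic for a given spec and seed.
    """
    rng = np.random.default_rng(seed)
    n_codons = spec.cds_length // 3
    codons = ["ATG"] + [ _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))]
                         for _ in range(n_codons - 2) ] + [_STOPS[rng.integers(3)]]
    for idx, codon in spec.required_codon_constraints:
        codons[idx - 1] = codon.upper()
    cds = "".join(codons)

    coding_split = (spec.exon_coding_lengths
                    if spec.exon_coding_lengths is not None
                    else _even_split(spec.cds_length, spec.n_exons))
    # transcript-orientation exon sequences (UTRs attached to terminal exons)
    pieces = []
    cursor = 0
    for i, L in enumerate(coding_split):
        seq = cds[cursor:cursor + L]
        cursor += L
        if i == 0:
            seq = _random_seq(rng, spec.utr5_length) + seq
        if i == len(coding_split) - 1:
            seq = seq + _random_seq(rng, spec.utr3_length)
        pieces.append(seq)

    flank5 = _random_seq(rng, spec.flank)
    flank3 = _random_seq(rng, spec.flank)
    genome_parts = [flank5]
    exon_intervals: list[tuple[int, int]] = []
    pos = len(flank5)
    for i, exon_seq in enumerate(pieces):
        exon_intervals.append((pos + 1, pos + len(exon_seq)))
        genome_parts.append(exon_seq)
        pos += len(exon_seq)
        if i < len(pieces) - 1:
            intron = "GT" + _random_seq(rng, spec.intron_length - 4) + "AG"
            genome_parts.append(intron)
            pos += len(intron)
    genome_parts.append(flank3)
    genome = "".join(genome_parts)

    cds_start = exon_intervals[0][0] + spec.utr5_length
    cds_end = exon_intervals[-1][1] - spec.utr3_length

    if spec.strand == "-":
        L = len(genome)
        genome = revcomp(genome)
        exon_intervals = [(L - e + 1, L - s + 1) for s, e in exon_intervals][::-1]
        cds_start, cds_end = L - cds_end + 1, L - cds_start + 1

    contig = spec.contig or f"{spec.gene}_contig"
    model = TranscriptModel(
        gene=spec.gene,
        transcript_id=f"{spec.gene}_tx1",
        contig=contig,
        strand=spec.strand,
        exons=exon_intervals,
        cds_start=cds_start,
        cds_end=cds_end,
        genomic_seq=genome,
    )
    model.validate()
    record = SeqRecord(Seq(genome), id=contig, description=f"synthetic {spec.gene} locus")
    return model, record


def _even_split(total: int, parts: int) -> tuple[int, ...]:
    base, rem = divmod(total, parts)
    return tuple(base + (1 if i < rem else 0) for i in range(parts))


def genomic_of_cdna(model: TranscriptModel, cdna_pos: int, offset: int = 0) -> int:
    """Genomic position of a coding cDNA position, optionally shifted by an
    intronic offset in transcript orientation (e.g. +1 = first donor base)."""
    if not 1 <= cdna_pos <= model.cds_len:
        raise ValidationError(f"cDNA position {cdna_pos} outside CDS")
    g = model._coding_order[cdna_pos - 1]
    return g + offset if model.strand == "+" else g - offset


def snv_for_cdna_change(model: TranscriptModel, cdna_pos: int, alt_cdna: str,
                        offset: int = 0) -> VariantSite:
    """Construct the genomic SNV realising a given cDNA-space substitution."""
    g = genomic_of_cdna(model, cdna_pos, offset)
    ref = model.base_at(g)
    alt = alt_cdna.upper() if model.strand == "+" else revcomp(alt_cdna.upper())
    return VariantSite(model.contig, g, ref, alt)


def copa_like_spec() -> ToyTranscriptSpec:
    """Minus-strand six-exon toy with an Arg codon (CGC) at residue 160, so
    a genomic G>A at the base pairing with cDNA 478 yields c.478C>T /
    p.Arg160Cys, as in the COPA Cr candidate."""
    return ToyTranscriptSpec(
        gene="COPA", strand="-", n_exons=6, cds_length=600,
        required_codon_constraints=((160, "CGC"),),
        exon_coding_lengths=(90, 90, 90, 90, 90, 150),
    )


def mitf_like_spec() -> ToyTranscriptSpec:
    """Plus-strand two-exon toy whose first coding exon ends at cDNA 33, so
    the first intronic base is the c.33+1 donor position, as in the MITF
    Hedlund splice variant."""
    return ToyTranscriptSpec(
        gene="MITF", strand="+", n_exons=2, cds_length=201,
        exon_coding_lengths=(33, 168),
    )


# ---------------------------------------------------------------------------
# genotyping tables from crosses
# ---------------------------------------------------------------------------

#: coat classes counted as cases in generated genotyping tables
DEFAULT_CASE_CLASSES = frozenset({CoatClass.WHITE_HAT, CoatClass.COMPLETELY_WHITE})


def generate_genotyping_table(
    rules: PhenotypeRuleSet,
    crosses: Sequence[tuple[tuple[TwoLocusGenotype, TwoLocusGenotype], int]],
    seed: int,
    case_classes: frozenset[CoatClass] = DEFAULT_CASE_CLASSES,
) -> list[GenotypeCountRow]:
    """Simulate crosses, phenotype the offspring, and aggregate to count rows."""
    rng = np.random.default_rng(seed)
    counts: dict[tuple[str, str, str], int] = {}
    for (p1, p2), n in crosses:
        child_seed = int(rng.integers(2**31))
        for g in simulate_cross(p1, p2, n, seed=child_seed):
            label = rules.predict(g).label
            key = (label.value, g.copa, g.mitf)
            counts[key] = counts.get(key, 0) + 1
    rows = []
    for (label, copa, mitf), n in sorted(counts.items()):
        group = "case" if CoatClass(label) in case_classes else "control"
        rows.append(GenotypeCountRow(label, group, copa, mitf, n))
    return rows


# ---------------------------------------------------------------------------
# fixture directory (VCF + GFF3 + FASTA + phenotype TSV + manifest)
# ---------------------------------------------------------------------------


def generate_fixture_dir(outdir: str | Path, seed: int,
                         cohort: CohortSpec | None = None) -> dict:
    """Write a complete, self-consistent fixture set to a directory.

    The planted causal variant is the c.478 C>T missense change of the
    COPA-like toy transcript, so the full pipeline (filter -> annotate ->
    associate) can run end to end on the generated files. Returns the
    manifest (also written as manifest.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    copa_model, copa_rec = generate_transcript(copa_like_spec(), seed=int(rng.integers(2**31)))
    mitf_model, mitf_rec = generate_transcript(mitf_like_spec(), seed=int(rng.integers(2**31)))
    causal = snv_for_cdna_change(copa_model, 478, "T")

    if cohort is None:
        cohort = CohortSpec(seed=int(rng.integers(2**31)))
    cohort.causal = CausalSpec(causal.contig, causal.pos, causal.ref, causal.alt)
    cohort.region_length = len(copa_model.genomic_seq)
    if cohort.n_background_variants > cohort.region_length // 2:
        cohort.n_background_variants = cohort.region_length // 2
    matrix, samples = generate_cohort(cohort, contig_seq=copa_model.genomic_seq)

    write_vcf(matrix, outdir / "cohort.vcf")
    write_gff3([copa_model, mitf_model], outdir / "transcripts.gff3")
    SeqIO.write([copa_rec, mitf_rec], str(outdir / "genome.fa"), "fasta")
    pheno_lines = ["sample_id\tphenotype_label\trole"]
    pheno_lines += [f"{s.sample_id}\t{s.phenotype_label}\t{s.role.value}" for s in samples]
    (outdir / "phenotypes.tsv").write_text("\n".join(pheno_lines) + "\n")
    (outdir / "genes.txt").write_text("COPA\nMITF\n")

    manifest = {
        "seed": seed,
        "causal_variant": str(causal),
        "n_cases": cohort.n_cases,
        "n_controls": cohort.n_controls,
        "n_background_variants": cohort.n_background_variants,
        "files": ["cohort.vcf", "transcripts.gff3", "genome.fa",
                  "phenotypes.tsv", "genes.txt"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
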