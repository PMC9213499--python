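"""Case-unique homozygous-variant segregation filtering.

The candidate-selection funnel for a fully penetrant recessive/codominant
trait mapped with one or few sequenced cases:

* stage 1 — keep variants where every case is homozygous for the alternate
  allele with sufficient read depth (default DP >= 3, i.e. coverage strictly
  greater than 2) and no control carries the allele (neither heterozygous
  nor homozygous-alternate);
* stage 2 — restrict to protein-coding regions and splice sites;
* stage 3 — rank surviving candidates by membership in a user-supplied
  gene list (e.g. known pigmentation genes) and by consequence severity.

With a single case the stage-1 rule reduces exactly to "homozygous in the
case, absent from every control".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .consequence import SEVERITY_ORDER, Consequence, TranscriptModel
from .errors import ValidationError
from .variant_io import GT, GenotypeMatrix, Role, VariantSite

logger = logging.getLogger(__name__)


class MissingControlPolicy(str, Enum):
    PASS = "pass"   # missing control genotypes do not exclude a variant
    FAIL = "fail"   # any missing control genotype excludes the variant


@dataclass
class FilterConfig:
    """Parameters of the segregation filter.

    ``min_case_depth`` defaults to 3 (coverage strictly greater than 2);
    ``control_disallowed`` defaults to {het, hom_alt} — a control may be
    homozygous reference (or missing, per ``treat_missing_control_as``).
    ``min_control_depth`` optionally applies the same depth requirement to
    controls (off by default: depth is a property of the sequenced case).
    """

    min_case_depth: int = 3
    require_case_hom_alt: bool = True
    control_disallowed: frozenset[GT] = frozenset({GT.HET, GT.HOM_ALT})
    treat_missing_control_as: MissingControlPolicy = MissingControlPolicy.PASS
    min_control_depth: int = 0

    def __post_init__(self) -> None:
        if self.min_case_depth < 0 or self.min_control_depth < 0:
            raise ValidationError("depth thresholds must be non-negative")
        self.control_disallowed = frozenset(GT(g) for g in self.control_disallowed)
        self.treat_missing_control_as = MissingControlPolicy(self.treat_missing_control_as)


@dataclass
class RankedCandidate:
    variant: VariantSite
    consequence: Consequence
    in_gene_list: bool
    rank: int


@dataclass
class FilterReport:
    n_input: int
    n_pass_stage1: int
    n_pass_stage2: int
    stage1_variants: list[VariantSite]
    stage2_variants: list[VariantSite]
    ranked: list[RankedCandidate]

    def __post_init__(self) -> None:
        if not (self.n_pass_stage2 <= self.n_pass_stage1 <= self.n_input):
            raise ValidationError("stage counts must be non-increasing")
        if (self.n_pass_stage1 != len(self.stage1_variants)
                or self.n_pass_stage2 != len(self.stage2_variants)):
            raise ValidationError("stage counts disagree with variant lists")

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_pass_stage1": self.n_pass_stage1,
            "n_pass_stage2": self.n_pass_stage2,
            "top_candidate": str(self.ranked[0].variant) if self.ranked else None,
        }


def stage1_segregation(matrix: GenotypeMatrix, config: FilterConfig) -> list[VariantSite]:
    """Variants where all cases are hom-alt at depth and no control carries the allele.

    Vectorised over the genotype/depth arrays; input order is preserved.
    """
    case_idx = matrix.sample_indices(Role.CASE)
    control_idx = matrix.sample_indices(Role.CONTROL)
    if not case_idx or not control_idx:
        raise ValidationError(
            f"segregation filter needs >= 1 case and >= 1 control "
            f"(got {len(case_idx)} cases, {len(control_idx)} controls)"
        )
    case_gt = matrix.gts[:, case_idx]
    case_dp = matrix.depths[:, case_idx]
    ctrl_gt = matrix.gts[:, control_idx]
    ctrl_dp = matrix.depths[:, control_idx]

    if config.require_case_hom_alt:
        ok_case = np.all((case_gt == GT.HOM_ALT.value)
                         & (case_dp >= config.min_case_depth), axis=1)
    else:
        ok_case = np.all((np.isin(case_gt, (GT.HOM_ALT.value, GT.HET.value)))
                         & (case_dp >= config.min_case_depth), axis=1)

    disallowed = np.array([g.value for g in config.control_disallowed], dtype=np.int8)
    bad_ctrl = np.isin(ctrl_gt, disallowed)
    if config.treat_missing_control_as is MissingControlPolicy.FAIL:
        bad_ctrl |= ctrl_gt == GT.MISSING.value
    if config.min_control_depth > 0:
        bad_ctrl |= ctrl_dp < config.min_control_depth
    ok_ctrl = ~np.any(bad_ctrl, axis=1)

    keep = ok_case & ok_ctrl
    return [v for v, k in zip(matrix.variants, keep) if k]


def stage2_region_restriction(
    variants: Sequence[VariantSite],
    transcripts: Sequence[TranscriptModel],
    splice_window: int = 2,
) -> list[VariantSite]:
    """Keep variants in a CDS exon or within the intronic splice window of
    an exon boundary of any transcript; order preserved."""
    if splice_window < 0:
        raise ValidationError("splice_window must be >= 0")
    out = []
    for v in variants:
        for tx in transcripts:
            if tx.contig == v.contig and tx.coding_or_splice(v.pos, splice_window):
                out.append(v)
                break
    return out


def stage3_prioritize(
    variants: Sequence[VariantSite],
    consequences: Sequence[Consequence],
    gene_list: set[str],
) -> list[RankedCandidate]:
    """Rank candidates: listed gene first, then severity, then input order."""
    if len(variants) != len(consequences):
        raise ValidationError(
            f"{len(variants)} variants but {len(consequences)} consequences"
        )
    keyed = []
    for i, (v, c) in enumerate(zip(variants, consequences)):
        in_list = c.gene in gene_list
        keyed.append(((0 if in_list else 1, SEVERITY_ORDER[c.category], i), v, c, in_list))
    keyed.sort(key=lambda t: t[0])
    return [RankedCandidate(v, c, in_list, rank)
            for rank, (_, v, c, in_list) in enumerate(keyed, start=1)]


def run_filter(
    matrix: GenotypeMatrix,
    config: FilterConfig,
    transcripts: Sequence[TranscriptModel],
    gene_list: set[str],
    splice_window: int = 2,
) -> FilterReport:
    """Run the full three-stage funnel and report per-stage counts."""
    from .consequence import annotate_best

    s1 = stage1_segregation(matrix, config)
    s2 = stage2_region_restriction(s1, transcripts, splice_window)
    consequences = [annotate_best(v, transcripts, splice_window) for v in s2]
    ranked = stage3_prioritize(s2, consequences, gene_list)
    logger.info("segregation funnel: %d input -> %d stage1 -> %d stage2",
                len(matrix.variants), len(s1), len(s2))
    return FilterReport(
        n_input=len(matrix.variants),
        n_pass_stage1=len(s1),
        n_pass_stage2=len(s2),
        stage1_variants=s1,
        stage2_variants=s2,
        ranked=ranked,
    )
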