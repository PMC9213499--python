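"""Shared fixtures: toy transcripts, genotype matrices, genotyping rows."""

from __future__ import annotations

import numpy as np
import pytest

from minkseg import (GT, FilterConfig, GenotypeMatrix, Role, SampleRecord,
                     VariantSite)
from minkseg.datasets import PHENOTYPE_CLASS_MAP, load_genotyping_counts
from minkseg.synthetic_data import (copa_like_spec, generate_transcript,
                                    mitf_like_spec)


@pytest.fixture(scope="session")
def copa_model():
    """Minus-strand toy with Arg codon CGC at residue 160 (c.478..480)."""
    model, _ = generate_transcript(copa_like_spec(), seed=7)
    return model


@pytest.fixture(scope="session")
def mitf_model():
    """Plus-strand toy whose first coding exon ends at cDNA position 33."""
    model, _ = generate_transcript(mitf_like_spec(), seed=3)
    return model


@pytest.fixture(scope="session")
def genotyping_rows():
    return load_genotyping_counts()


@pytest.fixture(scope="session")
def phenotype_class_map():
    return dict(PHENOTYPE_CLASS_MAP)


def make_matrix(gt_rows, dp_rows, n_cases=1, contig="chr1"):
    """Build a GenotypeMatrix from integer genotype/depth grids; the first
    ``n_cases`` samples are cases, the rest controls."""
    gt = np.asarray(gt_rows, dtype=np.int8)
    dp = np.asarray(dp_rows, dtype=np.int32)
    n_var, n_samp = gt.shape
    variants = [VariantSite(contig, 100 + i, "A", "G") for i in range(n_var)]
    samples = [
        SampleRecord(f"s{j}", "case" if j < n_cases else "ctrl",
                     Role.CASE if j < n_cases else Role.CONTROL)
        for j in range(n_samp)
    ]
    return GenotypeMatrix(variants, samples, gt, dp)


def random_matrix(rng, n_var=50, n_samp=6, n_cases=2, max_depth=10):
    """Random matrix over all four genotype states for oracle comparisons."""
    gt = rng.integers(0, 4, size=(n_var, n_samp))
    dp = rng.integers(0, max_depth + 1, size=(n_var, n_samp))
    return make_matrix(gt, dp, n_cases=n_cases)


def stage1_oracle(matrix, config: FilterConfig):
    """Naive per-sample double loop re-implementing the stage-1 rule."""
    out = []
    case_idx = matrix.sample_indices(Role.CASE)
    control_idx = matrix.sample_indices(Role.CONTROL)
    for i, v in enumerate(matrix.variants):
        ok = True
        for j in case_idx:
            call = matrix.call(i, j)
            wanted = (GT.HOM_ALT,) if config.require_case_hom_alt else (GT.HOM_ALT, GT.HET)
            if call.gt not in wanted or call.depth < config.min_case_depth:
                ok = False
        for j in control_idx:
            call = matrix.call(i, j)
            if call.gt in config.control_disallowed:
                ok = False
            if (config.treat_missing_control_as.value == "fail"
                    and call.gt is GT.MISSING):
                ok = False
            if config.min_control_depth and call.depth < config.min_control_depth:
                ok = False
        if ok:
            out.append(v)
    return out
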