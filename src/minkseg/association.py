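"""Allele-count association statistics for a candidate locus.

Genotype count rows (phenotype group, diploid genotype string, number of
animals) are collapsed into a 2x2 allele-count table — each diploid animal
contributes two allele observations to its group — and tested for
association of one allele with case status.

The default inference is the odds ratio with the Haldane–Anscombe
continuity correction (0.5 added to every cell when any cell is zero,
as happens when the risk allele is absent from all controls) and Wald
inference on ln(OR):

    SE = sqrt(1/a + 1/b + 1/c + 1/d)          (corrected cells)
    CI = exp(ln OR +/- z_{1-alpha/2} * SE)
    p  = 2 * (1 - Phi(|ln OR| / SE))

Fisher's exact test is provided as a labelled alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import math
import warnings

import pandas as pd
from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class GenotypeCountRow:
    """One aggregated genotyping row: a phenotype, its genotype(s), a count."""

    phenotype_label: str
    group: Literal["case", "control"]
    genotype_locus1: str
    genotype_locus2: str | None = None
    n_animals: int = 1

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise ValidationError(f"group must be case/control, got {self.group!r}")
        if self.n_animals < 1:
            raise ValidationError("n_animals must be >= 1")
        for g in (self.genotype_locus1, self.genotype_locus2):
            if g is not None and len(g.split("/")) != 2:
                raise ValidationError(f"genotype {g!r} is not two '/'-separated alleles")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Allele counts: a/b = case allele-of-interest/other, c/d = control."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("cell counts must be non-negative")

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)

    def corrected(self) -> tuple[float, float, float, float]:
        """Haldane–Anscombe: add 0.5 to every cell iff any cell is zero."""
        if self.has_zero_cell:
            return self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5
        return float(self.a), float(self.b), float(self.c), float(self.d)


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    z: float
    correction_applied: bool
    confidence: float = 0.95
    method: str = "wald_haldane"

    def formatted(self) -> str:
        """Caption-style one-liner (OR to 3 sig. figs, CI to 2 dp, p to 2 sig. figs)."""
        return (f"p = {float(f'{self.p_value:.2g}'):g}; "
                f"OR = {float(f'{self.odds_ratio:.3g}'):g}; "
                f"{self.confidence:.0%} CI {self.ci_low:.2f}-{self.ci_high:.2f}")


def build_allele_table(rows: Sequence[GenotypeCountRow], allele: str,
                       locus: int = 1) -> ContingencyTable2x2:
    """Collapse genotype count rows into a 2x2 allele table for one allele.

    Each animal contributes 2 allele observations to its group. ``locus``
    selects genotype_locus1 (1) or genotype_locus2 (2).
    """
    a = b = c = d = 0
    seen = False
    for row in rows:
        g = row.genotype_locus1 if locus == 1 else row.genotype_locus2
        if g is None:
            raise ValidationError(f"row {row.phenotype_label!r} lacks locus {locus} genotype")
        alleles = g.split("/")
        k = alleles.count(allele)
        if k:
            seen = True
        if row.group == "case":
            a += k * row.n_animals
            b += (2 - k) * row.n_animals
        else:
            c += k * row.n_animals
            d += (2 - k) * row.n_animals
    if rows and not seen:
        warnings.warn(f"allele {allele!r} absent from every genotype", stacklevel=2)
    return ContingencyTable2x2(a, b, c, d)


def _corrected_or_se(table: ContingencyTable2x2) -> tuple[float, float, bool]:
    if (table.a == 0 and table.b == 0) or (table.c == 0 and table.d == 0):
        raise ValidationError("odds ratio undefined: one group has no observations")
    a, b, c, d = table.corrected()
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_, se, table.has_zero_cell


def odds_ratio_haldane(table: ContingencyTable2x2) -> tuple[float, bool]:
    """(odds ratio, correction_applied) with the Haldane–Anscombe correction."""
    or_, _, corrected = _corrected_or_se(table)
    return or_, corrected


def critical_z(confidence: float, precision: int | None = 2) -> float:
    """Normal critical value for a two-sided interval.

    By default rounded to two decimals (1.96, 2.58, ...) — the textbook
    values conventionally used when such genotyping tables are analysed by
    hand or with epidemiology calculators, and the convention required to
    reproduce published intervals digit for digit. Pass ``precision=None``
    for the full-precision quantile.
    """
    if not 0 < confidence < 1:
        raise ValidationError(f"confidence must be in (0,1), got {confidence}")
    z = float(stats.norm.ppf(0.5 + confidence / 2))
    return round(z, precision) if precision is not None else z


def wald_interval(table: ContingencyTable2x2, confidence: float = 0.95,
                  z_precision: int | None = 2) -> tuple[float, float]:
    """Wald CI for the (corrected) odds ratio on the log scale."""
    or_, se, _ = _corrected_or_se(table)
    z = critical_z(confidence, z_precision)
    return math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se)


def wald_p(table: ContingencyTable2x2) -> float:
    """Two-sided Wald p-value for ln(OR) = 0."""
    or_, se, _ = _corrected_or_se(table)
    z = math.log(or_) / se
    return 2 * stats.norm.sf(abs(z))


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p (sum of hypergeometric probabilities <=
    that of the observed table)."""
    _, p = stats.fisher_exact([[table.a, table.b], [table.c, table.d]],
                              alternative="two-sided")
    return float(p)


def associate(
    rows: Sequence[GenotypeCountRow],
    allele: str,
    locus: int = 1,
    confidence: float = 0.95,
    method: str = "wald_haldane",
) -> AssociationResult:
    """Full association analysis of one allele at one locus."""
    table = build_allele_table(rows, allele, locus)
    or_, se, corrected = _corrected_or_se(table)
    lo, hi = wald_interval(table, confidence)
    z = math.log(or_) / se
    if method == "wald_haldane":
        p = wald_p(table)
    elif method == "fisher":
        p = fisher_exact(table)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return AssociationResult(or_, lo, hi, p, z, corrected, confidence, method)


def read_genotype_counts(path: str | Path) -> list[GenotypeCountRow]:
    """Read a genotyping count table (TSV/CSV).

    Columns: phenotype_label, group, genotype_locus1, [genotype_locus2],
    n_animals.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"phenotype_label", "group", "genotype_locus1", "n_animals"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"genotype count table {path} must have columns {sorted(required)}"
        )
    rows = []
    for _, r in df.iterrows():
        g2 = r.get("genotype_locus2")
        if g2 is not None and (pd.isna(g2) or g2 == ""):
            g2 = None
        rows.append(GenotypeCountRow(
            phenotype_label=str(r["phenotype_label"]),
            group=str(r["group"]).strip().lower(),
            genotype_locus1=str(r["genotype_locus1"]),
            genotype_locus2=g2,
            n_animals=int(r["n_animals"]),
        ))
    return rows
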