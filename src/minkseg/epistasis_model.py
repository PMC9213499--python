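"""Two-locus genotype -> coat-phenotype model for COPA and MITF alleles.

The model encodes the non-allelic interaction between two mink
depigmentation alleles:

* ``Cr`` — a codominant COPA allele (T at the candidate SNV; C is wild
  type). Heterozygotes (``C/T``) show the "white hat" pattern of white
  guard hairs on spine and head; homozygotes (``T/T``) are effectively
  completely white with dark eyes and normal hearing.
* ``h`` — the Hedlund-white MITF allele (A at the splice-donor SNV; G is
  wild type). Homozygotes (``A/A``) are completely white and deaf;
  heterozygotes (``G/A``) show ventral white spotting.

Double heterozygotes (``C/T``, ``G/A``) are completely white with dark
eyes and normal hearing — the epistatic interaction the model exists to
express: dorsal (Cr/+) and ventral (h/+) depigmentation zones fuse.

Genotype combinations never observed in the source cohort (``C/T A/A``
and ``T/T A/A``) are extrapolated to completely white; the rule set flags
them so downstream reports can distinguish observed from extrapolated
classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError

COPA_GENOTYPES = ("C/C", "C/T", "T/T")
MITF_GENOTYPES = ("G/G", "G/A", "A/A")


def _normalize(genotype: str, order: str) -> str:
    """Canonicalise an unphased diploid genotype string ("T/C" -> "C/T")."""
    alleles = genotype.strip().split("/")
    if len(alleles) != 2:
        raise ValidationError(f"genotype {genotype!r} is not two '/'-separated alleles")
    rank = {a: i for i, a in enumerate(order)}
    unknown = [a for a in alleles if a not in rank]
    if unknown:
        raise ValidationError(f"unknown allele(s) {unknown} in genotype {genotype!r}")
    return "/".join(sorted(alleles, key=rank.__getitem__))


@dataclass(frozen=True)
class TwoLocusGenotype:
    """Unphased diploid genotypes at the COPA and MITF loci.

    Alleles: COPA C (wild type) / T (Cr); MITF G (wild type) / A (h).
    Genotype strings are canonicalised (wild-type allele first).
    """

    copa: str
    mitf: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "copa", _normalize(self.copa, "CT"))
        object.__setattr__(self, "mitf", _normalize(self.mitf, "GA"))

    @staticmethod
    def all_genotypes() -> list["TwoLocusGenotype"]:
        return [TwoLocusGenotype(c, m) for c in COPA_GENOTYPES for m in MITF_GENOTYPES]


class CoatClass(str, Enum):
    STANDARD = "standard"
    WHITE_HAT = "white_hat"
    COMPLETELY_WHITE = "completely_white"
    HEDLUND_WHITE_DEAF = "hedlund_white_deaf"
    VENTRAL_SPOTTING = "ventral_spotting"
    WHITE_HAT_PLUS_SPOTTING = "white_hat_plus_spotting"


@dataclass(frozen=True)
class PhenotypeClass:
    label: CoatClass
    eye_colour: str = "dark"   # dark-eyed in every class of this model
    hearing: str = "normal"
    extrapolated: bool = False  # not observed in the source cohort


_DEFAULT_RULES: dict[tuple[str, str], PhenotypeClass] = {
    ("C/C", "G/G"): PhenotypeClass(CoatClass.STANDARD),
    ("C/C", "G/A"): PhenotypeClass(CoatClass.VENTRAL_SPOTTING),
    ("C/C", "A/A"): PhenotypeClass(CoatClass.HEDLUND_WHITE_DEAF, hearing="impaired"),
    ("C/T", "G/G"): PhenotypeClass(CoatClass.WHITE_HAT),
    ("C/T", "G/A"): PhenotypeClass(CoatClass.COMPLETELY_WHITE),
    ("C/T", "A/A"): PhenotypeClass(CoatClass.COMPLETELY_WHITE, extrapolated=True),
    ("T/T", "G/G"): PhenotypeClass(CoatClass.COMPLETELY_WHITE),
    ("T/T", "G/A"): PhenotypeClass(CoatClass.COMPLETELY_WHITE),
    ("T/T", "A/A"): PhenotypeClass(CoatClass.COMPLETELY_WHITE, extrapolated=True),
}


@dataclass
class PhenotypeRuleSet:
    """Total, deterministic map from all 9 two-locus genotypes to classes."""

    rules: dict[tuple[str, str], PhenotypeClass]

    def __post_init__(self) -> None:
        expected = {(c, m) for c in COPA_GENOTYPES for m in MITF_GENOTYPES}
        if set(self.rules) != expected:
            missing = expected - set(self.rules)
            extra = set(self.rules) - expected
            raise ValidationError(
                f"rule set must cover all 9 genotypes (missing {sorted(missing)}, "
                f"unexpected {sorted(extra)})"
            )

    def predict(self, g: TwoLocusGenotype) -> PhenotypeClass:
        return self.rules[(g.copa, g.mitf)]

    # plain-text (TSV) round trip so alternative rule hypotheses can be tested
    def to_table(self, path: str | Path) -> None:
        lines = ["copa\tmitf\tclass\thearing\textrapolated"]
        for (c, m) in [(c, m) for c in COPA_GENOTYPES for m in MITF_GENOTYPES]:
            p = self.rules[(c, m)]
            lines.append(f"{c}\t{m}\t{p.label.value}\t{p.hearing}\t{int(p.extrapolated)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_table(cls, path: str | Path) -> "PhenotypeRuleSet":
        rules = {}
        lines = Path(path).read_text().strip().splitlines()
        for line in lines[1:]:
            c, m, label, hearing, extra = line.split("\t")
            rules[(c, m)] = PhenotypeClass(CoatClass(label), hearing=hearing,
                                           extrapolated=bool(int(extra)))
        return cls(rules)


def default_rules() -> PhenotypeRuleSet:
    return PhenotypeRuleSet(dict(_DEFAULT_RULES))


def predict_phenotype(g: TwoLocusGenotype,
                      rules: PhenotypeRuleSet | None = None) -> PhenotypeClass:
    """Predicted coat class for a two-locus genotype under a rule set."""
    return (rules or default_rules()).predict(g)


@dataclass(frozen=True)
class ConcordanceRow:
    genotype: TwoLocusGenotype
    observed_label: str
    n_animals: int
    predicted: CoatClass
    observed_class: CoatClass
    consistent: bool


@dataclass(frozen=True)
class ConcordanceReport:
    rows: list[ConcordanceRow]

    @property
    def n_consistent(self) -> int:
        return sum(1 for r in self.rows if r.consistent)

    @property
    def n_inconsistent(self) -> int:
        return sum(1 for r in self.rows if not r.consistent)

    @property
    def n_animals(self) -> int:
        return sum(r.n_animals for r in self.rows)


def concordance_check(
    observations: Sequence[tuple[TwoLocusGenotype, str, int]],
    rules: PhenotypeRuleSet,
    label_map: Mapping[str, CoatClass],
) -> ConcordanceReport:
    """Mark each observed (genotype, phenotype label, n) row consistent iff
    the rule set's prediction matches the label's mapped coat class."""
    rows = []
    for genotype, label, n in observations:
        if label not in label_map:
            raise ValidationError(f"phenotype label {label!r} has no class mapping")
        predicted = rules.predict(genotype).label
        observed = CoatClass(label_map[label])
        rows.append(ConcordanceRow(genotype, label, n, predicted, observed,
                                   predicted == observed))
    return ConcordanceReport(rows)


def simulate_cross(
    parent1: TwoLocusGenotype,
    parent2: TwoLocusGenotype,
    n_offspring: int,
    seed: int,
    recombination_fraction: float = 0.5,
) -> list[TwoLocusGenotype]:
    """Mendelian sampling of offspring two-locus genotypes.

    Each parent transmits one allele per locus. With the default
    recombination fraction 0.5 the loci segregate independently (COPA and
    MITF lie on different chromosomes in carnivores); smaller fractions
    model linkage, treating each parent's genotype strings as haplotypes
    in the order written.
    """
    if n_offspring < 0:
        raise ValidationError("n_offspring must be >= 0")
    if not 0 <= recombination_fraction <= 0.5:
        raise ValidationError("recombination fraction must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    hap = [(p.copa.split("/"), p.mitf.split("/")) for p in (parent1, parent2)]
    # vectorised: haplotype pick per parent, then a recombination flip at MITF
    picks = rng.integers(2, size=(n_offspring, 2))
    flips = rng.random(size=(n_offspring, 2)) < recombination_fraction
    out = []
    for k in range(n_offspring):
        gametes = []
        for p_idx, (copa_alleles, mitf_alleles) in enumerate(hap):
            i = int(picks[k, p_idx])
            j = 1 - i if flips[k, p_idx] else i
            gametes.append((copa_alleles[i], mitf_alleles[j]))
        out.append(TwoLocusGenotype(f"{gametes[0][0]}/{gametes[1][0]}",
                                    f"{gametes[0][1]}/{gametes[1][1]}"))
    return out
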