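"""Published genotyping counts for the Black crystal mink cohort.

The study cohort behind the COPA/MITF analysis: 17 Black-crystal-phenotype
animals (10 heterozygous "white hat" carriers and 7 completely white,
dark-eyed, normally hearing animals) and 34 animals with other coat
colours. Genotypes are given at the COPA candidate SNV (alleles C/T; T is
the Cr allele) and the MITF splice-donor SNV (alleles G/A; A is the
Hedlund h allele).

These counts are the input data for the association and concordance
analyses; they are data, not expected test output.
"""

from __future__ import annotations

from .association import GenotypeCountRow
from .epistasis_model import CoatClass

#: "white hat" heterozygous carriers are flagged *, completely white
#: animals **, mirroring the published table's footnotes.
BLACK_CRYSTAL_GENOTYPING: tuple[GenotypeCountRow, ...] = (
    GenotypeCountRow("Black crystal*", "case", "T/C", "G/G", 10),
    GenotypeCountRow("Black crystal**", "case", "T/T", "G/G", 3),
    GenotypeCountRow("Black crystal**", "case", "T/T", "G/A", 1),
    GenotypeCountRow("Black crystal**", "case", "T/C", "G/A", 3),
    GenotypeCountRow("Standard dark brown", "control", "C/C", "G/G", 25),
    GenotypeCountRow("Violet", "control", "C/C", "G/G", 1),
    GenotypeCountRow("Royle pastel", "control", "C/C", "G/G", 1),
    GenotypeCountRow("Hedlund white", "control", "C/C", "A/A", 1),
    GenotypeCountRow("Moyle", "control", "C/C", "G/G", 1),
    GenotypeCountRow("Silverblue", "control", "C/C", "G/G", 3),
    GenotypeCountRow("Shadow Silverblue", "control", "C/C", "G/G", 1),
    GenotypeCountRow("Black cross", "control", "C/C", "G/G", 1),
)

#: free-text phenotype label -> coat class at the two modelled loci. Coat
#: colours governed by other genes (violet, moyle, ...) are wild type at
#: COPA and MITF, hence "standard" in this two-locus model.
PHENOTYPE_CLASS_MAP: dict[str, CoatClass] = {
    "Black crystal*": CoatClass.WHITE_HAT,
    "Black crystal**": CoatClass.COMPLETELY_WHITE,
    "Standard dark brown": CoatClass.STANDARD,
    "Violet": CoatClass.STANDARD,
    "Royle pastel": CoatClass.STANDARD,
    "Hedlund white": CoatClass.HEDLUND_WHITE_DEAF,
    "Moyle": CoatClass.STANDARD,
    "Silverblue": CoatClass.STANDARD,
    "Shadow Silverblue": CoatClass.STANDARD,
    "Black cross": CoatClass.STANDARD,
}


def load_genotyping_counts() -> list[GenotypeCountRow]:
    """The published two-locus genotyping counts (17 cases, 34 controls)."""
    return list(BLACK_CRYSTAL_GENOTYPING)
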