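"""Genotype-matrix I/O: VCF and phenotype tables.

The in-memory substrate of the pipeline is a dense :class:`GenotypeMatrix`:
an ordered list of biallelic variant sites by an ordered list of samples,
with one diploid genotype call and one read depth per cell. Multi-allelic
VCF records are decomposed into one biallelic site per ALT allele on read,
so every downstream stage can reason about a single alternate allele.

Coordinates are 1-based throughout, matching VCF convention; any interval
arithmetic elsewhere converts at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import ValidationError

logger = logging.getLogger(__name__)


class Role(str, Enum):
    CASE = "case"
    CONTROL = "control"
    UNASSIGNED = "unassigned"


class GT(int, Enum):
    """Diploid genotype state relative to a single alternate allele."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = 3


#: VCF textual representation of each genotype state (unphased).
_GT_TO_VCF = {GT.HOM_REF: "0/0", GT.HET: "0/1", GT.HOM_ALT: "1/1", GT.MISSING: "./."}


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    phenotype_label: str
    role: Role


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNV or indel site (1-based position)."""

    contig: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValidationError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.contig}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def __str__(self) -> str:  # mirrors the contig:pos ref/alt reporting style
        return f"{self.contig}:{self.pos} {self.ref}/{self.alt}"


@dataclass(frozen=True)
class GenotypeCall:
    gt: GT
    depth: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValidationError(f"depth must be non-negative, got {self.depth}")


class GenotypeMatrix:
    """Dense variants x samples grid of genotype calls with depths.

    Stored as two integer arrays (genotype codes and depths) so the
    segregation filter can operate vectorised.
    """

    def __init__(
        self,
        variants: Sequence[VariantSite],
        samples: Sequence[SampleRecord],
        gts: np.ndarray,
        depths: np.ndarray,
    ) -> None:
        gts = np.asarray(gts, dtype=np.int8)
        depths = np.asarray(depths, dtype=np.int32)
        expected = (len(variants), len(samples))
        if gts.shape != expected or depths.shape != expected:
            raise ValidationError(
                f"call grid shape {gts.shape}/{depths.shape} does not match "
                f"{len(variants)} variants x {len(samples)} samples"
            )
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample ids in matrix")
        if np.any(depths < 0):
            raise ValidationError("negative depth in matrix")
        self.variants = list(variants)
        self.samples = list(samples)
        self.gts = gts
        self.depths = depths

    @property
    def shape(self) -> tuple[int, int]:
        return self.gts.shape

    def call(self, variant_idx: int, sample_idx: int) -> GenotypeCall:
        return GenotypeCall(GT(int(self.gts[variant_idx, sample_idx])),
                            int(self.depths[variant_idx, sample_idx]))

    def sample_indices(self, role: Role) -> list[int]:
        return [i for i, s in enumerate(self.samples) if s.role is role]

    @classmethod
    def from_calls(
        cls,
        variants: Sequence[VariantSite],
        samples: Sequence[SampleRecord],
        calls: Sequence[Sequence[GenotypeCall]],
    ) -> "GenotypeMatrix":
        gts = np.array([[c.gt.value for c in row] for row in calls], dtype=np.int8)
        depths = np.array([[c.depth for c in row] for row in calls], dtype=np.int32)
        gts = gts.reshape(len(variants), len(samples))
        depths = depths.reshape(len(variants), len(samples))
        return cls(variants, samples, gts, depths)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.variants == other.variants
            and self.samples == other.samples
            and np.array_equal(self.gts, other.gts)
            and np.array_equal(self.depths, other.depths)
        )


def recode_genotype(allele_pair: tuple[int | None, int | None], alt_index: int) -> GT:
    """Re-code a raw diploid GT (allele indices) against one ALT allele.

    ``alt_index`` is the 1-based index of the ALT allele in the original
    record. Any allele that is not ``alt_index`` (reference or another ALT)
    counts as "other". A missing allele makes the whole call missing.
    """
    a, b = allele_pair
    if a is None or b is None:
        return GT.MISSING
    n_alt = int(a == alt_index) + int(b == alt_index)
    return (GT.HOM_REF, GT.HET, GT.HOM_ALT)[n_alt]


def read_vcf(
    path: str | Path,
    phenotype_map: Mapping[str, tuple[str, Role | str]],
) -> GenotypeMatrix:
    """Read a VCF 4.x file into a :class:`GenotypeMatrix`.

    ``phenotype_map`` maps sample id to ``(phenotype_label, role)``; roles
    may be given as strings. VCF samples absent from the map are dropped
    with a warning; map entries absent from the VCF raise.

    Multi-allelic records are decomposed into one biallelic site per ALT,
    with genotypes re-coded per alternate allele. ``./.`` becomes missing
    regardless of DP; absent DP becomes depth 0.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValidationError(f"malformed VCF {path}: {exc}") from exc

    vcf_samples = list(vcf.header.samples)
    missing_from_vcf = sorted(set(phenotype_map) - set(vcf_samples))
    if missing_from_vcf:
        raise ValidationError(
            "samples in phenotype map but not in VCF: " + ", ".join(missing_from_vcf)
        )
    kept = [s for s in vcf_samples if s in phenotype_map]
    dropped = [s for s in vcf_samples if s not in phenotype_map]
    if dropped:
        logger.warning("dropping %d VCF sample(s) without phenotype: %s",
                       len(dropped), ", ".join(dropped))
    samples = [
        SampleRecord(s, phenotype_map[s][0], Role(phenotype_map[s][1])) for s in kept
    ]

    variants: list[VariantSite] = []
    gt_rows: list[list[int]] = []
    dp_rows: list[list[int]] = []
    for line_no, rec in enumerate(vcf, start=1):
        alts = rec.alts or ()
        raw = []
        for s in kept:
            call = rec.samples[s]
            pair = call.get("GT", (None, None))
            if pair is None:
                pair = (None, None)
            dp = call.get("DP")
            raw.append((tuple(pair), int(dp) if dp is not None else 0))
        for k, alt in enumerate(alts, start=1):
            if alt is None or alt in ("*", "<NON_REF>"):
                continue
            try:
                site = VariantSite(rec.contig, rec.pos, rec.ref, str(alt), rec.id)
            except ValidationError as exc:
                raise ValidationError(f"record {line_no} of {path}: {exc}") from exc
            variants.append(site)
            gt_rows.append([recode_genotype(pair, k).value for pair, _ in raw])
            dp_rows.append([dp for _, dp in raw])
    vcf.close()

    n = len(variants)
    gts = np.array(gt_rows, dtype=np.int8).reshape(n, len(samples))
    depths = np.array(dp_rows, dtype=np.int32).reshape(n, len(samples))
    return GenotypeMatrix(variants, samples, gts, depths)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a matrix as an uncompressed VCF 4.2 file.

    Each biallelic site becomes one record; the output round-trips through
    :func:`read_vcf` losslessly for GT and DP. Written as plain text so the
    output is byte-deterministic for identical matrices.
    """
    path = Path(path)
    contigs = []
    for v in matrix.variants:
        if v.contig not in contigs:
            contigs.append(v.contig)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
    lines.append("\t".join(header[:-1] + ["INFO", "FORMAT"]
                           + [s.sample_id for s in matrix.samples]))
    for i, v in enumerate(matrix.variants):
        cells = [
            v.contig, str(v.pos), v.id or ".", v.ref, v.alt, ".", ".", ".", "GT:DP",
        ]
        for j in range(len(matrix.samples)):
            call = matrix.call(i, j)
            cells.append(f"{_GT_TO_VCF[call.gt]}:{call.depth}")
        lines.append("\t".join(cells))
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise ValidationError(f"cannot write VCF to {path}: {exc}") from exc


_VALID_ROLES = {r.value for r in Role}


def read_phenotype_table(path: str | Path) -> list[SampleRecord]:
    """Read a delimited phenotype table (columns: sample_id, phenotype_label, role).

    Tab- or comma-delimited; role tokens are case-insensitive. Duplicate
    sample ids and unknown role tokens are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"sample_id", "phenotype_label", "role"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"phenotype table {path} must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"duplicate sample_id(s) in {path}: {sorted(set(dup))}")
    records = []
    for _, row in df.iterrows():
        role_token = str(row["role"]).strip().lower()
        if role_token not in _VALID_ROLES:
            raise ValidationError(
                f"unknown role {row['role']!r} for sample {row['sample_id']!r} "
                f"(expected one of {sorted(_VALID_ROLES)})"
            )
        records.append(
            SampleRecord(str(row["sample_id"]), str(row["phenotype_label"]),
                         Role(role_token))
        )
    return records


def phenotype_map_from_records(
    records: Iterable[SampleRecord],
) -> dict[str, tuple[str, Role]]:
    """Convenience: phenotype table records -> the mapping read_vcf expects."""
    return {r.sample_id: (r.phenotype_label, r.role) for r in records}
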