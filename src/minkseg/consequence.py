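"""Minimal strand-aware coding-consequence annotation for SNVs.

Given a transcript model (exon/CDS intervals plus the genomic sequence) the
annotator translates a genomic single-nucleotide variant into coding-DNA
("c.") and protein ("p.") descriptions in simplified HGVS style:
``c.478C>T``, ``p.Arg160Cys`` for a coding substitution, ``c.33+1G>A`` for
the first intronic base past a donor site.

Coding positions are numbered 1..CDS-length from the A of the start ATG in
transcript orientation; for minus-strand transcripts genomic alleles are
reverse-complemented into cDNA space before codon lookup. Intronic
positions within ``SPLICE_WINDOW`` bases of an exon boundary are classed as
splice donor/acceptor (the canonical GT/AG dinucleotide window). Exonic
positions outside the CDS are classed UTR without c.-/c.* numbering.

Only the standard nuclear genetic code is used. Indels and MNVs are
rejected explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .errors import UnsupportedVariantError, ValidationError
from .variant_io import VariantSite

#: intronic distance (bp) from an exon boundary treated as a splice site
SPLICE_WINDOW = 2

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Category(str, Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    SPLICE_DONOR = "splice_donor"
    SPLICE_ACCEPTOR = "splice_acceptor"
    INTRONIC = "intronic"
    UTR = "utr"
    INTERGENIC = "intergenic"


#: severity ranking used by candidate prioritisation (lower = more severe)
SEVERITY_ORDER = {
    Category.STOP_GAINED: 0,
    Category.STOP_LOST: 0,
    Category.SPLICE_DONOR: 1,
    Category.SPLICE_ACCEPTOR: 1,
    Category.MISSENSE: 2,
    Category.SYNONYMOUS: 3,
    Category.UTR: 4,
    Category.INTRONIC: 4,
    Category.INTERGENIC: 4,
}


@dataclass(frozen=True)
class CdnaCoord:
    """A cDNA-space coordinate.

    ``kind`` is one of coding / intronic / utr / intergenic. For coding
    positions ``pos`` is the 1-based coding position and ``offset`` is 0;
    for intronic positions ``pos`` anchors the nearest exonic coding base
    and ``offset`` is the signed intronic distance (+ past a donor,
    - before an acceptor, in transcript orientation).
    """

    kind: str
    pos: int | None = None
    offset: int = 0

    def __str__(self) -> str:
        if self.kind == "coding":
            return str(self.pos)
        if self.kind == "intronic" and self.pos is not None:
            return f"{self.pos}{self.offset:+d}"
        return self.kind


@dataclass
class TranscriptModel:
    """Strand-aware exon/CDS model over an explicit genomic sequence.

    ``exons`` are 1-based inclusive genomic intervals sorted by genomic
    position; ``cds_start``/``cds_end`` are the genomic bounds of the CDS
    (irrespective of strand); ``genomic_seq`` is the contig sequence (or a
    slice of it whose first base sits at genomic position ``seq_offset``).
    """

    gene: str
    transcript_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    genomic_seq: str
    seq_offset: int = 1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValidationError(f"overlapping/unsorted exons in {self.transcript_id}")
        for s, e in self.exons:
            if s > e or s < 1:
                raise ValidationError(f"bad exon interval ({s},{e})")
        if self.cds_start > self.cds_end:
            raise ValidationError("cds_start > cds_end")
        self._index_coding()

    # -- sequence access -------------------------------------------------

    def base_at(self, genomic_pos: int) -> str:
        i = genomic_pos - self.seq_offset
        if i < 0 or i >= len(self.genomic_seq):
            raise ValidationError(
                f"position {genomic_pos} outside sequence of {self.transcript_id}"
            )
        return self.genomic_seq[i].upper()

    def _index_coding(self) -> None:
        # genomic positions of coding bases, in genomic order
        genomic: list[int] = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                genomic.extend(range(lo, hi + 1))
        if self.strand == "-":
            genomic = genomic[::-1]  # transcript orientation
        self._coding_order = genomic
        self._g2c = {g: i + 1 for i, g in enumerate(genomic)}

    @property
    def cds_len(self) -> int:
        return len(self._coding_order)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def cds_sequence(self) -> str:
        seq = "".join(self.base_at(g) for g in self._coding_order)
        # _coding_order is already 5'->3' in transcript orientation; minus-
        # strand bases still need complementing into transcript space
        return seq if self.strand == "+" else seq.translate(_COMPLEMENT)

    def protein_sequence(self) -> str:
        return str(Seq(self.cds_sequence()).translate())

    def validate(self) -> None:
        """Check biological well-formedness (length, start, stop, no internal stop)."""
        if self.cds_len == 0 or self.cds_len % 3 != 0:
            raise ValidationError(
                f"CDS length {self.cds_len} of {self.transcript_id} not a positive multiple of 3"
            )
        cds = self.cds_sequence()
        if cds[:3] != "ATG":
            raise ValidationError(f"CDS of {self.transcript_id} does not start with ATG")
        prot = str(Seq(cds).translate())
        if not prot.endswith("*"):
            raise ValidationError(f"CDS of {self.transcript_id} lacks a terminal stop")
        if "*" in prot[:-1]:
            raise ValidationError(f"internal stop codon in {self.transcript_id}")

    # -- coordinate mapping ----------------------------------------------

    def _exon_index_of(self, pos: int) -> int | None:
        for i, (s, e) in enumerate(self.exons):
            if s <= pos <= e:
                return i
        return None

    def cdna_position(self, genomic_pos: int) -> CdnaCoord:
        """Map a genomic position to cDNA space (see :class:`CdnaCoord`).

        Intronic positions anchor to the boundary on the nearer side of the
        intron; ties go to the donor side in transcript orientation.
        """
        lo, hi = self.span
        if genomic_pos < lo or genomic_pos > hi:
            return CdnaCoord("intergenic")
        c = self._g2c.get(genomic_pos)
        if c is not None:
            return CdnaCoord("coding", c, 0)
        if self._exon_index_of(genomic_pos) is not None:
            return CdnaCoord("utr")
        # intronic: locate the flanking exon boundaries
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 < genomic_pos < s2:
                d_left = genomic_pos - e1     # distance past left exon end
                d_right = s2 - genomic_pos    # distance before right exon start
                if self.strand == "+":
                    donor_anchor, donor_d = e1, d_left
                    acceptor_anchor, acceptor_d = s2, d_right
                else:
                    donor_anchor, donor_d = s2, d_right
                    acceptor_anchor, acceptor_d = e1, d_left
                if donor_d <= acceptor_d:
                    anchor, offset = donor_anchor, donor_d
                else:
                    anchor, offset = acceptor_anchor, -acceptor_d
                return CdnaCoord("intronic", self._g2c.get(anchor), offset)
        return CdnaCoord("intergenic")  # unreachable for well-formed exons

    def codon_of(self, cdna_pos: int) -> tuple[int, int]:
        """(1-based codon index, 0-based offset within codon) of a coding position."""
        if not 1 <= cdna_pos <= self.cds_len:
            raise ValidationError(
                f"cDNA position {cdna_pos} outside CDS 1..{self.cds_len}"
            )
        return (cdna_pos - 1) // 3 + 1, (cdna_pos - 1) % 3

    def coding_or_splice(self, genomic_pos: int, splice_window: int = SPLICE_WINDOW) -> bool:
        """True if the position is in a CDS exon part or within the intronic
        splice window of an exon/intron boundary."""
        coord = self.cdna_position(genomic_pos)
        if coord.kind == "coding":
            return True
        return coord.kind == "intronic" and abs(coord.offset) <= splice_window


@dataclass(frozen=True)
class Consequence:
    """cDNA- and protein-level description of a genomic SNV."""

    gene: str
    transcript_id: str
    variant: VariantSite
    category: Category
    cdna: CdnaCoord
    ref_base_cdna: str | None = None
    alt_base_cdna: str | None = None
    codon_index: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None

    @property
    def hgvs_c(self) -> str | None:
        if self.cdna.kind == "coding":
            return f"c.{self.cdna.pos}{self.ref_base_cdna}>{self.alt_base_cdna}"
        if self.cdna.kind == "intronic" and self.cdna.pos is not None:
            return (f"c.{self.cdna.pos}{self.cdna.offset:+d}"
                    f"{self.ref_base_cdna}>{self.alt_base_cdna}")
        return None

    @property
    def hgvs_p(self) -> str | None:
        if self.ref_aa is None or self.alt_aa is None:
            return None
        return f"p.{_aa3(self.ref_aa)}{self.codon_index}{_aa3(self.alt_aa)}"


def _aa3(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


def annotate_snv(
    variant: VariantSite,
    transcript: TranscriptModel,
    splice_window: int = SPLICE_WINDOW,
) -> Consequence:
    """Annotate a genomic SNV against one transcript model.

    The variant's REF allele is checked against the transcript's genomic
    sequence; a mismatch raises. Alleles are reverse-complemented into
    transcript orientation for minus-strand models before codon lookup.
    """
    if not variant.is_snv:
        raise UnsupportedVariantError(
            f"only SNVs are supported, got {variant.ref}>{variant.alt} at "
            f"{variant.contig}:{variant.pos}"
        )
    if variant.contig != transcript.contig:
        raise ValidationError(
            f"variant contig {variant.contig} does not match transcript contig "
            f"{transcript.contig}"
        )
    coord = transcript.cdna_position(variant.pos)
    if coord.kind == "intergenic":
        return Consequence(transcript.gene, transcript.transcript_id, variant,
                           Category.INTERGENIC, coord)

    observed = transcript.base_at(variant.pos)
    if observed != variant.ref.upper():
        raise ValidationError(
            f"REF mismatch at {variant.contig}:{variant.pos}: VCF says "
            f"{variant.ref}, sequence has {observed}"
        )
    if transcript.strand == "+":
        ref_c, alt_c = variant.ref.upper(), variant.alt.upper()
    else:
        ref_c, alt_c = revcomp(variant.ref.upper()), revcomp(variant.alt.upper())

    if coord.kind == "utr":
        return Consequence(transcript.gene, transcript.transcript_id, variant,
                           Category.UTR, coord, ref_c, alt_c)
    if coord.kind == "intronic":
        if 1 <= coord.offset <= splice_window:
            cat = Category.SPLICE_DONOR
        elif -splice_window <= coord.offset <= -1:
            cat = Category.SPLICE_ACCEPTOR
        else:
            cat = Category.INTRONIC
        return Consequence(transcript.gene, transcript.transcript_id, variant,
                           cat, coord, ref_c, alt_c)

    # coding
    codon_index, in_codon = transcript.codon_of(coord.pos)
    cds = transcript.cds_sequence()
    start = (codon_index - 1) * 3
    ref_codon = cds[start:start + 3]
    alt_codon = ref_codon[:in_codon] + alt_c + ref_codon[in_codon + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        cat = Category.SYNONYMOUS
    elif alt_aa == "*":
        cat = Category.STOP_GAINED
    elif ref_aa == "*":
        cat = Category.STOP_LOST
    else:
        cat = Category.MISSENSE
    return Consequence(transcript.gene, transcript.transcript_id, variant, cat,
                       coord, ref_c, alt_c, codon_index, ref_codon, alt_codon,
                       ref_aa, alt_aa)


def annotate_best(
    variant: VariantSite,
    transcripts: Sequence[TranscriptModel],
    splice_window: int = SPLICE_WINDOW,
) -> Consequence:
    """Annotate against every transcript on the variant's contig and return
    the most severe consequence (intergenic if none overlap)."""
    best: Consequence | None = None
    for tx in transcripts:
        if tx.contig != variant.contig:
            continue
        cons = annotate_snv(variant, tx, splice_window)
        if best is None or SEVERITY_ORDER[cons.category] < SEVERITY_ORDER[best.category]:
            best = cons
    if best is None:
        return Consequence("", "", variant, Category.INTERGENIC, CdnaCoord("intergenic"))
    return best


# -- GFF3 + FASTA loading ------------------------------------------------


def load_transcripts(
    gff3_path: str | Path,
    fasta_path: str | Path,
    validate: bool = True,
) -> list[TranscriptModel]:
    """Load transcript models from a GFF3 (gene/mRNA/exon/CDS) and a FASTA.

    Each mRNA feature becomes one :class:`TranscriptModel`; the gene symbol
    is taken from the parent gene's Name attribute (falling back to IDs).
    """
    from Bio import SeqIO

    gff3_path, fasta_path = Path(gff3_path), Path(fasta_path)
    for p in (gff3_path, fasta_path):
        if not p.exists():
            raise ValidationError(f"file not found: {p}")
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(str(gff3_path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    models: list[TranscriptModel] = []
    for mrna in db.features_of_type("mRNA"):
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        if not exons or not cds:
            raise ValidationError(f"mRNA {mrna.id} lacks exon or CDS features")
        gene_name = mrna.id
        for parent in db.parents(mrna, featuretype="gene"):
            gene_name = parent.attributes.get("Name", [parent.id])[0]
        if mrna.seqid not in seqs:
            raise ValidationError(f"contig {mrna.seqid} absent from {fasta_path}")
        model = TranscriptModel(
            gene=gene_name,
            transcript_id=mrna.id,
            contig=mrna.seqid,
            strand=mrna.strand,
            exons=exons,
            cds_start=min(s for s, _ in cds),
            cds_end=max(e for _, e in cds),
            genomic_seq=seqs[mrna.seqid],
        )
        if validate:
            model.validate()
        models.append(model)
    return models


def write_gff3(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as a minimal GFF3 (gene/mRNA/exon/CDS)."""
    lines = ["##gff-version 3"]
    for m in models:
        lo, hi = m.span
        gene_id = f"gene:{m.gene}"
        attrs = lambda **kw: ";".join(f"{k}={v}" for k, v in kw.items())  # noqa: E731
        lines.append("\t".join([m.contig, "minkseg", "gene", str(lo), str(hi), ".",
                                m.strand, ".", attrs(ID=gene_id, Name=m.gene)]))
        lines.append("\t".join([m.contig, "minkseg", "mRNA", str(lo), str(hi), ".",
                                m.strand, ".",
                                attrs(ID=m.transcript_id, Parent=gene_id, Name=m.transcript_id)]))
        cds_parts = []
        for i, (s, e) in enumerate(m.exons, start=1):
            lines.append("\t".join([m.contig, "minkseg", "exon", str(s), str(e), ".",
                                    m.strand, ".",
                                    attrs(ID=f"{m.transcript_id}.exon{i}",
                                          Parent=m.transcript_id)]))
            cs, ce = max(s, m.cds_start), min(e, m.cds_end)
            if cs <= ce:
                cds_parts.append((i, cs, ce))
        # phase: bases of the segment's first codon already seen upstream,
        # accumulated in transcript orientation
        order = cds_parts if m.strand == "+" else cds_parts[::-1]
        phases: dict[int, int] = {}
        seen = 0
        for i, cs, ce in order:
            phases[i] = (3 - seen % 3) % 3
            seen += ce - cs + 1
        for i, cs, ce in cds_parts:
            lines.append("\t".join([m.contig, "minkseg", "CDS", str(cs), str(ce),
                                    ".", m.strand, str(phases[i]),
                                    attrs(ID=f"{m.transcript_id}.cds{i}",
                                          Parent=m.transcript_id)]))
    Path(path).write_text("\n".join(lines) + "\n")
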