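"""Readers and writers for the formats the screen pipeline touches.

Variant calls travel as minimal VCF 4.2, gene structures as GFF3, sequences
as FASTA and the mutability panel as a two-column TSV.  Everything is parsed
into small frozen domain types with eager validation; coordinates are kept
1-based and closed throughout (both VCF and GFF3 use that convention), and
conversion to 0-based happens only at sequence-slicing time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

_DNA = set("ACGTN")


class VcfParseError(ValueError):
    """Structurally malformed VCF; message carries the offending line number."""


@dataclass(frozen=True)
class GenomeSequence:
    """One contig of an uppercase A/C/G/T/N reference sequence."""

    contig_name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.contig_name!r}: empty sequence")
        bad = set(self.sequence) - _DNA
        if bad:
            raise ValueError(
                f"contig {self.contig_name!r}: non-DNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based position."""
        return self.sequence[position - 1]


@dataclass(frozen=True, order=True)
class VariantCall:
    """A homozygous single-nucleotide substitution, 1-based."""

    contig: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(
                f"only single-nucleotide alleles are modeled: "
                f"{self.ref_allele}>{self.alt_allele} at {self.contig}:{self.position}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"ref and alt identical at {self.contig}:{self.position}"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity triple used for subtraction and deduplication."""
        return (self.contig, self.position, self.alt_allele)


@dataclass(frozen=True)
class StrainVariantSet:
    """One strain's variant calls, sorted by (contig, position), deduplicated."""

    strain_id: str
    variants: tuple[VariantCall, ...]

    @classmethod
    def from_calls(cls, strain_id: str, calls: Iterable[VariantCall]) -> "StrainVariantSet":
        seen: dict[tuple[str, int, str], VariantCall] = {}
        for c in calls:
            seen.setdefault(c.key, c)
        ordered = tuple(sorted(seen.values(), key=lambda c: (c.contig, c.position, c.alt_allele)))
        return cls(strain_id, ordered)

    def __post_init__(self) -> None:
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ValueError(f"strain {self.strain_id!r}: duplicate variant triples")
        coords = [(v.contig, v.position) for v in self.variants]
        if coords != sorted(coords):
            raise ValueError(f"strain {self.strain_id!r}: variants not coordinate-sorted")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)


@dataclass(frozen=True)
class GeneModel:
    """A gene's single CDS chain on a named contig.

    ``cds_intervals`` are 1-based closed [start, end] pairs, ascending and
    non-overlapping regardless of strand; minus-strand genes are handled at
    translation time by reverse-complementing the concatenated CDS.
    """

    gene_id: str
    contig: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    gene_span: tuple[int, int]
    complete: bool = True

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        prev_end = 0
        for start, end in self.cds_intervals:
            if start > end:
                raise ValueError(f"gene {self.gene_id!r}: interval {start}-{end} inverted")
            if start <= prev_end:
                raise ValueError(
                    f"gene {self.gene_id!r}: CDS intervals overlap or are unsorted"
                )
            prev_end = end
        if self.cds_intervals:
            lo = self.cds_intervals[0][0]
            hi = self.cds_intervals[-1][1]
            if not (self.gene_span[0] <= lo and hi <= self.gene_span[1]):
                raise ValueError(f"gene {self.gene_id!r}: gene_span does not contain CDS")
        if self.complete and self.cds_length % 3 != 0:
            raise ValueError(
                f"gene {self.gene_id!r}: complete CDS length {self.cds_length} "
                f"not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_intervals)

    def contains(self, position: int) -> bool:
        """Whether a 1-based position lies within the gene span."""
        return self.gene_span[0] <= position <= self.gene_span[1]

    def cds_offset(self, position: int) -> int | None:
        """0-based offset of a genomic position within the spliced CDS.

        The offset is counted in translation order (reverse-complement order
        for minus-strand genes); ``None`` when the position is not in any
        CDS interval.
        """
        running = 0
        for start, end in self.cds_intervals:
            if start <= position <= end:
                fwd = running + (position - start)
                if self.strand == "+":
                    return fwd
                return self.cds_length - 1 - fwd
            running += end - start + 1
        return None

    def near_cds_boundary(self, position: int, margin: int = 2) -> bool:
        """True for intronic/flanking positions within ``margin`` bp of a CDS edge."""
        if self.cds_offset(position) is not None:
            return False
        for start, end in self.cds_intervals:
            if start - margin <= position < start or end < position <= end + margin:
                return True
        return False


@dataclass(frozen=True)
class MutabilityTable:
    """Per-gene hit counts from a mutagenized reference panel of known size.

    The panel emulates the Million Mutation Project usage: a gene's count m
    over ``panel_size`` sequenced strains yields its per-genome hit
    probability m / panel_size.
    """

    panel_size: int
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.panel_size <= 0:
            raise ValueError("panel_size must be positive")
        for gene, m in self.counts.items():
            if m < 0:
                raise ValueError(f"gene {gene!r}: negative panel count {m}")
            if m > self.panel_size:
                raise ValueError(
                    f"gene {gene!r}: count {m} exceeds panel size {self.panel_size}"
                )

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.counts

    def __getitem__(self, gene_id: str) -> int:
        return self.counts[gene_id]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _validate_vcf_structure(path: Path) -> None:
    """Cheap structural pass so malformed files fail with a line number.

    htslib is deliberately lenient; this pass restores the strictness the
    pipeline wants (a fileformat line, 8+ tab-separated columns, integer POS).
    """
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##fileformat=VCF"):
            raise VcfParseError(f"{path}: line 1: missing ##fileformat=VCF header")
        saw_column_header = False
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_column_header = True
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise VcfParseError(
                    f"{path}: line {lineno}: expected >=8 tab-separated columns, "
                    f"got {len(fields)}"
                )
            if not fields[1].isdigit():
                raise VcfParseError(
                    f"{path}: line {lineno}: POS {fields[1]!r} is not a positive integer"
                )
        if not saw_column_header:
            raise VcfParseError(f"{path}: missing #CHROM column header line")


def read_vcf(path: str | Path, strain_id: str) -> StrainVariantSet:
    """Read SNV records from a VCF 4.x file into a :class:`StrainVariantSet`.

    Non-SNV records (indels, MNVs, symbolic alleles) are skipped and counted
    in a log message.  Multi-allelic records are split into one call per
    single-nucleotide alt allele.  Genotype fields are ignored: the screen
    analyzes homozygosed strains.
    """
    path = Path(path)
    _validate_vcf_structure(path)
    calls: list[VariantCall] = []
    skipped = 0
    for record in VCF(str(path)):
        ref = record.REF
        for alt in record.ALT:
            if len(ref) == 1 and len(alt) == 1 and set(ref + alt) <= set("ACGT"):
                calls.append(VariantCall(record.CHROM, record.POS, ref, alt))
            else:
                skipped += 1
    if skipped:
        logger.info("read_vcf(%s): skipped %d non-SNV allele(s)", path, skipped)
    return StrainVariantSet.from_calls(strain_id, calls)


def write_vcf(variant_set: StrainVariantSet, path: str | Path) -> None:
    """Write a minimal VCF 4.2 file (CHROM POS ID REF ALT QUAL FILTER INFO)."""
    path = Path(path)
    contigs = sorted({v.contig for v in variant_set})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=modscreen strain={variant_set.strain_id}\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variant_set:
            fh.write(
                f"{v.contig}\t{v.position}\t.\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\tPASS\t.\n"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse gene/CDS features of a GFF3 file into :class:`GeneModel` objects.

    CDS features may be parented to the gene directly or through an mRNA;
    intervals are collected per gene and must not overlap.  Genes whose total
    CDS length is not a multiple of 3 are kept but flagged incomplete.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        intervals: list[tuple[int, int]] = []
        for cds in db.children(gene, featuretype="CDS"):
            intervals.append((cds.start, cds.end))
        intervals.sort()
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"gene {gene.id!r}: overlapping CDS intervals "
                    f"{s1}-{e1} and {s2}-{e2}"
                )
        length = sum(e - s + 1 for s, e in intervals)
        models.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand,
                cds_intervals=tuple(intervals),
                gene_span=(gene.start, gene.end),
                complete=(length % 3 == 0),
            )
        )
    # orphan CDS check: every CDS must resolve to a gene ancestor
    gene_ids = {m.gene_id for m in models}
    for cds in db.features_of_type("CDS"):
        ancestors = {a.id for a in db.parents(cds, featuretype="gene")}
        if not ancestors & gene_ids:
            raise ValueError(f"CDS {cds.id or cds.start} has no parent gene")
    models.sort(key=lambda m: (m.contig, m.gene_span[0], m.gene_id))
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    """Emit GeneModels as GFF3 with gene and CDS features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            attrs = f"ID={m.gene_id}"
            fh.write(
                f"{m.contig}\tmodscreen\tgene\t{m.gene_span[0]}\t{m.gene_span[1]}"
                f"\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for start, end in m.cds_intervals:
                fh.write(
                    f"{m.contig}\tmodscreen\tCDS\t{start}\t{end}\t.\t{m.strand}"
                    f"\t0\tParent={m.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a genome FASTA into a dict of contig name -> GenomeSequence."""
    genome: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = GenomeSequence(rec.id, str(rec.seq).upper())
    if not genome:
        raise ValueError(f"{path}: no FASTA records")
    return genome


def write_genome(genome: Mapping[str, GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            seq = genome[name].sequence
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_proteome(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into a dict of name -> amino-acid string."""
    prots = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not prots:
        raise ValueError(f"{path}: no FASTA records")
    return prots


# ---------------------------------------------------------------------------
# Mutability TSV
# ---------------------------------------------------------------------------

def read_mutability_table(path: str | Path, panel_size: int) -> MutabilityTable:
    """Read a gene_id/count TSV (header required) into a MutabilityTable."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns (gene_id, count)")
    gene_col, count_col = df.columns[0], df.columns[1]
    counts = {str(g): int(c) for g, c in zip(df[gene_col], df[count_col])}
    return MutabilityTable(panel_size=panel_size, counts=counts)


def write_mutability_table(table: MutabilityTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tpanel_hits\n")
        for gene in sorted(table.counts):
            fh.write(f"{gene}\t{table.counts[gene]}\n")
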