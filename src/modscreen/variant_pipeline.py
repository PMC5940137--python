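"""Variant triage for the modifier screen.

Three steps reproduce the screen's downstream analysis: remove variant calls
shared with the unmutagenized parental strain, classify each remaining SNV's
coding effect against the gene models, and collapse per-strain annotations
into a gene x strain incidence matrix from which recurrently hit candidate
genes are read off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .formats_io import GeneModel, GenomeSequence, StrainVariantSet, VariantCall

#: Effects counted as candidate-qualifying by default: the screen tabulates
#: protein-altering coding variants, not synonymous or intronic changes.
DEFAULT_QUALIFYING = frozenset({"missense", "nonsense", "stop_loss", "start_loss"})

EFFECTS = (
    "intergenic",
    "intronic",
    "synonymous",
    "missense",
    "nonsense",
    "stop_loss",
    "start_loss",
)

_CODING_EFFECTS = frozenset({"synonymous", "missense", "nonsense", "stop_loss", "start_loss"})


class RefMismatchError(ValueError):
    """VCF ref allele disagrees with the reference genome at that position."""


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant call with its coding-effect annotation.

    ``codon_change`` and ``aa_change`` are populated only for coding effects;
    ``near_splice`` flags intronic/flanking positions within 2 bp of a CDS
    boundary (splice-site effects themselves are not modeled).
    """

    variant: VariantCall
    gene_id: str | None
    effect: str
    codon_change: tuple[str, str] | None = None
    aa_change: tuple[str, int, str] | None = None
    near_splice: bool = False

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if (self.gene_id is None) != (self.effect == "intergenic"):
            raise ValueError("gene_id must be None exactly for intergenic variants")
        if (self.codon_change is not None) != (self.effect in _CODING_EFFECTS):
            raise ValueError("codon_change present iff effect is coding")


def subtract_parental(
    strain: StrainVariantSet, parental: StrainVariantSet
) -> StrainVariantSet:
    """Remove calls present in the parental strain (same contig/pos/alt)."""
    parental_keys = {v.key for v in parental}
    kept = [v for v in strain if v.key not in parental_keys]
    return StrainVariantSet(strain.strain_id, tuple(kept))


def _spliced_cds(model: GeneModel, contig_seq: str) -> str:
    """Concatenated CDS in translation order (sense strand, 5'->3')."""
    parts = [contig_seq[start - 1 : end] for start, end in model.cds_intervals]
    cds = "".join(parts)
    if model.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def _classify_in_gene(
    v: VariantCall, model: GeneModel, contig_seq: str
) -> AnnotatedVariant:
    offset = model.cds_offset(v.position)
    if offset is None:
        return AnnotatedVariant(
            variant=v,
            gene_id=model.gene_id,
            effect="intronic",
            near_splice=model.near_cds_boundary(v.position),
        )
    cds = _spliced_cds(model, contig_seq)
    alt_base = v.alt_allele
    if model.strand == "-":
        alt_base = str(Seq(alt_base).reverse_complement())
    codon_index = offset // 3
    within = offset % 3
    ref_codon = cds[3 * codon_index : 3 * codon_index + 3]
    if len(ref_codon) < 3:
        # trailing partial codon of an incomplete model: no effect call possible
        return AnnotatedVariant(
            variant=v, gene_id=model.gene_id, effect="intronic", near_splice=False
        )
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == "*" and ref_aa != "*":
        effect = "nonsense"
    elif ref_aa == "*" and alt_aa != "*":
        effect = "stop_loss"
    elif codon_index == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        effect = "start_loss"
    elif ref_aa == alt_aa:
        effect = "synonymous"
    else:
        effect = "missense"
    return AnnotatedVariant(
        variant=v,
        gene_id=model.gene_id,
        effect=effect,
        codon_change=(ref_codon, alt_codon),
        aa_change=(ref_aa, codon_index + 1, alt_aa),
    )


def classify_variant(
    v: VariantCall,
    models: Sequence[GeneModel],
    genome: Mapping[str, GenomeSequence],
) -> list[AnnotatedVariant]:
    """Classify one SNV's effect against every gene model it falls in.

    Returns one annotation per overlapping gene so that incidence counting
    never silently drops a candidate; a variant outside every gene span
    yields a single intergenic annotation.  A ref allele disagreeing with
    the genome raises :class:`RefMismatchError` — this catches coordinate-
    convention bugs rather than papering over them.
    """
    if v.contig not in genome:
        raise KeyError(f"contig {v.contig!r} not in genome")
    contig_seq = genome[v.contig].sequence
    if v.position > len(contig_seq):
        raise RefMismatchError(
            f"{v.contig}:{v.position} beyond contig end ({len(contig_seq)})"
        )
    genome_base = contig_seq[v.position - 1]
    if genome_base != v.ref_allele:
        raise RefMismatchError(
            f"{v.contig}:{v.position}: VCF ref {v.ref_allele!r} != genome {genome_base!r}"
        )
    overlapping = [
        m for m in models if m.contig == v.contig and m.contains(v.position)
    ]
    if not overlapping:
        return [AnnotatedVariant(variant=v, gene_id=None, effect="intergenic")]
    return [_classify_in_gene(v, m, contig_seq) for m in overlapping]


def annotate_strain(
    variant_set: StrainVariantSet,
    models: Sequence[GeneModel],
    genome: Mapping[str, GenomeSequence],
) -> list[AnnotatedVariant]:
    """Classify every variant of a strain; flat list over variants x genes."""
    out: list[AnnotatedVariant] = []
    for v in variant_set:
        out.extend(classify_variant(v, models, genome))
    return out


@dataclass(frozen=True)
class GeneHitMatrix:
    """Boolean genes x strains incidence of qualifying coding variants.

    A cell is True when the strain carries at least one variant with a
    qualifying effect in that gene; multiple alleles in the same gene and
    strain still count that strain once.  Per-gene k values (number of hit
    strains) are the row sums.
    """

    hits: pd.DataFrame  # bool, index=genes, columns=strains
    qualifying_effects: frozenset[str]

    @property
    def genes(self) -> list[str]:
        return list(self.hits.index)

    @property
    def strains(self) -> list[str]:
        return list(self.hits.columns)

    @property
    def n_strains(self) -> int:
        return self.hits.shape[1]

    def k(self, gene_id: str) -> int:
        return int(self.hits.loc[gene_id].sum())

    def gene_k(self) -> pd.Series:
        """Per-gene number of strains hit, descending."""
        return self.hits.sum(axis=1).sort_values(ascending=False)


def build_hit_matrix(
    annotated: Mapping[str, Iterable[AnnotatedVariant]],
    qualifying: Iterable[str] = DEFAULT_QUALIFYING,
) -> GeneHitMatrix:
    """Collapse per-strain annotations into a GeneHitMatrix.

    ``annotated`` maps strain_id -> annotations (as from
    :func:`annotate_strain`).  Genes appear as rows if any strain has a
    qualifying variant in them; strains appear as columns unconditionally.
    """
    qualifying = frozenset(qualifying)
    unknown = qualifying - set(EFFECTS)
    if unknown:
        raise ValueError(f"unknown qualifying effects {sorted(unknown)}")
    strains = list(annotated)
    if len(set(strains)) != len(strains):
        raise ValueError("duplicate strain ids")
    per_strain_genes: dict[str, set[str]] = {}
    for strain_id, annots in annotated.items():
        per_strain_genes[strain_id] = {
            a.gene_id for a in annots if a.gene_id is not None and a.effect in qualifying
        }
    genes = sorted(set().union(*per_strain_genes.values()) if per_strain_genes else set())
    data = {
        s: [g in per_strain_genes[s] for g in genes] for s in strains
    }
    df = pd.DataFrame(data, index=genes, columns=strains, dtype=bool)
    return GeneHitMatrix(hits=df, qualifying_effects=qualifying)


def annotations_to_frame(annots: Iterable[AnnotatedVariant]) -> pd.DataFrame:
    """Tabular view of annotations (contig, pos, ref, alt, gene, effect, aa)."""
    rows = []
    for a in annots:
        aa = "" if a.aa_change is None else f"{a.aa_change[0]}{a.aa_change[1]}{a.aa_change[2]}"
        rows.append(
            {
                "contig": a.variant.contig,
                "pos": a.variant.position,
                "ref": a.variant.ref_allele,
                "alt": a.variant.alt_allele,
                "gene_id": a.gene_id or "",
                "effect": a.effect,
                "aa_change": aa,
                "near_splice": a.near_splice,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["contig", "pos", "ref", "alt", "gene_id", "effect", "aa_change", "near_splice"],
    )
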