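"""Parental subtraction, coding-effect classification and the hit matrix.

The classification tests rely on an independent brute-force oracle: rebuild
the full spliced CDS from the genome, substitute the base, translate both
complete proteins with Biopython and diff them — no reuse of the pipeline's
per-codon arithmetic.
"""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from modscreen.formats_io import GeneModel, GenomeSequence, StrainVariantSet, VariantCall
from modscreen.variant_pipeline import (
    DEFAULT_QUALIFYING,
    AnnotatedVariant,
    RefMismatchError,
    annotate_strain,
    build_hit_matrix,
    classify_variant,
    subtract_parental,
)

from conftest import make_set


# ---------------------------------------------------------------------------
# oracle: full-protein translate-and-diff
# ---------------------------------------------------------------------------

def oracle_effect(model, genome, variant):
    """Effect by rebuilding and translating the full ref and alt proteins."""
    seq = genome[model.contig].sequence
    alt_seq = seq[: variant.position - 1] + variant.alt_allele + seq[variant.position :]

    def spliced(s):
        cds = "".join(s[a - 1 : b] for a, b in model.cds_intervals)
        return str(Seq(cds).reverse_complement()) if model.strand == "-" else cds

    ref_cds, alt_cds = spliced(seq), spliced(alt_seq)
    if ref_cds == alt_cds:
        return "intronic" if model.contains(variant.position) else "intergenic"
    ref_prot = str(Seq(ref_cds).translate())
    alt_prot = str(Seq(alt_cds).translate())
    (diff_index,) = [i for i in range(len(ref_prot)) if ref_prot[i] != alt_prot[i]] or [None]
    if diff_index is None:
        return "synonymous"
    if alt_prot[diff_index] == "*":
        return "nonsense"
    if ref_prot[diff_index] == "*":
        return "stop_loss"
    if diff_index == 0 and ref_cds[:3] == "ATG":
        return "start_loss"
    return "missense"


def random_two_exon_gene(rng, strand):
    """Random genome containing one two-exon gene with a clean CDS."""
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < 10:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in stops:
            codons.append(c)
    cds = "ATG" + "".join(codons) + "TAA"
    cut = int(rng.integers(1, len(cds)))
    intron = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 30))))
    region = cds[:cut] + intron + cds[cut:]
    if strand == "-":
        region = str(Seq(region).reverse_complement())
        iv = [(0, len(cds) - cut - 1), (len(cds) - cut + len(intron), len(region) - 1)]
    else:
        iv = [(0, cut - 1), (cut + len(intron), len(region) - 1)]
    pad = "".join(rng.choice(list("ACGT"), size=25))
    start = len(pad) + 1
    seq = pad + region + pad
    model = GeneModel(
        gene_id="rg",
        contig="c",
        strand=strand,
        cds_intervals=tuple((start + a, start + b) for a, b in iv),
        gene_span=(start, start + len(region) - 1),
    )
    return model, {"c": GenomeSequence("c", seq)}


class TestSubtractParental:
    def test_self_subtraction_is_empty(self):
        s = make_set("a", [("chrI", 5, "G", "A"), ("chrII", 9, "C", "T")])
        assert len(subtract_parental(s, s)) == 0

    def test_empty_parental_is_identity(self):
        s = make_set("a", [("chrI", 5, "G", "A")])
        assert subtract_parental(s, StrainVariantSet("p", ())) == s

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_matches_set_difference_and_is_idempotent(self, data):
        def triples(label):
            return data.draw(
                st.lists(
                    st.tuples(
                        st.sampled_from(["chrI", "chrII"]),
                        st.integers(1, 200),
                        st.just("G"),
                        st.sampled_from(["A", "T", "C"]),
                    ),
                    max_size=30,
                ),
                label=label,
            )

        strain = make_set("s", triples("strain"))
        parental = make_set("p", triples("parental"))
        result = subtract_parental(strain, parental)
        expected = {v.key for v in strain} - {v.key for v in parental}
        assert {v.key for v in result} == expected
        assert subtract_parental(result, parental) == result


class TestClassifyVariant:
    def test_intergenic_outside_all_spans(self, toy_gene, toy_genome):
        (a,) = classify_variant(
            VariantCall("chrI", 5, "A", "G"), [toy_gene], toy_genome
        )
        assert a.effect == "intergenic" and a.gene_id is None

    def test_nonsense_at_toy_gene(self, toy_gene, toy_genome):
        # CDS ATG CAA GGA TAA; C>T at CDS base 4 turns codon 2 CAA -> TAA
        (a,) = classify_variant(
            VariantCall("chrI", 104, "C", "T"), [toy_gene], toy_genome
        )
        assert a.effect == "nonsense"
        assert a.codon_change == ("CAA", "TAA")
        assert a.aa_change == ("Q", 2, "*")

    def test_every_position_and_alt_agrees_with_oracle_on_toy_gene(
        self, toy_gene, toy_genome
    ):
        seq = toy_genome["chrI"].sequence
        for pos in range(101, 113):
            ref = seq[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                (a,) = classify_variant(
                    VariantCall("chrI", pos, ref, alt), [toy_gene], toy_genome
                )
                assert a.effect == oracle_effect(
                    toy_gene, toy_genome, VariantCall("chrI", pos, ref, alt)
                ), f"disagreement at {pos}{ref}>{alt}"

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("seed", range(8))
    def test_randomized_genes_agree_with_oracle_everywhere(self, strand, seed):
        rng = np.random.default_rng(1000 * (strand == "-") + seed)
        model, genome = random_two_exon_gene(rng, strand)
        seq = genome["c"].sequence
        for pos in range(1, len(seq) + 1):
            ref = seq[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                v = VariantCall("c", pos, ref, alt)
                (a,) = classify_variant(v, [model], genome)
                assert a.effect == oracle_effect(model, genome, v), (
                    f"{strand} strand seed {seed}: {pos}{ref}>{alt}: "
                    f"{a.effect} != oracle"
                )

    def test_ref_mismatch_is_an_error_naming_position(self, toy_gene, toy_genome):
        with pytest.raises(RefMismatchError, match="chrI:101"):
            classify_variant(VariantCall("chrI", 101, "C", "T"), [toy_gene], toy_genome)

    def test_intronic_and_near_splice_flag(self):
        rng = np.random.default_rng(3)
        model, genome = random_two_exon_gene(rng, "+")
        intron_positions = [
            p
            for p in range(model.gene_span[0], model.gene_span[1] + 1)
            if model.cds_offset(p) is None
        ]
        first_exon_end = model.cds_intervals[0][1]
        ref = genome["c"].sequence[first_exon_end]  # first intron base
        alt = "A" if ref != "A" else "C"
        (a,) = classify_variant(
            VariantCall("c", first_exon_end + 1, ref, alt), [model], genome
        )
        assert a.effect == "intronic" and a.near_splice
        deep = [p for p in intron_positions
                if not model.near_cds_boundary(p)]
        ref = genome["c"].sequence[deep[0] - 1]
        alt = "A" if ref != "A" else "C"
        (a,) = classify_variant(VariantCall("c", deep[0], ref, alt), [model], genome)
        assert a.effect == "intronic" and not a.near_splice

    def test_overlapping_genes_each_get_an_annotation(self, toy_gene, toy_genome):
        twin = GeneModel(
            gene_id="twin",
            contig="chrI",
            strand="+",
            cds_intervals=((101, 112),),
            gene_span=(101, 112),
        )
        annots = classify_variant(
            VariantCall("chrI", 104, "C", "T"), [toy_gene, twin], toy_genome
        )
        assert {a.gene_id for a in annots} == {"toy", "twin"}


class TestHitMatrix:
    def _annot(self, gene, effect, pos=104):
        return AnnotatedVariant(
            variant=VariantCall("chrI", pos, "C", "T"),
            gene_id=gene,
            effect=effect,
            codon_change=("CAA", "TAA") if effect in DEFAULT_QUALIFYING or effect == "synonymous" else None,
        )

    def test_single_missense_counts_once(self):
        m = build_hit_matrix({"s1": [self._annot("A", "missense")]})
        assert m.k("A") == 1

    def test_two_alleles_same_gene_same_strain_count_once(self):
        annots = [self._annot("A", "missense", 104), self._annot("A", "nonsense", 107)]
        m = build_hit_matrix({"s1": annots})
        assert m.k("A") == 1

    def test_synonymous_and_intronic_not_qualifying_by_default(self):
        m = build_hit_matrix(
            {"s1": [self._annot("A", "synonymous"),
                    AnnotatedVariant(VariantCall("chrI", 99, "A", "G"), "A", "intronic")]}
        )
        assert "A" not in m.genes
        m2 = build_hit_matrix(
            {"s1": [self._annot("A", "synonymous")]},
            qualifying={"synonymous"},
        )
        assert m2.k("A") == 1

    def test_column_sums_bounded_by_qualifying_gene_count(self, sim_screen):
        sim, parental, strains, table, truth = sim_screen
        annotated = {
            sid: annotate_strain(subtract_parental(vs, parental), sim.models, sim.genome)
            for sid, vs in strains.items()
        }
        matrix = build_hit_matrix(annotated)
        for sid, annots in annotated.items():
            qualifying_genes = {
                a.gene_id for a in annots if a.effect in DEFAULT_QUALIFYING
            }
            assert matrix.hits[sid].sum() <= len(qualifying_genes)

    def test_injected_gene_reaches_intended_k(self, sim_screen):
        sim, parental, strains, table, truth = sim_screen
        annotated = {
            sid: annotate_strain(subtract_parental(vs, parental), sim.models, sim.genome)
            for sid, vs in strains.items()
        }
        matrix = build_hit_matrix(annotated)
        for gene, k in truth.injected.items():
            assert matrix.k(gene) >= k  # background hits may add to injections
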