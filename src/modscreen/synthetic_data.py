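"""Synthetic study generator with recorded ground truth.

Emulates the downstream product of an EMS lethality-modifier screen: a
parental strain's variant background shared by S mutagenized survivor
strains, each carrying Poisson-distributed private SNVs with the EMS
substitution bias (mostly G:C -> A:T transitions), plus a handful of
"modifier" genes deliberately hit by qualifying coding variants in 2-4
strains.  A companion mutability panel (counts per gene over a fixed panel
of sequenced mutagenized strains) is drawn from a skewed distribution so the
recurrence scorer has realistic calibration input.  Separate generators
produce reference-normalized intensity tables and smFISH molecule counts at
the magnitudes reported for early-endoderm quantitation (end-1 stage means
47/109/214, set-3 mean 444 molecules per embryo).

Everything is driven by a single numpy Generator seeded from the config;
draw order is fixed (genome, then parental variants, then per-strain
backgrounds in strain order, then injections, then panel counts), so a seed
pins the full fixture byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .embryo_stats import SmFishEmbryo, write_smfish_table
from .formats_io import (
    GeneModel,
    GenomeSequence,
    MutabilityTable,
    StrainVariantSet,
    VariantCall,
    write_genome,
    write_gene_models,
    write_mutability_table,
    write_vcf,
)

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"

#: smFISH molecule-count magnitudes used as generator defaults.
END1_STAGE_MEANS = {"8-cell": 47.0, "16-cell": 109.0, "32-cell": 214.0}
SET3_MEAN = 444.0


@dataclass(frozen=True)
class ScreenSimConfig:
    """Shape and rates of a simulated screen.

    Defaults mirror the screen being emulated where its outcome is known
    (17 strains; injected modifiers hit 4x and 2x with panel count 6 and 4,
    the counts of the two genes actually recovered); genome shape, the
    per-strain mutation mean and the panel count model are toy-scale choices
    documented in the methods note.
    """

    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 60_000
    n_genes: int = 80
    n_strains: int = 17
    parental_variant_count: int = 50
    mutations_per_strain: float = 30.0
    ems_transition_fraction: float = 0.87
    injected_modifiers: tuple[tuple[str, int], ...] = (("g001", 4), ("g002", 2))
    injected_panel_counts: tuple[int, ...] = (6, 4)
    panel_size: int = 2007
    panel_count_mean: float = 30.0
    panel_count_shape: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ems_transition_fraction <= 1.0:
            raise ValueError("ems_transition_fraction must be in [0, 1]")
        for gene, k in self.injected_modifiers:
            if not 0 <= k <= self.n_strains:
                raise ValueError(f"injected k={k} for {gene!r} exceeds strain count")
        if len(self.injected_panel_counts) != len(self.injected_modifiers):
            raise ValueError("need one injected panel count per injected modifier")


@dataclass
class TruthRecord:
    """Ground truth emitted alongside the fixture files."""

    injected: dict[str, int] = field(default_factory=dict)
    parental_variants: list[tuple[str, int, str, str]] = field(default_factory=list)
    strain_variants: dict[str, list[tuple[str, int, str, str, str]]] = field(
        default_factory=dict
    )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


class ScreenSimulator:
    """Stateful simulator: genome first, then the screen, then fixtures."""

    def __init__(self, config: ScreenSimConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.genome: dict[str, GenomeSequence] | None = None
        self.models: list[GeneModel] | None = None
        self.screen: tuple | None = None  # cached simulate_screen() result

    # -- genome ----------------------------------------------------------

    def simulate_genome(self) -> tuple[dict[str, GenomeSequence], list[GeneModel]]:
        """Random contigs carrying non-overlapping multi-exon genes.

        Every CDS starts with ATG, ends with a stop, has length divisible
        by 3 and no internal stop codons; half the genes go on the minus
        strand.  Raises when the requested gene count cannot be placed.
        """
        cfg = self.config
        rng = self.rng
        contig_names = [f"chr{i + 1}" for i in range(cfg.n_contigs)]
        contig_arrays = {
            name: list(rng.choice(list(_BASES), size=cfg.contig_length))
            for name in contig_names
        }
        models: list[GeneModel] = []
        cursors = {name: 1 for name in contig_names}  # next free 1-based position
        for gene_index in range(cfg.n_genes):
            gene_id = f"g{gene_index + 1:03d}"
            contig = contig_names[gene_index % cfg.n_contigs]
            n_codons = int(rng.integers(40, 101))  # 120-300 bp CDS
            n_exons = int(rng.integers(2, 4))
            strand = "+" if rng.random() < 0.5 else "-"
            region, intervals_rel = self._build_gene_region(n_codons, n_exons, strand)
            gap = int(rng.integers(80, 200))
            start = cursors[contig] + gap
            end = start + len(region) - 1
            if end > cfg.contig_length:
                raise ValueError(
                    f"cannot place gene {gene_id}: contigs too short for "
                    f"{cfg.n_genes} genes"
                )
            arr = contig_arrays[contig]
            arr[start - 1 : end] = list(region)
            intervals = tuple(
                (start + s, start + e) for s, e in intervals_rel
            )
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    contig=contig,
                    strand=strand,
                    cds_intervals=intervals,
                    gene_span=(start, end),
                )
            )
            cursors[contig] = end + 1
        genome = {
            name: GenomeSequence(name, "".join(arr)) for name, arr in contig_arrays.items()
        }
        models.sort(key=lambda m: (m.contig, m.gene_span[0]))
        self.genome, self.models = genome, models
        return genome, models

    def _random_codon(self) -> str:
        while True:
            codon = "".join(self.rng.choice(list(_BASES), size=3))
            if codon not in _STOPS:
                return codon

    def _build_gene_region(
        self, n_codons: int, n_exons: int, strand: str
    ) -> tuple[str, list[tuple[int, int]]]:
        """Gene region sequence plus 0-based relative CDS intervals."""
        rng = self.rng
        cds = "ATG" + "".join(self._random_codon() for _ in range(n_codons - 2))
        cds += str(rng.choice(sorted(_STOPS)))
        # split into exons at random codon-agnostic cut points
        cuts = sorted(rng.choice(np.arange(1, len(cds)), size=n_exons - 1, replace=False))
        pieces = [cds[a:b] for a, b in zip([0] + list(cuts), list(cuts) + [len(cds)])]
        introns = ["".join(rng.choice(list(_BASES), size=int(rng.integers(20, 61))))
                   for _ in range(n_exons - 1)]
        region_parts: list[str] = []
        intervals: list[tuple[int, int]] = []
        offset = 0
        for i, piece in enumerate(pieces):
            intervals.append((offset, offset + len(piece) - 1))
            region_parts.append(piece)
            offset += len(piece)
            if i < len(introns):
                region_parts.append(introns[i])
                offset += len(introns[i])
        region = "".join(region_parts)
        if strand == "-":
            L = len(region)
            region = str(Seq(region).reverse_complement())
            intervals = sorted((L - 1 - e, L - 1 - s) for s, e in intervals)
        return region, intervals

    # -- screen ----------------------------------------------------------

    def simulate_screen(
        self,
    ) -> tuple[StrainVariantSet, dict[str, StrainVariantSet], MutabilityTable, TruthRecord]:
        """Parental + per-strain variant sets, mutability panel, ground truth."""
        if self.genome is None or self.models is None:
            raise RuntimeError("simulate_genome() must run before simulate_screen()")
        cfg = self.config
        rng = self.rng
        truth = TruthRecord(injected={g: k for g, k in cfg.injected_modifiers})

        parental_calls = self._random_snvs(cfg.parental_variant_count, ems_bias=False)
        parental = StrainVariantSet.from_calls("parental", parental_calls)
        truth.parental_variants = [
            (v.contig, v.position, v.ref_allele, v.alt_allele) for v in parental
        ]

        strain_ids = [f"strain_{i + 1:02d}" for i in range(cfg.n_strains)]
        private: dict[str, list[tuple[VariantCall, str]]] = {s: [] for s in strain_ids}
        for strain_id in strain_ids:
            n = int(rng.poisson(cfg.mutations_per_strain))
            for call in self._random_snvs(n, ems_bias=True):
                private[strain_id].append((call, "background"))

        model_by_id = {m.gene_id: m for m in self.models}
        for gene_id, k in cfg.injected_modifiers:
            if gene_id not in model_by_id:
                raise ValueError(f"injected modifier {gene_id!r} not in simulated genome")
            chosen = rng.choice(len(strain_ids), size=k, replace=False)
            for j, strain_idx in enumerate(chosen):
                want = "nonsense" if j % 2 == 0 else "missense"
                call = self._coding_variant(model_by_id[gene_id], want)
                private[strain_ids[int(strain_idx)]].append((call, f"injected:{want}"))

        strains: dict[str, StrainVariantSet] = {}
        for strain_id in strain_ids:
            calls = list(parental.variants) + [c for c, _ in private[strain_id]]
            strains[strain_id] = StrainVariantSet.from_calls(strain_id, calls)
            truth.strain_variants[strain_id] = [
                (c.contig, c.position, c.ref_allele, c.alt_allele, label)
                for c, label in sorted(private[strain_id], key=lambda t: (t[0].contig, t[0].position))
            ]

        table = self._simulate_mutability()
        self.screen = (parental, strains, table, truth)
        return self.screen

    def _random_snvs(self, n: int, ems_bias: bool) -> list[VariantCall]:
        """Random SNVs; with ems_bias, a configured fraction are G>A / C>T."""
        cfg = self.config
        rng = self.rng
        names = sorted(self.genome)
        calls: list[VariantCall] = []
        while len(calls) < n:
            contig = names[int(rng.integers(len(names)))]
            seq = self.genome[contig].sequence
            pos = int(rng.integers(1, len(seq) + 1))
            ref = seq[pos - 1]
            if ems_bias and rng.random() < cfg.ems_transition_fraction:
                if ref == "G":
                    alt = "A"
                elif ref == "C":
                    alt = "T"
                else:
                    continue  # resample until a G/C site is drawn
            else:
                alt = str(rng.choice([b for b in _BASES if b != ref]))
            calls.append(VariantCall(contig, pos, ref, alt))
        return calls

    def _coding_variant(self, model: GeneModel, want: str) -> VariantCall:
        """A single substitution in the gene guaranteed to have effect ``want``."""
        from .variant_pipeline import classify_variant  # local to avoid cycle

        seq = self.genome[model.contig].sequence
        candidates: list[VariantCall] = []
        for start, end in model.cds_intervals:
            for pos in range(start, end + 1):
                ref = seq[pos - 1]
                for alt in _BASES:
                    if alt == ref:
                        continue
                    v = VariantCall(model.contig, pos, ref, alt)
                    annots = classify_variant(v, [model], self.genome)
                    if any(a.gene_id == model.gene_id and a.effect == want for a in annots):
                        candidates.append(v)
        if not candidates:
            raise ValueError(
                f"gene {model.gene_id!r} too short to host a {want} variant"
            )
        return candidates[int(self.rng.integers(len(candidates)))]

    def _simulate_mutability(self) -> MutabilityTable:
        """Skewed per-gene panel counts: 1 + gamma-Poisson (negative binomial).

        The +1 shift keeps every gene's per-genome probability positive, as
        expected for genome-wide counts over ~2000 mutagenized strains.
        Injected modifiers get their configured counts.
        """
        cfg = self.config
        rng = self.rng
        counts: dict[str, int] = {}
        shape = cfg.panel_count_shape
        mean = max(cfg.panel_count_mean - 1.0, 0.1)
        for m in self.models:
            lam = rng.gamma(shape, mean / shape)
            counts[m.gene_id] = min(1 + int(rng.poisson(lam)), cfg.panel_size)
        for (gene_id, _), panel_count in zip(
            cfg.injected_modifiers, cfg.injected_panel_counts
        ):
            counts[gene_id] = panel_count
        return MutabilityTable(panel_size=cfg.panel_size, counts=counts)

    # -- fixtures --------------------------------------------------------

    def write_fixtures(self, outdir: str | Path) -> dict[str, Path]:
        """Emit genome.fa, models.gff3, VCFs, mutability.tsv and truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.genome is None:
            self.simulate_genome()
        parental, strains, table, truth = self.screen or self.simulate_screen()
        paths: dict[str, Path] = {}
        paths["genome"] = outdir / "genome.fa"
        write_genome(self.genome, paths["genome"])
        paths["models"] = outdir / "models.gff3"
        write_gene_models(self.models, paths["models"])
        paths["parental"] = outdir / "parental.vcf"
        write_vcf(parental, paths["parental"])
        for strain_id, vset in strains.items():
            p = outdir / f"{strain_id}.vcf"
            write_vcf(vset, p)
            paths[strain_id] = p
        paths["mutability"] = outdir / "mutability.tsv"
        write_mutability_table(table, paths["mutability"])
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(truth.to_json())
        return paths


# ---------------------------------------------------------------------------
# module-level convenience wrappers
# ---------------------------------------------------------------------------

def simulate_genome(config: ScreenSimConfig):
    return ScreenSimulator(config).simulate_genome()


def simulate_screen(config: ScreenSimConfig):
    """Genome + screen in one deterministic stream; returns the simulator too."""
    sim = ScreenSimulator(config)
    sim.simulate_genome()
    return sim, *sim.simulate_screen()


def simulate_intensity_data(
    folds: Mapping[str, float],
    noise_sd: float = 0.6,
    n_per_strain: int = 20,
    n_experiments: int = 2,
    reference_strain: str = "reference",
    seed: int = 0,
) -> pd.DataFrame:
    """Reference-normalized-intensity generator with batch structure.

    Each embryo's raw intensity is ``batch_scale * fold * lognormal noise``
    where the lognormal factor has unit mean (sigma = ``noise_sd`` on the
    log scale), so normalized values are unbiased for the true fold.  The
    reference strain is included in every experiment at fold 1.  Default
    noise_sd 0.6 matches the roughly 0.7 coefficient of variation seen in
    embryo immunofluorescence.
    """
    if any(f <= 0 for f in folds.values()):
        raise ValueError("folds must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    all_folds = {reference_strain: 1.0, **folds}
    for exp_index in range(n_experiments):
        exp_id = f"exp{exp_index + 1}"
        batch_scale = float(rng.uniform(100.0, 400.0))  # arbitrary camera units
        for strain, fold in all_folds.items():
            for embryo_index in range(n_per_strain):
                if noise_sd > 0:
                    noise = float(
                        rng.lognormal(mean=-0.5 * noise_sd**2, sigma=noise_sd)
                    )
                else:
                    noise = 1.0
                rows.append(
                    {
                        "strain_id": strain,
                        "experiment_id": exp_id,
                        "embryo_id": f"{exp_id}_{strain}_{embryo_index + 1}",
                        "intensity": batch_scale * fold * noise,
                    }
                )
    return pd.DataFrame(rows)


def simulate_smfish(
    stage_means: Mapping[str, float] | None = None,
    set3_mean: float = SET3_MEAN,
    n_per_group: int = 20,
    genotype_effect: float = 1.0,
    genotypes: Sequence[str] = ("N2", "pqn-82"),
    dispersion: float = 10.0,
    seed: int = 0,
) -> list[SmFishEmbryo]:
    """Per-embryo smFISH molecule counts, negative-binomial around stage means.

    ``genotype_effect`` multiplies the end-1 mean of every genotype after
    the first (1.0 = null).  ``dispersion`` is the gamma-Poisson size
    parameter (larger = closer to Poisson).
    """
    stage_means = dict(stage_means) if stage_means is not None else dict(END1_STAGE_MEANS)
    if any(m < 0 for m in stage_means.values()) or set3_mean < 0:
        raise ValueError("means must be non-negative")
    rng = np.random.default_rng(seed)

    def draw(mean: float) -> int:
        if mean == 0:
            return 0
        p = dispersion / (dispersion + mean)
        return int(rng.negative_binomial(dispersion, p))

    embryos: list[SmFishEmbryo] = []
    for stage, end1_mean in stage_means.items():
        for g_index, genotype in enumerate(genotypes):
            mean = end1_mean * (genotype_effect if g_index > 0 else 1.0)
            for _ in range(n_per_group):
                embryos.append(
                    SmFishEmbryo(
                        genotype=genotype,
                        stage=stage,
                        end1_count=draw(mean),
                        set3_count=draw(set3_mean),
                    )
                )
    return embryos


def write_intensity_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_smfish_fixture(embryos: list[SmFishEmbryo], path: str | Path) -> None:
    write_smfish_table(embryos, path)
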