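"""Screen-sizing arithmetic for EMS modifier screens.

Standard C. elegans accounting: each surviving fertile F1 from a mutagenized
P0 carries two independently mutagenized haploid genomes, so a screen of
n_p0 P0 animals each yielding f fertile F1 interrogates G = 2 * n_p0 * f
haploid genomes.  At a per-gene loss-of-function rate r (mutations per gene
per gamete), hits in a fully detectable gene arrive approximately Poisson
with mean G * r.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import poisson

#: Default per-gene loss-of-function rate: half of Brenner's 5e-4 per gene
#: at 50 mM EMS, reflecting the milder 25 mM regime.
DEFAULT_RATE_PER_GENE = 2.5e-4

#: Haploid genomes contributed per fertile F1 (two mutagenized gametes).
GENOMES_PER_F1 = 2


@dataclass(frozen=True)
class ScreenDesignParams:
    """Inputs of the genome-count arithmetic."""

    n_p0: int
    fertile_per_p0: float
    rate_per_gene: float = DEFAULT_RATE_PER_GENE
    genomes_per_f1: int = GENOMES_PER_F1

    def __post_init__(self) -> None:
        if self.n_p0 < 0 or self.fertile_per_p0 < 0 or self.rate_per_gene < 0:
            raise ValueError("screen-design parameters must be non-negative")

    @property
    def genomes(self) -> float:
        return haploid_genomes(self.n_p0, self.fertile_per_p0, self.genomes_per_f1)


def haploid_genomes(
    n_p0: int, fertile_per_p0: float, genomes_per_f1: int = GENOMES_PER_F1
) -> float:
    """Haploid genomes screened: n_p0 * fertile_per_p0 * genomes_per_f1."""
    if n_p0 < 0 or fertile_per_p0 < 0:
        raise ValueError("inputs must be non-negative")
    return n_p0 * fertile_per_p0 * genomes_per_f1


def expected_detections(genomes: float, rate_per_gene: float = DEFAULT_RATE_PER_GENE) -> float:
    """Expected number of independent hits in one fully detectable gene."""
    if genomes < 0 or rate_per_gene < 0:
        raise ValueError("inputs must be non-negative")
    return genomes * rate_per_gene


def detection_probability(
    genomes: float, rate_per_gene: float = DEFAULT_RATE_PER_GENE, k: int = 1
) -> float:
    """P(at least k independent hits), X ~ Poisson(genomes * rate_per_gene)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    lam = expected_detections(genomes, rate_per_gene)
    return float(poisson.sf(k - 1, lam))
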