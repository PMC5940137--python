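"""Mutability-calibrated recurrence probabilities for multiply-hit genes.

A gene hit in k of S independently mutagenized strains is scored against the
chance of that recurrence given the gene's intrinsic mutability, estimated
from a sequenced mutagenized panel (the Million Mutation Project pattern):
a gene with m hits across a panel of N strains has per-genome hit
probability p = m/N, and the chance of seeing exactly k hits among S screen
strains is the binomial point mass C(S,k) p^k (1-p)^(S-k).  The point mass
is the default score; the conventional upper tail P(X >= k) is available as
``mode="tail"`` and is the better choice when designing new screens.

Probabilities are reported both numerically and as one-significant-digit
scientific strings ("2.E-07"), the precision at which such screens are
customarily summarized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from scipy.stats import binom

from .formats_io import MutabilityTable
from .variant_pipeline import GeneHitMatrix

#: Strain count of the Million Mutation Project panel; overridable everywhere.
DEFAULT_PANEL_SIZE = 2007


@dataclass(frozen=True)
class RecurrenceResult:
    """Per-gene recurrence score."""

    gene_id: str
    k: int
    S: int
    m: int
    p: float
    prob: float
    prob_text: str
    m_imputed: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.prob <= 1.0):
            raise ValueError(f"gene {self.gene_id!r}: probability out of [0, 1]")


def per_genome_probability(m: int, panel_size: int = DEFAULT_PANEL_SIZE) -> float:
    """Per-haploid-genome hit probability p = m / panel_size."""
    if panel_size <= 0:
        raise ValueError("panel_size must be positive")
    if not 0 <= m <= panel_size:
        raise ValueError(f"panel count m={m} outside [0, {panel_size}]")
    return m / panel_size


def recurrence_probability(
    m: int,
    k: int,
    S: int,
    panel_size: int = DEFAULT_PANEL_SIZE,
    mode: str = "point",
    scale: float = 1.0,
) -> float:
    """Probability of k hit strains among S under mutability p = m/panel_size.

    mode="point" returns the exact-k binomial mass; mode="tail" returns
    P(X >= k).  ``scale`` optionally multiplies p to model a mutagenesis
    weaker (scale < 1) or stronger than the panel's; with the default 1.0
    the score is an over-estimate for a weaker screen.
    """
    if not 0 <= k <= S:
        raise ValueError(f"k={k} outside [0, S={S}]")
    p = per_genome_probability(m, panel_size) * scale
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"scaled p={p} outside [0, 1]")
    if mode == "point":
        return float(binom.pmf(k, S, p))
    if mode == "tail":
        return float(binom.sf(k - 1, S, p))
    raise ValueError(f"mode must be 'point' or 'tail', got {mode!r}")


def format_probability(prob: float) -> str:
    """One-significant-digit scientific string, half-up, e.g. 0.00183 -> "2.E-03".

    The mantissa carries into the exponent when it rounds to 10
    (0.095 -> "1.E-01"); exponents print with sign and two digits.
    """
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"probability {prob} outside [0, 1]")
    if prob == 0.0:
        return "0.E+00"
    d = Decimal(repr(float(prob)))
    exp = d.adjusted()
    digit = int(d.scaleb(-exp).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    if digit == 10:
        digit, exp = 1, exp + 1
    return f"{digit}.E{exp:+03d}"


def rank_candidates(
    matrix: GeneHitMatrix,
    table: MutabilityTable,
    min_k: int = 2,
    mode: str = "point",
    scale: float = 1.0,
) -> list[RecurrenceResult]:
    """Score and rank every gene hit in at least ``min_k`` strains.

    Results sort ascending by recurrence probability, ties broken by
    descending k then gene_id.  Genes absent from the mutability table are
    scored with the table's median count and flagged ``m_imputed``.
    """
    if min_k < 0:
        raise ValueError("min_k must be non-negative")
    S = matrix.n_strains
    fallback = _median_count(table)
    results: list[RecurrenceResult] = []
    for gene_id in matrix.genes:
        k = matrix.k(gene_id)
        if k < min_k:
            continue
        imputed = gene_id not in table
        m = fallback if imputed else table[gene_id]
        p = per_genome_probability(m, table.panel_size) * scale
        prob = recurrence_probability(m, k, S, table.panel_size, mode=mode, scale=scale)
        results.append(
            RecurrenceResult(
                gene_id=gene_id,
                k=k,
                S=S,
                m=m,
                p=p,
                prob=prob,
                prob_text=format_probability(prob),
                m_imputed=imputed,
            )
        )
    results.sort(key=lambda r: (r.prob, -r.k, r.gene_id))
    return results


def _median_count(table: MutabilityTable) -> int:
    counts = sorted(table.counts.values())
    if not counts:
        return 0
    return int(counts[len(counts) // 2])


def expected_multihit_genes(table: MutabilityTable, S: int, k: int = 2) -> float:
    """Expected number of genes hit in >= k of S strains by chance alone.

    Sums each gene's binomial upper-tail probability; the genome-wide
    multiplicity context for the per-gene scores.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    return float(
        sum(
            recurrence_probability(m, k, S, table.panel_size, mode="tail")
            for m in table.counts.values()
        )
    )


def results_to_frame(results: list[RecurrenceResult]) -> pd.DataFrame:
    """Candidate table mirroring the screen-summary layout."""
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "panel_hits": r.m,
                "n_strains_hit": r.k,
                "per_genome_p": r.p,
                "prob": r.prob,
                "prob_text": r.prob_text,
                "m_imputed": r.m_imputed,
            }
            for r in results
        ],
        columns=[
            "gene_id",
            "panel_hits",
            "n_strains_hit",
            "per_genome_p",
            "prob",
            "prob_text",
            "m_imputed",
        ],
    )


def binomial_coefficient(n: int, k: int) -> int:
    """Exact C(n, k); exposed for cross-checks of the closed-form score."""
    return math.comb(n, k)
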