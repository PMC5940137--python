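"""Embryo-quantitation statistics.

Covers the quantitative comparisons made downstream of the screen:
reference-normalized immunofluorescence intensities with fold-change
summaries and Wilcoxon-Mann-Whitney rank tests, notched-boxplot half-widths
(1.6 IQR / sqrt(n) per side), 2x2 count-table proportions, and per-embryo
smFISH transcript-ratio t-tests.

Intensity tables are plain DataFrames with columns
(strain_id, experiment_id, embryo_id, intensity); raw intensities are in
arbitrary background-corrected fluorescence units and only become
comparable across imaging sessions after per-experiment normalization to a
common reference strain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

INTENSITY_COLUMNS = ["strain_id", "experiment_id", "embryo_id", "intensity"]

#: Notch half-width constant of the median confidence interval.
NOTCH_CONSTANT = 1.6


@dataclass(frozen=True)
class SmFishEmbryo:
    """Per-embryo smFISH molecule counts of a target and a control mRNA."""

    genotype: str
    stage: str
    end1_count: int
    set3_count: int

    def __post_init__(self) -> None:
        if self.end1_count < 0 or self.set3_count < 0:
            raise ValueError("molecule counts must be non-negative")

    @property
    def ratio(self) -> float:
        if self.set3_count == 0:
            raise ZeroDivisionError("ratio undefined when control count is 0")
        return self.end1_count / self.set3_count


def _check_intensity_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in INTENSITY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"intensity table missing columns {missing}")
    if not np.isfinite(table["intensity"].to_numpy(float)).all():
        raise ValueError("non-finite intensity values")
    return table


def normalize_intensities(table: pd.DataFrame, reference_strain: str) -> pd.DataFrame:
    """Divide each intensity by its experiment's mean reference intensity.

    Every experiment batch must contain the reference strain; after
    normalization the reference strain's mean is exactly 1 within each
    batch, which removes session-to-session illumination and staining
    differences while preserving within-batch fold relationships.
    """
    table = _check_intensity_table(table)
    out = table.copy()
    for exp, sub in table.groupby("experiment_id"):
        ref = sub.loc[sub["strain_id"] == reference_strain, "intensity"]
        if ref.empty:
            raise ValueError(
                f"experiment {exp!r}: reference strain {reference_strain!r} absent"
            )
        ref_mean = float(ref.mean())
        if ref_mean <= 0:
            raise ValueError(f"experiment {exp!r}: non-positive reference mean")
        out.loc[sub.index, "intensity"] = sub["intensity"] / ref_mean
    return out


def fold_change_summary(normalized: pd.DataFrame, strain: str) -> tuple[float, float]:
    """Mean and sample SD (n-1) of a strain's normalized intensities."""
    values = _check_intensity_table(normalized).loc[
        normalized["strain_id"] == strain, "intensity"
    ].to_numpy(float)
    if values.size < 2:
        raise ValueError(f"strain {strain!r}: need >= 2 embryos, got {values.size}")
    return float(values.mean()), float(values.std(ddof=1))


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value.

    Exact enumeration when n_x + n_y <= 20 and there are no ties; otherwise
    the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if x.size + y.size <= 20 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(res.pvalue, 1.0))


def notch_halfwidth(values) -> float:
    """Notched-boxplot half-width 1.6 * IQR / sqrt(n).

    IQR uses linear-interpolation (type-7) quantiles.  Two notches that do
    not overlap indicate medians that differ at roughly the 5% level.
    """
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("need at least one observation")
    q25, q75 = np.quantile(values, [0.25, 0.75])
    return float(NOTCH_CONSTANT * (q75 - q25) / np.sqrt(values.size))


def proportion_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-group percent-positive summary of a labeled 2x2-style count table.

    ``counts`` needs columns (group, positive, negative); the output adds
    n = positive + negative and percent positive rounded half-up to the
    nearest integer.
    """
    for col in ("group", "positive", "negative"):
        if col not in counts.columns:
            raise ValueError(f"count table missing column {col!r}")
    pos = counts["positive"].to_numpy()
    neg = counts["negative"].to_numpy()
    if (pos < 0).any() or (neg < 0).any():
        raise ValueError("counts must be non-negative")
    n = pos + neg
    if (n == 0).any():
        raise ValueError("zero total count in a group")
    pct = 100.0 * pos / n
    # half-up, not banker's rounding, to match conventional table formatting
    pct_int = np.floor(pct + 0.5).astype(int)
    return pd.DataFrame(
        {
            "group": counts["group"].to_numpy(),
            "positive": pos,
            "negative": neg,
            "n": n,
            "percent_positive": pct_int,
        }
    )


def smfish_ratio_test(
    embryos,
    genotype_a: str,
    genotype_b: str,
    stage: str,
    equal_var: bool = True,
) -> float:
    """Two-sided t-test on per-embryo end-1/set-3 ratios at one stage.

    Student's pooled-variance t by default; ``equal_var=False`` switches to
    Welch.  Needs >= 2 embryos per genotype at the stage.
    """
    ratios = {genotype_a: [], genotype_b: []}
    for e in embryos:
        if e.stage == stage and e.genotype in ratios and e.set3_count > 0:
            ratios[e.genotype].append(e.ratio)
    a = np.asarray(ratios[genotype_a], float)
    b = np.asarray(ratios[genotype_b], float)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"need >= 2 embryos per genotype at stage {stage!r}: "
            f"{genotype_a}={a.size}, {genotype_b}={b.size}"
        )
    if a.size == b.size and np.allclose(np.sort(a), np.sort(b)):
        return 1.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.pvalue)


def read_intensity_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return _check_intensity_table(df)


def read_count_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_smfish_table(path) -> list[SmFishEmbryo]:
    df = pd.read_csv(path, sep="\t")
    return [
        SmFishEmbryo(
            genotype=str(r.genotype),
            stage=str(r.stage),
            end1_count=int(r.end1_count),
            set3_count=int(r.set3_count),
        )
        for r in df.itertuples()
    ]


def write_smfish_table(embryos, path) -> None:
    pd.DataFrame(
        [
            {
                "genotype": e.genotype,
                "stage": e.stage,
                "end1_count": e.end1_count,
                "set3_count": e.set3_count,
            }
            for e in embryos
        ]
    ).to_csv(path, sep="\t", index=False)
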