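"""Group comparison workflow for per-neuron observations.

The workflow mirrors standard practice for this kind of data: screen each
metric with Shapiro-Wilk normality and Levene variance-homogeneity tests;
compare two groups with an unpaired t-test (normal) or Mann-Whitney U
(non-parametric); compare more than two groups with a Kruskal-Wallis
omnibus test followed by Dunn's pairwise test with Holm multiplicity
correction.  Descriptive summaries use Tukey boxplot conventions
(median, mean, quartiles, whiskers at the most extreme points within
1.5 x IQR).

Multi-level (animal random effect) models are out of scope; a warning is
attached when an ``animal_id`` grouping is present so users know a mixed
model may be warranted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScreenFlags",
    "Descriptives",
    "ComparisonReport",
    "screen",
    "compare",
    "describe",
    "dunn_test",
    "normalize_to_control",
]

ALPHA = 0.05


@dataclass(frozen=True)
class ScreenFlags:
    shapiro_p: dict
    levene_p: float
    normal: bool
    small_groups: tuple[str, ...] = ()


@dataclass(frozen=True)
class Descriptives:
    n: int
    median: float
    mean: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float


@dataclass(frozen=True)
class ComparisonReport:
    test: str
    statistic: float
    p_value: float
    flags: ScreenFlags
    groups: dict
    descriptives: dict
    posthoc: pd.DataFrame | None = None
    warnings: tuple[str, ...] = ()


def screen(groups: dict[str, np.ndarray], alpha: float = ALPHA) -> ScreenFlags:
    """Per-group Shapiro-Wilk p and across-group Levene p.

    The data are treated as normal only when every group passes
    Shapiro-Wilk at ``alpha``; groups with fewer than 3 observations
    cannot be screened and force the non-parametric path.
    """
    shapiro_p: dict[str, float] = {}
    small: list[str] = []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 3:
            small.append(name)
            shapiro_p[name] = float("nan")
        else:
            shapiro_p[name] = float(sps.shapiro(vals).pvalue)
    arrays = [np.asarray(v, float) for v in groups.values() if len(v) >= 3]
    levene_p = float(sps.levene(*arrays).pvalue) if len(arrays) >= 2 else float("nan")
    normal = not small and all(p > alpha for p in shapiro_p.values())
    return ScreenFlags(shapiro_p, levene_p, normal, tuple(small))


def describe(values: np.ndarray) -> Descriptives:
    """Tukey boxplot summary: median, mean, type-7 quartiles and whiskers at
    the most extreme data points within 1.5 x IQR of the quartiles."""
    v = np.asarray(values, dtype=float)
    if len(v) < 1:
        raise ValueError("describe requires at least one observation")
    q1, q3 = np.quantile(v, [0.25, 0.75])  # linear interpolation (type 7)
    iqr = q3 - q1
    inside = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
    return Descriptives(len(v), float(np.median(v)), float(v.mean()),
                        float(q1), float(q3), float(inside.min()), float(inside.max()))


def dunn_test(groups: dict[str, np.ndarray],
              p_adjust: str | None = "holm") -> pd.DataFrame:
    """Dunn's post-hoc test on pooled ranks with tie correction.

    For groups i, j with mean pooled ranks Rbar_i, Rbar_j over N total
    observations, z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))
    where T = sum(t^3 - t) / (12 (N - 1)) over tie groups; two-sided normal
    p-values, optionally Holm-adjusted.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    sizes: dict[str, int] = {}
    start = 0
    for g, a in zip(names, arrays):
        mean_rank[g] = float(ranks[start:start + len(a)].mean())
        sizes[g] = len(a)
        start += len(a)
    _, counts = np.unique(pooled, return_counts=True)
    ties = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - ties

    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            gi, gj = names[i], names[j]
            se = np.sqrt(var_base * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
            z = (mean_rank[gi] - mean_rank[gj]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group1": gi, "group2": gj, "z": z, "p_raw": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if p_adjust is not None and len(df):
        df["p_corrected"] = multipletests(df["p_raw"], method=p_adjust)[1]
    return df


def compare(groups: dict[str, np.ndarray], flags: ScreenFlags | None = None,
            animal_ids: dict[str, np.ndarray] | None = None) -> ComparisonReport:
    """Test-selection workflow over >= 2 groups of per-neuron values.

    Two groups: unpaired t-test when screening passed, otherwise
    Mann-Whitney U.  More than two: Kruskal-Wallis omnibus, then Dunn
    pairwise with Holm correction (post hoc only after the omnibus).
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups to compare")
    if flags is None:
        flags = screen(groups)
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    notes: list[str] = []
    if animal_ids:
        n_animals = {g: len(np.unique(a)) for g, a in animal_ids.items()}
        if any(n > 1 for n in n_animals.values()):
            notes.append(
                "observations cluster within animals; a multi-level (animal "
                "random effect) model may be warranted and is not fitted here")
    posthoc = None
    if len(groups) == 2:
        if flags.normal:
            res = sps.ttest_ind(*arrays)
            test = "t-test"
        else:
            res = sps.mannwhitneyu(*arrays, alternative="two-sided")
            test = "mann-whitney-u"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        res = sps.kruskal(*arrays)
        test = "kruskal-wallis"
        stat, p = float(res.statistic), float(res.pvalue)
        posthoc = dunn_test(groups, p_adjust="holm")
    desc = {g: describe(v) for g, v in groups.items()}
    return ComparisonReport(test, stat, p, flags, {g: len(v) for g, v in groups.items()},
                            desc, posthoc, tuple(notes))


def normalize_to_control(df: pd.DataFrame, value_col: str, control: str,
                         condition_col: str = "condition",
                         experiment_col: str = "experiment_id") -> pd.Series:
    """Divide each value by the mean of the control condition within its
    experiment block (per-experiment normalization to the control)."""
    ctrl_means = (df[df[condition_col] == control]
                  .groupby(experiment_col)[value_col].mean())
    missing = set(df[experiment_col].unique()) - set(ctrl_means.index)
    if missing:
        raise ValueError(f"experiments without a {control!r} control block: {sorted(missing)}")
    out = df[value_col] / df[experiment_col].map(ctrl_means)
    return out.rename(f"{value_col}_norm")
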