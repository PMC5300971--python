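"""Nonparametric group comparisons implemented from their formulas.

Tie-corrected Kruskal-Wallis (chi-square approximation), Dunn's pairwise
posttest (two-sided normal z with Bonferroni adjustment over all pairs,
the Prism convention), Spearman rank correlation (Pearson on mid-ranks,
t approximation) and simple least-squares regression, plus a cohort
report that runs every variable through KW + Dunn per patient group.

Mid-ranks are used everywhere; the KW tie-correction factor is
1 - sum(t^3 - t)/(N^3 - N) over tie groups. Only large-sample
approximations are provided (chi-square / normal / t); p-values on very
small groups are approximate.

Significance stars follow the usual figure convention:
* p < 0.05, ** p < 0.01, *** p < 0.001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata, t as t_dist

from . import synthetic as _syn

logger = logging.getLogger(__name__)

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for cut, stars in STAR_THRESHOLDS:
        if p < cut:
            return stars
    return ""


def _tie_term(all_values: np.ndarray) -> float:
    """sum(t^3 - t) over groups of tied values."""
    _, counts = np.unique(all_values, return_counts=True)
    return float((counts.astype(float) ** 3 - counts).sum())


@dataclass
class RankTestResult:
    """Result of a rank test (H for KW, z for a Dunn pair)."""

    statistic: float
    df: int
    p_raw: float
    p_adjusted: float
    adjustment: str
    group_labels: tuple
    mean_ranks: tuple[float, ...]
    tie_correction: float
    stars: str = ""
    low_power: bool = False

    def __post_init__(self) -> None:
        self.stars = significance_stars(self.p_adjusted)


@dataclass
class CorrelationResult:
    """Spearman rho or least-squares fit summary."""

    n: int
    rho: float | None = None
    slope: float | None = None
    intercept: float | None = None
    r_squared: float | None = None
    p: float = float("nan")


def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    return arrays


def kruskal_wallis(
    groups: Sequence[Sequence[float]], labels: Sequence | None = None
) -> RankTestResult:
    """Tie-corrected Kruskal-Wallis H test.

    H = [12/(N(N+1)) * sum R_g^2/n_g - 3(N+1)] / (1 - sum(t^3-t)/(N^3-N)),
    with p from the chi-square distribution on k-1 df. All-identical data
    give H = 0, p = 1.
    """
    arrays = _check_groups(groups)
    labels = tuple(labels) if labels is not None else tuple(range(len(arrays)))
    pooled = np.concatenate(arrays)
    N = len(pooled)
    ranks = rankdata(pooled)  # mid-ranks
    mean_ranks = []
    rank_sum_sq = 0.0
    start = 0
    for a in arrays:
        r = ranks[start : start + len(a)]
        start += len(a)
        mean_ranks.append(float(r.mean()))
        rank_sum_sq += r.sum() ** 2 / len(a)
    tie = _tie_term(pooled)
    correction = 1.0 - tie / (N**3 - N) if N > 1 else 1.0
    if correction <= 0:  # every value identical
        return RankTestResult(
            statistic=0.0, df=len(arrays) - 1, p_raw=1.0, p_adjusted=1.0,
            adjustment="none", group_labels=labels,
            mean_ranks=tuple(mean_ranks), tie_correction=1.0,
        )
    H = (12.0 / (N * (N + 1)) * rank_sum_sq - 3.0 * (N + 1)) / correction
    H = max(H, 0.0)
    df = len(arrays) - 1
    p = float(chi2.sf(H, df))
    return RankTestResult(
        statistic=H, df=df, p_raw=p, p_adjusted=p, adjustment="none",
        group_labels=labels, mean_ranks=tuple(mean_ranks),
        tie_correction=correction,
    )


def dunn_posttest(
    groups: Sequence[Sequence[float]],
    labels: Sequence | None = None,
    adjustment: str = "bonferroni",
) -> list[RankTestResult]:
    """Dunn's pairwise rank comparisons after a Kruskal-Wallis test.

    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)]
    with T = sum(t^3 - t); two-sided p from the normal distribution,
    Bonferroni-adjusted over all k(k-1)/2 pairs by default. Pairs with a
    singleton group are computed but flagged low-power.
    """
    if adjustment not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    arrays = _check_groups(groups)
    labels = tuple(labels) if labels is not None else tuple(range(len(arrays)))
    pooled = np.concatenate(arrays)
    N = len(pooled)
    ranks = rankdata(pooled)
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(float(ranks[start : start + len(a)].mean()))
        start += len(a)
    tie = _tie_term(pooled)
    base_var = N * (N + 1) / 12.0 - (tie / (12.0 * (N - 1)) if N > 1 else 0.0)
    n_pairs = len(arrays) * (len(arrays) - 1) // 2
    out = []
    for i, j in combinations(range(len(arrays)), 2):
        ni, nj = len(arrays[i]), len(arrays[j])
        denom = np.sqrt(base_var * (1.0 / ni + 1.0 / nj))
        z = (mean_ranks[i] - mean_ranks[j]) / denom if denom > 0 else 0.0
        p = float(2.0 * norm.sf(abs(z))) if denom > 0 else 1.0
        p_adj = min(1.0, p * n_pairs) if adjustment == "bonferroni" else p
        out.append(
            RankTestResult(
                statistic=float(z), df=0, p_raw=p, p_adjusted=p_adj,
                adjustment=adjustment, group_labels=(labels[i], labels[j]),
                mean_ranks=(mean_ranks[i], mean_ranks[j]),
                tie_correction=1.0 - tie / (N**3 - N) if N > 1 else 1.0,
                low_power=min(ni, nj) < 2,
            )
        )
    return out


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation: Pearson correlation of mid-ranks, with a
    t-approximation p-value (needs n >= 3 and non-constant ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx, ry = rankdata(x), rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        logger.warning("spearman undefined: zero variance in ranks")
        return CorrelationResult(n=n, rho=float("nan"), p=float("nan"))
    rho = float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))
    rho = float(np.clip(rho, -1.0, 1.0))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t_stat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * t_dist.sf(abs(t_stat), n - 2))
    return CorrelationResult(n=n, rho=rho, p=p)


def linear_regression(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Simple least-squares regression of y on x with r^2 and a t-test on
    the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise ValueError("var(x) = 0: slope undefined")
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if n > 2 and ss_res > 0:
        se = np.sqrt(ss_res / (n - 2) / sxx)
        p = float(2.0 * t_dist.sf(abs(slope) / se, n - 2))
    else:
        p = 0.0
    return CorrelationResult(
        n=n, slope=float(slope), intercept=intercept, r_squared=float(r2), p=p
    )


# ---------------------------------------------------------------------------
# cohort report

def _iqr(values: np.ndarray) -> tuple[float, float]:
    return tuple(np.percentile(values, [25.0, 75.0]))


def group_report(
    freq_matrix: pd.DataFrame | None,
    metadata: pd.DataFrame | None,
    grouping: Mapping[str, str],
    metadata_fields: Sequence[str] | None = None,
    adjustment: str = "bonferroni",
) -> pd.DataFrame:
    """Compare every variable between patient groups.

    Variables are the population-frequency columns (``freq_matrix`` rows
    indexed by patient) and the numeric metadata fields (T0 rows). Each
    output row holds group medians with IQR, the KW p-value, and the
    Dunn pairwise adjusted p-values with significance stars. Variables
    missing for every patient are skipped with a warning.
    """
    assign = dict(grouping)
    group_labels = sorted(set(assign.values()))

    variables: list[tuple[str, pd.Series]] = []
    if freq_matrix is not None:
        for pop in freq_matrix.columns:
            variables.append((pop, freq_matrix[pop]))
    if metadata is not None:
        t0 = metadata[metadata["timepoint"] == "T0"]
        t0 = t0.set_index("patient_id")
        fields = (
            list(metadata_fields)
            if metadata_fields is not None
            else [f for f in _syn.METADATA_FIELDS if f in t0.columns]
        )
        for f in fields:
            variables.append((f, pd.to_numeric(t0[f], errors="coerce")))

    rows = []
    for name, series in variables:
        per_group = []
        for g in group_labels:
            members = [p for p, lbl in assign.items() if lbl == g]
            vals = series.reindex(members).dropna().to_numpy(float)
            per_group.append(vals)
        if all(len(v) == 0 for v in per_group):
            logger.warning("variable %s missing for all patients; skipped", name)
            continue
        if any(len(v) == 0 for v in per_group):
            logger.warning("variable %s missing for a whole group; skipped", name)
            continue
        kw = kruskal_wallis(per_group, labels=group_labels)
        dunn = dunn_posttest(per_group, labels=group_labels, adjustment=adjustment)
        row: dict = {"variable": name, "kw_H": kw.statistic, "kw_p": kw.p_adjusted}
        for g, vals in zip(group_labels, per_group):
            q1, q3 = _iqr(vals)
            row[f"median_{g}"] = float(np.median(vals))
            row[f"iqr_{g}"] = f"{q1:.3g}-{q3:.3g}"
            row[f"n_{g}"] = len(vals)
        for pair in dunn:
            a, b = pair.group_labels
            row[f"dunn_p_{a}_vs_{b}"] = pair.p_adjusted
            row[f"stars_{a}_vs_{b}"] = pair.stars
        rows.append(row)
    return pd.DataFrame(rows)


def save_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.4g")


__all__ = [
    "RankTestResult", "CorrelationResult",
    "kruskal_wallis", "dunn_posttest", "spearman", "linear_regression",
    "group_report", "save_report", "significance_stars", "STAR_THRESHOLDS",
]
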