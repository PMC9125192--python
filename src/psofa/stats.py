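"""Nonparametric statistics for severity analysis.

The analysis contract is rank-based throughout: Spearman rank correlation
(with an OLS regression line and 95% confidence band for plotting),
Kruskal-Wallis between-group ANOVA on ranks followed by Dunn's pairwise
z-tests, Friedman within-group ANOVA on ranks with Dunn contrasts against
baseline, and the Schoenfeld event-count formula behind the survival-based
sample-size estimate.

Spearman uses mid-ranks for ties; the p-value comes from the exact
permutation distribution for n <= 9 and the t approximation otherwise.
Dunn's z-tests are reported unadjusted by default (as classic desktop
statistics packages of the era did); Bonferroni and Holm adjustments are
selectable and the choice is recorded in the output.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "RankTestResult",
    "spearman",
    "kruskal_wallis_dunn",
    "friedman_dunn",
    "survival_sample_size",
]

Adjust = Literal["none", "bonferroni", "holm"]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_value: float
    method: str
    slope: float
    intercept: float
    band: pd.DataFrame  # columns: x, fit, lower, upper (95%)

    def summary(self) -> str:
        return (
            f"Spearman r = {self.r:.3f} (n = {self.n}, p = {self.p_value:.4g},"
            f" {self.method}); fit y = {self.slope:.4g} x + {self.intercept:.4g}"
        )


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_value: float
    df: int
    pairwise: pd.DataFrame  # per-contrast Dunn table
    adjust: str
    degenerate: bool = False

    def summary(self) -> str:
        lines = [
            f"statistic = {self.statistic:.4f}, df = {self.df},"
            f" p = {self.p_value:.4g} (Dunn adjust: {self.adjust})"
        ]
        if self.degenerate:
            lines.append("WARNING: degenerate (all-tied) data")
        lines.append(self.pairwise.to_string(index=False))
        return "\n".join(lines)


def _spearman_r(rx: np.ndarray, ry: np.ndarray) -> float:
    sx = rx.std()
    sy = ry.std()
    return float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with a plotting regression band.

    Mid-ranks handle ties; constant vectors are rejected (r undefined).
    The regression line and 95% confidence band are OLS on the original
    scales, provided for figure reproduction only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman r undefined")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    r = _spearman_r(rx, ry)

    if n <= 9:
        method = "exact permutation"
        perms = np.array(list(itertools.permutations(ry)))
        pc = perms - perms.mean(axis=1, keepdims=True)
        rs = (pc @ (rx - rx.mean())) / (n * rx.std() * ry.std())
        p_value = float(np.mean(np.abs(rs) >= abs(r) - 1e-12))
    else:
        method = "t approximation"
        if abs(r) >= 1.0:
            p_value = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1 - r * r))
            p_value = float(2 * sps.t.sf(abs(t), df=n - 2))

    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    grid = np.linspace(x.min(), x.max(), min(100, max(n, 10)))
    pred = fit.get_prediction(sm.add_constant(grid))
    ci = pred.conf_int(alpha=0.05)
    band = pd.DataFrame(
        {
            "x": grid,
            "fit": pred.predicted_mean,
            "lower": ci[:, 0],
            "upper": ci[:, 1],
        }
    )
    return CorrelationResult(
        r=r,
        n=n,
        p_value=p_value,
        method=method,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        band=band,
    )


def _adjust_p(p: np.ndarray, adjust: Adjust) -> np.ndarray:
    if adjust == "none":
        return p
    if adjust == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    if adjust == "holm":
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        return adj
    raise ValueError(f"unknown adjustment {adjust!r}")


def kruskal_wallis_dunn(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    adjust: Adjust = "none",
) -> RankTestResult:
    """Kruskal-Wallis H (tie-corrected) with Dunn's pairwise z-tests.

    ``groups`` is a list of >= 2 samples, each of size >= 2.  The H
    statistic and its chi-square p come from scipy; Dunn's z uses the
    pooled mean ranks with the standard tie-corrected variance.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    labels = list(labels) if labels else [f"g{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    degenerate = np.ptp(pooled) == 0
    if degenerate:
        H, p = 0.0, 1.0
    else:
        H, p = sps.kruskal(*groups)

    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term

    rows = []
    for (i, j) in itertools.combinations(range(len(groups)), 2):
        se = math.sqrt(var_base * (1 / sizes[i] + 1 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "z": z,
                "p_raw": 2 * sps.norm.sf(abs(z)),
            }
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = _adjust_p(table["p_raw"].to_numpy(), adjust)
    return RankTestResult(
        statistic=float(H),
        p_value=float(p),
        df=len(groups) - 1,
        pairwise=table,
        adjust=adjust,
        degenerate=bool(degenerate),
    )


def friedman_dunn(
    blocks: np.ndarray | pd.DataFrame,
    treatment_labels: Sequence[str] | None = None,
    baseline: int = 0,
    adjust: Adjust = "none",
) -> RankTestResult:
    """Friedman chi-square over repeated measures with Dunn contrasts vs
    baseline.

    ``blocks`` has one row per subject and one column per repeated time
    point; contrasts compare each column's mean within-block rank against
    the ``baseline`` column (default: the first, e.g. t = 16 h).
    """
    arr = np.asarray(blocks, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2 or arr.shape[0] < 2:
        raise ValueError("need a 2-d blocks array, >= 2 subjects x >= 2 times")
    n, k = arr.shape
    labels = (
        list(treatment_labels)
        if treatment_labels
        else [f"t{i}" for i in range(k)]
    )
    degenerate = all(np.ptp(row) == 0 for row in arr)
    if degenerate:
        chi2, p = 0.0, 1.0
    else:
        chi2, p = sps.friedmanchisquare(*[arr[:, j] for j in range(k)])

    within = np.apply_along_axis(sps.rankdata, 1, arr)
    mean_ranks = within.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    rows = []
    for j in range(k):
        if j == baseline:
            continue
        z = (mean_ranks[j] - mean_ranks[baseline]) / se
        rows.append(
            {
                "treatment": labels[j],
                "baseline": labels[baseline],
                "z": z,
                "p_raw": 2 * sps.norm.sf(abs(z)),
            }
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = _adjust_p(table["p_raw"].to_numpy(), adjust)
    return RankTestResult(
        statistic=float(chi2),
        p_value=float(p),
        df=k - 1,
        pairwise=table,
        adjust=adjust,
        degenerate=bool(degenerate),
    )


@dataclass(frozen=True)
class SampleSizeResult:
    required_events: int
    n_control: int
    n_experimental: int
    assumptions: dict


def survival_sample_size(
    hazard_ratio: float,
    power: float = 0.9,
    alpha: float = 0.05,
    allocation_fraction: float = 0.25,
    event_prob_control: float = 0.05,
    event_prob_experimental: float = 0.20,
) -> SampleSizeResult:
    """Schoenfeld event-count formula for a two-arm log-rank design.

    d = (z_{1-a/2} + z_{1-b})^2 / (p (1-p) (ln HR)^2) with allocation
    fraction p for the control arm, then total n from the assumed
    per-arm event probabilities.  All assumptions are echoed in the
    output; the event probabilities are inputs, not constants.
    """
    if not (0 < hazard_ratio) or hazard_ratio == 1:
        raise ValueError("hazard_ratio must be > 0 and != 1")
    if not (0 < alpha < 1 and 0 < power < 1 and 0 < allocation_fraction < 1):
        raise ValueError("alpha, power, allocation_fraction must be in (0, 1)")
    z = sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power)
    p = allocation_fraction
    d = z**2 / (p * (1 - p) * math.log(hazard_ratio) ** 2)
    events = math.ceil(d)
    mean_event_prob = (
        p * event_prob_control + (1 - p) * event_prob_experimental
    )
    n_total = math.ceil(d / mean_event_prob)
    n_control = math.ceil(n_total * p)
    n_experimental = n_total - n_control
    return SampleSizeResult(
        required_events=events,
        n_control=n_control,
        n_experimental=n_experimental,
        assumptions={
            "hazard_ratio": hazard_ratio,
            "power": power,
            "alpha": alpha,
            "allocation_fraction": p,
            "event_prob_control": event_prob_control,
            "event_prob_experimental": event_prob_experimental,
            "required_events_exact": d,
        },
    )
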