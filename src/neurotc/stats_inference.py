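"""Nonparametric inference stage: paired state contrasts, cognition
contrasts, multiplicity control, and the p-value uniformity check.

Within-subject state contrasts (ASM high/low days, SWS vs non-SWS, IED bins)
use the paired two-sided Wilcoxon signed-rank test.  Across-subject contrasts
of EEG features between cognitively impaired and non-impaired groups use the
Brunner-Munzel test, appropriate for non-normal, heteroscedastic TC
distributions; the effect size is the nonparametric relative effect
P(X < Y) + 0.5 P(X = Y) estimated from midranks.  Multiplicity across the
comparison grid is controlled with Benjamini-Hochberg at alpha = 0.05, and
each feature family's p-value distribution is compared against Uniform(0, 1)
with a one-sided Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "impairment_flags",
    "relative_effect",
    "paired_wilcoxon",
    "brunner_munzel",
    "bh_correct",
    "ks_uniform",
    "run_comparison_grid",
    "COGNITIVE_DOMAINS",
]

COGNITIVE_DOMAINS = ("language", "verbal_memory", "working_memory", "attention")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    relative_effect: float
    n_x: int
    n_y: int
    significant_raw: bool | None = None
    significant_bh: bool | None = None


def impairment_flags(
    scores: pd.DataFrame,
    z_cut: float = -1.0,
    min_tests: int = 2,
) -> pd.DataFrame:
    """Per-domain cognitive impairment flags from test scores and norms.

    ``scores`` has columns (subject, domain, test, score, norm_mean,
    norm_sd).  A domain is impaired when at least ``min_tests`` of its tests
    score at or below ``z_cut`` SDs under the norm mean (boundary inclusive).
    Returns one row per (subject, domain) with columns z_below_count, n_tests
    and impaired.
    """
    df = scores.copy()
    if df["norm_sd"].le(0).any() or df["norm_sd"].isna().any():
        raise ValueError("norm_sd must be positive for every test")
    df["z"] = (df["score"] - df["norm_mean"]) / df["norm_sd"]
    out = (
        df.assign(below=df["z"] <= z_cut)
        .groupby(["subject", "domain"])
        .agg(z_below_count=("below", "sum"), n_tests=("z", "size"))
        .reset_index()
    )
    out["impaired"] = out["z_below_count"] >= min_tests
    return out


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sstats.rankdata(pooled, method="average")


def relative_effect(x: np.ndarray, y: np.ndarray) -> float:
    """Nonparametric relative effect P(X < Y) + 0.5 P(X = Y) from midranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    ranks = _midranks(np.concatenate([x, y]))
    mean_rank_y = ranks[nx:].mean()
    return float((mean_rank_y - (ny + 1) / 2.0) / nx)


def paired_wilcoxon(x, y) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    d = y - x
    if np.count_nonzero(d) == 0:
        raise ValueError("all paired differences are zero: test undefined")
    res = sstats.wilcoxon(x, y, alternative="two-sided")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        relative_effect=relative_effect(x, y),
        n_x=x.size,
        n_y=y.size,
    )


def _bm_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Brunner-Munzel statistic and Satterthwaite-type df (standard form)."""
    nx, ny = x.size, y.size
    ranks = _midranks(np.concatenate([x, y]))
    rx, ry = ranks[:nx], ranks[nx:]
    rx_in = sstats.rankdata(x, method="average")
    ry_in = sstats.rankdata(y, method="average")
    sx2 = np.var(rx - rx_in, ddof=1)
    sy2 = np.var(ry - ry_in, ddof=1)
    sigma2 = nx * sx2 + ny * sy2
    if sigma2 == 0.0:
        return np.nan, np.nan
    stat = (ry.mean() - rx.mean()) / np.sqrt((nx + ny) * sigma2 / (nx * ny))
    df = sigma2 ** 2 / (
        (nx * sx2) ** 2 / (nx - 1) + (ny * sy2) ** 2 / (ny - 1)
    )
    return float(stat), float(df)


def brunner_munzel(x, y, method: str = "t") -> TestResult:
    """Brunner-Munzel two-sided test of x vs y.

    ``method='t'`` uses the t-approximation with Satterthwaite-type degrees
    of freedom (scipy's form); ``method='exact'`` enumerates the permutation
    distribution of the statistic (intended for group sizes <= 10).  Degenerate
    rank variances (e.g. complete separation) yield p_value = NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    effect = relative_effect(x, y)
    stat, df = _bm_statistic(x, y)
    if np.isnan(stat):
        return TestResult(np.nan, np.nan, effect, x.size, y.size)
    if method == "t":
        res = sstats.brunnermunzel(x, y, alternative="two-sided")
        return TestResult(
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            relative_effect=effect,
            n_x=x.size,
            n_y=y.size,
        )
    if method == "exact":
        pooled = np.concatenate([x, y])
        n, nx = pooled.size, x.size
        observed = abs(stat)
        count = total = 0
        for idx in combinations(range(n), nx):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            s, _ = _bm_statistic(pooled[mask], pooled[~mask])
            if np.isnan(s):
                continue
            total += 1
            if abs(s) >= observed - 1e-12:
                count += 1
        p = count / total if total else np.nan
        return TestResult(stat, float(p), effect, x.size, y.size)
    raise ValueError(f"unknown method {method!r}")


def bh_correct(p_values, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level ``alpha``."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def ks_uniform(p_values) -> float:
    """One-sided KS test of p-values against Uniform(0, 1).

    The alternative is that the empirical CDF lies above the uniform CDF,
    i.e. p-values cluster near zero as expected under true effects.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 5:
        raise ValueError("need at least 5 p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    res = sstats.kstest(p, "uniform", alternative="greater")
    return float(res.pvalue)


def run_comparison_grid(
    cohort: pd.DataFrame,
    flags: pd.DataFrame,
    alpha: float = 0.05,
    min_group: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impaired-vs-non-impaired Brunner-Munzel tests over the full grid.

    ``cohort`` is long-form with columns (subject, feature, context, value);
    ``flags`` has columns (subject, domain, impaired).  For every (feature,
    context, domain) cell with at least ``min_group`` subjects per group the
    Brunner-Munzel test runs with x = impaired, y = non-impaired; cells with
    insufficient samples are reported empty (NaN p).  BH correction spans
    all testable cells of the run; per-feature KS uniformity is evaluated on
    each feature's cell p-values.

    Returns ``(results, ks_table)``.
    """
    rows = []
    for (feature, context), grp in cohort.groupby(["feature", "context"]):
        merged = grp.merge(flags, on="subject")
        for domain, sub in merged.groupby("domain"):
            x = sub.loc[sub["impaired"], "value"].to_numpy()
            y = sub.loc[~sub["impaired"], "value"].to_numpy()
            row = {
                "feature": feature,
                "context": context,
                "domain": domain,
                "n_x": x.size,
                "n_y": y.size,
            }
            if x.size >= min_group and y.size >= min_group:
                res = brunner_munzel(x, y)
                row.update(
                    statistic=res.statistic,
                    p=res.p_value,
                    relative_effect=res.relative_effect,
                )
            else:
                row.update(statistic=np.nan, p=np.nan, relative_effect=np.nan)
            rows.append(row)
    results = pd.DataFrame(rows)
    tested = results["p"].notna()
    results["significant_raw"] = False
    results["significant_bh"] = False
    if tested.any():
        results.loc[tested, "significant_raw"] = results.loc[tested, "p"] < alpha
        results.loc[tested, "significant_bh"] = bh_correct(
            results.loc[tested, "p"].to_numpy(), alpha=alpha
        )
    ks_rows = []
    for feature, grp in results.groupby("feature"):
        p = grp["p"].dropna().to_numpy()
        ks_rows.append(
            {
                "feature": feature,
                "n_cells": p.size,
                "ks_p": ks_uniform(p) if p.size >= 5 else np.nan,
            }
        )
    return results, pd.DataFrame(ks_rows)
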