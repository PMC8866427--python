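"""Blocked nonparametric comparison of the two recording methods.

The omnibus comparison is a Friedman test: the 9 condition-by-interval
combinations of a simulation family serve as blocks, the k = 2 recording
methods as treatments, and each block contributes one value per treatment
(that cell's mean error across replicates).  Kendall's W = chi2 / (n(k-1))
is reported as the effect size; W = 1 means the treatment ordering is
unanimous across blocks.  The Friedman statistic is computed from the
classic rank formula (average ranks on ties, no tie correction):

    chi2 = 12 / (n k (k+1)) * sum_j R_j^2  -  3 n (k+1)

with R_j the rank sum of treatment j, referred to a chi-squared
distribution on k - 1 degrees of freedom.  The formula is implemented
here rather than delegated because the standard library routine does not
accept the two-treatment design used for this comparison.

Post-hoc, each cell's 100 paired (pinpoint, one-zero) errors on the same
streams feed a two-sided Wilcoxon signed-rank test; the 9 raw p-values per
family are Benjamini-Hochberg FDR adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FriedmanResult",
    "friedman_blocked",
    "paired_wilcoxon",
    "bh_fdr_adjust",
    "compare_methods",
]


class DegenerateInputError(ValueError):
    """The test statistic is undefined for this input."""


@dataclass(frozen=True)
class FriedmanResult:
    chi_square: float
    df: int
    p_value: float
    kendalls_w: float
    n_blocks: int
    k_treatments: int


def friedman_blocked(values: np.ndarray) -> FriedmanResult:
    """Friedman test on an ``n_blocks x k_treatments`` matrix.

    Ranks are assigned within each block (average ranks on ties).  Blocks
    that are entirely tied contribute equal rank sums, so a matrix of
    constant blocks yields chi2 = 0 and p = 1 rather than an error.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be a 2-D (blocks x treatments) matrix")
    n, k = values.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 blocks and 2 treatments, got {n}x{k}")
    if np.isnan(values).any():
        raise ValueError("missing cells are not supported")
    ranks = stats.rankdata(values, axis=1)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    chi2 = max(chi2, 0.0)  # guard tiny negative round-off on fully tied input
    df = k - 1
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    w = chi2 / (n * (k - 1))
    return FriedmanResult(
        chi_square=float(chi2),
        df=df,
        p_value=p,
        kendalls_w=float(w),
        n_blocks=n,
        k_treatments=k,
    )


def paired_wilcoxon(
    differences: np.ndarray,
    zero_method: str = "wilcox",
    exact_threshold: int = 25,
) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired differences.

    Zero differences are dropped before ranking under the default
    ``"wilcox"`` convention (``"pratt"`` keeps them in the ranking).  The
    exact null distribution is used for at most ``exact_threshold``
    non-zero differences; beyond that, the normal approximation with
    continuity correction.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise DegenerateInputError("no differences supplied")
    n_nonzero = int(np.count_nonzero(d))
    if n_nonzero == 0:
        raise DegenerateInputError(
            "all paired differences are zero; the signed-rank statistic is undefined"
        )
    method = "exact" if n_nonzero <= exact_threshold else "approx"
    res = stats.wilcoxon(
        d,
        zero_method=zero_method,
        alternative="two-sided",
        method=method,
        correction=(method == "approx"),
    )
    return float(res.pvalue)


def bh_fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_methods(
    tidy: pd.DataFrame,
    error_scale: str = "signed",
    zero_method: str = "wilcox",
) -> dict:
    """Run the full inference battery on one family's tidy replicate table.

    Friedman consumes one mean error per (cell, method); ``error_scale``
    selects signed (default) or absolute mean errors for the ranking.
    Post-hocs are paired Wilcoxon tests on the per-replicate
    ``one_zero - pinpoint`` error differences within each cell, with BH-FDR
    adjustment across the cells of the family.

    Returns ``{"friedman": FriedmanResult, "posthoc": DataFrame}`` where
    the post-hoc table has one row per (condition, interval) cell.
    """
    families = tidy["family"].unique()
    if len(families) != 1:
        raise ValueError("compare_methods expects a single-family tidy table")
    if error_scale not in ("signed", "absolute"):
        raise ValueError("error_scale must be 'signed' or 'absolute'")

    err = tidy["error"].abs() if error_scale == "absolute" else tidy["error"]
    cell_means = (
        tidy.assign(err=err)
        .groupby(["condition", "interval", "method"], sort=True)["err"]
        .mean()
        .unstack("method")
    )
    friedman = friedman_blocked(cell_means.to_numpy())

    wide = tidy.pivot_table(
        index=["condition", "interval", "replicate"], columns="method", values="error"
    )
    diffs = (wide["one_zero"] - wide["pinpoint"]).rename("diff").reset_index()
    rows = []
    for (condition, interval), group in diffs.groupby(["condition", "interval"], sort=True):
        p = paired_wilcoxon(group["diff"].to_numpy(), zero_method=zero_method)
        rows.append({"condition": condition, "interval": interval, "p_raw": p})
    posthoc = pd.DataFrame(rows)
    posthoc["q_fdr"] = bh_fdr_adjust(posthoc["p_raw"].to_numpy())
    return {"friedman": friedman, "posthoc": posthoc}
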