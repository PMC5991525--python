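"""Exact and count-based statistics shared by every pipeline stage.

Fisher exact tests (one- and two-sided) on 2x2 tables, Benjamini-Hochberg
FDR adjustment, median-of-ratios library-size normalization, and a
self-contained negative-binomial Wald test for two-group differential
expression of repeat families and genes.

The NB test is deliberately simple: median-of-ratios size factors, a
method-of-moments dispersion per feature moderated by a mean-rank rolling
median trend, and a Wald z on the log fold change with a 0.5 pseudocount.
It trades the dispersion-shrinkage machinery of full DE packages for a
desk-testable model of the same class; see docs/methods.md for calibration
properties and limitations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

P_FLOOR = 1e-300

#: minimum NB dispersion; below this the model is effectively Poisson
DISPERSION_FLOOR = 0.01


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for a 2x2 test: rows = (test, background), cols = (positive, negative).

    ``a`` = positives in the test group, ``b`` = negatives in the test group,
    ``c`` / ``d`` the same for the background group.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError(f"counts must be non-negative integers, got {v}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def _margins(t: ContingencyTable2x2) -> tuple[int, int, int]:
    # (total N, positive-column total K, test-row total n)
    return t.n, t.a + t.c, t.a + t.b


def fisher_one_sided(t: ContingencyTable2x2) -> float:
    """Upper-tail Fisher exact p for over-representation of positives in the test group.

    P(X >= a) under the hypergeometric null with the table's margins. A table
    with an empty margin carries no information: returns 1 with a warning.
    """
    N, K, n = _margins(t)
    if K == 0 or n == 0 or K == N or n == N:
        warnings.warn("empty margin in 2x2 table; Fisher p set to 1", stacklevel=2)
        return 1.0
    p = float(sps.hypergeom.sf(t.a - 1, N, K, n))
    return max(min(p, 1.0), P_FLOOR)


def fisher_two_sided(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by the minimum-likelihood rule.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed that of the observed table (the convention of
    R's fisher.test and scipy).
    """
    N, K, n = _margins(t)
    if K == 0 or n == 0 or K == N or n == N:
        warnings.warn("empty margin in 2x2 table; Fisher p set to 1", stacklevel=2)
        return 1.0
    lo, hi = max(0, n + K - N), min(n, K)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, N, K, n)
    p_obs = pmf[t.a - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return max(min(p, 1.0), P_FLOOR)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (features x samples), rescaled to geometric mean 1.

    Each sample's factor is the median across features of its ratio to the
    geometric-mean pseudo-reference, using only features positive in every
    sample. Falls back to total-count ratios (with a warning) when no feature
    is positive in all samples.
    """
    if counts.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    mat = counts.to_numpy(dtype=float)
    all_pos = np.all(mat > 0, axis=1)
    if not all_pos.any():
        warnings.warn(
            "no feature positive in all samples; using total-count size factors",
            stacklevel=2,
        )
        factors = mat.sum(axis=0)
        if np.any(factors <= 0):
            raise ValueError("a sample has zero total counts")
    else:
        log_mat = np.log(mat[all_pos])
        log_ref = log_mat.mean(axis=1)
        factors = np.exp(np.median(log_mat - log_ref[:, None], axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _trended_dispersion(base_mean: np.ndarray, disp_mom: np.ndarray, window: int = 101) -> np.ndarray:
    """Rolling mean of per-feature MoM dispersions over the mean rank.

    Moderates the very noisy per-feature estimates (4 df at 3 vs 3) toward the
    local trend; a mean (not median) is used because the per-feature estimates
    are right-skewed and a median would bias the dispersion low, inflating the
    Wald statistic. The floor is applied after smoothing.
    """
    order = np.argsort(base_mean, kind="mergesort")
    sorted_disp = pd.Series(disp_mom[order])
    w = min(window, len(sorted_disp))
    trend_sorted = (
        sorted_disp.rolling(w, center=True, min_periods=1).mean().to_numpy()
    )
    trend = np.empty_like(trend_sorted)
    trend[order] = trend_sorted
    return np.maximum(trend, DISPERSION_FLOOR)


def nb_test(
    counts: pd.DataFrame,
    condition: Sequence[str],
    reference: str,
    pseudocount: float = 0.5,
    factors: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Two-group negative-binomial Wald test on a features x samples count table.

    Parameters
    ----------
    counts : integer DataFrame, features x samples.
    condition : per-sample group labels (exactly two distinct values).
    reference : the label of the control group; log2fc is treatment/control.
    pseudocount : added to each group's normalized mean before the fold change.
    factors : optional precomputed size factors (computed otherwise).

    Returns a DataFrame indexed by feature with columns ``base_mean``,
    ``log2fc``, ``p``, ``padj``. Features with all-zero counts are dropped.
    With a single sample in either group the fold change is still reported
    but ``p``/``padj`` are NaN.
    """
    condition = np.asarray(list(condition))
    if len(condition) != counts.shape[1]:
        raise ValueError("condition length must match sample count")
    groups = pd.unique(condition)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    if reference not in groups:
        raise ValueError(f"reference {reference!r} not among labels {list(groups)}")
    treatment = [g for g in groups if g != reference][0]

    keep = counts.sum(axis=1) > 0
    counts = counts.loc[keep]
    if factors is None:
        factors = size_factors(counts)
    norm = counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]

    idx_t = condition == treatment
    idx_c = condition == reference
    n_t, n_c = int(idx_t.sum()), int(idx_c.sum())
    mu_t = norm[:, idx_t].mean(axis=1)
    mu_c = norm[:, idx_c].mean(axis=1)
    base_mean = norm.mean(axis=1)
    log2fc = np.log2(mu_t + pseudocount) - np.log2(mu_c + pseudocount)

    out = pd.DataFrame(
        {"base_mean": base_mean, "log2fc": log2fc}, index=counts.index
    )
    if n_t < 2 or n_c < 2:
        out["p"] = np.nan
        out["padj"] = np.nan
        return out

    # pooled within-group variance -> per-feature MoM dispersion
    var_t = norm[:, idx_t].var(axis=1, ddof=1)
    var_c = norm[:, idx_c].var(axis=1, ddof=1)
    pooled_var = ((n_t - 1) * var_t + (n_c - 1) * var_c) / (n_t + n_c - 2)
    mu = 0.5 * (mu_t + mu_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_mom = np.where(mu > 0, (pooled_var - mu) / np.square(mu), 0.0)
    disp = _trended_dispersion(base_mean, disp_mom)

    # delta-method variance of the log-mean difference under NB(mu, disp)
    mt = mu_t + pseudocount
    mc = mu_c + pseudocount
    se_ln = np.sqrt((1.0 / mt + disp) / n_t + (1.0 / mc + disp) / n_c)
    z = (np.log(mt) - np.log(mc)) / se_ln
    p = 2.0 * sps.norm.sf(np.abs(z))
    p = np.clip(p, P_FLOOR, 1.0)
    out["p"] = p
    out["padj"] = bh_adjust(p)
    return out
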