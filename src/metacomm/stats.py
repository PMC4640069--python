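"""Statistical primitives shared by every pipeline stage.

Diversity, the classical rank tests, a Monte-Carlo Fisher exact test for
r x c contingency tables with fixed margins, and Benjamini–Hochberg
step-up FDR adjustment.  Rank tests and the KS test delegate to
scipy.stats behind a uniform :class:`TestResult` surface; the
Monte-Carlo Fisher test (table-probability statistic, Patefield
fixed-margin sampling, repeated-estimate reporting) is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "TestResult",
    "inverse_simpson",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "ks_two_sample",
    "fisher_exact_mc",
    "bh_adjust",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_replicates: int | None = None
    mc_se: float | None = None  # Monte-Carlo standard error of p_value

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def inverse_simpson(counts_or_props) -> float:
    """Inverse Simpson's diversity index, 1 / sum(p_i^2).

    The effective number of equally abundant taxa; lies in [1, S] where
    S is the number of taxa present, reaching S only on the uniform
    distribution.
    """
    x = np.asarray(counts_or_props, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative abundance")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = x / total
    return 1.0 / np.sum(p * p)


def mann_whitney_u(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann–Whitney U-test.

    ``mode='exact'`` enumerates the null rank distribution (valid
    without ties), ``'normal_approx'`` uses the tie-corrected normal
    approximation, ``'auto'`` picks exact for small tie-free samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if mode == "auto":
        mode = "exact" if (x.size + y.size <= 20 and not has_ties) else "normal_approx"
    if mode not in ("exact", "normal_approx"):
        raise ValueError(f"unknown mode {mode!r}")
    method = "exact" if mode == "exact" else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      method=f"mann-whitney-u ({mode})")


def wilcoxon_signed_rank(diffs, mode: str = "auto") -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking.  ``mode='exact'``
    enumerates sign patterns (n <= 15 by default), otherwise a normal
    approximation with tie correction is used.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero; no test possible")
    has_ties = len(np.unique(np.abs(d))) < d.size
    if mode == "auto":
        mode = "exact" if (d.size <= 15 and not has_ties) else "normal_approx"
    if mode not in ("exact", "normal_approx"):
        raise ValueError(f"unknown mode {mode!r}")
    method = "exact" if mode == "exact" else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", mode=method, correction=False)
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      method=f"wilcoxon-signed-rank ({mode})")


def ks_two_sample(x, y) -> TestResult:
    """Two-sided two-sample Kolmogorov–Smirnov test (asymptotic p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("KS test needs at least 2 observations per sample")
    res = sps.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      method="ks-two-sample")


def _log_table_prob(tables: np.ndarray, row_m: np.ndarray, col_m: np.ndarray) -> np.ndarray:
    """Null hypergeometric log-probability of r x c tables with fixed margins."""
    n = row_m.sum()
    const = gammaln(row_m + 1).sum() + gammaln(col_m + 1).sum() - gammaln(n + 1)
    return const - gammaln(tables + 1).sum(axis=(-2, -1))


def fisher_exact_mc(
    table,
    n_replicates: int = 10_000,
    n_repeats: int = 1_000,
    seed: int | None = None,
) -> TestResult:
    """Monte-Carlo Fisher's exact test for an r x c contingency table.

    The test statistic is the null hypergeometric probability of the
    table given its margins; replicate tables are drawn uniformly from
    the fixed-margin null (Patefield sampling).  Each repeat yields
    p = (1 + #{P_sim <= P_obs}) / (1 + n_replicates); the reported
    p-value is the mean over ``n_repeats`` repeats and ``mc_se`` its
    standard error, mirroring the "mean P over iterations" convention.
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2 or obs.size < 4 or min(obs.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(obs < 0):
        raise ValueError("negative cell count")
    row_m = obs.sum(axis=1)
    col_m = obs.sum(axis=0)
    if np.any(row_m == 0) or np.any(col_m == 0):
        raise ValueError("zero margin; drop empty rows/columns first")
    if n_replicates < 1 or n_repeats < 1:
        raise ValueError("n_replicates and n_repeats must be >= 1")

    rng = np.random.default_rng(seed)
    log_p_obs = float(_log_table_prob(obs[np.newaxis], row_m, col_m)[0])
    dist = sps.random_table(row_m, col_m)
    tol = 1e-7 * max(1.0, abs(log_p_obs))  # float slack for P_sim == P_obs
    p_per_repeat = np.empty(n_repeats)
    # sample in batches per repeat to bound memory
    for r in range(n_repeats):
        sims = dist.rvs(n_replicates, random_state=rng)
        log_p_sim = _log_table_prob(sims, row_m, col_m)
        hits = int(np.sum(log_p_sim <= log_p_obs + tol))
        p_per_repeat[r] = (1 + hits) / (1 + n_replicates)
    p = float(p_per_repeat.mean())
    se = float(p_per_repeat.std(ddof=1) / np.sqrt(n_repeats)) if n_repeats > 1 else 0.0
    return TestResult(
        statistic=float(np.exp(log_p_obs)),
        p_value=min(p, 1.0),
        method="fisher-exact-mc",
        n_replicates=n_replicates,
        mc_se=se,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, input order preserved.

    q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
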