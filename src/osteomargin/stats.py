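"""Statistical layer: exact contingency tests, corrected odds ratios,
penalized logistic regression, and rank-based group comparisons.

The primary outcome (intratumoral cut yes/no by guidance condition) is a
2 x K contingency table analyzed with the Freeman-Halton extension of
Fisher's exact test, computed here by full enumeration of tables with the
observed margins in log space.  Univariate odds ratios versus the AR
reference use the Haldane-Anscombe continuity correction (0.5 added to
every cell), the only convention consistent with all three point estimates
printed for the study data (2.44, 0.16, 0.05), and Woolf log-scale
confidence intervals.  The multivariable model is a logistic regression of
the intratumoral flag on condition, tumor and surgeon; because one
condition has zero events, plain maximum likelihood diverges, and Firth's
bias-reduction penalty (Jeffreys prior) is engaged to keep the estimates
finite.  Continuous outcomes are compared with the tie-corrected
Kruskal-Wallis test and the Steel-Dwass-Critchlow-Fligner all-pairs
post hoc referred to the studentized-range distribution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit, gammaln

__all__ = [
    "ContingencyTable",
    "OddsRatioResult",
    "fisher_exact",
    "odds_ratio_cc",
    "LogisticFit",
    "logistic_fit",
    "kruskal_wallis",
    "sdcf_posthoc",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2 x K counts of a binary outcome across K groups."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ("yes", "no")
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != 2 or counts.shape[1] < 2:
            raise ValueError(f"expected a 2 x K table with K >= 2, got {counts.shape}")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)) or np.any(counts < 0):
                raise ValueError("counts must be non-negative integers")
            counts = counts.astype(np.int64)
        object.__setattr__(self, "counts", counts.astype(np.int64))
        if not self.col_labels:
            object.__setattr__(
                self, "col_labels", tuple(f"group{i + 1}" for i in range(counts.shape[1]))
            )

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _log_table_probability(table: np.ndarray, log_n_fact: float) -> float:
    """Log multivariate-hypergeometric probability of a table given margins."""
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    return float(
        gammaln(row + 1).sum()
        + gammaln(col + 1).sum()
        - log_n_fact
        - gammaln(table + 1).sum()
    )


def _enumerate_first_rows(col_totals: np.ndarray, row_total: int):
    """All ways to split ``row_total`` into cells bounded by column totals."""
    k = len(col_totals)

    def rec(idx: int, remaining: int, prefix: tuple[int, ...]):
        if idx == k - 1:
            if remaining <= col_totals[idx]:
                yield prefix + (remaining,)
            return
        tail_cap = int(col_totals[idx + 1 :].sum())
        lo = max(0, remaining - tail_cap)
        hi = min(int(col_totals[idx]), remaining)
        for a in range(lo, hi + 1):
            yield from rec(idx + 1, remaining - a, prefix + (a,))

    yield from rec(0, row_total, ())


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided exact p for a 2 x K table (Freeman-Halton for K > 2).

    Enumerates every table with the observed margins and sums the
    multivariate-hypergeometric probabilities of those no more probable
    than the observed table, working in log space for stability.
    """
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("table has an empty row or column")
    col_totals = counts.sum(axis=0)
    row_total = int(counts.sum(axis=1)[0])
    log_n_fact = float(gammaln(counts.sum() + 1))
    log_p_obs = _log_table_probability(counts, log_n_fact)
    tol = 1e-7 * max(1.0, abs(log_p_obs))

    log_probs = []
    for first_row in _enumerate_first_rows(col_totals, row_total):
        cand = np.vstack([first_row, col_totals - np.array(first_row)])
        lp = _log_table_probability(cand, log_n_fact)
        if lp <= log_p_obs + tol:
            log_probs.append(lp)
    m = max(log_probs)
    p = float(np.exp(m) * np.sum(np.exp(np.array(log_probs) - m)))
    return min(p, 1.0)


@dataclass(frozen=True)
class OddsRatioResult:
    """Continuity-corrected odds ratio with a Woolf log-scale CI."""

    estimate: float
    ci_low: float
    ci_high: float
    correction_applied: bool
    reference: str

    def __post_init__(self) -> None:
        if self.estimate <= 0:
            raise ValueError("odds ratio must be positive")
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("CI must bracket the estimate")


def odds_ratio_cc(
    exposed: tuple[int, int],
    reference: tuple[int, int],
    alpha: float = 0.05,
    reference_name: str = "reference",
) -> OddsRatioResult:
    """Haldane-Anscombe corrected OR of ``exposed`` (events, non-events)
    versus ``reference``, with a Woolf confidence interval.

    0.5 is added to all four cells unconditionally, which keeps the
    estimate finite with zero cells and is the convention that reproduces
    the study's printed univariate estimates.  Note the Woolf interval on
    the corrected table is an approximation; exact or profile intervals
    will differ, especially for sparse tables.
    """
    a, b = exposed
    c, d = reference
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    estimate = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - alpha / 2)
    log_or = np.log(estimate)
    return OddsRatioResult(
        float(estimate),
        float(np.exp(log_or - z * se)),
        float(np.exp(log_or + z * se)),
        True,
        reference_name,
    )


@dataclass
class LogisticFit:
    """Fitted (possibly Firth-penalized) logistic regression."""

    params: pd.Series
    bse: pd.Series
    method: str  # "mle" or "firth"
    n_iter: int
    converged: bool

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        z = sps.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "coef": self.params,
                "or": np.exp(self.params),
                "or_low": np.exp(self.params - z * self.bse),
                "or_high": np.exp(self.params + z * self.bse),
            }
        )


def _irls(
    x: np.ndarray, y: np.ndarray, firth: bool, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    n, p = x.shape
    beta = np.zeros(p)
    for it in range(1, max_iter + 1):
        eta = x @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        xtw = x.T * w
        info = xtw @ x
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular information matrix in IRLS") from exc
        if firth:
            # Hat diagonals of W^(1/2) X (X'WX)^-1 X' W^(1/2).
            h = np.einsum("ij,jk,ik->i", x * w[:, None], info_inv, x)
            score = x.T @ (y - mu + h * (0.5 - mu))
        else:
            score = x.T @ (y - mu)
        step = info_inv @ score
        # Step-halving for stability on nearly separated data.
        for _ in range(20):
            if np.max(np.abs(step)) < 50:
                break
            step = step / 2
        beta_new = beta + step
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            se = np.sqrt(np.diag(np.linalg.inv(info)))
            return beta, se, it, True
        beta = beta_new
    eta = x @ beta
    mu = expit(eta)
    info = (x.T * (mu * (1 - mu))) @ x
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se, max_iter, False


def logistic_fit(
    outcome: np.ndarray,
    predictors: pd.DataFrame,
    reference_levels: dict[str, str] | None = None,
    firth: bool | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> LogisticFit:
    """Logistic regression of a binary outcome on categorical predictors.

    Predictors are dummy-coded against their reference level (first level
    by default).  ``firth=None`` selects automatically: Firth's penalty is
    engaged when any predictor level has zero events in either direction
    (the quasi-separation that makes plain MLE diverge, as happens for a
    guidance condition with no intratumoral cuts); otherwise plain MLE by
    IRLS is used.  Raises on non-convergence.
    """
    y = np.asarray(outcome, dtype=float)
    if y.ndim != 1 or not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be a binary 0/1 vector")
    if y.sum() < 1:
        raise ValueError("at least one event required")

    reference_levels = reference_levels or {}
    design = [pd.Series(np.ones(len(y)), name="intercept")]
    for col in predictors.columns:
        series = predictors[col].astype(str)
        levels = sorted(series.unique())
        ref = reference_levels.get(col, levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not found in predictor {col!r}")
        for level in levels:
            if level != ref:
                design.append(
                    pd.Series((series == level).astype(float), name=f"{col}[{level}]")
                )
    x_df = pd.concat(design, axis=1)
    x = x_df.to_numpy()
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient after dummy coding")

    if firth is None:
        firth = False
        for col in x_df.columns[1:]:
            mask = x_df[col].to_numpy() > 0
            if y[mask].sum() in (0, mask.sum()):
                firth = True
                break

    beta, se, n_iter, converged = _irls(x, y, firth, max_iter, tol)
    if not converged:
        raise RuntimeError(
            f"logistic fit ({'Firth' if firth else 'MLE'}) did not converge in "
            f"{max_iter} iterations; max |score step| still above {tol}"
        )
    index = list(x_df.columns)
    return LogisticFit(
        pd.Series(beta, index=index),
        pd.Series(se, index=index),
        "firth" if firth else "mle",
        n_iter,
        converged,
    )


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    if len(groups) < 2:
        raise ValueError("at least two groups required")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("every group must contain at least one observation")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def _pairwise_sdcf_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Studentized-range-scale statistic for one pair (tie-corrected)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1, n2 = len(a), len(b)
    n = n1 + n2
    w = ranks[:n1].sum()
    expect = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0
    return float(np.sqrt(2.0) * abs(w - expect) / np.sqrt(var))


def sdcf_posthoc(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    compute_p: bool = True,
) -> pd.DataFrame:
    """Steel-Dwass-Critchlow-Fligner all-pairs comparison.

    For each pair of groups the standardized pairwise Wilcoxon rank-sum
    statistic (scaled by sqrt(2)) is referred to the studentized-range
    distribution with k groups and infinite degrees of freedom, which
    controls the family-wise error rate across all k(k-1)/2 comparisons.
    Returns a frame with columns group_a, group_b, statistic, p_value;
    ``compute_p=False`` skips the (comparatively slow) distribution lookup,
    leaving the statistic to be compared against a critical value.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("at least two groups required")
    if any(len(g) == 0 for g in arrays):
        raise ValueError("every group must contain at least one observation")
    k = len(arrays)
    labels = labels or [f"group{i + 1}" for i in range(k)]
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        q = _pairwise_sdcf_statistic(arrays[i], arrays[j])
        if compute_p:
            p = float(sps.studentized_range.sf(q, k, np.inf)) if q > 0 else 1.0
        else:
            p = np.nan
        rows.append(
            {"group_a": labels[i], "group_b": labels[j], "statistic": q, "p_value": p}
        )
    return pd.DataFrame(rows)
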