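"""Association battery: exact 2x2 and rank tests, adjusted regressions,
random-intercept mixed models and FDR control.

The exact tests are implemented from their sampling distributions
(hypergeometric probability-mass enumeration; rank-sum distribution by
dynamic programming) so that small-sample behaviour is fully specified and
testable against brute-force enumeration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "fisher_exact_2x2",
    "wilcoxon_rank_sum",
    "logistic_cb",
    "lm_adjusted",
    "lmm_random_intercepts",
    "benjamini_hochberg",
]

# relative slack when comparing table probabilities to the observed one,
# guarding against floating-point noise in the <= comparison
_PMF_RELATIVE_GATE = 1.0 + 1e-7

EXACT_WILCOXON_MAX_N = 20


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = mutant/wildtype and columns = CB/NCB."""

    a: int  # mutant, benefit
    b: int  # mutant, no benefit
    c: int  # wildtype, benefit
    d: int  # wildtype, no benefit

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class AssociationResult:
    test_name: str
    estimate: float
    p_value: float
    n: int
    adjustment: tuple = ()
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of range: {self.p_value}")


def fisher_exact_2x2(table: ContingencyTable2x2) -> AssociationResult:
    """Two-sided Fisher's exact test by probability-mass enumeration.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed that of the observed table.
    The estimate is the sample odds ratio ad/bc (infinite when bc = 0).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    row1 = a + b
    col1 = a + c
    if row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        warnings.warn("a zero margin makes the table degenerate; p = 1.0",
                      stacklevel=2)
        p = 1.0
    else:
        dist = hypergeom(n, col1, row1)
        support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
        pmf = dist.pmf(support)
        observed = dist.pmf(a)
        p = float(min(pmf[pmf <= observed * _PMF_RELATIVE_GATE].sum(), 1.0))
        if 1.0 - p < 1e-9:  # full-support sums drift below 1 in float
            p = 1.0
    if b * c == 0:
        odds_ratio = math.inf if a * d > 0 else math.nan
    else:
        odds_ratio = (a * d) / (b * c)
    return AssociationResult(
        test_name="fisher_exact",
        estimate=odds_ratio,
        p_value=p,
        n=n,
        details={"table": [[a, b], [c, d]]},
    )


def _rank_sum_distribution(n_x: int, n_total: int) -> np.ndarray:
    """Number of ways to choose ``n_x`` of ranks 1..n_total with each
    possible rank sum; index i = count for rank sum i."""
    max_sum = n_x * n_total
    counts = np.zeros((n_x + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for rank in range(1, n_total + 1):
        for k in range(min(rank, n_x), 0, -1):
            counts[k, rank:] += counts[k - 1, :-rank] if rank else counts[k - 1]
    return counts[n_x]


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> AssociationResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact by enumeration of the rank-sum distribution when the pooled size
    is at most 20 and there are no ties; otherwise a normal approximation
    with mid-ranks, tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    n_x, n_y = x.size, y.size
    n = n_x + n_y
    if np.unique(pooled).size == 1:
        return AssociationResult(
            test_name="wilcoxon_rank_sum", estimate=0.0, p_value=1.0, n=n
        )
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty(n, dtype=float)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i: j + 1]] = (i + j) / 2.0 + 1.0  # mid-ranks
        i = j + 1
    w = float(ranks[:n_x].sum())
    mean_w = n_x * (n + 1) / 2.0
    has_ties = np.unique(pooled).size < n

    if n <= EXACT_WILCOXON_MAX_N and not has_ties:
        dist = _rank_sum_distribution(n_x, n)
        total = dist.sum()
        w_int = int(round(w))
        lower = dist[: w_int + 1].sum() / total
        upper = dist[w_int:].sum() / total
        p = float(min(1.0, 2.0 * min(lower, upper)))
        method = "exact"
    else:
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts ** 3 - tie_counts).sum()
        var_w = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        delta = w - mean_w
        z = max(abs(delta) - 0.5, 0.0) / math.sqrt(var_w)
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
        method = "normal_approx"
    return AssociationResult(
        test_name="wilcoxon_rank_sum",
        estimate=w - mean_w,
        p_value=p,
        n=n,
        details={"rank_sum": w, "method": method},
    )


def _design_frame(b2m, covariates) -> pd.DataFrame:
    frame = pd.DataFrame({"b2m": np.asarray(b2m, dtype=float)})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        for col in cov.columns:
            series = cov[col]
            if series.dtype == object or isinstance(
                series.dtype, pd.CategoricalDtype
            ):
                levels = sorted(series.astype(str).unique())
                for level in levels[1:]:  # first level is the reference
                    frame[f"{col}[{level}]"] = (
                        series.astype(str) == level
                    ).astype(float)
            else:
                frame[col] = series.astype(float)
    return frame


def logistic_cb(
    outcome: Sequence[int], b2m: Sequence[int], covariates=None
) -> AssociationResult:
    """Logistic regression of a binary outcome on mutation status.

    Fit by maximum likelihood (IRLS); reports the status coefficient, its
    Wald two-sided p-value and odds ratio.  Perfect separation is flagged
    and the p-value reported as missing.
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    design = _design_frame(b2m, covariates)
    if design["b2m"].nunique() < 2:
        # degenerate intercept-only fit: status carries no information
        intercept = math.log(y.mean() / (1.0 - y.mean()))
        return AssociationResult(
            test_name="logistic_regression",
            estimate=math.nan,
            p_value=math.nan,
            n=len(y),
            details={"intercept": intercept, "separated": False},
        )
    exog = sm.add_constant(design, has_constant="add")
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            fit = sm.Logit(y, exog).fit(disp=0)
        except Exception:
            separated = True
    if not separated:
        coefs = np.abs(fit.params.values)
        if not fit.mle_retvals.get("converged", True) or coefs.max() > 15:
            separated = True
    if separated:
        warnings.warn(
            "possible perfect separation in logistic fit; p reported as NaN",
            stacklevel=2,
        )
        beta = math.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                refit = sm.Logit(y, exog).fit_regularized(disp=0, alpha=1e-8)
                beta = float(refit.params["b2m"])
            except Exception:
                pass
        return AssociationResult(
            test_name="logistic_regression",
            estimate=beta,
            p_value=math.nan,
            n=len(y),
            adjustment=tuple(c for c in design.columns if c != "b2m"),
            details={
                "odds_ratio": math.exp(beta) if not math.isnan(beta) else math.nan,
                "separated": True,
            },
        )
    beta = float(fit.params["b2m"])
    return AssociationResult(
        test_name="logistic_regression",
        estimate=beta,
        p_value=float(fit.pvalues["b2m"]),
        n=len(y),
        adjustment=tuple(c for c in design.columns if c != "b2m"),
        details={
            "odds_ratio": math.exp(beta),
            "intercept": float(fit.params["const"]),
            "separated": False,
        },
    )


def lm_adjusted(
    y: Sequence[float], b2m: Sequence[int], covariates=None
) -> AssociationResult:
    """OLS of a numeric response on mutation status plus covariates.

    Reports the status coefficient and its two-sided t-test p-value.
    Rank-deficient designs raise an error naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    design = _design_frame(b2m, covariates)
    exog = sm.add_constant(design, has_constant="add")
    if len(y) <= exog.shape[1]:
        raise ValueError("need more observations than parameters")
    rank = np.linalg.matrix_rank(exog.values)
    if rank < exog.shape[1]:
        culprits = []
        kept = [exog.columns[0]]
        for col in exog.columns[1:]:
            trial = exog[kept + [col]].values
            if np.linalg.matrix_rank(trial) < len(kept) + 1:
                culprits.append(col)
            else:
                kept.append(col)
        raise ValueError(f"rank-deficient design; collinear columns: {culprits}")
    fit = sm.OLS(y, exog).fit()
    return AssociationResult(
        test_name="ols",
        estimate=float(fit.params["b2m"]),
        p_value=float(fit.pvalues["b2m"]),
        n=len(y),
        adjustment=tuple(c for c in design.columns if c != "b2m"),
    )


def lmm_random_intercepts(
    y: Sequence[float],
    b2m: Sequence[int],
    groups: pd.DataFrame,
) -> AssociationResult:
    """Mixed model with a random intercept per grouping factor (REML).

    ``groups`` holds one or two categorical columns.  When the factors
    carry a single level in total the model degrades to plain OLS.
    """
    y = np.asarray(y, dtype=float)
    groups = pd.DataFrame(groups).reset_index(drop=True)
    if groups.shape[1] not in (1, 2):
        raise ValueError("groups must contain one or two columns")
    n_levels = sum(groups[c].astype(str).nunique() for c in groups.columns)
    if n_levels <= groups.shape[1]:
        # degenerate: every factor is constant, random intercepts vanish
        result = lm_adjusted(y, b2m)
        result.test_name = "lmm_random_intercepts(degenerate->ols)"
        result.details["variance_components"] = {
            c: 0.0 for c in groups.columns
        }
        return result
    frame = pd.DataFrame({"y": y, "b2m": np.asarray(b2m, dtype=float)})
    for col in groups.columns:
        frame[col] = groups[col].astype(str).values
    vc_formula = {col: f"0 + C({col})" for col in groups.columns}
    frame["_all"] = 1
    model = smf.mixedlm(
        "y ~ b2m", data=frame, groups="_all", vc_formula=vc_formula
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=True)
            converged = bool(getattr(fit, "converged", True))
        except Exception as exc:
            warnings.warn(f"mixed model failed to converge: {exc}", stacklevel=2)
            result = lm_adjusted(y, b2m)
            result.test_name = "lmm_random_intercepts(nonconverged->ols)"
            result.details["converged"] = False
            return result
    vc_names = list(getattr(model.exog_vc, "names", groups.columns))
    vcs = {name: float(fit.vcomp[i]) for i, name in enumerate(vc_names)}
    if not converged:
        warnings.warn("mixed model flagged as non-converged", stacklevel=2)
    return AssociationResult(
        test_name="lmm_random_intercepts",
        estimate=float(fit.params["b2m"]),
        p_value=float(fit.pvalues["b2m"]),
        n=len(y),
        adjustment=tuple(groups.columns),
        details={
            "variance_components": vcs,
            "residual_variance": float(fit.scale),
            "converged": converged,
            "method": "REML",
        },
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m, dtype=float)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        value = p[idx] * m / rank_from_top
        running_min = min(running_min, value)
        adjusted[idx] = running_min
    return np.minimum(adjusted, 1.0)
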