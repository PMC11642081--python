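"""Covariate-adjusted between-cluster prevalence comparison.

Each disease (and each ICD-11-adapted disease group) is regressed on
cluster membership with binomial logistic regression, adjusting for age,
sex, socioeconomic position (SEP) and smoking.  The reported quantity is
the odds ratio of the cluster-2 indicator with its Wald 95% CI and
two-sided Wald p-value.  Records with missing SEP are dropped listwise per
model.  No multiplicity correction is applied by default (per-outcome
p-values, as in the source tables); a Benjamini-Hochberg option exists.

The maximum-likelihood fit is iteratively reweighted least squares (via the
binomial GLM machinery of statsmodels); quasi-complete separation — common
here because several diseases have zero cases in one cluster — is detected
from exploding standardized coefficients and flagged rather than silently
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import Cohort, GROUP_LABELS

__all__ = [
    "LogisticFit",
    "AdjustedResult",
    "fit_logistic",
    "disease_cluster_comparison",
    "group_cluster_comparison",
    "ClusterPrevalenceComparison",
    "ComparisonResults",
    "DegenerateOutcomeError",
    "SingularDesignError",
]

SEPARATION_BETA = 15.0  # |beta| on the standardized scale flagging separation


class DegenerateOutcomeError(ValueError):
    """Outcome is all-0 or all-1: the model is not estimable."""


class SingularDesignError(ValueError):
    """Design matrix is rank-deficient (perfect collinearity)."""


@dataclass
class LogisticFit:
    """Maximum-likelihood binomial logistic fit.

    ``params``/``cov`` are indexed by the design column names; ``separation``
    marks quasi-complete separation (estimates unbounded, p-values unusable).
    """

    params: pd.Series
    cov: pd.DataFrame
    converged: bool
    iterations: int
    n_used: int
    separation: bool = False

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def wald_p(self, term: str) -> float:
        z = self.params[term] / self.bse[term]
        return float(2 * stats.norm.sf(abs(z)))


def fit_logistic(y, X, maxiter: int = 100, tol: float = 1e-10) -> LogisticFit:
    """IRLS maximum-likelihood logistic regression.

    ``X`` must include the intercept column.  Raises
    :class:`DegenerateOutcomeError` for constant outcomes and
    :class:`SingularDesignError` for rank-deficient designs; separation is
    detected and flagged, never silent.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    if y.min() == y.max():
        raise DegenerateOutcomeError("outcome constant: all 0 or all 1")
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise SingularDesignError("design matrix is rank-deficient")

    model = sm.GLM(y, Xv, family=sm.families.Binomial())
    res = model.fit(maxiter=maxiter, tol=tol)
    params = pd.Series(res.params, index=X.columns)
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)

    # separation guard: coefficient magnitude on the predictor-SD scale
    scales = Xv.std(axis=0)
    scales[scales == 0] = 1.0  # intercept
    separation = bool((np.abs(params.to_numpy() * scales) > SEPARATION_BETA).any())

    return LogisticFit(params=params, cov=cov, converged=bool(res.converged),
                       iterations=int(getattr(res, "fit_history", {}).get("iteration", maxiter))
                       if hasattr(res, "fit_history") else maxiter,
                       n_used=y.shape[0], separation=separation)


@dataclass
class AdjustedResult:
    """Adjusted cluster effect for one outcome (disease or disease group)."""

    outcome: str
    level: str                      # "disease" | "group"
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    n_used: int
    enriched_in: int | None = None  # cluster id with the higher adjusted odds
    testable: bool = True
    note: str | None = None

    @property
    def significant(self) -> bool:
        return bool(self.testable and self.p_value is not None and self.p_value < 0.05)


def _design(cohort: Cohort, assignments: np.ndarray, outcome: np.ndarray
            ) -> tuple[np.ndarray, pd.DataFrame]:
    assignments = np.asarray(assignments)
    clusters = np.unique(assignments)
    if clusters.size != 2:
        raise ValueError("adjusted comparison requires exactly two clusters")
    frame = cohort.frame
    X = pd.DataFrame({
        "intercept": 1.0,
        "cluster2": (assignments == clusters[1]).astype(float),
        "age": frame["age"].to_numpy(float),
        "sex_male": (frame["sex"] == "male").to_numpy(float),
        "sep": frame["sep"].to_numpy(float),
        "smoking": frame["smoking"].to_numpy(float),
    })
    keep = ~X["sep"].isna()
    return outcome[keep.to_numpy()], X.loc[keep].reset_index(drop=True)


def _adjusted(cohort: Cohort, assignments: np.ndarray, outcome: np.ndarray,
              name: str, level: str) -> AdjustedResult:
    y, X = _design(cohort, assignments, np.asarray(outcome, dtype=float))
    n_used = y.shape[0]
    try:
        fit = fit_logistic(y, X)
    except DegenerateOutcomeError:
        return AdjustedResult(outcome=name, level=level, odds_ratio=None,
                              ci_low=None, ci_high=None, p_value=None,
                              n_used=n_used, testable=False,
                              note="outcome absent (or universal): not testable")
    beta = fit.params["cluster2"]
    se = fit.bse["cluster2"]
    with np.errstate(over="ignore"):  # separated fits overflow to inf
        or_, lo, hi = np.exp([beta, beta - 1.96 * se, beta + 1.96 * se])
    result = AdjustedResult(
        outcome=name, level=level,
        odds_ratio=float(or_),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=fit.wald_p("cluster2"),
        n_used=fit.n_used,
        enriched_in=2 if beta > 0 else 1,
    )
    if fit.separation:
        result.testable = False
        result.note = "quasi-complete separation: Wald inference unreliable"
    return result


def disease_cluster_comparison(cohort: Cohort, assignments, disease: str
                               ) -> AdjustedResult:
    """Adjusted cluster comparison for one disease flag."""
    if disease not in cohort.codebook.diseases:
        raise KeyError(f"unknown disease: {disease!r}")
    outcome = cohort.frame[disease].to_numpy()
    return _adjusted(cohort, assignments, outcome, disease, "disease")


def group_cluster_comparison(cohort: Cohort, assignments, group: str
                             ) -> AdjustedResult:
    """Adjusted cluster comparison for >=1 disease in an organ-system group."""
    if group not in GROUP_LABELS:
        raise KeyError(f"unknown disease group: {group!r}")
    members = cohort.codebook.group_members(group)
    outcome = (cohort.frame[list(members)].sum(axis=1) >= 1).to_numpy(int)
    return _adjusted(cohort, assignments, outcome, group, "group")


class ClusterPrevalenceComparison:
    """Model: all 26 diseases + 6 groups vs cluster membership, adjusted.

    ``fit()`` returns :class:`ComparisonResults` whose ``table`` collects
    one :class:`AdjustedResult` row per outcome.
    """

    def __init__(self, cohort: Cohort, assignments, bh_correct: bool = False):
        self.cohort = cohort
        self.assignments = np.asarray(assignments)
        self.bh_correct = bh_correct

    def fit(self) -> "ComparisonResults":
        results = [disease_cluster_comparison(self.cohort, self.assignments, d)
                   for d in self.cohort.codebook.diseases]
        results += [group_cluster_comparison(self.cohort, self.assignments, g)
                    for g in GROUP_LABELS]
        return ComparisonResults(results, bh_correct=self.bh_correct)


class ComparisonResults:
    def __init__(self, results: list[AdjustedResult], bh_correct: bool = False):
        self.results = results
        self.bh_correct = bh_correct

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append({
                "outcome": r.outcome, "level": r.level, "OR": r.odds_ratio,
                "CI_low": r.ci_low, "CI_high": r.ci_high, "p": r.p_value,
                "significant": r.significant, "enriched_in": r.enriched_in,
                "n_used": r.n_used, "note": r.note,
            })
        out = pd.DataFrame(rows)
        if self.bh_correct:
            mask = out["p"].notna()
            p = out.loc[mask, "p"].to_numpy()
            out.loc[mask, "p_bh"] = _benjamini_hochberg(p)
            out["significant"] = out.get("p_bh", out["p"]) < 0.05
        return out

    def summary(self) -> str:
        t = self.table
        sig = t[t["significant"]]
        lines = [
            "Adjusted between-cluster prevalence comparison "
            "(logistic regression; covariates: age, sex, SEP, smoking)",
            f"outcomes tested: {len(t)}   significant at 0.05: {len(sig)}",
        ]
        for _, r in sig.iterrows():
            lines.append(f"  {r['outcome']:34s} OR={r['OR']:8.2f} "
                         f"p={r['p']:.2e} enriched in cluster {r['enriched_in']}")
        return "\n".join(lines)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top
        running = min(running, p[idx] * m / i)
        adj[idx] = running
    return adj
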