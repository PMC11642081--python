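"""Descriptive analyses: disease-count distribution, prevalence tables, and
two-group comparisons (pooled-variance t-tests and Pearson chi-square).

Comorbidity is defined as >=1 systemic disease, multimorbidity as >=2.
Percentages are rounded half-up to one decimal for display, matching the
convention of the published tables; all stored values are unrounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, PatientRecord

__all__ = [
    "CountDistribution",
    "GroupComparison",
    "disease_count",
    "count_distribution",
    "prevalence_table",
    "compare_groups",
    "round_half_up",
]

CONTINUOUS_VARS = ("age", "sep", "n_pockets_ge6", "bop_pct", "n_teeth", "pisa_mm2")
CATEGORICAL_VARS = ("sex", "smoking")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (0.05 -> 0.1)."""
    factor = 10 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def disease_count(record: PatientRecord | np.ndarray) -> int:
    """Number of systemic diseases a patient carries (sum of the 26 flags)."""
    if isinstance(record, PatientRecord):
        return record.disease_count
    return int(np.asarray(record).sum())


@dataclass
class CountDistribution:
    """Distribution of the number of systemic diseases per patient.

    ``bins`` holds the patient counts for exactly 0, 1, 2, 3, 4 and >=5
    diseases.  The mean/SD are computed over comorbid patients (>=1 disease)
    — the convention of the published figure — with the total-population
    variants also stored, labelled.
    """

    bins: tuple[int, int, int, int, int, int]
    n_total: int
    mean_diseases: float | None          # among patients with >= 1 disease
    sd_diseases: float | None
    mean_diseases_total: float | None = None   # whole-cohort denominator
    sd_diseases_total: float | None = None
    max_diseases: int | None = None

    def __post_init__(self) -> None:
        if sum(self.bins) != self.n_total:
            raise ValueError("bins must sum to n_total")

    @property
    def n_comorbid(self) -> int:
        return self.n_total - self.bins[0]

    @property
    def n_multimorbid(self) -> int:
        return self.n_total - self.bins[0] - self.bins[1]

    @property
    def comorbidity_prevalence(self) -> float:
        """Share of patients with >= 1 systemic disease (fraction)."""
        return self.n_comorbid / self.n_total

    @property
    def multimorbidity_prevalence(self) -> float:
        """Share of patients with >= 2 systemic diseases (fraction)."""
        return self.n_multimorbid / self.n_total

    @classmethod
    def from_bins(cls, bins, n_total: int | None = None) -> "CountDistribution":
        """Build from published histogram bins (0,1,2,3,4,>=5 patients).

        Mean/SD are unavailable from binned data alone and left missing.
        """
        bins = tuple(int(b) for b in bins)
        if len(bins) != 6:
            raise ValueError("expected 6 bins: 0,1,2,3,4,>=5 diseases")
        total = int(n_total) if n_total is not None else sum(bins)
        return cls(bins=bins, n_total=total, mean_diseases=None, sd_diseases=None)

    def to_frame(self) -> pd.DataFrame:
        labels = ["0", "1", "2", "3", "4", ">=5"]
        pct = [100 * b / self.n_total for b in self.bins]
        return pd.DataFrame({"n_diseases": labels, "count": self.bins,
                             "percent": [round_half_up(p) for p in pct]})


def count_distribution(cohort: Cohort) -> CountDistribution:
    """Tabulate disease counts; comorbidity/multimorbidity prevalence included."""
    counts = cohort.disease_counts()
    bins = tuple(int((counts == k).sum()) for k in range(5)) + (int((counts >= 5).sum()),)
    comorbid = counts[counts >= 1]
    if comorbid.size:
        mean_c, sd_c = float(comorbid.mean()), float(comorbid.std(ddof=1)) if comorbid.size > 1 else 0.0
    else:
        mean_c = sd_c = None
    return CountDistribution(
        bins=bins[:5] + (bins[5],),
        n_total=len(cohort),
        mean_diseases=mean_c,
        sd_diseases=sd_c,
        mean_diseases_total=float(counts.mean()),
        sd_diseases_total=float(counts.std(ddof=1)) if counts.size > 1 else 0.0,
        max_diseases=int(counts.max()),
    )


def prevalence_table(cohort: Cohort, strata: dict[str, np.ndarray] | None = None
                     ) -> pd.DataFrame:
    """Per-disease count and percent for each stratum.

    ``strata`` maps stratum name -> boolean mask over cohort rows; the
    default reports the total population and the comorbid subgroup.  An
    empty stratum yields a missing percent.  Index: disease id; columns:
    MultiIndex (stratum, {count, percent}); percents rounded half-up to one
    decimal.
    """
    if strata is None:
        counts = cohort.disease_counts()
        strata = {"total": np.ones(len(cohort), bool), "comorbid": counts >= 1}
    flags = cohort.flags_matrix()
    out: dict[tuple[str, str], list] = {}
    for name, mask in strata.items():
        mask = np.asarray(mask, dtype=bool)
        n_stratum = int(mask.sum())
        cnt = flags[mask].sum(axis=0) if n_stratum else np.zeros(flags.shape[1], int)
        pct = [round_half_up(100 * c / n_stratum) if n_stratum else np.nan for c in cnt]
        out[(name, "count")] = [int(c) for c in cnt]
        out[(name, "percent")] = pct
    table = pd.DataFrame(out, index=list(cohort.codebook.diseases))
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["stratum", "measure"])
    table.attrs["stratum_sizes"] = {k: int(np.asarray(m, bool).sum()) for k, m in strata.items()}
    return table


@dataclass
class GroupComparison:
    """One two-group test: pooled t (continuous) or Pearson chi-square (2x2)."""

    variable: str
    test: str                      # "t" or "chi2"
    statistic: float
    p_value: float
    group_summaries: dict = field(default_factory=dict)
    df: float | None = None
    note: str | None = None

    @property
    def significant(self) -> bool:
        return bool(self.p_value < 0.05)


def _t_comparison(x0: np.ndarray, x1: np.ndarray, name: str,
                  welch: bool = False) -> GroupComparison:
    x0 = x0[~np.isnan(x0)]
    x1 = x1[~np.isnan(x1)]
    summaries = {
        "group0": {"n": x0.size, "mean": float(x0.mean()), "sd": float(x0.std(ddof=1))},
        "group1": {"n": x1.size, "mean": float(x1.mean()), "sd": float(x1.std(ddof=1))},
    }
    if x0.std(ddof=1) == 0 and x1.std(ddof=1) == 0:
        if x0.mean() == x1.mean():
            return GroupComparison(name, "t", 0.0, 1.0, summaries,
                                   note="zero variance in both groups")
        return GroupComparison(name, "t", np.nan, np.nan, summaries,
                               note="zero variance in both groups; statistic undefined")
    res = stats.ttest_ind(x0, x1, equal_var=not welch)
    df = x0.size + x1.size - 2 if not welch else res.df
    return GroupComparison(name, "t", float(res.statistic), float(res.pvalue),
                           summaries, df=float(df))


def _chi2_comparison(b0: np.ndarray, b1: np.ndarray, name: str) -> GroupComparison:
    table = np.array([
        [(b0 == 1).sum(), (b0 == 0).sum()],
        [(b1 == 1).sum(), (b1 == 0).sum()],
    ])
    summaries = {
        "group0": {"n": int(b0.size), "count": int(table[0, 0]),
                   "percent": round_half_up(100 * table[0, 0] / b0.size)},
        "group1": {"n": int(b1.size), "count": int(table[1, 0]),
                   "percent": round_half_up(100 * table[1, 0] / b1.size)},
    }
    if (table.sum(axis=0) == 0).any():
        return GroupComparison(name, "chi2", 0.0, 1.0, summaries,
                               note="degenerate margin; no association testable")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return GroupComparison(name, "chi2", float(chi2), float(p), summaries, df=float(dof))


def compare_groups(cohort: Cohort, grouping: np.ndarray,
                   variables: list[str] | None = None,
                   welch: bool = False) -> list[GroupComparison]:
    """Compare two patient groups variable-by-variable.

    ``grouping`` is a binary label per record (0/1 or boolean).  Continuous
    variables get a two-sample Student t-test with pooled variance (Welch
    behind the ``welch`` flag); binary variables get Pearson's uncorrected
    chi-square on the 2x2 table.  Two-sided p-values; no multiplicity
    correction (per-variable tests, as in the source tables).
    """
    grouping = np.asarray(grouping).astype(int)
    if set(np.unique(grouping)) - {0, 1}:
        raise ValueError("grouping must be binary")
    if (grouping == 0).sum() == 0 or (grouping == 1).sum() == 0:
        raise ValueError("both groups must be non-empty")
    variables = variables or list(CONTINUOUS_VARS) + list(CATEGORICAL_VARS)

    frame = cohort.frame
    results = []
    for var in variables:
        if var in CONTINUOUS_VARS:
            x = frame[var].to_numpy(dtype=float)
            results.append(_t_comparison(x[grouping == 0], x[grouping == 1], var, welch))
        elif var == "sex":
            b = (frame["sex"] == "female").to_numpy(int)
            results.append(_chi2_comparison(b[grouping == 0], b[grouping == 1], "sex_female"))
        elif var == "smoking":
            b = frame["smoking"].to_numpy(int)
            results.append(_chi2_comparison(b[grouping == 0], b[grouping == 1], var))
        elif var in cohort.codebook.diseases:
            b = frame[var].to_numpy(int)
            results.append(_chi2_comparison(b[grouping == 0], b[grouping == 1], var))
        else:
            raise KeyError(f"unknown variable: {var!r}")
    return results


def characteristics_table(cohort: Cohort, groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Cohort-characteristics table: mean +/- SD or n (%) per group column."""
    rows: dict[str, dict[str, str]] = {}
    frame = cohort.frame
    for name, mask in groups.items():
        mask = np.asarray(mask, bool)
        sub = frame.loc[mask]
        col: dict[str, str] = {"n": str(int(mask.sum()))}
        for var in CONTINUOUS_VARS:
            x = sub[var].dropna()
            col[var] = f"{x.mean():.1f} ± {x.std(ddof=1):.1f}" if len(x) > 1 else "-"
        n = len(sub)
        if n:
            f = int((sub["sex"] == "female").sum())
            s = int(sub["smoking"].sum())
            col["sex_female"] = f"{f} ({round_half_up(100 * f / n)})"
            col["smoking"] = f"{s} ({round_half_up(100 * s / n)})"
        rows[name] = col
    return pd.DataFrame(rows)
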