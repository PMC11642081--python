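"""Two-step clustering of patients on binary disease indicators.

The procedure mirrors the classical two-step approach for categorical data:

1. a sequential *leader pass* (pre-clustering) that condenses records into
   at most ``max_leaves`` dense leaves, each record joining its nearest leaf
   when the log-likelihood distance increase stays within a threshold;
2. *hierarchical agglomerative* merging of the leaves under the
   log-likelihood distance, recording BIC(J) for every candidate cluster
   count J;
3. automatic selection of the cluster count by the conventional two-stage
   criterion: a coarse bound from the relative BIC improvement, refined by
   the ratio of closest-pair merge distances.

For a cluster v over K binary attributes the log-likelihood cost is the
total entropy

    xi_v = N_v * sum_k E_vk,   E_vk = -sum_l (N_vkl/N_v) ln(N_vkl/N_v),

(natural log, 0 ln 0 := 0) and the distance between clusters a and b is the
cost increase of pooling them, d(a, b) = xi_{a+b} - xi_a - xi_b >= 0.
BIC(J) = 2 sum_v xi_v + J*K*ln N for binary attributes (one free parameter
per attribute per cluster).

The leader pass is order-dependent; by default records are visited in a
seeded random shuffle so that results are reproducible and independent of
input file order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "ClusterSummary",
    "cluster_cost",
    "ll_distance",
    "precluster",
    "agglomerate",
    "select_k",
    "TwoStepCluster",
    "TwoStepClusterResults",
]

# leader-pass threshold used when doubling up from zero
_BASE_THRESHOLD = 2.0 * np.log(2.0)

# Selection constants of the conventional two-stage criterion (configurable;
# not estimated from data).
BIC_RATIO_THRESHOLD = 0.04
DISTANCE_RATIO_FACTOR = 1.15


def _nlogn_table(n_max: int) -> np.ndarray:
    """Lookup table t[i] = i*ln(i) with t[0] = 0, for integer entropy sums."""
    t = np.zeros(n_max + 1)
    if n_max >= 1:
        idx = np.arange(1, n_max + 1, dtype=float)
        t[1:] = idx * np.log(idx)
    return t


def _cost_from_counts(sizes, ones, table: np.ndarray):
    """Vectorized xi for leaves given sizes (L,) and one-counts (L, K)."""
    sizes = np.atleast_1d(np.asarray(sizes, dtype=np.int64))
    ones = np.atleast_2d(np.asarray(ones, dtype=np.int64))
    K = ones.shape[-1]
    return K * table[sizes] - table[ones].sum(axis=-1) - table[sizes[..., None] - ones].sum(axis=-1)


@dataclass
class ClusterSummary:
    """Sufficient statistics of one cluster: size and per-attribute 1-counts."""

    n: int
    ones: np.ndarray  # (K,) counts of attribute value 1

    def __post_init__(self) -> None:
        self.ones = np.asarray(self.ones, dtype=np.int64)
        if self.n < 1:
            raise ValueError("cluster must contain at least one member")
        if ((self.ones < 0) | (self.ones > self.n)).any():
            raise ValueError("category counts must lie in [0, N_v]")

    @classmethod
    def from_flags(cls, flags: np.ndarray) -> "ClusterSummary":
        flags = np.atleast_2d(np.asarray(flags))
        return cls(n=flags.shape[0], ones=flags.sum(axis=0))

    def merge(self, other: "ClusterSummary") -> "ClusterSummary":
        if self.ones.shape != other.ones.shape:
            raise ValueError("summaries cover different attribute sets")
        return ClusterSummary(n=self.n + other.n, ones=self.ones + other.ones)


def cluster_cost(summary: ClusterSummary) -> float:
    """Log-likelihood cost xi_v = N_v * total attribute entropy (>= 0)."""
    table = _nlogn_table(summary.n)
    return float(_cost_from_counts(summary.n, summary.ones, table)[0])


def ll_distance(a: ClusterSummary, b: ClusterSummary) -> float:
    """Pooled-entropy increase d(a, b) = xi_{a+b} - xi_a - xi_b; symmetric, >= 0."""
    if a.ones.shape != b.ones.shape:
        raise ValueError("summaries cover different attribute sets")
    merged = a.merge(b)
    return cluster_cost(merged) - cluster_cost(a) - cluster_cost(b)


def _leader_pass(flags: np.ndarray, threshold: float, max_leaves: int):
    """Single sequential pass; returns (sizes, ones, leaf_costs, assign) or None
    when the leaf cap is exceeded."""
    n, K = flags.shape
    table = _nlogn_table(n)
    sizes = np.zeros(max_leaves, dtype=np.int64)
    ones = np.zeros((max_leaves, K), dtype=np.int64)
    costs = np.zeros(max_leaves)
    assign = np.empty(n, dtype=np.int64)
    L = 0
    for i in range(n):
        x = flags[i]
        if L:
            pool_sizes = sizes[:L] + 1
            pool_ones = ones[:L] + x
            pooled = _cost_from_counts(pool_sizes, pool_ones, table)
            d = pooled - costs[:L]  # singleton cost is 0
            j = int(np.argmin(d))
            # absolute epsilon absorbs float cancellation error in d == 0 cases
            if d[j] <= threshold + 1e-9:
                sizes[j] += 1
                ones[j] += x
                costs[j] = pooled[j]
                assign[i] = j
                continue
        if L == max_leaves:
            return None
        sizes[L] = 1
        ones[L] = x
        costs[L] = 0.0
        assign[i] = L
        L += 1
    return sizes[:L], ones[:L], costs[:L], assign


def precluster(flags_or_cohort, threshold: float = 0.0, max_leaves: int = 512,
               return_assignments: bool = False):
    """Leader-pass pre-clustering into at most ``max_leaves`` leaves.

    Each record joins the nearest leaf when the log-likelihood distance
    increase is at most ``threshold``, else starts a new leaf.  If the cap
    is exceeded the threshold is doubled (from ``2 ln 2`` when zero) and the
    pass is rebuilt from scratch.  Returns the leaf summaries (and record ->
    leaf assignments when requested); leaves partition the input.
    """
    if max_leaves < 2:
        raise ValueError("max_leaves must be >= 2")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    flags = flags_or_cohort.flags_matrix() if isinstance(flags_or_cohort, Cohort) \
        else np.asarray(flags_or_cohort)
    while True:
        out = _leader_pass(flags, threshold, max_leaves)
        if out is not None:
            sizes, ones, _, assign = out
            leaves = [ClusterSummary(int(s), o) for s, o in zip(sizes, ones)]
            return (leaves, assign) if return_assignments else leaves
        threshold = threshold * 2 if threshold > 0 else _BASE_THRESHOLD


@dataclass
class AgglomerationResult:
    """Merge history, BIC trace and per-J partitions from agglomeration."""

    bic_trace: dict[int, float]           # J -> BIC(J), J = 1..J_max
    dmin_trace: dict[int, float]          # J -> closest-pair distance at J clusters
    merge_history: list[tuple[int, int, int, float]]  # (J_before, i, j, distance)
    partitions: dict[int, np.ndarray]     # J -> leaf -> cluster-representative map
    n_records: int


def agglomerate(leaves: list[ClusterSummary], J_max: int = 15,
                n_records: int | None = None) -> AgglomerationResult:
    """Greedy closest-pair merging of leaves down to one cluster.

    Ties in closest-pair selection break on the lowest (i, j) index pair.
    BIC(J) = 2 sum xi_v + J*K*ln N is recorded for every J <= J_max, along
    with the closest-pair distance among the J active clusters (the cost of
    the merge J -> J-1) and the leaf partition at each J.
    """
    L = len(leaves)
    if L < 2:
        raise ValueError("agglomeration needs at least 2 leaves")
    K = leaves[0].ones.size
    N = n_records if n_records is not None else sum(s.n for s in leaves)
    table = _nlogn_table(N)

    sizes = np.array([s.n for s in leaves], dtype=np.int64)
    ones = np.vstack([s.ones for s in leaves]).astype(np.int64)
    costs = _cost_from_counts(sizes, ones, table)

    # pairwise distance matrix, upper triangle (i < j); inf elsewhere
    D = np.full((L, L), np.inf)
    for i in range(L - 1):
        js = np.arange(i + 1, L)
        pooled = _cost_from_counts(sizes[i] + sizes[js], ones[i] + ones[js], table)
        D[i, i + 1:] = pooled - costs[i] - costs[js]

    active = np.ones(L, dtype=bool)
    rep = np.arange(L)  # leaf -> current cluster representative (lowest index)
    log_n = np.log(N)

    bic_trace: dict[int, float] = {}
    dmin_trace: dict[int, float] = {}
    partitions: dict[int, np.ndarray] = {}
    merges: list[tuple[int, int, int, float]] = []

    J = L
    while True:
        if J <= J_max:
            bic_trace[J] = 2.0 * costs[active].sum() + J * K * log_n
            partitions[J] = rep.copy()
        if J == 1:
            break
        flat = int(np.argmin(D))  # row-major => lowest (i, j) on ties
        i, j = divmod(flat, L)
        d = D[i, j]
        if J <= J_max + 1:
            dmin_trace[J] = float(d)
        merges.append((J, int(i), int(j), float(d)))
        # merge j into i
        sizes[i] += sizes[j]
        ones[i] += ones[j]
        costs[i] = _cost_from_counts(sizes[i], ones[i], table)[0]
        active[j] = False
        rep[rep == j] = i
        D[j, :] = np.inf
        D[:, j] = np.inf
        others = np.flatnonzero(active)
        others = others[others != i]
        if others.size:
            pooled = _cost_from_counts(sizes[i] + sizes[others], ones[i] + ones[others], table)
            dvals = pooled - costs[i] - costs[others]
            lo = others[others < i]
            hi = others[others > i]
            D[lo, i] = dvals[others < i]
            D[i, hi] = dvals[others > i]
        J -= 1

    return AgglomerationResult(bic_trace=bic_trace, dmin_trace=dmin_trace,
                               merge_history=merges, partitions=partitions,
                               n_records=N)


def select_k(bic_trace: dict[int, float], dmin_trace: dict[int, float],
             bic_ratio: float = BIC_RATIO_THRESHOLD,
             dist_ratio: float = DISTANCE_RATIO_FACTOR) -> int:
    """Two-stage automatic cluster-count selection.

    Stage 1 (coarse): k_coarse is the smallest J whose relative BIC change
    R1(J) = [BIC(J-1) - BIC(J)] / [BIC(1) - BIC(2)] falls below ``bic_ratio``.
    Stage 2 (refine): among 2 <= J <= k_coarse, R2(J) = d_min(J)/d_min(J+1);
    the J with the largest R2 wins when the top two R2 values differ by a
    factor >= ``dist_ratio``, else the larger of the two J.  A degenerate
    trace (no BIC improvement from 1 to 2) yields k = 1.
    """
    J_vals = sorted(bic_trace)
    if len(J_vals) < 2:
        return 1
    denom = bic_trace[1] - bic_trace[2]
    if denom <= 0:
        return 1
    k_coarse = max(J_vals)
    for J in J_vals:
        if J < 2:
            continue
        r1 = (bic_trace[J - 1] - bic_trace[J]) / denom
        if r1 < bic_ratio:
            k_coarse = J
            break
    candidates = [J for J in range(2, k_coarse + 1)
                  if J in dmin_trace and (J + 1) in dmin_trace]
    if not candidates:
        return min(2, max(J_vals))
    r2 = {J: (dmin_trace[J] / dmin_trace[J + 1]) if dmin_trace[J + 1] > 0 else np.inf
          for J in candidates}
    ranked = sorted(candidates, key=lambda J: (-r2[J], J))
    if len(ranked) == 1:
        return ranked[0]
    best, second = ranked[0], ranked[1]
    if r2[second] == 0 or (np.isinf(r2[best]) and not np.isinf(r2[second])) \
            or r2[best] >= dist_ratio * r2[second]:
        return best
    return max(best, second)


class TwoStepCluster:
    """Two-step clustering model over a cohort's 26 binary disease flags.

    Parameters
    ----------
    cohort : Cohort or array-like of shape (n, K)
        The patients to cluster (typically the comorbid subset).
    threshold, max_leaves : leader-pass controls.
    j_max : largest cluster count considered in selection.
    shuffle, seed : visit records in a seeded random order (default) to
        neutralize the order dependence of the leader pass.
    """

    def __init__(self, cohort, *, threshold: float = 0.0, max_leaves: int = 512,
                 j_max: int = 15, shuffle: bool = True, seed: int = 0,
                 bic_ratio: float = BIC_RATIO_THRESHOLD,
                 dist_ratio: float = DISTANCE_RATIO_FACTOR):
        self.cohort = cohort if isinstance(cohort, Cohort) else None
        self.flags = cohort.flags_matrix() if isinstance(cohort, Cohort) \
            else np.asarray(cohort, dtype=np.int8)
        self.threshold = threshold
        self.max_leaves = max_leaves
        self.j_max = j_max
        self.shuffle = shuffle
        self.seed = seed
        self.bic_ratio = bic_ratio
        self.dist_ratio = dist_ratio

    def fit(self) -> "TwoStepClusterResults":
        n = self.flags.shape[0]
        order = (np.random.default_rng(self.seed).permutation(n)
                 if self.shuffle else np.arange(n))
        flags = self.flags[order]
        leaves, leaf_assign = precluster(flags, self.threshold, self.max_leaves,
                                         return_assignments=True)
        if len(leaves) == 1:
            k = 1
            record_cluster = np.zeros(n, dtype=int)
            agg = None
            bic = {1: 2.0 * cluster_cost(leaves[0]) + 1 * leaves[0].ones.size * np.log(n)}
            dmin: dict[int, float] = {}
        else:
            agg = agglomerate(leaves, J_max=self.j_max, n_records=n)
            bic, dmin = agg.bic_trace, agg.dmin_trace
            k = select_k(bic, dmin, self.bic_ratio, self.dist_ratio)
            rep = agg.partitions[k]
            record_cluster = rep[leaf_assign]

        # undo the shuffle, relabel clusters 1..k by descending size
        assignments = np.empty(n, dtype=int)
        assignments[order] = record_cluster
        uniq, counts = np.unique(assignments, return_counts=True)
        rank = {u: r + 1 for r, u in enumerate(uniq[np.argsort(-counts, kind="stable")])}
        assignments = np.array([rank[a] for a in assignments])

        profiles = pd.DataFrame(
            {c: self.flags[assignments == c].mean(axis=0) for c in range(1, k + 1)}
        ).T
        if self.cohort is not None:
            profiles.columns = list(self.cohort.codebook.diseases)
        profiles.index.name = "cluster"

        return TwoStepClusterResults(
            model=self, k=k, assignments=assignments, profiles=profiles,
            bic_trace=bic, dmin_trace=dmin,
            merge_history=agg.merge_history if agg else [],
            n_leaves=len(leaves),
        )


@dataclass
class TwoStepClusterResults:
    """Fitted clustering: selected k, assignments, profiles and traces."""

    model: TwoStepCluster
    k: int
    assignments: np.ndarray               # cluster id 1..k per record
    profiles: pd.DataFrame                # per-cluster disease prevalence
    bic_trace: dict[int, float]
    dmin_trace: dict[int, float]
    merge_history: list = field(default_factory=list)
    n_leaves: int = 0

    @property
    def cluster_sizes(self) -> dict[int, int]:
        uniq, counts = np.unique(self.assignments, return_counts=True)
        return {int(u): int(c) for u, c in zip(uniq, counts)}

    @property
    def cluster_shares(self) -> dict[int, float]:
        n = self.assignments.size
        return {c: s / n for c, s in self.cluster_sizes.items()}

    def assignments_series(self) -> pd.Series:
        if self.model.cohort is None:
            return pd.Series(self.assignments, name="cluster")
        return pd.Series(self.assignments, name="cluster",
                         index=self.model.cohort.frame["patient_id"].to_numpy())

    def summary(self) -> str:
        lines = [
            "Two-step cluster analysis (log-likelihood distance, binary attributes)",
            f"records: {self.assignments.size}   leaves: {self.n_leaves}   "
            f"selected k: {self.k}",
            "cluster sizes: " + ", ".join(
                f"{c}: {s} ({100 * s / self.assignments.size:.1f}%)"
                for c, s in self.cluster_sizes.items()),
            "BIC(J): " + ", ".join(f"{J}: {b:.1f}" for J, b in sorted(self.bic_trace.items())),
        ]
        if self.k > 1 and not self.profiles.empty:
            top = self.profiles.T
            lines.append("top discriminating diseases (prevalence by cluster):")
            spread = (top.max(axis=1) - top.min(axis=1)).sort_values(ascending=False)
            for d in spread.index[:5]:
                lines.append("  " + d + ": " + ", ".join(
                    f"{top.at[d, c]:.3f}" for c in top.columns))
        return "\n".join(lines)
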