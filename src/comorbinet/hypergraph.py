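"""Hypergraph analysis of disease co-occurrence among multimorbid patients.

Diseases are nodes; each multimorbid patient (>= 2 systemic diseases)
contributes a hyperedge — the set of diseases they carry.  From the
disease-by-patient incidence matrix M the symmetric co-occurrence adjacency
is A = M M^T - D_n, with D_n the diagonal of M M^T (per-disease occurrence
counts), so A has zero diagonal and A_ij counts the patients carrying both
diseases i and j.  Disease centrality is the principal (Perron)
eigenvector of A, computed by power iteration and normalized to unit
Euclidean norm.

The >=8-occurrence hyperedge filter is a visualization aid only: centrality
is computed on the full multimorbid incidence matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "IncidenceMatrix",
    "HyperedgeCatalog",
    "CooccurrenceAdjacency",
    "CentralityScores",
    "build_incidence",
    "catalog_hyperedges",
    "filter_catalog",
    "adjacency",
    "centrality",
    "export_hypergraph",
]


@dataclass
class IncidenceMatrix:
    """Binary diseases-by-patients matrix (rows: codebook order)."""

    M: np.ndarray
    disease_ids: tuple[str, ...]
    patient_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.int8)
        if self.M.shape != (len(self.disease_ids), len(self.patient_ids)):
            raise ValueError("incidence shape does not match labels")
        if not np.isin(self.M, (0, 1)).all():
            raise ValueError("incidence entries must be 0/1")

    @property
    def n_diseases(self) -> int:
        return self.M.shape[0]

    @property
    def n_patients(self) -> int:
        return self.M.shape[1]


@dataclass
class HyperedgeCatalog:
    """Unique disease combinations (|set| >= 2) with occurrence counts."""

    entries: dict[tuple[str, ...], int]

    def __post_init__(self) -> None:
        for combo, count in self.entries.items():
            if len(combo) < 2:
                raise ValueError(f"hyperedge {combo} has fewer than 2 diseases")
            if count < 1:
                raise ValueError("hyperedge counts must be >= 1")
            if tuple(sorted(combo)) != combo:
                raise ValueError(f"hyperedge {combo} must be a sorted tuple")

    @property
    def total_occurrences(self) -> int:
        return sum(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CooccurrenceAdjacency:
    """Symmetric co-occurrence matrix A = M M^T - D_n and the D_n used."""

    A: np.ndarray
    D_n: np.ndarray
    disease_ids: tuple[str, ...]


@dataclass
class CentralityScores:
    """Principal-eigenvector disease centrality, unit Euclidean norm."""

    scores: pd.Series          # index: disease id; non-negative
    eigenvalue: float
    iterations: int
    degenerate: bool = False   # top eigenvalue nearly multiple: vector non-unique

    def top(self, k: int = 3) -> list[str]:
        return list(self.scores.sort_values(ascending=False).index[:k])


def build_incidence(cohort: Cohort, min_diseases: int = 2) -> IncidenceMatrix:
    """Incidence matrix over patients with >= ``min_diseases`` diseases."""
    counts = cohort.disease_counts()
    mask = counts >= min_diseases
    if not mask.any():
        raise ValueError(f"no patient carries >= {min_diseases} diseases")
    sub = cohort.frame.loc[mask]
    M = sub[list(cohort.codebook.diseases)].to_numpy(dtype=np.int8).T
    return IncidenceMatrix(M=M, disease_ids=tuple(cohort.codebook.diseases),
                           patient_ids=tuple(str(p) for p in sub["patient_id"]))


def catalog_hyperedges(incidence: IncidenceMatrix) -> HyperedgeCatalog:
    """Group identical patient columns into unique disease-set hyperedges."""
    ids = np.array(incidence.disease_ids)
    entries: dict[tuple[str, ...], int] = {}
    for col in incidence.M.T:
        combo = tuple(sorted(ids[col.astype(bool)]))
        entries[combo] = entries.get(combo, 0) + 1
    return HyperedgeCatalog(entries=entries)


def filter_catalog(catalog: HyperedgeCatalog, min_count: int = 8) -> HyperedgeCatalog:
    """Retain hyperedges occurring at least ``min_count`` times (visualization)."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    kept = {c: n for c, n in catalog.entries.items() if n >= min_count}
    out = HyperedgeCatalog.__new__(HyperedgeCatalog)  # allow empty result
    out.entries = kept
    return out


def adjacency(incidence: IncidenceMatrix,
              diagonal: str = "counts") -> CooccurrenceAdjacency:
    """Co-occurrence adjacency A = M M^T - D_n.

    ``diagonal="counts"`` (default) takes D_n = diag(M M^T), the per-disease
    occurrence counts, which zeroes the diagonal and leaves A_ij = number of
    patients carrying both i and j.  ``diagonal="proportions"`` subtracts
    prevalence proportions instead (alternative reading of the published
    construction), leaving a mixed-scale diagonal.
    """
    MMT = incidence.M.astype(np.int64) @ incidence.M.astype(np.int64).T
    if diagonal == "counts":
        D = np.diag(np.diag(MMT))
        A = MMT - D
    elif diagonal == "proportions":
        prev = np.diag(MMT).astype(float) / incidence.n_patients
        D = np.diag(prev)
        A = MMT.astype(float) - D
    else:
        raise ValueError("diagonal must be 'counts' or 'proportions'")
    return CooccurrenceAdjacency(A=A, D_n=D, disease_ids=incidence.disease_ids)


def centrality(adj: CooccurrenceAdjacency, tol: float = 1e-12,
               max_iter: int = 100_000) -> CentralityScores:
    """Principal-eigenvector centrality by power iteration.

    Starts from the uniform vector; converges when the max-norm change of
    the unit-normalized iterate falls below ``tol``.  The sign is fixed so
    the largest-magnitude entry is positive; isolated diseases (zero row
    sum) score exactly 0.  An all-zero matrix is an error; a (near-)
    degenerate top eigenvalue is flagged.
    """
    A = np.asarray(adj.A, dtype=float)
    if not A.any():
        raise ValueError("all-zero adjacency: centrality undefined")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")

    connected = A.sum(axis=1) != 0
    B = A[np.ix_(connected, connected)]
    # positive spectral shift: keeps eigenvectors, makes the Perron eigenvalue
    # strictly dominant (a bipartite-like A has lambda_min = -lambda_max and
    # unshifted power iteration would oscillate)
    shift = float(B.sum(axis=1).max())
    Bs = B + shift * np.eye(B.shape[0])
    v = np.full(B.shape[0], 1.0 / np.sqrt(B.shape[0]))
    lam = 0.0
    for it in range(1, max_iter + 1):
        w = Bs @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("power iteration annihilated the start vector")
        w /= norm
        if np.max(np.abs(w - v)) < tol:
            v = w
            break
        v = w
    lam = float(v @ B @ v)

    # sign fix and re-embedding of isolated diseases as exact zeros
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    full = np.zeros(A.shape[0])
    full[connected] = v
    full = np.where(np.abs(full) < 1e-15, 0.0, full)
    nrm = np.linalg.norm(full)
    full /= nrm

    # multiplicity guard (cheap: the disease set is small)
    eigvals = np.linalg.eigvalsh(A)
    degenerate = bool(eigvals.size >= 2 and
                      abs(eigvals[-1] - eigvals[-2]) < 1e-9 * max(1.0, abs(eigvals[-1])))
    if degenerate:
        warnings.warn("top eigenvalue nearly degenerate: centrality vector "
                      "is not unique", stacklevel=2)
    return CentralityScores(scores=pd.Series(full, index=list(adj.disease_ids)),
                            eigenvalue=lam, iterations=it, degenerate=degenerate)


def export_hypergraph(catalog: HyperedgeCatalog, scores: CentralityScores,
                      out_dir) -> dict[str, Path]:
    """Write node/hyperedge TSV tables plus a JSON bundle; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    degree: dict[str, int] = {d: 0 for d in scores.scores.index}
    for combo, count in catalog.entries.items():
        for d in combo:
            degree[d] = degree.get(d, 0) + count

    nodes = pd.DataFrame({
        "disease": scores.scores.index,
        "centrality": scores.scores.to_numpy(),
        "degree": [degree.get(d, 0) for d in scores.scores.index],
    })
    nodes_path = out_dir / "nodes.tsv"
    nodes.to_csv(nodes_path, sep="\t", index=False)
    paths = {"nodes": nodes_path}

    if catalog.entries:
        edges = pd.DataFrame({
            "edge_id": [f"e{i}" for i in range(len(catalog.entries))],
            "diseases": ["|".join(c) for c in catalog.entries],
            "count": list(catalog.entries.values()),
        })
        edges_path = out_dir / "hyperedges.tsv"
        edges.to_csv(edges_path, sep="\t", index=False)
        paths["hyperedges"] = edges_path
    else:
        warnings.warn("hyperedge catalog is empty after filtering; "
                      "writing node table only", stacklevel=2)

    bundle_path = out_dir / "hypergraph.json"
    with open(bundle_path, "w", encoding="utf-8") as fh:
        json.dump({
            "nodes": nodes.to_dict(orient="records"),
            "hyperedges": [{"diseases": list(c), "count": n}
                           for c, n in catalog.entries.items()],
            "eigenvalue": scores.eigenvalue,
        }, fh, indent=2)
    paths["bundle"] = bundle_path
    return paths
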