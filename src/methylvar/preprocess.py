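"""Phenotype/probe residualization, marker standardization, relationship matrices.

The pipeline convention is: adjust the phenotype for age, age squared and
sex by OLS and carry the residuals forward; adjust every CpG probe for
technical and biological covariates (age, sex, batch, slide, cell-type
proportions, smoking score) and then scale each adjusted column to unit
variance.  Relationship matrices are (1/p)·Z·Zᵀ on the standardized
columns — the GRM when Z holds dosage z-scores, the omics relationship
matrix (ORM) when it holds residualized probe z-scores.  Relatedness
filtering keeps a subset of individuals whose pairwise relationship never
reaches the threshold, by greedy removal of the most-connected individual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ResidualizedMatrix",
    "RelationshipMatrix",
    "build_design",
    "residualize_phenotype",
    "residualize_and_standardize_markers",
    "compute_relationship_matrix",
    "grm_from_dosages",
    "filter_unrelated",
]

logger = logging.getLogger(__name__)

DEFAULT_PROBE_COVARIATES = ("age", "sex", "batch", "slide", "cell", "smoking_score")


@dataclass
class ResidualizedMatrix:
    """Covariate-adjusted, column-standardized marker matrix."""

    values: np.ndarray  # n x p, each column mean 0 / variance 1 (ddof=1)
    marker_ids: np.ndarray
    covariate_spec: tuple = ()
    dropped: list = field(default_factory=list)  # zero-variance columns removed

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class RelationshipMatrix:
    values: np.ndarray  # n x n symmetric
    kind: str  # "GRM" or "ORM"
    n_markers: int


def build_design(
    covariates: pd.DataFrame | None,
    columns=DEFAULT_PROBE_COVARIATES,
    n: int | None = None,
) -> tuple[np.ndarray, list]:
    """Assemble an OLS design (with intercept) from a covariate table.

    ``batch`` and ``slide`` expand to dummy indicators (first level
    dropped); ``cell`` expands to all ``cell_*`` simplex columns minus the
    first (the proportions sum to one, so the full set is collinear with
    the intercept).  Unknown names raise.
    """
    if covariates is None:
        if n is None:
            raise ValueError("need n when no covariates are supplied")
        return np.ones((n, 1)), ["intercept"]
    parts = [np.ones(len(covariates))]
    names = ["intercept"]
    for c in columns:
        if c in ("batch", "slide"):
            if c not in covariates.columns:
                continue
            d = pd.get_dummies(covariates[c].astype("category"), prefix=c, drop_first=True)
            parts.extend(d[col].to_numpy(float) for col in d.columns)
            names.extend(d.columns)
        elif c == "cell":
            cell_cols = [k for k in covariates.columns if k.startswith("cell_")]
            for col in cell_cols[1:]:
                parts.append(covariates[col].to_numpy(float))
                names.append(col)
        else:
            if c not in covariates.columns:
                raise KeyError(f"covariate column {c!r} not found")
            parts.append(covariates[c].to_numpy(float))
            names.append(c)
    return np.column_stack(parts), names


def _check_full_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns whose removal restores full column rank
        collinear = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                collinear.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")


def residualize_phenotype(
    phenotype: np.ndarray,
    covariates: pd.DataFrame,
    extra_fixed_effects: list | None = None,
) -> np.ndarray:
    """OLS residuals of the phenotype on intercept, age, age², sex (+extras).

    ``extra_fixed_effects`` names additional covariate columns — e.g. a
    precomputed polygenic score — absorbed as fixed effects before any
    variance decomposition.
    """
    y = np.asarray(phenotype, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("phenotype contains missing/non-finite values")
    for c in ("age", "sex"):
        if c not in covariates.columns:
            raise KeyError(f"covariates must include {c!r}")
    age = covariates["age"].to_numpy(float)
    cols = [np.ones_like(y), age, age**2, covariates["sex"].to_numpy(float)]
    names = ["intercept", "age", "age2", "sex"]
    for c in extra_fixed_effects or []:
        cols.append(covariates[c].to_numpy(float))
        names.append(c)
    X = np.column_stack(cols)
    _check_full_rank(X, names)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def residualize_and_standardize_markers(
    matrix: np.ndarray,
    marker_ids,
    covariates: pd.DataFrame | None = None,
    covariate_columns=DEFAULT_PROBE_COVARIATES,
) -> ResidualizedMatrix:
    """Residualize each marker column on the covariates, then z-score it.

    With ``covariates=None`` (the genotype convention) this is plain
    column standardization.  All-constant residual columns are dropped and
    recorded, never imputed.
    """
    M = np.asarray(matrix, dtype=float)
    if np.any(~np.isfinite(M)):
        raise ValueError("marker matrix contains missing/non-finite values")
    marker_ids = np.asarray(marker_ids)
    if covariates is not None and len(covariates) != M.shape[0]:
        raise ValueError("covariate table is not row-aligned with the marker matrix")
    X, names = build_design(covariates, covariate_columns, n=M.shape[0])
    coef, *_ = np.linalg.lstsq(X, M, rcond=None)
    R = M - X @ coef
    sd = R.std(axis=0, ddof=1)
    keep = sd > 1e-10
    dropped = list(marker_ids[~keep])
    if dropped:
        logger.warning("dropping %d zero-variance marker columns", len(dropped))
    Z = (R[:, keep] - R[:, keep].mean(axis=0)) / sd[keep]
    return ResidualizedMatrix(
        values=Z,
        marker_ids=marker_ids[keep],
        covariate_spec=tuple(names),
        dropped=dropped,
    )


def compute_relationship_matrix(
    z: ResidualizedMatrix, kind: str = "ORM", chunk_size: int = 10_000
) -> RelationshipMatrix:
    """(1/p)·Z·Zᵀ accumulated over marker blocks of ``chunk_size`` columns."""
    if z.p < 2:
        raise ValueError("need at least 2 markers for a relationship matrix")
    if kind not in ("GRM", "ORM"):
        raise ValueError("kind must be 'GRM' or 'ORM'")
    n = z.n
    A = np.zeros((n, n))
    for start in range(0, z.p, chunk_size):
        block = z.values[:, start : start + chunk_size]
        A += block @ block.T
    A /= z.p
    A = (A + A.T) / 2.0
    return RelationshipMatrix(values=A, kind=kind, n_markers=z.p)


def grm_from_dosages(dosages: np.ndarray, snp_ids=None) -> RelationshipMatrix:
    """GRM with the standard per-SNP centering 2p̂ and scaling √(2p̂(1−p̂))."""
    G = np.asarray(dosages, dtype=float)
    freq = G.mean(axis=0) / 2.0
    keep = (freq > 0) & (freq < 1)
    W = (G[:, keep] - 2 * freq[keep]) / np.sqrt(2 * freq[keep] * (1 - freq[keep]))
    A = W @ W.T / keep.sum()
    return RelationshipMatrix(values=(A + A.T) / 2.0, kind="GRM", n_markers=int(keep.sum()))


def filter_unrelated(rel: RelationshipMatrix, threshold: float = 0.05) -> np.ndarray:
    """Indices of a subset with all off-diagonal relationships < threshold.

    Greedy: while any off-diagonal entry ≥ threshold, remove the individual
    with the most above-threshold pairs; among equally connected
    individuals the highest index is removed (the lower index is kept).
    Returned indices preserve the original order.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    A = rel.values
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("relationship matrix is not symmetric")
    n = A.shape[0]
    adj = (np.abs(A) >= threshold).astype(int)
    np.fill_diagonal(adj, 0)
    alive = np.ones(n, dtype=bool)
    degree = adj.sum(axis=1)
    while True:
        deg_alive = np.where(alive, degree, -1)
        dmax = deg_alive.max()
        if dmax <= 0:
            break
        worst = int(np.flatnonzero(deg_alive == dmax)[-1])
        alive[worst] = False
        degree -= adj[worst]
        degree[worst] = 0
        adj[worst, :] = 0
        adj[:, worst] = 0
    return np.flatnonzero(alive)
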