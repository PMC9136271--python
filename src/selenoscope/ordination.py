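"""Constrained correspondence analysis with collinearity pruning.

The community table (samples × OTUs) is converted to the chi-square
standardized residual matrix Q̄ = D_r^{−1/2}(P − r cᵀ)D_c^{−1/2} where P
is the table scaled to a grand total of one and r, c its row and column
masses.  Q̄ is regressed onto the row-weighted, centered explanatory
variables; the SVD of the fitted part yields the constrained axes and
the SVD of the residual the unconstrained axes.  Eigenvalues are squared
singular values; their sum (constrained + unconstrained) equals the
total inertia Σ Q̄², the chi-square statistic of the table divided by its
grand total.

Scores use the symmetric ("scaling 3") convention: site and feature
scores each carry the square root of the singular values.  Axis signs
are fixed by making the largest-magnitude feature score on each axis
positive.

Explanatory variables are pruned before fitting: exactly collinear
columns are removed by QR rank detection, then variables are dropped
iteratively while the largest variance-inflation factor exceeds a
threshold (default 10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from selenoscope.datamodel import ValidationError

__all__ = ["CcaResult", "vif_prune", "cca_fit"]

_EPS = 1e-10


@dataclass
class CcaResult:
    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    total_inertia: float
    constrained_inertia: float
    site_scores: pd.DataFrame
    feature_scores: pd.DataFrame
    biplot_scores: pd.DataFrame


def _vif(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1/(1−R²) regressing it on the others + intercept."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(len(y)), others])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - ss_res / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_prune(
    constraint_matrix: pd.DataFrame, threshold: float = 10.0
) -> tuple[pd.DataFrame, list[str]]:
    """Drop collinear explanatory variables until max VIF ≤ threshold.

    Exactly collinear columns go first (QR rank detection, keeping the
    earliest linearly independent columns); then the column with the
    largest VIF is dropped repeatedly, ties breaking toward the later
    column index.  Returns (pruned matrix, dropped column names).
    """
    if constraint_matrix.shape[1] < 1:
        raise ValidationError("need at least one explanatory variable")
    X = constraint_matrix.to_numpy(dtype=float)
    names = list(constraint_matrix.columns)
    dropped: list[str] = []

    # exact collinearity: greedy QR — keep columns that enlarge the rank
    centered = X - X.mean(axis=0)
    keep: list[int] = []
    for j in range(centered.shape[1]):
        trial = centered[:, keep + [j]]
        if np.linalg.matrix_rank(trial, tol=1e-9 * max(1.0, np.abs(trial).max())) > len(keep):
            keep.append(j)
        else:
            dropped.append(names[j])
    cols = [names[j] for j in keep]
    X = X[:, keep]

    while X.shape[1] > 1:
        vifs = np.array([_vif(X, j) for j in range(X.shape[1])])
        worst = float(np.max(vifs))
        if worst <= threshold:
            break
        j = int(np.flatnonzero(vifs == worst)[-1])  # later column on ties
        dropped.append(cols[j])
        cols = cols[:j] + cols[j + 1 :]
        X = np.delete(X, j, axis=1)
    if X.shape[1] == 0:
        raise ValidationError(
            "all explanatory variables dropped; raise the VIF threshold"
        )
    return constraint_matrix[cols], dropped


def cca_fit(otu_counts: pd.DataFrame, constraints: pd.DataFrame) -> CcaResult:
    """Constrained correspondence analysis of samples × OTUs counts.

    ``constraints`` is samples × variables, aligned by index with
    ``otu_counts``.  OTUs with zero total are dropped with a warning;
    samples with zero total raise.
    """
    if list(otu_counts.index) != list(constraints.index):
        constraints = constraints.reindex(otu_counts.index)
        if constraints.isna().any().any():
            raise ValidationError("constraints missing for some samples")
    X = otu_counts.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValidationError("negative community values")
    row_tot = X.sum(axis=1)
    if (row_tot <= 0).any():
        bad = otu_counts.index[row_tot <= 0][0]
        raise ValidationError(f"sample {bad!r} has zero total")
    col_tot = X.sum(axis=0)
    if (col_tot <= 0).any():
        empty = list(otu_counts.columns[col_tot <= 0])
        warnings.warn(f"dropping OTUs with zero total: {empty}")
        otu_counts = otu_counts.loc[:, col_tot > 0]
        X = otu_counts.to_numpy(dtype=float)
        col_tot = X.sum(axis=0)

    grand = X.sum()
    P = X / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    Dr_isqrt = 1.0 / np.sqrt(r)
    Dc_isqrt = 1.0 / np.sqrt(c)
    Qbar = Dr_isqrt[:, None] * (P - np.outer(r, c)) * Dc_isqrt[None, :]
    total_inertia = float((Qbar**2).sum())

    Z = constraints.to_numpy(dtype=float)
    # center under row weights, then weight rows by sqrt(r)
    Z = Z - (r[:, None] * Z).sum(axis=0)
    Zw = np.sqrt(r)[:, None] * Z
    rank = np.linalg.matrix_rank(Zw)
    if rank == 0:
        raise ValidationError("constraint matrix has rank 0 after weighting")

    # projection of Qbar onto col-space of Zw via least squares
    coef, _, _, _ = np.linalg.lstsq(Zw, Qbar, rcond=None)
    fitted = Zw @ coef
    residual = Qbar - fitted

    max_axes = min(rank, X.shape[0] - 1, X.shape[1] - 1)
    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    keep = s**2 > _EPS * max(1.0, total_inertia)
    U, s, Vt = U[:, keep][:, :max_axes], s[keep][:max_axes], Vt[keep][:max_axes]
    constrained_eigs = s**2

    Ur, sr, Vtr = np.linalg.svd(residual, full_matrices=False)
    keep_r = sr**2 > _EPS * max(1.0, total_inertia)
    Ur, sr, Vtr = Ur[:, keep_r], sr[keep_r], Vtr[keep_r]
    unconstrained_eigs = sr**2

    # symmetric scaling: both sides carry sqrt of singular values
    axes = [f"CCA{i+1}" for i in range(len(s))]
    site = Dr_isqrt[:, None] * U * np.sqrt(s)[None, :]
    feat = (Dc_isqrt[:, None] * Vt.T) * np.sqrt(s)[None, :]
    # sign convention: largest-|score| feature positive per axis
    for k in range(feat.shape[1]):
        i_max = int(np.argmax(np.abs(feat[:, k])))
        if feat[i_max, k] < 0:
            feat[:, k] *= -1
            site[:, k] *= -1
            U[:, k] *= -1

    # biplot scores: weighted correlation of constraints with site axes (U)
    biplot = np.zeros((Z.shape[1], len(s)))
    for j in range(Z.shape[1]):
        zj = Zw[:, j]
        norm = np.linalg.norm(zj)
        if norm > 0:
            biplot[j] = (zj @ U) / norm

    return CcaResult(
        constrained_eigenvalues=constrained_eigs,
        unconstrained_eigenvalues=unconstrained_eigs,
        total_inertia=total_inertia,
        constrained_inertia=float(constrained_eigs.sum()),
        site_scores=pd.DataFrame(site, index=otu_counts.index, columns=axes),
        feature_scores=pd.DataFrame(feat, index=otu_counts.columns, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=constraints.columns, columns=axes),
    )
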