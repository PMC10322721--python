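"""PCA receptor gradients and the leave-one-receptor-out dependence statistic.

Given an areas x receptors density matrix, each receptor column is
z-scored (so high-density receptors do not dominate) and the gradients
are the principal components of the normalized matrix ``X = U S V^T``:
per-area PC scores ``Z = U S``, per-receptor loadings ``V`` and variance
fractions ``s_k^2 / sum_j s_j^2``.

The *gradient dependence* ``g`` of PC ``n`` on receptor ``r`` measures
how much the spatial pattern of that gradient relies on the receptor.
The first ``n - 1`` PCs are removed from the data (deflation), receptor
``r``'s column is dropped, and the first-PC scores of the reduced matrix
(computed without re-centering or re-scaling) are correlated with the
original PC-``n`` scores:

    g = 1 - rho^2,   rho = corr(Z_n, Z^{PCn+}_{1, r-})

Squaring makes ``g`` invariant to the arbitrary signs of PCs, so
``g`` in [0, 1]; ``g ~ 0`` means the gradient survives removal of the
receptor, ``g ~ 1`` means the gradient's spatial pattern collapses
without it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density_maps import ReceptorMatrix
from .exceptions import DataError, NumericalError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "GradientResult",
    "DependenceTable",
    "zscore_columns",
    "pca",
    "total_density",
    "fingerprint",
    "extreme_ratio",
    "gradient_dependence",
    "dependence_table",
    "receptor_space",
]


@dataclass
class GradientResult:
    """SVD factors of the z-scored matrix plus derived quantities.

    ``X_norm = U @ diag(S) @ V.T``; PC scores ``Z = U @ diag(S)`` are a
    DataFrame indexed by area, loadings ``V`` a DataFrame indexed by
    receptor; ``variance_fractions`` sum to 1 over all retained
    components (m = min(A, R), no truncation).
    """

    X_norm: pd.DataFrame
    U: np.ndarray
    S: np.ndarray
    V: pd.DataFrame
    Z: pd.DataFrame
    variance_fractions: np.ndarray

    @property
    def n_components(self) -> int:
        return self.S.shape[0]


@dataclass
class DependenceTable:
    """Gradient dependence g (and underlying rho) per PC x receptor."""

    g: pd.DataFrame
    rho: pd.DataFrame


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, ReceptorMatrix):
        return matrix.values
    return pd.DataFrame(matrix)


def zscore_columns(matrix) -> pd.DataFrame:
    """z-score each receptor column (mean 0, SD 1 with n-1 denominator).

    Rows (areas) with any missing entry are dropped listwise with a
    logged count; a constant column is a data error naming the receptor.
    """
    df = _as_frame(matrix).astype(float)
    complete = df.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("zscore_columns: dropping %d incomplete areas", n_dropped)
        df = df.loc[complete]
    sd = df.std(ddof=1)
    dead = sd.index[~(sd > 0)]
    if len(dead):
        raise DataError(f"constant receptor column(s): {list(map(str, dead))}")
    return (df - df.mean()) / sd


def pca(X_norm: pd.DataFrame) -> GradientResult:
    """Singular value decomposition of the normalized matrix.

    Sign convention (the SVD leaves each component's sign arbitrary):
    PC1 is oriented so its loading sum is positive, which makes the PC1
    scores correlate positively with total normalized density; every
    later PC is oriented so its largest-|loading| receptor loads
    positively.
    """
    X = X_norm.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise DataError("X_norm contains non-finite entries")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    V = Vt.T
    signs = np.ones(S.shape[0])
    if S.shape[0] >= 1:
        s0 = np.sign(V[:, 0].sum())
        signs[0] = s0 if s0 != 0 else 1.0
    for k in range(1, S.shape[0]):
        j = int(np.argmax(np.abs(V[:, k])))
        sk = np.sign(V[j, k])
        signs[k] = sk if sk != 0 else 1.0
    U = U * signs
    V = V * signs
    Z = U * S
    total = (S**2).sum()
    frac = S**2 / total if total > 0 else np.zeros_like(S)
    pcs = [f"PC{k + 1}" for k in range(S.shape[0])]
    return GradientResult(
        X_norm=X_norm,
        U=U,
        S=S,
        V=pd.DataFrame(V, index=X_norm.columns, columns=pcs),
        Z=pd.DataFrame(Z, index=X_norm.index, columns=pcs),
        variance_fractions=frac,
    )


def total_density(matrix) -> pd.Series:
    """Per-area total density (row sum over receptors)."""
    df = _as_frame(matrix)
    out = df.sum(axis=1)
    out.name = "total_density"
    return out


def fingerprint(matrix, area: str) -> tuple[pd.Series, float]:
    """One area's receptor-density vector in canonical order, plus total."""
    df = _as_frame(matrix)
    if area not in df.index:
        raise KeyError(f"unknown area {area!r}")
    row = df.loc[area]
    return row, float(row.sum())


def extreme_ratio(matrix, receptor: str, reference_area: str | None = None
                  ) -> tuple[float, str, str]:
    """Max/min density ratio for one receptor (or max over a reference area).

    Returns (ratio, argmax area, argmin-or-reference area).
    """
    df = _as_frame(matrix)
    if receptor not in df.columns:
        raise KeyError(f"unknown receptor {receptor!r}")
    col = df[receptor].dropna()
    top = str(col.idxmax())
    if reference_area is not None:
        if reference_area not in col.index:
            raise KeyError(f"unknown reference area {reference_area!r}")
        denom_area = str(reference_area)
    else:
        denom_area = str(col.idxmin())
    denom = float(col.loc[denom_area])
    if denom <= 0:
        raise DataError(f"non-positive denominator density in area {denom_area}")
    return float(col.max()) / denom, top, denom_area


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise NumericalError("zero-variance projection in dependence statistic")
    return float(a @ b / (na * nb))


def gradient_dependence(X_norm: pd.DataFrame, n: int, receptor: str,
                        result: GradientResult | None = None,
                        return_rho: bool = False):
    """Gradient dependence g of PC ``n`` (1-based) on one receptor.

    Steps: deflate the first n-1 PCs (``X^{PCn+} = Z_{n+} V_{n+}^T``),
    drop the receptor's column, take the first-PC scores of the reduced
    matrix *without re-centering or re-scaling*, correlate with the
    original ``Z_n`` and return ``g = 1 - rho^2``.
    """
    if n < 1:
        raise ParameterError("PC index n is 1-based and must be >= 1")
    if X_norm.shape[1] < 3:
        raise ParameterError("need at least 3 receptors")
    if receptor not in X_norm.columns:
        raise KeyError(f"unknown receptor {receptor!r}")
    res = result if result is not None else pca(X_norm)
    if n > res.n_components:
        raise ParameterError(f"PC index {n} exceeds {res.n_components} components")
    Z = res.Z.to_numpy()
    V = res.V.to_numpy()
    X_defl = Z[:, n - 1:] @ V[:, n - 1:].T
    cols = list(X_norm.columns)
    keep = [i for i, c in enumerate(cols) if c != receptor]
    X_red = X_defl[:, keep]
    U2, S2, _ = np.linalg.svd(X_red, full_matrices=False)
    if S2[0] <= 0:
        raise NumericalError("reduced matrix has rank 0")
    z1 = U2[:, 0] * S2[0]
    rho = _pearson(Z[:, n - 1], z1)
    rho = float(np.clip(rho, -1.0, 1.0))  # guard round-off past |rho| = 1
    if return_rho:
        return 1.0 - rho**2, rho
    return 1.0 - rho**2


def dependence_table(X_norm: pd.DataFrame, n_pcs: int | None = None) -> DependenceTable:
    """Gradient dependence for every (PC, receptor) pair."""
    res = pca(X_norm)
    m = res.n_components if n_pcs is None else min(n_pcs, res.n_components)
    receptors = list(X_norm.columns)
    g = np.empty((m, len(receptors)))
    rho = np.empty_like(g)
    for i in range(m):
        for j, r in enumerate(receptors):
            g[i, j], rho[i, j] = gradient_dependence(X_norm, i + 1, r,
                                                     result=res, return_rho=True)
    idx = [f"PC{k + 1}" for k in range(m)]
    return DependenceTable(
        g=pd.DataFrame(g, index=idx, columns=receptors),
        rho=pd.DataFrame(rho, index=idx, columns=receptors),
    )


def receptor_space(result: GradientResult, labels: pd.Series | None = None) -> pd.DataFrame:
    """Per-area (PC1, PC2) coordinates — the 2-D 'receptor space'."""
    if result.n_components < 2:
        raise ParameterError("receptor space needs at least 2 components")
    out = result.Z[["PC1", "PC2"]].copy()
    if labels is not None:
        out["group"] = labels.reindex(out.index)
    return out
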