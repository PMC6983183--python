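"""Ordination of the HRV feature table with external-variable fitting.

PCA is computed on the correlation matrix (features are standardized first;
units across the eleven features are incommensurate).  External clinical
variables (AHI, ODI, ESS, ...) are related to the ordination by

* vector fitting — the direction in the component plane along which the
  variable has maximal correlation, its squared multiple correlation R^2,
  and a permutation p-value obtained by comparing the observed R^2 with the
  null distribution under random permutation of the variable
  (add-one tail probability, 999 permutations by default);
* surface fitting — a least-squares linear trend of the variable over the
  first two component scores; for a linear trend the isoclines are parallel,
  equally spaced lines perpendicular to the fitted vector.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "OrdinationResult", "VectorFit", "SurfaceFit",
    "standardize_features", "pca", "fit_vector", "fit_surface",
]


@dataclass
class OrdinationResult:
    scores: pd.DataFrame      # subjects x components
    loadings: pd.DataFrame    # features x components
    variance_explained: np.ndarray

    def __post_init__(self) -> None:
        total = float(np.sum(self.variance_explained))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"variance_explained sums to {total}, expected 1")
        if np.any(np.diff(self.variance_explained) > 1e-12):
            raise ValueError("components must be ordered by decreasing variance")


@dataclass
class VectorFit:
    variable: str
    direction: np.ndarray     # unit vector in component space
    r_squared: float
    p_value: float
    n_permutations: int


@dataclass
class SurfaceFit:
    variable: str
    coefficients: np.ndarray  # (intercept, b1, b2) over (PC1, PC2)
    r_squared: float
    isocline_levels: np.ndarray

    @property
    def gradient_direction(self) -> np.ndarray:
        """Unit gradient of the linear surface; coincides with the fitted vector."""
        g = self.coefficients[1:]
        return g / np.linalg.norm(g)

    def isocline_offsets(self) -> np.ndarray:
        """Signed distances of the isocline lines from the origin.

        For a linear surface with equally spaced levels these are equally
        spaced — the diagnostic of linearity in the ordination plane.
        """
        g = self.coefficients[1:]
        return (self.isocline_levels - self.coefficients[0]) / np.linalg.norm(g)


def standardize_features(table: pd.DataFrame) -> pd.DataFrame:
    """Center each feature to mean 0 and scale to unit (sample) SD."""
    if len(table) < 2:
        raise ValueError("standardization requires at least 2 subjects")
    values = table.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("feature table contains non-finite values")
    sd = values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [table.columns[i] for i in zero]
        raise ValueError(f"zero-variance feature(s): {names}")
    z = (values - values.mean(axis=0)) / sd
    return pd.DataFrame(z, index=table.index, columns=table.columns)


def pca(table: pd.DataFrame) -> OrdinationResult:
    """Principal components of a standardized feature table.

    Keeps all ``min(n_subjects, n_features)`` components so the explained
    variance fractions sum to 1.  Component signs are oriented so that the
    feature with the largest loading magnitude on each component is positive
    (reproducible biplots).
    """
    X = table.to_numpy(dtype=float)
    n_comp = min(X.shape)
    model = PCA(n_components=n_comp, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # features x components, orthonormal columns
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n_comp)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip
    comp_names = [f"PC{j + 1}" for j in range(n_comp)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=table.columns, columns=comp_names),
        variance_explained=model.explained_variance_ratio_,
    )


def _check_variable(ord_res: OrdinationResult, variable: np.ndarray) -> np.ndarray:
    y = np.asarray(variable, dtype=float)
    if y.ndim != 1 or y.size != len(ord_res.scores):
        raise ValueError("variable length must equal the number of subjects")
    if not np.all(np.isfinite(y)):
        raise ValueError("variable contains non-finite values")
    if np.ptp(y) == 0:
        raise ValueError("variable is constant; vector/surface fitting undefined")
    return y


def fit_vector(ord_res: OrdinationResult, variable: np.ndarray,
               name: str = "variable", n_perm: int = 999, seed: int = 0,
               n_axes: int = 2) -> VectorFit:
    """Direction of maximal correlation of a variable in the component plane.

    The direction is the (normalized) regression of the variable on the
    first ``n_axes`` component scores; R^2 is the squared multiple
    correlation of that regression.  Significance is the tail probability of
    the observed R^2 under random permutation of the variable:
    ``p = (1 + #{R2_perm >= R2_obs}) / (1 + n_perm)``.
    """
    y = _check_variable(ord_res, variable)
    S = ord_res.scores.to_numpy()[:, :n_axes]
    yc = y - y.mean()
    Q, _ = np.linalg.qr(S - S.mean(axis=0))  # orthonormal basis of the plane
    ss_tot = float(yc @ yc)
    r2 = float(np.sum((Q.T @ yc) ** 2) / ss_tot)
    beta, *_ = np.linalg.lstsq(S - S.mean(axis=0), yc, rcond=None)
    norm = np.linalg.norm(beta)
    direction = beta / norm if norm > 0 else np.full(n_axes, np.nan)

    rng = np.random.default_rng(seed)
    n = y.size
    perms = np.empty((n_perm, n), dtype=np.intp)
    for k in range(n_perm):
        perms[k] = rng.permutation(n)
    # ||Q^T y_perm||^2 row-wise; total sum of squares is permutation-invariant
    proj = yc[perms] @ Q
    r2_perm = np.sum(proj**2, axis=1) / ss_tot
    n_ge = int(np.sum(r2_perm >= r2))
    p = (1 + n_ge) / (1 + n_perm)
    return VectorFit(variable=name, direction=direction, r_squared=r2,
                     p_value=p, n_permutations=n_perm)


def fit_surface(ord_res: OrdinationResult, variable: np.ndarray,
                name: str = "variable", n_levels: int = 9) -> SurfaceFit:
    """Least-squares linear trend of a variable over the first two components.

    Isocline levels default to ``n_levels`` equally spaced values spanning
    the fitted range, so a linear trend yields parallel, equally spaced
    contour lines.
    """
    y = _check_variable(ord_res, variable)
    S = ord_res.scores.to_numpy()[:, :2]
    X = np.column_stack([np.ones(len(y)), S])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    levels = np.linspace(fitted.min(), fitted.max(), n_levels)
    return SurfaceFit(variable=name, coefficients=coef, r_squared=r2,
                      isocline_levels=levels)
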