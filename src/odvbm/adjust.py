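"""Voxelwise nuisance-covariate removal by multiple linear regression.

Before group comparison, tissue-density maps are corrected for intracranial
volume, age, clinic site and time from randomization to scan: at each voxel
an ordinary-least-squares model over the pooled cohort is fit and the fitted
nuisance contribution subtracted.  Adjusted maps are returned as
``residual + grand_mean`` (the per-voxel cohort mean), so they remain on the
tissue-density scale.

The transformer is scikit-learn shaped (`fit`/`transform` on a
subjects-by-voxels matrix); :func:`build_design`, :func:`fit_nuisance` and
:func:`residualize` are thin functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["DesignMatrix", "NuisanceRegressor", "build_design", "fit_nuisance", "residualize"]

_CONTINUOUS = ["icv", "age", "time_to_scan"]


@dataclass
class DesignMatrix:
    """Named nuisance design: intercept, centered continuous covariates and
    reference-coded site indicators (first site alphabetically is reference)."""

    columns: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError("values must be (subjects, len(columns))")
        if np.linalg.matrix_rank(self.values) < len(self.columns):
            raise ValueError("degenerate design: columns are collinear")


def build_design(frame: pd.DataFrame) -> DesignMatrix:
    """Build the nuisance design from a covariate table.

    Continuous covariates (icv, age, time_to_scan) are centered at their
    sample means; k sites produce k-1 indicator columns against the
    alphabetically first site.
    """
    n = len(frame)
    cols, mats = ["intercept"], [np.ones((n, 1))]
    for c in _CONTINUOUS:
        v = frame[c].to_numpy(dtype=float)
        mats.append((v - v.mean())[:, None])
        cols.append(c)
    sites = sorted(frame["site"].astype(str).unique())
    for s in sites[1:]:
        mats.append((frame["site"].astype(str) == s).to_numpy(float)[:, None])
        cols.append(f"site[{s}]")
    if n < len(cols) + 2:
        raise ValueError(f"need >= {len(cols) + 2} subjects for {len(cols)} columns")
    return DesignMatrix(columns=cols, values=np.hstack(mats))


class NuisanceRegressor(BaseEstimator, TransformerMixin):
    """Voxelwise OLS nuisance removal.

    Parameters
    ----------
    protect : array-like of shape (n_subjects,), optional
        Binary group labels to protect: when given, a centered group
        indicator is included in the fit so that nuisance slopes are
        estimated adjusting for group, but the group effect itself is not
        removed from the data.
    clip_negative : bool, default False
        Clip adjusted values at 0 (off by default so residuals stay exactly
        orthogonal to the design).

    Attributes
    ----------
    coef_ : ndarray of shape (n_columns, n_voxels)
        Per-voxel nuisance slopes (rows ordered as ``design_.columns``).
    grand_mean_ : ndarray of shape (n_voxels,)
        Per-voxel cohort mean; adjusted maps equal residual + grand_mean_.
    design_ : DesignMatrix
    """

    def __init__(self, protect=None, clip_negative: bool = False):
        self.protect = protect
        self.clip_negative = clip_negative

    def fit(self, X, design: DesignMatrix):
        X = np.asarray(X, dtype=np.float64)
        Z = design.values
        if X.shape[0] != Z.shape[0]:
            raise ValueError("X rows must align with design rows")
        if X.shape[0] < Z.shape[1]:
            raise ValueError("underdetermined fit: fewer subjects than columns")
        if self.protect is not None:
            g = np.asarray(self.protect, dtype=float)
            Zfit = np.hstack([Z, (g - g.mean())[:, None]])
        else:
            Zfit = Z
        beta, *_ = np.linalg.lstsq(Zfit, X, rcond=None)
        self.design_ = design
        self.coef_ = beta[: Z.shape[1]]
        self._protect_coef = beta[Z.shape[1]:] if self.protect is not None else None
        self.grand_mean_ = X.mean(axis=0)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        Z = self.design_.values
        if X.shape[0] != Z.shape[0]:
            raise ValueError("X rows must align with the fitted design rows")
        # remove every nuisance column except the intercept, then re-center
        # on the cohort mean so adjusted maps stay on the density scale
        nuis = [i for i, c in enumerate(self.design_.columns) if c != "intercept"]
        adjusted = X - Z[:, nuis] @ self.coef_[nuis]
        adjusted = adjusted - adjusted.mean(axis=0) + self.grand_mean_
        if self.clip_negative:
            adjusted = np.clip(adjusted, 0.0, None)
        return adjusted

    def coefficients_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coef_.T, columns=self.design_.columns)


def fit_nuisance(X, design: DesignMatrix, protect=None) -> NuisanceRegressor:
    return NuisanceRegressor(protect=protect).fit(X, design)


def residualize(X, model: NuisanceRegressor) -> np.ndarray:
    return model.transform(X)
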