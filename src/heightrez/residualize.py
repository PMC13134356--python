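"""Sex-standardized height and its non-genetic residual.

Height in cm is standardized within sex, a mixed model predicts the height
Z-score from the polygenic score, sex and ancestry PCs with genetic
relatedness, household and census block as random effects (model 1; model 2
adds age and age squared), and the non-genetic component of height is the
fixed-effects-only residual:

    height_rez     = height Z - X beta_hat (model 1)
    height_rez_age = height Z - X beta_hat (model 2)

Random-effect BLUPs are deliberately NOT subtracted: the residual should
retain shared-environment signal (household, neighbourhood), not remove it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .varcomp import VarCompFit, reml_fit


def standardize_height(height_cm, sex, weights=None):
    """Within-sex Z-score of height, using sample means and SDs.

    Unweighted by default (means/SDs are plain sample statistics); pass
    survey weights for a weighted variant. Each sex stratum needs >= 2
    members.
    """
    h = np.asarray(height_cm, dtype=float)
    s = np.asarray(sex)
    if (h <= 0).any():
        raise DataError("height_cm must be positive")
    bad = set(np.unique(s)) - {"F", "M"}
    if bad:
        raise DataError(f"sex must be 'F' or 'M', got {sorted(bad)}")
    z = np.empty_like(h)
    w = np.ones_like(h) if weights is None else np.asarray(weights, dtype=float)
    for lvl in np.unique(s):
        idx = s == lvl
        if idx.sum() < 2:
            raise DataError(f"sex stratum {lvl!r} has < 2 members")
        mu = np.average(h[idx], weights=w[idx])
        var = np.average((h[idx] - mu) ** 2, weights=w[idx])
        var *= idx.sum() / (idx.sum() - 1) if weights is None else 1.0
        z[idx] = (h[idx] - mu) / np.sqrt(var)
    return z


def _design(pgs, sex, pcs, age=None):
    pgs = np.asarray(pgs, dtype=float)
    pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
    if pcs.shape[0] != len(pgs):
        pcs = pcs.T
    sex_m = (np.asarray(sex) == "M").astype(float)
    cols = [np.ones_like(pgs), pgs, sex_m] + [pcs[:, j] for j in range(pcs.shape[1])]
    names = ["intercept", "pgs", "sex_M"] + [f"PC{j + 1}" for j in range(pcs.shape[1])]
    if age is not None:
        a = np.asarray(age, dtype=float)
        cols += [a, a**2]
        names += ["age", "age2"]
    return np.column_stack(cols), names


def fit_height_model(height_z, pgs, sex, pcs, kernels, kernel_names=None,
                     include_age=False, age=None, **reml_kwargs) -> VarCompFit:
    """Fit the height prediction mixed model (model 1, or model 2 with age).

    Fixed effects: intercept, PGS, sex, the supplied PCs, and (when
    ``include_age``) age and age^2. Random effects come from ``kernels``
    (GRM, household, block). Delegates to :func:`heightrez.varcomp.reml_fit`.
    """
    if include_age and age is None:
        raise DataError("include_age=True requires the age vector")
    X, names = _design(pgs, sex, pcs, age if include_age else None)
    return reml_fit(np.asarray(height_z, dtype=float), X, kernels,
                    kernel_names=kernel_names, beta_names=names, **reml_kwargs)


@dataclass
class ResidualSet:
    """Per-participant height Z-scores and fixed-effects-only residuals."""

    table: pd.DataFrame  # id, height_z, height_rez, height_rez_age,
                         # fitted_fixed_m1, fitted_fixed_m2

    def write_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)


def extract_residuals(ids, height_z, fit_m1: VarCompFit, fit_m2: VarCompFit,
                      pgs, sex, pcs, age) -> ResidualSet:
    """Fixed-effects-only residuals from the two converged height models."""
    for fit in (fit_m1, fit_m2):
        if not fit.converged:
            raise DataError("residual extraction requires converged fits")
    z = np.asarray(height_z, dtype=float)
    X1, _ = _design(pgs, sex, pcs)
    X2, _ = _design(pgs, sex, pcs, age)
    if X1.shape[1] != len(fit_m1.beta) or X2.shape[1] != len(fit_m2.beta):
        raise DataError("fit coefficient count does not match the design")
    if len(ids) != len(z):
        raise DataError("ids and height_z are misaligned")
    fitted1 = X1 @ fit_m1.beta
    fitted2 = X2 @ fit_m2.beta
    return ResidualSet(pd.DataFrame({
        "id": np.asarray(ids),
        "height_z": z,
        "height_rez": z - fitted1,
        "height_rez_age": z - fitted2,
        "fitted_fixed_m1": fitted1,
        "fitted_fixed_m2": fitted2,
    }))
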