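"""Design-based estimation for stratified multistage samples.

Weighted means and weighted linear regression with Taylor-linearized
variance: score residuals are totalled within primary sampling units (PSUs),
and the between-PSU variability within strata estimates the design variance
(the "with replacement" first-stage approximation, no finite-population
correction). Design degrees of freedom follow the standard convention
``#PSUs - #strata``; confidence intervals use the t distribution on those
df. Point estimates depend on weights only through relative weights.

Missing data are handled as domain (subpopulation) estimation: units with a
missing outcome or covariate keep their design membership — they contribute
zero score, but their stratum/PSU still counts — so variance strata are not
silently collapsed by missingness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DesignError, RankDeficiencyError


@dataclass
class SurveyDesign:
    """Per-participant stratum, PSU (nested in stratum) and weight."""

    stratum: np.ndarray
    psu: np.ndarray
    weight: np.ndarray

    def __post_init__(self):
        self.stratum = np.asarray(self.stratum)
        self.psu = np.asarray(self.psu)
        self.weight = np.asarray(self.weight, dtype=float)
        if not (len(self.stratum) == len(self.psu) == len(self.weight)):
            raise DesignError("stratum, psu, weight must have equal length")
        if not np.all(np.isfinite(self.weight)) or (self.weight <= 0).any():
            raise DesignError("weights must be finite and > 0")
        cells = pd.DataFrame({"s": self.stratum, "p": self.psu})
        per = cells.drop_duplicates().groupby("s").size()
        single = per[per < 2]
        if len(single):
            raise DesignError(
                f"stratum/strata {list(single.index)} contribute a single PSU; "
                "variance is inestimable (collapse strata or merge PSUs)")

    def __len__(self):
        return len(self.weight)

    @property
    def n_psus(self):
        return len(pd.DataFrame({"s": self.stratum, "p": self.psu}).drop_duplicates())

    @property
    def n_strata(self):
        return len(np.unique(self.stratum))

    @property
    def df(self):
        return self.n_psus - self.n_strata

    @classmethod
    def from_frame(cls, df, stratum="stratum", psu="psu", weight="weight"):
        return cls(df[stratum].to_numpy(), df[psu].to_numpy(),
                   df[weight].to_numpy(float))

    def subset(self, mask):
        """Design for a subset refit (drops units and unused strata/PSUs)."""
        mask = np.asarray(mask)
        return SurveyDesign(self.stratum[mask], self.psu[mask], self.weight[mask])


@dataclass
class AssocResult:
    """Survey-regression output: estimates, linearized SEs, CIs, Wald stats."""

    params: pd.DataFrame       # term, beta, se, ci_lo, ci_hi, t, p
    cov: np.ndarray
    df: int
    r_squared: float
    n: int

    def __getitem__(self, term):
        return self.params.set_index("term").loc[term]

    def to_json_dict(self):
        return {"params": self.params.to_dict(orient="records"),
                "df": self.df, "r_squared": self.r_squared, "n": self.n}


def _psu_total_variance(z, design: SurveyDesign):
    """Between-PSU variance of the total of linearized scores ``z``.

    ``z`` is (n, k); units with missing data must already carry zero rows.
    """
    df = pd.DataFrame(z)
    df["_s"] = design.stratum
    df["_p"] = design.psu
    totals = df.groupby(["_s", "_p"], sort=True).sum()
    k = z.shape[1]
    V = np.zeros((k, k))
    for s, grp in totals.groupby(level=0):
        a = grp.to_numpy()
        nh = a.shape[0]
        if nh < 2:
            raise DesignError(f"stratum {s} has a single PSU")
        d = a - a.mean(axis=0)
        V += nh / (nh - 1) * (d.T @ d)
    return V


def svy_mean(x, design: SurveyDesign):
    """Survey-weighted mean with Taylor-linearized SE.

    Missing values of ``x`` are dropped from the estimator (their weight does
    not enter the ratio) but their PSUs keep design membership. Returns
    ``(mean, se)``.
    """
    x = np.asarray(x, dtype=float)
    if len(x) != len(design):
        raise DataError("x and design are misaligned")
    ok = np.isfinite(x)
    if not ok.any():
        raise DataError("no non-missing observations")
    w = np.where(ok, design.weight, 0.0)
    sw = w.sum()
    mean = float((w * np.where(ok, x, 0.0)).sum() / sw)
    # linearized score of the ratio estimator
    z = (w * (np.where(ok, x, 0.0) - mean) / sw)[:, None]
    var = _psu_total_variance(z, design)[0, 0]
    return mean, float(np.sqrt(var))


def svy_lm(y, X, design: SurveyDesign, names=None) -> AssocResult:
    """Survey-weighted least squares with Taylor-linearized covariance.

    ``beta = (X'WX)^-1 X'Wy``; the covariance sandwiches the between-PSU
    variance of the weighted score totals ``w_i x_i e_i``. Complete cases
    only enter the normal equations; incomplete units keep design membership
    (domain semantics). CIs use ``t`` on ``#PSUs - #strata`` df.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y) or len(y) != len(design):
        raise DataError("y, X and design are misaligned")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    n_used = int(ok.sum())
    w = np.where(ok, design.weight, 0.0)
    Xc = np.where(ok[:, None], X, 0.0)
    yc = np.where(ok, y, 0.0)

    xtwx = (Xc * w[:, None]).T @ Xc
    rank = np.linalg.matrix_rank(xtwx)
    if rank < X.shape[1]:
        q, r = np.linalg.qr(Xc[ok] * np.sqrt(design.weight[ok])[:, None])
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.where(diag < diag.max() * 1e-10)[0]]
        raise RankDeficiencyError(
            f"design matrix rank deficient on the analysis set; "
            f"collinear column(s): {bad}", bad)
    ddf = design.df
    if ddf <= 0:
        raise DesignError("design degrees of freedom <= 0")
    xtwx_inv = np.linalg.inv(xtwx)
    beta = xtwx_inv @ ((Xc * w[:, None]).T @ yc)
    resid = yc - Xc @ beta
    scores = Xc * (w * resid)[:, None]
    meat = _psu_total_variance(scores, design)
    cov = xtwx_inv @ meat @ xtwx_inv
    se = np.sqrt(np.diag(cov))
    tcrit = stats.t.ppf(0.975, ddf)
    tstat = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    pvals = 2 * stats.t.sf(np.abs(tstat), ddf)
    ybar = (w * yc).sum() / w.sum()
    tss = float(w[ok] @ (y[ok] - ybar) ** 2)
    rss = float(w[ok] @ resid[ok] ** 2)
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    params = pd.DataFrame({
        "term": names, "beta": beta, "se": se,
        "ci_lo": beta - tcrit * se, "ci_hi": beta + tcrit * se,
        "t": tstat, "p": pvals,
    })
    return AssocResult(params=params, cov=cov, df=int(ddf), r_squared=r2, n=n_used)


def svy_interaction_test(result: AssocResult, terms) -> tuple[float, float]:
    """Joint Wald test of the named coefficients with design df.

    Returns ``(F_statistic, p_value)`` where F = W/q on (q, df) degrees of
    freedom, W the Wald quadratic form of the q tested coefficients. For a
    single term this squares the coefficient's t statistic exactly.
    """
    if isinstance(terms, str):
        terms = [terms]
    all_terms = list(result.params["term"])
    idx = []
    for t in terms:
        if t not in all_terms:
            raise DataError(f"term {t!r} not in the fitted model")
        idx.append(all_terms.index(t))
    b = result.params["beta"].to_numpy()[idx]
    V = result.cov[np.ix_(idx, idx)]
    W = float(b @ np.linalg.solve(V, b))
    q = len(idx)
    F = W / q
    p = float(stats.f.sf(F, q, result.df))
    return F, p
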