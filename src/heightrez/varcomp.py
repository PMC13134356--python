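"""Genetic relationship matrix, principal components, and REML variance
components.

The mixed model throughout is

    y ~ N(X beta,  sum_k sigma2_k K_k  +  sigma2_e I)

where each kernel ``K_k`` is either a genetic relationship matrix (GRM) or
the block-diagonal indicator kernel of a grouping factor (household, census
block). Variance components are estimated by restricted maximum likelihood
using Average-Information (AI) updates with EM fallback steps when an AI
proposal leaves the parameter space; for the single-GRM model an
eigen-rotation path (decompose the GRM once, profile the restricted
likelihood over the heritability ratio) gives the same maximum much faster
and is the default there.

Narrow-sense heritability is ``sigma2_g`` over a chosen denominator with a
delta-method CI from the AI-matrix-based covariance of the variance
components. Haseman-Elston regression (phenotype cross-products on GRM
entries) is provided as an independent moment-based estimator used for
cross-checks.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .errors import (ConvergenceError, DataError, InvalidParameterError,
                     RankDeficiencyError)
from .synth import GenotypeMatrix


# ---------------------------------------------------------------------------
# GRM

def compute_grm(genotypes: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """VanRaden method-1 GRM from dosages with sample allele frequencies.

    ``G = Z Z' / m`` with ``z_ij = (d_ij - 2 p_j) / sqrt(2 p_j (1 - p_j))``
    and ``p_j`` the sample frequency of the counted allele. Monomorphic SNPs
    are dropped with a warning. Returns ``(G, ids)``.
    """
    d = np.asarray(genotypes.dosages, dtype=float)
    if d.shape[0] < 2:
        raise DataError("GRM needs at least 2 participants")
    p = np.nanmean(d, axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise DataError("all SNPs are monomorphic; GRM undefined")
    if not poly.all():
        warnings.warn(f"dropping {int((~poly).sum())} monomorphic SNP(s) from GRM")
    d = d[:, poly]
    p = p[poly]
    z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    z = np.nan_to_num(z)  # missing dosage contributes 0 after centering
    g = (z @ z.T) / z.shape[1]
    return (g + g.T) / 2.0, np.asarray(genotypes.ids)


def top_pcs(grm: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-``k`` eigenvectors of the GRM, unit norm, eigenvalue-descending.

    Sign convention: the largest-magnitude loading of each PC is positive.
    Returns ``(pcs, eigenvalues)``.
    """
    if k <= 0:
        raise InvalidParameterError("k must be >= 1")
    n = grm.shape[0]
    if k >= n:
        raise InvalidParameterError(f"k must be < n ({n})")
    vals, vecs = linalg.eigh(grm, subset_by_index=(n - k, n - 1))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for j in range(k):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vecs, vals


# ---------------------------------------------------------------------------
# REML

@dataclass
class VarCompFit:
    """REML fit: fixed effects, variance components, and diagnostics."""

    beta: np.ndarray
    beta_cov: np.ndarray
    beta_names: list[str]
    varcomp: dict[str, float]            # includes "error"
    varcomp_cov: np.ndarray              # AI-based covariance, component order
    varcomp_names: list[str]
    loglik: float
    converged: bool
    n_iter: int
    trajectory: list = field(default_factory=list)
    method: str = "ai"

    @property
    def sigma2(self) -> np.ndarray:
        return np.array([self.varcomp[k] for k in self.varcomp_names])

    def to_json_dict(self):
        return {
            "beta": dict(zip(self.beta_names, self.beta.tolist())),
            "varcomp": self.varcomp,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "method": self.method,
        }


def _check_full_rank(X, names):
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    bad = diag < max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    if bad.any():
        cols = [names[i] for i in np.where(bad)[0]]
        raise RankDeficiencyError(
            f"design matrix rank deficient; collinear column(s): {cols}", cols)


def _as_kernel(k, n):
    k = np.asarray(k)
    if k.ndim == 2:
        if k.shape != (n, n):
            raise DataError(f"kernel shape {k.shape} does not match n={n}")
        return (k + k.T) / 2.0
    if k.ndim == 1:
        if k.shape[0] != n:
            raise DataError("grouping factor length does not match n")
        codes = pd.factorize(k)[0]
        if (codes < 0).any():
            raise DataError("grouping factor contains missing values")
        return (codes[:, None] == codes[None, :]).astype(float)
    raise DataError("kernel must be an n x n matrix or a length-n grouping factor")


def _reml_ll_only(y, X, V):
    """Restricted log-likelihood of V without forming V^-1 (for line search)."""
    cho = linalg.cho_factor(V, lower=True, check_finite=False)
    logdet_v = 2.0 * np.log(np.diag(cho[0])).sum()
    rhs = np.column_stack([X, y])
    sol = linalg.cho_solve(cho, rhs, check_finite=False)
    vinv_x, vinv_y = sol[:, :-1], sol[:, -1]
    xtvx = X.T @ vinv_x
    cho_x = linalg.cho_factor(xtvx, lower=True, check_finite=False)
    logdet_x = 2.0 * np.log(np.diag(cho_x[0])).sum()
    xty = X.T @ vinv_y
    ypy = float(y @ vinv_y) - float(xty @ linalg.cho_solve(cho_x, xty,
                                                           check_finite=False))
    return -0.5 * (logdet_v + logdet_x + ypy)


def _reml_ll_parts(y, X, V):
    """Return (loglik, P y, Vinv, P) for the restricted likelihood of V."""
    n, p = X.shape
    cho = linalg.cho_factor(V, lower=True, check_finite=False)
    logdet_v = 2.0 * np.log(np.diag(cho[0])).sum()
    vinv = linalg.cho_solve(cho, np.eye(n), check_finite=False)
    vinv_x = vinv @ X
    xtvx = X.T @ vinv_x
    cho_x = linalg.cho_factor(xtvx, lower=True, check_finite=False)
    logdet_x = 2.0 * np.log(np.diag(cho_x[0])).sum()
    proj = vinv - vinv_x @ linalg.cho_solve(cho_x, vinv_x.T, check_finite=False)
    py = proj @ y
    ll = -0.5 * (logdet_v + logdet_x + float(y @ py))
    return ll, py, vinv, proj, xtvx


def reml_fit(y, X, kernels, kernel_names=None, beta_names=None,
             method="auto", max_iter=200, tol=1e-6) -> VarCompFit:
    """AI-REML for ``y ~ N(X beta, sum_k sigma2_k K_k + sigma2_e I)``.

    ``kernels`` is an ordered list of n x n relatedness matrices and/or
    length-n grouping-factor arrays (converted to indicator kernels). An
    identity error kernel is always appended. AI (Newton-type) proposals that
    would push a component negative fall back to EM updates for the offending
    components, with a small non-negative floor (boundary projection).
    Convergence: successive restricted log-likelihoods differ by < ``tol``.

    ``method="eigen"`` (auto-selected for a single dense kernel) rotates into
    the kernel eigenbasis and profiles the likelihood over the variance
    ratio; it reaches the same maximum as the generic path.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.shape[0]
    if X.shape[0] != n:
        raise DataError("y and X have different lengths")
    if beta_names is None:
        beta_names = [f"x{j}" for j in range(X.shape[1])]
    _check_full_rank(X, beta_names)
    ks = [_as_kernel(k, n) for k in kernels]
    if kernel_names is None:
        kernel_names = [f"k{j}" for j in range(len(ks))]
    kernel_names = list(kernel_names) + ["error"]
    ks.append(np.eye(n))
    nk = len(ks)

    # identifiability screen: rank of the kernel Gram matrix
    flat = np.stack([k.ravel() for k in ks])
    gram = flat @ flat.T
    if np.linalg.matrix_rank(gram, tol=1e-8 * np.trace(gram)) < nk:
        warnings.warn("variance components are not separately identifiable: "
                      "kernels are linearly dependent; only identifiable "
                      "combinations (e.g. their total) are meaningful")

    if method == "auto":
        method = "eigen" if (nk == 2 and np.asarray(kernels[0]).ndim == 2) else "ai"
    if method == "eigen":
        if nk != 2:
            raise InvalidParameterError("eigen method requires exactly one kernel")
        return _reml_eigen(y, X, ks[0], kernel_names, beta_names, tol)

    # initial values: equal split of the OLS residual variance
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    var0 = float(np.var(y - X @ beta_ols, ddof=X.shape[1]))
    theta = np.full(nk, var0 / nk)
    floor = 1e-8 * var0
    trajectory = []
    ll_old = -np.inf
    converged = False

    for it in range(max_iter):
        V = sum(t * k for t, k in zip(theta, ks))
        ll, py, vinv, proj, xtvx = _reml_ll_parts(y, X, V)

        kpy = np.stack([k @ py for k in ks])               # nk x n
        tr_pk = np.array([float(np.sum(proj * k)) for k in ks])
        score = -0.5 * (tr_pk - kpy @ py)
        pkpy = kpy @ proj                                   # nk x n
        ai = 0.5 * (pkpy @ kpy.T)
        ai = (ai + ai.T) / 2.0

        trajectory.append({"iter": it, "loglik": ll, "theta": theta.tolist()})
        if it > 0 and abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll

        try:
            delta = linalg.solve(ai, score, assume_a="pos")
        except linalg.LinAlgError:
            delta = np.linalg.pinv(ai) @ score
        prop = theta + delta
        neg = prop < floor
        if neg.any():
            # EM fallback for components the AI step pushed out of bounds;
            # when EM also points downhill, project to the boundary (EM decay
            # near zero is geometric and would stall convergence)
            em = theta + theta**2 * (kpy @ py - tr_pk) / n
            prop[neg] = np.where(em[neg] >= theta[neg],
                                 np.maximum(em[neg], floor), floor)
        # step-halving guard against likelihood decreases; if no step along
        # the proposal improves the likelihood we are at the optimum
        improved = False
        for _ in range(12):
            V_try = sum(t * k for t, k in zip(prop, ks))
            try:
                ll_try = _reml_ll_only(y, X, V_try)
            except linalg.LinAlgError:
                ll_try = -np.inf
            if ll_try >= ll - 1e-10:
                improved = True
                break
            prop = (prop + theta) / 2.0
        if not improved:
            converged = True
            break
        theta = np.maximum(prop, floor)
    else:
        raise ConvergenceError(
            f"REML did not converge in {max_iter} iterations", trajectory)

    # components stuck at the floor are reported as exact zeros; the final
    # GLS pass below uses that same V so beta is consistent with varcomp
    theta = np.where(theta <= 2 * floor, 0.0, theta)
    V = sum(t * k for t, k in zip(theta, ks))
    ll, py, vinv, proj, xtvx = _reml_ll_parts(y, X, V)
    vinv_x = vinv @ X
    beta_cov = np.linalg.inv(xtvx)
    beta = beta_cov @ (vinv_x.T @ y)
    kpy = np.stack([k @ py for k in ks])
    pkpy = kpy @ proj
    ai = 0.5 * (pkpy @ kpy.T)
    ai = (ai + ai.T) / 2.0
    try:
        vc_cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        vc_cov = np.linalg.pinv(ai)
        warnings.warn("AI matrix singular at convergence; component "
                      "covariance is a pseudo-inverse")

    return VarCompFit(
        beta=beta, beta_cov=beta_cov, beta_names=list(beta_names),
        varcomp=dict(zip(kernel_names, theta.tolist())),
        varcomp_cov=vc_cov, varcomp_names=kernel_names,
        loglik=ll, converged=True, n_iter=len(trajectory),
        trajectory=trajectory, method="ai")


def _reml_eigen(y, X, G, kernel_names, beta_names, tol):
    """Single-kernel REML in the eigenbasis of G, profiled over the ratio."""
    n, p = X.shape
    lam, U = linalg.eigh(G)
    yt = U.T @ y
    Xt = U.T @ X

    def neg_profile_ll(h):
        v0 = h * lam + (1.0 - h)
        if (v0 <= 0).any():
            return np.inf
        w = 1.0 / v0
        xtwx = (Xt * w[:, None]).T @ Xt
        cho = linalg.cho_factor(xtwx, check_finite=False)
        bw = linalg.cho_solve(cho, (Xt * w[:, None]).T @ yt, check_finite=False)
        r = yt - Xt @ bw
        q = float(r @ (w * r))
        s_hat = q / (n - p)
        logdet_x = 2.0 * np.log(np.diag(cho[0])).sum()
        return 0.5 * (np.log(v0).sum() + (n - p) * np.log(s_hat) + logdet_x)

    res = optimize.minimize_scalar(neg_profile_ll, bounds=(0.0, 1.0 - 1e-9),
                                   method="bounded",
                                   options={"xatol": 1e-12})
    h = float(res.x)
    v0 = h * lam + (1.0 - h)
    w = 1.0 / v0
    xtwx = (Xt * w[:, None]).T @ Xt
    bw = np.linalg.solve(xtwx, (Xt * w[:, None]).T @ yt)
    r = yt - Xt @ bw
    s_hat = float(r @ (w * r)) / (n - p)
    theta = np.array([s_hat * h, s_hat * (1.0 - h)])
    if theta[0] < 1e-10 * s_hat:
        theta[0] = 0.0

    # full restricted log-likelihood and AI covariance at the optimum
    V_diag = theta[0] * lam + theta[1]
    wv = 1.0 / V_diag
    xtvx = (Xt * wv[:, None]).T @ Xt
    beta_cov = np.linalg.inv(xtvx)
    beta = beta_cov @ ((Xt * wv[:, None]).T @ yt)
    resid = yt - Xt @ beta
    py = wv * resid - (wv[:, None] * Xt) @ (beta_cov @ ((Xt * wv[:, None]).T @ resid))
    ll = -0.5 * (np.log(V_diag).sum() + np.linalg.slogdet(xtvx)[1]
                 + float(yt @ py))
    kpy = np.stack([lam * py, py])
    # P applied to a vector in the eigenbasis
    def P_apply(v):
        wv_v = wv * v
        return wv_v - (wv[:, None] * Xt) @ (beta_cov @ (Xt.T @ wv_v))
    pkpy = np.stack([P_apply(kpy[0]), P_apply(kpy[1])])
    ai = 0.5 * (pkpy @ kpy.T)
    ai = (ai + ai.T) / 2.0
    try:
        vc_cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        vc_cov = np.linalg.pinv(ai)

    return VarCompFit(
        beta=beta, beta_cov=beta_cov, beta_names=list(beta_names),
        varcomp=dict(zip(kernel_names, theta.tolist())),
        varcomp_cov=vc_cov, varcomp_names=kernel_names,
        loglik=float(ll), converged=bool(res.success), n_iter=int(res.nfev),
        method="eigen")


# ---------------------------------------------------------------------------
# heritability and variance explained

def heritability(fit: VarCompFit, denominator: str = "all_components",
                 component: str | None = None):
    """Heritability from a REML fit with a delta-method 95% CI.

    ``denominator="all_components"`` uses the total of every variance
    component; ``"grm_plus_error"`` uses only the GRM component plus error.
    ``component`` names the genetic component (default: the first kernel).
    Returns ``(h2, (lo, hi), se)`` with the CI clamped to [0, 1].
    """
    if not fit.converged:
        raise ConvergenceError("heritability requires a converged fit")
    names = fit.varcomp_names
    comp = component or names[0]
    if comp not in names:
        raise InvalidParameterError(f"unknown component {comp!r}")
    sig = fit.sigma2
    gi = names.index(comp)
    if denominator == "all_components":
        denom_idx = list(range(len(names)))
    elif denominator == "grm_plus_error":
        denom_idx = [gi, names.index("error")]
    else:
        raise InvalidParameterError(f"unknown denominator {denominator!r}")
    S = float(sig[denom_idx].sum())
    if S <= 0:
        raise DataError("denominator of heritability is zero")
    h2 = float(sig[gi] / S)
    grad = np.zeros(len(names))
    for j in denom_idx:
        grad[j] = -sig[gi] / S**2
    grad[gi] += 1.0 / S
    var_h2 = float(grad @ fit.varcomp_cov @ grad)
    se = np.sqrt(max(var_h2, 0.0))
    lo = max(h2 - 1.96 * se, 0.0)
    hi = min(h2 + 1.96 * se, 1.0)
    return h2, (lo, hi), se


def variance_explained(y, X_base, x_add, weights=None):
    """Incremental R-squared of ``x_add`` over ``X_base`` (least squares).

    Unweighted by default; pass survey weights for a weighted variant.
    Returns 0 with a warning when ``x_add`` is collinear with the base set.
    """
    y = np.asarray(y, dtype=float).ravel()
    X_base = np.atleast_2d(np.asarray(X_base, dtype=float))
    x_add = np.asarray(x_add, dtype=float)
    if x_add.ndim == 1:
        x_add = x_add[:, None]
    X_full = np.hstack([X_base, x_add])
    if np.linalg.matrix_rank(X_full) <= np.linalg.matrix_rank(X_base):
        warnings.warn("added column(s) collinear with base design; increment 0")
        return 0.0
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    def r2(Xm):
        sw = np.sqrt(w)
        b, *_ = np.linalg.lstsq(Xm * sw[:, None], y * sw, rcond=None)
        resid = y - Xm @ b
        ybar = np.average(y, weights=w)
        return 1.0 - float(w @ resid**2) / float(w @ (y - ybar)**2)

    return r2(X_full) - r2(X_base)


def haseman_elston(y, grm, X=None):
    """Haseman-Elston regression: phenotype cross-products on GRM entries.

    ``y`` is residualized on ``X`` (OLS) when given, then pairwise products
    ``y_i y_j`` (i<j) are regressed on the off-diagonal GRM entries; the
    slope estimates ``sigma2_g``. Returns ``(sigma2_g, se)`` with the naive
    OLS standard error.
    """
    y = np.asarray(y, dtype=float).ravel()
    if X is not None:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        y = y - X @ b
    n = len(y)
    iu = np.triu_indices(n, k=1)
    prod = np.outer(y, y)[iu]
    g = np.asarray(grm)[iu]
    gc = g - g.mean()
    slope = float(gc @ (prod - prod.mean()) / (gc @ gc))
    resid = (prod - prod.mean()) - slope * gc
    se = float(np.sqrt(resid @ resid / (len(prod) - 2) / (gc @ gc)))
    return slope, se


# ---------------------------------------------------------------------------
# GRM I/O (GCTA-style text triplets and plain square TSV)

def write_grm(grm, ids, prefix, n_snps=0):
    """Write ``<prefix>.grm.gz`` (i, j, n_snps, value; 1-based lower triangle)
    and ``<prefix>.grm.id``."""
    n = grm.shape[0]
    with gzip.open(f"{prefix}.grm.gz", "wt") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{n_snps}\t{grm[i, j]:.10g}\n")
    with open(f"{prefix}.grm.id", "w") as fh:
        for pid in ids:
            fh.write(f"{pid}\t{pid}\n")


def read_grm(prefix):
    n_ids = sum(1 for _ in open(f"{prefix}.grm.id"))
    ids = [line.split()[1] for line in open(f"{prefix}.grm.id")]
    g = np.zeros((n_ids, n_ids))
    with gzip.open(f"{prefix}.grm.gz", "rt") as fh:
        for line in fh:
            i, j, _, v = line.split()
            g[int(i) - 1, int(j) - 1] = g[int(j) - 1, int(i) - 1] = float(v)
    return g, np.array(ids)


def write_grm_tsv(grm, ids, path):
    pd.DataFrame(grm, index=ids, columns=ids).to_csv(path, sep="\t")


def read_grm_tsv(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(float), df.index.to_numpy()
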