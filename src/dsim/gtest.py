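"""Variance-component score test for association between a response vector
and a set of covariates ("global test"-style quadratic form).

The two-group stage builds the covariate-by-group interaction M_jk = X_jk*c_j
and tests H0: theta^2 = 0 for random interaction coefficients, using the
corrected residuals as response and the contrast c as the null design.

The statistic is T = r' M M' r / (p * sigma2_hat), where r is the response
residualized on the null design and sigma2_hat = r'r / (n - q).  Under
Gaussian errors the event {T >= t} is a quadratic form in normal variables
with shifted weights, so an exact p-value is available by Imhof's numerical
inversion; the default asymptotic p-value is a moment-matched scaled
chi-square (Satterthwaite), which is cheap and adequate because final dSIM
inference is permutation-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.stats import chi2

from .datamodel import GroupContrast

log = logging.getLogger(__name__)

__all__ = [
    "InteractionMatrix",
    "GlobalTestResult",
    "make_contrast",
    "make_interaction",
    "global_test",
]


class GlobalTestError(ValueError):
    pass


@dataclass
class InteractionMatrix:
    """n x p matrix with entries M_jk = X_jk * c_j (covariate x group)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GlobalTestError("interaction matrix must be 2-D")


@dataclass
class GlobalTestResult:
    statistic: float
    p_asymptotic: float
    z_scores: np.ndarray  # standardized per-covariate influences
    dof_null: int


def make_contrast(labels) -> GroupContrast:
    """Zero-sum contrast from two-level labels (see GroupContrast)."""
    return GroupContrast.from_labels(labels)


def make_interaction(X: np.ndarray, contrast: GroupContrast) -> InteractionMatrix:
    """M = X * c, row-wise; X is samples x probes."""
    X = np.asarray(X, dtype=float)
    c = contrast.c
    if X.shape[0] != c.size:
        raise GlobalTestError(f"X has {X.shape[0]} rows but contrast has {c.size}")
    return InteractionMatrix(values=X * c[:, None])


def _null_basis(null_design: np.ndarray, n: int) -> np.ndarray:
    D = np.asarray(null_design, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    if D.shape[0] != n:
        raise GlobalTestError("null design row count does not match response length")
    Q, Rm = np.linalg.qr(D)
    keep = np.abs(np.diag(Rm)) > 1e-10 * max(1.0, np.abs(np.diag(Rm)).max())
    Q = Q[:, keep]
    if Q.shape[1] >= n:
        raise GlobalTestError("null design is full rank; no residual degrees of freedom")
    return Q


def imhof_prob_nonneg(weights: np.ndarray) -> float:
    """P(sum_i w_i Z_i^2 >= 0) for iid standard normal Z, by Imhof's formula."""
    w = np.asarray(weights, dtype=float)
    w = w[np.abs(w) > 1e-14 * max(1.0, np.abs(w).max() if w.size else 1.0)]
    if w.size == 0:
        return 1.0
    if np.all(w >= 0):
        return 1.0
    if np.all(w <= 0):
        return 0.0
    w = w / np.abs(w).max()

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(w * u))
        log_rho = 0.25 * np.sum(np.log1p((w * u) ** 2))
        return np.sin(theta) / (u * np.exp(log_rho))

    val, _ = integrate.quad(integrand, 0.0, np.inf, limit=300)
    return float(np.clip(0.5 + val / np.pi, 0.0, 1.0))


def _satterthwaite_sf(t, sum_w, sum_w2, d):
    """Two-moment scaled chi-square upper tail for the studentized statistic.

    ``sum_w``/``sum_w2`` are the trace and squared-trace of the projected
    kernel weights; ``d`` is the residual dimension n - q.  The mean and
    variance matched are those of the exact null ratio
    T = d * (r'Ar / r'r), r spherical in d dimensions:

        E T   = tr(A),
        var T = 2 (d * tr(A^2) - tr(A)^2) / (d + 2),

    which accounts for the shared residual vector in numerator and variance
    estimate (the naive chi-square variance 2 tr(A^2) overshoots).
    """
    t = np.asarray(t, dtype=float)
    sum_w = np.asarray(sum_w, dtype=float)
    sum_w2 = np.asarray(sum_w2, dtype=float)
    mean = sum_w
    var = 2.0 * (d * sum_w2 - sum_w**2) / (d + 2.0)
    var = np.where(var > 0, var, 2.0 * sum_w2)  # degenerate flat spectrum
    ok = (mean > 0) & (var > 0)
    a = np.where(ok, var / (2.0 * np.where(mean > 0, mean, 1.0)), 1.0)
    g = np.where(ok, 2.0 * mean**2 / np.where(var > 0, var, 1.0), 1.0)
    vals = chi2.sf(np.where(ok, t / a, 0.0), g)
    out = np.where(ok, vals, np.where(t > 0, 0.0, 1.0))
    return out if out.ndim else float(out)


def global_test(
    R: np.ndarray,
    M: InteractionMatrix | np.ndarray,
    null_design: np.ndarray,
    method: str = "satterthwaite",
) -> GlobalTestResult:
    """Score test of a zero variance component for the columns of M.

    Parameters
    ----------
    R : response vector (corrected residuals in the two-group stage).
    M : interaction (or covariate) matrix, samples x probes.
    null_design : columns spanning the null-model mean space (the contrast c
        for the two-group stage; a column of ones for a per-group fit).
    method : "satterthwaite" (default) or "exact" (Imhof series).
    """
    R = np.asarray(R, dtype=float).ravel()
    Mv = M.values if isinstance(M, InteractionMatrix) else np.asarray(M, dtype=float)
    n = R.size
    if Mv.shape[0] != n:
        raise GlobalTestError(f"M has {Mv.shape[0]} rows but R has {n} entries")
    p = Mv.shape[1]
    if p == 0:
        raise GlobalTestError("no covariates in M")
    Q = _null_basis(null_design, n)
    q = Q.shape[1]
    r = R - Q @ (Q.T @ R)
    rss = float(r @ r)
    if rss <= 1e-28 * max(1.0, float(R @ R)):
        log.warning("global_test: response lies in the null space; degenerate")
        return GlobalTestResult(0.0, 1.0, np.zeros(p), q)
    sigma2 = rss / (n - q)
    Mt = Mv - Q @ (Q.T @ Mv)
    score = Mt.T @ r  # == M' r since r is orthogonal to the null space
    T = float(score @ score) / (p * sigma2)

    sv = np.linalg.svd(Mt, compute_uv=False)
    mu = sv**2 / p  # weights of the numerator quadratic form
    if T <= 0 or mu.sum() <= 0:
        p_asym = 1.0
        T = 0.0
    elif method == "satterthwaite":
        p_asym = float(_satterthwaite_sf(T, mu.sum(), np.sum(mu**2), n - q))
    elif method == "exact":
        r_dim = n - q
        # exactly r_dim weights: rank(Mt) <= r_dim, so surplus singular
        # values are numerical zeros and must not enter the series
        mu_r = np.sort(mu)[::-1][:r_dim]
        w = np.concatenate([mu_r, np.zeros(r_dim - mu_r.size)]) - T / r_dim
        p_asym = imhof_prob_nonneg(w)
    else:
        raise GlobalTestError(f"unknown method {method!r}")

    col_norm = np.linalg.norm(Mt, axis=0)
    z = np.zeros(p)
    nz = col_norm > 0
    z[nz] = score[nz] / (np.sqrt(sigma2) * col_norm[nz])
    return GlobalTestResult(statistic=T, p_asymptotic=p_asym, z_scores=z, dof_null=q)


def exact_rejection_threshold(
    Mt_or_weights: np.ndarray, n_minus_q: int, alpha: float = 0.05, is_weights: bool = False
) -> float:
    """Statistic threshold t* with exact-series P(T >= t*) = alpha.

    The exact p-value is monotone decreasing in T, so the rejection region of
    the exact evaluator is {T > t*}; solving once makes large Monte Carlo
    calibration studies cheap.
    """
    from scipy.optimize import brentq

    if is_weights:
        mu = np.asarray(Mt_or_weights, dtype=float)
    else:
        sv = np.linalg.svd(np.asarray(Mt_or_weights, dtype=float), compute_uv=False)
        mu = sv**2 / Mt_or_weights.shape[1]
    mu = np.sort(mu)[::-1][:n_minus_q]
    mu_full = np.concatenate([mu, np.zeros(n_minus_q - mu.size)])

    def pv(t):
        return imhof_prob_nonneg(mu_full - t / n_minus_q)

    lo, hi = 1e-9, 10.0 * max(mu.sum(), 1.0)
    while pv(hi) > alpha:
        hi *= 4.0
    return float(brentq(lambda t: pv(t) - alpha, lo, hi, xtol=1e-10))
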