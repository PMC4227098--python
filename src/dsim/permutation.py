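"""Shared-permutation p-value matrix and FDP-controlled multiple testing.

Sample labels of the covariate matrix are permuted B times; the SAME B
permutations are applied to every dependent probe so that the joint
dependence of the m test statistics is preserved — required by the
quantile-count FDP bound applied afterwards.  The penalty and residuals of
the baseline correction are reused across permutations by default (permuting
the rows of X leaves X'X unchanged); a slow path refits residuals per
permutation at the stored penalty.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel import GroupContrast, WindowMap, OmicsMatrix
from .gtest import _satterthwaite_sf
from .ridge import loocv_predictions

log = logging.getLogger(__name__)

__all__ = [
    "PermutationPValueMatrix",
    "FDPResult",
    "draw_permutations",
    "permuted_pvalues",
    "empirical_pvalue",
    "meinshausen_adjust",
]


class PermutationError(ValueError):
    pass


@dataclass
class PermutationPValueMatrix:
    """m x (B+1) matrix of test p-values: observed column + B permuted."""

    values: np.ndarray
    probe_ids: list[str]
    permutation_seed: int
    B: int
    shared_permutations: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), self.B + 1):
            raise PermutationError(
                f"matrix shape {self.values.shape} != (m, B+1) = "
                f"({len(self.probe_ids)}, {self.B + 1})"
            )
        if np.any((self.values < 0) | (self.values > 1)):
            raise PermutationError("p-values outside [0, 1]")
        if not self.shared_permutations:
            raise PermutationError(
                "FDP control requires the same permutations for every probe"
            )

    @property
    def observed(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def permuted(self) -> np.ndarray:
        return self.values[:, 1:]


@dataclass
class FDPResult:
    """FDP-adjusted values per dependent probe and the selected set."""

    probe_ids: list[str]
    adjusted: np.ndarray
    level: float
    confidence_alpha: float
    selected: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.adjusted = np.asarray(self.adjusted, dtype=float)
        self.selected = self.adjusted <= self.level


def draw_permutations(n: int, B: int, seed: int) -> np.ndarray:
    """B uniform random permutations of range(n) (identity not excluded)."""
    if B < 1:
        raise PermutationError(f"B must be >= 1, got {B}")
    rng = np.random.default_rng(seed)
    return np.vstack([rng.permutation(n) for _ in range(B)])


def _probe_pvalue_row(R, Xw, c, perms, chunk=256):
    """Observed + permuted score-test p-values for one dependent probe.

    Response R is residualized on c; each permuted column uses
    M_b = Xw[perm_b] * c with the unpermuted contrast.  Vectorized over
    permutations; in the balanced-groups case c^2 is constant, so the
    Satterthwaite weights are permutation-invariant and only the statistic
    needs recomputing.
    """
    n, pw = Xw.shape
    B = perms.shape[0]
    cc = float(c @ c)
    r = R - c * (float(c @ R) / cc)
    rss = float(r @ r)
    if rss <= 0 or pw == 0:
        return np.ones(B + 1)
    sigma2 = rss / (n - 1)

    # the observed column is computed through the very same vectorized code
    # path (as the identity permutation) so that a literal identity draw
    # reproduces it bit for bit
    all_perms = np.vstack([np.arange(n)[None, :], perms])
    balanced = np.ptp(c * c) < 1e-12 * np.max(c * c)
    c2 = c * c
    out = np.empty(B + 1)
    sum_w0 = sum_w20 = None
    if balanced:
        # weights are permutation-invariant when c^2 is constant: compute
        # them once from the unpermuted design
        v0 = np.einsum("n,nk->k", c2, Xw)
        G0 = np.einsum("nk,n,nl->kl", Xw, c2, Xw) - np.outer(v0, v0) / cc
        sum_w0 = float(np.einsum("kk", G0)) / pw
        sum_w20 = float(np.einsum("kl,kl", G0, G0)) / pw**2
    for lo in range(0, B + 1, chunk):
        pm = all_perms[lo : lo + chunk]
        Xp = Xw[pm]  # (b, n, pw)
        M = Xp * c[None, :, None]
        score = np.einsum("bnk,n->bk", M, r)
        T = np.einsum("bk,bk->b", score, score) / (pw * sigma2)
        if balanced:
            out[lo : lo + pm.shape[0]] = _satterthwaite_sf(T, sum_w0, sum_w20, n - 1)
            continue
        v = np.einsum("n,bnk->bk", c2, Xp)
        G = np.einsum("bnk,n,bnl->bkl", Xp, c2, Xp) - np.einsum("bk,bl->bkl", v, v) / cc
        sum_w = np.einsum("bkk->b", G) / pw
        sum_w2 = np.einsum("bkl,bkl->b", G, G) / pw**2
        out[lo : lo + pm.shape[0]] = _satterthwaite_sf(T, sum_w, sum_w2, n - 1)
    return out


def permuted_pvalues(
    R_all: np.ndarray,
    X: OmicsMatrix,
    windows: WindowMap,
    contrast: GroupContrast,
    B: int,
    seed: int,
    recompute_residuals: bool = False,
    dep_probe_ids: list[str] | None = None,
    y_all: np.ndarray | None = None,
    lambda_stars: np.ndarray | None = None,
) -> PermutationPValueMatrix:
    """Build the m x (B+1) p-value matrix with shared permutations.

    Parameters
    ----------
    R_all : (m, n) matrix of cross-validated residuals (one row per
        dependent probe, aligned with ``dep_probe_ids``).
    X : covariate matrix (probes x samples) whose sample labels are permuted.
    recompute_residuals : if True, residuals are refit per permutation at the
        stored penalty ``lambda_stars`` from ``y_all`` (slow path); by
        default the observed residuals are reused for every permutation.
    """
    R_all = np.asarray(R_all, dtype=float)
    m, n = R_all.shape
    if X.n_samples != n:
        raise PermutationError("covariate matrix and residuals disagree on n")
    if dep_probe_ids is None:
        dep_probe_ids = [f"probe_{i}" for i in range(m)]
    if recompute_residuals and (y_all is None or lambda_stars is None):
        raise PermutationError(
            "recompute_residuals=True needs y_all and lambda_stars"
        )
    perms = draw_permutations(n, B, seed)
    widx = windows.indices(X.probe_ids)
    c = contrast.c
    Xs = X.samples_view()  # n x p
    values = np.ones((m, B + 1))
    for i, pid in enumerate(dep_probe_ids):
        w = widx.get(pid)
        if w is None or w.size == 0:
            log.warning("probe %r: empty window; p-values set to 1", pid)
            continue
        Xw = Xs[:, w]
        if not recompute_residuals:
            values[i] = _probe_pvalue_row(R_all[i], Xw, c, perms)
        else:
            y = y_all[i]
            lam = float(lambda_stars[i])
            row = np.empty(B + 1)
            row[0] = _probe_pvalue_row(R_all[i], Xw, c, perms[:0])[0]
            for b in range(B):
                Xp = Xw[perms[b]]
                R_b = y - loocv_predictions(y, Xp, lam)
                row[1 + b] = _probe_pvalue_row(R_b, Xp, c, perms[:0])[0]
            values[i] = row
    return PermutationPValueMatrix(
        values=values,
        probe_ids=list(dep_probe_ids),
        permutation_seed=seed,
        B=B,
    )


def empirical_pvalue(row: np.ndarray) -> float:
    """(1 + #{permuted <= observed}) / (B + 1); lower bound 1/(B+1)."""
    row = np.asarray(row, dtype=float)
    B = row.size - 1
    if B < 1:
        raise PermutationError("row needs at least one permuted entry")
    return float((1 + np.sum(row[1:] <= row[0])) / (B + 1))


def meinshausen_adjust(
    P: PermutationPValueMatrix, confidence_alpha: float = 0.05, level: float = 0.05
) -> FDPResult:
    """Permutation-based FDP-controlling adjustment of the observed p-values.

    For sorted observed p-values t_(1) <= ... <= t_(m), the null count at
    threshold t under permutation b is V_b(t) = #{i : P[i, b] <= t}; the
    (1 - alpha) envelope Vbar(t) is the ceil((1-alpha)*B)-th smallest of the
    B counts.  The rank-k bound is min(1, Vbar(t_(k)) / k), made monotone by
    a running maximum; tied observed p-values share the larger value.  The
    adjusted value upper-bounds (with confidence 1 - alpha) the false
    discovery proportion of the set {adjusted <= level}.
    """
    if not (0.0 < confidence_alpha < 1.0):
        raise PermutationError("confidence_alpha must be in (0, 1)")
    if not (0.0 < level < 1.0) and level != 0.0:
        raise PermutationError("level must be in [0, 1)")
    B = P.B
    k_idx = math.ceil((1.0 - confidence_alpha) * B)
    if k_idx < 1 or k_idx > B:
        raise PermutationError(
            f"B={B} too small for the (1-{confidence_alpha}) quantile; increase B"
        )
    obs = P.observed
    perm = P.permuted
    m = obs.size
    order = np.argsort(obs, kind="stable")
    t_sorted = obs[order]
    # counts[k, b] = #{i : perm[i, b] <= t_sorted[k]} via per-column sorting
    perm_sorted = np.sort(perm, axis=0)
    counts = np.empty((m, B), dtype=int)
    for b in range(B):
        counts[:, b] = np.searchsorted(perm_sorted[:, b], t_sorted, side="right")
    vbar = np.sort(counts, axis=1)[:, k_idx - 1]
    bound = np.minimum(1.0, vbar / np.arange(1, m + 1))
    adjusted_sorted = np.maximum.accumulate(bound)
    # tied observed p-values share the larger adjusted value
    for k in range(m - 2, -1, -1):
        if t_sorted[k] == t_sorted[k + 1]:
            adjusted_sorted[k] = adjusted_sorted[k + 1]
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return FDPResult(
        probe_ids=list(P.probe_ids),
        adjusted=adjusted,
        level=level,
        confidence_alpha=confidence_alpha,
    )
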