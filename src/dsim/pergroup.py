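"""Per-group baseline analysis: the association of each dependent probe with
its covariate window is tested within each sample group independently
(variance-component score test, intercept-only null), with
Benjamini-Hochberg FDR control per group.

This comparator is asymptotic-only by design; its power depends on the group
sample size, which is exactly the phenomenon the joint two-group test
avoids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datamodel import GroupContrast, OmicsMatrix, WindowMap
from .gtest import global_test

log = logging.getLogger(__name__)

__all__ = ["PerGroupResult", "sim_test", "bh_adjust", "run_pergroup"]


@dataclass
class PerGroupResult:
    probe_ids: list[str]
    p: np.ndarray  # (m, 2): column g-1 holds group-g p-values
    q: np.ndarray  # BH-adjusted
    selected: np.ndarray  # q <= fdr
    fdr: float

    def to_frame(self, group: int) -> pd.DataFrame:
        g = group - 1
        return pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "p": self.p[:, g],
                "q": self.q[:, g],
                "selected": self.selected[:, g],
            }
        )


def sim_test(y: np.ndarray, X_window: np.ndarray, samples: np.ndarray) -> float:
    """Asymptotic p-value for association of y with X_window on a sample
    subset (intercept-only null)."""
    samples = np.asarray(samples, dtype=int)
    if samples.size < 3:
        raise ValueError(f"need >= 3 samples in the subset, got {samples.size}")
    y_s = np.asarray(y, dtype=float)[samples]
    X_s = np.asarray(X_window, dtype=float)[samples]
    if np.ptp(y_s) == 0.0:
        log.warning("sim_test: degenerate response on subset; p = 1")
        return 1.0
    res = global_test(y_s, X_s, np.ones((samples.size, 1)))
    return res.p_asymptotic


def bh_adjust(p: np.ndarray, fdr: float) -> tuple[np.ndarray, np.ndarray]:
    """Step-up BH adjusted values (monotone) and the selection at ``fdr``."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q <= fdr


def run_pergroup(
    Y: OmicsMatrix,
    X: OmicsMatrix,
    windows: WindowMap,
    groups: GroupContrast,
    fdr: float = 0.05,
) -> PerGroupResult:
    """Fit the per-group association test for every dependent probe.

    Note: power differs between the groups whenever their sample sizes do;
    compare with the joint two-group analysis before interpreting
    group-specific selections.
    """
    widx = windows.indices(X.probe_ids)
    Xs = X.samples_view()
    m = Y.n_probes
    p_mat = np.ones((m, 2))
    for i, pid in enumerate(Y.probe_ids):
        w = widx.get(pid)
        if w is None or w.size == 0:
            log.warning("probe %r: empty window; skipped in per-group analysis", pid)
            continue
        y = Y.values[i]
        for g in (1, 2):
            idx = groups.group_indices(g)
            p_mat[i, g - 1] = sim_test(y, Xs[:, w], idx)
    q_mat = np.ones_like(p_mat)
    sel = np.zeros_like(p_mat, dtype=bool)
    for g in (0, 1):
        q_mat[:, g], sel[:, g] = bh_adjust(p_mat[:, g], fdr)
    return PerGroupResult(
        probe_ids=list(Y.probe_ids), p=p_mat, q=q_mat, selected=sel, fdr=fdr
    )
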