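"""Synthetic two-platform datasets with known differential-association truth,
plus the evaluation metrics and the penalty-stability sweep.

Generation order is dependent-data first: the dependent matrix (copy-number
style) gets group-wise mean-shifted aberration segments plus Gaussian noise,
and the covariate matrix (expression style) is generated per group as a
linear function of the locally averaged dependent signal plus Gaussian
noise.  The truth mask marks dependent probes whose covariate window
contains at least one covariate whose linear coefficient differs between the
two groups — a pure function of the design, never of the noise seed.

All numeric preset constants below are this module's own calibrated
defaults; they are chosen so that the differential presets have mid-range
sensitivity and the null presets are clean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GroupContrast, OmicsMatrix
from .permutation import (
    PermutationPValueMatrix,
    draw_permutations,
    meinshausen_adjust,
    _probe_pvalue_row,
)
from .ridge import select_lambda, loocv_predictions, default_lambda_grid

log = logging.getLogger(__name__)

__all__ = [
    "Region",
    "SimulationDesign",
    "SimulatedDataset",
    "EvaluationMetrics",
    "simulate_dataset",
    "preset",
    "PRESET_NAMES",
    "evaluate",
    "lambda_stability_sweep",
]


@dataclass(frozen=True)
class Region:
    """A genomic interval [start, end] (bp) with a per-group parameter pair.

    For aberration regions the pair is the dependent-data mean shift per
    group; for association regions it is the linear coefficient linking the
    covariate signal to the local dependent signal per group.
    """

    start: int
    end: int
    g1: float
    g2: float

    @property
    def differential(self) -> bool:
        return self.g1 != self.g2


@dataclass
class SimulationDesign:
    n_g1: int
    n_g2: int
    m: int  # dependent probes
    p: int  # covariate probes
    span_bp: int = 10_000_000
    aberration_regions: tuple[Region, ...] = ()
    association_regions: tuple[Region, ...] = ()
    amp_sd: float = 0.7  # per-sample, per-region segment amplitude spread
    noise_sd_y: float = 0.2
    noise_sd_x: float = 0.8
    window_bp: int = 1_000_000  # analysis window width (probes within +- half)
    avg_radius_bp: int = 200_000  # dependent probes averaged into a covariate's signal
    seed: int = 0
    chromosome: str = "1"
    arm: str = "q"

    def __post_init__(self) -> None:
        regs = sorted(self.aberration_regions, key=lambda r: r.start)
        for a, b in zip(regs, regs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping aberration regions [{a.start},{a.end}] and "
                    f"[{b.start},{b.end}]"
                )

    @property
    def n(self) -> int:
        return self.n_g1 + self.n_g2

    def dep_positions(self) -> np.ndarray:
        step = self.span_bp // self.m
        return step * np.arange(1, self.m + 1)

    def cov_positions(self) -> np.ndarray:
        step = self.span_bp / self.p
        return np.round(step * np.arange(1, self.p + 1)).astype(int)

    def _coef(self, pos: np.ndarray) -> np.ndarray:
        """(p, 2) per-group coefficients at covariate positions."""
        out = np.zeros((pos.size, 2))
        for reg in self.association_regions:
            inside = (pos >= reg.start) & (pos <= reg.end)
            out[inside, 0] = reg.g1
            out[inside, 1] = reg.g2
        return out

    def truth_mask(self) -> np.ndarray:
        """True where a probe genuinely carries differential association.

        Three conditions: the probe sits inside an aberration segment (so its
        values share the segment amplitude); some covariate with
        group-differing coefficients lies within its analysis window; and
        that covariate draws its signal from the same segment (its averaging
        neighbourhood reaches the segment).  A window-only rule would also
        flag flanking probes that contain no signal whatsoever.
        """
        dep = self.dep_positions()
        cov = self.cov_positions()
        coef = self._coef(cov)
        diff_pos = cov[coef[:, 0] != coef[:, 1]]
        half = self.window_bp / 2.0
        truth = np.zeros(self.m, dtype=bool)
        for i, dp in enumerate(dep):
            reg = next(
                (r for r in self.aberration_regions if r.start <= dp <= r.end), None
            )
            if reg is None:
                continue
            in_window = np.abs(diff_pos - dp) <= half
            feeds_segment = (diff_pos >= reg.start - self.avg_radius_bp) & (
                diff_pos <= reg.end + self.avg_radius_bp
            )
            truth[i] = bool(np.any(in_window & feeds_segment))
        return truth


@dataclass
class SimulatedDataset:
    y: OmicsMatrix
    x: OmicsMatrix
    labels: np.ndarray
    truth: np.ndarray
    dep_ann: pd.DataFrame
    cov_ann: pd.DataFrame

    def __iter__(self):  # allow (Y, X, labels, truth) unpacking
        return iter((self.y, self.x, self.labels, self.truth))

    @property
    def contrast(self) -> GroupContrast:
        return GroupContrast(labels=self.labels, sample_ids=list(self.y.sample_ids))


def _annotation(prefix: str, positions: np.ndarray, chrom: str, arm: str) -> pd.DataFrame:
    ids = [f"{prefix}_{i + 1:04d}" for i in range(positions.size)]
    return pd.DataFrame(
        {
            "probe_id": ids,
            "chromosome": chrom,
            "arm": arm,
            "start": positions,
            "end": positions,
        }
    )


def simulate_dataset(design: SimulationDesign, seed: int | None = None) -> SimulatedDataset:
    """Draw one dataset; deterministic given the seed, truth independent of it."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n1, n2, n = design.n_g1, design.n_g2, design.n
    labels = np.r_[np.ones(n1, dtype=int), 2 * np.ones(n2, dtype=int)]
    g_col = labels - 1  # 0/1 per sample

    dep_pos = design.dep_positions()
    cov_pos = design.cov_positions()

    # each aberration segment carries one amplitude per sample (the whole
    # segment is gained/lost together), shared by every probe in the segment
    Y = np.zeros((design.m, n))
    for reg in design.aberration_regions:
        inside = (dep_pos >= reg.start) & (dep_pos <= reg.end)
        mean = np.where(labels == 1, reg.g1, reg.g2)
        amp = mean + rng.normal(0.0, design.amp_sd, size=n)
        Y[inside] += amp
    Y += rng.normal(0.0, design.noise_sd_y, size=(design.m, n))

    coef = design._coef(cov_pos)
    X = np.empty((design.p, n))
    for k, cp in enumerate(cov_pos):
        near = np.flatnonzero(np.abs(dep_pos - cp) <= design.avg_radius_bp)
        if near.size == 0:  # fall back to the single nearest dependent probe
            near = np.asarray([int(np.argmin(np.abs(dep_pos - cp)))])
        base = Y[near].mean(axis=0)
        X[k] = coef[k, g_col] * base
    X += rng.normal(0.0, design.noise_sd_x, size=X.shape)

    dep_ann = _annotation("cn", dep_pos, design.chromosome, design.arm)
    cov_ann = _annotation("ge", cov_pos, design.chromosome, design.arm)
    sample_ids = [f"s{j + 1:03d}" for j in range(n)]
    y_mat = OmicsMatrix(Y, dep_ann["probe_id"].tolist(), sample_ids, role="dependent")
    x_mat = OmicsMatrix(X, cov_ann["probe_id"].tolist(), sample_ids, role="covariate")
    return SimulatedDataset(
        y=y_mat,
        x=x_mat,
        labels=labels,
        truth=design.truth_mask(),
        dep_ann=dep_ann,
        cov_ann=cov_ann,
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

# Two aberration segments on a 10 Mb arm; the second one carries the
# differential association in the differential presets.
_REGION_A = (1_800_000, 3_200_000)
_REGION_B = (5_800_000, 7_200_000)

PRESET_NAMES = (
    "S1",
    "S2",
    "S3",
    "C1.1",
    "C1.2",
    "C2.1",
    "C2.2",
    "unbalanced_null",
    "lambda_sens",
)


def preset(name: str) -> SimulationDesign:
    """Fully parameterized designs for the validation studies.

    S1: same association in both groups (specificity check; truth all false).
    S2: shared association in region A, attenuated group-2 association in
        region B (truth true around B).
    S3: association in region B for group 1 only.
    C1.1/C1.2: no differential association, with identical (1.1) vs
        different (1.2) dependent-data aberration means per group.
    C2.1/C2.2: differential association, identical vs different aberration
        means.
    unbalanced_null: 45 samples split 30/15, identical association in both
        groups (truth all false).
    lambda_sens: an S2-style design for the penalty-stability sweep.
    """
    base = dict(n_g1=65, n_g2=65, m=100, p=150)
    shared = Region(*_REGION_A, 1.0, 1.0)
    ab_equal = (Region(*_REGION_A, 1.0, 1.0), Region(*_REGION_B, 1.0, 1.0))
    ab_shifted = (Region(*_REGION_A, 1.0, 2.0), Region(*_REGION_B, 1.0, 2.0))
    assoc_same = (shared, Region(*_REGION_B, 1.0, 1.0))
    # an attenuated same-sign coefficient is near-invisible after the shared
    # baseline fit (the compromise slope can equalize both groups' residual
    # covariances), so the "different pattern" preset crosses zero; the small
    # magnitude plus extra dependent-probe noise keeps sensitivity off the
    # ceiling
    assoc_diff = (shared, Region(*_REGION_B, 1.0, -0.05))
    assoc_one_group = (shared, Region(*_REGION_B, 1.0, 0.0))
    if name == "S1":
        return SimulationDesign(**base, aberration_regions=ab_equal, association_regions=assoc_same)
    if name == "S2":
        return SimulationDesign(
            **base,
            aberration_regions=ab_equal,
            association_regions=assoc_diff,
            noise_sd_y=0.4,
            noise_sd_x=0.9,
        )
    if name == "S3":
        return SimulationDesign(
            **base,
            aberration_regions=ab_equal,
            association_regions=assoc_one_group,
            noise_sd_y=0.3,
        )
    if name == "C1.1":
        return SimulationDesign(**base, aberration_regions=ab_equal, association_regions=assoc_same)
    if name == "C1.2":
        return SimulationDesign(
            **base, aberration_regions=ab_shifted, association_regions=assoc_same
        )
    if name == "C2.1":
        return SimulationDesign(**base, aberration_regions=ab_equal, association_regions=assoc_diff)
    if name == "C2.2":
        return SimulationDesign(
            **base, aberration_regions=ab_shifted, association_regions=assoc_diff
        )
    if name == "unbalanced_null":
        # weak association so per-group power is limited by group size
        return SimulationDesign(
            n_g1=30,
            n_g2=15,
            m=100,
            p=150,
            amp_sd=0.35,
            aberration_regions=ab_equal,
            association_regions=assoc_same,
        )
    if name == "lambda_sens":
        # strong sign-flip so the differential probe stays clear of the
        # selection boundary throughout the penalty sweep
        return SimulationDesign(
            n_g1=50,
            n_g2=50,
            m=40,
            p=80,
            span_bp=4_000_000,
            aberration_regions=(Region(2_200_000, 3_000_000, 1.0, 1.0),),
            association_regions=(Region(2_200_000, 3_000_000, 1.0, -0.5),),
        )
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)

    def __post_init__(self) -> None:
        m = self.tp + self.fp + self.tn + self.fn
        self.accuracy = (self.tp + self.tn) / m if m else 1.0
        pos = self.tp + self.fn
        neg = self.tn + self.fp
        self.sensitivity = self.tp / pos if pos else 1.0
        self.specificity = self.tn / neg if neg else 1.0


def evaluate(selected: np.ndarray, truth: np.ndarray) -> EvaluationMetrics:
    selected = np.asarray(selected, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if selected.shape != truth.shape:
        raise ValueError("selected and truth have different lengths")
    return EvaluationMetrics(
        tp=int(np.sum(selected & truth)),
        fp=int(np.sum(selected & ~truth)),
        tn=int(np.sum(~selected & ~truth)),
        fn=int(np.sum(~selected & truth)),
    )


# ---------------------------------------------------------------------------
# penalty-stability sweep
# ---------------------------------------------------------------------------


def lambda_stability_sweep(
    y_probe: np.ndarray,
    X_window: np.ndarray,
    contrast: GroupContrast,
    n_points: int = 50,
    span: float = 10.0,
    B: int = 100,
    seed: int = 0,
    level: float = 0.01,
    confidence_alpha: float = 0.05,
) -> pd.DataFrame:
    """Re-run the full single-probe chain over a log-range of penalties.

    At each penalty in ``[lambda_star/span, lambda_star*span]`` (geometric,
    ``n_points`` values) the LOO residuals are recomputed, then the
    permutation p-value row and its FDP adjustment, with ONE fixed set of
    permutations across the whole sweep.  Returns columns
    ``(lam, p_observed, adjusted, selected)``.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if span < 1.0:
        raise ValueError("span must be >= 1")
    y = np.asarray(y_probe, dtype=float).ravel()
    Xw = np.asarray(X_window, dtype=float)
    fit = select_lambda(y, Xw)
    lam_star = fit.lambda_star
    lams = np.geomspace(lam_star / span, lam_star * span, n_points)
    perms = draw_permutations(y.size, B, seed)
    rows = []
    for lam in lams:
        R = y - loocv_predictions(y, Xw, lam)
        pvals = _probe_pvalue_row(R, Xw, contrast.c, perms)
        P = PermutationPValueMatrix(
            values=pvals[None, :], probe_ids=["probe"], permutation_seed=seed, B=B
        )
        fdp = meinshausen_adjust(P, confidence_alpha=confidence_alpha, level=level)
        rows.append(
            {
                "lam": float(lam),
                "p_observed": float(pvals[0]),
                "adjusted": float(fdp.adjusted[0]),
                "selected": bool(fdp.selected[0]),
            }
        )
    return pd.DataFrame(rows)
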