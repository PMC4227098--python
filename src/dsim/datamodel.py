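"""Typed containers for probe-by-sample matrices, probe annotation, sample
grouping, and the dependent-probe -> covariate-window mapping, together with
readers/writers for the tab-delimited on-disk formats.

On disk, matrices are probes x samples (rows are probes).  Where the
statistics need a samples x probes view, :meth:`OmicsMatrix.samples_view`
provides it without copying the container.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ROLES = ("dependent", "covariate")

ANNOTATION_COLUMNS = ["probe_id", "chromosome", "arm", "start", "end"]


class DataModelError(ValueError):
    """Raised on malformed inputs (duplicate ids, bad cells, empty joins)."""


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


@dataclass
class OmicsMatrix:
    """A numeric probes x samples matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_probes, n_samples)
        Finite float matrix.
    probe_ids, sample_ids : list of str
        Row / column identifiers; duplicates are rejected.
    role : {"dependent", "covariate"}
        Which side of the association model the matrix plays.
    """

    values: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]
    role: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.role not in ROLES:
            raise DataModelError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.values.ndim != 2:
            raise DataModelError("values must be a 2-D array")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise DataModelError(
                f"shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise DataModelError(f"duplicate {name} id: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            raise DataModelError("matrix contains non-finite values")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_view(self) -> np.ndarray:
        """samples x probes view of the data (no copy)."""
        return self.values.T

    def probe_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.probe_ids)}

    def subset_samples(self, order: np.ndarray) -> "OmicsMatrix":
        """New matrix with samples taken (and reordered) by integer index."""
        order = np.asarray(order, dtype=int)
        return OmicsMatrix(
            values=self.values[:, order],
            probe_ids=list(self.probe_ids),
            sample_ids=[self.sample_ids[i] for i in order],
            role=self.role,
        )

    def row(self, probe_id: str) -> np.ndarray:
        return self.values[self.probe_index()[probe_id]]


def _first_duplicate(ids) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_matrix(path, role: str, missing: str = "strict") -> OmicsMatrix:
    """Read a tab-delimited probes x samples matrix.

    First column holds probe ids, the header row holds sample ids.

    ``missing`` is either ``"strict"`` (any missing cell is an error) or
    ``"impute_rowmean"`` (missing cells are replaced by the probe's mean over
    the non-missing samples).
    """
    if missing not in ("strict", "impute_rowmean"):
        raise DataModelError(f"unknown missing-value policy {missing!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    probe_ids = [str(p) for p in raw.index]
    sample_ids = [str(s) for s in raw.columns]
    for name, ids in (("probe", probe_ids), ("sample", sample_ids)):
        dup = _first_duplicate(ids)
        if dup is not None:
            raise DataModelError(f"{path}: duplicate {name} id: {dup!r}")
    was_missing = raw.isna()
    vals = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = vals.isna() & ~was_missing
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise DataModelError(
            f"{path}: non-numeric value {raw.iat[i, j]!r} at probe "
            f"{probe_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    arr = vals.to_numpy(dtype=float)
    if np.isnan(arr).any():
        if missing == "strict":
            i, j = np.argwhere(np.isnan(arr))[0]
            raise DataModelError(
                f"{path}: missing value at probe {probe_ids[i]!r}, sample "
                f"{sample_ids[j]!r} (policy=strict)"
            )
        rowmean = np.nanmean(arr, axis=1)
        if np.isnan(rowmean).any():
            i = int(np.argwhere(np.isnan(rowmean))[0])
            raise DataModelError(f"{path}: probe {probe_ids[i]!r} has no observed values")
        idx = np.argwhere(np.isnan(arr))
        arr[idx[:, 0], idx[:, 1]] = rowmean[idx[:, 0]]
        log.warning("%s: imputed %d missing cells with row means", path, len(idx))
    return OmicsMatrix(values=arr, probe_ids=probe_ids, sample_ids=sample_ids, role=role)


def write_matrix(mat: OmicsMatrix, path) -> None:
    df = pd.DataFrame(mat.values, index=mat.probe_ids, columns=mat.sample_ids)
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeAnnotation:
    """Genomic location of one probe (1-based, inclusive coordinates)."""

    probe_id: str
    chromosome: str
    arm: str | None
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataModelError(
                f"probe {self.probe_id!r}: start {self.start} > end {self.end}"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


def read_annotation(path, bed: bool = False) -> pd.DataFrame:
    """Read a probe annotation TSV: ``probe_id chromosome arm start end``.

    With ``bed=True`` the coordinates are interpreted as 0-based half-open
    and converted to 1-based inclusive on read.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str, "arm": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise DataModelError(f"{path}: annotation missing columns {missing}")
    df = df[ANNOTATION_COLUMNS].copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if bed:
        df["start"] = df["start"] + 1  # end of a half-open interval is already inclusive
    dup = _first_duplicate(df["probe_id"].tolist())
    if dup is not None:
        raise DataModelError(f"{path}: duplicate probe id in annotation: {dup!r}")
    if (df["start"] > df["end"]).any():
        bad = df.loc[df["start"] > df["end"], "probe_id"].iloc[0]
        raise DataModelError(f"{path}: probe {bad!r} has start > end")
    return df


def write_annotation(df: pd.DataFrame, path) -> None:
    df[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------


@dataclass
class GroupContrast:
    """Two-level sample grouping and its zero-sum contrast encoding.

    ``c[j] = n_G2 / n`` for group-1 samples and ``-n_G1 / n`` for group-2
    samples, so that ``sum(c) == 0``.
    """

    labels: np.ndarray  # values in {1, 2}, aligned to a sample ordering
    sample_ids: list[str] | None = None
    n_g1: int = field(init=False)
    n_g2: int = field(init=False)
    c: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise DataModelError("labels must be 1-D")
        uniq = set(self.labels.tolist())
        if uniq != {1, 2}:
            raise DataModelError(f"labels must take exactly the values {{1, 2}}, got {sorted(uniq)}")
        self.n_g1 = int(np.sum(self.labels == 1))
        self.n_g2 = int(np.sum(self.labels == 2))
        if self.n_g1 < 2 or self.n_g2 < 2:
            raise DataModelError(
                f"each group needs >= 2 samples (got {self.n_g1} and {self.n_g2})"
            )
        n = self.n
        self.c = np.where(self.labels == 1, self.n_g2 / n, -self.n_g1 / n)
        if self.sample_ids is not None:
            self.sample_ids = [str(s) for s in self.sample_ids]
            if len(self.sample_ids) != n:
                raise DataModelError("sample_ids length does not match labels")
            dup = _first_duplicate(self.sample_ids)
            if dup is not None:
                raise DataModelError(f"duplicate sample id in grouping: {dup!r}")

    @property
    def n(self) -> int:
        return int(self.labels.size)

    @classmethod
    def from_labels(cls, labels, sample_ids=None) -> "GroupContrast":
        """Build from arbitrary two-level labels.

        Labels already coded 1/2 are kept; otherwise the lexicographically
        smaller label becomes group 1 (deterministic).
        """
        arr = np.asarray(labels)
        uniq = sorted({str(x) for x in arr.tolist()})
        if len(uniq) != 2:
            raise DataModelError(f"need exactly two distinct group labels, got {uniq}")
        if uniq == ["1", "2"]:
            coded = np.asarray([int(str(x)) for x in arr.tolist()])
        else:
            coded = np.where(np.asarray([str(x) for x in arr.tolist()]) == uniq[0], 1, 2)
        return cls(labels=coded, sample_ids=sample_ids)

    def group_indices(self, group: int) -> np.ndarray:
        return np.flatnonzero(self.labels == group)

    def subset(self, order: np.ndarray) -> "GroupContrast":
        order = np.asarray(order, dtype=int)
        ids = None if self.sample_ids is None else [self.sample_ids[i] for i in order]
        return GroupContrast(labels=self.labels[order], sample_ids=ids)


def read_groups(path) -> GroupContrast:
    """Read a grouping TSV ``sample_id<TAB>group`` with group in {1, 2}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise DataModelError(f"{path}: grouping file needs columns sample_id, group")
    return GroupContrast.from_labels(df["group"].tolist(), sample_ids=df["sample_id"].tolist())


def write_groups(contrast: GroupContrast, path) -> None:
    if contrast.sample_ids is None:
        raise DataModelError("cannot write a grouping without sample ids")
    pd.DataFrame({"sample_id": contrast.sample_ids, "group": contrast.labels}).to_csv(
        path, sep="\t", index=False
    )


def align_samples(
    y_mat: OmicsMatrix, x_mat: OmicsMatrix, groups: GroupContrast
) -> tuple[OmicsMatrix, OmicsMatrix, GroupContrast]:
    """Restrict all three inputs to their common samples, in one ordering.

    The ordering is that of ``y_mat`` restricted to the intersection.
    Dropped samples are logged.  A group left with < 2 samples is an error.
    """
    if groups.sample_ids is None:
        raise DataModelError("grouping has no sample ids; cannot align")
    x_pos = {s: i for i, s in enumerate(x_mat.sample_ids)}
    g_pos = {s: i for i, s in enumerate(groups.sample_ids)}
    keep = [s for s in y_mat.sample_ids if s in x_pos and s in g_pos]
    if not keep:
        raise DataModelError("no samples shared between matrices and grouping")
    dropped = (
        (set(y_mat.sample_ids) | set(x_mat.sample_ids) | set(groups.sample_ids))
        - set(keep)
    )
    if dropped:
        log.warning("align_samples: dropping %d unshared samples: %s",
                    len(dropped), sorted(dropped)[:10])
    y_order = [y_mat.sample_ids.index(s) for s in keep]
    y2 = y_mat.subset_samples(np.asarray(y_order))
    x2 = x_mat.subset_samples(np.asarray([x_pos[s] for s in keep]))
    g2 = groups.subset(np.asarray([g_pos[s] for s in keep]))  # validates group sizes
    return y2, x2, g2


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


@dataclass
class WindowMap:
    """Ordered covariate probe ids forming the gene set of each dependent probe."""

    windows: dict[str, list[str]]

    def __getitem__(self, probe_id: str) -> list[str]:
        return self.windows[probe_id]

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.windows

    def items(self):
        return self.windows.items()

    def indices(self, cov_probe_ids: list[str]) -> dict[str, np.ndarray]:
        """Map each window to integer row indices into a covariate matrix."""
        pos = {p: i for i, p in enumerate(cov_probe_ids)}
        out: dict[str, np.ndarray] = {}
        for dep, covs in self.windows.items():
            try:
                out[dep] = np.asarray([pos[p] for p in covs], dtype=int)
            except KeyError as e:
                raise DataModelError(
                    f"window of {dep!r} references unknown covariate probe {e.args[0]!r}"
                ) from None
        return out


def build_windows(
    dep_ann: pd.DataFrame,
    cov_ann: pd.DataFrame,
    mode: str = "arm",
    window_bp: int | None = None,
) -> WindowMap:
    """Assign to every dependent probe its covariate window.

    mode="arm": all covariate probes on the same chromosome and arm.
    mode="bp_window": all covariate probes whose midpoint lies within
    ``window_bp / 2`` of the dependent probe's midpoint (closed interval).

    Windows are ordered by covariate midpoint, ties broken by probe id.
    Membership depends only on annotation content, never on row order.
    """
    if mode not in ("arm", "bp_window"):
        raise DataModelError(f"unknown window mode {mode!r}")
    if mode == "bp_window":
        if window_bp is None or window_bp <= 0:
            raise DataModelError("mode=bp_window requires window_bp > 0")
    cov = cov_ann.copy()
    cov["mid"] = 0.5 * (cov["start"] + cov["end"])
    cov = cov.sort_values(["mid", "probe_id"], kind="mergesort")
    windows: dict[str, list[str]] = {}
    for rec in dep_ann.itertuples(index=False):
        dep_mid = 0.5 * (rec.start + rec.end)
        if mode == "arm":
            if pd.isna(rec.arm):
                raise DataModelError(
                    f"dependent probe {rec.probe_id!r} lacks an arm label (mode=arm)"
                )
            sel = cov[(cov["chromosome"] == rec.chromosome) & (cov["arm"] == rec.arm)]
        else:
            half = window_bp / 2.0
            sel = cov[
                (cov["chromosome"] == rec.chromosome)
                & (cov["mid"] >= dep_mid - half)
                & (cov["mid"] <= dep_mid + half)
            ]
        ids = sel["probe_id"].tolist()
        if not ids:
            log.warning("dependent probe %r has an empty covariate window", rec.probe_id)
        windows[str(rec.probe_id)] = ids
    return WindowMap(windows=windows)
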