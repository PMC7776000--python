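"""Sliding-window dynamic functional connectivity (dFC) construction.

A subject's regional time series (T timepoints x R regions) is turned into a
set of L = R(R-1)/2 link time series by computing the Pearson correlation of
every region pair inside a rectangular window slid along the scan.  The
canonical link order is the column-wise lower triangle of the R x R
correlation matrix: pairs (i, j) with i > j, enumerated j = 0..R-2 (outer),
i = j+1..R-1 (inner), 0-based.  This order is fixed so feature indices are
stable across runs and files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RoiTimeSeries",
    "WindowSpec",
    "LinkIndex",
    "DfcSeries",
    "sliding_window_fc",
    "static_fc",
    "vectorize_lower_triangle",
    "devectorize_lower_triangle",
    "n_windows",
]


class ConstantSignalError(ValueError):
    """A region's signal is constant where a correlation is required."""


@dataclass
class RoiTimeSeries:
    """One subject's T x R matrix of regional signals.

    Parameters
    ----------
    values : ndarray of shape (T, R)
        Regional signals, one column per region (arbitrary units).
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    roi_ids : list of str, optional
        Unique region identifiers; defaults to ``roi_000``, ``roi_001``, ...
    """

    values: np.ndarray
    tr_seconds: float = 2.0
    roi_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x R matrix")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 timepoints")
        if not self.roi_ids:
            self.roi_ids = [f"roi_{k:03d}" for k in range(self.values.shape[1])]
        if len(self.roi_ids) != self.values.shape[1]:
            raise ValueError("roi_ids length does not match number of columns")
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValueError("roi_ids must be unique")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class WindowSpec:
    """Rectangular sliding-window parameters (width and step in TRs)."""

    width_trs: int = 20
    step_trs: int = 1
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        if self.width_trs < 1:
            raise ValueError("width_trs must be >= 1")
        if self.step_trs < 1:
            raise ValueError("step_trs must be >= 1")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def width_seconds(self) -> float:
        return self.width_trs * self.tr_seconds

    @property
    def step_seconds(self) -> float:
        return self.step_trs * self.tr_seconds


def n_windows(n_timepoints: int, width_trs: int, step_trs: int) -> int:
    """Number of full windows: floor((T - w)/step) + 1; partial windows drop."""
    if width_trs > n_timepoints:
        raise ValueError(
            f"window width {width_trs} exceeds series length {n_timepoints}"
        )
    return (n_timepoints - width_trs) // step_trs + 1


@dataclass(frozen=True)
class LinkIndex:
    """Canonical bijection between link indices and unordered ROI pairs.

    Pair l maps to (i_l, j_l) with i_l > j_l in column-wise lower-triangle
    order: (1,0), (2,0), ..., (R-1,0), (2,1), (3,1), ...
    """

    n_rois: int

    def __post_init__(self) -> None:
        if self.n_rois < 2:
            raise ValueError("need at least 2 ROIs")

    @property
    def n_links(self) -> int:
        return self.n_rois * (self.n_rois - 1) // 2

    @property
    def pairs(self) -> np.ndarray:
        """(L, 2) array of (i, j) with i > j in canonical order."""
        j, i = np.triu_indices(self.n_rois, k=1)
        return np.column_stack([i, j])

    def link_of(self, a: int, b: int) -> int:
        """Link index of the unordered pair {a, b}."""
        if a == b:
            raise ValueError("a link joins two distinct ROIs")
        i, j = (a, b) if a > b else (b, a)
        # links before column j: sum_{c<j} (R-1-c); offset within column: i-j-1
        r = self.n_rois
        return j * (r - 1) - j * (j - 1) // 2 + (i - j - 1)


@dataclass
class DfcSeries:
    """L x W matrix of windowed link correlations for one subject."""

    values: np.ndarray
    window_spec: WindowSpec
    link_index: LinkIndex
    window_start_trs: np.ndarray

    @property
    def n_links(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]


def vectorize_lower_triangle(matrix: np.ndarray) -> tuple[np.ndarray, LinkIndex]:
    """Extract the lower triangle of a square symmetric matrix in canonical order."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {matrix.shape}")
    index = LinkIndex(matrix.shape[0])
    pairs = index.pairs
    return matrix[pairs[:, 0], pairs[:, 1]], index


def devectorize_lower_triangle(vector: np.ndarray, diagonal: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_lower_triangle` (symmetric, fixed diagonal)."""
    vector = np.asarray(vector, dtype=float)
    L = vector.shape[0]
    r = int(round((1 + np.sqrt(1 + 8 * L)) / 2))
    if r * (r - 1) // 2 != L:
        raise ValueError(f"length {L} is not a triangular number")
    out = np.full((r, r), diagonal)
    pairs = LinkIndex(r).pairs
    out[pairs[:, 0], pairs[:, 1]] = vector
    out[pairs[:, 1], pairs[:, 0]] = vector
    return out


def _check_constant(segment: np.ndarray, roi_ids: list[str], where: str) -> None:
    sd = segment.std(axis=0)
    # mean-subtraction roundoff leaves ~1e-16 residuals on constant columns
    tol = 1e-12 * np.maximum(1.0, np.abs(segment).max(axis=0))
    bad = np.flatnonzero(sd <= tol)
    if bad.size:
        names = ", ".join(roi_ids[k] for k in bad[:5])
        raise ConstantSignalError(
            f"constant signal for ROI(s) {names} {where}; "
            "Pearson correlation is undefined"
        )


def sliding_window_fc(ts: RoiTimeSeries, spec: WindowSpec | None = None) -> DfcSeries:
    """Windowed Pearson correlations of every ROI pair.

    Entry (l, k) is the correlation of the pair mapped to link l over
    timepoints [start_k, start_k + width).  Raises
    :class:`ConstantSignalError` naming the ROI and window if any region is
    constant within a window.
    """
    spec = spec or WindowSpec()
    T, R = ts.values.shape
    W = n_windows(T, spec.width_trs, spec.step_trs)
    index = LinkIndex(R)
    pairs = index.pairs
    starts = np.arange(W) * spec.step_trs
    out = np.empty((index.n_links, W))
    for k, s in enumerate(starts):
        seg = ts.values[s : s + spec.width_trs]
        _check_constant(seg, ts.roi_ids, f"in window {k} (start TR {s})")
        c = np.corrcoef(seg, rowvar=False)
        out[:, k] = c[pairs[:, 0], pairs[:, 1]]
    return DfcSeries(out, spec, index, starts)


def static_fc(ts: RoiTimeSeries) -> tuple[np.ndarray, LinkIndex]:
    """Lower-triangle vector of the full-scan correlation matrix."""
    _check_constant(ts.values, ts.roi_ids, "over the full series")
    return vectorize_lower_triangle(np.corrcoef(ts.values, rowvar=False))
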