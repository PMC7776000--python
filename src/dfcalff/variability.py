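"""Temporal variability of dFC: the dFC-ALFF statistic and feature tables.

dFC-ALFF is the summed single-sided Fourier amplitude of a windowed-
connectivity time series inside a low-frequency band (default 0 to 1/w Hz,
w the window length in seconds), quantifying how strongly a connection's
strength fluctuates over the scan.  The series mean is removed before the
transform and the zero-frequency bin excluded: the statistic measures
fluctuation, not mean connection strength.  Per-subject feature vectors are
standardized to z-scores across links, which makes every downstream result
invariant to the amplitude convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .dfc import DfcSeries, LinkIndex, RoiTimeSeries, WindowSpec, sliding_window_fc, static_fc

__all__ = [
    "AlffSpec",
    "FeatureTable",
    "dfc_alff",
    "zscore_within_subject",
    "build_feature_table",
    "DfcAlffExtractor",
    "StaticFcExtractor",
]


@dataclass(frozen=True)
class AlffSpec:
    """Frequency band and sampling interval for the dFC-ALFF computation.

    The sampling interval of a dFC series is one window step
    (``step_trs * tr_seconds``, default 2 s).  The default band upper edge is
    1/w = 0.025 Hz for the default 40-s window.
    """

    band_low_hz: float = 0.0
    band_high_hz: float = 0.025
    sampling_interval_seconds: float = 2.0

    def __post_init__(self) -> None:
        nyquist = 1.0 / (2.0 * self.sampling_interval_seconds)
        if not (0.0 <= self.band_low_hz < self.band_high_hz):
            raise ValueError("need 0 <= band_low_hz < band_high_hz")
        if self.band_high_hz > nyquist + 1e-12:
            raise ValueError(
                f"band_high_hz {self.band_high_hz} exceeds the dFC Nyquist "
                f"frequency {nyquist}"
            )


def _single_sided_amplitudes(rows: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Single-sided amplitude spectrum of each demeaned row.

    Returns (amplitudes, frequencies) with amplitude 2|X_k|/W for
    0 < k < W/2 and |X_k|/W at the Nyquist bin (even W), so a pure sinusoid
    of amplitude a recovers a and Parseval's identity holds bin-wise.
    """
    rows = np.asarray(rows, dtype=float)
    W = rows.shape[-1]
    demeaned = rows - rows.mean(axis=-1, keepdims=True)
    spectrum = np.fft.rfft(demeaned, axis=-1)
    freqs = np.fft.rfftfreq(W, d=dt)
    amps = 2.0 * np.abs(spectrum) / W
    if W % 2 == 0:
        amps[..., -1] /= 2.0  # Nyquist bin appears once in the DFT
    return amps, freqs


def dfc_alff(series: DfcSeries, spec: AlffSpec | None = None) -> np.ndarray:
    """Summed in-band single-sided amplitude per link (length L vector).

    Bin inclusion is half-open, band_low < f <= band_high, so the DC bin is
    excluded exactly once (the mean is removed anyway) and the band edge is
    included.
    """
    spec = spec or AlffSpec(sampling_interval_seconds=series.window_spec.step_seconds)
    if series.n_windows < 4:
        raise ValueError("need at least 4 windows to resolve a spectrum")
    amps, freqs = _single_sided_amplitudes(series.values, spec.sampling_interval_seconds)
    eps = 1e-12
    in_band = (freqs > spec.band_low_hz + eps) & (freqs <= spec.band_high_hz + eps)
    return amps[:, in_band].sum(axis=1)


def zscore_within_subject(raw: np.ndarray) -> np.ndarray:
    """Standardize a subject's link-feature vector to mean 0, sd 1.

    Uses the sample standard deviation (divisor L-1).  Invariant under
    positive affine rescaling of the input, so the spectral amplitude
    convention cannot leak into downstream models.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size < 2:
        raise ValueError("expected a vector of at least 2 link features")
    sd = raw.std(ddof=1)
    if sd == 0:
        raise ValueError("zero dispersion across links; features carry no information")
    return (raw - raw.mean()) / sd


@dataclass
class FeatureTable:
    """Cohort feature matrix (subjects x links) aligned to a score vector."""

    values: np.ndarray
    feature_kind: str  # "dfc_alff" or "static_fc"
    link_index: LinkIndex
    subject_ids: list[str]
    scores: np.ndarray
    control_scores: np.ndarray | None = None
    motion_summary: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError("row count does not match subject_ids")
        if self.scores.shape[0] != self.values.shape[0]:
            raise ValueError("scores not aligned to rows")
        if np.isnan(self.values).any():
            raise ValueError("feature table contains missing values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_links(self) -> int:
        return self.values.shape[1]

    def with_scores(self, scores: np.ndarray) -> "FeatureTable":
        """Same features with a substituted target vector (control analyses)."""
        return FeatureTable(
            self.values, self.feature_kind, self.link_index, self.subject_ids,
            np.asarray(scores, dtype=float), self.control_scores, self.motion_summary,
        )


class DfcAlffExtractor(TransformerMixin, BaseEstimator):
    """Transform stacked subject time series into z-scored dFC-ALFF features.

    Input X has shape (n_subjects, T, R); output (n_subjects, R(R-1)/2).

    Parameters
    ----------
    width_trs, step_trs : int
        Sliding-window width and step, in TRs.
    tr_seconds : float
        Sampling interval of the input series.
    band_low_hz, band_high_hz : float or None
        dFC-ALFF band; ``band_high_hz=None`` means 1/w Hz for window
        length w seconds.
    zscore : bool
        Standardize each subject's link vector (the modeling convention).
    """

    def __init__(self, width_trs: int = 20, step_trs: int = 1, tr_seconds: float = 2.0,
                 band_low_hz: float = 0.0, band_high_hz: float | None = None,
                 zscore: bool = True):
        self.width_trs = width_trs
        self.step_trs = step_trs
        self.tr_seconds = tr_seconds
        self.band_low_hz = band_low_hz
        self.band_high_hz = band_high_hz
        self.zscore = zscore

    def _specs(self) -> tuple[WindowSpec, AlffSpec]:
        wspec = WindowSpec(self.width_trs, self.step_trs, self.tr_seconds)
        high = self.band_high_hz
        if high is None:
            high = 1.0 / wspec.width_seconds
        return wspec, AlffSpec(self.band_low_hz, high, wspec.step_seconds)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected X of shape (n_subjects, T, R)")
        self.n_rois_ = X.shape[2]
        self.link_index_ = LinkIndex(self.n_rois_)
        self.n_features_out_ = self.link_index_.n_links
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        wspec, aspec = self._specs()
        rows = []
        for values in X:
            series = sliding_window_fc(RoiTimeSeries(values, self.tr_seconds), wspec)
            raw = dfc_alff(series, aspec)
            rows.append(zscore_within_subject(raw) if self.zscore else raw)
        return np.asarray(rows)


class StaticFcExtractor(TransformerMixin, BaseEstimator):
    """Transform stacked subject time series into z-scored static-FC features.

    The conventional comparator: one whole-scan correlation per link,
    standardized per subject exactly like the dFC-ALFF features.
    """

    def __init__(self, tr_seconds: float = 2.0, zscore: bool = True):
        self.tr_seconds = tr_seconds
        self.zscore = zscore

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected X of shape (n_subjects, T, R)")
        self.n_rois_ = X.shape[2]
        self.link_index_ = LinkIndex(self.n_rois_)
        self.n_features_out_ = self.link_index_.n_links
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        rows = []
        for values in X:
            raw, _ = static_fc(RoiTimeSeries(values, self.tr_seconds))
            rows.append(zscore_within_subject(raw) if self.zscore else raw)
        return np.asarray(rows)


def build_feature_table(
    series_by_subject: dict[str, RoiTimeSeries],
    scores: dict[str, float],
    feature_kind: str = "dfc_alff",
    window_spec: WindowSpec | None = None,
    alff_spec: AlffSpec | None = None,
    control_scores: dict[str, float] | None = None,
    motion_summary: dict[str, float] | None = None,
) -> FeatureTable:
    """Assemble per-subject feature vectors into the cohort modeling matrix.

    Rows follow the subject order of ``series_by_subject`` and are aligned to
    the score table by subject ID; an ID mismatch raises with the unmatched
    IDs listed.
    """
    if feature_kind not in ("dfc_alff", "static_fc"):
        raise ValueError(f"unknown feature_kind {feature_kind!r}")
    unmatched = sorted(set(series_by_subject) ^ set(scores))
    if unmatched:
        raise ValueError(f"subject IDs do not match between series and scores: {unmatched}")
    subject_ids = list(series_by_subject)
    rows = []
    link_index = None
    for sid in subject_ids:
        ts = series_by_subject[sid]
        if feature_kind == "dfc_alff":
            wspec = window_spec or WindowSpec(tr_seconds=ts.tr_seconds)
            series = sliding_window_fc(ts, wspec)
            aspec = alff_spec or AlffSpec(
                band_high_hz=1.0 / wspec.width_seconds,
                sampling_interval_seconds=wspec.step_seconds,
            )
            raw = dfc_alff(series, aspec)
            link_index = series.link_index
        else:
            raw, link_index = static_fc(ts)
        rows.append(zscore_within_subject(raw))
    score_vec = np.array([scores[s] for s in subject_ids], dtype=float)
    ctrl = None
    if control_scores is not None:
        ctrl = np.array([control_scores[s] for s in subject_ids], dtype=float)
    motion = None
    if motion_summary is not None:
        motion = np.array([motion_summary[s] for s in subject_ids], dtype=float)
    return FeatureTable(
        np.asarray(rows), feature_kind, link_index, subject_ids, score_vec, ctrl, motion
    )
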