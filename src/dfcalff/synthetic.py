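"""Synthetic cohorts with score-dependent slow modulation of link coupling.

No public cohort exists for the analysis this package implements, so the
generator emulates the statistical structure the pipeline assumes: band-
limited (0.01-0.08 Hz) regional signals; a continuous per-subject behavioral
score; a set of planted inter-network region pairs whose coupling is slowly
amplitude-modulated, with modulation depth a monotone function of the score
(decreasing for "negative-effect" links, increasing for "positive-effect"
ones); score-independent head-motion random walks; and a score-independent
control score.

The construction: a planted pair (i, j) shares a component m(t) * v(t) added
to both regions, with v(t) band-limited unit-variance noise and
m(t) = sqrt(max(0, 1 + A(y) * sin(2*pi*f_m*t))).  The windowed Pearson
correlation of the two regions rises and falls with m(t), so the link's
dFC-ALFF is an increasing function of the depth A — the planted effect is
visible to exactly the statistic under test.  The modulation frequency
defaults to 0.01 Hz, inside the 0-1/w = 0-0.025 Hz dFC-ALFF band.

Everything is a pure function of the configuration (including the seed):
identical configs give byte-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dfc import RoiTimeSeries

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "bandlimited_noise",
    "generate_motion",
    "ConfigError",
]


class ConfigError(ValueError):
    """A generator-configuration invariant is violated."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the acquisition the pipeline targets: 200 volumes at
    TR = 2 s with the first 5 discarded (195 retained), 160 regions grouped
    into six networks, signals band-passed to 0.01-0.08 Hz, behavioral
    scores uniform over 6-29 (the observed range of the target instrument)
    and control scores uniform over 24-57 (the observed anxiety-scale
    range).  ``effect_links_neg`` / ``effect_links_pos`` list planted
    inter-network ROI pairs; their modulation depth interpolates linearly
    over the score range between the two ends of ``depth_range`` (the
    default (2.0, 0.1) makes a negative-effect link's modulation fall from
    2.0 at the minimum score — deep swings that silence the coupling for
    part of each cycle, via the clip of m^2 at zero — to 0.1 at the
    maximum; a positive-effect link mirrors the map).  ``mean_effect_links``
    optionally
    plant a score-dependent *mean* coupling gain instead (no slow
    modulation), producing a cohort only static FC can see.
    """

    n_subjects: int = 60
    n_rois: int = 160
    network_sizes: tuple[int, ...] | None = None
    n_volumes_acquired: int = 200
    n_discard: int = 5
    tr_seconds: float = 2.0
    band: tuple[float, float] = (0.01, 0.08)
    score_range: tuple[float, float] = (6.0, 29.0)
    control_score_range: tuple[float, float] = (24.0, 57.0)
    effect_links_neg: tuple[tuple[int, int], ...] = ()
    effect_links_pos: tuple[tuple[int, int], ...] = ()
    mean_effect_links: tuple[tuple[int, int], ...] = ()
    modulation_freq_hz: float = 0.01
    depth_range: tuple[float, float] = (2.0, 0.1)
    mean_gain_range: tuple[float, float] = (0.2, 1.2)
    noise_sd: float = 0.5
    motion_step_sd: float = 0.05
    seed: int = 0

    def resolved_network_sizes(self) -> tuple[int, ...]:
        from .contributions import default_network_sizes

        if self.network_sizes is not None:
            return tuple(self.network_sizes)
        return default_network_sizes(self.n_rois)

    def network_of(self, roi: int) -> int:
        bounds = np.cumsum(self.resolved_network_sizes())
        return int(np.searchsorted(bounds, roi, side="right"))

    def validate(self) -> None:
        sizes = self.resolved_network_sizes()
        if sum(sizes) != self.n_rois:
            raise ConfigError(
                f"network_sizes sum to {sum(sizes)}, not n_rois={self.n_rois}"
            )
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        low, high = self.band
        if not (0.0 < low < high < nyquist):
            raise ConfigError(
                f"band {self.band} must satisfy 0 < low < high < Nyquist ({nyquist})"
            )
        if not (0 <= self.n_discard < self.n_volumes_acquired):
            raise ConfigError("n_discard must be < n_volumes_acquired")
        if self.n_subjects < 1 or self.n_rois < 2:
            raise ConfigError("need at least 1 subject and 2 ROIs")
        if self.noise_sd < 0 or self.motion_step_sd < 0:
            raise ConfigError("noise_sd and motion_step_sd must be >= 0")
        if self.score_range[0] >= self.score_range[1]:
            raise ConfigError("score_range must be increasing")
        for pair in (*self.effect_links_neg, *self.effect_links_pos,
                     *self.mean_effect_links):
            i, j = pair
            if i == j or not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                raise ConfigError(f"effect link {pair} is not a valid ROI pair")
            if self.network_of(i) == self.network_of(j):
                raise ConfigError(
                    f"effect link {pair} connects ROIs within one network; "
                    "planted links must be inter-network"
                )

    @property
    def n_timepoints(self) -> int:
        return self.n_volumes_acquired - self.n_discard


@dataclass
class SyntheticCohort:
    """A generated cohort: series, scores, motion, and the planted truth."""

    series: list[RoiTimeSeries]
    subject_ids: list[str]
    scores: np.ndarray
    control_scores: np.ndarray
    motion_series: list[np.ndarray]  # each (T, 3), mm
    ground_truth: dict
    config: GeneratorConfig

    @property
    def n_subjects(self) -> int:
        return len(self.series)

    def series_by_subject(self) -> dict[str, RoiTimeSeries]:
        return dict(zip(self.subject_ids, self.series))

    def scores_by_subject(self) -> dict[str, float]:
        return dict(zip(self.subject_ids, self.scores.tolist()))

    def control_scores_by_subject(self) -> dict[str, float]:
        return dict(zip(self.subject_ids, self.control_scores.tolist()))

    def stacked(self) -> np.ndarray:
        """(n_subjects, T, R) array for the sklearn transformers."""
        return np.stack([ts.values for ts in self.series])


def _band_mask(n: int, dt: float, band: tuple[float, float]) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=dt)
    mask = (freqs >= band[0] - 1e-12) & (freqs <= band[1] + 1e-12)
    if not mask.any():
        # keep the single closest bin so a degenerate band still has support
        mask[np.argmin(np.abs(freqs - 0.5 * (band[0] + band[1])))] = True
    mask[0] = False
    return mask


def bandlimited_noise(
    n_timepoints: int,
    tr: float,
    band: tuple[float, float],
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Zero-mean, unit-variance noise confined to a frequency band.

    Implemented by frequency-domain masking of white noise: exact band
    control (out-of-band power is zero up to float error, well beyond the
    20 dB attenuation a recursive filter would give).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    nyquist = 1.0 / (2.0 * tr)
    if not (0.0 <= band[0] < band[1] <= nyquist):
        raise ValueError(f"band {band} outside (0, Nyquist={nyquist})")
    white = rng.standard_normal(n_timepoints)
    spectrum = np.fft.rfft(white)
    spectrum[~_band_mask(n_timepoints, tr, band)] = 0.0
    signal = np.fft.irfft(spectrum, n=n_timepoints)
    signal -= signal.mean()
    sd = signal.std()
    if sd == 0:
        raise ValueError("band too narrow: no spectral support")
    return signal / sd


def generate_motion(
    n_timepoints: int,
    step_sd: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Random-walk translation parameters (T x 3, mm), score-independent."""
    if step_sd < 0:
        raise ValueError("step_sd must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    steps = rng.standard_normal((n_timepoints, 3)) * step_sd
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


def _depth(score: float, score_range: tuple[float, float],
           depth_range: tuple[float, float]) -> float:
    lo, hi = score_range
    frac = (score - lo) / (hi - lo)
    return depth_range[0] + frac * (depth_range[1] - depth_range[0])


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a full cohort per the configuration; deterministic given seed.

    Scores, control scores, motion and signal noise come from independent
    seed-derived streams, so control scores and motion are independent of
    the planted modulation by construction.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_scores, ss_control, ss_motion, ss_signals = root.spawn(4)
    rng_scores = np.random.default_rng(ss_scores)
    rng_control = np.random.default_rng(ss_control)
    rng_motion = np.random.default_rng(ss_motion)
    rng_signals = np.random.default_rng(ss_signals)

    n, T, R = config.n_subjects, config.n_timepoints, config.n_rois
    scores = rng_scores.uniform(*config.score_range, size=n)
    control = rng_control.uniform(*config.control_score_range, size=n)
    t = np.arange(T) * config.tr_seconds
    f_m = config.modulation_freq_hz

    neg = [tuple(p) for p in config.effect_links_neg]
    pos = [tuple(p) for p in config.effect_links_pos]
    mean_links = [tuple(p) for p in config.mean_effect_links]
    d_lo, d_hi = config.depth_range

    series: list[RoiTimeSeries] = []
    motion: list[np.ndarray] = []
    subject_ids = [f"sub_{k:03d}" for k in range(n)]
    truth_links = []
    for pair in neg:
        truth_links.append({"pair": list(pair), "sign": -1,
                            "depth_range": [d_lo, d_hi]})
    for pair in pos:
        truth_links.append({"pair": list(pair), "sign": 1,
                            "depth_range": [d_hi, d_lo]})

    for s in range(n):
        values = np.empty((T, R))
        for r in range(R):
            values[:, r] = config.noise_sd * bandlimited_noise(
                T, config.tr_seconds, config.band, rng_signals
            )
        for pair, sign in [(p, -1) for p in neg] + [(p, 1) for p in pos]:
            # negative-effect links: depth falls with score; positive: rises
            rng_pair = rng_signals  # same stream; order is deterministic
            v = bandlimited_noise(T, config.tr_seconds, config.band, rng_pair)
            if sign < 0:
                depth = _depth(scores[s], config.score_range, (d_lo, d_hi))
            else:
                depth = _depth(scores[s], config.score_range, (d_hi, d_lo))
            m = np.sqrt(np.maximum(0.0, 1.0 + depth * np.sin(2 * np.pi * f_m * t)))
            shared = m * v
            values[:, pair[0]] += shared
            values[:, pair[1]] += shared
        for pair in mean_links:
            v = bandlimited_noise(T, config.tr_seconds, config.band, rng_signals)
            gain = _depth(scores[s], config.score_range, config.mean_gain_range)
            values[:, pair[0]] += gain * v
            values[:, pair[1]] += gain * v
        series.append(RoiTimeSeries(values, config.tr_seconds))
        motion.append(generate_motion(T, config.motion_step_sd, rng_motion))

    ground_truth = {
        "links": truth_links,
        "mean_effect_links": [list(p) for p in mean_links],
        "modulation_freq_hz": f_m,
    }
    return SyntheticCohort(series, subject_ids, scores, control, motion,
                           ground_truth, config)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write a cohort as TSV/JSON files plus a manifest (provenance record)."""
    from . import io as dio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for sid, ts in zip(cohort.subject_ids, cohort.series):
        path = out / f"{sid}_series.tsv"
        dio.write_subject_series(path, ts)
        files.append(path.name)
    for sid, m in zip(cohort.subject_ids, cohort.motion_series):
        path = out / f"{sid}_motion.tsv"
        dio.write_motion(path, m)
        files.append(path.name)
    dio.write_scores(out / "scores.tsv", cohort.subject_ids, cohort.scores,
                     cohort.control_scores)
    files.append("scores.tsv")
    (out / "ground_truth.json").write_text(json.dumps(cohort.ground_truth, indent=2))
    files.append("ground_truth.json")
    manifest = {
        "config": asdict(cohort.config),
        "files": files,
        "n_subjects": cohort.n_subjects,
        "tr_seconds": cohort.config.tr_seconds,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    return out
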