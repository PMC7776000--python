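"""Validation analyses: static-FC comparator, head-motion screening, control target.

Three checks accompany the primary dFC-ALFF association: (a) the same CPM
pipeline on conventional static-FC features, to show the dynamic statistic
carries the signal; (b) Pearson correlation of every consensus feature with
per-subject head motion (mean framewise displacement) under FDR correction,
to rule motion out as the driver; and (c) the identical pipeline with an
unrelated control score (an anxiety scale in the motivating study) as the
target, which should find nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cpm import CpmConfig, CpmResult, nested_loocv
from .network_models import benjamini_hochberg
from .variability import FeatureTable

__all__ = [
    "MotionSummary",
    "ConfoundReport",
    "framewise_displacement",
    "motion_confound_check",
    "control_target_run",
    "static_comparator_run",
]


@dataclass
class MotionSummary:
    """Framewise displacement series and its per-subject mean (mm)."""

    fd_series: np.ndarray  # length T-1
    mean_fd: float


def framewise_displacement(motion: np.ndarray) -> MotionSummary:
    """FD per volume: Euclidean norm of the first differences of the three
    translation parameters.

    Input is a T x 3 (or T x 6; only the first three columns, the
    translations in mm, enter the formula) motion-parameter series.  The
    subject-level summary is the mean FD.  Invariant to a constant offset of
    the translations.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[0] < 2:
        raise ValueError("need a T x 3 series with at least 2 volumes")
    if motion.shape[1] < 3:
        raise ValueError("need at least 3 translation columns")
    deltas = np.diff(motion[:, :3], axis=0)
    fd = np.sqrt((deltas ** 2).sum(axis=1))
    return MotionSummary(fd, float(fd.mean()))


@dataclass
class ConfoundReport:
    """Motion screening of the consensus features plus the control-target run."""

    motion_table: pd.DataFrame  # link, r, p, p_fdr, significant
    n_significant: int
    n_nonsignificant: int
    control_result: CpmResult | None = None

    def __post_init__(self) -> None:
        if self.n_significant + self.n_nonsignificant != len(self.motion_table):
            raise ValueError("significance counts do not sum to the consensus size")


def motion_confound_check(
    features: FeatureTable,
    links: np.ndarray,
    mean_fd: np.ndarray,
    q: float = 0.05,
) -> ConfoundReport:
    """Correlate each consensus feature with per-subject mean FD.

    Two-sided Pearson p-values are BH-FDR adjusted across the consensus set;
    the report counts significant and non-significant features.
    """
    from .cpm import correlation_pvalues

    links = np.asarray(links, dtype=int)
    mean_fd = np.asarray(mean_fd, dtype=float)
    if mean_fd.shape[0] != features.n_subjects:
        raise ValueError(
            f"{mean_fd.shape[0]} motion summaries for {features.n_subjects} subjects"
        )
    r, p = correlation_pvalues(features.values[:, links], mean_fd)
    adjusted, reject = benjamini_hochberg(p, q)
    table = pd.DataFrame({
        "link": links, "r": r, "p": p, "p_fdr": adjusted, "significant": reject,
    })
    return ConfoundReport(table, int(reject.sum()), int((~reject).sum()))


def control_target_run(
    features: FeatureTable,
    control_scores: np.ndarray | None = None,
    config: CpmConfig | None = None,
) -> CpmResult:
    """The identical CPM pipeline with the control score as the target.

    Every pipeline decision is shared with the primary run; only the target
    column differs.  Defaults to the table's own control_scores.
    """
    if control_scores is None:
        control_scores = features.control_scores
    if control_scores is None:
        raise ValueError("no control scores supplied")
    return nested_loocv(features, config, scores=np.asarray(control_scores, dtype=float),
                        label="control")


def static_comparator_run(
    static_features: FeatureTable,
    config: CpmConfig | None = None,
) -> CpmResult:
    """Full nested-LOOCV CPM on static-FC features (the comparator run)."""
    if static_features.feature_kind != "static_fc":
        raise ValueError("expected a static_fc feature table")
    return nested_loocv(static_features, config, label="static")
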