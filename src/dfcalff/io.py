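"""Tabular text I/O: subject series, scores, partitions, features, results.

All exchange formats are TSV with a header row (JSON for structured
results), so every artifact is diffable and survives any transport.  Readers
fail loudly with the offending row or ID rather than propagating NaN.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .contributions import NetworkPartition
from .cpm import CpmConfig, CpmResult, FoldRecord
from .dfc import LinkIndex, RoiTimeSeries
from .variability import FeatureTable

__all__ = [
    "read_subject_series",
    "write_subject_series",
    "read_scores",
    "write_scores",
    "read_motion",
    "write_motion",
    "read_partition",
    "write_partition",
    "read_feature_table",
    "write_feature_table",
    "result_to_json",
    "result_from_json",
]


class ParseError(ValueError):
    """A tabular input file violates its format contract."""


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.ParserError as err:
        raise ParseError(f"{path}: {err}") from err


def read_subject_series(path: str | Path, tr_seconds: float = 2.0) -> RoiTimeSeries:
    """Read a T x R series TSV (header row = ROI IDs, numeric body)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):  # pandas silently mangles duplicates
        raise ParseError(f"{path}: duplicate ROI IDs in header")
    df = _read_tsv(path)
    roi_ids = [str(c) for c in df.columns]
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        bad = df.map(lambda v: not isinstance(v, (int, float, np.number)))
        row = int(bad.any(axis=1).idxmax())
        raise ParseError(f"{path}: non-numeric cell in data row {row}")
    nan_rows = np.flatnonzero(np.isnan(values).any(axis=1))
    if nan_rows.size:
        raise ParseError(f"{path}: missing cell in data row {nan_rows[0]}")
    return RoiTimeSeries(values.astype(float), tr_seconds, roi_ids)


def write_subject_series(path: str | Path, ts: RoiTimeSeries) -> None:
    pd.DataFrame(ts.values, columns=ts.roi_ids).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a score table: columns subject_id, score[, control_score]."""
    df = _read_tsv(path)
    if "subject_id" not in df.columns or "score" not in df.columns:
        raise ParseError(f"{path}: expected columns subject_id and score")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ParseError(f"{path}: duplicate subject IDs {dups}")
    return df


def write_scores(path: str | Path, subject_ids: list[str], scores: np.ndarray,
                 control_scores: np.ndarray | None = None) -> None:
    data = {"subject_id": subject_ids, "score": np.asarray(scores, dtype=float)}
    if control_scores is not None:
        data["control_score"] = np.asarray(control_scores, dtype=float)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_motion(path: str | Path) -> np.ndarray:
    """Read a T x 3 (or T x 6) motion-parameter TSV."""
    df = _read_tsv(path)
    values = df.to_numpy(dtype=float)
    if values.shape[1] < 3:
        raise ParseError(f"{path}: need at least 3 motion columns")
    return values


def write_motion(path: str | Path, motion: np.ndarray) -> None:
    motion = np.asarray(motion, dtype=float)
    cols = ["trans_x_mm", "trans_y_mm", "trans_z_mm"][: motion.shape[1]]
    cols += [f"param_{k}" for k in range(len(cols), motion.shape[1])]
    pd.DataFrame(motion, columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_partition(path: str | Path,
                   expected_roi_ids: list[str] | None = None) -> NetworkPartition:
    """Read a partition TSV: columns roi_id, network[, x, y, z]."""
    df = _read_tsv(path)
    for col in ("roi_id", "network"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if df["network"].isna().any():
        missing = df.loc[df["network"].isna(), "roi_id"].tolist()
        raise ParseError(f"{path}: ROIs without a network label: {missing}")
    roi_ids = [str(r) for r in df["roi_id"]]
    if expected_roi_ids is not None:
        absent = sorted(set(expected_roi_ids) - set(roi_ids))
        if absent:
            raise ParseError(f"{path}: ROIs present in series but unlabeled here: {absent}")
        order = {r: k for k, r in enumerate(expected_roi_ids)}
        df = df.iloc[np.argsort([order.get(r, len(order)) for r in roi_ids])]
        roi_ids = [str(r) for r in df["roi_id"]]
    coords = None
    if {"x", "y", "z"}.issubset(df.columns):
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    return NetworkPartition([str(n) for n in df["network"]], roi_ids, coords)


def write_partition(path: str | Path, partition: NetworkPartition) -> None:
    data = {"roi_id": partition.roi_ids, "network": partition.labels}
    df = pd.DataFrame(data)
    if partition.coordinates is not None:
        df[["x", "y", "z"]] = np.asarray(partition.coordinates, dtype=float)
    df.to_csv(path, sep="\t", index=False)


def write_feature_table(path: str | Path, table: FeatureTable) -> None:
    """Write subjects x links TSV plus a JSON sidecar with the conventions."""
    path = Path(path)
    df = pd.DataFrame(table.values,
                      columns=[f"link_{k}" for k in range(table.n_links)])
    df.insert(0, "subject_id", table.subject_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = {
        "feature_kind": table.feature_kind,
        "n_rois": table.link_index.n_rois,
        "link_order": "column-wise lower triangle, 0-based, (i>j)",
        "scores": np.asarray(table.scores, dtype=float).tolist(),
        "control_scores": (None if table.control_scores is None
                           else np.asarray(table.control_scores, dtype=float).tolist()),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    df = _read_tsv(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    subject_ids = [str(s) for s in df["subject_id"]]
    values = df.drop(columns=["subject_id"]).to_numpy(dtype=float)
    ctrl = sidecar.get("control_scores")
    return FeatureTable(
        values, sidecar["feature_kind"], LinkIndex(sidecar["n_rois"]),
        subject_ids, np.asarray(sidecar["scores"], dtype=float),
        None if ctrl is None else np.asarray(ctrl, dtype=float),
    )


def result_to_json(result: CpmResult) -> dict:
    return {
        "label": result.label,
        "association_r": result.association_r,
        "association_p": result.association_p,
        "subject_ids": result.subject_ids,
        "predictions": result.predictions.tolist(),
        "config": dataclasses.asdict(result.config),
        "solver": "sklearn.svm.SVR(kernel='linear')",
        "folds": [
            {
                "held_out_subject_id": f.held_out_subject_id,
                "chosen_p": f.chosen_p,
                "selected_links": f.selected_links.tolist(),
                "link_signs": f.link_signs.tolist(),
                "prediction": f.prediction,
                "inner_r": f.inner_r,
            }
            for f in result.folds
        ],
    }


def result_from_json(payload: dict) -> CpmResult:
    cfg = dict(payload["config"])
    cfg["p_grid"] = tuple(cfg["p_grid"])
    folds = [
        FoldRecord(
            f["held_out_subject_id"], f["chosen_p"],
            np.asarray(f["selected_links"], dtype=int),
            np.asarray(f["link_signs"], dtype=int),
            f["prediction"], f["inner_r"],
        )
        for f in payload["folds"]
    ]
    return CpmResult(
        folds, np.asarray(payload["predictions"], dtype=float),
        payload["association_r"], payload["association_p"],
        payload["subject_ids"], CpmConfig(**cfg), payload.get("label", "primary"),
    )
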