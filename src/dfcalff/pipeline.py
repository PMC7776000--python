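"""End-to-end pipeline driver with a provenance manifest.

Chains simulate -> dFC features -> CPM -> contributions -> network models ->
validation on a directory layout, recording every stage output with a
content checksum so a rerun with the same configuration is verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as dio
from .contributions import NetworkPartition, contribution_report
from .cpm import CpmConfig, nested_loocv
from .network_models import run_network_models
from .synthetic import GeneratorConfig, generate_cohort, write_cohort
from .validation import (control_target_run, framewise_displacement,
                         motion_confound_check, static_comparator_run)
from .variability import AlffSpec, FeatureTable, build_feature_table
from .dfc import WindowSpec
from .contributions import consensus_links

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "pipeline_run"]


@dataclass
class RunConfig:
    """Everything a full run needs; serialized verbatim into the manifest."""

    out_dir: str
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    window: WindowSpec = field(default_factory=WindowSpec)
    alff: AlffSpec | None = None
    cpm: CpmConfig = field(default_factory=CpmConfig)
    run_network_models: bool = True
    run_validation: bool = True
    log_level: str = "INFO"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def pipeline_run(config: RunConfig) -> Path:
    """Run the full synthetic-cohort analysis; returns the run directory.

    Aborts on a stage failure with the stage name, persisting the partial
    manifest; deterministic stages reproduce identical checksums on rerun.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log")
    log_handler.setLevel(config.log_level)
    logging.getLogger("dfcalff").addHandler(log_handler)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    manifest_path = out / "manifest.json"

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            f.name: _sha256(f) for f in files
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    stage = "simulate"
    try:
        cohort = generate_cohort(config.generator)
        cohort_dir = out / "cohort"
        write_cohort(cohort, cohort_dir)
        record(stage, sorted(cohort_dir.glob("*")))

        stage = "features"
        wspec = config.window
        aspec = config.alff or AlffSpec(
            band_high_hz=1.0 / wspec.width_seconds,
            sampling_interval_seconds=wspec.step_seconds,
        )
        motion_means = {
            sid: framewise_displacement(m).mean_fd
            for sid, m in zip(cohort.subject_ids, cohort.motion_series)
        }
        table = build_feature_table(
            cohort.series_by_subject(), cohort.scores_by_subject(), "dfc_alff",
            wspec, aspec, cohort.control_scores_by_subject(), motion_means,
        )
        dio.write_feature_table(out / "features_dfc_alff.tsv", table)
        static_table = build_feature_table(
            cohort.series_by_subject(), cohort.scores_by_subject(), "static_fc",
            control_scores=cohort.control_scores_by_subject(),
        )
        dio.write_feature_table(out / "features_static_fc.tsv", static_table)
        record(stage, [out / "features_dfc_alff.tsv", out / "features_static_fc.tsv"])

        stage = "cpm"
        result = nested_loocv(table, config.cpm)
        (out / "cpm_result.json").write_text(
            json.dumps(dio.result_to_json(result), indent=2))
        record(stage, [out / "cpm_result.json"])

        stage = "contributions"
        sizes = config.generator.resolved_network_sizes()
        from .contributions import DEFAULT_NETWORKS
        partition = NetworkPartition.from_sizes(
            dict(zip(DEFAULT_NETWORKS, sizes)))
        partition.roi_ids = cohort.series[0].roi_ids
        report = contribution_report(result, table, partition)
        report.links.to_csv(out / "contrib_links.tsv", sep="\t", index=False)
        report.region_degrees.to_csv(out / "contrib_regions.tsv", sep="\t", index=False)
        report.network_table.to_csv(out / "contrib_networks.tsv", sep="\t", index=False)
        report.pairwise_table.to_csv(out / "contrib_pairs.tsv", sep="\t", index=False)
        report.inter_share.to_csv(out / "contrib_inter_share.tsv", sep="\t", index=False)
        record(stage, sorted(out.glob("contrib_*.tsv")))

        if config.run_network_models:
            stage = "network_models"
            nm = run_network_models(table, partition, config.cpm)
            nm.to_csv(out / "network_models.tsv", sep="\t", index=False)
            record(stage, [out / "network_models.tsv"])

        if config.run_validation:
            stage = "validation"
            links, _ = consensus_links(result)
            fd = np.array([motion_means[s] for s in cohort.subject_ids])
            files = []
            if len(links):
                confound = motion_confound_check(table, links, fd)
                confound.motion_table.to_csv(
                    out / "motion_confound.tsv", sep="\t", index=False)
                files.append(out / "motion_confound.tsv")
            # a comparator/control run that selects nothing anywhere is a
            # legitimate negative outcome, recorded rather than fatal
            from .cpm import EmptySelectionError

            for name, runner in (
                ("control", lambda: control_target_run(table, cohort.control_scores,
                                                       config.cpm)),
                ("static", lambda: static_comparator_run(static_table, config.cpm)),
            ):
                path = out / f"{name}_result.json"
                try:
                    payload = dio.result_to_json(runner())
                except EmptySelectionError as err:
                    logger.info("%s run found no model: %s", name, err)
                    payload = {"label": name, "status": "no_model", "reason": str(err)}
                path.write_text(json.dumps(payload, indent=2))
                files.append(path)
            record(stage, files)
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    finally:
        logging.getLogger("dfcalff").removeHandler(log_handler)
        log_handler.close()
    return out
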