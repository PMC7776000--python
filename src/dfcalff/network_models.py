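"""Network-restricted CPM models with false-discovery-rate control.

The whole-brain model is repeated on link subsets: one model per network
using only its intra-network links (six models for the six-network
partition) and one per network pair using only the links that join the two
(15 models for six networks).  Raw association p-values are
Benjamini-Hochberg adjusted; the intra and pairwise families are corrected
separately by default (matching their separate reporting), with a combined
family available.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .contributions import NetworkPartition
from .cpm import CpmConfig, EmptySelectionError, nested_loocv
from .dfc import LinkIndex
from .variability import FeatureTable

__all__ = [
    "restrict_links",
    "run_network_models",
    "benjamini_hochberg",
]

logger = logging.getLogger(__name__)


def restrict_links(
    link_index: LinkIndex,
    partition: NetworkPartition,
    spec: tuple,
) -> np.ndarray:
    """Link indices of an intra-network or pairwise inter-network subset.

    ``spec`` is ``("intra", net)`` (both endpoints in net) or
    ``("pair", net_a, net_b)`` (one endpoint in each).
    """
    labels = partition.label_array()
    known = set(partition.networks)
    for net in spec[1:]:
        if net not in known:
            raise ValueError(f"unknown network label {net!r}")
    pairs = link_index.pairs
    la, lb = labels[pairs[:, 0]], labels[pairs[:, 1]]
    if spec[0] == "intra":
        net = spec[1]
        mask = (la == net) & (lb == net)
    elif spec[0] == "pair":
        na, nb = spec[1], spec[2]
        if na == nb:
            raise ValueError("a pair spec needs two distinct networks")
        mask = ((la == na) & (lb == nb)) | ((la == nb) & (lb == na))
    else:
        raise ValueError(f"unknown subset kind {spec[0]!r}")
    return np.flatnonzero(mask)


def benjamini_hochberg(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns (adjusted p-values, rejection flags at level q).
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy(), np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)) or np.any(np.isnan(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return adjusted, reject


def run_network_models(
    features: FeatureTable,
    partition: NetworkPartition,
    config: CpmConfig | None = None,
    q: float = 0.05,
    combined_family: bool = False,
) -> pd.DataFrame:
    """Nested-LOOCV CPM per intra-network and pairwise link subset.

    One row per model with subset size, association r/p, FDR-adjusted p and
    a significance flag at level ``q``.  A subset on which the run fails
    (e.g. too few links pass selection at every grid threshold) is reported
    as a failed row, never dropped silently; failed rows are excluded from
    the FDR family and never flagged significant.
    """
    config = config or CpmConfig()
    nets = partition.networks
    specs = [("intra", n) for n in nets]
    specs += [("pair", nets[a], nets[b]) for a in range(len(nets))
              for b in range(a + 1, len(nets))]
    rows = []
    for spec in specs:
        subset = restrict_links(features.link_index, partition, spec)
        model_id = spec[1] if spec[0] == "intra" else f"{spec[1]}-{spec[2]}"
        row = {
            "model": model_id, "kind": spec[0], "n_links": int(subset.size),
            "association_r": np.nan, "association_p": np.nan, "status": "ok",
        }
        if subset.size == 0:
            row["status"] = "failed: no links in subset"
            rows.append(row)
            continue
        try:
            result = nested_loocv(
                features.values[:, subset], config, scores=features.scores,
                subject_ids=features.subject_ids, label=f"network:{model_id}",
            )
            row["association_r"] = result.association_r
            row["association_p"] = result.association_p
        except (EmptySelectionError, ValueError) as err:
            logger.warning("network model %s failed: %s", model_id, err)
            row["status"] = f"failed: {err}"
        rows.append(row)
    table = pd.DataFrame(rows)

    table["p_fdr"] = np.nan
    table["significant"] = False
    families = [table.index] if combined_family else [
        table.index[table["kind"] == "intra"],
        table.index[table["kind"] == "pair"],
    ]
    for fam in families:
        ok = fam[table.loc[fam, "association_p"].notna()]
        if len(ok) == 0:
            continue
        adjusted, reject = benjamini_hochberg(table.loc[ok, "association_p"].to_numpy(), q)
        table.loc[ok, "p_fdr"] = adjusted
        table.loc[ok, "significant"] = reject
    return table
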