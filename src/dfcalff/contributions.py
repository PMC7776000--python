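"""Contribution decomposition of a fitted CPM at link, region and network level.

Consensus links are those selected in 100% of outer LOOCV folds (with a
unanimous correlation sign).  Each consensus link's contribution is the mean,
over outer folds, of the Pearson correlation between its feature and the
score on that fold's training subjects.  Region degree sums half the
absolute contribution of every incident link; network-level indices split
intra- from inter-network links (an inter-network link donates half its
contribution to each endpoint network) and are normalized by N_max/N to
offset unequal network sizes.  Negatively and positively correlated links
are summarized separately throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cpm import CpmResult
from .dfc import LinkIndex
from .variability import FeatureTable

__all__ = [
    "NetworkPartition",
    "ContributionReport",
    "consensus_links",
    "link_contribution",
    "region_degree",
    "network_indices",
    "pairwise_percentages",
    "inter_network_share",
    "contribution_report",
    "DEFAULT_NETWORKS",
    "default_network_sizes",
]

logger = logging.getLogger(__name__)

DEFAULT_NETWORKS = ("CON", "FPN", "DMN", "SMN", "OcN", "CereN")

# Published network sizes of the 160-ROI atlas the six-network grouping
# comes from; configurable, must sum to the ROI count.
_DEFAULT_SIZES_160 = (32, 21, 34, 33, 22, 18)


def default_network_sizes(n_rois: int = 160) -> tuple[int, ...]:
    """Default six-network ROI counts; exact atlas sizes at R=160, else a
    near-even six-way split."""
    if n_rois == 160:
        return _DEFAULT_SIZES_160
    base, extra = divmod(n_rois, 6)
    return tuple(base + (1 if k < extra else 0) for k in range(6))


@dataclass
class NetworkPartition:
    """Assignment of every ROI to exactly one functional network.

    ``labels[k]`` is the network of ROI index k; ``roi_ids`` aligns indices
    with identifiers; optional MNI coordinates ride along for reporting.
    """

    labels: list[str]
    roi_ids: list[str] = field(default_factory=list)
    coordinates: np.ndarray | None = None  # (R, 3) MNI mm, optional

    def __post_init__(self) -> None:
        if not self.roi_ids:
            self.roi_ids = [f"roi_{k:03d}" for k in range(len(self.labels))]
        if len(self.roi_ids) != len(self.labels):
            raise ValueError("roi_ids and labels lengths differ")
        if len(self.networks) < 2:
            raise ValueError("need at least 2 networks")

    @property
    def n_rois(self) -> int:
        return len(self.labels)

    @property
    def networks(self) -> list[str]:
        """Network names in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab)
        return list(seen)

    @property
    def network_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for lab in self.labels:
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes

    @classmethod
    def from_sizes(cls, sizes: dict[str, int] | None = None,
                   n_rois: int | None = None) -> "NetworkPartition":
        """Contiguous-block partition from per-network ROI counts."""
        if sizes is None:
            if n_rois is None:
                raise ValueError("provide sizes or n_rois")
            sizes = dict(zip(DEFAULT_NETWORKS, default_network_sizes(n_rois)))
        labels = [net for net, n in sizes.items() for _ in range(n)]
        return cls(labels)

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels)


@dataclass
class ContributionReport:
    """Link-, region- and network-level contribution summary."""

    links: pd.DataFrame  # link, roi_i, roi_j, sign, contribution
    region_degrees: pd.DataFrame  # roi_id, network, weight
    network_table: pd.DataFrame  # network, sign_group, intra_index, inter_index (normalized)
    pairwise_table: pd.DataFrame  # net_a, net_b, sign_group, percent
    inter_share: pd.DataFrame  # sign_group, n_inter, n_total, percent


def consensus_links(result: CpmResult) -> tuple[np.ndarray, np.ndarray]:
    """Links selected in every outer fold with a unanimous sign.

    Returns (link indices, signs).  Links selected everywhere but with a
    sign that flips across folds are excluded and logged; an empty set is
    allowed (and logged).
    """
    if not result.folds:
        raise ValueError("result has no folds")
    sign_maps = []
    common: set[int] | None = None
    for fold in result.folds:
        m = dict(zip(fold.selected_links.tolist(), fold.link_signs.tolist()))
        sign_maps.append(m)
        common = set(m) if common is None else common & set(m)
    links, signs = [], []
    for l in sorted(common):
        fold_signs = {m[l] for m in sign_maps}
        if len(fold_signs) > 1:
            logger.info("link %d selected in all folds but with inconsistent sign; excluded", l)
            continue
        links.append(l)
        signs.append(fold_signs.pop())
    if not links:
        logger.info("no consensus links (empty set)")
    return np.asarray(links, dtype=int), np.asarray(signs, dtype=int)


def _train_masks(result: CpmResult) -> np.ndarray:
    """(n_folds, n_subjects) boolean training masks from held-out IDs."""
    ids = result.subject_ids
    pos = {s: k for k, s in enumerate(ids)}
    masks = np.ones((len(result.folds), len(ids)), dtype=bool)
    for f, fold in enumerate(result.folds):
        masks[f, pos[fold.held_out_subject_id]] = False
    return masks


def link_contribution(
    features: np.ndarray,
    scores: np.ndarray,
    result: CpmResult,
    links: np.ndarray,
) -> np.ndarray:
    """Mean training-set correlation of each link with the score across folds."""
    if len(links) == 0:
        raise ValueError("consensus link set is empty")
    X = np.asarray(features, dtype=float)[:, links]
    y = np.asarray(scores, dtype=float)
    masks = _train_masks(result)
    per_fold = np.empty((masks.shape[0], len(links)))
    for f, tr in enumerate(masks):
        Xc = X[tr] - X[tr].mean(axis=0)
        yc = y[tr] - y[tr].mean()
        denom = np.sqrt((Xc ** 2).sum(axis=0)) * np.sqrt((yc ** 2).sum())
        per_fold[f] = (Xc.T @ yc) / denom
    return per_fold.mean(axis=0)


def region_degree(
    contributions: np.ndarray,
    links: np.ndarray,
    link_index: LinkIndex,
) -> np.ndarray:
    """Per-ROI weight: sum of half the absolute contribution of incident links."""
    weights = np.zeros(link_index.n_rois)
    pairs = link_index.pairs
    for c, l in zip(np.asarray(contributions, dtype=float), np.asarray(links, dtype=int)):
        i, j = pairs[l]
        weights[i] += 0.5 * abs(c)
        weights[j] += 0.5 * abs(c)
    return weights


def _link_networks(links: np.ndarray, link_index: LinkIndex,
                   partition: NetworkPartition) -> tuple[np.ndarray, np.ndarray]:
    if partition.n_rois != link_index.n_rois:
        raise ValueError(
            f"partition covers {partition.n_rois} ROIs but links refer to "
            f"{link_index.n_rois}"
        )
    labels = partition.label_array()
    pairs = link_index.pairs[np.asarray(links, dtype=int)]
    return labels[pairs[:, 0]], labels[pairs[:, 1]]


def network_indices(
    contributions: np.ndarray,
    signs: np.ndarray,
    links: np.ndarray,
    link_index: LinkIndex,
    partition: NetworkPartition,
    signed_sums: bool = False,
) -> pd.DataFrame:
    """Normalized intra- and inter-network association indices per sign group.

    intra(net) sums the |contribution| of links with both ends in net;
    inter(net) sums half the |contribution| of links with exactly one end in
    net; both are multiplied by N_max/N to correct for unequal network sizes.
    With ``signed_sums=True`` raw signed contributions are summed instead.
    """
    contributions = np.asarray(contributions, dtype=float)
    signs = np.asarray(signs, dtype=int)
    la, lb = _link_networks(links, link_index, partition)
    sizes = partition.network_sizes
    n_max = max(sizes.values())
    vals = contributions if signed_sums else np.abs(contributions)
    rows = []
    for group, gsign in (("negative", -1), ("positive", 1)):
        in_group = signs == gsign
        for net in partition.networks:
            intra = vals[in_group & (la == net) & (lb == net)].sum()
            inter = 0.5 * vals[in_group & ((la == net) ^ (lb == net))].sum()
            factor = n_max / sizes[net]
            rows.append({
                "network": net, "sign_group": group,
                "intra_index": intra * factor, "inter_index": inter * factor,
                "intra_index_raw": intra, "inter_index_raw": inter,
            })
    return pd.DataFrame(rows)


def pairwise_percentages(
    contributions: np.ndarray,
    signs: np.ndarray,
    links: np.ndarray,
    link_index: LinkIndex,
    partition: NetworkPartition,
) -> pd.DataFrame:
    """Share (%) of each network pair in the inter-network contribution sum,
    per sign group.  A sign group with no inter-network links yields no rows
    (logged)."""
    contributions = np.abs(np.asarray(contributions, dtype=float))
    signs = np.asarray(signs, dtype=int)
    la, lb = _link_networks(links, link_index, partition)
    nets = partition.networks
    rows = []
    for group, gsign in (("negative", -1), ("positive", 1)):
        inter = (signs == gsign) & (la != lb)
        total = contributions[inter].sum()
        if total == 0:
            logger.info("no inter-network links in the %s sign group", group)
            continue
        for a in range(len(nets)):
            for b in range(a + 1, len(nets)):
                na, nb = nets[a], nets[b]
                in_pair = inter & (((la == na) & (lb == nb)) | ((la == nb) & (lb == na)))
                rows.append({
                    "net_a": na, "net_b": nb, "sign_group": group,
                    "percent": 100.0 * contributions[in_pair].sum() / total,
                })
    return pd.DataFrame(rows, columns=["net_a", "net_b", "sign_group", "percent"])


def inter_network_share(
    links: np.ndarray,
    signs: np.ndarray,
    link_index: LinkIndex,
    partition: NetworkPartition,
) -> pd.DataFrame:
    """Fraction of consensus links that cross networks, per sign group.

    Percent is rounded to 2 decimals for reporting; counts are kept.  Empty
    sign groups are omitted (logged)."""
    signs = np.asarray(signs, dtype=int)
    la, lb = _link_networks(links, link_index, partition)
    rows = []
    for group, gsign in (("negative", -1), ("positive", 1)):
        in_group = signs == gsign
        n_total = int(in_group.sum())
        if n_total == 0:
            logger.info("no links in the %s sign group", group)
            continue
        n_inter = int((in_group & (la != lb)).sum())
        rows.append({
            "sign_group": group, "n_inter": n_inter, "n_total": n_total,
            "percent": round(100.0 * n_inter / n_total, 2),
        })
    return pd.DataFrame(rows, columns=["sign_group", "n_inter", "n_total", "percent"])


def contribution_report(
    result: CpmResult,
    features: FeatureTable,
    partition: NetworkPartition,
) -> ContributionReport:
    """Assemble the full link/region/network contribution decomposition."""
    links, signs = consensus_links(result)
    link_index = features.link_index
    if len(links):
        contribs = link_contribution(features.values, features.scores, result, links)
    else:
        contribs = np.empty(0)
    pairs = link_index.pairs
    link_rows = pd.DataFrame({
        "link": links,
        "roi_i": [partition.roi_ids[pairs[l][0]] for l in links],
        "roi_j": [partition.roi_ids[pairs[l][1]] for l in links],
        "net_i": [partition.labels[pairs[l][0]] for l in links],
        "net_j": [partition.labels[pairs[l][1]] for l in links],
        "sign": signs,
        "contribution": contribs,
    })
    degrees = region_degree(contribs, links, link_index) if len(links) else np.zeros(link_index.n_rois)
    region_rows = pd.DataFrame({
        "roi_id": partition.roi_ids,
        "network": partition.labels,
        "weight": degrees,
    })
    if partition.coordinates is not None:
        region_rows[["x", "y", "z"]] = np.asarray(partition.coordinates, dtype=float)
    if len(links):
        net_table = network_indices(contribs, signs, links, link_index, partition)
        pair_table = pairwise_percentages(contribs, signs, links, link_index, partition)
        share = inter_network_share(links, signs, link_index, partition)
    else:
        net_table = pd.DataFrame()
        pair_table = pd.DataFrame()
        share = pd.DataFrame()
    return ContributionReport(link_rows, region_rows, net_table, pair_table, share)
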