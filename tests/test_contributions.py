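"""Consensus links and link/region/network contribution decomposition."""

import numpy as np
import pandas as pd
import pytest

from dfcalff import (CpmConfig, LinkIndex, NetworkPartition, consensus_links,
                     inter_network_share, link_contribution, network_indices,
                     pairwise_percentages, region_degree)
from dfcalff.cpm import CpmResult, FoldRecord


def _result_from_selections(selections, signs_per_fold, n_subjects=None):
    n = n_subjects or len(selections)
    ids = [f"s{k}" for k in range(n)]
    folds = [
        FoldRecord(ids[k], 0.01, np.asarray(sel, dtype=int),
                   np.asarray(sg, dtype=int), 0.0, 0.5)
        for k, (sel, sg) in enumerate(zip(selections, signs_per_fold))
    ]
    return CpmResult(folds, np.zeros(n), 0.0, 1.0, ids, CpmConfig())


class TestConsensusLinks:
    def test_unanimous_link_included_missing_one_excluded(self):
        sels = [[1, 2, 5], [1, 2], [2, 1]]
        signs = [[1, -1, 1], [1, -1], [-1, 1]]
        links, sgn = consensus_links(_result_from_selections(sels, signs))
        assert list(links) == [1, 2]
        assert list(sgn) == [1, -1]

    def test_sign_flip_excluded(self):
        sels = [[3, 4], [3, 4]]
        signs = [[1, 1], [-1, 1]]
        links, sgn = consensus_links(_result_from_selections(sels, signs))
        assert list(links) == [4]

    def test_matches_bruteforce_intersection(self, rng):
        sels, sgns = [], []
        for _ in range(10):
            sel = np.sort(rng.choice(50, size=20, replace=False))
            sels.append(sel)
            sgns.append(np.where(sel % 3 == 0, -1, 1))
        links, _ = consensus_links(_result_from_selections(sels, sgns))
        expected = set(sels[0])
        for s in sels[1:]:
            expected &= set(s)
        assert set(links) == expected  # signs here depend only on the link


class TestLinkContribution:
    def test_perfect_feature_contributes_one(self, rng):
        n = 8
        y = rng.uniform(0, 10, n)
        X = rng.standard_normal((n, 3))
        X[:, 0] = y
        sels = [[0]] * n
        signs = [[1]] * n
        result = _result_from_selections(sels, signs)
        contrib = link_contribution(X, y, result, np.array([0]))
        assert contrib[0] == pytest.approx(1.0)

    def test_matches_explicit_per_fold_loop(self, rng):
        from scipy import stats

        n = 12
        y = rng.uniform(0, 10, n)
        X = rng.standard_normal((n, 3))
        result = _result_from_selections([[0, 1, 2]] * n, [[1, 1, 1]] * n)
        contrib = link_contribution(X, y, result, np.array([0, 1, 2]))
        for l in range(3):
            per_fold = []
            for h in range(n):
                keep = [k for k in range(n) if k != h]
                per_fold.append(stats.pearsonr(X[keep, l], y[keep]).statistic)
            assert contrib[l] == pytest.approx(np.mean(per_fold), abs=1e-12)


class TestRegionDegree:
    def test_single_link_splits_half_half(self):
        index = LinkIndex(4)
        link = index.link_of(0, 1)
        w = region_degree(np.array([-0.6]), np.array([link]), index)
        assert w[0] == pytest.approx(0.3) and w[1] == pytest.approx(0.3)
        assert w[2] == w[3] == 0.0

    def test_path_hand_computation(self):
        index = LinkIndex(3)
        links = np.array([index.link_of(0, 1), index.link_of(1, 2)])
        w = region_degree(np.array([0.4, -0.2]), links, index)
        np.testing.assert_allclose(w, [0.2, 0.3, 0.1])

    def test_matches_bruteforce_accumulation(self, rng):
        index = LinkIndex(8)
        links = rng.choice(index.n_links, size=10, replace=False)
        contribs = rng.standard_normal(10)
        w = region_degree(contribs, links, index)
        expected = np.zeros(8)
        for c, l in zip(contribs, links):
            i, j = index.pairs[l]
            expected[i] += 0.5 * abs(c)
            expected[j] += 0.5 * abs(c)
        np.testing.assert_allclose(w, expected, atol=1e-12)

    def test_degree_conservation(self, rng):
        index = LinkIndex(10)
        links = rng.choice(index.n_links, size=12, replace=False)
        contribs = rng.standard_normal(12)
        w = region_degree(contribs, links, index)
        assert w.sum() == pytest.approx(np.abs(contribs).sum(), abs=1e-12)


@pytest.fixture
def toy_partition():
    # 3 networks, sizes 4/3/2 over 9 ROIs
    return NetworkPartition(["A"] * 4 + ["B"] * 3 + ["C"] * 2)


class TestNetworkIndices:
    def test_intra_only_links_zero_inter(self, toy_partition):
        index = LinkIndex(9)
        links = np.array([index.link_of(0, 1), index.link_of(1, 2)])
        table = network_indices(np.array([-0.5, -0.3]), np.array([-1, -1]),
                                links, index, toy_partition)
        assert (table["inter_index"] == 0).all()

    def test_hand_computed_toy_table(self, toy_partition):
        index = LinkIndex(9)
        links = np.array([
            index.link_of(0, 1),  # intra A
            index.link_of(4, 5),  # intra B
            index.link_of(0, 4),  # A-B
            index.link_of(0, 7),  # A-C
            index.link_of(4, 7),  # B-C
            index.link_of(2, 3),  # intra A, positive
        ])
        contribs = np.array([-0.4, -0.2, -0.6, -0.1, -0.3, 0.5])
        signs = np.array([-1, -1, -1, -1, -1, 1])
        table = network_indices(contribs, signs, links, index, toy_partition)
        neg = table[table.sign_group == "negative"].set_index("network")
        # N_max = 4; factors: A->1, B->4/3, C->2
        assert neg.loc["A", "intra_index"] == pytest.approx(0.4 * 1.0)
        assert neg.loc["B", "intra_index"] == pytest.approx(0.2 * 4 / 3)
        assert neg.loc["A", "inter_index"] == pytest.approx(0.5 * (0.6 + 0.1) * 1.0)
        assert neg.loc["B", "inter_index"] == pytest.approx(0.5 * (0.6 + 0.3) * 4 / 3)
        assert neg.loc["C", "inter_index"] == pytest.approx(0.5 * (0.1 + 0.3) * 2.0)
        pos = table[table.sign_group == "positive"].set_index("network")
        assert pos.loc["A", "intra_index"] == pytest.approx(0.5)
        assert pos.loc["A", "inter_index"] == 0.0

    def test_allocation_conservation_pre_normalization(self, rng, toy_partition):
        index = LinkIndex(9)
        links = rng.choice(index.n_links, size=15, replace=False)
        contribs = rng.standard_normal(15)
        signs = np.where(contribs < 0, -1, 1)
        table = network_indices(contribs, signs, links, index, toy_partition)
        labels = toy_partition.label_array()
        pairs = index.pairs[links]
        inter_mask = labels[pairs[:, 0]] != labels[pairs[:, 1]]
        assert table["inter_index_raw"].sum() == pytest.approx(
            np.abs(contribs[inter_mask]).sum(), abs=1e-12
        )

    def test_max_size_network_unnormalized(self, toy_partition):
        index = LinkIndex(9)
        links = np.array([index.link_of(0, 1)])
        table = network_indices(np.array([-0.8]), np.array([-1]), links, index,
                                toy_partition)
        neg = table[table.sign_group == "negative"].set_index("network")
        assert neg.loc["A", "intra_index"] == neg.loc["A", "intra_index_raw"]


class TestPairwisePercentages:
    def test_single_pair_takes_all(self, toy_partition):
        index = LinkIndex(9)
        links = np.array([index.link_of(0, 4), index.link_of(1, 5)])
        table = pairwise_percentages(np.array([-0.3, -0.7]), np.array([-1, -1]),
                                     links, index, toy_partition)
        neg = table[table.sign_group == "negative"]
        ab = neg[(neg.net_a == "A") & (neg.net_b == "B")]["percent"].iloc[0]
        assert ab == pytest.approx(100.0)
        assert neg["percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_matches_bruteforce(self, rng, toy_partition):
        index = LinkIndex(9)
        links = rng.choice(index.n_links, size=14, replace=False)
        contribs = rng.standard_normal(14)
        signs = np.where(contribs < 0, -1, 1)
        table = pairwise_percentages(contribs, signs, links, index, toy_partition)
        labels = toy_partition.label_array()
        pairs = index.pairs[links]
        for _, row in table.iterrows():
            gsign = -1 if row.sign_group == "negative" else 1
            inter = (signs == gsign) & (labels[pairs[:, 0]] != labels[pairs[:, 1]])
            in_pair = inter & (
                ((labels[pairs[:, 0]] == row.net_a) & (labels[pairs[:, 1]] == row.net_b))
                | ((labels[pairs[:, 0]] == row.net_b) & (labels[pairs[:, 1]] == row.net_a))
            )
            expected = 100 * np.abs(contribs[in_pair]).sum() / np.abs(contribs[inter]).sum()
            assert row.percent == pytest.approx(expected, abs=1e-12)
        for group in ("negative", "positive"):
            sub = table[table.sign_group == group]
            if len(sub):
                assert sub.percent.sum() == pytest.approx(100.0, abs=1e-9)


class TestInterNetworkShare:
    def test_reported_share_arithmetic(self, toy_partition):
        """54 of 66 inter-network links -> 81.82%; 31 of 37 -> 83.78%."""
        index = LinkIndex(9)
        intra = index.link_of(0, 1)
        inter = index.link_of(0, 4)
        links = np.array([inter] * 54 + [intra] * 12 + [inter] * 31 + [intra] * 6)
        signs = np.array([-1] * 66 + [1] * 37)
        table = inter_network_share(links, signs, index, toy_partition)
        neg = table[table.sign_group == "negative"].iloc[0]
        pos = table[table.sign_group == "positive"].iloc[0]
        assert (neg.n_inter, neg.n_total, neg.percent) == (54, 66, 81.82)
        assert (pos.n_inter, pos.n_total, pos.percent) == (31, 37, 83.78)

    def test_all_intra_gives_zero_percent(self, toy_partition):
        index = LinkIndex(9)
        links = np.array([index.link_of(0, 1), index.link_of(4, 5)])
        table = inter_network_share(links, np.array([-1, -1]), index, toy_partition)
        assert table.iloc[0].percent == 0.0

    def test_empty_sign_group_omitted(self, toy_partition):
        index = LinkIndex(9)
        links = np.array([index.link_of(0, 4)])
        table = inter_network_share(links, np.array([-1]), index, toy_partition)
        assert list(table.sign_group) == ["negative"]


class TestPlantedRecovery:
    def test_consensus_recovers_planted_links_with_signs(
            self, effect_cpm_result, effect_features, planted_links,
            six_net_partition):
        """On the strong-effect cohort at least half the planted links are
        consensus links with negative contributions."""
        links, signs = consensus_links(effect_cpm_result)
        recovered = [l for l in planted_links if l in set(links)]
        assert len(recovered) >= 5
        contrib = link_contribution(
            effect_features.values, effect_features.scores, effect_cpm_result,
            np.asarray(links),
        )
        by_link = dict(zip(links, contrib))
        sign_of = dict(zip(links, signs))
        for l in recovered:
            assert sign_of[l] == -1
            assert by_link[l] < 0
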