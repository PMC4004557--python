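"""Wavelet texture features, watershed over-segmentation, RSG and clustering."""

import itertools

import numpy as np
import networkx as nx
import pytest

import retseg
from retseg.io import FovMask, GrayImage
from retseg.segment import _clip_to_fov
from retseg.texture import (
    build_rsg,
    merge_to_two,
    partition_texture,
    spectral_partition,
    texture_gradient,
    watershed_oversegment,
    wavelet_features,
)


def brute_force_min_ncut(G):
    """Exhaustive minimum normalized cut over all 2-partitions."""
    nodes = sorted(G.nodes)
    best, best_parts = np.inf, None
    for r in range(1, len(nodes) // 2 + 1):
        for side in itertools.combinations(nodes, r):
            a, b = set(side), set(nodes) - set(side)
            cut = sum(
                d["weight"] for u, v, d in G.edges(data=True)
                if (u in a) != (v in a)
            )
            vol_a = sum(d["weight"] for u, v, d in G.edges(data=True) if u in a or v in a)
            vol_b = sum(d["weight"] for u, v, d in G.edges(data=True) if u in b or v in b)
            score = cut / vol_a + cut / vol_b
            if score < best:
                best, best_parts = score, (a, b)
    return best_parts


def two_clique_graph():
    g = nx.Graph()
    for off in (0, 5):
        for i in range(5):
            for j in range(i + 1, 5):
                g.add_edge(i + off + 1, j + off + 1, weight=1.0)
    g.add_edge(1, 6, weight=0.01)
    return g


class TestWaveletFeatures:
    def test_constant_image_no_energy(self):
        feats = wavelet_features(GrayImage(np.full((64, 64), 0.4)), energy_smooth=0)
        for sb in feats.subbands:
            assert np.abs(sb).max() < 1e-8

    def test_subband_shapes_match_input(self):
        feats = wavelet_features(GrayImage(np.zeros((50, 70))))
        assert len(feats.subbands) == 3 * feats.levels
        for sb in feats.subbands:
            assert sb.shape == (50, 70)

    def test_fine_vs_coarse_energy_split(self):
        rng = np.random.default_rng(2)
        yy, xx = np.mgrid[0:64, 0:128]
        img = np.zeros((64, 128))
        img[:, :64] = (yy[:, :64] + xx[:, :64]) % 2  # period-2 checkerboard
        img[:, 64:] = (np.sin(yy[:, 64:] / 8.0) * np.sin(xx[:, 64:] / 8.0) > 0)
        feats = wavelet_features(GrayImage(img), energy_smooth=0)
        fine = sum(feats.subbands[:3])  # level 1 (highest frequency)
        coarse = sum(feats.subbands[-3:])  # coarsest level
        assert fine[:, :64].mean() > fine[:, 64:].mean()
        assert coarse[:, 64:].mean() > coarse[:, :64].mean()

    def test_levels_validation(self):
        with pytest.raises(ValueError):
            wavelet_features(GrayImage(np.zeros((64, 64))), levels=7)
        with pytest.raises(ValueError):
            wavelet_features(GrayImage(np.zeros((4, 4))), levels=3)


class TestWatershed:
    def test_constant_gradient_single_region(self):
        reg = watershed_oversegment(GrayImage(np.full((32, 32), 0.5)), h=0.05)
        assert reg.n_regions == 1

    def test_two_basins_two_regions(self):
        yy, xx = np.mgrid[0:64, 0:64]
        g = (1.0
             - 0.5 * np.exp(-((yy - 20) ** 2 + (xx - 20) ** 2) / 60.0)
             - 0.5 * np.exp(-((yy - 44) ** 2 + (xx - 44) ** 2) / 60.0))
        reg = watershed_oversegment(GrayImage(g / g.max()), h=0.05, presmooth_radius=0)
        assert reg.n_regions == 2

    def test_region_count_monotone_in_h(self, two_texture_phantom):
        _, img, truth = two_texture_phantom
        pre = _clip_to_fov(
            retseg.tophat_preprocess(retseg.extract_green(img), 30), truth.fov
        )
        grad = texture_gradient(wavelet_features(pre))
        counts = [
            watershed_oversegment(grad, h=h, fov=truth.fov).n_regions
            for h in (0.02, 0.05, 0.1, 0.3)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_offset_invariance(self):
        rng = np.random.default_rng(3)
        g = rng.random((48, 48)) * 0.5
        a = watershed_oversegment(GrayImage(g), h=0.05, presmooth_radius=0)
        b = watershed_oversegment(GrayImage(g + 0.3), h=0.05, presmooth_radius=0)
        assert a.n_regions == b.n_regions

    def test_labels_tile_fov(self, two_texture_phantom):
        _, img, truth = two_texture_phantom
        pre = _clip_to_fov(
            retseg.tophat_preprocess(retseg.extract_green(img), 30), truth.fov
        )
        grad = texture_gradient(wavelet_features(pre))
        reg = watershed_oversegment(grad, fov=truth.fov)
        assert ((reg.labels > 0) == truth.fov.pixels).all()


class TestRegionGraph:
    def _simple_regions(self):
        from retseg.texture import RegionLabelImage

        labels = np.zeros((16, 16), dtype=np.int32)
        labels[:, :8], labels[:, 8:] = 1, 2
        return RegionLabelImage(labels=labels, n_regions=2)

    def test_identical_texture_weight_one(self):
        reg = self._simple_regions()
        img = GrayImage(np.full((16, 16), 0.5))
        feats = wavelet_features(img, levels=2, energy_smooth=0)
        g = build_rsg(reg, feats, img)
        assert g.number_of_edges() == 1
        assert g[1][2]["weight"] == pytest.approx(1.0, abs=1e-9)

    def test_single_region_no_edges(self):
        from retseg.texture import RegionLabelImage

        labels = np.ones((16, 16), dtype=np.int32)
        reg = RegionLabelImage(labels=labels, n_regions=1)
        img = GrayImage(np.zeros((16, 16)))
        g = build_rsg(reg, wavelet_features(img, levels=2), img)
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_weights_symmetric_on_phantom_regions(self, two_texture_phantom):
        _, img, truth = two_texture_phantom
        pre = _clip_to_fov(
            retseg.tophat_preprocess(retseg.extract_green(img), 30), truth.fov
        )
        feats = wavelet_features(pre)
        reg = watershed_oversegment(texture_gradient(feats), fov=truth.fov)
        g = build_rsg(reg, feats, pre)
        for u, v, d in g.edges(data=True):
            assert g[u][v]["weight"] == g[v][u]["weight"]
            assert 0.0 < d["weight"] <= 1.0


class TestSpectralPartition:
    def test_k_one_single_cluster(self):
        g = two_clique_graph()
        assign = spectral_partition(g, k=1)
        assert len(set(assign.values())) == 1

    def test_two_cliques_recovered_exactly(self):
        g = two_clique_graph()
        assign = spectral_partition(g, k=2, seed=0)
        got = frozenset(
            frozenset(n for n, c in assign.items() if c == cid)
            for cid in set(assign.values())
        )
        a, b = brute_force_min_ncut(g)
        assert got == frozenset({frozenset(a), frozenset(b)})

    def test_node_permutation_invariance(self):
        g = two_clique_graph()
        rng = np.random.default_rng(3)
        perm = dict(zip(sorted(g.nodes), rng.permutation(sorted(g.nodes))))
        h = nx.relabel_nodes(g, perm)
        a = spectral_partition(g, k=2, seed=0)
        b = spectral_partition(h, k=2, seed=0)
        groups_a = frozenset(
            frozenset(perm[n] for n, c in a.items() if c == cid)
            for cid in set(a.values())
        )
        groups_b = frozenset(
            frozenset(n for n, c in b.items() if c == cid)
            for cid in set(b.values())
        )
        assert groups_a == groups_b

    def test_disconnected_graph_per_component(self):
        g = nx.Graph()
        g.add_edge(1, 2, weight=1.0)
        g.add_edge(3, 4, weight=1.0)
        assign = spectral_partition(g, k=2, seed=0)
        assert assign[1] == assign[2] and assign[3] == assign[4]
        assert assign[1] != assign[3]


class TestMergeToTwo:
    def test_single_cluster_warns(self, caplog, two_texture_phantom):
        _, img, truth = two_texture_phantom
        pre = _clip_to_fov(
            retseg.tophat_preprocess(retseg.extract_green(img), 30), truth.fov
        )
        feats = wavelet_features(pre)
        reg = watershed_oversegment(texture_gradient(feats), fov=truth.fov)
        clusters = {rid: 0 for rid in range(1, reg.n_regions + 1)}
        with caplog.at_level("WARNING"):
            part = merge_to_two(clusters, reg, pre)
        labels_in = set(np.unique(part.labels[truth.fov.pixels]))
        assert labels_in == {1}

    def test_two_texture_phantom_agreement(self, two_texture_phantom):
        _, img, truth = two_texture_phantom
        pre = _clip_to_fov(
            retseg.tophat_preprocess(retseg.extract_green(img), 30), truth.fov
        )
        part = partition_texture(pre, truth.fov, seed=0)
        pt, fovp = truth.partition_truth.labels, truth.fov.pixels
        direct = ((part.labels == pt) & fovp).sum()
        swapped = ((part.labels == (3 - pt)) & fovp & (pt > 0)).sum()
        assert max(direct, swapped) / fovp.sum() >= 0.85

    def test_override_forces_label(self, two_texture_phantom):
        _, img, truth = two_texture_phantom
        pre = _clip_to_fov(
            retseg.tophat_preprocess(retseg.extract_green(img), 30), truth.fov
        )
        feats = wavelet_features(pre)
        reg = watershed_oversegment(texture_gradient(feats), fov=truth.fov)
        g = build_rsg(reg, feats, pre)
        clusters = spectral_partition(g, k=min(4, reg.n_regions), seed=0)
        part = merge_to_two(
            clusters, reg, pre, override={c: 2 for c in set(clusters.values())}
        )
        assert set(np.unique(part.labels[truth.fov.pixels])) == {2}

    def test_composition_tiles_fov_with_two_labels(self, two_texture_phantom):
        _, img, truth = two_texture_phantom
        pre = _clip_to_fov(
            retseg.tophat_preprocess(retseg.extract_green(img), 30), truth.fov
        )
        part = partition_texture(pre, truth.fov, seed=0)
        assert ((part.labels > 0) == truth.fov.pixels).all()
        assert set(np.unique(part.labels[truth.fov.pixels])) <= {1, 2}
        assert part.connectivity_threshold[1] < part.connectivity_threshold[2]
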