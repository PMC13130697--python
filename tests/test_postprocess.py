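"""Connected-component analysis and the size filter."""

import numpy as np
import pytest

from ccband import (
    AdjacencyGraph,
    PostprocessConfig,
    SuperpixelMap,
    apply_postprocessing,
    components_to_mask,
    disease_components,
    size_filter,
)


def random_graph(rng, n_nodes, p_edge=0.08):
    edges = set()
    for a in range(n_nodes):
        for b in range(a + 1, n_nodes):
            if rng.random() < p_edge:
                edges.add((a, b))
    return AdjacencyGraph(n_nodes, frozenset(edges))


def bfs_components(nodes, edges):
    """Brute-force BFS oracle over the induced subgraph."""
    nodes = set(nodes)
    adj = {n: set() for n in nodes}
    for a, b in edges:
        if a in nodes and b in nodes:
            adj[a].add(b)
            adj[b].add(a)
    seen, comps = set(), []
    for start in sorted(nodes):
        if start in seen:
            continue
        queue, comp = [start], set()
        while queue:
            cur = queue.pop()
            if cur in comp:
                continue
            comp.add(cur)
            queue.extend(adj[cur] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return comps


class TestDiseaseComponents:
    def test_no_disease_gives_empty_partition(self, rng):
        graph = random_graph(rng, 20)
        assert disease_components(np.zeros(20, dtype=int), graph) == []

    def test_all_disease_on_connected_graph_is_one_component(self):
        edges = frozenset((i, i + 1) for i in range(9))
        graph = AdjacencyGraph(10, edges)
        comps = disease_components(np.ones(10, dtype=int), graph)
        assert len(comps) == 1 and len(comps[0]) == 10

    def test_matches_bfs_oracle_on_random_graphs(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 101))
            graph = random_graph(rng, n)
            pred = (rng.random(n) < 0.4).astype(int)
            comps = disease_components(pred, graph)
            oracle = bfs_components(np.where(pred == 1)[0].tolist(), graph.edges)
            assert sorted(comps, key=min) == sorted(oracle, key=min)

    def test_prediction_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            disease_components(np.ones(5, dtype=int), random_graph(rng, 6))


class TestSizeFilter:
    def test_nine_removed_ten_kept(self):
        comps = [frozenset(range(9)), frozenset(range(100, 110))]
        kept = size_filter(comps, PostprocessConfig(min_component_superpixels=10))
        assert kept == [frozenset(range(100, 110))]

    def test_mixed_sizes(self):
        comps = [
            frozenset(range(12)),
            frozenset(range(20, 23)),
            frozenset([99]),
        ]
        kept = size_filter(comps, PostprocessConfig())
        assert kept == [frozenset(range(12))]

    def test_min_size_one_is_identity(self):
        comps = [frozenset([1]), frozenset([2, 3])]
        assert size_filter(comps, PostprocessConfig(min_component_superpixels=1)) == comps

    def test_no_small_component_survives_reanalysis(self, rng):
        # post-filter output re-analysed: every surviving component >= 10
        for _ in range(100):
            n = int(rng.integers(10, 101))
            graph = random_graph(rng, n)
            pred = (rng.random(n) < 0.5).astype(int)
            surviving = size_filter(
                disease_components(pred, graph), PostprocessConfig()
            )
            survivors = set().union(*surviving) if surviving else set()
            re_pred = np.zeros(n, dtype=int)
            for s in survivors:
                re_pred[s] = 1
            for comp in disease_components(re_pred, graph):
                assert len(comp) >= 10

    def test_monotone_in_min_size(self, rng):
        graph = random_graph(rng, 60)
        pred = (rng.random(60) < 0.5).astype(int)
        comps = disease_components(pred, graph)
        previous = None
        for m in (1, 5, 10, 20):
            kept = size_filter(comps, PostprocessConfig(min_component_superpixels=m))
            pixels = set().union(*kept) if kept else set()
            if previous is not None:
                assert pixels <= previous
            previous = pixels


class TestComponentsToMask:
    def quadrants(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[:4, 4:] = 1
        labels[4:, :4] = 2
        labels[4:, 4:] = 3
        return SuperpixelMap(labels)

    def test_empty_survivors_empty_mask(self):
        mask = components_to_mask([], self.quadrants())
        assert mask.is_empty

    def test_pixel_count_conservation(self):
        spmap = self.quadrants()
        mask = components_to_mask([frozenset([0, 3])], spmap)
        assert mask.pixels.sum() == spmap.counts[0] + spmap.counts[3]

    def test_roundtrip_majority_recovers_surviving_set(self):
        spmap = self.quadrants()
        surviving = [frozenset([1, 2])]
        mask = components_to_mask(surviving, spmap)
        recovered = {
            sp
            for sp in range(spmap.n_superpixels)
            if mask.pixels[spmap.labels == sp].mean() > 0.5
        }
        assert recovered == {1, 2}

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            components_to_mask([frozenset([9])], self.quadrants())


class TestApplyPostprocessing:
    def test_filtered_prediction_consistent_with_mask(self, rng):
        labels = np.repeat(np.arange(16), 4)[:, None].repeat(8, axis=1)
        spmap = SuperpixelMap(labels.astype(int))
        edges = frozenset((i, i + 1) for i in range(15))
        graph = AdjacencyGraph(16, edges)
        pred = np.zeros(16, dtype=int)
        pred[2:13] = 1  # chain of 11 -> survives
        pred[15] = 1  # isolated -> removed
        result = apply_postprocessing(pred, spmap, graph, PostprocessConfig())
        assert result.filtered_prediction.sum() == 11
        assert result.mask.pixels.sum() == 11 * 32
        assert [len(c) for c in result.surviving] == [11]
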