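"""Graph construction, normalized-cut trees, widgets and refinement."""

import itertools

import networkx as nx
import numpy as np
import pytest

import histoseg as hs
from histoseg import transfer
from histoseg.volume_io import BACKGROUND, GM, VESSEL, DURA


def hist_from_counts(counts):
    """A Histogram2D with prescribed counts on integer-unit bins.

    The voxel map is a placeholder; these histograms exercise the graph and
    tree machinery, which depends only on the bin grid.
    """
    counts = np.asarray(counts, dtype=np.int64)
    nx_b, ny_b = counts.shape
    return hs.Histogram2D(
        edges_x=np.arange(nx_b + 1, dtype=float),
        edges_y=np.arange(ny_b + 1, dtype=float),
        counts=counts,
        voxel_bin=np.full((1, 1, 1, 2), -1, dtype=np.int64),
        voxel_size=np.ones(3), affine=np.eye(4))


def exhaustive_min_ncut(W):
    """Brute-force minimum Ncut over all 2-partitions of a small graph."""
    n = W.shape[0]
    d = W.sum(axis=1)
    total = d.sum()
    best = np.inf
    for bits in range(1, 2 ** (n - 1)):
        a = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        cut = W[np.ix_(a, ~a)].sum()
        assoc_a, assoc_b = d[a].sum(), d[~a].sum()
        if assoc_a == 0 or assoc_b == 0:
            continue
        best = min(best, cut / assoc_a + cut / assoc_b)
    return best


def random_connected_graph(rng, n):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    order = rng.permutation(n)
    for i in range(1, n):  # random spanning tree
        j = order[rng.integers(0, i)]
        g.add_edge(int(order[i]), int(j), weight=float(rng.uniform(0.1, 1.0)))
    extra = rng.integers(0, n)
    for _ in range(extra):
        u, v = rng.integers(0, n, 2)
        if u != v:
            g.add_edge(int(u), int(v), weight=float(rng.uniform(0.1, 1.0)))
    return g


class TestBinGraph:
    def test_two_equal_bins_weight_one(self):
        h = hist_from_counts([[5, 5], [0, 0]])
        g = hs.build_bin_graph(h)
        assert g.number_of_edges() == 1
        (_, _, w), = g.edges(data="weight")
        assert w == pytest.approx(1.0)

    def test_extreme_count_contrast_decays(self):
        h = hist_from_counts([[1, 60000], [0, 0]])
        g = hs.build_bin_graph(h, sigma_w=0.1)
        (_, _, w), = g.edges(data="weight")
        assert w < np.exp(-10)

    def test_3x3_full_grid_has_20_edges(self):
        h = hist_from_counts(np.full((3, 3), 4))
        g = hs.build_bin_graph(h)
        assert g.number_of_nodes() == 9
        assert g.number_of_edges() == 20

    def test_islands_are_bridged(self):
        counts = np.zeros((6, 6), dtype=int)
        counts[0, 0] = 5
        counts[5, 5] = 7
        counts[5, 4] = 7
        g = hs.build_bin_graph(hist_from_counts(counts))
        assert nx.is_connected(g)

    def test_single_bin_rejected(self):
        h = hist_from_counts([[3, 0], [0, 0]])
        with pytest.raises(ValueError, match="2 nonzero"):
            hs.build_bin_graph(h)


class TestNcutTree:
    def test_root_is_single_cluster(self):
        h = hist_from_counts(np.full((3, 3), 4))
        tree = hs.normalized_cut_tree(hs.build_bin_graph(h), max_depth=2)
        level0 = tree.levels[0]
        assert set(np.unique(level0)) == {0}

    def test_two_cliques_split_first(self):
        g = nx.Graph(bin_shape=(8, 1))
        for block in (range(4), range(4, 8)):
            for u, v in itertools.combinations(block, 2):
                g.add_edge(u, v, weight=1.0)
        g.add_edge(0, 4, weight=0.01)
        tree = hs.normalized_cut_tree(g, max_depth=1)
        kids = tree.root.children
        sides = {frozenset(tree.nodes[k].bins.tolist()) for k in kids}
        assert sides == {frozenset(range(4)), frozenset(range(4, 8))}
        # the achieved value matches the exhaustive optimum
        W = nx.to_numpy_array(g, nodelist=range(8), weight="weight")
        assert tree.root.ncut_value == pytest.approx(exhaustive_min_ncut(W), abs=1e-9)

    def test_first_split_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(5, 13))
            g = random_connected_graph(rng, n)
            g.graph["bin_shape"] = (n, 1)
            tree = hs.normalized_cut_tree(g, max_depth=1)
            W = nx.to_numpy_array(g, nodelist=range(n), weight="weight")
            assert tree.root.ncut_value == pytest.approx(
                exhaustive_min_ncut(W), abs=1e-9)

    def test_levels_are_mece_and_refining(self, rng):
        counts = rng.integers(0, 50, size=(12, 12))
        h = hist_from_counts(counts)
        tree = hs.normalized_cut_tree(hs.build_bin_graph(h), max_depth=4)
        nzero = (h.counts > 0)
        prev = None
        for level in tree.levels:
            assert np.all((level >= 0) == nzero)  # MECE over nonzero bins
            if prev is not None:
                # refinement: every deeper cluster lies inside one parent
                parent_of = {}
                for idx in np.argwhere(nzero):
                    parent_of.setdefault(level[tuple(idx)],
                                         set()).add(prev[tuple(idx)])
                assert all(len(v) == 1 for v in parent_of.values())
            prev = level

    def test_depth_capped_at_8(self):
        h = hist_from_counts(np.full((3, 3), 4))
        with pytest.raises(ValueError, match="max_depth"):
            hs.normalized_cut_tree(hs.build_bin_graph(h), max_depth=9)

    def test_determinism(self, rng):
        counts = rng.integers(0, 30, size=(10, 10))
        h = hist_from_counts(counts)
        t1 = hs.normalized_cut_tree(hs.build_bin_graph(h), max_depth=4)
        t2 = hs.normalized_cut_tree(hs.build_bin_graph(h), max_depth=4)
        assert sorted(t1.nodes) == sorted(t2.nodes)
        for nid in t1.nodes:
            np.testing.assert_array_equal(t1.nodes[nid].bins, t2.nodes[nid].bins)

    def test_disconnected_graph_rejected(self):
        g = nx.Graph(bin_shape=(4, 1))
        g.add_edge(0, 1, weight=1.0)
        g.add_edge(2, 3, weight=1.0)
        with pytest.raises(ValueError, match="connected"):
            hs.normalized_cut_tree(g)


class TestSelectNodes:
    @pytest.fixture()
    def tree(self, rng):
        h = hist_from_counts(rng.integers(1, 30, size=(6, 6)))
        return hs.normalized_cut_tree(hs.build_bin_graph(h), max_depth=3)

    def test_root_selects_all(self, tree):
        tf = hs.select_nodes(tree, ["0"])
        assert tf.bin_mask.sum() == len(tree.root.bins)

    def test_sibling_union_equals_root(self, tree):
        kids = tree.root.children
        if kids is None:
            pytest.skip("degenerate tree")
        tf = hs.select_nodes(tree, list(kids))
        np.testing.assert_array_equal(tf.bin_mask,
                                      hs.select_nodes(tree, ["0"]).bin_mask)

    def test_leaf_mask_size(self, tree):
        leaf = next(n for n in tree.nodes.values() if n.children is None)
        tf = hs.select_nodes(tree, [leaf.node_id])
        assert tf.bin_mask.sum() == len(leaf.bins)

    def test_unknown_id_lists_known(self, tree):
        with pytest.raises(KeyError, match="known ids"):
            hs.select_nodes(tree, ["9.9"])


class TestSector:
    @pytest.fixture()
    def hist(self):
        return hist_from_counts(np.full((4, 4), 2))

    def test_zero_radius_empty(self, hist):
        w = hs.SectorWidget(center=(2, 2), radius=0.0)
        assert hs.sector_transfer(hist, w).bin_mask.sum() == 0

    def test_full_circle_covers_all(self, hist):
        w = hs.SectorWidget(center=(2, 2), radius=100.0)
        assert hs.sector_transfer(hist, w).bin_mask.all()

    def test_quarter_sector_geometric_oracle(self, hist):
        w = hs.SectorWidget(center=(0.0, 0.0), radius=100.0,
                            theta_min=0.0, theta_max=90.0)
        tf = hs.sector_transfer(hist, w)
        cx, cy = np.meshgrid(hist.centers_x(), hist.centers_y(), indexing="ij")
        ang = np.degrees(np.arctan2(cy, cx))
        expect = (ang >= 0) & (ang <= 90)
        np.testing.assert_array_equal(tf.bin_mask, expect)

    def test_reflex_sweep_rejected_beyond_360(self):
        with pytest.raises(ValueError, match="sweep"):
            hs.SectorWidget(center=(0, 0), radius=1, theta_min=0, theta_max=400)


class TestRefinement:
    def test_select_all_keeps_input(self, small_clean_phantom, rng):
        _, stack, truth, mask = small_clean_phantom
        ratio = hs.ratio_image(stack.contrasts[0], stack.contrasts[1])
        h = hs.build_histogram(ratio, ratio, mask, clip_percentiles=(0, 100))
        tf = transfer.TransferFunction(np.ones(h.nbins, dtype=bool))
        out = hs.refine_segmentation(truth, tf, h)
        np.testing.assert_array_equal(out.labels, truth.labels)

    def test_select_none_removes_all_gm(self, small_clean_phantom):
        _, stack, truth, mask = small_clean_phantom
        ratio = hs.ratio_image(stack.contrasts[0], stack.contrasts[1])
        h = hs.build_histogram(ratio, ratio, mask, clip_percentiles=(0, 100))
        tf = transfer.TransferFunction(np.zeros(h.nbins, dtype=bool))
        out = hs.refine_segmentation(truth, tf, h)
        assert (out.labels == GM).sum() == 0
        # non-GM labels untouched
        keep = truth.labels != GM
        np.testing.assert_array_equal(out.labels[keep], truth.labels[keep])

    def test_never_adds_gm_and_monotone(self, small_clean_phantom, rng):
        _, stack, truth, mask = small_clean_phantom
        ratio = hs.ratio_image(stack.contrasts[0], stack.contrasts[1])
        h = hs.build_histogram(ratio, ratio, mask, clip_percentiles=(0, 100))
        small = rng.random(h.nbins) > 0.6
        big = small | (rng.random(h.nbins) > 0.6)
        out_small = hs.refine_segmentation(truth, transfer.TransferFunction(small), h)
        out_big = hs.refine_segmentation(truth, transfer.TransferFunction(big), h)
        assert (out_small.labels == GM).sum() <= (truth.labels == GM).sum()
        # superset transfer function removes a subset of voxels
        assert np.all((out_small.labels == GM) <= (out_big.labels == GM))


class TestAutoBrainSelect:
    def test_vessel_arc_excluded_on_phantom(self, small_clean_phantom):
        from scipy import ndimage
        _, stack, truth, mask = small_clean_phantom
        ratio = hs.ratio_image(stack.contrasts[0], stack.contrasts[1])
        res = hs.gramag_refine(ratio, hs.corrupt_segmentation(truth, [VESSEL, DURA]),
                               mask, smooth_iterations=0)
        sel = hs.bins_to_voxels(res.histogram, res.tf.bin_mask).labels.astype(bool)
        vd = (truth.labels == VESSEL) | (truth.labels == DURA)
        assert (sel & vd).sum() / vd.sum() < 0.2
        gm_interior = ndimage.binary_erosion(truth.labels == GM)
        assert (sel & gm_interior).sum() / gm_interior.sum() > 0.9

    def test_determinism(self, small_clean_phantom):
        _, stack, truth, mask = small_clean_phantom
        ratio = hs.ratio_image(stack.contrasts[0], stack.contrasts[1])
        r1 = hs.gramag_refine(ratio, truth, mask, smooth_iterations=0)
        r2 = hs.gramag_refine(ratio, truth, mask, smooth_iterations=0)
        np.testing.assert_array_equal(r1.tf.bin_mask, r2.tf.bin_mask)
        assert r1.tf.provenance == r2.tf.provenance


class TestPersistence:
    def test_tree_json_round_trip(self, rng, tmp_path):
        h = hist_from_counts(rng.integers(1, 20, size=(5, 5)))
        tree = hs.normalized_cut_tree(hs.build_bin_graph(h), max_depth=3)
        p = tmp_path / "tree.json"
        hs.save_tree(tree, p)
        back = hs.load_tree(p)
        assert sorted(back.nodes) == sorted(tree.nodes)
        for nid in tree.nodes:
            np.testing.assert_array_equal(back.nodes[nid].bins, tree.nodes[nid].bins)
            assert back.nodes[nid].children == tree.nodes[nid].children

    def test_transfer_round_trip(self, rng, tmp_path):
        tf = transfer.TransferFunction(rng.random((6, 6)) > 0.5, provenance="x")
        p = tmp_path / "tf.npz"
        hs.save_transfer(tf, p)
        back = hs.load_transfer(p)
        np.testing.assert_array_equal(back.bin_mask, tf.bin_mask)
        assert back.provenance == "x"
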