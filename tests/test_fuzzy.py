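"""Alpha-cut geometry: tree construction, pruned search, MC estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import inspire as ip
from inspire import _kernels
from inspire.fuzzy import RectNode, split_rect, tree_array_length, _corner_cell


def walk_nodes(tree, mem):
    """Yield (node index, rectangle) over the build subdivision."""
    stack = [(1, RectNode(np.zeros(mem.ndim, np.int64), np.array(mem.shape)))]
    while stack:
        i, node = stack.pop()
        yield i, node
        if not node.is_leaf:
            left, right, _ = split_rect(node, tree.spacing)
            stack.append((2 * i, left))
            stack.append((2 * i + 1, right))


class TestAlphaTree:
    def test_constant_image_all_nodes_constant(self):
        img = ip.FuzzyImage(np.full((4, 4), 0.4))
        tree = ip.build_alpha_tree(img)
        for i, node in walk_nodes(tree, img.memberships):
            assert tree.values[i] == pytest.approx(0.4)

    def test_root_is_global_max(self, random_image):
        tree = ip.build_alpha_tree(random_image)
        assert tree.root_value == random_image.memberships.max()

    def test_every_node_is_brute_force_max(self, random_image):
        mem = random_image.memberships
        tree = ip.build_alpha_tree(random_image)
        for i, node in walk_nodes(tree, mem):
            sl = tuple(slice(y, y + r) for y, r in zip(node.y, node.R))
            assert tree.values[i] == mem[sl].max()

    def test_complement_tree(self, random_image):
        tree = ip.build_alpha_tree(random_image, complement=True)
        assert tree.root_value == pytest.approx(1.0 - random_image.memberships.min())

    def test_array_length_bound(self, rng):
        for shape in [(8, 8), (7, 9), (5, 3, 4)]:
            img = ip.FuzzyImage(rng.random(shape))
            tree = ip.build_alpha_tree(img)
            assert len(tree.values) == tree_array_length(shape)
            max_i = max(i for i, _ in walk_nodes(tree, img.memberships))
            assert max_i < len(tree.values)


class TestSplitRect:
    def test_even_split(self):
        left, right, k = split_rect(RectNode((0, 0), (4, 2)), (1, 1))
        assert k == 0
        assert tuple(left.R) == (2, 2) and tuple(right.R) == (2, 2)
        assert tuple(right.y) == (2, 0)

    def test_spacing_weighted_axis(self):
        # s*(R-1) = (2, 4) -> split along dimension 1
        _, _, k = split_rect(RectNode((0, 0), (3, 3)), (1, 2))
        assert k == 1

    def test_tie_breaks_to_lowest_axis(self):
        _, _, k = split_rect(RectNode((0, 0), (2, 2)), (1, 1))
        assert k == 0

    def test_split_partitions_exactly(self):
        node = RectNode((1, 2), (5, 3))
        left, right, k = split_rect(node, (1, 1))
        assert left.R[k] + right.R[k] == node.R[k]
        assert right.y[k] == left.y[k] + left.R[k]
        assert left.R[k] == 3  # ceil(5/2)

    def test_leaf_split_is_error(self):
        with pytest.raises(ValueError):
            split_rect(RectNode((0, 0), (1, 1)), (1, 1))


class TestBounds:
    def test_inside_rectangle_is_zero(self):
        assert ip.rect_lower_bound((1.5, 0.5), RectNode((0, 0), (3, 3)), (1, 1)) == 0.0

    def test_corner_distance(self):
        b = ip.rect_lower_bound((5.0, 5.0), RectNode((0, 0), (3, 3)), (1, 1))
        assert b == pytest.approx(np.sqrt(18.0))

    def test_one_spel_outside(self):
        assert ip.rect_lower_bound((-2.0, 0.0), RectNode((0, 0), (3, 3)), (2, 1)) == 2.0

    def test_bound_never_exceeds_true_distance(self, rng):
        node = RectNode((2, 1), (3, 4))
        s = np.array([1.0, 1.5])
        spels = np.array(
            [[y0, y1] for y0 in range(2, 5) for y1 in range(1, 5)], dtype=float
        ) * s
        for _ in range(50):
            p = rng.uniform(-3, 10, 2)
            b = ip.rect_lower_bound(p, node, s)
            assert b <= np.linalg.norm(spels - p, axis=1).min() + 1e-12

    def test_relaxed_identity_at_beta_one(self, rng):
        node = RectNode((0, 0), (4, 4))
        for _ in range(20):
            p = rng.uniform(-5, 10, 2)
            assert ip.relaxed_lower_bound(p, node, (1, 1), d_t=3.0, beta=1.0) == (
                ip.rect_lower_bound(p, node, (1, 1))
            )

    def test_relaxed_values(self):
        node = RectNode((0,), (1,))
        # bound = 30 -> 20 + 1.2 * 10 = 32
        assert ip.relaxed_lower_bound((30.0,), node, (1.0,), 20.0, 1.2) == pytest.approx(32.0)
        # bound = 10 <= d_t -> unchanged
        assert ip.relaxed_lower_bound((10.0,), node, (1.0,), 20.0, 1.2) == pytest.approx(10.0)


def brute_cut_nearest(corners, mem, spacing, alpha, d_init):
    sel = np.argwhere(mem >= alpha)
    if len(sel) == 0:
        return np.full(len(corners), d_init)
    d = np.linalg.norm(
        corners[:, None, :] * spacing - sel[None, :, :] * spacing, axis=-1
    ).min(1)
    return np.minimum(d, d_init)


class TestAlphaCutSearch:
    def test_empty_cut_keeps_initial_distance(self, random_image):
        tree = ip.build_alpha_tree(random_image)
        alpha = random_image.memberships.max() + 1e-6
        D = ip.alpha_cut_search(np.array([[0, 0], [1, 1]]), alpha, tree, 7.0)
        assert np.all(D == 7.0)

    def test_corner_on_object_spel_is_zero(self, random_image):
        mem = random_image.memberships
        tree = ip.build_alpha_tree(random_image)
        ij = np.unravel_index(np.argmax(mem), mem.shape)
        D = ip.alpha_cut_search(np.array([ij]), mem[ij], tree, 10.0)
        assert D[0] == 0.0

    def test_matches_linear_scan(self, rng):
        """Exact search (beta = 1) equals brute force on random cases."""
        for _ in range(20):
            mem = rng.random((8, 8))
            img = ip.FuzzyImage(mem)
            tree = ip.build_alpha_tree(img)
            base = rng.integers(0, 7, 2)
            corners = base + np.array([[0, 0], [1, 0], [0, 1], [1, 1]])
            alpha = rng.random()
            D = ip.alpha_cut_search(corners, alpha, tree, 12.0)
            expected = brute_cut_nearest(corners, mem, img.spacing, alpha, 12.0)
            np.testing.assert_array_equal(D, expected)

    def test_joint_kernel_equals_reference(self, rng):
        """One batched multi-level traversal returns the same distances as
        the recursive single-level search."""
        for _ in range(10):
            mem = rng.random((9, 6))
            img = ip.FuzzyImage(mem, spacing=(1.0, 2.0))
            tree = ip.build_alpha_tree(img)
            base = np.array([rng.integers(0, 8), rng.integers(0, 5)])
            corners = (base + np.array([[0, 0], [1, 0], [0, 1], [1, 1]])).astype(np.int64)
            alphas = rng.random(5)
            D = np.full((5, 4), 15.0)
            _kernels.search_joint(
                tree.values, tree.N, tree.spacing, corners, alphas, D, 0.0, 1.0
            )
            for l, a in enumerate(alphas):
                ref = ip.alpha_cut_search(corners, a, tree, 15.0)
                np.testing.assert_array_equal(D[l], ref)

    def test_relaxed_search_contract(self, rng):
        """With beta > 1 the result is exact below d_t and bounded above by
        d_t + beta (true - d_t) otherwise."""
        mem = (rng.random((16, 16)) > 0.97).astype(float)
        img = ip.FuzzyImage(mem)
        tree = ip.build_alpha_tree(img)
        d_t, beta, d_max = 4.0, 1.5, 25.0
        for _ in range(100):
            base = rng.integers(0, 15, 2)
            corners = base + np.array([[0, 0], [1, 0], [0, 1], [1, 1]])
            D = ip.alpha_cut_search(corners, 0.5, tree, d_max, d_t=d_t, beta=beta)
            true = brute_cut_nearest(corners, mem, img.spacing, 0.5, d_max)
            for d, t in zip(D, true):
                if t <= d_t:
                    assert d == t
                else:
                    assert t <= d + 1e-12
                    assert d <= d_t + beta * (t - d_t) + 1e-12


class TestMCPointDistance:
    def test_on_object_spel_full_height(self):
        mem = np.zeros((8, 8))
        mem[3, 4] = 1.0
        img = ip.FuzzyImage(mem)
        trees = ip.build_trees(img)
        est = ip.mc_point_distance((3.0, 4.0), 1.0, trees, n_alpha=9, d_max=10.0)
        assert est.value == 0.0

    def test_symmetric_complement_case(self):
        # h = 0 on a zero spel: every alpha goes to the complement branch,
        # whose cuts contain that spel -> distance 0
        mem = np.zeros((6, 6))
        mem[2, 2] = 1.0
        img = ip.FuzzyImage(mem)
        trees = ip.build_trees(img)
        est = ip.mc_point_distance((4.0, 4.0), 0.0, trees, n_alpha=9, d_max=10.0)
        assert est.value == 0.0

    def test_matches_exact_quadrature_at_shared_levels(self, rng):
        """The tree path reproduces the exhaustive linear-scan quadrature."""
        for _ in range(5):
            mem = rng.random((6, 6))
            img = ip.FuzzyImage(mem)
            trees = ip.build_trees(img)
            vals = np.unique(np.concatenate([mem.ravel(), 1.0 - mem.ravel()]))
            levels = np.clip((vals[:-1] + vals[1:]) / 2.0, 1e-9, 1 - 1e-9)
            p = rng.uniform(0.2, 4.8, 2)
            h = rng.random()
            est = ip.mc_point_distance(p, h, trees, alphas=levels, d_max=8.0)
            exact = ip.exact_alpha_distance(p, h, img, levels, 8.0)
            assert est.value == pytest.approx(exact, abs=1e-9)

    def test_reference_and_joint_methods_identical(self, rng):
        mem = rng.random((7, 7))
        trees = ip.build_trees(ip.FuzzyImage(mem))
        levels = rng.random(6)
        p, h = rng.uniform(0.5, 5.5, 2), rng.random()
        a = ip.mc_point_distance(p, h, trees, alphas=levels, d_max=9.0)
        b = ip.mc_point_distance(p, h, trees, alphas=levels, d_max=9.0, method="reference")
        assert a.value == b.value
        np.testing.assert_array_equal(a.corner_distances, b.corner_distances)

    def test_monotone_in_alpha_below_height(self, rng):
        """Larger alpha shrinks the cut, so d' is non-decreasing in alpha."""
        mem = rng.random((8, 8))
        trees = ip.build_trees(ip.FuzzyImage(mem))
        p = (3.3, 4.6)
        prev = -1.0
        for a in np.linspace(0.05, 0.95, 10):
            est = ip.mc_point_distance(p, 1.0, trees, alphas=[a], d_max=12.0)
            assert est.value >= prev - 1e-12
            prev = est.value

    def test_truncation_at_d_max(self, rng):
        mem = (rng.random((10, 10)) > 0.98).astype(float)
        trees = ip.build_trees(ip.FuzzyImage(mem))
        est = ip.mc_point_distance((5.0, 5.0), 1.0, trees, n_alpha=11, d_max=2.5)
        assert np.all(est.corner_distances <= 2.5)
        assert np.all(est.corner_distances >= 0.0)

    def test_out_of_domain_raises(self, random_image):
        trees = ip.build_trees(random_image)
        with pytest.raises(ip.OutOfDomainError):
            ip.mc_point_distance((-0.5, 3.0), 0.5, trees, n_alpha=3, d_max=5.0)

    def test_gradient_points_away_from_object(self):
        mem = np.zeros((9, 9))
        mem[4, 2] = 1.0
        trees = ip.build_trees(ip.FuzzyImage(mem))
        est = ip.mc_point_distance((4.3, 6.5), 1.0, trees, n_alpha=5, d_max=12.0)
        assert est.gradient[1] > 0  # distance grows moving away along axis 1

    def test_empty_cut_level_contributes_d_max(self):
        mem = np.full((5, 5), 0.3)
        img = ip.FuzzyImage(mem)
        # level above all memberships: object branch saturates at d_max
        v = ip.exact_alpha_distance((2.0, 2.0), 1.0, img, [0.9], 6.0)
        assert v == pytest.approx(6.0)

    def test_single_spel_hand_geometry(self):
        mem = np.zeros((8, 8))
        mem[2, 1] = 0.8
        img = ip.FuzzyImage(mem)
        # p at distance 5 from the object spel, any level <= 0.8 contributes 5
        v = ip.exact_alpha_distance((2.0, 6.0), 1.0, img, [0.4, 0.7], 20.0)
        assert v == pytest.approx(5.0)


class TestUnbiasedness:
    def test_mc_mean_matches_exact_integral(self, rng):
        """E[d'] over uniform alpha equals the truncated exact integral."""
        mem = rng.random((6, 6))
        img = ip.FuzzyImage(mem)
        trees = ip.build_trees(img)
        p, h, d_max = (2.7, 3.1), 0.6, 6.0
        exact = ip.exact_amd_quadrature(p, h, img, d_max)
        draws = rng.random(20000)
        vals = np.array(
            [ip.mc_point_distance(p, h, trees, alphas=[a], d_max=d_max).value for a in draws[:4000]]
        )
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean() - exact) < 3 * se + 1e-12


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
def test_kronecker_alpha_levels_in_open_unit_interval(offset, _):
    levels = ip.fuzzy.sample_alphas(9, np.random.default_rng(int(offset * 1e6)))
    assert np.all((levels > 0) & (levels < 1))


def test_corner_cell_clamps_to_grid():
    base, u, inside = _corner_cell(np.array([[7.0, 0.0]]), np.array([8, 8]), np.ones(2))
    assert inside[0]
    assert tuple(base[0]) == (6, 0)
    assert u[0, 0] == pytest.approx(1.0)
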