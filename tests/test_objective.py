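"""Symmetric objective: directed distances, inverse inconsistency, gradients."""

import numpy as np
import pytest

import inspire as ip
from inspire.bspline import BSplineField
from inspire.objective import (
    MCConfig,
    NoOverlapError,
    ObjectivePair,
    aw_iic,
    directed_amd,
    point_iic,
    total_objective,
)


def binary_image(shape, spels):
    mem = np.zeros(shape)
    for ij in spels:
        mem[ij] = 1.0
    return ip.FuzzyImage(mem)


def all_points(shape):
    return np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), -1
    ).reshape(-1, len(shape))


def exhaustive_levels(*images):
    vals = np.concatenate(
        [np.concatenate([im.memberships.ravel(), 1 - im.memberships.ravel()]) for im in images]
    )
    vals = np.unique(vals)
    mids = (vals[:-1] + vals[1:]) / 2
    return np.clip(mids, 1e-9, 1 - 1e-9)


class TestDirectedAMD:
    def test_self_distance_zero_on_binary_image(self):
        img = binary_image((12, 12), [(3, 4), (8, 8), (5, 9)])
        trees = ip.build_trees(img)
        T = BSplineField.for_domain((12, 12), (1, 1), (4, 4))
        v, kept, _, _ = directed_amd(
            img, trees, T, all_points((12, 12)), MCConfig(d_max=5.0), alphas=[0.5]
        )
        assert v == 0.0
        assert kept.all()

    def test_single_point_at_known_distance(self):
        img = binary_image((16, 16), [(8, 3)])
        trees = ip.build_trees(img)
        A = binary_image((16, 16), [(8, 8)])
        T = BSplineField.for_domain((16, 16), (1, 1), (4, 4))
        # fuzzy point at (8, 8) with h = 1, object spel at (8, 3): distance 5
        v, _, _, _ = directed_amd(
            A, trees, T, [(8, 8)], MCConfig(d_max=12.0), alphas=[0.5]
        )
        assert v == pytest.approx(5.0)

    def test_weight_rescaling_invariance(self, rng):
        img = ip.FuzzyImage(rng.random((10, 10)))
        trees = ip.build_trees(img)
        A = ip.FuzzyImage(rng.random((10, 10)))
        T = BSplineField.for_domain((10, 10), (1, 1), (4, 4))
        pts = all_points((10, 10))
        w = rng.random(len(pts)) + 0.1
        v1, _, _, _ = directed_amd(A, trees, T, pts, MCConfig(d_max=5.0), [0.3, 0.7], w)
        v2, _, _, _ = directed_amd(A, trees, T, pts, MCConfig(d_max=5.0), [0.3, 0.7], 2 * w)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_no_overlap_raises(self):
        img = binary_image((8, 8), [(4, 4)])
        trees = ip.build_trees(img)
        T = BSplineField.for_domain((8, 8), (1, 1), (4, 4))
        T.coeffs[...] = [100.0, 100.0]  # everything lands outside
        with pytest.raises(NoOverlapError):
            directed_amd(img, trees, T, [(4, 4)], MCConfig(d_max=5.0), [0.5])


class TestPointIIC:
    def test_mutually_inverse_transforms(self):
        a = BSplineField.for_domain((20, 20), (1, 1), (5, 5))
        b = BSplineField.for_domain((20, 20), (1, 1), (5, 5))
        a.coeffs[...] = [2.0, 1.0]
        b.coeffs[...] = [-2.0, -1.0]
        assert point_iic(a, b, [(9.0, 9.0)]) == pytest.approx(0.0, abs=1e-24)

    def test_shift_against_identity(self):
        a = BSplineField.for_domain((20, 20), (1, 1), (5, 5))
        b = BSplineField.for_domain((20, 20), (1, 1), (5, 5))
        a.coeffs[...] = [3.0, 4.0]
        assert point_iic(a, b, [(8.0, 8.0)]) == pytest.approx(12.5)  # ||v||^2 / 2

    def test_non_negative(self, rng):
        a = BSplineField.for_domain((20, 20), (1, 1), (5, 5))
        b = BSplineField.for_domain((20, 20), (1, 1), (5, 5))
        a.coeffs = rng.normal(size=a.coeffs.shape)
        b.coeffs = rng.normal(size=b.coeffs.shape)
        vals = point_iic(a, b, rng.uniform(2, 18, (20, 2)))
        assert np.all(vals >= 0)


class TestAwIIC:
    def test_inverse_pair_is_zero(self):
        a = BSplineField.for_domain((24, 24), (1, 1), (5, 5))
        b = BSplineField.for_domain((24, 24), (1, 1), (5, 5))
        a.coeffs[...] = [1.5, 0.0]
        b.coeffs[...] = [-1.5, 0.0]
        v, gf, gb = aw_iic(a, b, np.array([[10.0, 10.0], [12.0, 8.0]]))
        assert v == pytest.approx(0.0, abs=1e-24)

    def test_constant_residual(self, rng):
        a = BSplineField.for_domain((24, 24), (1, 1), (5, 5))
        b = BSplineField.for_domain((24, 24), (1, 1), (5, 5))
        b.coeffs[...] = [0.6, -0.8]  # round trip offset r, |r| = 1
        pts = rng.uniform(8.0, 16.0, (15, 2))
        v, _, _ = aw_iic(a, b, pts)
        assert v == pytest.approx(0.5)

    def test_empty_kept_set_is_zero_with_zero_gradient(self):
        a = BSplineField.for_domain((24, 24), (1, 1), (5, 5))
        b = BSplineField.for_domain((24, 24), (1, 1), (5, 5))
        v, gf, gb = aw_iic(a, b, np.array([[5.0, 5.0]]), kept=np.array([False]))
        assert v == 0.0
        assert np.all(gf == 0) and np.all(gb == 0)

    def test_gradients_match_finite_differences(self, rng):
        a = BSplineField.for_domain((24, 24), (1, 1), (6, 6))
        b = BSplineField.for_domain((24, 24), (1, 1), (6, 6))
        a.coeffs = rng.normal(scale=0.8, size=a.coeffs.shape)
        b.coeffs = rng.normal(scale=0.8, size=b.coeffs.shape)
        pts = rng.uniform(3.0, 21.0, (25, 2))
        v, gf, gb = aw_iic(a, b, pts)
        h = 1e-6
        for fld, g in ((a, gf), (b, gb)):
            flat = fld.coeffs.ravel()
            for i in rng.choice(fld.n_params, 12, replace=False):
                old = flat[i]
                flat[i] = old + h
                vp = aw_iic(a, b, pts)[0]
                flat[i] = old - h
                vm = aw_iic(a, b, pts)[0]
                flat[i] = old
                assert g[i] == pytest.approx((vp - vm) / (2 * h), abs=1e-5)


class TestTotalObjective:
    def _setup(self, rng, shape=(16, 16), lam=0.02):
        A = ip.FuzzyImage(np.round(rng.random(shape) * 8) / 8)
        B = ip.FuzzyImage(np.round(rng.random(shape) * 8) / 8)
        ta = BSplineField.for_domain(shape, (1, 1), (5, 5))
        tb = BSplineField.for_domain(shape, (1, 1), (5, 5))
        ta.coeffs = rng.normal(scale=0.7, size=ta.coeffs.shape)
        tb.coeffs = rng.normal(scale=0.7, size=tb.coeffs.shape)
        pair = ObjectivePair(ta, tb, lam=lam)
        levels = exhaustive_levels(A, B)
        mc = MCConfig(d_max=6.0, alphas=levels)
        pa = rng.integers(2, 14, (40, 2))
        pb = rng.integers(2, 14, (40, 2))
        return A, B, pair, mc, levels, pa, pb

    def test_lambda_zero_is_pure_distance_mean(self, rng):
        A, B, pair, mc, levels, pa, pb = self._setup(rng, lam=0.0)
        rep = total_objective(
            pair, A, B, ip.build_trees(A), ip.build_trees(B), pa, pb, mc, alphas=levels
        )
        d_ab, d_ba, iic_ab, iic_ba = rep.components
        assert iic_ab == 0.0 and iic_ba == 0.0
        assert rep.J == pytest.approx(0.5 * (d_ab + d_ba))

    def test_symmetry_under_argument_swap(self, rng):
        A, B, pair, mc, levels, pa, pb = self._setup(rng)
        ta, tb = pair.t_ab, pair.t_ba
        rep1 = total_objective(
            pair, A, B, ip.build_trees(A), ip.build_trees(B), pa, pb, mc, alphas=levels
        )
        swapped = ObjectivePair(tb, ta, lam=pair.lam)
        rep2 = total_objective(
            swapped, B, A, ip.build_trees(B), ip.build_trees(A), pb, pa, mc, alphas=levels
        )
        assert rep1.J == rep2.J
        np.testing.assert_array_equal(rep1.grad_ab, rep2.grad_ba)

    def test_recomposition_from_parts(self, rng):
        A, B, pair, mc, levels, pa, pb = self._setup(rng)
        trees_a, trees_b = ip.build_trees(A), ip.build_trees(B)
        rep = total_objective(pair, A, B, trees_a, trees_b, pa, pb, mc, alphas=levels)
        d_ab, k_a, _, _ = directed_amd(A, trees_b, pair.t_ab, pa, mc, levels)
        d_ba, k_b, _, _ = directed_amd(B, trees_a, pair.t_ba, pb, mc, levels)
        i_ab, _, _ = aw_iic(pair.t_ab, pair.t_ba, pa.astype(float), kept=k_a)
        i_ba, _, _ = aw_iic(pair.t_ba, pair.t_ab, pb.astype(float), kept=k_b)
        expected = 0.5 * (d_ab + d_ba) + 0.5 * pair.lam * (i_ab + i_ba)
        assert rep.J == pytest.approx(expected, rel=1e-12)

    def test_penalty_monotone_in_lambda(self, rng):
        A, B, pair, mc, levels, pa, pb = self._setup(rng)
        trees_a, trees_b = ip.build_trees(A), ip.build_trees(B)
        prev = -np.inf
        for lam in (0.0, 0.01, 0.1, 1.0):
            p = ObjectivePair(pair.t_ab, pair.t_ba, lam=lam)
            rep = total_objective(p, A, B, trees_a, trees_b, pa, pb, mc, alphas=levels)
            assert rep.J >= prev
            prev = rep.J

    def test_distance_term_dominates_for_small_residuals(self, rng):
        """The non-squared distance blends with the squared inconsistency:
        shrinking a joint perturbation, the IIC share of J vanishes faster."""
        A, B, pair, mc, levels, pa, pb = self._setup(rng, lam=1.0)
        trees_a, trees_b = ip.build_trees(A), ip.build_trees(B)
        base = pair.t_ab.coeffs.copy(), pair.t_ba.coeffs.copy()
        ratios = []
        for scale in (1.0, 0.1):
            pair.t_ab.coeffs = base[0] * scale
            pair.t_ba.coeffs = base[1] * scale
            rep = total_objective(pair, A, B, trees_a, trees_b, pa, pb, mc, alphas=levels)
            d_ab, d_ba, i_ab, i_ba = rep.components
            ratios.append((i_ab + i_ba) / max(d_ab + d_ba, 1e-30))
        assert ratios[1] < ratios[0]

    def test_gradient_matches_finite_differences(self, rng):
        """Full analytic gradient of J (distance + IIC chain rule) against
        central differences, interpolation-consistent spatial gradient."""
        A, B, pair, mc, levels, pa, pb = self._setup(rng)
        mc.gradient_mode = "interp"
        trees_a, trees_b = ip.build_trees(A), ip.build_trees(B)

        def keep_generic(T, pts):
            tp = T.transform(pts.astype(float))
            u = tp - np.floor(tp)
            return np.all((u > 0.1) & (u < 0.9), axis=1) & np.all(
                (tp > 0.5) & (tp < 14.5), axis=1
            )

        pa = pa[keep_generic(pair.t_ab, pa)]
        pb = pb[keep_generic(pair.t_ba, pb)]
        rep = total_objective(pair, A, B, trees_a, trees_b, pa, pb, mc, alphas=levels)
        h = 1e-5
        for fld, g in ((pair.t_ab, rep.grad_ab), (pair.t_ba, rep.grad_ba)):
            flat = fld.coeffs.ravel()
            for i in rng.choice(fld.n_params, 10, replace=False):
                old = flat[i]
                flat[i] = old + h
                Jp = total_objective(pair, A, B, trees_a, trees_b, pa, pb, mc, alphas=levels).J
                flat[i] = old - h
                Jm = total_objective(pair, A, B, trees_a, trees_b, pa, pb, mc, alphas=levels).J
                flat[i] = old
                fd = (Jp - Jm) / (2 * h)
                assert g[i] == pytest.approx(fd, abs=1e-6 + 1e-3 * abs(fd))
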