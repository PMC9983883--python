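"""Images as spatial fuzzy sets and the alpha-cut point-to-set distance.

A grayscale image is treated as a fuzzy set: each spel (pixel/voxel) carries
a membership in [0, 1].  The bidirectional alpha-cut point-to-set distance
between a fuzzy point p (position + height h) and a fuzzy set S is

    d_alpha(p, S) = int_0^h d(p, aS) da  +  int_0^{1-h} d(p, a S-bar) da,

where ``aS`` is the crisp set of spels with membership >= a.  This module
estimates that distance, and its spatial gradient, by Monte Carlo sampling
of cut levels combined with a pruned search over an augmented max-KD-tree,
evaluated at the 2^n grid corners around p and interpolated to sub-spel
positions.  Distances are truncated at a cap d_max (empty cuts saturate
there).

Two code paths exist for every search: a pure-Python reference that follows
the recursive algorithms literally, and batched numba kernels used by the
registration loop.  They are asserted identical in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels


class OutOfDomainError(ValueError):
    """A query point lies outside the hull of the grid's spel centers."""


# ----------------------------------------------------------------------
# Domain types
# ----------------------------------------------------------------------
@dataclass
class FuzzyImage:
    """A membership grid with spel spacing and optional mask / weights."""

    memberships: np.ndarray
    spacing: np.ndarray = None
    mask: Optional[np.ndarray] = None
    weights: Optional[np.ndarray] = None

    def __post_init__(self):
        self.memberships = np.ascontiguousarray(self.memberships, dtype=np.float64)
        if self.spacing is None:
            self.spacing = np.ones(self.memberships.ndim)
        self.spacing = np.atleast_1d(np.asarray(self.spacing, dtype=np.float64))
        if self.memberships.size == 0:
            raise ValueError("empty image")
        if np.any(self.memberships < 0) or np.any(self.memberships > 1):
            raise ValueError("memberships must lie in [0, 1]")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")
        for grid, name in ((self.mask, "mask"), (self.weights, "weights")):
            if grid is not None and grid.shape != self.memberships.shape:
                raise ValueError(f"{name} shape mismatch")
        if self.weights is not None and np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")

    @property
    def shape(self):
        return self.memberships.shape

    @property
    def ndim(self) -> int:
        return self.memberships.ndim

    @property
    def extent(self) -> np.ndarray:
        """Physical extent: distance between first and last spel centers."""
        return (np.array(self.shape) - 1) * self.spacing

    @property
    def diameter(self) -> float:
        """Length of the image diagonal (used to scale d_max)."""
        return float(np.linalg.norm(self.extent))

    def complement(self) -> "FuzzyImage":
        return FuzzyImage(1.0 - self.memberships, self.spacing, self.mask, self.weights)


@dataclass
class RectNode:
    """A sub-rectangle of the grid: minimal corner y and size R (in spels)."""

    y: np.ndarray
    R: np.ndarray

    def __post_init__(self):
        self.y = np.atleast_1d(np.asarray(self.y, dtype=np.int64))
        self.R = np.atleast_1d(np.asarray(self.R, dtype=np.int64))
        if np.any(self.R < 1):
            raise ValueError("rectangle sizes must be positive")

    @property
    def is_leaf(self) -> bool:
        return int(np.prod(self.R)) == 1


@dataclass
class AlphaTree:
    """Implicit array-stored augmented max-KD-tree over an image grid.

    ``values[i]`` holds the maximum membership of node i's sub-rectangle;
    children of node i are 2i and 2i+1, the root is node 1.
    """

    values: np.ndarray
    N: np.ndarray
    spacing: np.ndarray

    @property
    def root_value(self) -> float:
        return float(self.values[1])


@dataclass
class DistanceEstimate:
    """Result of a point-to-set distance query."""

    value: float
    gradient: np.ndarray
    corner_distances: np.ndarray


@dataclass
class ImageTrees:
    """The pair of trees tau(S) and tau(S-bar) used by the estimator."""

    obj: AlphaTree
    comp: AlphaTree
    image: FuzzyImage = field(repr=False, default=None)


# ----------------------------------------------------------------------
# Tree construction and rectangle primitives
# ----------------------------------------------------------------------
def split_rect(node: RectNode, spacing) -> tuple[RectNode, RectNode, int]:
    """Split a rectangle in half (to integer precision) along its widest axis.

    The axis is argmax_k s_k (R_k - 1); ties break to the lowest dimension
    index.  The left child receives ceil(R_k / 2) spels, matching the build
    recursion so search and build traverse identical rectangles.
    """
    if node.is_leaf:
        raise ValueError("cannot split a leaf rectangle")
    s = np.atleast_1d(np.asarray(spacing, dtype=np.float64))
    k = int(np.argmax(s * (node.R - 1)))
    half = (int(node.R[k]) + 1) // 2
    yl, Rl = node.y.copy(), node.R.copy()
    Rl[k] = half
    yr, Rr = node.y.copy(), node.R.copy()
    yr[k] += half
    Rr[k] -= half
    return RectNode(yl, Rl), RectNode(yr, Rr), k


def tree_array_length(shape) -> int:
    return 2 ** (1 + int(sum(math.ceil(math.log2(n)) for n in np.atleast_1d(shape) if n > 1)))


def build_alpha_tree(image: FuzzyImage, complement: bool = False) -> AlphaTree:
    """Build the augmented max-KD-tree of an image (or of its complement)."""
    mem = 1.0 - image.memberships if complement else image.memberships
    N = np.array(image.shape, dtype=np.int64)
    values = np.full(tree_array_length(N), -1.0)
    _kernels.build_tree(np.ascontiguousarray(mem.ravel()), N, image.spacing, values)
    return AlphaTree(values, N, image.spacing.copy())


def build_trees(image: FuzzyImage) -> ImageTrees:
    return ImageTrees(build_alpha_tree(image), build_alpha_tree(image, complement=True), image)


def rect_lower_bound(p, node: RectNode, spacing) -> float:
    """Distance from p to the nearest spel center inside the rectangle."""
    p = np.atleast_1d(np.asarray(p, dtype=np.float64))
    s = np.atleast_1d(np.asarray(spacing, dtype=np.float64))
    lo = node.y * s
    hi = (node.y + node.R - 1) * s
    d = np.maximum(0.0, np.maximum(lo - p, p - hi))
    return float(np.sqrt(np.sum(d * d)))


def relaxed_lower_bound(p, node: RectNode, spacing, d_t: float, beta: float) -> float:
    """Lower bound relaxed by beta beyond the threshold d_t (beta >= 1)."""
    b = rect_lower_bound(p, node, spacing)
    return b if b <= d_t else d_t + beta * (b - d_t)


# ----------------------------------------------------------------------
# Reference (recursive) search — mirrors the literal search procedure
# ----------------------------------------------------------------------
def alpha_cut_search(
    corners,
    alpha: float,
    tree: AlphaTree,
    d_init: float,
    d_t: float = 0.0,
    beta: float = 1.0,
):
    """Distances from grid-point corners to the nearest spel of the alpha-cut.

    With beta = 1 the result is exact: ``min(d_init, distance to the nearest
    spel with membership >= alpha)`` per corner.  Sub-trees are pruned when
    the cut level exceeds the node's stored maximum or when every current
    distance is already within the (relaxed) lower bound; the child nearer
    the first corner is visited first.
    """
    corners = np.atleast_2d(np.asarray(corners, dtype=np.int64))
    s = tree.spacing
    P = corners * s
    D = np.full(len(corners), float(d_init))

    def search(i: int, node: RectNode):
        tau = tree.values[i]
        if alpha > tau or all(
            D[j] <= relaxed_lower_bound(P[j], node, s, d_t, beta) for j in range(len(D))
        ):
            return
        if node.is_leaf:
            dj = np.linalg.norm(P - node.y * s, axis=1)
            np.minimum(D, dj, out=D)
            return
        left, right, k = split_rect(node, s)
        if P[0, k] <= right.y[k] * s[k]:
            search(2 * i, left)
            search(2 * i + 1, right)
        else:
            search(2 * i + 1, right)
            search(2 * i, left)

    search(1, RectNode(np.zeros(len(tree.N), dtype=np.int64), tree.N))
    return D


# ----------------------------------------------------------------------
# Interpolation helpers shared by all estimator paths
# ----------------------------------------------------------------------
def _corner_cell(points, N, spacing):
    """Cell base index, fractional offsets and in-domain mask per point."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    hi = (N - 1) * spacing
    inside = np.all((pts >= 0.0) & (pts <= hi), axis=1)
    t = pts / spacing
    base = np.minimum(np.floor(t).astype(np.int64), N - 2)
    base = np.maximum(base, 0)
    u = t - base
    return base, u, inside


def _interp_value(D, u):
    """Multilinear interpolation of per-corner values at offsets u."""
    P, C = D.shape
    n = u.shape[1]
    w = np.ones((P, C))
    for k in range(n):
        bit = (np.arange(C) >> k) & 1
        w *= np.where(bit[None, :] == 1, u[:, k : k + 1], 1.0 - u[:, k : k + 1])
    return np.sum(D * w, axis=1)


def _interp_gradient(D, u, spacing, mode: str):
    """Spatial gradient of the interpolated corner-distance surface.

    mode="midpoint": the discrete gradient evaluated at the cell mid-point
    (the method's choice, robust at saddle points of the surface).
    mode="interp": the exact derivative of the multilinear surface at u
    (consistent with the interpolated value; used for gradient checks).
    """
    P, C = D.shape
    n = u.shape[1]
    g = np.empty((P, n))
    idx = np.arange(C)
    for k in range(n):
        hi = idx[(idx >> k) & 1 == 1]
        lo = hi & ~(1 << k)
        diffs = D[:, hi] - D[:, lo]  # (P, C/2)
        if mode == "midpoint":
            g[:, k] = diffs.mean(axis=1) / spacing[k]
        elif mode == "interp":
            w = np.ones((P, C // 2))
            for k2 in range(n):
                if k2 == k:
                    continue
                bit = (lo >> k2) & 1
                w *= np.where(bit[None, :] == 1, u[:, k2 : k2 + 1], 1.0 - u[:, k2 : k2 + 1])
            g[:, k] = np.sum(diffs * w, axis=1) / spacing[k]
        else:
            raise ValueError(f"unknown gradient mode {mode!r}")
    return g


# ----------------------------------------------------------------------
# Monte Carlo estimator
# ----------------------------------------------------------------------
def corner_distance_tables(
    points,
    heights,
    trees: ImageTrees,
    alphas,
    d_max: float,
    d_t: float = 0.0,
    beta: float = 1.0,
    method: str = "joint",
):
    """Per-corner averaged alpha-cut distances for a batch of fuzzy points.

    Returns ``(D, base, u, inside)`` with D of shape (P, 2^n).  Rows of
    out-of-domain points are left at d_max and flagged False in `inside`.
    ``method="joint"`` runs all cut levels in one batched tree traversal;
    ``method="reference"`` loops the recursive single-level search and must
    return identical distances.
    """
    N = trees.obj.N
    s = trees.obj.spacing
    alphas = np.ascontiguousarray(np.atleast_1d(alphas), dtype=np.float64)
    base, u, inside = _corner_cell(points, N, s)
    heights = np.atleast_1d(np.asarray(heights, dtype=np.float64))
    P = len(base)
    C = 1 << len(N)
    D = np.full((P, C), float(d_max))
    if method == "joint":
        if inside.any():
            sub = np.empty((int(inside.sum()), C))
            _kernels.mc_corner_tables(
                trees.obj.values,
                trees.comp.values,
                N,
                s,
                np.ascontiguousarray(base[inside]),
                np.ascontiguousarray(heights[inside]),
                alphas,
                float(d_max),
                float(d_t),
                float(beta),
                sub,
            )
            D[inside] = sub
    elif method == "reference":
        offs = np.stack(
            [(np.arange(C) >> k) & 1 for k in range(len(N))], axis=1
        ).astype(np.int64)
        for p in range(P):
            if not inside[p]:
                continue
            corners = base[p][None, :] + offs
            acc = np.zeros(C)
            for a in alphas:
                if a <= heights[p]:
                    acc += alpha_cut_search(corners, a, trees.obj, d_max, d_t, beta)
                else:
                    acc += alpha_cut_search(corners, 1.0 - a, trees.comp, d_max, d_t, beta)
            D[p] = acc / len(alphas)
    else:
        raise ValueError(f"unknown method {method!r}")
    return D, base, u, inside


def mc_point_distance(
    point,
    height: float,
    trees: ImageTrees,
    n_alpha: int = 7,
    d_max: float = None,
    *,
    alphas=None,
    rng=None,
    d_t: float = 0.0,
    beta: float = 1.0,
    gradient_mode: str = "midpoint",
    method: str = "joint",
) -> DistanceEstimate:
    """Estimate d_alpha(p, S) and its spatial gradient at one fuzzy point.

    Cut levels are either given explicitly (`alphas`) or drawn as a
    1-D Kronecker (golden-ratio) sequence offset by `rng` — stratified yet
    unbiased over (0, 1).  Raises :class:`OutOfDomainError` for points whose
    corner cell is not inside the grid.
    """
    if d_max is None:
        d_max = trees.obj.image.diameter if trees.obj.image is not None else float(
            np.linalg.norm((trees.obj.N - 1) * trees.obj.spacing)
        )
    if alphas is None:
        alphas = sample_alphas(n_alpha, rng)
    D, base, u, inside = corner_distance_tables(
        [point], [height], trees, alphas, d_max, d_t, beta, method
    )
    if not inside[0]:
        raise OutOfDomainError(f"point {point} outside the grid hull")
    value = float(_interp_value(D, u)[0])
    grad = _interp_gradient(D, u, trees.obj.spacing, gradient_mode)[0]
    return DistanceEstimate(value, grad, D[0])


def sample_alphas(n_alpha: int, rng=None) -> np.ndarray:
    """Stratified cut levels: golden-ratio Kronecker sequence, random offset.

    With no rng the offset is 0 (deterministic).  Levels of exactly 0 are
    nudged into (0, 1): the level-0 cut is the whole domain and contributes
    distance 0 regardless.
    """
    inv_phi = 0.6180339887498949
    offset = float(rng.random()) if rng is not None else 0.0
    a = (offset + (1.0 + np.arange(n_alpha)) * inv_phi) % 1.0
    a[a == 0.0] = 1e-12
    return a


# ----------------------------------------------------------------------
# Exhaustive oracles (no tree; small images only)
# ----------------------------------------------------------------------
def _brute_cut_distance(corners_phys, mem, spacing, alpha, d_max):
    """Linear-scan distance from each corner to the nearest spel with
    membership >= alpha, truncated at d_max."""
    sel = np.argwhere(mem >= alpha)
    if len(sel) == 0:
        return np.full(len(corners_phys), float(d_max))
    pts = sel * spacing
    d = np.sqrt(((corners_phys[:, None, :] - pts[None, :, :]) ** 2).sum(-1)).min(1)
    return np.minimum(d, d_max)


def exact_alpha_distance(point, height, image: FuzzyImage, levels, d_max: float) -> float:
    """O(N)-scan evaluation of the same discrete quadrature as the Monte
    Carlo estimator, for a given list of cut levels (test oracle)."""
    D = exact_corner_table(point, height, image, levels, d_max)
    base, u, inside = _corner_cell([point], np.array(image.shape), image.spacing)
    if not inside[0]:
        raise OutOfDomainError(f"point {point} outside the grid hull")
    return float(_interp_value(D[None, :], u)[0])


def exact_corner_table(point, height, image: FuzzyImage, levels, d_max: float):
    N = np.array(image.shape)
    base, u, inside = _corner_cell([point], N, image.spacing)
    n = image.ndim
    C = 1 << n
    offs = np.stack([(np.arange(C) >> k) & 1 for k in range(n)], axis=1)
    corners = (base[0][None, :] + offs) * image.spacing
    acc = np.zeros(C)
    mem = image.memberships
    for a in np.atleast_1d(levels):
        if a <= height:
            acc += _brute_cut_distance(corners, mem, image.spacing, a, d_max)
        else:
            acc += _brute_cut_distance(corners, 1.0 - mem, image.spacing, 1.0 - a, d_max)
    return acc / len(np.atleast_1d(levels))


def exact_amd_quadrature(point, height, image: FuzzyImage, d_max: float) -> float:
    """Exact bidirectional alpha-cut distance (the integral itself), with
    distances truncated at d_max, via piecewise-constant level quadrature.

    This is the quantity the Monte Carlo estimator is unbiased for when the
    cut levels are uniform on (0, 1).
    """
    N = np.array(image.shape)
    base, u, inside = _corner_cell([point], N, image.spacing)
    if not inside[0]:
        raise OutOfDomainError(f"point {point} outside the grid hull")
    n = image.ndim
    C = 1 << n
    offs = np.stack([(np.arange(C) >> k) & 1 for k in range(n)], axis=1)
    corners = (base[0][None, :] + offs) * image.spacing

    def directed(mem, upper):
        # int_0^upper d(p, aS) da, piecewise constant between distinct levels
        vals = np.unique(mem)
        acc = np.zeros(C)
        lo = 0.0
        for v in vals:
            if lo >= upper:
                break
            hi = min(v, upper)
            if hi > lo:
                # for a in (lo, hi], the cut is {mem >= v}
                acc += (hi - lo) * _brute_cut_distance(corners, mem, image.spacing, v, d_max)
                lo = hi
        if lo < upper:  # a above the largest membership: empty cut
            acc += (upper - lo) * d_max
        return acc

    total = directed(image.memberships, height) + directed(1.0 - image.memberships, 1.0 - height)
    return float(_interp_value(total[None, :], u)[0])
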