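"""Cubic B-spline free-form deformation (FFD) transformation model.

A transformation ``T(x) = x + sum_i B(u) * Phi_i`` is parameterized by a
rectangular mesh of control-point displacement vectors with uniform
per-dimension spacing.  Points outside the finite support of the mesh are
mapped by the identity.  All coordinates are physical and continuous, with
spel (pixel/voxel) centers at ``index * spacing``, 0-based.

The mesh for an image domain is placed so that the cubic-basis indexing of
the FFD model is valid for every in-image point: with ``c_k`` control points
along dimension *k* and image extent ``E_k`` (distance between the first and
last spel centers), the control spacing is ``delta_k = E_k / (c_k - 3)`` and
the mesh origin sits one spacing before the image origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu


def basis_weights(u):
    """Cubic B-spline basis values ``(B0, B1, B2, B3)`` at fractional offset u.

    ``u`` may be scalar or an array; the result has a leading axis of size 4.
    The four weights are non-negative and sum to 1 (partition of unity).
    """
    u = np.asarray(u, dtype=np.float64)
    v = 1.0 - u
    b0 = v * v * v / 6.0
    b1 = (3 * u**3 - 6 * u**2 + 4) / 6.0
    b2 = (-3 * u**3 + 3 * u**2 + 3 * u + 1) / 6.0
    b3 = u**3 / 6.0
    return np.stack([b0, b1, b2, b3])


def basis_derivs(u):
    """Derivatives ``dB_i/du`` of the cubic basis at fractional offset u."""
    u = np.asarray(u, dtype=np.float64)
    v = 1.0 - u
    d0 = -v * v / 2.0
    d1 = (9 * u**2 - 12 * u) / 6.0
    d2 = (-9 * u**2 + 6 * u + 3) / 6.0
    d3 = u * u / 2.0
    return np.stack([d0, d1, d2, d3])


def _offset_grid(n):
    """All 4^n tensor-product offsets, shape (4^n, n), C order."""
    return np.stack(np.meshgrid(*([np.arange(4)] * n), indexing="ij"), axis=-1).reshape(-1, n)


@dataclass
class BSplineField:
    """A cubic B-spline displacement field in physical coordinates.

    Attributes
    ----------
    coeffs : ndarray, shape (c_1, ..., c_n, n)
        Control-point displacement vectors Phi.
    spacing : ndarray, shape (n,)
        Control-point spacing delta per dimension (strictly positive).
    origin : ndarray, shape (n,)
        Physical position of control point with index (0, ..., 0).
    """

    coeffs: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64)
        self.spacing = np.atleast_1d(np.asarray(self.spacing, dtype=np.float64))
        self.origin = np.atleast_1d(np.asarray(self.origin, dtype=np.float64))
        n = self.ndim
        if self.coeffs.shape[-1] != n or self.coeffs.ndim != n + 1:
            raise ValueError("coeffs must have shape (c_1, ..., c_n, n)")
        if np.any(np.array(self.counts) < 4):
            raise ValueError("need at least 4 control points per dimension")
        if np.any(self.spacing <= 0):
            raise ValueError("control spacing must be strictly positive")

    # ------------------------------------------------------------------
    @property
    def ndim(self) -> int:
        return len(self.spacing)

    @property
    def counts(self):
        return self.coeffs.shape[:-1]

    @property
    def n_params(self) -> int:
        return self.coeffs.size

    @classmethod
    def for_domain(cls, shape, spacing, counts) -> "BSplineField":
        """Zero field whose support covers an image of `shape` spels."""
        shape = np.atleast_1d(np.asarray(shape))
        spacing = np.atleast_1d(np.asarray(spacing, dtype=np.float64))
        counts = np.atleast_1d(np.asarray(counts, dtype=int))
        extent = (shape - 1) * spacing
        delta = extent / (counts - 3)
        origin = -delta
        coeffs = np.zeros(tuple(counts) + (len(shape),))
        return cls(coeffs, delta, origin)

    # ------------------------------------------------------------------
    def _locate(self, points):
        """Cell index z, fractional offset u and in-support mask per point."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        t = (pts - self.origin) / self.spacing
        c = np.array(self.counts)
        tol = 1e-9  # support boundary is inclusive up to rounding
        inside = np.all((t >= 1.0 - tol) & (t <= c - 2.0 + tol), axis=1)
        zf = np.floor(t).astype(np.int64)
        z = np.minimum(zf - 1, c - 4)  # right edge: u degenerates to 1
        z = np.maximum(z, 0)
        u = t - (z + 1)
        return pts, z, u, inside

    def support_weights(self, points, deriv_axis=None):
        """Tensor-product basis weights of the supporting control points.

        Returns ``(flat_idx, w, inside)`` where ``flat_idx`` has shape
        (P, 4^n) with flattened control-point indices, ``w`` the matching
        weights (rows of out-of-support points are zeroed), and ``inside``
        the boolean support mask.  With ``deriv_axis=k`` the weights are the
        derivatives of the basis product with respect to coordinate k
        (chain rule through u_k, i.e. divided by spacing[k]).
        """
        pts, z, u, inside = self._locate(points)
        n = self.ndim
        offs = _offset_grid(n)  # (4^n, n)
        w = np.ones((len(pts), 4**n))
        for k in range(n):
            if deriv_axis == k:
                wk = basis_derivs(u[:, k]).T / self.spacing[k]  # (P, 4)
            else:
                wk = basis_weights(u[:, k]).T
            w *= wk[:, offs[:, k]]
        idx = z[:, None, :] + offs[None, :, :]
        flat = np.ravel_multi_index(np.moveaxis(idx, -1, 0), self.counts)
        w[~inside] = 0.0
        flat[~inside] = 0
        return flat, w, inside

    def displacement(self, points):
        """Displacement vectors at `points`; zero outside the support."""
        flat, w, inside = self.support_weights(points)
        cf = self.coeffs.reshape(-1, self.ndim)
        disp = np.einsum("pk,pkd->pd", w, cf[flat])
        disp[~inside] = 0.0
        return disp

    def transform(self, points):
        """Apply ``T(x) = x + displacement(x)`` to an array of points."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return pts + self.displacement(pts)

    def spatial_jacobian(self, points):
        """Jacobian dT/dx, shape (P, n, n); identity outside the support."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        n = self.ndim
        J = np.tile(np.eye(n), (len(pts), 1, 1))
        cf = self.coeffs.reshape(-1, n)
        for k in range(n):
            flat, w, inside = self.support_weights(pts, deriv_axis=k)
            J[:, :, k] += np.einsum("pk,pkd->pd", w, cf[flat])
            # out-of-support rows contribute 0 (weights already zeroed)
        return J

    # ------------------------------------------------------------------
    def refine(self, new_counts, samples_per_span: int = 4) -> "BSplineField":
        """Re-fit this field on a (finer) control mesh by linear least squares.

        The displacement is sampled on a dense grid over the support interior
        (`samples_per_span` samples per knot span of the *new* mesh, at least
        4) and the new basis is fit to those samples.  Count progressions need
        not be dyadic.
        """
        if samples_per_span < 4:
            raise ValueError("need at least 4 samples per knot span")
        new_counts = np.atleast_1d(np.asarray(new_counts, dtype=int))
        if np.any(new_counts < np.array(self.counts)):
            raise ValueError("refinement must not reduce control counts")
        # support interior in physical coords: t in [1, c-2]
        lo = self.origin + self.spacing
        hi = self.origin + (np.array(self.counts) - 2) * self.spacing
        extent = hi - lo
        new_delta = extent / (new_counts - 3)
        new_origin = lo - new_delta
        target = BSplineField(
            np.zeros(tuple(new_counts) + (self.ndim,)), new_delta, new_origin
        )
        axes = [
            np.linspace(lo[k], hi[k], samples_per_span * (new_counts[k] - 3) + 1)
            for k in range(self.ndim)
        ]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, self.ndim)
        flat, w, inside = target.support_weights(grid)
        if not np.all(inside):
            raise RuntimeError("dense fit grid escaped the new support")
        P, K = w.shape
        rows = np.repeat(np.arange(P), K)
        A = sparse.csc_matrix(
            (w.ravel(), (rows, flat.ravel())), shape=(P, int(np.prod(new_counts)))
        )
        rhs = self.displacement(grid)
        lu = splu((A.T @ A).tocsc())
        sol = np.column_stack([lu.solve(A.T @ rhs[:, d]) for d in range(self.ndim)])
        target.coeffs = sol.reshape(tuple(new_counts) + (self.ndim,))
        return target

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "dimension": self.ndim,
            "counts": [int(c) for c in self.counts],
            "spacing": self.spacing.tolist(),
            "origin": self.origin.tolist(),
            "direction": "axis-aligned",
            "coefficients": self.coeffs.ravel().tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BSplineField":
        counts = d["counts"]
        coeffs = np.array(d["coefficients"], dtype=np.float64).reshape(
            tuple(counts) + (d["dimension"],)
        )
        return cls(coeffs, np.array(d["spacing"]), np.array(d["origin"]))

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "BSplineField":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def dense_displacement(self, shape, spacing):
        """Sample the displacement on a full image grid.

        Returns an array of shape ``shape + (n,)`` suitable for export as a
        multi-component image (TIFF in 2-D, NIfTI in 3-D).
        """
        shape = tuple(int(s) for s in np.atleast_1d(shape))
        axes = [np.arange(s) * sp for s, sp in zip(shape, np.atleast_1d(spacing))]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, self.ndim)
        return self.displacement(grid).reshape(shape + (self.ndim,))


def compose_points(outer: BSplineField, inner: BSplineField, points):
    """Evaluate ``outer(inner(x))`` pointwise, with no field resampling."""
    return outer.transform(inner.transform(points))
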