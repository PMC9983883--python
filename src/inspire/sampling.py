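"""Stochastic point selection for subsampled optimization.

Two streams are mixed per draw: a quasi-uniform stream from an
n-dimensional Kronecker sequence driven by generalized golden ratios, and a
gradient-weighted stream whose probabilities follow the normalized Gaussian
gradient magnitude of the image.  Smooth regions align early during
registration and then contribute little gradient; weighting samples toward
edges keeps the optimization informative, while the uniform component keeps
flat regions covered (important for the inverse-consistency penalty).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .fuzzy import FuzzyImage


@dataclass
class SamplerConfig:
    """Mixture sampler parameters.

    m : probability of drawing from the gradient-weighted stream.
    sigma_gm : scale (in spels) of the Gaussian derivative.
    t_gm : gradient magnitudes below this are zeroed (default 0).
    fraction : fraction of domain spels drawn per iteration.
    quasi_uniform : use the Kronecker stream for the uniform component
        (a plain RNG-uniform stream is available for ablation).
    """

    m: float = 0.5
    sigma_gm: float = 2.0
    t_gm: float = 0.0
    fraction: float = 0.05
    quasi_uniform: bool = True

    def __post_init__(self):
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("m must be in [0, 1]")
        if self.sigma_gm <= 0 or self.t_gm < 0:
            raise ValueError("invalid gradient-map parameters")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")


def golden_ratios(n: int) -> np.ndarray:
    """Generalized golden-ratio irrationals a_j = phi_n^(-j), j = 1..n.

    phi_i is the fixed point of x = (1 + x)^(1/(i+1)), found by fixed-point
    iteration to 1e-14 (phi_1 is the golden ratio, phi_2 the plastic number).
    """
    if n < 1:
        raise ValueError("dimension must be >= 1")
    x = 1.5
    for _ in range(200):
        x_new = (1.0 + x) ** (1.0 / (n + 1))
        if abs(x_new - x) < 1e-14:
            x = x_new
            break
        x = x_new
    return x ** -(1.0 + np.arange(n))


def kronecker_points(count: int, N, start: int = 0) -> np.ndarray:
    """Integer grid points x_j(i) = floor((i a_j mod 1) N_j), i from `start`.

    Deterministic and low-discrepancy; i = 0 yields the origin.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    N = np.atleast_1d(np.asarray(N, dtype=np.int64))
    a = golden_ratios(len(N))
    i = (start + np.arange(count, dtype=np.float64))[:, None]
    return np.floor((i * a[None, :] % 1.0) * N[None, :]).astype(np.int64)


def gradient_weight_map(
    image: FuzzyImage, sigma_gm: float, t_gm: float = 0.0
) -> Optional[np.ndarray]:
    """Normalized Gaussian gradient-magnitude probability grid.

    The per-axis Gaussian first derivatives at scale sigma_gm (reflect
    boundary handling) are combined into a Euclidean magnitude; values below
    t_gm are zeroed and the grid normalized to sum 1.  Returns None when the
    map is degenerate (everything zeroed), in which case callers fall back
    to uniform sampling.
    """
    gm = ndimage.gaussian_gradient_magnitude(image.memberships, sigma_gm, mode="reflect")
    gm[gm < t_gm] = 0.0
    total = gm.sum()
    if total <= 0.0 or not np.isfinite(total):
        return None
    return gm / total


@dataclass
class PointSampler:
    """Per-level sampler caching the (transformation-independent) weight map.

    The gradient map depends only on the image, so it is computed once per
    pyramid level and reused for every iteration at that level.
    """

    image: FuzzyImage
    config: SamplerConfig

    def __post_init__(self):
        self.grad_map = (
            gradient_weight_map(self.image, self.config.sigma_gm, self.config.t_gm)
            if self.config.m > 0
            else None
        )
        self._cdf = None
        if self.grad_map is not None:
            self._cdf = np.cumsum(self.grad_map.ravel())
            self._cdf[-1] = 1.0
        self._seq_len = int(np.prod(self.image.shape))

    @property
    def count_per_iteration(self) -> int:
        return max(1, int(round(self.config.fraction * np.prod(self.image.shape))))

    def draw(self, count: int, rng: np.random.Generator):
        """Draw `count` spel indices (with replacement) from the mixture.

        Returns ``(points, weights)``; weights are identically 1 (the
        objective normalizes by their sum).
        """
        if count < 1:
            raise ValueError("count must be >= 1")
        shape = np.array(self.image.shape, dtype=np.int64)
        use_grad = (
            rng.random(count) < self.config.m if self._cdf is not None else np.zeros(count, bool)
        )
        pts = np.empty((count, self.image.ndim), dtype=np.int64)
        n_u = int((~use_grad).sum())
        if n_u:
            if self.config.quasi_uniform:
                start = int(rng.integers(0, 2**31))
                pts[~use_grad] = kronecker_points(n_u, shape, start=start)
            else:
                pts[~use_grad] = np.column_stack(
                    [rng.integers(0, s, n_u) for s in shape]
                )
        n_g = int(use_grad.sum())
        if n_g:
            flat = np.searchsorted(self._cdf, rng.random(n_g), side="right")
            flat = np.minimum(flat, self._cdf.size - 1)
            pts[use_grad] = np.column_stack(np.unravel_index(flat, self.image.shape))
        return pts, np.ones(count)


def draw_points(image: FuzzyImage, count: int, config: SamplerConfig, rng):
    """One-shot mixture draw (builds the weight map; see PointSampler to
    amortize it across iterations)."""
    return PointSampler(image, config).draw(count, rng)
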