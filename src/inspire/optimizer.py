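"""Stochastic gradient descent with momentum over B-spline parameters.

The raw partial derivative of the objective with respect to a control
parameter scales with how many sampled points fall inside that parameter's
local support.  To decouple the step-size from grid coarseness and sampling
noise, each derivative is divided by ``gamma_i + eps`` where gamma_i sums
the parameter's total influence (basis-weight mass, plus the
lambda-weighted influence through the composed round-trip transforms) over
the kept sample points.  The ratio is invariant under uniform rescaling of
the point weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .objective import MCConfig, ObjectivePair, ObjectiveReport, total_objective


@dataclass
class SGDMState:
    """Heavy-ball SGDM state: v <- mu v - eta g_scaled; params += v."""

    step_size: float
    momentum: float = 0.0
    eps: float = 0.01
    velocity: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.step_size <= 0:
            raise ValueError("step size must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


def derivative_scales(pair: ObjectivePair, report: ObjectiveReport):
    """Per-parameter scale factors gamma for both transforms.

    For a parameter i = (control point cp, component c) of T_AB:

        gamma_i = sum_{P_A} w |dT_AB(x)/dT_AB^i|
                + lambda sum_{P_A} w |d(T_BA(T_AB(x)))/dT_AB^i|
                + lambda sum_{P_B} w |d(T_AB(T_BA(x)))/dT_AB^i|

    computed from the same basis weights and Jacobians as the gradient
    (the direct derivative norm is the tensor-product basis weight; the
    composed one additionally picks up the column norm of the outer field's
    spatial Jacobian at the composed location).
    """
    lam = pair.lam

    def gamma_for(t_own, t_other, batch_own, batch_other):
        n = t_own.ndim
        n_cp = int(np.prod(t_own.counts))
        g = np.zeros((n_cp, n))
        if batch_own.kept.any():
            x = batch_own.points_phys[batch_own.kept]
            w = batch_own.weights[batch_own.kept]
            flat, bw, _ = t_own.support_weights(x)
            direct = np.zeros(n_cp)
            np.add.at(direct, flat, w[:, None] * bw)
            g += direct[:, None]
            if lam > 0:
                y = t_own.transform(x)
                Jcol = np.linalg.norm(t_other.spatial_jacobian(y), axis=1)  # (P, n)
                comp = np.zeros((n_cp, n))
                np.add.at(comp, flat, (w[:, None] * bw)[:, :, None] * Jcol[:, None, :])
                g += lam * comp
        if lam > 0 and batch_other.kept.any():
            xo = batch_other.points_phys[batch_other.kept]
            wo = batch_other.weights[batch_other.kept]
            yo = t_other.transform(xo)
            flat_o, bw_o, _ = t_own.support_weights(yo)
            outer = np.zeros(n_cp)
            np.add.at(outer, flat_o, wo[:, None] * bw_o)
            g += lam * outer[:, None]
        return g.ravel()

    gamma_ab = gamma_for(pair.t_ab, pair.t_ba, report.batch_a, report.batch_b)
    gamma_ba = gamma_for(pair.t_ba, pair.t_ab, report.batch_b, report.batch_a)
    return gamma_ab, gamma_ba


def scale_factor(pair: ObjectivePair, report: ObjectiveReport, i: int) -> float:
    """gamma for a single parameter of T_AB (see derivative_scales)."""
    return float(derivative_scales(pair, report)[0][i])


def sgdm_step(state: SGDMState, params: np.ndarray, gradient: np.ndarray, scales=None):
    """One heavy-ball update on a flat parameter vector (in place)."""
    g = gradient if scales is None else gradient / (scales + state.eps)
    if state.velocity is None:
        state.velocity = np.zeros_like(params)
    state.velocity = state.momentum * state.velocity - state.step_size * g
    params += state.velocity
    return params


@dataclass
class StageTrace:
    """Per-iteration log of one optimization stage."""

    J: list = field(default_factory=list)
    components: list = field(default_factory=list)

    def as_rows(self):
        return [
            (i, j) + tuple(c) for i, (j, c) in enumerate(zip(self.J, self.components))
        ]


def run_stage(
    image_a,
    image_b,
    trees_a,
    trees_b,
    pair: ObjectivePair,
    sampler_a,
    sampler_b,
    mc: MCConfig,
    iterations: int,
    step_size: float,
    momentum: float,
    rng: np.random.Generator,
    eps: float = 0.01,
) -> StageTrace:
    """Jointly optimize T_AB and T_BA for one coarse-to-fine stage.

    Each iteration redraws sample points and cut levels, evaluates the
    objective and its gradients, rescales per parameter and applies one
    SGDM update to both parameter vectors.  Velocities start at zero (fresh
    state per stage).  Non-finite objective or gradients abort with a
    diagnostic.
    """
    trace = StageTrace()
    state_ab = SGDMState(step_size, momentum, eps)
    state_ba = SGDMState(step_size, momentum, eps)
    n_a = sampler_a.count_per_iteration
    n_b = sampler_b.count_per_iteration
    for it in range(iterations):
        pts_a, _ = sampler_a.draw(n_a, rng)
        pts_b, _ = sampler_b.draw(n_b, rng)
        report = total_objective(
            pair, image_a, image_b, trees_a, trees_b, pts_a, pts_b, mc, rng=rng
        )
        if not np.isfinite(report.J) or not (
            np.all(np.isfinite(report.grad_ab)) and np.all(np.isfinite(report.grad_ba))
        ):
            raise FloatingPointError(f"non-finite objective/gradient at iteration {it}")
        gamma_ab, gamma_ba = derivative_scales(pair, report)
        sgdm_step(state_ab, pair.t_ab.coeffs.ravel(), report.grad_ab_raw, gamma_ab)
        sgdm_step(state_ba, pair.t_ba.coeffs.ravel(), report.grad_ba_raw, gamma_ba)
        trace.J.append(report.J)
        trace.components.append(report.components)
    return trace
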