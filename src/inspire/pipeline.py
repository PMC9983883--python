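"""End-to-end coarse-to-fine registration driver.

A registration is a sequence of stages.  Each stage works on one level of a
Gaussian resolution pyramid with one control-mesh density: the inputs are
smoothed and downsampled, alpha-trees are built for both images and their
complements, the transformation pair is refined to the stage's control
count, and a fixed number of SGDM iterations is run.  Fields live in
physical coordinates, so a field estimated on a coarse level applies
unchanged on finer levels.

Convention: with floating image A and reference image B, ``T_AB`` maps
floating-image coordinates into reference space; rendering the floating
image on the reference grid therefore samples it at ``T_BA(y)``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import yaml
from scipy import ndimage
from skimage import exposure
from skimage.measure import block_reduce

from .bspline import BSplineField
from .fuzzy import FuzzyImage, build_trees, _corner_cell
from .objective import MCConfig, ObjectivePair, aw_iic, directed_amd
from .optimizer import StageTrace, run_stage
from .sampling import PointSampler, SamplerConfig


@dataclass
class StageLevel:
    """One coarse-to-fine level of the schedule."""

    subsampling_factor: int = 1
    sigma: float = 0.0
    control_points: int = 8
    iterations: int = 100
    sampling_fraction: float = 0.05
    d_max_fraction: float = 0.1  # of the image diameter
    step_size: float = 1.0
    momentum: float = 0.3
    gw_m: float = 0.5
    gw_sigma: float = 2.0


@dataclass
class StageSchedule:
    """Ordered per-level records plus global constants.

    Levels must run coarse to fine: non-increasing subsampling factors are
    not required, but control counts must be non-decreasing.
    """

    levels: list
    lam: float = 0.0
    n_alpha: int = 7
    q: float = 0.0  # robust-normalization percentile
    histeq: bool = False
    histeq_bins: int = 256
    beta: float = 1.0
    d_t: float = 0.0
    t_gm: float = 0.0
    gradient_mode: str = "midpoint"

    def __post_init__(self):
        cps = [lv.control_points for lv in self.levels]
        if any(b < a for a, b in zip(cps, cps[1:])):
            raise ValueError("control-point counts must be non-decreasing")
        if any(lv.subsampling_factor < 1 for lv in self.levels):
            raise ValueError("subsampling factors must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "StageSchedule":
        levels = [StageLevel(**lv) for lv in d["levels"]]
        extra = {k: v for k, v in d.items() if k != "levels"}
        return cls(levels=levels, **extra)

    def to_dict(self) -> dict:
        return {
            "levels": [vars(lv) for lv in self.levels],
            **{
                k: getattr(self, k)
                for k in ("lam", "n_alpha", "q", "histeq", "histeq_bins", "beta", "d_t",
                          "t_gm", "gradient_mode")
            },
        }

    @classmethod
    def load(cls, path) -> "StageSchedule":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def save(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_preset(name: str) -> StageSchedule:
    """Load a shipped schedule preset (``retinal``, ``fire``, ``brain3d``,
    ``phantom``)."""
    ref = importlib.resources.files("inspire") / "presets" / f"{name}.yaml"
    return StageSchedule.from_dict(yaml.safe_load(ref.read_text()))


# ----------------------------------------------------------------------
# Preprocessing and pyramids
# ----------------------------------------------------------------------
def preprocess(
    image,
    q: float = 0.0,
    histeq: bool = False,
    bins: int = 256,
    spacing=None,
    mask=None,
) -> FuzzyImage:
    """Robust normalization to [0, 1] with optional histogram equalization.

    Intensities are clipped at the q and (100 - q) percentiles and scaled
    to the unit interval; a constant image maps to all zeros.
    """
    if not 0.0 <= q < 50.0:
        raise ValueError("percentile q must be in [0, 50)")
    arr = np.asarray(image, dtype=np.float64)
    lo, hi = np.percentile(arr, [q, 100.0 - q])
    if hi <= lo:
        mem = np.zeros_like(arr)
    else:
        mem = np.clip((arr - lo) / (hi - lo), 0.0, 1.0)
        if histeq:
            mem = exposure.equalize_hist(mem, nbins=bins)
    return FuzzyImage(mem, spacing, mask=mask)


def fundus_preprocess(image, sigma: float = 10.0, q_lo: float = 0.01, q_hi: float = 0.75):
    """Optional preset for fundus-like inputs: channel averaging, Gaussian
    bias-field subtraction, robust normalization at asymmetric percentiles."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3].mean(axis=-1)
    arr = arr - ndimage.gaussian_filter(arr, sigma)
    lo, hi = np.percentile(arr, [q_lo, 100.0 - q_hi])
    if hi <= lo:
        return np.zeros_like(arr)
    return np.clip((arr - lo) / (hi - lo), 0.0, 1.0)


def pyramid_level(image: FuzzyImage, factor: int, sigma: float) -> FuzzyImage:
    """One Gaussian pyramid level: smooth with `sigma` (0 = none), then
    block-mean downsample by `factor`; masks downsample by majority vote."""
    mem = image.memberships
    if sigma > 0:
        mem = ndimage.gaussian_filter(mem, sigma, mode="reflect")
    mask = image.mask
    if factor > 1:
        crop = tuple(slice(0, (s // factor) * factor) for s in mem.shape)
        mem = block_reduce(mem[crop], (factor,) * mem.ndim, np.mean)
        if mask is not None:
            mask = block_reduce(mask[crop].astype(float), (factor,) * mem.ndim, np.mean) > 0.5
    mem = np.clip(mem, 0.0, 1.0)
    return FuzzyImage(mem, image.spacing * factor, mask=mask)


def build_pyramid(image: FuzzyImage, schedule: StageSchedule):
    """Per-level preprocessed images, ordered as the schedule's levels."""
    return [
        pyramid_level(image, lv.subsampling_factor, lv.sigma) for lv in schedule.levels
    ]


# ----------------------------------------------------------------------
# Registration driver
# ----------------------------------------------------------------------
@dataclass
class RegistrationResult:
    t_ab: BSplineField  # floating -> reference
    t_ba: BSplineField  # reference -> floating
    traces: list
    levels: list = dc_field(default_factory=list)


def register(
    reference,
    floating,
    schedule: StageSchedule,
    rng,
    ref_mask=None,
    flo_mask=None,
    spacing=None,
    preprocessed: bool = False,
    callback=None,
) -> RegistrationResult:
    """Symmetric deformable registration of a floating image to a reference.

    Raw intensity arrays (or FuzzyImages if ``preprocessed=True``) are
    normalized, pyramided, and registered through the schedule's stages.
    Two runs with the same seed and schedule are bit-identical.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if preprocessed:
        img_a, img_b = floating, reference
    else:
        img_a = preprocess(floating, schedule.q, schedule.histeq, schedule.histeq_bins,
                           spacing, flo_mask)
        img_b = preprocess(reference, schedule.q, schedule.histeq, schedule.histeq_bins,
                           spacing, ref_mask)
    if img_a.ndim != img_b.ndim:
        raise ValueError("images must share dimensionality")
    pyr_a = build_pyramid(img_a, schedule)
    pyr_b = build_pyramid(img_b, schedule)

    first = schedule.levels[0]
    n = img_a.ndim
    t_ab = BSplineField.for_domain(img_a.shape, img_a.spacing, (first.control_points,) * n)
    t_ba = BSplineField.for_domain(img_b.shape, img_b.spacing, (first.control_points,) * n)
    traces = []
    for li, lv in enumerate(schedule.levels):
        a, b = pyr_a[li], pyr_b[li]
        if li > 0 and lv.control_points != schedule.levels[li - 1].control_points:
            t_ab = t_ab.refine((lv.control_points,) * n)
            t_ba = t_ba.refine((lv.control_points,) * n)
        trees_a = build_trees(a)
        trees_b = build_trees(b)
        mc = MCConfig(
            n_alpha=schedule.n_alpha,
            d_max=lv.d_max_fraction * b.diameter,
            d_t=schedule.d_t,
            beta=schedule.beta,
            gradient_mode=schedule.gradient_mode,
        )
        cfg = SamplerConfig(
            m=lv.gw_m, sigma_gm=lv.gw_sigma, t_gm=schedule.t_gm,
            fraction=lv.sampling_fraction,
        )
        pair = ObjectivePair(
            t_ab, t_ba, lam=schedule.lam,
            mask_a=a.mask, mask_b=b.mask,
            weights_a=a.weights, weights_b=b.weights,
        )
        trace = run_stage(
            a, b, trees_a, trees_b, pair,
            PointSampler(a, cfg), PointSampler(b, cfg),
            mc, lv.iterations, lv.step_size, lv.momentum, rng,
        )
        traces.append(trace)
        if callback is not None:
            callback(li, pair, trace)
    return RegistrationResult(t_ab, t_ba, traces, levels=[vars(lv) for lv in schedule.levels])


def mean_iic(t_ab: BSplineField, t_ba: BSplineField, shape, spacing, stride: int = 4):
    """Mean round-trip inverse inconsistency over a regular grid (both
    directions averaged); an evaluation metric, not a training term."""
    axes = [np.arange(0, s, stride) * sp for s, sp in zip(shape, np.atleast_1d(spacing))]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, len(shape))
    v_ab, _, _ = aw_iic(t_ab, t_ba, grid)
    v_ba, _, _ = aw_iic(t_ba, t_ab, grid)
    return 0.5 * (v_ab + v_ba)


# ----------------------------------------------------------------------
# Warping and landmark transfer
# ----------------------------------------------------------------------
def warp(
    image,
    result_or_field,
    direction: str = "flo-to-ref",
    interpolation: str = "linear",
    spacing=None,
):
    """Resample an image through the symmetric pair (pull-back sampling).

    To render the floating image on the reference grid, each reference grid
    point y is sampled at ``T_BA(y)`` (linear for intensities, nearest for
    masks and label maps); ``direction="ref-to-flo"`` reverses the roles.
    """
    arr = np.asarray(image)
    if isinstance(result_or_field, RegistrationResult):
        fld = result_or_field.t_ba if direction == "flo-to-ref" else result_or_field.t_ab
    else:
        fld = result_or_field
    spacing = np.ones(arr.ndim) if spacing is None else np.atleast_1d(spacing)
    axes = [np.arange(s) * sp for s, sp in zip(arr.shape, spacing)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, arr.ndim)
    mapped = fld.transform(grid) / spacing  # to index coordinates
    order = 1 if interpolation == "linear" else 0
    out = ndimage.map_coordinates(
        arr.astype(np.float64), mapped.T, order=order, mode="constant", cval=0.0
    )
    out = out.reshape(arr.shape)
    if interpolation != "linear":
        out = out.astype(arr.dtype)
    return out


def transform_landmarks(points, field: BSplineField):
    """Map landmark coordinates (physical) through a transformation field."""
    return field.transform(points)


# ----------------------------------------------------------------------
# Coarse rigid pre-alignment (plain grid search)
# ----------------------------------------------------------------------
@dataclass
class RigidTransform:
    """2-D rotation about the image center plus a translation."""

    angle: float  # radians
    translation: np.ndarray
    center: np.ndarray

    def transform(self, points):
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        c, s = np.cos(self.angle), np.sin(self.angle)
        R = np.array([[c, -s], [s, c]])
        return (pts - self.center) @ R.T + self.center + self.translation


def rigid_prealign(
    reference: FuzzyImage,
    floating: FuzzyImage,
    angles,
    min_overlap: float = 0.4,
    downsample: int = 4,
    translation_step: int = 2,
    translation_range: Optional[int] = None,
    n_alpha: int = 7,
) -> RigidTransform:
    """Exhaustive coarse grid search for a rigid initialization (2-D).

    Candidate poses combine the given rotation angles with a translation
    grid at `downsample`-reduced resolution; each is scored by the directed
    alpha-AMD of the transformed floating samples into the reference, with
    full-domain sampling.  Candidates whose mask overlap falls below
    `min_overlap` are rejected; if none is admissible an error is raised.
    """
    if reference.ndim != 2:
        raise ValueError("rigid pre-alignment is implemented for 2-D images")
    ref = pyramid_level(reference, downsample, 0.0)
    flo = pyramid_level(floating, downsample, 0.0)
    trees_ref = build_trees(ref)
    mc = MCConfig(n_alpha=n_alpha, d_max=0.25 * ref.diameter)
    alphas = (0.5 + np.arange(n_alpha)) / n_alpha
    pts_idx = np.stack(np.meshgrid(*[np.arange(s) for s in flo.shape], indexing="ij"),
                       axis=-1).reshape(-1, 2)
    src = pts_idx * flo.spacing
    heights = flo.memberships[tuple(pts_idx.T)]
    mask_f = (flo.mask[tuple(pts_idx.T)] if flo.mask is not None
              else np.ones(len(pts_idx), bool))
    center = 0.5 * flo.extent
    extent = ref.extent
    if translation_range is None:
        translation_range = int(min(ref.shape) // 4)
    steps = np.arange(-translation_range, translation_range + 1, translation_step)
    best, best_score = None, np.inf
    from .fuzzy import _interp_value, corner_distance_tables

    for ang in np.atleast_1d(angles):
        c, s = np.cos(ang), np.sin(ang)
        R = np.array([[c, -s], [s, c]])
        rot = (src - center) @ R.T + center
        for tx in steps * ref.spacing[0]:
            for ty in steps * ref.spacing[1]:
                tp = rot + np.array([tx, ty])
                inside = np.all((tp >= 0) & (tp <= extent), axis=1)
                if ref.mask is not None:
                    idx = np.clip(np.round(tp / ref.spacing).astype(int), 0,
                                  np.array(ref.shape) - 1)
                    inside &= ref.mask[tuple(idx.T)]
                kept = inside & mask_f
                overlap = kept.sum() / max(mask_f.sum(), 1)
                if overlap < min_overlap:
                    continue
                D, base, u, ins = corner_distance_tables(
                    tp[kept], heights[kept], trees_ref, alphas, mc.d_max
                )
                score = float(np.mean(_interp_value(D, u)))
                if score < best_score:
                    best_score = score
                    best = RigidTransform(float(ang), np.array([tx, ty]), center)
    if best is None:
        raise RuntimeError("no admissible pose: all candidates below the overlap floor")
    return best
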