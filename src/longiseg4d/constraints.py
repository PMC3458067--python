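"""Coupling constraints between level sets and across time points.

Two band penalties act on the signed-distance fields:

* **Cortical thickness**: on the WM/GM interface (zero set of phi1) the value
  of phi2 is the local GM thickness; it is pushed into a plausible band
  [d_min, d_max] mm (default 1–6.5 mm), and symmetrically phi1 evaluated on
  the GM/CSF interface is pushed into [-d_max, -d_min].
* **Longitudinal consistency**: the current interface is pushed to lie
  between the -epsilon and +epsilon level sets of interfaces warped from the
  other time points of the same subject (default epsilon 1.5 mm), weighted
  per source time point.

Both penalties are region-based: a C1 one-sided quadratic band-violation
profile of the partner (or warped reference) signed distance is integrated
over the region membership of the constrained field, so they are zero with
identically zero force exactly when the configuration is in band, and their
pointwise forces advect the zero set straight back into band without the
curvature-shrink bias an interface-integral (geodesic) form would add.  A
compact-support Heaviside/delta pair keeps the in-band zero exact.  Forces
are exact gradients of the discrete sums.

Time-point weights grow with source age (later scans have higher tissue
contrast and guide more strongly) and decay with temporal distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import (
    LevelSetField,
    compact_heaviside,
    cosine_delta,
    reinitialize,
)

__all__ = [
    "ThicknessRange",
    "LongitudinalRange",
    "TemporalWeights",
    "band_hinge",
    "band_hinge_prime",
    "thickness_penalty",
    "temporal_weights",
    "warp_image",
    "warp_levelset",
    "longitudinal_penalty",
]

logger = logging.getLogger(__name__)

_GRAD_FLOOR = 1e-8


@dataclass
class ThicknessRange:
    """Acceptable cortical thickness band [d_min, d_max] in mm."""

    d_min: float = 1.0
    d_max: float = 6.5

    def __post_init__(self):
        if not (0 < self.d_min < self.d_max):
            raise ValueError("thickness range requires 0 < d_min < d_max")


@dataclass
class LongitudinalRange:
    """Symmetric allowed displacement band +/- epsilon (mm) across time."""

    epsilon: float = 1.5

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("longitudinal epsilon must be >= 0")


@dataclass
class TemporalWeights:
    """Normalized per-source weights for one target time point."""

    indices: tuple[int, ...]
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.indices) != self.weights.size:
            raise ValueError("indices and weights must align")
        if self.weights.size and (np.any(self.weights < 0)):
            raise ValueError("weights must be nonnegative")

    def as_dict(self) -> dict[int, float]:
        return {i: float(w) for i, w in zip(self.indices, self.weights)}


def band_hinge(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """One-sided quadratic band violation: (v-lo)^2 below, (v-hi)^2 above, 0 in band."""
    v = np.asarray(v, dtype=float)
    below = np.minimum(v - lo, 0.0)
    above = np.maximum(v - hi, 0.0)
    return below * below + above * above


def band_hinge_prime(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return 2.0 * np.minimum(v - lo, 0.0) + 2.0 * np.maximum(v - hi, 0.0)


def _below_sq(v: np.ndarray, a: float):
    """((v - a)^-)^2 and its derivative: penalizes values below a."""
    d = np.minimum(v - a, 0.0)
    return d * d, 2.0 * d


def _above_sq(v: np.ndarray, b: float):
    """((v - b)^+)^2 and its derivative: penalizes values above b."""
    d = np.maximum(v - b, 0.0)
    return d * d, 2.0 * d


def thickness_penalty(
    phi1: LevelSetField,
    phi2: LevelSetField,
    rng: ThicknessRange,
    eps: float,
    scale: float = 1.0,
):
    """Cortical-thickness band energy and forces on (phi1, phi2).

    Region-based one-sided quadratic band penalty.  With both fields signed
    distances, phi2 evaluated inside the WM region measures the remaining GM
    envelope; the energy

        E = sum H(phi1) ((phi2 - d_min)^-)^2
          + (1-H(phi1)) H(phi2) ((phi2 - d_max)^+)^2
          + (1-H(phi2)) ((phi1 + d_min)^+)^2
          + (1-H(phi1)) H(phi2) ((phi1 + d_max)^-)^2    (times voxel volume)

    penalizes WM interior closer than d_min to the GM/CSF interface, GM band
    deeper than d_max, and mirrors both constraints onto phi1 as seen from
    outside the GM envelope.  It is zero, with identically zero forces, on
    any nested geometry whose band lies in [d_min, d_max]; violations are
    penalized quadratically and the (pointwise, exact-gradient) forces push
    both interfaces back into band.  A compact-support Heaviside keeps the
    in-band zero exact.

    ``scale`` converts the hinge from mm^2 into energy units; for the
    constraint to actually bind against the data term it must make a
    voxel-scale violation cost comparable to strong intensity evidence (the
    evolution config supplies ~100 per mm^2).
    """
    vol = float(np.prod(phi1.spacing)) * scale
    v1, v2 = phi1.values, phi2.values
    h1 = compact_heaviside(v1, eps)
    h2 = compact_heaviside(v2, eps)
    d1 = cosine_delta(v1, eps)
    d2 = cosine_delta(v2, eps)

    thin, thin_p = _below_sq(v2, rng.d_min)          # GM band < d_min (seen from WM)
    thick, thick_p = _above_sq(v2, rng.d_max)        # GM band > d_max (seen in GM)
    near, near_p = _above_sq(v1, -rng.d_min)         # Gamma1 too close, seen outside Gamma2
    far, far_p = _below_sq(v1, -rng.d_max)           # Gamma1 too far, seen in GM

    gm = (1.0 - h1) * h2
    energy = float(np.sum(h1 * thin + gm * thick + (1.0 - h2) * near + gm * far) * vol)

    f1 = (
        d1 * thin
        - d1 * h2 * thick
        + (1.0 - h2) * near_p
        - d1 * h2 * far
        + gm * far_p
    )
    f2 = (
        h1 * thin_p
        + d2 * (1.0 - h1) * thick
        + gm * thick_p
        - d2 * near
        + d2 * (1.0 - h1) * far
    )
    return energy, f1 * vol, f2 * vol


def temporal_weights(
    ages: list[float],
    target_index: int,
    tau_age: float = 3.0,
    tau_dist: float = 6.0,
) -> TemporalWeights:
    """Guidance weights of the other time points for one target.

    w_s  proportional to  exp(age_s / tau_age - |age_s - age_t| / tau_dist),
    normalized over sources != target.  With tau_age <= tau_dist the weights
    are non-decreasing in source age (the last, highest-contrast scan is
    always the strongest guide) while still decaying with temporal distance
    between same-age candidates.  A single time point yields empty weights.
    """
    ages_arr = np.asarray(ages, dtype=float)
    if np.any(np.diff(ages_arr) <= 0):
        raise ValueError("ages must be strictly increasing")
    if not (0 <= target_index < ages_arr.size):
        raise IndexError("target_index out of range")
    if ages_arr.size < 2:
        return TemporalWeights(indices=(), weights=np.empty(0))
    src = [i for i in range(ages_arr.size) if i != target_index]
    t = ages_arr[target_index]
    raw = np.exp(ages_arr[src] / tau_age - np.abs(ages_arr[src] - t) / tau_dist)
    return TemporalWeights(indices=tuple(src), weights=raw / raw.sum())


def warp_image(
    values: np.ndarray,
    deformation: np.ndarray,
    spacing,
    order: int = 1,
) -> np.ndarray:
    """Resample ``values`` at x + u(x); u in mm maps the target grid into the
    source domain.  Out-of-domain samples use nearest-edge extension."""
    spacing = np.atleast_1d(np.asarray(spacing, dtype=float))
    if deformation.shape[0] != values.ndim:
        raise ValueError("deformation must have one component per axis")
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in values.shape], indexing="ij")
    coords = [g + deformation[ax] / spacing[ax] for ax, g in enumerate(grids)]
    oob = np.zeros(values.shape, dtype=bool)
    for ax, c in enumerate(coords):
        oob |= (c < 0) | (c > values.shape[ax] - 1)
    if np.any(oob):
        logger.info("warp: %d samples outside domain, nearest-edge extended", int(oob.sum()))
    return ndimage.map_coordinates(values, coords, order=order, mode="nearest")


def warp_levelset(phi_source: LevelSetField, deformation: np.ndarray) -> LevelSetField:
    """Warp a signed-distance field by a deformation and re-distance it.

    Interpolation breaks the eikonal property, so the warped field is
    reinitialized; its zero set maps consistently with warped labels.
    """
    warped = warp_image(phi_source.values, deformation, phi_source.spacing, order=1)
    return reinitialize(LevelSetField(warped, phi_source.spacing))


def longitudinal_penalty(
    phi_current: LevelSetField,
    warped: list[LevelSetField],
    weights: TemporalWeights | np.ndarray,
    rng: LongitudinalRange,
    eps: float,
    scale: float = 1.0,
):
    """Longitudinal band energy and force on the current field.

    Region-based band penalty against warped reference signed distances
    phi~_s with per-source weights w_s:

        E = sum_s w_s sum_x [ H(phi) ((phi~_s + eps)^-)^2
                            + (1-H(phi)) ((phi~_s - eps)^+)^2 ] * voxvol

    Zero, with identically zero force, iff the current interface falls
    between the -epsilon and +epsilon level sets of every reference (no
    interior voxel that a reference puts farther than epsilon outside, and
    vice versa).  Violations are penalized quadratically; the force
    delta(phi) (R - S) advects the zero set toward the band.  Linear in the
    weights; an empty reference list gives zero energy and force.
    """
    w = weights.weights if isinstance(weights, TemporalWeights) else np.asarray(weights, float)
    if len(warped) != np.size(w):
        raise ValueError("one weight per warped reference required")
    vals = phi_current.values
    if not warped:
        return 0.0, np.zeros_like(vals)
    vol = float(np.prod(phi_current.spacing)) * scale
    h = compact_heaviside(vals, eps)
    d = cosine_delta(vals, eps)
    inside_cost = np.zeros_like(vals)   # interior voxels the reference puts far outside
    outside_cost = np.zeros_like(vals)  # exterior voxels the reference puts far inside
    for ws, ref in zip(np.ravel(w), warped):
        r, _ = _below_sq(ref.values, -rng.epsilon)
        s, _ = _above_sq(ref.values, rng.epsilon)
        inside_cost += ws * r
        outside_cost += ws * s
    energy = float(np.sum(h * inside_cost + (1.0 - h) * outside_cost) * vol)
    force = d * (inside_cost - outside_cost) * vol
    return energy, force
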