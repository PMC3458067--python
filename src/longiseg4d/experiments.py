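"""Benchmark experiments on synthetic longitudinal phantoms.

Each function builds a phantom under fixed study conditions, runs the model,
and returns the measured quantities.  They are the substance behind the
validation suite and the reproduction script; problem sizes (2D grids of
96-128 voxels per side, five time points) are chosen so a full pass runs on
a laptop in minutes.
"""

from __future__ import annotations

import copy
import warnings

import numpy as np

from .constraints import LongitudinalRange
from .evolution import (
    EvolutionConfig,
    evolve_single_timepoint,
    initialize_series,
    run_4d_pipeline,
)
from .fitting import MultiModalImage
from .geometry import LevelSetTriple, signed_distance_from_mask
from .model import CoupledLevelSetModel
from .phantom import (
    PhantomSpec,
    _smooth_random_field,
    dice_ratio,
    generate_phantom,
    gm_band_widths,
    high_contrast_means,
    make_atlas,
    pairwise_deformation,
    temporal_consistency,
)

__all__ = [
    "high_contrast_recovery",
    "fa_benefit",
    "longitudinal_benefit",
    "epsilon_sweep",
    "thickness_pinch",
    "series_spec",
]

TISSUES = (("wm", 3), ("gm", 2), ("csf", 1))


def high_contrast_recovery(seed: int, shape=(128, 128)) -> dict[str, float]:
    """Single-scan recovery of a well-separated phantom (SNR 10).

    One T1-like channel, adult-like age, ~5 noise-SD separation between
    adjacent tissue classes; returns per-tissue Dice against ground truth.
    """
    spec = PhantomSpec(
        shape=shape, ages=(12.0,), channels=("t1",), seed=seed,
        deformation_mm=0.0, tissue_means=high_contrast_means(),
    )
    sample = generate_phantom(spec)[0]
    result = CoupledLevelSetModel(sample.image, None, EvolutionConfig()).fit()
    return result.dice(sample.labels)


def fa_benefit(seed: int, shape=(128, 128)) -> dict[str, float]:
    """WM recovery at the isointense age with vs without the FA channel.

    T1 and T2 WM/GM means are exactly equal at the isointense age, so the
    only WM/GM intensity information is in FA; both runs share a blurred
    population-style prior.  Returns the two WM Dice values and their gap.
    """
    spec = PhantomSpec(shape=shape, ages=(7.0,), seed=seed, deformation_mm=0.0)
    sample = generate_phantom(spec)[0]
    atlas = make_atlas(sample.labels, sample.image.spacing)
    img2 = MultiModalImage(
        sample.image.channels[:2], sample.image.spacing, age_months=7.0
    )
    wm3 = CoupledLevelSetModel(sample.image, atlas, EvolutionConfig()).fit().dice(sample.labels)["wm"]
    wm2 = CoupledLevelSetModel(img2, atlas, EvolutionConfig()).fit().dice(sample.labels)["wm"]
    return {"wm_with_fa": wm3, "wm_without_fa": wm2, "gap": wm3 - wm2}


def series_spec(seed: int, shape=(128, 128)) -> PhantomSpec:
    """Standard five-age longitudinal series for the 4D experiments.

    T1+T2 only (the hard, FA-less condition), 1 mm inter-age deformations,
    and a regionally varying GM thickness profile the blurred prior cannot
    encode - the situation the longitudinal constraint exists for.
    """
    small = min(shape) < 128
    return PhantomSpec(
        shape=shape, channels=("t1", "t2"), seed=seed, deformation_mm=1.0,
        gm_thickness_amp_mm=1.8, gm_thickness_freq=4,
        wm_radius_mm=22.0 if small else 26.0,
        wm_wave_amp_mm=3.0 if small else 4.0,
        csf_thickness_mm=3.5 if small else 4.0,
    )


def _series_inputs(spec: PhantomSpec):
    samples = generate_phantom(spec)
    images = [s.image for s in samples]
    atlases = [make_atlas(s.labels, s.image.spacing) for s in samples]
    n = len(samples)
    defs = {
        (t, s): pairwise_deformation(samples, t, s)
        for t in range(n) for s in range(n) if s != t
    }
    truths = [s.labels for s in samples]
    return samples, images, atlases, defs, truths


def longitudinal_benefit(seed: int, shape=(128, 128)) -> dict[str, float]:
    """Guided vs unguided refinement of a five-age series, equal budgets.

    Both runs start from the same per-scan initial fits and spend the same
    refinement iterations; only the guided run sees interfaces warped from
    the other time points (known ground-truth correspondences).  Reports WM
    Dice at the most isointense age (6 months) and the cross-age warped-label
    consistency for both runs.
    """
    spec = series_spec(seed, shape)
    samples, images, atlases, defs, truths = _series_inputs(spec)
    iso = int(np.argmin([abs(a - 7.0) for a in spec.ages]))

    init = initialize_series(images, atlases, EvolutionConfig())
    out = {}
    for tag, w in (("unguided", 0.0), ("guided", None)):
        cfg = EvolutionConfig() if w is None else EvolutionConfig(weight_longitudinal=w)
        state = run_4d_pipeline(
            images, atlases, cfg, deformations=defs, state=copy.deepcopy(init)
        )
        labels = state.labels()
        out[f"iso_wm_{tag}"] = dice_ratio(labels[iso], truths[iso], 3)
        out[f"iso_gm_{tag}"] = dice_ratio(labels[iso], truths[iso], 2)
        out[f"consistency_{tag}"] = temporal_consistency(labels, samples)
        out[f"mean_wm_{tag}"] = float(
            np.mean([dice_ratio(l, t, 3) for l, t in zip(labels, truths)])
        )
    out["iso_wm_gain"] = out["iso_wm_guided"] - out["iso_wm_unguided"]
    out["consistency_gain"] = out["consistency_guided"] - out["consistency_unguided"]
    return out


def epsilon_sweep(
    seed: int,
    shape=(96, 96),
    eps_values=(0.0, 0.5, 1.5, 3.0),
    registration_error_rms_mm: float = 1.0,
) -> dict[float, float]:
    """Isointense WM Dice as a function of the longitudinal band width.

    Ground-truth correspondences are corrupted by a smooth random field of
    the given RMS amplitude (emulating registration error); one shared
    initialization is refined once per band width.  The reference behaviour
    is an inverted, flat-bottomed U over epsilon: a zero band drags
    registration errors into the segmentation, a too-wide band gives no
    guidance.
    """
    spec = series_spec(seed, shape)
    samples, images, atlases, defs, truths = _series_inputs(spec)
    iso = int(np.argmin([abs(a - 7.0) for a in spec.ages]))
    rng = np.random.default_rng(seed + 1000)
    noisy = {}
    for key, u in defs.items():
        err = np.stack([
            _smooth_random_field(rng, spec.shape, spec.spacing, 12.0)
            for _ in range(len(spec.shape))
        ])
        err *= registration_error_rms_mm / np.sqrt(np.mean(err**2))
        noisy[key] = u + err

    init = initialize_series(images, atlases, EvolutionConfig(max_outer_iter=1))
    out = {}
    for eps in eps_values:
        cfg = EvolutionConfig(max_outer_iter=1)
        cfg.longitudinal = LongitudinalRange(eps)
        state = run_4d_pipeline(
            images, atlases, cfg, deformations=noisy, state=copy.deepcopy(init)
        )
        out[float(eps)] = dice_ratio(state.labels()[iso], truths[iso], 3)
    return out


def thickness_pinch(seed: int) -> dict[str, float]:
    """Minimum GM band width with and without the thickness constraint.

    An isointense phantom (no WM/GM intensity information) carries a focal
    0.4 mm GM pinch; both runs start from the true pinched geometry at
    0.5 mm spacing.  The constrained run must re-open the band toward d_min,
    the unconstrained run has no reason to.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # the pinch leaves the plausible band on purpose
        spec = PhantomSpec(
            shape=(128, 128), spacing=0.5, ages=(7.0,), seed=seed,
            channels=("t1", "t2"), deformation_mm=0.0, bias_sigma_mm=12.0,
            wm_radius_mm=16.0, wm_wave_amp_mm=2.5, csf_thickness_mm=3.0,
            gm_thickness_mm=3.0, pinch_depth_mm=2.6, pinch_angle=1.2, pinch_width=0.5,
        )
        sample = generate_phantom(spec)[0]
    m1 = sample.labels == 3
    m2 = m1 | (sample.labels == 2)
    m3 = m2 | (sample.labels == 1)
    sp = sample.image.spacing
    init = LevelSetTriple(*[signed_distance_from_mask(m, sp) for m in (m1, m2, m3)])
    out = {}
    for tag, cfg in (
        ("constrained", EvolutionConfig(max_inner_iter=200)),
        ("unconstrained", EvolutionConfig(weight_thickness=0.0, max_inner_iter=200)),
    ):
        ls, _ = evolve_single_timepoint(sample.image, init.copy(), None, cfg)
        out[f"min_band_{tag}"] = float(gm_band_widths(ls).min())
    out["threshold"] = 1.0 - 0.5 * min(sp)  # d_min minus half a voxel
    return out
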