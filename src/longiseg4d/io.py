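"""NIfTI readers/writers, configuration serialization and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .constraints import LongitudinalRange, ThicknessRange
from .evolution import EvolutionConfig, TimeSeriesState
from .fitting import AtlasPrior, MultiModalImage
from .phantom import dice_ratio

__all__ = [
    "read_multimodal",
    "read_atlas",
    "read_labels",
    "write_nifti",
    "write_outputs",
    "RunManifest",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
]

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def _default_affine(spacing, ndim3=True):
    aff = np.eye(4)
    for i, s in enumerate(spacing[:3]):
        aff[i, i] = s
    return aff


def _load_volume(path):
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    # squeeze a trailing singleton so 2D test volumes round-trip
    if data.ndim == 3 and data.shape[-1] == 1:
        data = data[..., 0]
    return data, img.affine, img.header.get_zooms()


def read_multimodal(paths: list[str | Path], age_months: float = 0.0) -> MultiModalImage:
    """Load co-registered channel volumes (order T1, T2, FA) as one stack.

    All channels must share grid shape, voxel spacing and affine; violations
    raise with the offending channel named.  Voxel spacing (mm) comes from
    the NIfTI header; the world affine of the first channel is preserved.
    """
    if not paths:
        raise ValueError("at least one channel path required")
    channels = []
    ref_shape = ref_aff = ref_zoom = None
    for i, p in enumerate(paths):
        data, aff, zooms = _load_volume(p)
        if not np.all(np.isfinite(data)):
            raise ValueError(f"channel {i} ({p}): non-finite voxels")
        if ref_shape is None:
            ref_shape, ref_aff, ref_zoom = data.shape, aff, zooms
        else:
            if data.shape != ref_shape:
                raise ValueError(
                    f"channel {i} ({p}): grid {data.shape} != {ref_shape} of channel 0"
                )
            if not np.allclose(aff, ref_aff, atol=1e-4):
                raise ValueError(f"channel {i} ({p}): affine differs from channel 0")
        channels.append(data)
    spacing = tuple(float(z) for z in ref_zoom[: channels[0].ndim])
    return MultiModalImage(
        channels=np.stack(channels), spacing=spacing, age_months=age_months, affine=ref_aff
    )


def read_atlas(paths: list[str | Path]) -> AtlasPrior:
    """Load the 4 prior probability volumes, order WM, GM, CSF, BG."""
    if len(paths) != 4:
        raise ValueError("atlas prior requires 4 volumes (WM, GM, CSF, BG)")
    maps = [_load_volume(p)[0] for p in paths]
    return AtlasPrior(np.stack(maps))


def read_labels(path: str | Path) -> np.ndarray:
    data, _, _ = _load_volume(path)
    return np.rint(data).astype(np.uint8)


def write_nifti(arr: np.ndarray, path: str | Path, spacing=None, affine=None, dtype=None):
    if dtype is not None:
        arr = arr.astype(dtype)
    data = arr
    if data.ndim == 2:
        data = data[..., None]
    if affine is None:
        affine = _default_affine(list(spacing) + [1.0] if spacing is not None else [1.0] * 3)
    nib.save(nib.Nifti1Image(data, affine), str(path))


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-exactly."""

    config: dict
    seed: int
    version: str = __version__
    inputs: list[dict] = field(default_factory=list)
    metrics: dict = field(default_factory=dict)

    def save(self, path: str | Path):
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_outputs(
    state: TimeSeriesState,
    outdir: str | Path,
    cfg: EvolutionConfig,
    truths: list[np.ndarray] | None = None,
    input_paths: list[str | Path] | None = None,
) -> RunManifest:
    """Write labels, distance fields, energy trace, metrics and manifest.

    Per time point: ``labels_t{i:02d}.nii.gz`` (uint8; 0=BG, 1=CSF, 2=GM,
    3=WM) and ``phi{1,2,3}_t{i:02d}.nii.gz`` (float32 signed distance, mm);
    plus ``energy_trace.csv``, ``metrics.json`` and ``manifest.json``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    probe.write_text("ok")  # fail before any compute-heavy serialization
    probe.unlink()

    rows = []
    metrics: dict = {"dice": []}
    for i, tp in enumerate(state.timepoints):
        spacing = tp.image.spacing
        affine = tp.image.affine
        write_nifti(tp.labels, out / f"labels_t{i:02d}.nii.gz", spacing, affine, np.uint8)
        for j, phi in enumerate(tp.levelsets.fields(), start=1):
            write_nifti(
                phi.values, out / f"phi{j}_t{i:02d}.nii.gz", spacing, affine, np.float32
            )
        for h in tp.history:
            bk = h["energy"]
            rows.append(
                {
                    "timepoint": i,
                    "age_months": tp.age_months,
                    "iteration": h["iteration"],
                    "phase": h["phase"],
                    "total": bk.total,
                    "data": bk.data,
                    "length": bk.length,
                    "thickness": bk.thickness,
                    "longitudinal": bk.longitudinal,
                }
            )
        if truths is not None:
            labels = tp.labels
            metrics["dice"].append(
                {
                    "timepoint": i,
                    "age_months": tp.age_months,
                    "wm": dice_ratio(labels, truths[i], 3),
                    "gm": dice_ratio(labels, truths[i], 2),
                    "csf": dice_ratio(labels, truths[i], 1),
                }
            )
    pd.DataFrame(rows).to_csv(out / "energy_trace.csv", index=False)
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))

    manifest = RunManifest(
        config=config_to_dict(cfg),
        seed=cfg.seed,
        inputs=[
            {"path": str(p), "sha256": file_checksum(p)} for p in (input_paths or [])
        ],
        metrics=metrics,
    )
    manifest.save(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Config serialization
# ---------------------------------------------------------------------------

def config_to_dict(cfg: EvolutionConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["thickness"] = [cfg.thickness.d_min, cfg.thickness.d_max]
    d["longitudinal"] = cfg.longitudinal.epsilon
    return d


def config_from_dict(d: dict) -> EvolutionConfig:
    d = dict(d)
    if "thickness" in d and not isinstance(d["thickness"], ThicknessRange):
        lo, hi = d["thickness"]
        d["thickness"] = ThicknessRange(lo, hi)
    if "longitudinal" in d and not isinstance(d["longitudinal"], LongitudinalRange):
        d["longitudinal"] = LongitudinalRange(float(d["longitudinal"]))
    return EvolutionConfig(**d)


def load_config(path: str | Path) -> EvolutionConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()) or {})


def save_config(cfg: EvolutionConfig, path: str | Path):
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg)))
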