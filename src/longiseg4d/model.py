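"""Model / Results interface over the coupled level-set machinery.

`CoupledLevelSetModel` fits the single-scan coupled three-surface model to a
multi-modal image; `LongitudinalLevelSetModel` fits the full longitudinally
guided model to a serial acquisition.  Both follow the familiar pattern of
statistical modelling packages: the model object holds data and
configuration, ``fit()`` runs the minimization and returns a results object
carrying the segmentation, the energy trace and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evolution import (
    EvolutionConfig,
    TimeSeriesState,
    evolve_single_timepoint,
    initialize_levelsets,
    run_4d_pipeline,
)
from .fitting import AtlasPrior, MultiModalImage
from .geometry import LABEL_CSF, LABEL_GM, LABEL_WM, LevelSetTriple
from .phantom import dice_ratio

__all__ = [
    "CoupledLevelSetModel",
    "LongitudinalLevelSetModel",
    "SegmentationResults",
    "LongitudinalResults",
]

_TISSUE_CODES = {"wm": LABEL_WM, "gm": LABEL_GM, "csf": LABEL_CSF}


def _history_frame(history: list[dict]) -> pd.DataFrame:
    rows = []
    for h in history:
        bk = h["energy"]
        rows.append(
            {
                "iteration": h["iteration"],
                "phase": h["phase"],
                "total": bk.total,
                "data": bk.data,
                "length": bk.length,
                "thickness": bk.thickness,
                "longitudinal": bk.longitudinal,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SegmentationResults:
    """Fitted single-scan segmentation: labels, level sets, energy trace."""

    levelsets: LevelSetTriple
    labels: np.ndarray
    energy_trace: pd.DataFrame
    config: EvolutionConfig
    age_months: float = 0.0

    def volumes(self) -> dict[str, float]:
        """Tissue volumes in mm^d (area in 2D)."""
        vol = float(np.prod(self.levelsets.spacing))
        return {name: float((self.labels == code).sum()) * vol for name, code in _TISSUE_CODES.items()}

    def dice(self, truth: np.ndarray) -> dict[str, float]:
        return {name: dice_ratio(self.labels, truth, code) for name, code in _TISSUE_CODES.items()}

    def summary(self, truth: np.ndarray | None = None) -> str:
        lines = [
            "Coupled level-set segmentation results",
            "=" * 46,
            f"age (months): {self.age_months:g}   grid: {self.labels.shape}",
            f"iterations:   {len(self.energy_trace)}",
        ]
        if len(self.energy_trace):
            last = self.energy_trace.iloc[-1]
            lines.append(
                "final energy: total={total:.4f} (data={data:.4f}, length={length:.4f}, "
                "thickness={thickness:.4f}, longitudinal={longitudinal:.4f})".format(**last)
            )
        vols = self.volumes()
        lines.append(
            "volumes:      " + "  ".join(f"{k.upper()}={v:.0f}" for k, v in vols.items())
        )
        if truth is not None:
            dr = self.dice(truth)
            lines.append(
                "Dice ratio:   " + "  ".join(f"{k.upper()}={v:.3f}" for k, v in dr.items())
            )
        return "\n".join(lines)


@dataclass
class LongitudinalResults:
    """Fitted serial segmentation: per-time-point results plus the 4D state."""

    state: TimeSeriesState
    config: EvolutionConfig

    @property
    def timepoints(self) -> list[SegmentationResults]:
        return [
            SegmentationResults(
                levelsets=tp.levelsets,
                labels=tp.labels,
                energy_trace=_history_frame(tp.history),
                config=self.config,
                age_months=tp.age_months,
            )
            for tp in self.state.timepoints
        ]

    def labels(self) -> list[np.ndarray]:
        return self.state.labels()

    def dice(self, truths: list[np.ndarray]) -> pd.DataFrame:
        rows = []
        for tp, truth in zip(self.timepoints, truths):
            row = {"age_months": tp.age_months}
            row.update(tp.dice(truth))
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self, truths: list[np.ndarray] | None = None) -> str:
        lines = [
            "Longitudinally guided level-set segmentation",
            "=" * 46,
            f"time points: {len(self.state.timepoints)}  ages: {self.state.ages}",
        ]
        for i, tp in enumerate(self.timepoints):
            vols = tp.volumes()
            line = f"  t={tp.age_months:>5g} mo  " + "  ".join(
                f"{k.upper()}={v:.0f}" for k, v in vols.items()
            )
            if truths is not None:
                dr = tp.dice(truths[i])
                line += "  Dice " + "/".join(f"{dr[k]:.3f}" for k in ("wm", "gm", "csf"))
            lines.append(line)
        return "\n".join(lines)


class CoupledLevelSetModel:
    """Single-scan coupled three-surface segmentation model.

    Parameters
    ----------
    image : MultiModalImage
        Co-registered modality stack (T1[, T2[, FA]]).
    atlas : AtlasPrior, optional
        Tissue probability prior; uniform when omitted.
    config : EvolutionConfig, optional
        Energy weights and numerical controls.
    """

    def __init__(
        self,
        image: MultiModalImage,
        atlas: AtlasPrior | None = None,
        config: EvolutionConfig | None = None,
    ):
        self.image = image
        self.atlas = atlas
        self.config = config or EvolutionConfig()

    def fit(self, init: LevelSetTriple | None = None) -> SegmentationResults:
        ls0 = init if init is not None else initialize_levelsets(
            self.image, self.atlas, seed=self.config.seed
        )
        ls, history = evolve_single_timepoint(self.image, ls0, self.atlas, self.config)
        from .geometry import extract_labels

        return SegmentationResults(
            levelsets=ls,
            labels=extract_labels(ls),
            energy_trace=_history_frame(history),
            config=self.config,
            age_months=self.image.age_months,
        )


class LongitudinalLevelSetModel:
    """Longitudinally guided segmentation of a serial acquisition.

    Accepts per-time-point images (strictly increasing ages), optional
    atlases and optionally known pairwise deformations; ``fit()`` runs the
    iterated registration/segmentation alternation.
    """

    def __init__(
        self,
        images: list[MultiModalImage],
        atlases: AtlasPrior | list[AtlasPrior | None] | None = None,
        config: EvolutionConfig | None = None,
        deformations: dict[tuple[int, int], np.ndarray] | None = None,
    ):
        ages = [img.age_months for img in images]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("time-point ages must be strictly increasing")
        self.images = images
        self.atlases = atlases
        self.config = config or EvolutionConfig()
        self.deformations = deformations

    def fit(self) -> LongitudinalResults:
        state = run_4d_pipeline(
            self.images, self.atlases, self.config, deformations=self.deformations
        )
        return LongitudinalResults(state=state, config=self.config)
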