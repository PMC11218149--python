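"""Model/Results interface for sparse-slice segmentation completion.

:class:`SliceCompletionModel` is built from one volume, its (full or
sparse) annotation and a gap, with a choice of backend:

* ``backend="interp"`` — deterministic shape-based interpolation of
  signed distance fields (no training);
* ``backend="net"`` — per-volume overfit training of a small 2D U-Net on
  the manual sections only.

``fit()`` returns a :class:`SliceCompletionResults` carrying the completed
label map, the schedule, the estimated expert time saving, the training
log (for the learned backend) and Dice diagnostics against any reference,
with a ``summary()`` table in the spirit of statistical modelling
packages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import completion_net, interp, metrics
from .completion_net import NetworkSpec, TrainConfig, TrainedModel
from .schedule import (
    GapSchedule,
    SparseLabelMap,
    build_schedule,
    foreground_extent,
    mask_annotations,
    time_saving,
)
from .volume_io import KIDNEY, TUMOR, LabelMap, Volume


class SliceCompletionModel:
    """Completion of withheld sections of one annotated volume.

    Parameters
    ----------
    volume : Volume
        The grayscale image (only used by the learned backend).
    annotation : LabelMap or SparseLabelMap
        Full reference annotation (it will be masked by the schedule) or
        an already-sparse annotation.
    gap : int, optional
        Interval of automatically completed sections between manual ones;
        ignored when ``annotation`` is already sparse.
    backend : {"interp", "net"}
    network_spec, train_config : optional
        Hyperparameters for the learned backend.
    """

    def __init__(self, volume: Volume, annotation: LabelMap | SparseLabelMap,
                 gap: int = 0, backend: str = "interp",
                 network_spec: NetworkSpec | None = None,
                 train_config: TrainConfig | None = None,
                 extent: tuple[int, int] | str | None = None):
        if backend not in ("interp", "net"):
            raise ValueError(f"unknown backend {backend!r}; choose 'interp' or 'net'")
        self.volume = volume
        self.backend = backend
        if isinstance(annotation, SparseLabelMap):
            self.sparse = annotation
            self.schedule = annotation.schedule
        else:
            if extent == "auto":
                extent = foreground_extent(annotation)
            self.schedule = build_schedule(annotation.n_slices, gap, extent=extent)
            self.sparse = mask_annotations(annotation, self.schedule)
        self.network_spec = network_spec or NetworkSpec()
        self.train_config = train_config or TrainConfig()

    def fit(self, seed: int | None = None) -> "SliceCompletionResults":
        """Run the backend and return the completed segmentation."""
        trained: TrainedModel | None = None
        if self.backend == "interp":
            completed = interp.complete_by_interpolation(self.sparse)
        else:
            cfg = self.train_config
            if seed is not None:
                cfg = TrainConfig(**{**cfg.__dict__, "seed": seed})
            trained = completion_net.train_ov2assion(
                self.volume, self.sparse, self.network_spec, cfg)
            completed = completion_net.complete(trained, self.volume, self.sparse)
        return SliceCompletionResults(model=self, completed=completed, trained=trained)


@dataclass
class SliceCompletionResults:
    """Fitted completion: label map, diagnostics and summary table."""

    model: SliceCompletionModel
    completed: LabelMap
    trained: TrainedModel | None = None

    @property
    def schedule(self) -> GapSchedule:
        return self.model.schedule

    @property
    def time_saving(self) -> float:
        return time_saving(self.schedule.gap)

    @property
    def training_log(self) -> pd.DataFrame | None:
        if self.trained is None:
            return None
        return pd.DataFrame(self.trained.log, columns=["epoch", "loss"])

    def dice(self, reference: LabelMap, structure: int,
             scope: str = "all") -> float:
        """Dice against a full reference, on all or withheld slices only."""
        slices = None if scope == "all" else self.schedule.automatic_indices
        return metrics.dice_per_structure(self.completed, reference, structure, slices)

    def dice_table(self, reference: LabelMap) -> pd.DataFrame:
        rows = {}
        for code, name in ((KIDNEY, "kidney"), (TUMOR, "tumor")):
            rows[name] = {
                "all_slices": self.dice(reference, code, "all"),
                "withheld_slices": (self.dice(reference, code, "withheld")
                                    if self.schedule.n_automatic else np.nan),
            }
        return pd.DataFrame(rows).T

    def summary(self, reference: LabelMap | None = None) -> str:
        s = self.schedule
        lines = [
            "        Sparse-Slice Completion Results",
            "=" * 48,
            f"backend:              {self.model.backend}",
            f"gap:                  {s.gap}",
            f"slices:               {s.n_slices} "
            f"({s.n_manual} manual, {s.n_automatic} completed)",
            f"manual fraction:      {s.manual_fraction:.3f}",
            f"est. time saving:     {metrics.round_half_up(self.time_saving * 100, 0):.0f}%",
        ]
        if self.trained is not None:
            lines.append(f"epochs trained:       {len(self.trained.log)}")
            lines.append(f"final loss:           {self.trained.log[-1][1]:.4f}")
            lines.append(f"parameters:           {self.trained.net.n_parameters()}")
        if reference is not None:
            lines.append("-" * 48)
            lines.append("Dice vs reference      all     withheld")
            table = self.dice_table(reference)
            for name, row in table.iterrows():
                wh = f"{row['withheld_slices']:.3f}" if np.isfinite(row["withheld_slices"]) else "  --"
                lines.append(f"  {name:<18} {row['all_slices']:.3f}    {wh}")
        lines.append("=" * 48)
        return "\n".join(lines)
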