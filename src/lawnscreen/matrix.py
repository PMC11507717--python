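"""Promoter-by-neuron measurement matrices.

The screen's design matrix M is a lines x neurons incidence matrix:
``M[i, j] == 1`` when line i's promoter drives opsin expression in neuron
class j, else 0.  Native matrices are binary; corruption experiments may
replace nonzero entries with values in [0, 0.5], so entries are stored as
floats in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NEURON_CLASSES = ("interneuron", "sensory", "motor")


@dataclass(frozen=True)
class MeasurementMatrix:
    """Lines x neurons incidence matrix with per-neuron class annotations.

    Parameters
    ----------
    line_ids : tuple of str
        Row labels (one per transgenic line / promoter).
    neuron_ids : tuple of str
        Column labels (one per neuron class).
    values : ndarray of shape (n_lines, n_neurons)
        Entries in [0, 1]; exactly {0, 1} for uncorrupted matrices.
    class_annotation : dict
        Maps each neuron id to 'interneuron' | 'sensory' | 'motor'.
    """

    line_ids: tuple
    neuron_ids: tuple
    values: np.ndarray
    class_annotation: dict = field(default_factory=dict)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "line_ids", tuple(self.line_ids))
        object.__setattr__(self, "neuron_ids", tuple(self.neuron_ids))
        if values.ndim != 2:
            raise ValueError("matrix values must be 2-D")
        if values.shape != (len(self.line_ids), len(self.neuron_ids)):
            raise ValueError(
                f"shape {values.shape} does not match "
                f"{len(self.line_ids)} line ids x {len(self.neuron_ids)} neuron ids"
            )
        if np.any(values < 0) or np.any(values > 1):
            raise ValueError("matrix entries must lie in [0, 1]")
        if values.shape[0] and not values.any(axis=1).all():
            raise ValueError("measurement matrix has an all-zero row")
        unknown = set(self.class_annotation.values()) - set(NEURON_CLASSES)
        if unknown:
            raise ValueError(f"unknown neuron classes: {sorted(unknown)}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def neurons_of_class(self, cls: str) -> list:
        """Neuron ids annotated with the given class."""
        if cls not in NEURON_CLASSES:
            raise ValueError(f"unknown class {cls!r}")
        return [n for n in self.neuron_ids if self.class_annotation.get(n) == cls]

    def column(self, neuron_id: str) -> np.ndarray:
        return self.values[:, self.neuron_ids.index(neuron_id)]

    def drop_lines(self, line_ids) -> "MeasurementMatrix":
        """Return a copy with the given lines (rows) removed."""
        drop = set(line_ids)
        missing = drop - set(self.line_ids)
        if missing:
            raise KeyError(f"unknown line ids: {sorted(missing)}")
        keep = [i for i, lid in enumerate(self.line_ids) if lid not in drop]
        return MeasurementMatrix(
            line_ids=tuple(self.line_ids[i] for i in keep),
            neuron_ids=self.neuron_ids,
            values=self.values[keep].copy(),
            class_annotation=dict(self.class_annotation),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.line_ids), columns=list(self.neuron_ids)
        ).rename_axis("line_id")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, class_annotation=None) -> "MeasurementMatrix":
        return cls(
            line_ids=tuple(str(i) for i in frame.index),
            neuron_ids=tuple(str(c) for c in frame.columns),
            values=frame.to_numpy(dtype=float),
            class_annotation=dict(class_annotation or {}),
        )
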