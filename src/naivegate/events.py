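"""Event-matrix container for one donor's cytometry data.

An :class:`EventMatrix` holds an events × markers intensity matrix together
with its scale state. Intensities start on the instrument's ``raw`` scale,
are variance-stabilized to the ``asinh`` scale (``asinh(x / cofactor)``),
and may be z-scored per marker to the ``scaled`` state used for neighbor
search. Scale transitions only ever move forward: raw → asinh → scaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

SCALES = ("raw", "asinh", "scaled")


class ScaleError(ValueError):
    """Raised when an operation receives a matrix on the wrong scale."""


@dataclass
class EventMatrix:
    """One donor's events × markers intensity table.

    Parameters
    ----------
    values
        Float matrix of shape (n_events, n_markers). No missing values.
    markers
        Ordered, unique marker names, one per column.
    donor_id
        Donor identifier carried through the pipeline.
    scale
        One of ``raw``, ``asinh``, ``scaled``.
    cofactor
        The asinh cofactor, recorded once the matrix leaves the raw scale.
    """

    values: np.ndarray
    markers: list[str]
    donor_id: str = ""
    scale: str = "raw"
    cofactor: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D events × markers matrix")
        self.markers = list(self.markers)
        if self.values.shape[1] != len(self.markers):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.markers)} marker names"
            )
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker names must be unique")
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if not np.isfinite(self.values).all():
            raise ValueError("event matrix contains non-finite values")
        if self.scale != "raw" and (self.cofactor is None or self.cofactor <= 0):
            raise ScaleError("non-raw matrices must record a positive cofactor")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def marker_index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise KeyError(f"marker {marker!r} not in panel") from None

    def column(self, marker: str) -> np.ndarray:
        return self.values[:, self.marker_index(marker)]

    def select_markers(self, markers: Sequence[str]) -> "EventMatrix":
        idx = [self.marker_index(m) for m in markers]
        return replace(self, values=self.values[:, idx], markers=list(markers))

    def select_events(self, index: np.ndarray) -> "EventMatrix":
        return replace(self, values=self.values[np.asarray(index)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.markers)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        donor_id: str = "",
        scale: str = "raw",
        cofactor: float | None = None,
    ) -> "EventMatrix":
        return cls(
            values=df.to_numpy(dtype=np.float64),
            markers=[str(c) for c in df.columns],
            donor_id=donor_id,
            scale=scale,
            cofactor=cofactor,
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path, donor_id: str = "", scale: str = "raw", cofactor: float | None = None
    ) -> "EventMatrix":
        return cls.from_dataframe(
            pd.read_csv(path), donor_id=donor_id, scale=scale, cofactor=cofactor
        )
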