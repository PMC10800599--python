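"""Subjects × biomarkers concentration tables.

Concentrations are non-negative (pg/mL scale); a value of exactly zero
means the analyte fell below the assay's limit of detection (LOD) and was
recorded as such.  NaN is not a valid concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RESERVED_COLUMNS = ("subject_id", "group", "timepoint")


@dataclass
class PanelTable:
    """A biomarker panel: one row per subject (× timepoint), one column per marker.

    Parameters
    ----------
    values : (n_rows, n_markers) array of non-negative concentrations.
    subject_id : row labels; a subject may appear once per timepoint.
    group : two-level group label per row (e.g. ``"sham"`` / ``"TBI"``).
    timepoint : timepoint label per row (e.g. ``"day60"``).
    markers : unique marker names, one per column.
    """

    values: np.ndarray
    subject_id: np.ndarray
    group: np.ndarray
    timepoint: np.ndarray
    markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_id = np.asarray(self.subject_id)
        self.group = np.asarray(self.group)
        self.timepoint = np.asarray(self.timepoint)
        self.markers = list(self.markers)
        n, m = self.values.shape
        for name, arr in (("subject_id", self.subject_id),
                          ("group", self.group),
                          ("timepoint", self.timepoint)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per row "
                                 f"({arr.shape} vs {n} rows)")
        if len(self.markers) != m:
            raise ValueError(f"{m} columns but {len(self.markers)} marker names")
        if len(set(self.markers)) != m:
            raise ValueError("marker names must be unique")
        if np.isnan(self.values).any():
            raise ValueError("NaN concentrations are not allowed "
                             "(below-LOD values are recorded as 0)")
        if (self.values < 0).any():
            raise ValueError("concentrations must be non-negative")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"subject_id": self.subject_id,
                           "group": self.group,
                           "timepoint": self.timepoint})
        for j, name in enumerate(self.markers):
            df[name] = self.values[:, j]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PanelTable":
        missing = [c for c in RESERVED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"panel is missing reserved columns: {missing}")
        markers = [c for c in df.columns if c not in RESERVED_COLUMNS]
        if not markers:
            raise ValueError("panel has no marker columns")
        return cls(values=df[markers].to_numpy(dtype=float),
                   subject_id=df["subject_id"].to_numpy(),
                   group=df["group"].to_numpy(),
                   timepoint=df["timepoint"].to_numpy(),
                   markers=markers)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PanelTable":
        # round_trip parsing keeps write->read->write bitwise stable
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))

    def select(self, group=None, timepoint=None) -> "PanelTable":
        """Subset rows by group and/or timepoint label."""
        keep = np.ones(self.n_rows, dtype=bool)
        if group is not None:
            keep &= self.group == group
        if timepoint is not None:
            keep &= self.timepoint == timepoint
        return PanelTable(self.values[keep], self.subject_id[keep],
                          self.group[keep], self.timepoint[keep],
                          list(self.markers))

    def timepoints(self) -> list:
        seen: list = []
        for t in self.timepoint:
            if t not in seen:
                seen.append(t)
        return seen
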