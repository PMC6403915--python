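"""Degradation datasets: (time, Mn) series and their CSV representation.

The canonical on-disk form is a CSV with columns ``time_days`` and
``Mn_g_mol`` (optional ``Mw_g_mol`` and ``PD``); units are fixed in the
column names to prevent silent unit drift.  Extra columns are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("time_days", "Mn_g_mol")
OPTIONAL_COLUMNS = ("Mw_g_mol", "PD")


class DatasetValidationError(ValueError):
    """The dataset violates its structural invariants."""


@dataclass
class DegradationDataset:
    """A molecular-weight decay series for one specimen / radiation dose.

    ``times_days`` non-negative and strictly increasing; ``Mn`` strictly
    positive (g mol^-1).  ``Mn0``/``PD0`` are the specimen's initial
    properties; when absent they default to the first observation and a
    polydispersity of 1.6 (typical of the polyester films modelled here —
    note the predicted Mn decay does not depend on PD0, which only enters
    the Mw/PD outputs).
    """

    times_days: np.ndarray
    Mn: np.ndarray
    dose_label: str = ""
    Mw: np.ndarray | None = None
    PD: np.ndarray | None = None
    Mn0: float | None = None
    PD0: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_days = np.asarray(self.times_days, dtype=float)
        self.Mn = np.asarray(self.Mn, dtype=float)
        if self.times_days.shape != self.Mn.shape or self.times_days.ndim != 1:
            raise DatasetValidationError(
                "times_days and Mn must be 1-D arrays of equal length")
        if np.any(self.times_days < 0):
            bad = int(np.flatnonzero(self.times_days < 0)[0])
            raise DatasetValidationError(
                f"negative time at row {bad}: {self.times_days[bad]}")
        if np.any(np.diff(self.times_days) <= 0):
            bad = int(np.flatnonzero(np.diff(self.times_days) <= 0)[0]) + 1
            raise DatasetValidationError(
                f"times not strictly increasing at row {bad}")
        if np.any(self.Mn <= 0):
            bad = int(np.flatnonzero(self.Mn <= 0)[0])
            raise DatasetValidationError(
                f"non-positive Mn at row {bad}: {self.Mn[bad]}")

    def __len__(self) -> int:
        return self.times_days.size

    @property
    def initial_mn(self) -> float:
        return float(self.Mn0) if self.Mn0 is not None else float(self.Mn[0])

    @property
    def initial_pd(self) -> float:
        if self.PD0 is not None:
            return float(self.PD0)
        if self.PD is not None:
            return float(self.PD[0])
        return 1.6

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame({"time_days": self.times_days,
                            "Mn_g_mol": self.Mn})
        if self.Mw is not None:
            out["Mw_g_mol"] = self.Mw
        if self.PD is not None:
            out["PD"] = self.PD
        return out

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dose_label: str = "",
                       **kwargs) -> "DegradationDataset":
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetValidationError(
                f"missing required columns: {missing}; "
                f"expected header {list(REQUIRED_COLUMNS)}")
        for col in REQUIRED_COLUMNS + tuple(c for c in OPTIONAL_COLUMNS
                                            if c in df.columns):
            numeric = pd.to_numeric(df[col], errors="coerce")
            if numeric.isna().any():
                bad = int(np.flatnonzero(numeric.isna())[0])
                raise DatasetValidationError(
                    f"non-numeric value in column {col!r} at row {bad}: "
                    f"{df[col].iloc[bad]!r}")
        return cls(
            times_days=df["time_days"].to_numpy(dtype=float),
            Mn=df["Mn_g_mol"].to_numpy(dtype=float),
            Mw=(df["Mw_g_mol"].to_numpy(dtype=float)
                if "Mw_g_mol" in df.columns else None),
            PD=(df["PD"].to_numpy(dtype=float)
                if "PD" in df.columns else None),
            dose_label=dose_label,
            **kwargs,
        )


def read_dataset(path, dose_label: str | None = None) -> DegradationDataset:
    """Read a degradation CSV, with clear errors naming offending rows."""
    df = pd.read_csv(path)
    label = dose_label if dose_label is not None else str(path)
    return DegradationDataset.from_dataframe(df, dose_label=label)


def write_dataset(dataset: DegradationDataset, path) -> None:
    """Write the dataset as CSV; a read round trip preserves all values."""
    dataset.to_dataframe().to_csv(path, index=False)
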