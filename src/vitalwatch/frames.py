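"""Timestamped multichannel vital-sign container and its CSV dialect.

A :class:`SensorFrame` wraps a :class:`pandas.DataFrame` with one ``time``
column (seconds offset, strictly increasing) plus one numeric column per
channel.  Missing observations are ``NaN``; the missingness mask is derived,
never stored separately.

The on-disk dialect is plain CSV with the same header.  A combined blood
pressure column written in the clinical ``"120/80"`` text form is split on
read into ``systolic_bp`` / ``diastolic_bp``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SensorFrame", "ValidationError"]

TIME_COLUMN = "time"

#: Clinical column name that may hold "systolic/diastolic" text on disk.
BP_TEXT_COLUMN = "blood_pressure"


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


@dataclass
class SensorFrame:
    """Multichannel physiological stream.

    Parameters
    ----------
    data
        DataFrame with a ``time`` column (float seconds) and one float
        column per channel.  ``NaN`` marks a missing observation.
    channel_units
        Optional mapping channel name -> unit string (``"bpm"``,
        ``"mmHg"``, ``"%"``, ``"breaths/min"`` ...), carried as metadata.
    """

    data: pd.DataFrame
    channel_units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if TIME_COLUMN not in self.data.columns:
            raise ValidationError(f"frame must contain a '{TIME_COLUMN}' column")
        t = self.data[TIME_COLUMN].to_numpy(dtype=float)
        if len(t) == 0:
            raise ValidationError("frame must contain at least one row")
        if not np.all(np.isfinite(t)):
            raise ValidationError("timestamps must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        if len(self.channels) == 0:
            raise ValidationError("frame must contain at least one channel")
        # Channel payload is always float so NaN can mark missingness.
        for ch in self.channels:
            self.data[ch] = self.data[ch].astype(float)

    @property
    def channels(self) -> list[str]:
        return [c for c in self.data.columns if c != TIME_COLUMN]

    @property
    def times(self) -> np.ndarray:
        return self.data[TIME_COLUMN].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)

    def values(self, channel: str) -> np.ndarray:
        if channel not in self.channels:
            raise KeyError(f"unknown channel {channel!r}; have {self.channels}")
        return self.data[channel].to_numpy(dtype=float)

    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask (True = missing) over the channel columns."""
        return self.data[self.channels].isna()

    def copy(self) -> "SensorFrame":
        return SensorFrame(self.data.copy(), dict(self.channel_units))

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path) -> None:
        """Write the stream; missing observations become empty cells."""
        self.data.to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path, channel_units: dict[str, str] | None = None) -> "SensorFrame":
        """Read a stream CSV, splitting a ``"120/80"`` blood-pressure column.

        Rows where the combined column is empty yield missing values in both
        split channels.
        """
        df = pd.read_csv(path)
        if BP_TEXT_COLUMN in df.columns:
            sys_vals, dia_vals = [], []
            for cell in df[BP_TEXT_COLUMN]:
                if isinstance(cell, str) and "/" in cell:
                    s, d = cell.split("/", 1)
                    sys_vals.append(float(s))
                    dia_vals.append(float(d))
                else:
                    sys_vals.append(np.nan)
                    dia_vals.append(np.nan)
            df = df.drop(columns=[BP_TEXT_COLUMN])
            df["systolic_bp"] = sys_vals
            df["diastolic_bp"] = dia_vals
        return cls(df, channel_units or {})

    def equals(self, other: "SensorFrame") -> bool:
        return self.data.equals(other.data)
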