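"""Dynamic areas of interest: two stacked rectangles that move with the face.

The upper rectangle covers the eyes/forehead half of the face, the lower one
the mouth/chin half. The two rectangles are equal-sized, vertically abutting,
and translate with the stimulus face, so a fixed screen location can change
AOI label as the face moves.

Boundary convention: rectangles are half-open in x (``x_min <= x < x_max``);
in y the shared edge between the halves belongs to the *upper* rectangle
(upper is closed at its bottom edge, lower open at its top edge), so the two
halves partition the face region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

#: Integer AOI codes used internally; ``AOI_LABELS[code]`` gives the name.
AOI_LABELS = ("none", "upper", "lower")
AOI_NONE, AOI_UPPER, AOI_LOWER = 0, 1, 2


@dataclass
class DynamicAOIPair:
    """Time-indexed upper/lower rectangles for one stimulus.

    Rectangle rows are ``(x_min, y_min, x_max, y_max)`` sampled at
    ``times_ms``; between samples the position is a step function (the
    rectangle at the most recent timestamp applies). Lookups are defined on
    ``[times_ms[0], valid_until_ms]``.
    """

    times_ms: np.ndarray
    upper: np.ndarray
    lower: np.ndarray
    valid_until_ms: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        if self.times_ms.ndim != 1 or len(self.times_ms) == 0:
            raise DataError("AOI trajectory needs at least one timestamp")
        if self.upper.shape != (len(self.times_ms), 4) or self.lower.shape != self.upper.shape:
            raise DataError("AOI rectangle arrays must be (n_times, 4)")
        if np.any(np.diff(self.times_ms) <= 0):
            raise DataError("AOI trajectory timestamps must be strictly increasing")
        if self.valid_until_ms is None:
            step = np.median(np.diff(self.times_ms)) if len(self.times_ms) > 1 else 0.0
            self.valid_until_ms = float(self.times_ms[-1] + step)

    def _indices(self, t_ms: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        if np.any(t < self.times_ms[0] - 1e-9) or np.any(t > self.valid_until_ms + 1e-9):
            bad = t[(t < self.times_ms[0] - 1e-9) | (t > self.valid_until_ms + 1e-9)][0]
            raise DataError(f"AOI trajectory not defined at t={bad} ms")
        return np.clip(np.searchsorted(self.times_ms, t, side="right") - 1, 0, None)

    def rects_at(self, t_ms: float) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(upper_rect, lower_rect)`` at time ``t_ms``."""
        i = self._indices(np.array([t_ms]))[0]
        return self.upper[i], self.lower[i]

    def label(self, t_ms, x, y, valid=None) -> np.ndarray:
        """Vectorised AOI codes (0 none, 1 upper, 2 lower) for gaze samples.

        Invalid (track-lost) samples are labelled ``none``.
        """
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        idx = self._indices(t)
        up, lo = self.upper[idx], self.lower[idx]
        with np.errstate(invalid="ignore"):
            in_upper = (
                (x >= up[:, 0]) & (x < up[:, 2]) & (y >= up[:, 1]) & (y <= up[:, 3])
            )
            in_lower = (
                (x >= lo[:, 0]) & (x < lo[:, 2]) & (y > lo[:, 1]) & (y < lo[:, 3])
            )
        codes = np.where(in_upper, AOI_UPPER, np.where(in_lower, AOI_LOWER, AOI_NONE))
        if valid is not None:
            codes = np.where(np.atleast_1d(valid).astype(bool), codes, AOI_NONE)
        return codes

    def to_frame(self, stimulus_id: str) -> pd.DataFrame:
        """Long-format trajectory table (one row per timestamp per region)."""
        cols = ["x_min", "y_min", "x_max", "y_max"]
        rows = []
        for region, rects in (("upper", self.upper), ("lower", self.lower)):
            df = pd.DataFrame(rects, columns=cols)
            df.insert(0, "region", region)
            df.insert(0, "time_ms", self.times_ms)
            df.insert(0, "stimulus_id", stimulus_id)
            rows.append(df)
        return pd.concat(rows, ignore_index=True).sort_values(
            ["time_ms", "region"], ascending=[True, False], ignore_index=True
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DynamicAOIPair":
        up = df[df["region"] == "upper"].sort_values("time_ms")
        lo = df[df["region"] == "lower"].sort_values("time_ms")
        if len(up) == 0 or len(up) != len(lo):
            raise DataError("AOI trajectory table must have matching upper/lower rows")
        if not np.allclose(up["time_ms"].to_numpy(), lo["time_ms"].to_numpy()):
            raise DataError("upper and lower AOI rows must share timestamps")
        cols = ["x_min", "y_min", "x_max", "y_max"]
        return cls(up["time_ms"].to_numpy(), up[cols].to_numpy(), lo[cols].to_numpy())
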