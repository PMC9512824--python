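"""Lightweight containers for time-series responses.

A :class:`ResponseTrace` is a single response waveform (dF/F or mV) with its
sampling interval and the stimulus window it belongs to; a :class:`TraceSet`
bundles the per-unit traces produced by the simulators, keyed by spatial
position so that downstream metrics can relate responses to stimulus geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ResponseTrace", "TraceSet"]


@dataclass
class ResponseTrace:
    """One response time series with stimulus-condition metadata.

    Parameters
    ----------
    values : array of response values (dF/F or mV), one per time sample.
    dt : sampling interval in ms.
    stim_window : half-open ``[start, end)`` window in ms marking the
        stimulation period used by peak/mean metrics.
    condition_label : free-form stimulus condition tag.
    """

    values: np.ndarray
    dt: float = 1.0
    stim_window: tuple[float, float] | None = None
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("ResponseTrace.values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.stim_window is not None:
            lo, hi = self.stim_window
            if not (0 <= lo < hi <= self.duration_ms):
                raise ValueError("stim_window must lie within the trace")

    @property
    def n_t(self) -> int:
        return self.values.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.n_t * self.dt

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_t) * self.dt

    def window_slice(self, window: tuple[float, float] | None = None) -> slice:
        """Index slice covering ``window`` (defaults to ``stim_window``)."""
        win = window if window is not None else self.stim_window
        if win is None:
            return slice(0, self.n_t)
        lo = int(np.floor(win[0] / self.dt))
        hi = int(np.ceil(win[1] / self.dt))
        return slice(max(lo, 0), min(hi, self.n_t))

    def windowed(self, window: tuple[float, float] | None = None) -> np.ndarray:
        return self.values[self.window_slice(window)]


@dataclass
class TraceSet:
    """Per-unit response traces sharing a common time base.

    ``values`` has shape ``(n_units, n_t)``; ``positions`` holds the unit
    coordinates in µm, shape ``(n_units, 2)`` (y stays 0 for 1-D geometries).
    ``components`` optionally keeps same-shaped auxiliary arrays (e.g. the
    separate center and surround activations of a linear RF population).
    """

    values: np.ndarray
    dt: float = 1.0
    positions: np.ndarray | None = None
    condition_label: str = ""
    stim_window: tuple[float, float] | None = None
    components: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.positions is not None:
            self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
            if self.positions.shape[1] == 1:
                self.positions = np.column_stack(
                    [self.positions[:, 0], np.zeros(len(self.positions))]
                )
            if self.positions.shape[0] != self.n_units:
                raise ValueError("positions/values length mismatch")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_t(self) -> int:
        return self.values.shape[1]

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_t) * self.dt

    def trace(self, i: int) -> ResponseTrace:
        return ResponseTrace(
            self.values[i],
            dt=self.dt,
            stim_window=self.stim_window,
            condition_label=self.condition_label,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (unit_id, x, y, t_ms, value)."""
        n_u, n_t = self.values.shape
        pos = self.positions if self.positions is not None else np.zeros((n_u, 2))
        return pd.DataFrame(
            {
                "unit_id": np.repeat(np.arange(n_u), n_t),
                "x": np.repeat(pos[:, 0], n_t),
                "y": np.repeat(pos[:, 1], n_t),
                "t_ms": np.tile(self.time_ms, n_u),
                "value": self.values.ravel(),
            }
        )
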