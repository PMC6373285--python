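"""Uniformly sampled time histories.

:class:`SignalCurve` is the common currency of the package: prescribed skull
kinematics, brain-skull relative displacements, intracranial pressures and
bridging-vein attachment motions are all carried as uniformly sampled curves
in SI units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SignalCurve", "align_pair"]

#: relative tolerance for uniform-spacing validation
_SPACING_RTOL = 1e-9


@dataclass(frozen=True)
class SignalCurve:
    """A uniformly sampled time history.

    Parameters
    ----------
    times :
        Sample times in seconds, strictly increasing and uniformly spaced
        (within 1e-9 relative tolerance). At least two samples.
    values :
        Channel values (m, m/s^2, Pa, rad/s^2, ... depending on channel).
    channel_label :
        Free-text channel identifier used in reports.
    """

    times: np.ndarray
    values: np.ndarray
    channel_label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if times.size != values.size:
            raise ValueError(
                f"times ({times.size}) and values ({values.size}) differ in length"
            )
        if times.size < 2:
            raise ValueError("a SignalCurve needs at least two samples")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        dt = steps.mean()
        if np.any(np.abs(steps - dt) > _SPACING_RTOL * max(abs(dt), 1.0) + 1e-15):
            raise ValueError("times must be uniformly spaced")

    @property
    def sample_interval(self) -> float:
        """Sampling step in seconds."""
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    # ------------------------------------------------------------------
    def resample(self, new_times: np.ndarray) -> "SignalCurve":
        """Linearly interpolate onto ``new_times`` (edge values clamped)."""
        new_times = np.asarray(new_times, dtype=float)
        vals = np.interp(new_times, self.times, self.values)
        return SignalCurve(new_times, vals, self.channel_label)

    def window(self, t_start: float, t_end: float) -> "SignalCurve":
        """Restrict to samples with ``t_start <= t <= t_end``."""
        mask = (self.times >= t_start - 1e-15) & (self.times <= t_end + 1e-15)
        if mask.sum() < 2:
            raise ValueError("window retains fewer than two samples")
        return SignalCurve(self.times[mask], self.values[mask], self.channel_label)

    def shifted(self, delta_t: float) -> "SignalCurve":
        """Return the curve delayed by ``delta_t`` seconds (same grid)."""
        return SignalCurve(self.times + delta_t, self.values, self.channel_label)

    # ------------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path, channel_label: str | None = None) -> "SignalCurve":
        """Read a two-column ``time,value`` CSV (comment lines ``#`` ignored)."""
        df = pd.read_csv(path, comment="#")
        cols = [c.strip().lower() for c in df.columns]
        df.columns = cols
        if "time" not in cols or "value" not in cols:
            raise ValueError(f"{path}: expected columns 'time,value', got {cols}")
        label = channel_label if channel_label is not None else Path(path).stem
        return cls(df["time"].to_numpy(float), df["value"].to_numpy(float), label)

    def to_csv(self, path: str | Path, unit: str = "") -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if unit:
                fh.write(f"# unit: {unit}\n")
            pd.DataFrame({"time": self.times, "value": self.values}).to_csv(
                fh, index=False
            )


def align_pair(ref: SignalCurve, test: SignalCurve, eval_window=None):
    """Resample two curves onto a common uniform grid.

    The grid covers ``eval_window`` (default: the overlap of the two curves)
    at the finer of the two sampling intervals. Inputs are not modified.

    Returns ``(ref_aligned, test_aligned)``.

    Raises
    ------
    ValueError
        If the curves (and window) share no common support.
    """
    t0 = max(ref.times[0], test.times[0])
    t1 = min(ref.times[-1], test.times[-1])
    if eval_window is not None:
        t0 = max(t0, float(eval_window[0]))
        t1 = min(t1, float(eval_window[1]))
    dt = min(ref.sample_interval, test.sample_interval)
    if t1 - t0 < dt:
        raise ValueError("no common support: curves do not overlap the window")
    n = int(round((t1 - t0) / dt)) + 1
    grid = t0 + dt * np.arange(n)
    grid = grid[grid <= t1 + 1e-12]
    return ref.resample(grid), test.resample(grid)
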