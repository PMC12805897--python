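"""Tidy time-course containers shared by the simulator, fit, and summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["TimeCourse", "courses_to_frame", "courses_from_frame"]

TIDY_COLUMNS = ["cell_line", "variant", "replicate", "time_min", "signal"]


@dataclass(frozen=True)
class TimeCourse:
    """One replicate's (time, signal) series for one variant in one cell line.

    Times are minutes post-transfection, strictly increasing, with at least
    four points (two local rate parameters are fit per curve, in the context
    of two shared global rates).  Signal is a non-negative arbitrary unit.
    """

    cell_line: str
    variant: str
    replicate: int
    times: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise ValueError("times and signal must be 1-D and of equal length")
        if t.size < 4:
            raise ValueError("a time course needs at least 4 observations")
        if not np.all(np.isfinite(t)) or np.any(np.diff(t) <= 0) or np.any(t < 0):
            raise ValueError("times must be finite, non-negative, strictly increasing")
        if not np.all(np.isfinite(y)) or np.any(y < 0):
            raise ValueError("signal must be finite and non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", y)

    @property
    def n_points(self) -> int:
        return int(self.times.size)


def courses_to_frame(courses: Iterable[TimeCourse]) -> pd.DataFrame:
    """Flatten TimeCourses into the tidy long format used on disk."""
    frames = []
    for tc in courses:
        frames.append(
            pd.DataFrame(
                {
                    "cell_line": tc.cell_line,
                    "variant": tc.variant,
                    "replicate": tc.replicate,
                    "time_min": tc.times,
                    "signal": tc.signal,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=TIDY_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def courses_from_frame(frame: pd.DataFrame) -> list[TimeCourse]:
    """Rebuild TimeCourses from a tidy frame (one per cell/variant/replicate)."""
    missing = set(TIDY_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"tidy frame is missing columns: {sorted(missing)}")
    courses = []
    for (cell, variant, rep), grp in frame.groupby(
        ["cell_line", "variant", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_min")
        courses.append(
            TimeCourse(
                cell_line=str(cell),
                variant=str(variant),
                replicate=int(rep),
                times=grp["time_min"].to_numpy(dtype=float),
                signal=grp["signal"].to_numpy(dtype=float),
            )
        )
    return courses
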