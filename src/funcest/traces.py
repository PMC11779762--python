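"""Raw drawn traces and their conversion to fixed-grid response functions.

A digitized drawing arrives as an ordered sequence of (x, y) points. Three
steps make it consumable by the measurement model: axes are normalized to
[-1, 1]; x-backtracking is repaired (first pass wins, later overlapping
points dropped); and the trace is down-sampled by linear interpolation onto
a fixed grid of 40 evenly spaced x-locations spanning [-1, 1]. Grid points
outside a short trace's span take the nearest endpoint's y (constant
extrapolation) and the record is flagged, so incomplete drawings can be
filtered or weighted downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateTraceError, InvalidArgumentError

__all__ = [
    "DrawnTrace",
    "ResponseFunction",
    "GRID_SIZE",
    "response_grid",
    "normalize_axes",
    "repair_trace",
    "resample_to_grid",
    "process_trace",
]

#: Number of evenly spaced grid points the processed responses live on.
GRID_SIZE = 40


def response_grid(n: int = GRID_SIZE) -> np.ndarray:
    """The fixed response grid: ``n`` evenly spaced points spanning [-1, 1]."""
    return np.linspace(-1.0, 1.0, n)


@dataclass(frozen=True)
class DrawnTrace:
    """An ordered digitized trace for one participant x problem."""

    x: np.ndarray
    y: np.ndarray
    participant_id: str = ""
    problem_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise InvalidArgumentError("x and y must be 1-D and the same length")
        if self.x.size < 2:
            raise DegenerateTraceError("a trace needs at least 2 points")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise InvalidArgumentError("trace coordinates must be finite")

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of (x, y) points in drawing order."""
        return np.column_stack([self.x, self.y])

    def __len__(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class ResponseFunction:
    """A processed response on the fixed 40-point grid."""

    grid_x: np.ndarray
    y: np.ndarray
    participant_id: str = ""
    problem_id: str = ""
    extrapolated: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_x", np.asarray(self.grid_x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        n = self.grid_x.size
        if n != self.y.size:
            raise InvalidArgumentError("grid_x and y must have the same length")
        spacing = np.diff(self.grid_x)
        if n < 2 or np.max(np.abs(spacing - 2.0 / (n - 1))) >= 1e-12:
            raise InvalidArgumentError("grid must be evenly spaced over [-1, 1]")
        if not np.all(np.isfinite(self.y)):
            raise InvalidArgumentError("y must be finite")


def normalize_axes(trace: DrawnTrace, axis_limits) -> DrawnTrace:
    """Affinely map the axis limits onto [-1, 1] on both axes.

    ``axis_limits`` is (xmin, xmax, ymin, ymax) in digitizer units.
    """
    xmin, xmax, ymin, ymax = (float(v) for v in axis_limits)
    if xmax <= xmin or ymax <= ymin:
        raise InvalidArgumentError("axis limits must satisfy xmax > xmin, ymax > ymin")
    x = 2.0 * (trace.x - xmin) / (xmax - xmin) - 1.0
    y = 2.0 * (trace.y - ymin) / (ymax - ymin) - 1.0
    return DrawnTrace(x, y, trace.participant_id, trace.problem_id)


def repair_trace(trace: DrawnTrace, x_tolerance: float = 1e-6) -> DrawnTrace:
    """Remove x-backtracking: first pass wins, later overlapping points drop.

    Walks the trace in drawing order keeping a running maximum of x; a point
    is kept only if its x exceeds every x already kept (beyond
    ``x_tolerance``), so the output x-sequence is strictly increasing. At
    duplicate x the earliest y is kept.
    """
    if x_tolerance < 0:
        raise InvalidArgumentError("x_tolerance must be >= 0")
    keep = np.zeros(len(trace), dtype=bool)
    x_max = -np.inf
    for i, xi in enumerate(trace.x):
        if xi > x_max + x_tolerance or (x_max == -np.inf):
            keep[i] = True
            x_max = xi
    if keep.sum() < 2:
        raise DegenerateTraceError("fewer than 2 points survive trace repair")
    return DrawnTrace(
        trace.x[keep], trace.y[keep], trace.participant_id, trace.problem_id
    )


def resample_to_grid(trace: DrawnTrace, grid_size: int = GRID_SIZE) -> ResponseFunction:
    """Linearly interpolate a repaired trace onto the fixed response grid.

    Grid points outside the trace's x-span take the nearest endpoint's y
    (constant extrapolation); the result is flagged when that happens.
    """
    if np.any(np.diff(trace.x) < 0):
        raise InvalidArgumentError("trace must be repaired (non-decreasing x) first")
    if np.unique(trace.x).size < 2:
        raise DegenerateTraceError("need at least 2 distinct x values to resample")
    grid = response_grid(grid_size)
    y = np.interp(grid, trace.x, trace.y)
    extrapolated = bool(grid[0] < trace.x[0] - 1e-12 or grid[-1] > trace.x[-1] + 1e-12)
    return ResponseFunction(
        grid_x=grid,
        y=y,
        participant_id=trace.participant_id,
        problem_id=trace.problem_id,
        extrapolated=extrapolated,
    )


def process_trace(
    trace: DrawnTrace,
    axis_limits=(-1.0, 1.0, -1.0, 1.0),
    x_tolerance: float = 1e-6,
    grid_size: int = GRID_SIZE,
) -> ResponseFunction:
    """normalize -> repair -> resample, the full processing chain."""
    return resample_to_grid(
        repair_trace(normalize_axes(trace, axis_limits), x_tolerance), grid_size
    )
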