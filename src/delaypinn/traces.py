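"""Container for sets of response time traces on a shared grid."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeTraceSet"]


@dataclass
class TimeTraceSet:
    """N response traces sampled on a common, strictly increasing time grid.

    ``traces`` has shape (N, d); ``grid`` has shape (d,).  Time is in hours.
    ``known_lambda_d`` carries an externally measured decay/dilution rate when
    available (used to run the estimator in fixed-decay mode).
    """

    grid: np.ndarray
    traces: np.ndarray
    known_lambda_d: float | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.grid.ndim != 1:
            raise ValueError("grid must be one-dimensional")
        if self.grid.size < 4:
            raise ValueError(f"need at least 4 time points, got {self.grid.size}")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.traces.shape[1] != self.grid.size:
            raise ValueError(
                f"trace length {self.traces.shape[1]} does not match grid "
                f"length {self.grid.size}"
            )
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces contain non-finite values")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")

    @property
    def n_traces(self) -> int:
        return self.traces.shape[0]

    @property
    def n_times(self) -> int:
        return self.grid.size

    def mean_trace(self) -> np.ndarray:
        return self.traces.mean(axis=0)
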