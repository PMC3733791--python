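"""Periodic time-series measurement container.

A :class:`TimeSeriesDataset` holds sampling times ``t_j`` (assumed to cover
one oscillation period), per-state measured means and per-point standard
deviations.  The standard deviations double as the weights of the
chi-square fitting cost, so they must be strictly positive wherever a mean
is present.  Individual missing measurements are encoded as NaN means and
simply drop out of the cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError

__all__ = ["TimeSeriesDataset"]


@dataclass
class TimeSeriesDataset:
    times: np.ndarray                  # (M,) strictly increasing
    means: np.ndarray                  # (NEQ, M), NaN = missing point
    stds: np.ndarray | None = None     # (NEQ, M) positive, or None (noise-free truth)
    state_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        if self.times.ndim != 1 or self.times.size < 2:
            raise ArgumentError("times must be a 1-d grid with at least 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ArgumentError("times must be strictly increasing")
        if self.means.shape[1] != self.times.size:
            raise ArgumentError(
                f"means shape {self.means.shape} incompatible with M={self.times.size}"
            )
        if np.any(np.isinf(self.means)):
            raise ArgumentError("means must be finite (NaN marks a missing point)")
        if self.stds is not None:
            self.stds = np.atleast_2d(np.asarray(self.stds, dtype=float))
            if self.stds.shape != self.means.shape:
                raise ArgumentError("stds must have the same shape as means")
            observed = ~np.isnan(self.means)
            if np.any(~(self.stds[observed] > 0)):
                raise ArgumentError("stds must be > 0 at every observed point")
        if self.state_names is None:
            self.state_names = [f"x{i + 1}" for i in range(self.means.shape[0])]
        else:
            self.state_names = list(self.state_names)
            if len(self.state_names) != self.means.shape[0]:
                raise ArgumentError("state_names length must match number of state rows")

    @property
    def n_samples(self) -> int:
        """Number of sampling points M."""
        return self.times.size

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing (state, time) entries."""
        return ~np.isnan(self.means)

    def to_frame(self) -> pd.DataFrame:
        """Wide table: ``time`` column plus ``<state>_mean`` / ``<state>_std`` pairs."""
        data = {"time": self.times}
        for i, name in enumerate(self.state_names):
            data[f"{name}_mean"] = self.means[i]
            data[f"{name}_std"] = (
                self.stds[i] if self.stds is not None else np.full(self.n_samples, np.nan)
            )
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TimeSeriesDataset":
        if "time" not in frame.columns:
            raise ArgumentError("dataset table requires a 'time' column")
        names = []
        for col in frame.columns:
            if col.endswith("_mean"):
                names.append(col[: -len("_mean")])
        if not names:
            raise ArgumentError("dataset table has no '<state>_mean' columns")
        for name in names:
            if f"{name}_std" not in frame.columns:
                raise ArgumentError(f"missing column '{name}_std'")
        means = np.vstack([frame[f"{n}_mean"].to_numpy(float) for n in names])
        stds = np.vstack([frame[f"{n}_std"].to_numpy(float) for n in names])
        if np.all(np.isnan(stds)):
            stds = None
        return cls(
            times=frame["time"].to_numpy(float),
            means=means,
            stds=stds,
            state_names=names,
        )
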