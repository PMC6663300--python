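"""Time-series container and nonuniform embedding.

A recording is a real-valued array of shape (samples, processes,
replications).  Network inference operates on *embedded* variables: a
candidate variable is a (process, lag) pair, and its realization vector is
the process time series shifted back by ``lag`` samples.  To make
conditional-mutual-information values comparable across iterations of the
greedy selection, all embedded variables share the same realization rows:
the first ``max_lag`` samples of every replication are dropped once, and
every variable (including the target's present state, lag 0) is read off
the remaining rows.  Replications are pooled along the sample axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["TimeSeriesData", "Candidate", "Embedding"]


@dataclass(frozen=True, order=True)
class Candidate:
    """A single embedded past variable: process index and positive lag.

    Ordering (process first, then lag) doubles as the deterministic
    tie-break used by the greedy selection.
    """

    process: int
    lag: int

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise ValueError(f"lag must be >= 0, got {self.lag}")
        if self.process < 0:
            raise ValueError(f"process index must be >= 0, got {self.process}")


@dataclass
class TimeSeriesData:
    """Multivariate recording: (T samples) x (N processes) x (R replications).

    Parameters
    ----------
    values
        Array of shape (T, N) or (T, N, R); a 2-D array is treated as a
        single replication.
    labels
        Optional process names; defaults to ``["X0", "X1", ...]``.
    """

    values: np.ndarray
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim == 2:
            arr = arr[:, :, np.newaxis]
        if arr.ndim != 3:
            raise ValueError(
                f"expected a (T, N) or (T, N, R) array, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at sample {bad[0]}, process {bad[1]}, "
                f"replication {bad[2]}"
            )
        self.values = arr
        if self.labels is None:
            self.labels = [f"X{i}" for i in range(arr.shape[1])]
        elif len(self.labels) != arr.shape[1]:
            raise ValueError(
                f"{len(self.labels)} labels for {arr.shape[1]} processes"
            )
        else:
            self.labels = list(self.labels)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_processes(self) -> int:
        return self.values.shape[1]

    @property
    def n_replications(self) -> int:
        return self.values.shape[2]


@dataclass
class Embedding:
    """Shared realization rows for all embedded variables of a recording.

    The embedding drops the first ``max_lag`` samples of each replication
    and pools the remaining rows replication-major, giving
    ``M = (T - max_lag) * R`` effective samples.  ``column(candidate)``
    returns the (M,)-realization of a (process, lag) variable; lag 0 is the
    present state.
    """

    data: TimeSeriesData
    max_lag: int
    n_effective: int = field(init=False)
    replication_slices: list[slice] = field(init=False)

    def __post_init__(self) -> None:
        T, _, R = self.data.values.shape
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        per_rep = T - self.max_lag
        if per_rep < 2:
            raise ValueError(
                f"time series too short: T={T} with max_lag={self.max_lag}"
            )
        self.n_effective = per_rep * R
        self.replication_slices = [
            slice(r * per_rep, (r + 1) * per_rep) for r in range(R)
        ]

    def column(self, candidate: Candidate) -> np.ndarray:
        """Realization vector of ``candidate``, pooled over replications."""
        if candidate.lag > self.max_lag:
            raise ValueError(
                f"lag {candidate.lag} exceeds embedding max_lag {self.max_lag}"
            )
        T = self.data.n_samples
        lo = self.max_lag - candidate.lag
        hi = T - candidate.lag
        # (per_rep, R) -> pooled replication-major
        block = self.data.values[lo:hi, candidate.process, :]
        return block.T.reshape(-1)

    def columns(self, candidates: Sequence[Candidate]) -> np.ndarray:
        """Stack realizations of ``candidates`` as an (M, len) matrix."""
        if len(candidates) == 0:
            return np.empty((self.n_effective, 0))
        return np.column_stack([self.column(c) for c in candidates])

    def present(self, process: int) -> np.ndarray:
        """Realization of the present state of ``process`` (lag 0)."""
        return self.column(Candidate(process, 0))
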