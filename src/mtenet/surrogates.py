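"""Surrogate generation for permutation-based null distributions.

A surrogate destroys the temporal relationship between one embedded source
variable and the target while preserving the source's marginal
distribution; the target and all conditioning variables are left
untouched.  Two permutation schemes:

* ``shuffle_replications`` — whole replications of the candidate are
  swapped (each replication's internal sample order is preserved).  Valid
  only when the number of distinct replication permutations exceeds the
  requested surrogate count.
* ``shuffle_embedded_samples`` — embedded sample indices are permuted
  within each replication; used when replications are absent or too few.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import Candidate, Embedding

__all__ = ["SurrogateScheme", "permute_column", "generate_candidate_surrogate"]

_MODES = ("shuffle_replications", "shuffle_embedded_samples")


@dataclass(frozen=True)
class SurrogateScheme:
    """Permutation mode plus the seed of its random stream."""

    mode: str = "shuffle_embedded_samples"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")

    def validate(self, n_replications: int, n_surrogates: int) -> None:
        """Check the scheme can supply ``n_surrogates`` distinct permutations."""
        if self.mode == "shuffle_replications":
            if n_replications == 1:
                raise ValueError(
                    "shuffle_replications needs more than one replication; "
                    "use shuffle_embedded_samples instead"
                )
            if math.factorial(n_replications) <= n_surrogates:
                raise ValueError(
                    f"{n_replications}! = {math.factorial(n_replications)} "
                    f"distinct replication permutations cannot support "
                    f"{n_surrogates} surrogates"
                )


def permute_column(
    column: np.ndarray,
    replication_slices: list[slice],
    mode: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Return a permuted copy of one embedded realization column."""
    out = np.empty_like(column)
    if mode == "shuffle_replications":
        if len(replication_slices) == 1:
            raise ValueError(
                "shuffle_replications needs more than one replication; "
                "use shuffle_embedded_samples instead"
            )
        order = rng.permutation(len(replication_slices))
        for dst, src in zip(replication_slices, order):
            out[dst] = column[replication_slices[src]]
    elif mode == "shuffle_embedded_samples":
        for sl in replication_slices:
            out[sl] = column[sl][rng.permutation(sl.stop - sl.start)]
    else:
        raise ValueError(f"unknown surrogate mode {mode!r}")
    return out


def generate_candidate_surrogate(
    embedding: Embedding,
    candidate: Candidate,
    scheme: SurrogateScheme,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Permuted realization vector of ``candidate``; everything else untouched.

    The permutation may coincide with the identity by chance — surrogates
    are draws from the permutation null, not constrained to differ from
    the observed ordering.
    """
    if rng is None:
        rng = np.random.default_rng(scheme.rng_seed)
    column = embedding.column(candidate)
    return permute_column(column, embedding.replication_slices, scheme.mode, rng)
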