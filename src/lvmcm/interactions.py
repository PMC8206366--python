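"""Random competitive interaction matrices.

Within every patch, species compete through a common interaction matrix ``A``.
Self-limitation is fixed: ``A[i, i] = 1`` for all species.  Each off-diagonal
effect of species j on species i is sampled independently — set to a constant
``strength`` with probability ``connectance`` and zero otherwise — so
``A[i, j]`` and ``A[j, i]`` are independent directed effects.  The default
(strength 0.5, connectance 0.5) gives off-diagonal mean 0.25 and variance
0.0625.  A pluggable sampler allows continuous coefficient distributions; the
discrete default is kept for efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["InteractionMatrix", "sample_interactions", "extend_interactions"]

# A sampler maps (shape, rng) -> array of off-diagonal coefficients.
Sampler = Callable[[tuple, np.random.Generator], np.ndarray]


def _bernoulli_sampler(connectance: float, strength: float) -> Sampler:
    def sample(shape, rng):
        return np.where(rng.random(shape) < connectance, strength, 0.0)

    return sample


@dataclass
class InteractionMatrix:
    """Competitive coefficients with the sampling law that generated them."""

    A: np.ndarray
    connectance: float
    strength: float

    @property
    def S(self) -> int:
        return self.A.shape[0]

    def to_csv(self, path) -> None:
        """Write the coefficient matrix as dense CSV."""
        import pandas as pd

        pd.DataFrame(self.A).to_csv(path, index_label="species")

    @classmethod
    def from_csv(cls, path, connectance: float = 0.5, strength: float = 0.5):
        import pandas as pd

        A = pd.read_csv(path, index_col="species").to_numpy(float)
        return cls(A=A, connectance=connectance, strength=strength)

    def delete(self, indices) -> "InteractionMatrix":
        """Remove species by deleting their rows and columns."""
        keep = np.setdiff1d(np.arange(self.S), np.asarray(indices, int))
        return InteractionMatrix(
            A=self.A[np.ix_(keep, keep)].copy(),
            connectance=self.connectance,
            strength=self.strength,
        )


def sample_interactions(
    S: int,
    connectance: float = 0.5,
    strength: float = 0.5,
    seed: int | np.random.Generator = None,
    sampler: Sampler | None = None,
) -> InteractionMatrix:
    """Sample an S x S competition matrix with unit diagonal.

    Off-diagonal entries are independent draws from ``sampler`` (default:
    ``strength`` with probability ``connectance``, else 0).
    """
    if S < 1:
        raise ValueError(f"need at least one species, got S={S}")
    if not (0 <= connectance <= 1):
        raise ValueError(f"connectance must lie in [0, 1], got {connectance}")
    if not (0 < strength <= 1):
        raise ValueError(f"strength must lie in (0, 1], got {strength}")
    rng = np.random.default_rng(seed)
    if sampler is None:
        sampler = _bernoulli_sampler(connectance, strength)
    A = sampler((S, S), rng)
    np.fill_diagonal(A, 1.0)
    return InteractionMatrix(A=A, connectance=connectance, strength=strength)


def extend_interactions(
    im: InteractionMatrix,
    n_new: int,
    seed: int | np.random.Generator = None,
    sampler: Sampler | None = None,
) -> InteractionMatrix:
    """Grow the matrix by ``n_new`` species without resampling residents.

    The top-left S x S block of the result equals ``im.A`` exactly; the new
    rows and columns follow the same sampling law.  Used by the assembly loop,
    which adds invaders incrementally.
    """
    if n_new < 0:
        raise ValueError(f"cannot extend by a negative count, got {n_new}")
    S = im.S
    if n_new == 0:
        return InteractionMatrix(im.A.copy(), im.connectance, im.strength)
    rng = np.random.default_rng(seed)
    if sampler is None:
        sampler = _bernoulli_sampler(im.connectance, im.strength)
    A = np.empty((S + n_new, S + n_new))
    A[:S, :S] = im.A
    A[:S, S:] = sampler((S, n_new), rng)
    A[S:, :S] = sampler((n_new, S), rng)
    block = sampler((n_new, n_new), rng)
    A[S:, S:] = block
    np.fill_diagonal(A[S:, S:], 1.0)
    return InteractionMatrix(A=A, connectance=im.connectance, strength=im.strength)
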