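"""Spatially autocorrelated intrinsic growth rates.

Environmental heterogeneity enters the model through the intrinsic growth-rate
matrix ``R`` (species x patches).  Each species' row is an independent draw from
a Gaussian random field over the patch network with mean ``mu = 1`` and
variance ``sigma2``, whose spatial covariance decays exponentially with
inter-patch distance: ``Sigma[x, y] = exp(-d_xy / phi)`` with autocorrelation
length ``phi``.  Sampling goes through the spectral (eigen) decomposition of
Sigma.  The environment is fixed in time: any compositional turnover the
dynamics generate is therefore autonomous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["EnvironmentField", "covariance", "sample_growth_rates"]

#: eigenvalues of Sigma below this are treated as numerically non-PSD
_PSD_TOL = -1e-10


def covariance(dist: np.ndarray, phi: float) -> np.ndarray:
    """Landscape covariance ``Sigma[x, y] = exp(-d_xy / phi)``.

    ``phi`` is the autocorrelation length: at separation ``d = phi`` the
    correlation has decayed to 1/e.  The diagonal is exactly one.
    """
    if phi <= 0:
        raise ValueError(f"autocorrelation length must be positive, got {phi}")
    return np.exp(-np.asarray(dist, dtype=float) / phi)


@dataclass
class EnvironmentField:
    """Gaussian-random-field growth rates over a fixed landscape.

    Caches the spectral factor ``L = Q @ sqrt(Lambda)`` of the landscape
    covariance so that additional species (e.g. invaders generated during
    assembly) can be sampled from the same field law without refactorising.
    """

    Sigma: np.ndarray
    mu: float = 1.0
    sigma2: float = 0.01
    phi: float = 10.0
    _L: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError(f"variance must be non-negative, got {self.sigma2}")
        evals, Q = np.linalg.eigh(self.Sigma)
        if evals.min() < _PSD_TOL:
            raise np.linalg.LinAlgError(
                f"covariance matrix is not positive semi-definite "
                f"(min eigenvalue {evals.min():.3e}); check the distance matrix"
            )
        evals = np.clip(evals, 0.0, None)
        self._L = Q * np.sqrt(evals)

    @property
    def N(self) -> int:
        return self.Sigma.shape[0]

    def sample(self, S: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``S`` independent species rows: ``mu + sigma * L @ z``."""
        z = rng.standard_normal((S, self.N))
        return self.mu + np.sqrt(self.sigma2) * z @ self._L.T


def sample_growth_rates(
    Sigma: np.ndarray,
    S: int,
    mu: float = 1.0,
    sigma2: float = 0.01,
    seed: int | np.random.Generator = None,
) -> np.ndarray:
    """Sample the S x N growth-rate matrix ``R`` from the field law.

    Each species row is an independent realisation ``mu + sigma * Q
    sqrt(Lambda) z`` with ``Sigma = Q Lambda Q^T`` and ``z`` standard normal.
    Tiny negative eigenvalues of Sigma (rounding noise) are clipped to zero;
    substantially negative ones raise, because they signal an invalid distance
    matrix rather than conditioning noise.
    """
    field_ = EnvironmentField(Sigma=np.asarray(Sigma, float), mu=mu, sigma2=sigma2)
    rng = np.random.default_rng(seed)
    return field_.sample(S, rng)


def write_growth_rates(R: np.ndarray, path: str | Path) -> None:
    """Write R as a species x patch CSV."""
    import pandas as pd

    pd.DataFrame(R).to_csv(path, index_label="species")


def read_growth_rates(path: str | Path) -> np.ndarray:
    import pandas as pd

    return pd.read_csv(path, index_col="species").to_numpy(float)
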