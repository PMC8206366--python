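"""Population dynamics: the spatial Lotka-Volterra system and its isolated limit.

The metacommunity obeys, for every species i and patch x,

    dB_ix/dt = B_ix (R_ix - sum_j A_ij B_jx) - e B_ix
               + sum_{y in N(x)} (e / k_y) exp(-d_xy / ell) B_iy,

or in matrix form ``dB/dt = B o (R - A B) + B D`` with ``o`` the Hadamard
product: logistic growth and competition within each patch, plus emigration
and distance-weighted immigration along the Gabriel edges.  A single patch
with an additive biomass influx ``eps`` per species per unit time,

    dB_i/dt = B_i (R_i - sum_j A_ij B_j) + eps,

is the isolated analogue of the mass effects a patch receives from its
neighbourhood; with ``eps > 0`` no species ever goes fully extinct, and the
system can wander along the heteroclinic network connecting the unstable
equilibria of the competition dynamics instead of freezing near one of them.

Integration uses a stiff adaptive BDF scheme with an analytic sparse Jacobian
(rtol 1e-8, atol 1e-10).  Trajectories are clamped to zero within the absolute
tolerance after each integration chunk; anything more negative aborts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .environment import EnvironmentField
from .interactions import InteractionMatrix
from .landscape import Landscape

__all__ = [
    "MetacommunityState",
    "CommunityTimeseries",
    "IsolatedConfig",
    "rhs",
    "simulate",
    "simulate_isolated",
    "simulate_isolated_with_pressure",
    "isolated_equilibrium",
    "source_diversity",
    "may_leonard_fixture",
]

RTOL = 1e-8
ATOL = 1e-10
#: stationarity criterion for equilibrium solves: max |dB/dt| below this
STATIONARY_TOL = 1e-10
#: default horizon for equilibrium solves (unit times)
EQUILIBRIUM_HORIZON = 1e4
#: biomass below which a population is considered absent
DETECTION_THRESHOLD = 1e-4


class InvalidStateError(ValueError):
    """Raised when biomasses are NaN or negative beyond solver tolerance."""


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the failing time."""

    def __init__(self, message: str, t: float):
        super().__init__(f"{message} (t={t:g})")
        self.t = t


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------


@dataclass
class MetacommunityState:
    """Current biomasses plus the fixed landscape/environment/interactions.

    ``species_ids`` are persistent labels: pruning removes rows but never
    renumbers survivors, so identities can be tracked through assembly.
    """

    B: np.ndarray  # (S, N), non-negative
    landscape: Landscape
    environment: EnvironmentField
    interactions: InteractionMatrix
    species_ids: np.ndarray = None
    time: float = 0.0

    def __post_init__(self):
        if self.species_ids is None:
            self.species_ids = np.arange(self.B.shape[0])
        self.species_ids = np.asarray(self.species_ids)
        self.validate()

    def validate(self) -> None:
        S, N = self.B.shape
        if np.any(~np.isfinite(self.B)) or self.B.min(initial=0.0) < -ATOL:
            raise InvalidStateError("biomass matrix contains NaN or negative values")
        if self.environment.N != N or self.landscape.N != N:
            raise InvalidStateError("patch dimensions of B, R and D disagree")
        if self.interactions.S != S or len(self.species_ids) != S:
            raise InvalidStateError("species dimensions of B, A and ids disagree")

    @property
    def S(self) -> int:
        return self.B.shape[0]

    @property
    def N(self) -> int:
        return self.B.shape[1]

    @property
    def R(self) -> np.ndarray:
        """Growth-rate matrix for the current species set (sampled lazily)."""
        return self._R

    _R: np.ndarray = field(init=False, repr=False, default=None)

    def save(self, path) -> None:
        """Checkpoint the full state (including landscape and field factor)
        to an HDF5 archive, sufficient to restart assembly or simulation."""
        import h5py

        ls = self.landscape
        with h5py.File(path, "w") as f:
            f.create_dataset("B", data=self.B)
            f.create_dataset("R", data=self.R)
            f.create_dataset("A", data=self.interactions.A)
            f.create_dataset("species_ids", data=self.species_ids)
            f.create_dataset("coords", data=ls.coords)
            f.create_dataset("adjacency", data=ls.adjacency)
            f.create_dataset("Sigma", data=self.environment.Sigma)
            f.attrs.update(
                time=self.time, e=ls.e, ell=ls.ell,
                mu=self.environment.mu, sigma2=self.environment.sigma2,
                phi=self.environment.phi,
                connectance=self.interactions.connectance,
                strength=self.interactions.strength,
            )

    @classmethod
    def load(cls, path) -> "MetacommunityState":
        import h5py

        from .environment import EnvironmentField
        from .interactions import InteractionMatrix
        from .landscape import Landscape, build_dispersal
        from scipy.spatial import distance_matrix

        with h5py.File(path, "r") as f:
            coords = f["coords"][...]
            dist = distance_matrix(coords, coords)
            adjacency = f["adjacency"][...].astype(bool)
            a = f.attrs
            landscape = Landscape(
                N=len(coords), coords=coords, dist=dist, adjacency=adjacency,
                D=build_dispersal(dist, adjacency, e=a["e"], ell=a["ell"]),
                e=float(a["e"]), ell=float(a["ell"]),
            )
            env = EnvironmentField(
                Sigma=f["Sigma"][...], mu=float(a["mu"]),
                sigma2=float(a["sigma2"]), phi=float(a["phi"]),
            )
            im = InteractionMatrix(
                A=f["A"][...], connectance=float(a["connectance"]),
                strength=float(a["strength"]),
            )
            return make_state(
                B=f["B"][...], R=f["R"][...], landscape=landscape,
                environment=env, interactions=im,
                species_ids=f["species_ids"][...], time=float(a["time"]),
            )

    def copy(self) -> "MetacommunityState":
        st = MetacommunityState(
            B=self.B.copy(),
            landscape=self.landscape,
            environment=self.environment,
            interactions=self.interactions,
            species_ids=self.species_ids.copy(),
            time=self.time,
        )
        st._R = None if self._R is None else self._R.copy()
        return st


def make_state(
    B: np.ndarray,
    R: np.ndarray,
    landscape: Landscape,
    environment: EnvironmentField,
    interactions: InteractionMatrix,
    species_ids=None,
    time: float = 0.0,
) -> MetacommunityState:
    """Build a state with an explicit growth-rate matrix."""
    st = MetacommunityState(
        B=B,
        landscape=landscape,
        environment=environment,
        interactions=interactions,
        species_ids=species_ids,
        time=time,
    )
    st._R = np.asarray(R, float)
    if st._R.shape != B.shape:
        raise InvalidStateError("R and B shapes disagree")
    return st


@dataclass
class CommunityTimeseries:
    """Biomass tensor ``B[i, x, t]`` sampled at fixed intervals.

    The basis of every turnover statistic: presence/absence, Bray-Curtis
    matrices, occupancy, species-time-area curves.
    """

    tensor: np.ndarray  # (S, N, T)
    times: np.ndarray  # (T,)
    species_ids: np.ndarray

    @property
    def t_max(self) -> int:
        return self.tensor.shape[2]

    @property
    def sample_interval(self) -> float:
        if len(self.times) < 2:
            return np.nan
        return float(self.times[1] - self.times[0])

    def patch(self, x: int) -> np.ndarray:
        """Species x time abundance matrix of one patch."""
        return self.tensor[:, x, :]

    def save(self, path: str | Path, **metadata) -> None:
        """Persist to a chunked HDF5 archive with metadata attributes."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("biomass", data=self.tensor, chunks=True, compression="gzip")
            f.create_dataset("times", data=self.times)
            f.create_dataset("species_ids", data=self.species_ids)
            for k, v in metadata.items():
                f.attrs[k] = v

    @classmethod
    def load(cls, path: str | Path) -> "CommunityTimeseries":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                tensor=f["biomass"][...],
                times=f["times"][...],
                species_ids=f["species_ids"][...],
            )

    def to_long_csv(self, path: str | Path) -> None:
        """Export as tidy long-format CSV (species_id, patch, t, biomass)."""
        import pandas as pd

        S, N, T = self.tensor.shape
        idx = np.indices((S, N, T))
        pd.DataFrame(
            {
                "species_id": self.species_ids[idx[0].ravel()],
                "patch": idx[1].ravel(),
                "t": self.times[idx[2].ravel()],
                "biomass": self.tensor.ravel(),
            }
        ).to_csv(path, index=False)


@dataclass
class IsolatedConfig:
    """An isolated Lotka-Volterra community under weak propagule pressure.

    ``epsilon`` is a constant biomass influx per species per unit time — the
    isolated stand-in for immigration from a species-rich neighbourhood.
    Growth rates are Normal(1, sigma2) (a single patch has no spatial
    structure to correlate over) and interactions follow the usual discrete
    law.
    """

    S: int
    epsilon: float = 1e-10
    sigma2: float = 0.01
    connectance: float = 0.5
    strength: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError(f"propagule pressure must be non-negative, got {self.epsilon}")


# ---------------------------------------------------------------------------
# right-hand side and Jacobian
# ---------------------------------------------------------------------------


def rhs(B: np.ndarray, R: np.ndarray, A: np.ndarray, D, eps: float = 0.0) -> np.ndarray:
    """Time derivative ``B o (R - A B) + B D (+ eps)`` of the biomass matrix."""
    B = np.asarray(B, float)
    if np.any(~np.isfinite(B)) or B.min(initial=0.0) < -ATOL:
        raise InvalidStateError("rhs called with NaN or negative biomass")
    growth = B * (R - A @ B)
    if D is not None:
        growth = growth + (D.T @ B.T).T
    if eps:
        growth = growth + eps
    return growth


class _System:
    """Flattened ODE system with an analytic sparse Jacobian.

    State layout: ``b[i * N + x] = B[i, x]`` (C order of the (S, N) matrix).
    The Jacobian splits into per-patch competition blocks and a dispersal part
    ``kron(I_S, D^T)`` that is constant in time.
    """

    def __init__(self, R, A, D, eps=0.0):
        self.R = R
        self.A = A
        self.D = D
        self.eps = eps
        self.S, self.N = R.shape
        S, N = self.S, self.N
        if D is not None:
            self._disp = sparse.kron(sparse.identity(S), D.T, format="csr")
        else:
            self._disp = None
        # index template for the per-patch S x S blocks
        ii, jj = np.meshgrid(np.arange(S), np.arange(S), indexing="ij")
        x = np.arange(N)
        self._rows = (ii[:, :, None] * N + x).ravel()
        self._cols = (jj[:, :, None] * N + x).ravel()

    def f(self, t, b):
        # evaluate on the non-negative part of the state: biomasses that
        # undershoot zero by solver error then feel no dynamics (a positive
        # growth rate acting on a negative excursion would amplify it
        # exponentially and collapse the step size)
        B = np.maximum(b, 0.0).reshape(self.S, self.N)
        out = B * (self.R - self.A @ B)
        if self._disp is not None:
            out = out + (self.D.T @ B.T).T
        if self.eps:
            out = out + self.eps
        return out.ravel()

    def jac(self, t, b):
        S, N = self.S, self.N
        B = np.maximum(b, 0.0).reshape(S, N)
        g = self.R - self.A @ B  # (S, N)
        # block[i, j, x] = -B[i, x] * A[i, j] + delta_ij * g[i, x]
        blocks = -B[:, None, :] * self.A[:, :, None]
        blocks[np.arange(S), np.arange(S), :] += g
        J = sparse.coo_matrix(
            (blocks.ravel(), (self._rows, self._cols)), shape=(S * N, S * N)
        ).tocsr()
        if self._disp is not None:
            J = J + self._disp
        return J


def _integrate(
    B0: np.ndarray,
    R: np.ndarray,
    A: np.ndarray,
    D,
    t0: float,
    duration: float,
    sample_every: float | None,
    eps: float = 0.0,
    chunk: float = 500.0,
):
    """Integrate the system, clamping tiny negatives between chunks.

    Returns ``(times, samples, B_final)`` where ``samples`` is (S, N, T).
    With ``sample_every=None`` only the final state is returned (T = 0).
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    system = _System(R, A, D, eps=eps)
    S, N = R.shape
    b = np.asarray(B0, float).reshape(S, N).copy()

    if sample_every is not None:
        n_samples = int(np.floor(duration / sample_every))
        sample_times = t0 + sample_every * np.arange(1, n_samples + 1)
    else:
        sample_times = np.array([])
    samples = np.empty((S, N, len(sample_times)))

    t = t0
    t_end = t0 + duration
    filled = 0
    while t < t_end - 1e-9:
        t_next = min(t + chunk, t_end)
        mask = (sample_times > t + 1e-9) & (sample_times <= t_next + 1e-9)
        t_eval = sample_times[mask]
        if t_eval.size and abs(t_eval[-1] - t_next) < 1e-9:
            eval_points = t_eval
        else:
            eval_points = np.concatenate([t_eval, [t_next]])
        sol = solve_ivp(
            system.f,
            (t, t_next),
            b.ravel(),
            method="BDF",
            jac=system.jac,
            rtol=RTOL,
            atol=ATOL,
            t_eval=eval_points,
        )
        if not sol.success:
            t_fail = sol.t[-1] if len(sol.t) else t
            raise IntegrationError(f"ODE solver failed: {sol.message}", t=t_fail)
        ys = sol.y
        if ys.min() < -1e-6:
            raise IntegrationError(
                f"biomass went negative beyond tolerance ({ys.min():.3e})", t=sol.t[-1]
            )
        np.clip(ys, 0.0, None, out=ys)
        n_here = t_eval.size
        if n_here:
            samples[:, :, filled : filled + n_here] = ys[:, :n_here].reshape(S, N, n_here)
            filled += n_here
        b = ys[:, -1].reshape(S, N)
        t = t_next
    return sample_times, samples, b


# ---------------------------------------------------------------------------
# public simulation API
# ---------------------------------------------------------------------------


def simulate(
    state: MetacommunityState,
    duration: float,
    sample_every: float = 1.0,
    update_state: bool = True,
) -> CommunityTimeseries:
    """Integrate the full metacommunity and sample at fixed intervals.

    Advances ``state`` to the final time in place unless ``update_state`` is
    False.  Samples are taken every ``sample_every`` unit times starting one
    interval after the current state time.
    """
    times, samples, B_final = _integrate(
        state.B,
        state.R,
        state.interactions.A,
        state.landscape.D,
        state.time,
        duration,
        sample_every,
    )
    if update_state:
        state.B = B_final
        state.time += duration
    return CommunityTimeseries(
        tensor=samples, times=times, species_ids=state.species_ids.copy()
    )


def advance(state: MetacommunityState, duration: float) -> None:
    """Integrate without sampling (used between invasions during assembly)."""
    _, _, B_final = _integrate(
        state.B, state.R, state.interactions.A, state.landscape.D,
        state.time, duration, sample_every=None,
    )
    state.B = B_final
    state.time += duration


def simulate_isolated(
    R: np.ndarray,
    A: np.ndarray,
    B0: np.ndarray,
    epsilon: float = 0.0,
    duration: float = 1e4,
    sample_every: float = 1.0,
) -> CommunityTimeseries:
    """Integrate a single isolated patch with additive propagule pressure.

    ``dB_i/dt = B_i (R_i - sum_j A_ij B_j) + epsilon``.  With ``epsilon = 0``
    this is the plain isolated Lotka-Volterra system.
    """
    S = len(R)
    times, samples, _ = _integrate(
        np.asarray(B0, float).reshape(S, 1),
        np.asarray(R, float).reshape(S, 1),
        np.asarray(A, float),
        None,
        0.0,
        duration,
        sample_every,
        eps=epsilon,
    )
    return CommunityTimeseries(tensor=samples, times=times, species_ids=np.arange(S))


def simulate_isolated_with_pressure(
    config: IsolatedConfig,
    duration: float = 1e4,
    sample_every: float = 1.0,
    B0: np.ndarray | None = None,
) -> CommunityTimeseries:
    """Sample a random isolated community from ``config`` and integrate it.

    Growth rates are Normal(1, sigma2); interactions follow the discrete law;
    the initial biomasses default to independent Uniform(0, 1) draws.
    """
    from .interactions import sample_interactions

    rng = np.random.default_rng(config.seed)
    R = rng.normal(1.0, np.sqrt(config.sigma2), size=config.S)
    A = sample_interactions(
        config.S, config.connectance, config.strength, seed=rng
    ).A
    if B0 is None:
        B0 = rng.uniform(0.0, 1.0, size=config.S)
    return simulate_isolated(
        R, A, B0, epsilon=config.epsilon, duration=duration, sample_every=sample_every
    )


def isolated_equilibrium(
    R_col: np.ndarray,
    A: np.ndarray,
    B0: np.ndarray | None = None,
    horizon: float = EQUILIBRIUM_HORIZON,
    tol: float = STATIONARY_TOL,
) -> tuple[np.ndarray, bool]:
    """Relax a single-patch community to stationarity.

    Integrates ``dB/dt = B o (R - A B)`` until ``max |dB/dt| < tol`` or the
    horizon is exhausted.  Returns ``(B, converged)``; ``converged`` False
    flags non-equilibrium dynamics (expected when the pool is in the
    multiple-attractor phase).  At a saturated equilibrium the surviving set
    satisfies ``R = A B`` restricted to its support.
    """
    R_col = np.asarray(R_col, float).ravel()
    S = len(R_col)
    if B0 is None:
        B0 = np.full(S, 1e-6)
    b = np.asarray(B0, float).reshape(S, 1).copy()
    R = R_col.reshape(S, 1)

    def stationary(b):
        # a tiny derivative alone is not enough: a trajectory lingering near
        # an unstable equilibrium of a heteroclinic network also has
        # |dB/dt| ~ 0 while an excluded species with positive invasion rate
        # is still (slowly) growing back, so require uninvadability too
        if np.max(np.abs(rhs(b, R, A, None))) >= tol:
            return False
        growth = R_col - A @ b.ravel()
        excluded = b.ravel() < DETECTION_THRESHOLD
        return not np.any(growth[excluded] > 1e-8)

    t = 0.0
    step = 200.0
    while t < horizon:
        span = min(step, horizon - t)
        _, _, b = _integrate(b, R, A, None, t, span, sample_every=None, chunk=span)
        t += span
        if stationary(b):
            return b.ravel(), True
    return b.ravel(), stationary(b)


def source_diversity(
    state: MetacommunityState, threshold: float = DETECTION_THRESHOLD
) -> tuple[np.ndarray, float, np.ndarray]:
    """Per-patch richness of populations persisting without immigration.

    Sets the off-diagonal of the dispersal operator to zero (the -e emigration
    diagonal is retained, so each patch becomes an isolated community with
    effective growth rates ``R[:, x] - e``), relaxes every patch to
    stationarity from the current biomasses and counts populations above the
    detection threshold.  Returns ``(counts, mean, converged_flags)``.  These
    source populations are the component of local diversity subject to strict
    local limits; mass effects can only add species on top.
    """
    counts = np.zeros(state.N, dtype=int)
    flags = np.zeros(state.N, dtype=bool)
    e = state.landscape.e
    for x in range(state.N):
        B_eq, ok = isolated_equilibrium(
            state.R[:, x] - e, state.interactions.A, B0=state.B[:, x]
        )
        counts[x] = int(np.sum(B_eq > threshold))
        flags[x] = ok
    return counts, float(counts.mean()), flags


def may_leonard_fixture(alpha: float = 0.8, beta: float = 1.3):
    """Three-species rock-paper-scissors community with a heteroclinic cycle.

    Species 1 beats 2 beats 3 beats 1: the cyclic interaction matrix has rows
    ``(1, alpha, beta)`` permuted, with ``0 < alpha < 1 < beta`` and
    ``alpha + beta > 2``.  The three single-species equilibria at biomass 1
    are each unstable to invasion by the next species in the cycle; without
    propagule pressure trajectories approach the connecting heteroclinic
    cycle, spending ever longer near each equilibrium.

    Returns ``(R, A)`` with ``R = (1, 1, 1)``.
    """
    if not (0 < alpha < 1 < beta and alpha + beta > 2):
        raise ValueError(
            f"heteroclinic cycle requires 0 < alpha < 1 < beta and "
            f"alpha + beta > 2; got alpha={alpha}, beta={beta}"
        )
    R = np.ones(3)
    A = np.array(
        [
            [1.0, alpha, beta],
            [beta, 1.0, alpha],
            [alpha, beta, 1.0],
        ]
    )
    return R, A
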