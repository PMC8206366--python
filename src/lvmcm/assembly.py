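"""Iterative regional invasion assembly.

Metacommunities are populated by repeatedly generating random species,
testing them for positive invasion fitness against the resident community,
introducing a batch of successful invaders at low abundance, simulating the
dynamics for a fixed inter-invasion interval, and removing species that have
dropped below the regional extinction threshold everywhere.  Through this
process local richness climbs until the onset of ecological structural
instability caps it; regional richness keeps growing for a while through
spatial differentiation of composition ("regionalisation") and finally
saturates, after which each successful introduction causes on average one
extinction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import dynamics as dyn
from .dynamics import MetacommunityState, make_state
from .environment import EnvironmentField
from .interactions import InteractionMatrix, extend_interactions
from .landscape import Landscape

__all__ = [
    "AssemblyConfig",
    "AssemblyRecord",
    "Candidate",
    "generate_candidates",
    "screen_candidates",
    "introduce",
    "prune_extinct",
    "assemble",
    "batch_size",
]

logger = logging.getLogger(__name__)


@dataclass
class AssemblyConfig:
    """Parameters of the invasion loop.

    The invader batch in each iteration is ``floor(batch_fraction * S) + 1``
    with S the current richness; ``candidate_multiplier`` times that many
    candidates are generated and tested.  Candidates are screened by
    introducing them at ``test_abundance`` into every patch, simulating for
    ``test_duration`` with the residents, and requiring an increasing biomass
    trajectory in at least one patch; residents are restored exactly
    afterwards.  Of the passers, a batch is selected at random and each member
    introduced at ``introduction_abundance`` into the patch where its
    proportional growth during testing was greatest.  ``inter_invasion_time``
    unit times of dynamics separate invasions, after which species below
    ``extinction_threshold`` in every patch are removed.
    """

    batch_fraction: float = 0.05
    candidate_multiplier: int = 5
    test_duration: float = 10.0
    test_abundance: float = 1e-6
    introduction_abundance: float = 1e-6
    inter_invasion_time: float = 500.0
    extinction_threshold: float = 1e-4
    max_invasions: int = 10_000
    # stop early when the regional-richness trend flattens below this
    # (species per invasion) over the trailing saturation_window invasions
    saturation_slope: float = 1e-3
    saturation_window: int = 500
    # measure source diversity every this many invasions (it requires a
    # per-patch equilibrium relaxation, so it is not free)
    source_every: int = 5
    # run the temporal-turnover assay at these invasion indices (and always
    # at the end); the assay simulates turnover_duration unit times and
    # analyses the second half
    turnover_checkpoints: tuple = ()
    turnover_duration: float = 2e4

    def __post_init__(self):
        if self.inter_invasion_time <= 0:
            raise ValueError("inter_invasion_time must be positive")
        for name in ("test_duration", "test_abundance", "introduction_abundance",
                     "extinction_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def batch(self, S: int) -> int:
        return int(np.floor(self.batch_fraction * S)) + 1


def batch_size(S: int, fraction: float = 0.05) -> int:
    """Invader batch rule: ``floor(fraction * S) + 1``."""
    return int(np.floor(fraction * S)) + 1


@dataclass
class Candidate:
    """A prospective invader: its growth-rate row and interaction extension."""

    R_row: np.ndarray  # (N,)
    A_row: np.ndarray  # effects of residents on the candidate, length S
    A_col: np.ndarray  # effects of the candidate on residents, length S
    A_new: float = 1.0  # self-limitation
    passed: bool = False
    best_patch: int = -1


@dataclass
class AssemblyRecord:
    """Per-invasion log of diversity and turnover statistics."""

    invasion: list = dc_field(default_factory=list)
    gamma: list = dc_field(default_factory=list)
    n_introduced: list = dc_field(default_factory=list)
    n_pruned: list = dc_field(default_factory=list)
    alpha_src: list = dc_field(default_factory=list)  # NaN when not measured
    beta_s: list = dc_field(default_factory=list)
    beta_t: list = dc_field(default_factory=list)  # NaN when not assayed

    def append(self, invasion, gamma, n_intro, n_pruned, alpha_src, beta_s, beta_t):
        self.invasion.append(invasion)
        self.gamma.append(gamma)
        self.n_introduced.append(n_intro)
        self.n_pruned.append(n_pruned)
        self.alpha_src.append(alpha_src)
        self.beta_s.append(beta_s)
        self.beta_t.append(beta_t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "invasion": self.invasion,
                "gamma": self.gamma,
                "n_introduced": self.n_introduced,
                "n_pruned": self.n_pruned,
                "alpha_src": self.alpha_src,
                "beta_s": self.beta_s,
                "beta_t": self.beta_t,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# invasion-loop operations
# ---------------------------------------------------------------------------


def generate_candidates(
    state: MetacommunityState, n: int, rng: np.random.Generator
) -> list[Candidate]:
    """Sample ``n`` candidate species from the environment and interaction laws."""
    R_rows = state.environment.sample(n, rng)
    im = state.interactions
    ext = extend_interactions(im, n, seed=rng)
    S = im.S
    return [
        Candidate(
            R_row=R_rows[k],
            A_row=ext.A[S + k, :S].copy(),
            A_col=ext.A[:S, S + k].copy(),
        )
        for k in range(n)
    ]


def screen_candidates(
    state: MetacommunityState,
    candidates: list[Candidate],
    test_duration: float = 10.0,
    test_abundance: float = 1e-6,
) -> list[Candidate]:
    """Screen candidates for positive growth somewhere in the network.

    All candidates are introduced simultaneously at ``test_abundance`` into
    every patch and the joint dynamics (residents + candidates) are simulated
    for ``test_duration``.  A candidate passes iff its final biomass exceeds
    its initial biomass in at least one patch; its best patch is the one with
    the largest proportional growth (ties broken by lowest patch index).
    Residents are restored to their pre-test state, so testing is
    side-effect-free.
    """
    if not candidates:
        return candidates
    S, N = state.S, state.N
    n = len(candidates)
    A_ext = np.empty((S + n, S + n))
    A_ext[:S, :S] = state.interactions.A
    for k, c in enumerate(candidates):
        A_ext[S + k, :S] = c.A_row
        A_ext[:S, S + k] = c.A_col
        A_ext[S + k, S + k] = c.A_new
    # candidates at test abundance do not measurably interact with each other;
    # treat their mutual effects as zero during the short test
    for k in range(n):
        for m in range(n):
            if k != m:
                A_ext[S + k, S + m] = 0.0
    R_ext = np.vstack([state.R, np.array([c.R_row for c in candidates])])
    B_ext = np.vstack([state.B, np.full((n, N), test_abundance)])
    _, _, B_final = dyn._integrate(
        B_ext, R_ext, A_ext, state.landscape.D,
        0.0, test_duration, sample_every=None, chunk=test_duration,
    )
    for k, c in enumerate(candidates):
        final = B_final[S + k]
        growth = final / test_abundance
        c.passed = bool(np.any(final > test_abundance))
        c.best_patch = int(np.argmax(growth))  # argmax takes the lowest index on ties
    return candidates


def introduce(
    state: MetacommunityState,
    chosen: list[Candidate],
    introduction_abundance: float = 1e-6,
    next_id: int = None,
    rng: np.random.Generator | None = None,
) -> MetacommunityState:
    """Add invaders to the community at low abundance in their best patch.

    Mutual interactions among the simultaneously introduced invaders are
    sampled from the interaction law, so the assembled matrix keeps the same
    statistics as one sampled in a single shot.
    """
    if not chosen:
        return state
    if rng is None:
        rng = np.random.default_rng()
    S, N = state.S, state.N
    n = len(chosen)
    A = np.empty((S + n, S + n))
    A[:S, :S] = state.interactions.A
    for k, c in enumerate(chosen):
        A[S + k, :S] = c.A_row
        A[:S, S + k] = c.A_col
    im = state.interactions
    block = np.where(
        rng.random((n, n)) < im.connectance, im.strength, 0.0
    )
    np.fill_diagonal(block, [c.A_new for c in chosen])
    A[S:, S:] = block
    R = np.vstack([state.R, np.array([c.R_row for c in chosen])])
    B = np.vstack([state.B, np.zeros((n, N))])
    for k, c in enumerate(chosen):
        B[S + k, c.best_patch] = introduction_abundance
    if next_id is None:
        next_id = int(state.species_ids.max(initial=-1)) + 1
    ids = np.concatenate([state.species_ids, next_id + np.arange(n)])
    new_state = make_state(
        B=B,
        R=R,
        landscape=state.landscape,
        environment=state.environment,
        interactions=InteractionMatrix(
            A=A,
            connectance=state.interactions.connectance,
            strength=state.interactions.strength,
        ),
        species_ids=ids,
        time=state.time,
    )
    return new_state


def prune_extinct(
    state: MetacommunityState, threshold: float = 1e-4
) -> MetacommunityState:
    """Remove species below the threshold in every patch of the network.

    Survivors keep their persistent ids, so occupancy can be tracked across
    the whole assembly.  Idempotent.
    """
    alive = state.B.max(axis=1) >= threshold
    if alive.all():
        return state
    keep = np.flatnonzero(alive)
    return make_state(
        B=state.B[keep],
        R=state.R[keep],
        landscape=state.landscape,
        environment=state.environment,
        interactions=InteractionMatrix(
            A=state.interactions.A[np.ix_(keep, keep)].copy(),
            connectance=state.interactions.connectance,
            strength=state.interactions.strength,
        ),
        species_ids=state.species_ids[keep],
        time=state.time,
    )


def _empty_state(
    landscape: Landscape, env: EnvironmentField, connectance: float, strength: float
) -> MetacommunityState:
    return make_state(
        B=np.zeros((0, landscape.N)),
        R=np.zeros((0, landscape.N)),
        landscape=landscape,
        environment=env,
        interactions=InteractionMatrix(
            A=np.zeros((0, 0)), connectance=connectance, strength=strength
        ),
        species_ids=np.array([], dtype=int),
    )


def assemble(
    landscape: Landscape,
    environment: EnvironmentField,
    config: AssemblyConfig,
    seed: int | np.random.SeedSequence = 0,
    connectance: float = 0.5,
    strength: float = 0.5,
    state: MetacommunityState | None = None,
) -> tuple[MetacommunityState, AssemblyRecord]:
    """Run the invasion loop until saturation or ``max_invasions``.

    Each iteration: generate candidates, test them, introduce a random batch
    of the passers, simulate ``inter_invasion_time`` unit times, prune
    regionally extinct species, and log regional richness gamma, spatial
    turnover beta_s (mean pairwise inter-patch Bray-Curtis of the snapshot),
    and — at the configured cadence — mean source diversity alpha_src and the
    temporal-turnover assay beta_t.
    """
    from .turnover import beta_diversities, detect_turnover

    rng = np.random.default_rng(seed)
    if state is None:
        state = _empty_state(landscape, environment, connectance, strength)
    record = AssemblyRecord()
    next_id = int(state.species_ids.max(initial=-1)) + 1

    for inv in range(1, config.max_invasions + 1):
        S = state.S
        batch = config.batch(S)
        candidates = generate_candidates(state, batch * config.candidate_multiplier, rng)
        candidates = screen_candidates(
            state, candidates, config.test_duration, config.test_abundance
        )
        passers = [c for c in candidates if c.passed]
        if len(passers) < batch:
            # one regeneration round, then accept the shortfall
            extra = generate_candidates(
                state, batch * config.candidate_multiplier, rng
            )
            extra = screen_candidates(
                state, extra, config.test_duration, config.test_abundance
            )
            passers += [c for c in extra if c.passed]
        if len(passers) > batch:
            idx = rng.choice(len(passers), size=batch, replace=False)
            chosen = [passers[i] for i in sorted(idx)]
        else:
            chosen = passers
        if len(chosen) < batch:
            logger.info("invasion %d: shortfall, only %d passers for batch %d",
                        inv, len(chosen), batch)
        state = introduce(state, chosen, config.introduction_abundance, next_id, rng=rng)
        next_id += len(chosen)
        dyn.advance(state, config.inter_invasion_time)
        before = state.S
        state = prune_extinct(state, config.extinction_threshold)
        n_pruned = before - state.S

        gamma = state.S
        beta_s, _ = beta_diversities(snapshot=state.B)
        if config.source_every and inv % config.source_every == 0:
            _, alpha_src, _ = dyn.source_diversity(state, config.extinction_threshold)
        else:
            alpha_src = np.nan
        if inv in set(config.turnover_checkpoints):
            beta_t = _turnover_assay(state, config)
        else:
            beta_t = np.nan
        record.append(inv, gamma, len(chosen), n_pruned, alpha_src, beta_s, beta_t)
        logger.info(
            "invasion %d: gamma=%d introduced=%d pruned=%d", inv, gamma, len(chosen), n_pruned
        )

        if _saturated(record, config):
            logger.info("regional richness saturated after %d invasions", inv)
            break
    return state, record


def _saturated(record: AssemblyRecord, config: AssemblyConfig) -> bool:
    w = config.saturation_window
    if len(record.gamma) < w:
        return False
    g = np.asarray(record.gamma[-w:], dtype=float)
    slope = np.polyfit(np.arange(w), g, 1)[0]
    return abs(slope) < config.saturation_slope


def _turnover_assay(state: MetacommunityState, config: AssemblyConfig) -> float:
    """Mean temporal Bray-Curtis over the second half of a long simulation.

    Runs on a copy: the assay never perturbs the assembly trajectory.
    """
    from .turnover import beta_diversities

    probe = state.copy()
    ts = dyn.simulate(probe, config.turnover_duration, sample_every=1.0)
    half = ts.t_max // 2
    tail = dyn.CommunityTimeseries(
        tensor=ts.tensor[:, :, half:],
        times=ts.times[half:],
        species_ids=ts.species_ids,
    )
    _, beta_t = beta_diversities(timeseries=tail)
    return beta_t
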