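"""Run configuration, serialisation and canned experiment recipes.

A :class:`RunConfig` collects every tunable of the simulator with the standard
defaults (interaction strength 0.5 with connectance 0.5, phi = 10,
sigma2 = 0.01, ell = 0.5, e = 0.01) and round-trips losslessly through YAML.
Recipes execute a named experiment end-to-end into an output directory:

``assemble_n``
    assemble an N-patch metacommunity, then assay temporal turnover.
``isolated_sweep``
    cluster count versus pool size S for isolated communities under weak
    propagule pressure; reports the smallest S with mean cluster count > 1.
``assembly_trajectory``
    diversity and turnover statistics along a single assembly (relaxed
    coupling: strength 0.3 with connectance 0.3, batch 0.1 S + 1), locating
    the invasion at which temporal turnover first sets in.
``star_scaled``
    species-time-area relation of a saturated metacommunity.
``parameter_sweep``
    temporal turnover across decades of ell, phi and sigma2 at fixed N.

All randomness derives from a single master seed via per-stage substreams, so
a recipe re-run with the same config and seed writes identical statistics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly as asm
from . import dynamics as dyn
from . import turnover as tno
from .environment import EnvironmentField, covariance
from .landscape import build_landscape

__all__ = ["RunConfig", "run_recipe", "RECIPES"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every model parameter in one serialisable block."""

    # landscape
    N: int = 8
    e: float = 0.01
    ell: float = 0.5
    # environment
    phi: float = 10.0
    sigma2: float = 0.01
    mu: float = 1.0
    # interactions
    connectance: float = 0.5
    strength: float = 0.5
    # isolated propagule pressure
    epsilon: float = 1e-10
    # assembly
    batch_fraction: float = 0.05
    candidate_multiplier: int = 5
    test_duration: float = 10.0
    test_abundance: float = 1e-6
    introduction_abundance: float = 1e-6
    inter_invasion_time: float = 500.0
    extinction_threshold: float = 1e-4
    max_invasions: int = 100
    saturation_slope: float = 1e-3
    saturation_window: int = 500
    source_every: int = 5
    turnover_checkpoints: tuple = ()
    turnover_duration: float = 2e4
    # sampling / analysis
    t_max: int = 10_000
    subsample_stride: int = 10
    detection_threshold: float = 1e-4
    cluster_cut: float = 0.25
    # reproducibility
    seed: int = 0

    def assembly_config(self) -> asm.AssemblyConfig:
        return asm.AssemblyConfig(
            batch_fraction=self.batch_fraction,
            candidate_multiplier=self.candidate_multiplier,
            test_duration=self.test_duration,
            test_abundance=self.test_abundance,
            introduction_abundance=self.introduction_abundance,
            inter_invasion_time=self.inter_invasion_time,
            extinction_threshold=self.extinction_threshold,
            max_invasions=self.max_invasions,
            saturation_slope=self.saturation_slope,
            saturation_window=self.saturation_window,
            source_every=self.source_every,
            turnover_checkpoints=tuple(self.turnover_checkpoints),
            turnover_duration=self.turnover_duration,
        )

    # -- serialisation -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["turnover_checkpoints"] = list(data["turnover_checkpoints"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["turnover_checkpoints"] = tuple(data.get("turnover_checkpoints", ()))
        return cls(**data)

    def replace(self, **overrides) -> "RunConfig":
        return dataclasses.replace(self, **overrides)


def _substreams(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def _build(config: RunConfig, ss_landscape, ss_env):
    landscape = build_landscape(
        config.N, np.random.default_rng(ss_landscape), e=config.e, ell=config.ell
    )
    env = EnvironmentField(
        Sigma=covariance(landscape.dist, config.phi),
        mu=config.mu,
        sigma2=config.sigma2,
        phi=config.phi,
    )
    return landscape, env


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------


def _recipe_assemble_n(config: RunConfig, out: Path) -> dict:
    """Assemble one metacommunity, then assay its temporal turnover."""
    ss = _substreams(config.seed, 3)
    landscape, env = _build(config, ss[0], ss[1])
    landscape.to_csv(out / "landscape")
    state, record = asm.assemble(
        landscape,
        env,
        config.assembly_config(),
        seed=ss[2],
        connectance=config.connectance,
        strength=config.strength,
    )
    record.to_csv(out / "record.csv")
    ts = dyn.simulate(state.copy(), 2 * config.t_max, sample_every=1.0)
    half = ts.t_max // 2
    tail = dyn.CommunityTimeseries(
        tensor=ts.tensor[:, :, half:], times=ts.times[half:], species_ids=ts.species_ids
    )
    beta_s, beta_t = tno.beta_diversities(timeseries=tail)
    per_patch = [
        tno.detect_turnover(tail, x, config.subsample_stride)
        for x in range(state.N)
    ]
    verdict = {
        "gamma": int(state.S),
        "beta_s": beta_s,
        "beta_t": beta_t,
        "turning_over": bool(beta_t > tno.TURNOVER_THRESHOLD),
        "patch_mean_bc": [m for _, m in per_patch],
    }
    (out / "verdict.json").write_text(json.dumps(verdict, indent=2))
    return verdict


def _recipe_isolated_sweep(config: RunConfig, out: Path, S_values=None, replicates=3,
                           duration=1e4, burn_in=200.0) -> dict:
    """Cluster count versus pool size for isolated communities with pressure.

    Each replicate starts from independent Uniform(0, 1) biomasses; the first
    ``burn_in`` unit times — an initial-condition relaxation allowance of a
    few times the single-population saturation time — are discarded before the
    ``duration``-sample window is analysed, so the cluster count measures
    states the attractor visits rather than the arbitrary starting transient.
    """
    if S_values is None:
        S_values = [20, 25, 30, 35, 40, 45, 50]
    rows = []
    root = np.random.SeedSequence(config.seed)
    for S in S_values:
        for rep, ss in enumerate(root.spawn(replicates)):
            cfg = dyn.IsolatedConfig(
                S=S,
                epsilon=config.epsilon,
                sigma2=config.sigma2,
                connectance=config.connectance,
                strength=config.strength,
                seed=ss,
            )
            ts = dyn.simulate_isolated_with_pressure(cfg, duration=burn_in + duration)
            keep = ts.times > burn_in
            ts = dyn.CommunityTimeseries(
                tensor=ts.tensor[:, :, keep], times=ts.times[keep],
                species_ids=ts.species_ids,
            )
            D = tno.temporal_dissimilarity(ts, 0, config.subsample_stride)
            k = tno.count_clusters(D, config.cluster_cut)
            _, mean_bc = tno.detect_turnover(ts, 0, config.subsample_stride)
            rows.append({"S": S, "replicate": rep, "clusters": k, "mean_bc": mean_bc})
            logger.info("isolated sweep S=%d rep=%d clusters=%d", S, rep, k)
    df = pd.DataFrame(rows)
    df.to_csv(out / "sweep.csv", index=False)
    means = df.groupby("S")["clusters"].mean()
    above = means[means > 1]
    threshold = int(above.index.min()) if len(above) else None
    result = {"threshold_S": threshold, "mean_clusters": means.to_dict()}
    (out / "threshold.json").write_text(json.dumps(result, indent=2))
    return result


def _recipe_assembly_trajectory(config: RunConfig, out: Path) -> dict:
    """Track diversity and turnover statistics along one assembly.

    Uses the relaxed coupling (strength 0.3, connectance 0.3) and the larger
    invasion batch 0.1 S + 1, which delays structural instability and makes
    the coincidence of local saturation and turnover onset visible.
    """
    cfg = config.replace(
        connectance=0.3, strength=0.3, batch_fraction=0.1, N=config.N or 32
    )
    ss = _substreams(cfg.seed, 3)
    landscape, env = _build(cfg, ss[0], ss[1])
    state, record = asm.assemble(
        landscape,
        env,
        cfg.assembly_config(),
        seed=ss[2],
        connectance=cfg.connectance,
        strength=cfg.strength,
    )
    record.to_csv(out / "record.csv")
    df = record.to_frame()
    crossed = df[df["beta_t"] > tno.TURNOVER_THRESHOLD]
    onset = int(crossed["invasion"].iloc[0]) if len(crossed) else None
    result = {
        "onset_invasion": onset,
        "final_gamma": int(state.S),
        "final_alpha_src": float(df["alpha_src"].dropna().iloc[-1])
        if df["alpha_src"].notna().any()
        else None,
    }
    (out / "onset.json").write_text(json.dumps(result, indent=2))
    return result


def _recipe_star_scaled(config: RunConfig, out: Path) -> dict:
    """Assemble, simulate a long series, and compute the STAR exponents."""
    ss = _substreams(config.seed, 3)
    landscape, env = _build(config, ss[0], ss[1])
    state, record = asm.assemble(
        landscape,
        env,
        config.assembly_config(),
        seed=ss[2],
        connectance=config.connectance,
        strength=config.strength,
    )
    record.to_csv(out / "record.csv")
    ts = dyn.simulate(state, config.t_max, sample_every=1.0)
    P = tno.presence_tensor(ts, config.detection_threshold)
    res = tno.star(P, landscape.coords)
    res.to_frame().to_csv(out / "star_table.csv")
    pd.DataFrame({"delta_T": res.time_windows, "z": res.z}).to_csv(
        out / "star_z.csv", index=False
    )
    pd.DataFrame({"delta_A": res.area_windows, "w": res.w}).to_csv(
        out / "star_w.csv", index=False
    )
    result = {
        "z_range": [float(res.z.min()), float(res.z.max())],
        "w_range": [float(res.w.min()), float(res.w.max())],
    }
    (out / "star.json").write_text(json.dumps(result, indent=2))
    return result


def _recipe_parameter_sweep(
    config: RunConfig, out: Path, ells=(0.05, 0.5, 5.0), phis=(1.0, 10.0, 100.0),
    sigma2s=(0.001, 0.01, 0.1),
) -> dict:
    """Temporal turnover across decades of ell, phi and sigma2 at fixed N."""
    rows = []
    base = config
    for name, values in (("ell", ells), ("phi", phis), ("sigma2", sigma2s)):
        for v in values:
            cfg = base.replace(**{name: v})
            ss = _substreams(cfg.seed, 3)
            landscape, env = _build(cfg, ss[0], ss[1])
            state, _ = asm.assemble(
                landscape, env, cfg.assembly_config(), seed=ss[2],
                connectance=cfg.connectance, strength=cfg.strength,
            )
            ts = dyn.simulate(state, config.t_max, sample_every=1.0)
            _, beta_t = tno.beta_diversities(timeseries=ts)
            rows.append({"parameter": name, "value": v, "gamma": state.S,
                         "beta_t": beta_t})
            logger.info("sweep %s=%g beta_t=%.3g", name, v, beta_t)
    df = pd.DataFrame(rows)
    df.to_csv(out / "parameter_sweep.csv", index=False)
    return {"rows": len(df)}


RECIPES = {
    "assemble_n": _recipe_assemble_n,
    "isolated_sweep": _recipe_isolated_sweep,
    "assembly_trajectory": _recipe_assembly_trajectory,
    "star_scaled": _recipe_star_scaled,
    "parameter_sweep": _recipe_parameter_sweep,
}


def run_recipe(
    name: str, out_dir: str | Path, config: RunConfig | None = None, **kwargs
) -> dict:
    """Execute a named experiment end-to-end into ``out_dir``.

    Writes the config used (``config.yaml``), a log, and the recipe's
    statistic CSV/JSON artefacts; returns the recipe's summary dict.
    """
    if name not in RECIPES:
        raise ValueError(f"unknown recipe {name!r}; choose from {sorted(RECIPES)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()
    config.to_yaml(out / "config.yaml")
    logger.info("running recipe %s into %s", name, out)
    return RECIPES[name](config, out, **kwargs)
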