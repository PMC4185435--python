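"""Synthetic observations, experiment-shaped fixtures, and the end-to-end
pipeline.

The raw scratch-assay micrographs behind the method are not deposited, so a
single stochastic realization of the simulator at known (Pm, Pp) — the same
protocol used to validate the inference on synthetic data — stands in for
experimental input.  A fixture records everything needed to regenerate its
summaries bit for bit: the true parameters, the simulation config, and the
seed.
"""

from __future__ import annotations

import json
import platform
import sys
from dataclasses import dataclass, replace as dc_replace
from pathlib import Path

import numpy as np

from . import io as sio
from .abc import (
    ABCConfig,
    abc_mcmc,
    epsilon_schedule,
    histogram_posterior,
    marginals,
    mean_and_ci,
    pilot_epsilon,
)
from .lattice import LatticeState, SimulationConfig, probs_to_rates, simulate
from .pairstats import SummarySet, map_coordinates_to_lattice, summarize

__all__ = [
    "ExperimentFixture",
    "make_synthetic_observation",
    "make_experiment_like_fixture",
    "write_fixture",
    "read_fixture",
    "run_pipeline",
    "PipelineError",
]

#: Geometry of a 900 um x 675 um field at 25 um spacing (one cell diameter).
FIELD_X, FIELD_Y = 36, 27


@dataclass
class ExperimentFixture:
    """A reproducible stand-in observation.

    ``summaries`` are exactly regenerable from ``(theta_true, sim_config,
    seed)``; ``states`` keeps the underlying snapshots so coordinate tables
    can be emitted.
    """

    theta_true: tuple[float, float]
    sim_config: SimulationConfig
    times: list[float]
    summaries: SummarySet
    seed: int
    states: list[LatticeState]


def make_synthetic_observation(
    theta_true: tuple[float, float],
    sim_config: SimulationConfig,
    times: list[float] | None = None,
    seed: int = 0,
) -> ExperimentFixture:
    """One simulator realization at ``theta_true``, summarized at ``times``
    (default 4, 8, 12 h — three snapshots subsampled from a continuously
    imaged assay)."""
    if times is None:
        times = [4.0, 8.0, 12.0]
    cfg = sim_config.replace(
        Pm=float(theta_true[0]),
        Pp=float(theta_true[1]),
        snapshot_times=[float(t) for t in times],
        seed=int(seed),
    )
    states = simulate(cfg)
    return ExperimentFixture(
        theta_true=(float(theta_true[0]), float(theta_true[1])),
        sim_config=cfg,
        times=[float(t) for t in times],
        summaries=summarize(states),
        seed=int(seed),
        states=states,
    )


def paper_style_sim_config(N0: int = 100, seed: int = 0) -> SimulationConfig:
    """The reference scratch-assay geometry: 36 x 27 sites (900 x 675 um at
    25 um spacing), initial band Y0 = 10, timestep 1/24 h."""
    return SimulationConfig(
        X=FIELD_X, Y=FIELD_Y, Y0=10, N0=N0, Pm=0.0, Pp=0.0,
        delta=25.0, tau=1.0 / 24.0, snapshot_times=[4.0, 8.0, 12.0], seed=seed,
    )


def make_experiment_like_fixture(seed: int = 0) -> ExperimentFixture:
    """A fixture shaped like the real assay: same field (36 x 27 at 25 um),
    N(0) = 102 cells in the band y <= 10, and true parameters drawn near the
    rates a scratch assay of 3T3 fibroblasts typically yields
    (D ~ 1350 um^2/h, lambda ~ 0.025 /h, i.e. Pm ~ 0.36, Pp ~ 0.00104)."""
    rng = np.random.default_rng(seed)
    pm = float(np.clip(rng.normal(0.36, 0.02), 0.0, 1.0))
    pp = float(np.clip(rng.normal(1.04e-3, 1e-4), 0.0, 1.0))
    cfg = paper_style_sim_config(N0=102, seed=seed)
    return make_synthetic_observation((pm, pp), cfg, seed=seed)


# ---------------------------------------------------------------------------
# fixture bundles on disk
# ---------------------------------------------------------------------------

def write_fixture(fixture: ExperimentFixture, directory) -> None:
    """Bundle: config.yaml, coords_t*.csv, summaries_t*.csv(+json), and a
    manifest with the seed and true parameters."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = fixture.sim_config
    sio.write_config(
        {
            "X": cfg.X, "Y": cfg.Y, "Y0": cfg.Y0, "N0": cfg.N0,
            "Pm": cfg.Pm, "Pp": cfg.Pp, "delta": cfg.delta, "tau": cfg.tau,
            "snapshot_times": list(cfg.snapshot_times), "seed": cfg.seed,
        },
        directory / "config.yaml",
    )
    for state in fixture.states:
        tag = f"{state.t:g}".replace(".", "p")
        coords = sio.states_to_coords([state], cfg.delta)
        sio.write_coords_csv(coords, directory / f"coords_t{tag}.csv")
    sio.write_summary_set(fixture.summaries, directory)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(
            {"theta_true": list(fixture.theta_true), "seed": fixture.seed,
             "times": fixture.times},
            fh, indent=1,
        )


def read_fixture(directory) -> ExperimentFixture:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    raw = sio.read_config(directory / "config.yaml")
    cfg = SimulationConfig(**raw)
    fixture = make_synthetic_observation(
        tuple(manifest["theta_true"]), cfg, times=manifest["times"],
        seed=manifest["seed"],
    )
    on_disk = sio.read_summary_set(directory)
    if not all(
        (a.c == b.c).all() and a.N == b.N
        for a, b in zip(fixture.summaries.counts, on_disk.counts)
    ):
        raise ValueError(
            f"summaries in {directory} do not match regeneration from the manifest"
        )
    return fixture


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _stage(name):
    def deco(fn):
        def wrapper(*a, **k):
            try:
                return fn(*a, **k)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("config")
def _load_pipeline_config(config_file) -> dict:
    cfg = sio.read_config(config_file)
    for key in ("observation", "sim", "abc", "output_dir"):
        if key not in cfg:
            raise ValueError(f"pipeline config lacks required section {key!r}")
    abc = cfg["abc"]
    if abc.get("epsilon") is None and not abc.get("tune", False):
        raise ValueError("abc.epsilon is unset and abc.tune is disabled")
    return cfg


@_stage("summarize")
def _load_observation(cfg: dict, sim_config: SimulationConfig) -> SummarySet:
    obs_cfg = cfg["observation"]
    kind = obs_cfg.get("kind", "synthetic")
    if kind == "synthetic":
        fixture = make_synthetic_observation(
            tuple(obs_cfg["theta_true"]), sim_config,
            times=sim_config.snapshot_times, seed=int(obs_cfg.get("seed", 0)),
        )
        return fixture.summaries
    if kind == "coords":
        df = sio.read_coords_csv(obs_cfg["coords_csv"])
        states = []
        for t in sim_config.snapshot_times:
            sub = df[np.isclose(df["time_h"], t)]
            state = map_coordinates_to_lattice(
                sub[["x_um", "y_um"]].to_numpy(), sim_config.delta,
                sim_config.X, sim_config.Y,
            )
            state.t = float(t)
            states.append(state)
        return summarize(states)
    raise ValueError(f"unknown observation kind {kind!r}")


def run_pipeline(config_file) -> dict:
    """summarize -> (optional) epsilon tuning -> ABC-MCMC -> marginals and
    credible intervals -> unit conversion; writes every artifact plus a log
    of seeds, versions and acceptance rates into ``output_dir``.

    Returns the posterior summary dict (also written as
    ``posterior_summary.json``).
    """
    cfg = _load_pipeline_config(config_file)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"python {sys.version.split()[0]} on {platform.platform()}",
        f"numpy {np.__version__}",
    ]

    sim_cfg = SimulationConfig(Pm=0.0, Pp=0.0, **cfg["sim"])
    observed = _load_observation(cfg, sim_cfg)
    sio.write_summary_set(observed, out / "summaries")
    log.append(f"observed N per time: {observed.N.tolist()}")

    abc_raw = cfg["abc"]
    abc_config = ABCConfig(
        sim_config=sim_cfg,
        epsilon=abc_raw.get("epsilon"),
        Gamma=tuple(abc_raw.get("Gamma", (1e-1, 1e-3))),
        M=int(abc_raw.get("M", 10_000)),
        statistic=abc_raw.get("statistic", "K"),
        seed=int(abc_raw["seed"]),
    )
    log.append(f"abc seed {abc_config.seed}, statistic {abc_config.statistic}")

    warm = None
    if abc_raw.get("tune", False):
        try:
            base = abc_config.epsilon or pilot_epsilon(
                abc_config, observed,
                quantile=float(abc_raw.get("pilot_quantile", 0.02)),
                n=int(abc_raw.get("pilot_n", 100)),
            )
            factors = abc_raw.get("factors", [1, 0.5, 0.25, 0.125, 0.0625, 0.03125])
            eps, table = epsilon_schedule(
                dc_replace(abc_config, epsilon=base), observed, factors,
                pilot_M=int(abc_raw.get("pilot_M", 600)),
            )
        except Exception as exc:
            raise PipelineError(f"stage 'epsilon-tune' failed: {exc}") from exc
        table.to_csv(out / "epsilon_schedule.csv", index=False)
        warm = table.attrs["warm_start"]
        abc_config = dc_replace(abc_config, epsilon=eps)
        log.append(f"tuned epsilon {eps} (warning={table.attrs['warning']})")

    try:
        chain = abc_mcmc(abc_config, observed, init_theta=warm)
    except Exception as exc:
        raise PipelineError(f"stage 'infer' failed: {exc}") from exc
    sio.write_chain_csv(chain, out / "chain.csv")
    log.append(f"acceptance rate {chain.acceptance_rate:.4f}")

    try:
        post = cfg.get("posterior", {})
        hist = histogram_posterior(
            chain, n_m=int(post.get("n_m", 100)), n_p=int(post.get("n_p", 10_000))
        )
        marg_pm, marg_pp = marginals(hist)
        level = float(post.get("ci_level", 0.90))
        summary = posterior_summary(
            marg_pm, marg_pp, sim_cfg.delta, sim_cfg.tau, level=level
        )
        summary["acceptance_rate"] = chain.acceptance_rate
        summary["epsilon"] = abc_config.epsilon
        summary["seed"] = abc_config.seed
        for name, marg in (("Pm", marg_pm), ("Pp", marg_pp)):
            with open(out / f"marginal_{name}.csv", "w") as fh:
                fh.write("cell_centre,mass\n")
                for ctr, mass in zip(marg.centres, marg.mass):
                    fh.write(f"{ctr!r},{mass!r}\n")
        with open(out / "posterior_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'posterior' failed: {exc}") from exc

    (out / "log.txt").write_text("\n".join(log) + "\n")
    return summary


def posterior_summary(marg_pm, marg_pp, delta: float, tau: float, level: float = 0.90) -> dict:
    """Mean, mode and mode-symmetric credible interval for both parameters,
    in probability units and converted to (D, lambda)."""
    out: dict = {}
    pm_stats = mean_and_ci(marg_pm, level=level)
    pp_stats = mean_and_ci(marg_pp, level=level)
    keys = ("mean", "mode", "ci_lo", "ci_hi")
    out["Pm"] = dict(zip(keys, pm_stats))
    out["Pp"] = dict(zip(keys, pp_stats))
    out["D_um2_per_h"] = {
        k: probs_to_rates(v, 0.0, delta, tau)[0] for k, v in out["Pm"].items()
    }
    out["lambda_per_h"] = {
        k: probs_to_rates(0.0, v, delta, tau)[1] for k, v in out["Pp"].items()
    }
    out["ci_level"] = level
    return out
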