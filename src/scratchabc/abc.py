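"""ABC-MCMC inference of (Pm, Pp) from snapshot summary statistics.

The likelihood of a snapshot sequence under the exclusion process is
intractable, so the posterior over theta = (Pm, Pp) is approximated by
approximate Bayesian computation: a parameter value is plausible when a
single fresh realization of the simulator at that value produces summary
statistics within a tolerance ``epsilon`` of the observed ones.  A
Metropolis random walk (uniform proposal increments of half-width
``Gamma = (Gamma_m, Gamma_p)``, uniform prior on the unit box) keeps the
chain in the region of parameter space that already matched the data, which
is vastly cheaper than plain rejection sampling when proliferation is slow.

The chain is discretized onto a histogram over the unit box to compute
marginal posteriors, means, mode-symmetric credible intervals, and the
Kullback-Leibler divergence from the uniform prior,
``D_KL(f || pi) = sum_j f_j log(f_j / pi_j)`` (natural log), used to rank
competing summary statistics: a higher divergence means the statistic
extracted more information from the same data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .lattice import SimulationConfig, initialize_lattice, advance
from .pairstats import STATISTICS, SummarySet, summarize, distance

__all__ = [
    "ABCConfig",
    "PosteriorChain",
    "PosteriorHistogram",
    "Marginal",
    "InitializationError",
    "abc_mcmc",
    "prior_predictive_distances",
    "pilot_epsilon",
    "epsilon_schedule",
    "histogram_posterior",
    "kl_divergence",
    "marginals",
    "mean_and_ci",
    "rank_statistics",
]


class InitializationError(RuntimeError):
    """No chain starting point found within the attempt budget."""


@dataclass
class ABCConfig:
    """Settings of one ABC-MCMC run.

    Attributes
    ----------
    sim_config : SimulationConfig
        Geometry, timestep and snapshot schedule of the forward model; its
        Pm/Pp fields are overwritten by each proposal.
    epsilon : float or None
        Acceptance threshold on the summary distance; None means it must be
        chosen (see :func:`pilot_epsilon` / :func:`epsilon_schedule`) before
        running the chain.
    Gamma : (float, float)
        Half-widths of the uniform proposal increments for Pm and Pp.
    M : int
        Total number of proposals (chain length, repeats included).
    statistic : {"q", "N", "c", "K"}
        Summary statistic compared inside the acceptance test.
    seed : int
        Seed for the chain's RNG (proposals and per-proposal simulations).
    init_attempts : int
        Budget of plain rejection-sampling draws for the starting point.
    """

    sim_config: SimulationConfig
    epsilon: float | None = None
    Gamma: tuple[float, float] = (1e-1, 1e-3)
    M: int = 10_000
    statistic: str = "K"
    seed: int = 0
    init_attempts: int = 20_000
    prior_box: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 1.0), (0.0, 1.0))

    def __post_init__(self) -> None:
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if self.Gamma[0] <= 0 or self.Gamma[1] <= 0:
            raise ValueError(f"Gamma components must be positive, got {self.Gamma}")
        if self.M < 1:
            raise ValueError(f"M must be >= 1, got {self.M}")
        if self.statistic not in STATISTICS:
            raise ValueError(f"statistic must be one of {STATISTICS}, got {self.statistic!r}")


@dataclass
class PosteriorChain:
    """ABC-MCMC output: M chain states (repeats included) in the unit box."""

    states: np.ndarray  # (M, 2): columns Pm, Pp
    accepted: np.ndarray  # (M,) bool: proposal accepted at this step
    distances: np.ndarray  # (M,) float: summary distance of proposal (NaN if out of box)
    observed: SummarySet
    config: ABCConfig
    initial: tuple[float, float] = (np.nan, np.nan)

    @property
    def M(self) -> int:
        return self.states.shape[0]

    @property
    def accept_count(self) -> int:
        return int(self.accepted.sum())

    @property
    def acceptance_rate(self) -> float:
        return self.accept_count / self.M

    def best_theta(self) -> tuple[float, float]:
        """Chain state whose accepting proposal had the smallest distance
        (falls back to the starting point if nothing was accepted)."""
        if self.accepted.any():
            d = np.where(self.accepted, self.distances, np.inf)
            m = int(np.argmin(d))
            return float(self.states[m, 0]), float(self.states[m, 1])
        return self.initial

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, self.M + 1),
                "Pm": self.states[:, 0],
                "Pp": self.states[:, 1],
                "accepted": self.accepted.astype(int),
                "distance": self.distances,
            }
        )


@dataclass
class PosteriorHistogram:
    """Normalized frequency of chain states on an n_m-by-n_p grid over the
    unit box (equally spaced bins in each direction)."""

    mass: np.ndarray
    n_m: int
    n_p: int

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.shape != (self.n_m, self.n_p):
            raise ValueError(
                f"mass must have shape ({self.n_m}, {self.n_p}), got {self.mass.shape}"
            )
        if (self.mass < 0).any():
            raise ValueError("histogram mass must be non-negative")
        if abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError("histogram mass must sum to 1")

    @property
    def pm_centres(self) -> np.ndarray:
        return (np.arange(self.n_m) + 0.5) / self.n_m

    @property
    def pp_centres(self) -> np.ndarray:
        return (np.arange(self.n_p) + 0.5) / self.n_p


@dataclass
class Marginal:
    """Univariate posterior on cell centres in [0, 1]; mass sums to 1."""

    centres: np.ndarray
    mass: np.ndarray


def _simulate_summaries(
    sim_config: SimulationConfig, theta: tuple[float, float], rng: np.random.Generator
) -> SummarySet:
    """One fresh realization at theta, summarized at the snapshot times."""
    cfg = sim_config.replace(Pm=float(theta[0]), Pp=float(theta[1]))
    state0 = initialize_lattice(cfg, rng)
    steps = sorted(cfg.steps_for_time(t) for t in cfg.snapshot_times)
    seed = int(rng.integers(0, 2**31 - 1))
    snaps = advance(state0, cfg.Pm, cfg.Pp, steps, seed, tau=cfg.tau)
    return summarize(snaps)


def _check_observed(config: ABCConfig, observed: SummarySet) -> None:
    sim = config.sim_config
    if (observed.X, observed.Y) != (sim.X, sim.Y):
        raise ValueError(
            f"observed lattice {(observed.X, observed.Y)} does not match "
            f"sim_config {(sim.X, sim.Y)}"
        )
    want = sorted(float(t) for t in sim.snapshot_times)
    if [float(t) for t in observed.times] != want:
        raise ValueError(
            f"observed times {observed.times} do not match snapshot_times {want}"
        )


def abc_mcmc(
    abc_config: ABCConfig,
    observed: SummarySet,
    init_theta: tuple[float, float] | None = None,
) -> PosteriorChain:
    """Sample the approximate posterior of (Pm, Pp) by ABC-MCMC.

    The starting point is found by plain rejection sampling from the uniform
    prior (distance <= epsilon).  Each of the M iterations proposes
    ``theta' = theta + (dPm, dPp)`` with components uniform on
    ``[-Gamma_m, Gamma_m]`` and ``[-Gamma_p, Gamma_p]``; proposals outside
    the prior box are rejected outright, otherwise one fresh simulation at
    theta' is summarized and the chain moves iff the distance is within
    epsilon.  All M states are returned, repeats included.

    ``init_theta`` warm-starts the search for the starting point: candidate
    start values are drawn from the proposal kernel around it (clipped to
    the box) instead of from the prior, which avoids the long cold start of
    prior rejection when epsilon is already tight.  The start still has to
    pass the distance test.
    """
    if abc_config.epsilon is None:
        raise ValueError("abc_config.epsilon is unset; tune it first")
    _check_observed(abc_config, observed)
    eps = abc_config.epsilon
    stat = abc_config.statistic
    (pm_lo, pm_hi), (pp_lo, pp_hi) = abc_config.prior_box
    g_m, g_p = abc_config.Gamma
    rng = np.random.default_rng(abc_config.seed)

    theta = None
    for _ in range(abc_config.init_attempts):
        if init_theta is None:
            cand = (rng.uniform(pm_lo, pm_hi), rng.uniform(pp_lo, pp_hi))
        else:
            cand = (
                float(np.clip(init_theta[0] + rng.uniform(-g_m, g_m), pm_lo, pm_hi)),
                float(np.clip(init_theta[1] + rng.uniform(-g_p, g_p), pp_lo, pp_hi)),
            )
        d = distance(observed, _simulate_summaries(abc_config.sim_config, cand, rng), stat)
        if d <= eps:
            theta = cand
            break
    theta0 = theta
    if theta is None:
        raise InitializationError(
            f"no starting point with distance <= epsilon={eps} found in "
            f"{abc_config.init_attempts} prior draws; consider a larger epsilon"
        )

    M = abc_config.M
    states = np.empty((M, 2))
    accepted = np.zeros(M, dtype=bool)
    distances = np.full(M, np.nan)
    for m in range(M):
        prop = (
            theta[0] + rng.uniform(-g_m, g_m),
            theta[1] + rng.uniform(-g_p, g_p),
        )
        if pm_lo <= prop[0] <= pm_hi and pp_lo <= prop[1] <= pp_hi:
            d = distance(
                observed, _simulate_summaries(abc_config.sim_config, prop, rng), stat
            )
            distances[m] = d
            if d <= eps:
                theta = prop
                accepted[m] = True
        states[m] = theta
    return PosteriorChain(
        states, accepted, distances, observed, abc_config, initial=theta0
    )


def prior_predictive_distances(
    abc_config: ABCConfig, observed: SummarySet, n: int = 200, seed: int | None = None
) -> np.ndarray:
    """Summary distances of ``n`` independent prior draws — the reference
    scale for choosing epsilon."""
    _check_observed(abc_config, observed)
    (pm_lo, pm_hi), (pp_lo, pp_hi) = abc_config.prior_box
    rng = np.random.default_rng(abc_config.seed if seed is None else seed)
    out = np.empty(n)
    for k in range(n):
        cand = (rng.uniform(pm_lo, pm_hi), rng.uniform(pp_lo, pp_hi))
        out[k] = distance(
            observed, _simulate_summaries(abc_config.sim_config, cand, rng),
            abc_config.statistic,
        )
    return out


def pilot_epsilon(
    abc_config: ABCConfig,
    observed: SummarySet,
    quantile: float = 0.02,
    n: int = 150,
    seed: int | None = None,
) -> float:
    """Epsilon as a low quantile of the prior-predictive distance
    distribution — the acceptance-rate-matched tolerance used when several
    statistics must be compared on an equal footing."""
    d = prior_predictive_distances(abc_config, observed, n=n, seed=seed)
    return float(np.quantile(d, quantile))


def epsilon_schedule(
    abc_config: ABCConfig,
    observed: SummarySet,
    factors: list[float],
    pilot_M: int = 600,
    tv_tol: float = 0.05,
    coarse_grid: tuple[int, int] = (20, 20),
    min_acceptance: float = 0.01,
) -> tuple[float, pd.DataFrame]:
    """Choose epsilon by posterior stability under threshold reduction.

    Runs a short chain (``pilot_M`` proposals) at each candidate epsilon —
    ``factors`` (strictly decreasing) scaled by ``abc_config.epsilon`` when
    that is set, used as absolute thresholds otherwise — descending through
    the schedule, with each pilot chain warm-started from the best state of
    the previous one.  Returns the largest candidate whose posterior
    histogram (on a coarse auxiliary grid) is within total-variation
    distance ``tv_tol`` of the next-smaller feasible candidate's.  A
    candidate is feasible when a start was found and the pilot acceptance
    rate is at least ``min_acceptance``.  If no candidate qualifies, the
    smallest feasible one is returned and the diagnostics table carries
    ``warning=True``.

    Returns
    -------
    (epsilon, table)
        The chosen threshold and a diagnostics DataFrame with columns
        ``epsilon``, ``acceptance_rate``, ``tv_to_next``, ``best_Pm``,
        ``best_Pp``; ``table.attrs`` holds ``warning``, ``chosen`` and a
        ``warm_start`` state for the production chain.
    """
    if len(factors) < 2:
        raise ValueError("epsilon schedule needs at least 2 candidate factors")
    factors = [float(f) for f in factors]
    if any(b >= a for a, b in zip(factors, factors[1:])):
        raise ValueError("factors must be strictly decreasing")
    base = abc_config.epsilon if abc_config.epsilon is not None else 1.0
    candidates = [f * base for f in factors]

    # common random numbers: every pilot chain shares one seed, so two
    # thresholds that accept the same proposals yield identical chains
    # (TV exactly 0) and the TV comparison is not dominated by chain noise
    pilot_seed = int(np.random.SeedSequence(abc_config.seed).generate_state(1)[0] % 2**31)
    n_m, n_p = coarse_grid
    hists: list[np.ndarray | None] = []
    rates: list[float] = []
    best: list[tuple[float, float] | None] = []
    warm: tuple[float, float] | None = None
    init_budget = min(abc_config.init_attempts, 10 * pilot_M)
    for eps in candidates:
        cfg = dc_replace(
            abc_config, epsilon=eps, M=pilot_M, seed=pilot_seed,
            init_attempts=init_budget,
        )
        try:
            chain = abc_mcmc(cfg, observed, init_theta=warm)
        except InitializationError:
            # this and any tighter threshold is below the attainable
            # distance floor for a fresh realization: stop descending
            hists.append(None)
            rates.append(0.0)
            best.append(None)
            break
        hists.append(histogram_posterior(chain, n_m=n_m, n_p=n_p).mass)
        rates.append(chain.acceptance_rate)
        best.append(chain.best_theta())
        # warm-start the next (tighter) candidate only once acceptance is
        # scarce; looser candidates keep identical cold starts so that
        # thresholds with identical acceptance behaviour compare as equal
        if chain.acceptance_rate < 0.5:
            warm = chain.best_theta()
    while len(hists) < len(candidates):
        hists.append(None)
        rates.append(np.nan)
        best.append(None)

    tv_next = np.full(len(candidates), np.nan)
    for i in range(len(candidates) - 1):
        if hists[i] is not None and hists[i + 1] is not None:
            tv_next[i] = 0.5 * np.abs(hists[i] - hists[i + 1]).sum()

    feasible = [
        i
        for i, h in enumerate(hists)
        if h is not None and rates[i] >= min_acceptance
    ]
    chosen_i = None
    for i in feasible:
        if np.isfinite(tv_next[i]) and tv_next[i] <= tv_tol and i + 1 in feasible:
            chosen_i = i
            break
    warning = chosen_i is None
    if chosen_i is None:
        # no stable pair: fall back to the smallest workable threshold
        chosen_i = feasible[-1] if feasible else 0
    table = pd.DataFrame(
        {
            "epsilon": candidates,
            "acceptance_rate": rates,
            "tv_to_next": tv_next,
            "best_Pm": [b[0] if b else np.nan for b in best],
            "best_Pp": [b[1] if b else np.nan for b in best],
        }
    )
    table.attrs["warning"] = warning
    table.attrs["chosen"] = candidates[chosen_i]
    table.attrs["warm_start"] = best[chosen_i]
    return candidates[chosen_i], table


def histogram_posterior(
    chain: PosteriorChain, n_m: int = 100, n_p: int = 10_000
) -> PosteriorHistogram:
    """Discretize the chain onto an n_m-by-n_p grid over the unit box and
    normalize to total mass 1."""
    if chain.M == 0:
        raise ValueError("empty chain")
    counts, _, _ = np.histogram2d(
        chain.states[:, 0],
        chain.states[:, 1],
        bins=[n_m, n_p],
        range=[[0.0, 1.0], [0.0, 1.0]],
    )
    return PosteriorHistogram(counts / counts.sum(), n_m, n_p)


def kl_divergence(hist: PosteriorHistogram) -> float:
    """Kullback-Leibler divergence of the posterior histogram from the
    uniform prior on the same grid (natural log; 0 log 0 := 0)."""
    f = hist.mass[hist.mass > 0]
    pi = 1.0 / (hist.n_m * hist.n_p)
    return float(np.sum(f * np.log(f / pi)))


def marginals(hist: PosteriorHistogram) -> tuple[Marginal, Marginal]:
    """Marginal posteriors of Pm and Pp (row and column sums)."""
    return (
        Marginal(hist.pm_centres, hist.mass.sum(axis=1)),
        Marginal(hist.pp_centres, hist.mass.sum(axis=0)),
    )


def mean_and_ci(marginal: Marginal, level: float = 0.90) -> tuple[float, float, float, float]:
    """Posterior mean, mode, and mode-symmetric credible interval.

    The interval starts at the modal cell (ties broken toward the smaller
    value) and grows symmetrically, one cell per side per step (clipped at
    the box edge), until it contains at least ``level`` of the mass.  The
    returned bounds are cell centres.
    """
    mass = np.asarray(marginal.mass, dtype=float)
    centres = np.asarray(marginal.centres, dtype=float)
    if abs(mass.sum() - 1.0) > 1e-6:
        raise ValueError("marginal mass must sum to 1")
    mean = float(np.sum(centres * mass))
    k = int(np.argmax(mass))
    lo = hi = k
    cum = mass[k]
    n = mass.size
    while cum < level and (lo > 0 or hi < n - 1):
        if lo > 0:
            lo -= 1
            cum += mass[lo]
        if hi < n - 1:
            hi += 1
            cum += mass[hi]
    return mean, float(centres[k]), float(centres[lo]), float(centres[hi])


def rank_statistics(
    observed_generator,
    abc_config: ABCConfig,
    statistics: tuple[str, ...] = STATISTICS,
    replicates: int = 3,
    n_m: int = 20,
    n_p: int = 200,
    pilot_quantile: float = 0.02,
    pilot_n: int = 100,
    factors: tuple[float, ...] = (1, 0.5, 0.25, 0.125, 0.0625, 0.03125),
    pilot_M: int = 600,
) -> pd.DataFrame:
    """Rank summary statistics by posterior information gain.

    For each statistic, the full inference pipeline is run on ``replicates``
    independently generated observations (same true parameters): a
    prior-predictive pilot sets the tolerance scale, the stability schedule
    (:func:`epsilon_schedule`) descends to the statistic's own attainable
    threshold, a chain of ``abc_config.M`` proposals is sampled at that
    threshold, and the posterior histograms are averaged over replicates.
    The table reports the Kullback-Leibler divergence of each averaged
    posterior from the uniform prior, sorted so the most informative
    statistic comes first.

    ``observed_generator(seed) -> SummarySet`` must produce an independent
    observation for each seed.  All randomness derives from
    ``abc_config.seed``, so the table is reproducible.
    """
    if replicates < 2:
        raise ValueError(f"need at least 2 replicates, got {replicates}")
    ss = np.random.SeedSequence(abc_config.seed)
    obs_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(replicates)]
    observations = [observed_generator(s) for s in obs_seeds]

    rows = []
    for stat in statistics:
        masses = []
        rates = []
        epss = []
        for r, obs in enumerate(observations):
            run_seed = int(
                np.random.SeedSequence([abc_config.seed, r, STATISTICS.index(stat)])
                .generate_state(1)[0] % 2**31
            )
            cfg = dc_replace(abc_config, statistic=stat, seed=run_seed, epsilon=None)
            base = pilot_epsilon(cfg, obs, quantile=pilot_quantile, n=pilot_n, seed=run_seed)
            eps, tbl = epsilon_schedule(
                dc_replace(cfg, epsilon=base), obs, list(factors), pilot_M=pilot_M,
            )
            cfg = dc_replace(cfg, epsilon=eps)
            chain = abc_mcmc(cfg, obs, init_theta=tbl.attrs["warm_start"])
            masses.append(histogram_posterior(chain, n_m=n_m, n_p=n_p).mass)
            rates.append(chain.acceptance_rate)
            epss.append(eps)
        avg = PosteriorHistogram(np.mean(masses, axis=0), n_m, n_p)
        rows.append(
            {
                "statistic": stat,
                "mean_dkl": kl_divergence(avg),
                "mean_epsilon": float(np.mean(epss)),
                "mean_acceptance_rate": float(np.mean(rates)),
            }
        )
    table = pd.DataFrame(rows).sort_values("mean_dkl", ascending=False, ignore_index=True)
    return table
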