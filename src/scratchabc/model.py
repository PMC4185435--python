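"""Model/results interface to the inference machinery.

:class:`ScratchAssayABC` bundles an observed :class:`~scratchabc.pairstats.SummarySet`
with the forward simulator configuration; ``fit()`` tunes the tolerance if
needed, runs the ABC-MCMC chain and returns an :class:`ABCResults` carrying
the posterior sample, marginal summaries, credible intervals and unit
conversions, in the fit/results style of statsmodels.

Example
-------
>>> from scratchabc import ScratchAssayABC, make_synthetic_observation, paper_style_sim_config
>>> fix = make_synthetic_observation((0.25, 2e-3), paper_style_sim_config(), seed=7)
>>> model = ScratchAssayABC(fix.summaries, fix.sim_config, statistic="K", M=2000)
>>> res = model.fit(seed=1)
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace as dc_replace

import numpy as np
import pandas as pd

from .abc import (
    ABCConfig,
    Marginal,
    PosteriorChain,
    PosteriorHistogram,
    abc_mcmc,
    epsilon_schedule,
    histogram_posterior,
    kl_divergence,
    marginals,
    mean_and_ci,
    pilot_epsilon,
)
from .lattice import SimulationConfig, probs_to_rates
from .pairstats import SummarySet, summarize, map_coordinates_to_lattice

__all__ = ["ScratchAssayABC", "ABCResults"]


class ScratchAssayABC:
    """ABC model for (Pm, Pp) given snapshot summary statistics.

    Parameters
    ----------
    observed : SummarySet
        Summaries {c(i), q(i), N} of the observed snapshots.
    sim_config : SimulationConfig
        Forward-model geometry and schedule; must match the observation
        (lattice dimensions and snapshot times).  Its Pm/Pp are placeholders.
    statistic : {"q", "N", "c", "K"}
        Summary statistic compared inside the acceptance test (default the
        combined statistic K).
    epsilon : float, optional
        Acceptance tolerance; left None it is tuned during ``fit``.
    Gamma : (float, float)
        Random-walk proposal half-widths for (Pm, Pp).
    M : int
        Chain length (number of proposals).
    """

    def __init__(
        self,
        observed: SummarySet,
        sim_config: SimulationConfig,
        statistic: str = "K",
        epsilon: float | None = None,
        Gamma: tuple[float, float] = (1e-1, 1e-3),
        M: int = 10_000,
    ) -> None:
        self.observed = observed
        self.sim_config = sim_config
        self.statistic = statistic
        self.epsilon = epsilon
        self.Gamma = Gamma
        self.M = M

    @classmethod
    def from_coordinates(
        cls,
        coords: pd.DataFrame,
        sim_config: SimulationConfig,
        **kwargs,
    ) -> "ScratchAssayABC":
        """Build the model from a centroid table (columns time_h, x_um, y_um)
        by discretizing each time point onto the simulation lattice."""
        states = []
        for t in sim_config.snapshot_times:
            sub = coords[np.isclose(coords["time_h"], float(t))]
            if sub.empty:
                raise ValueError(f"no centroids at time {t} h in the coordinate table")
            state = map_coordinates_to_lattice(
                sub[["x_um", "y_um"]].to_numpy(),
                sim_config.delta,
                sim_config.X,
                sim_config.Y,
            )
            state.t = float(t)
            states.append(state)
        return cls(summarize(states), sim_config, **kwargs)

    def _config(self, seed: int) -> ABCConfig:
        return ABCConfig(
            sim_config=self.sim_config,
            epsilon=self.epsilon,
            Gamma=self.Gamma,
            M=self.M,
            statistic=self.statistic,
            seed=seed,
        )

    def tune_epsilon(
        self,
        seed: int = 0,
        factors=(1, 0.5, 0.25, 0.125, 0.0625, 0.03125),
        pilot_quantile: float = 0.02,
        pilot_n: int = 100,
        pilot_M: int = 600,
    ) -> tuple[float, pd.DataFrame]:
        """Choose the tolerance: a prior-predictive pilot sets the scale,
        then the stability schedule descends until the posterior stops
        changing (or the acceptance rate floor is hit)."""
        cfg = self._config(seed)
        base = self.epsilon or pilot_epsilon(
            cfg, self.observed, quantile=pilot_quantile, n=pilot_n
        )
        eps, table = epsilon_schedule(
            dc_replace(cfg, epsilon=base), self.observed, list(factors), pilot_M=pilot_M
        )
        return eps, table

    def fit(self, seed: int = 0, tune: bool | None = None, **tune_kwargs) -> "ABCResults":
        """Run the inference and return an :class:`ABCResults`.

        ``tune=None`` tunes epsilon only when it was not given.  All
        randomness (tuning pilots, chain proposals, per-proposal
        simulations) derives from ``seed``.
        """
        ss = np.random.SeedSequence(seed)
        tune_seed, chain_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
        if tune is None:
            tune = self.epsilon is None
        epsilon = self.epsilon
        schedule = None
        warm = None
        if tune:
            epsilon, schedule = self.tune_epsilon(seed=tune_seed, **tune_kwargs)
            warm = schedule.attrs.get("warm_start")
        if epsilon is None:
            raise ValueError("epsilon is unset and tuning is disabled")
        cfg = dc_replace(self._config(chain_seed), epsilon=epsilon)
        chain = abc_mcmc(cfg, self.observed, init_theta=warm)
        return ABCResults(self, chain, schedule)


class ABCResults:
    """Posterior sample and derived summaries of a fitted model.

    Attributes
    ----------
    chain : PosteriorChain
        The raw ABC-MCMC states (repeats included).
    epsilon_schedule : DataFrame or None
        Tuning diagnostics when the tolerance was tuned during ``fit``.
    params : ndarray
        Posterior mean of (Pm, Pp) — the headline estimate.
    """

    #: default posterior discretization (per-parameter bins over [0, 1])
    DEFAULT_GRID = (100, 10_000)

    def __init__(self, model: ScratchAssayABC, chain: PosteriorChain, schedule=None) -> None:
        self.model = model
        self.chain = chain
        self.epsilon_schedule = schedule
        self._hist_cache: dict[tuple[int, int], PosteriorHistogram] = {}

    # -- posterior containers ------------------------------------------------

    def histogram(self, n_m: int | None = None, n_p: int | None = None) -> PosteriorHistogram:
        n_m = n_m or self.DEFAULT_GRID[0]
        n_p = n_p or self.DEFAULT_GRID[1]
        key = (n_m, n_p)
        if key not in self._hist_cache:
            self._hist_cache[key] = histogram_posterior(self.chain, n_m=n_m, n_p=n_p)
        return self._hist_cache[key]

    def marginals(self, n_m: int | None = None, n_p: int | None = None) -> tuple[Marginal, Marginal]:
        return marginals(self.histogram(n_m, n_p))

    def kl_divergence(self, n_m: int | None = None, n_p: int | None = None) -> float:
        """Information gained over the uniform prior, in nats."""
        return kl_divergence(self.histogram(n_m, n_p))

    # -- point and interval estimates ---------------------------------------

    @property
    def params(self) -> np.ndarray:
        return self.chain.states.mean(axis=0)

    @property
    def acceptance_rate(self) -> float:
        return self.chain.acceptance_rate

    def param_table(
        self, level: float = 0.90, n_m: int | None = None, n_p: int | None = None
    ) -> pd.DataFrame:
        """Mean, mode and mode-symmetric credible interval for Pm, Pp and
        their continuum counterparts D (um^2/h) and lambda (1/h)."""
        marg_pm, marg_pp = self.marginals(n_m, n_p)
        rows = {}
        rows["Pm"] = dict(zip(("mean", "mode", "ci_lo", "ci_hi"), mean_and_ci(marg_pm, level)))
        rows["Pp"] = dict(zip(("mean", "mode", "ci_lo", "ci_hi"), mean_and_ci(marg_pp, level)))
        delta, tau = self.model.sim_config.delta, self.model.sim_config.tau
        rows["D_um2_per_h"] = {
            k: probs_to_rates(v, 0.0, delta, tau)[0] for k, v in rows["Pm"].items()
        }
        rows["lambda_per_h"] = {
            k: probs_to_rates(0.0, v, delta, tau)[1] for k, v in rows["Pp"].items()
        }
        return pd.DataFrame(rows).T[["mean", "mode", "ci_lo", "ci_hi"]]

    def summary(self, level: float = 0.90) -> str:
        """Human-readable fit report."""
        cfg = self.chain.config
        tbl = self.param_table(level=level)
        lines = [
            "ABC-MCMC posterior for the lattice exclusion process",
            "=" * 60,
            f"statistic: {cfg.statistic}    epsilon: {cfg.epsilon:.6g}",
            f"chain length M: {cfg.M}    acceptance rate: {self.acceptance_rate:.3f}",
            f"proposal half-widths Gamma: {cfg.Gamma}",
            f"lattice: {self.model.sim_config.X} x {self.model.sim_config.Y}"
            f" (delta = {self.model.sim_config.delta} um, tau = {self.model.sim_config.tau:.6g} h)",
            f"observation times (h): {self.model.observed.times}",
            "-" * 60,
            tbl.to_string(float_format=lambda v: f"{v:.6g}"),
            "-" * 60,
            f"credible level: {level:.0%} (interval symmetric about the mode)",
        ]
        return "\n".join(lines)

    def plot_marginals(self, level: float = 0.90, axes=None):
        """Plot both marginal posteriors with mean and credible bounds."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(9, 3.2))
        for ax, marg, name in zip(axes, self.marginals(), ("$P_m$", "$P_p$")):
            mean, _, lo, hi = mean_and_ci(marg, level)
            ax.fill_between(marg.centres, marg.mass, step="mid", alpha=0.5)
            ax.axvline(mean, color="g", ls="--", label="mean")
            ax.axvline(lo, color="r", ls=":")
            ax.axvline(hi, color="r", ls=":", label=f"{level:.0%} CI")
            ax.set_xlabel(name)
            ax.set_ylabel("posterior mass")
            ax.legend(frameon=False)
        return axes
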