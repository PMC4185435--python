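"""Discrete exclusion-process simulator for collective cell spreading.

The model is a discrete-time random walk with volume exclusion and
proliferation on a 2-D square lattice of ``X`` by ``Y`` sites with spacing
``delta`` (one cell diameter, micrometres).  Each site holds at most one
agent.  During each timestep of duration ``tau`` (hours), ``N(t)`` agents are
selected with replacement and each attempts, with probability ``Pm``, to move
to one of its four nearest-neighbour sites chosen uniformly at random; then a
further ``N(t)`` agents are selected with replacement and each attempts, with
probability ``Pp``, to place a daughter on a uniformly chosen neighbour site.
Events whose target site is occupied or outside the domain are aborted
(volume exclusion; zero-flux boundaries).  There is no agent death, so ``N``
never decreases.

The per-step probabilities are interchangeable with the macroscopic cell
diffusivity ``D`` (um^2/h) and proliferation rate ``lam`` (1/h) through the
standard lattice-to-continuum relations::

    D = Pm * delta**2 / (4 * tau)        lam = Pp / tau

The x axis runs parallel to the initial scratch, the y axis perpendicular to
it; agents start uniformly at random in the band ``y <= Y0``.  Site indices
are 1-based in the public API and in serialized output.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "SimulationConfig",
    "LatticeState",
    "probs_to_rates",
    "rates_to_probs",
    "initialize_lattice",
    "motility_sweep",
    "proliferation_sweep",
    "simulate",
    "advance",
]


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def probs_to_rates(Pm: float, Pp: float, delta: float, tau: float) -> tuple[float, float]:
    """Convert per-timestep event probabilities to continuum rates.

    Parameters
    ----------
    Pm, Pp : float
        Motility and proliferation probabilities per timestep, in [0, 1].
    delta : float
        Lattice spacing (um), positive.
    tau : float
        Timestep duration (h), positive.

    Returns
    -------
    (D, lam) : tuple of float
        Cell diffusivity ``D = Pm * delta**2 / (4 * tau)`` in um^2/h and
        proliferation rate ``lam = Pp / tau`` in 1/h.
    """
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if not (0 <= Pm <= 1):
        raise ValueError(f"Pm must lie in [0, 1], got {Pm}")
    if not (0 <= Pp <= 1):
        raise ValueError(f"Pp must lie in [0, 1], got {Pp}")
    return Pm * delta * delta / (4.0 * tau), Pp / tau


def rates_to_probs(D: float, lam: float, delta: float, tau: float) -> tuple[float, float]:
    """Invert :func:`probs_to_rates`: continuum rates to per-step probabilities.

    Raises
    ------
    ValueError
        If the resulting probability falls outside [0, 1], which signals that
        ``tau`` is too large for the requested rates.
    """
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if D < 0 or lam < 0:
        raise ValueError(f"rates must be non-negative, got D={D}, lam={lam}")
    Pm = 4.0 * D * tau / (delta * delta)
    Pp = lam * tau
    if Pm > 1:
        raise ValueError(
            f"motility probability Pm={Pm} exceeds 1: tau={tau} is too large for D={D}"
        )
    if Pp > 1:
        raise ValueError(
            f"proliferation probability Pp={Pp} exceeds 1: tau={tau} is too large for lam={lam}"
        )
    return Pm, Pp


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Geometry, rates and schedule of one exclusion-process simulation.

    Attributes
    ----------
    X, Y : int
        Lattice width (parallel to scratch) and height (perpendicular), sites.
    Y0 : int
        Height of the initially occupied band: agents start in ``y <= Y0``.
    N0 : int
        Initial agent count, at most ``X * Y0``.
    Pm, Pp : float
        Per-timestep motility and proliferation probabilities.
    delta : float
        Lattice spacing in um (defaults to one cell diameter, 25 um).
    tau : float
        Timestep duration in hours (default 1/24 h = 2.5 min).
    snapshot_times : list of float
        Times (h) at which the lattice state is recorded; each must be a
        non-negative integer multiple of ``tau``.
    seed : int
        RNG seed; identical configs produce bit-identical realizations.
    """

    X: int
    Y: int
    Y0: int
    N0: int
    Pm: float
    Pp: float
    delta: float = 25.0
    tau: float = 1.0 / 24.0
    snapshot_times: list = field(default_factory=lambda: [4.0, 8.0, 12.0])
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.Pm <= 1):
            raise ValueError(f"Pm must lie in [0, 1], got {self.Pm}")
        if not (0 <= self.Pp <= 1):
            raise ValueError(f"Pp must lie in [0, 1], got {self.Pp}")
        if not (1 <= self.Y0 <= self.Y):
            raise ValueError(f"Y0 must lie in [1, Y], got Y0={self.Y0}, Y={self.Y}")
        if not (0 <= self.N0 <= self.X * self.Y0):
            raise ValueError(
                f"N0 must lie in [0, X*Y0] = [0, {self.X * self.Y0}], got {self.N0}"
            )
        if self.delta <= 0 or self.tau <= 0:
            raise ValueError("delta and tau must be positive")
        for t in self.snapshot_times:
            self.steps_for_time(t)

    def steps_for_time(self, t: float) -> int:
        """Number of completed timesteps at time ``t``; errors if ``t`` is not
        a non-negative integer multiple of ``tau``."""
        if t < 0:
            raise ValueError(f"snapshot time must be non-negative, got {t}")
        n = t / self.tau
        n_round = round(n)
        if abs(n - n_round) > 1e-9 * max(1.0, abs(n)):
            raise ValueError(
                f"snapshot time {t} h is not an integer multiple of tau={self.tau} h"
            )
        return int(n_round)

    def replace(self, **kwargs) -> "SimulationConfig":
        new = copy.copy(self)
        for k, v in kwargs.items():
            setattr(new, k, v)
        new.__post_init__()
        return new


@dataclass
class LatticeState:
    """Occupancy snapshot: ``occupancy[x-1, y-1]`` is 1 iff site (x, y) holds
    an agent (1-based indices); ``N`` agents at simulation time ``t`` (h)."""

    occupancy: np.ndarray
    N: int
    t: float

    def __post_init__(self) -> None:
        self.occupancy = np.ascontiguousarray(self.occupancy, dtype=np.uint8)
        if self.occupancy.ndim != 2:
            raise ValueError("occupancy must be a 2-D array")
        if self.occupancy.max(initial=0) > 1:
            raise ValueError("at most one agent per site")
        n_occ = int(self.occupancy.sum())
        if n_occ != self.N:
            raise ValueError(f"N={self.N} does not match {n_occ} occupied sites")

    @property
    def X(self) -> int:
        return self.occupancy.shape[0]

    @property
    def Y(self) -> int:
        return self.occupancy.shape[1]

    def coordinates(self) -> np.ndarray:
        """(N, 2) array of 1-based (x, y) site indices, lexicographic order."""
        xs, ys = np.nonzero(self.occupancy)
        return np.column_stack([xs + 1, ys + 1])

    def copy(self) -> "LatticeState":
        return LatticeState(self.occupancy.copy(), self.N, self.t)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------
# RNG: an inline xorshift64* stream (state threaded through the kernels),
# seeded from the simulation seed via splitmix64.  Consumption order per
# attempted event: selection index, event Bernoulli, then (only if the event
# fires) direction.  One stream per run; sweeps never reseed.

_INV_2_53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _next_u64(s):
    s ^= s >> np.uint64(12)
    s ^= (s << np.uint64(25)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s ^= s >> np.uint64(27)
    return s, (s * np.uint64(2685821657736338717)) & np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True)
def _mix_seed(seed):
    # splitmix64 finalizer: any 64-bit input -> well-mixed nonzero state
    z = (np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = z ^ (z >> np.uint64(31))
    if z == np.uint64(0):
        z = np.uint64(0x9E3779B97F4A7C15)
    return z


@njit(cache=True)
def _motility_sweep_k(occ, xs, ys, n, pm, state):
    X, Y = occ.shape
    un = np.uint64(n)
    for _ in range(n):
        state, z = _next_u64(state)
        j = int(((z >> np.uint64(32)) * un) >> np.uint64(32))
        state, z = _next_u64(state)
        if (z >> np.uint64(11)) * _INV_2_53 >= pm:
            continue
        state, z = _next_u64(state)
        d = int(z & np.uint64(3))
        x = xs[j]
        y = ys[j]
        if d == 0:
            nx, ny = x + 1, y
        elif d == 1:
            nx, ny = x - 1, y
        elif d == 2:
            nx, ny = x, y + 1
        else:
            nx, ny = x, y - 1
        if nx < 0 or nx >= X or ny < 0 or ny >= Y:
            continue
        if occ[nx, ny]:
            continue
        occ[x, y] = 0
        occ[nx, ny] = 1
        xs[j] = nx
        ys[j] = ny
    return state


@njit(cache=True)
def _proliferation_sweep_k(occ, xs, ys, n, pp, state):
    # Selection pool frozen at sweep start: exactly n attempts, daughters
    # (appended at index >= n) are not selectable until the next timestep.
    X, Y = occ.shape
    un = np.uint64(n)
    N = n
    for _ in range(n):
        state, z = _next_u64(state)
        j = int(((z >> np.uint64(32)) * un) >> np.uint64(32))
        state, z = _next_u64(state)
        if (z >> np.uint64(11)) * _INV_2_53 >= pp:
            continue
        state, z = _next_u64(state)
        d = int(z & np.uint64(3))
        x = xs[j]
        y = ys[j]
        if d == 0:
            nx, ny = x + 1, y
        elif d == 1:
            nx, ny = x - 1, y
        elif d == 2:
            nx, ny = x, y + 1
        else:
            nx, ny = x, y - 1
        if nx < 0 or nx >= X or ny < 0 or ny >= Y:
            continue
        if occ[nx, ny]:
            continue
        occ[nx, ny] = 1
        xs[N] = nx
        ys[N] = ny
        N += 1
    return N, state


@njit(cache=True)
def _motility_sweep_seeded(occ, xs, ys, n, pm, seed):
    _motility_sweep_k(occ, xs, ys, n, pm, _mix_seed(seed))


@njit(cache=True)
def _proliferation_sweep_seeded(occ, xs, ys, n, pp, seed):
    n_after, _ = _proliferation_sweep_k(occ, xs, ys, n, pp, _mix_seed(seed))
    return n_after


@njit(cache=True)
def _run_k(occ, xs, ys, N0, pm, pp, snap_steps, seed):
    state = _mix_seed(seed)
    X, Y = occ.shape
    n_snap = snap_steps.shape[0]
    snaps = np.empty((n_snap, X, Y), np.uint8)
    Ns = np.empty(n_snap, np.int64)
    N = N0
    k = 0
    while k < n_snap and snap_steps[k] == 0:
        snaps[k, :, :] = occ
        Ns[k] = N
        k += 1
    last = snap_steps[n_snap - 1]
    full = X * Y
    for step in range(1, last + 1):
        # a completely full lattice is frozen: every motility and
        # proliferation target is occupied, so the sweeps are exact no-ops
        if 0 < N < full:
            state = _motility_sweep_k(occ, xs, ys, N, pm, state)
            N, state = _proliferation_sweep_k(occ, xs, ys, N, pp, state)
        while k < n_snap and snap_steps[k] == step:
            snaps[k, :, :] = occ
            Ns[k] = N
            k += 1
    return snaps, Ns


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def initialize_lattice(config: SimulationConfig, rng: np.random.Generator) -> LatticeState:
    """Place ``N0`` agents uniformly at random, without replacement, among the
    ``X * Y0`` sites of the band ``y <= Y0``; all other sites empty; t = 0."""
    X, Y, Y0, N0 = config.X, config.Y, config.Y0, config.N0
    if N0 > X * Y0:
        raise ValueError(f"N0={N0} exceeds band capacity X*Y0={X * Y0}")
    occ = np.zeros((X, Y), dtype=np.uint8)
    sites = rng.choice(X * Y0, size=N0, replace=False)
    occ_band = occ[:, :Y0].reshape(-1)
    occ_band[sites] = 1
    occ[:, :Y0] = occ_band.reshape(X, Y0)
    return LatticeState(occ, int(N0), 0.0)


def _agent_arrays(state: LatticeState) -> tuple[np.ndarray, np.ndarray]:
    cap = state.X * state.Y
    xs = np.empty(cap, dtype=np.int64)
    ys = np.empty(cap, dtype=np.int64)
    ix, iy = np.nonzero(state.occupancy)
    xs[: state.N] = ix
    ys[: state.N] = iy
    return xs, ys


def _draw_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def motility_sweep(state: LatticeState, Pm: float, rng: np.random.Generator) -> LatticeState:
    """One motility sweep: ``N`` selections with replacement; each selected
    agent moves with probability ``Pm`` to a uniformly chosen neighbour site,
    aborted if the target is occupied or outside the domain.  Returns a new
    state; ``N`` and ``t`` unchanged (a sweep is half a timestep)."""
    if not (0 <= Pm <= 1):
        raise ValueError(f"Pm must lie in [0, 1], got {Pm}")
    new = state.copy()
    if new.N == 0:
        return new
    xs, ys = _agent_arrays(new)
    _motility_sweep_seeded(new.occupancy, xs, ys, new.N, Pm, _draw_seed(rng))
    return new


def proliferation_sweep(state: LatticeState, Pp: float, rng: np.random.Generator) -> LatticeState:
    """One proliferation sweep: ``N`` selections with replacement from the
    pool frozen at sweep start; each selected agent places a daughter on a
    uniformly chosen neighbour with probability ``Pp`` (aborted on occupied
    or off-domain targets).  ``N`` grows by the number of successful events."""
    if not (0 <= Pp <= 1):
        raise ValueError(f"Pp must lie in [0, 1], got {Pp}")
    new = state.copy()
    if new.N == 0:
        return new
    xs, ys = _agent_arrays(new)
    n_after = _proliferation_sweep_seeded(
        new.occupancy, xs, ys, new.N, Pp, _draw_seed(rng)
    )
    new.N = int(n_after)
    return new


def advance(
    state: LatticeState,
    Pm: float,
    Pp: float,
    snapshot_steps: list[int] | np.ndarray,
    seed: int,
    tau: float = 1.0 / 24.0,
) -> list[LatticeState]:
    """Advance ``state`` through full timesteps (motility sweep then
    proliferation sweep) and return copies at the requested step counts
    (sorted, non-negative).  The input state is not modified."""
    steps = np.asarray(sorted(int(s) for s in snapshot_steps), dtype=np.int64)
    if steps.size == 0:
        return []
    if steps[0] < 0:
        raise ValueError("snapshot steps must be non-negative")
    work = state.copy()
    xs, ys = _agent_arrays(work)
    snaps, Ns = _run_k(work.occupancy, xs, ys, work.N, Pm, Pp, steps, seed)
    return [
        LatticeState(snaps[k].copy(), int(Ns[k]), state.t + tau * int(steps[k]))
        for k in range(steps.size)
    ]


def simulate(config: SimulationConfig, rng: np.random.Generator | None = None) -> list[LatticeState]:
    """Run one realization and return deep-copied snapshots at
    ``config.snapshot_times``.

    Each timestep applies a motility sweep then a proliferation sweep.  With
    ``rng=None`` the realization is a pure function of ``config`` (including
    ``config.seed``): same config, same snapshots, bit for bit.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    steps = [config.steps_for_time(t) for t in config.snapshot_times]
    order = np.argsort(steps)
    state0 = initialize_lattice(config, rng)
    kernel_seed = _draw_seed(rng)
    snaps_sorted = advance(
        state0, config.Pm, config.Pp, [steps[i] for i in order], kernel_seed, tau=config.tau
    )
    out: list[LatticeState] = [None] * len(steps)  # type: ignore[list-item]
    for rank, i in enumerate(order):
        out[i] = snaps_sorted[rank]
    return out
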