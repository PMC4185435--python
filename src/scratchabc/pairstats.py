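"""Pair-distance counts, the pair correlation function, and summary distances.

Snapshots are reduced to low-dimensional summary statistics before being
compared inside the ABC machinery:

* ``c(i)`` — the number of unordered pairs of occupied sites lying in the
  same column ``x`` and separated by ``i`` rows, for ``i = 1 .. Y-1``.  Pairs
  are counted in the y direction only (perpendicular to the scratch), where
  the spatial signal of a spreading front lives.
* ``chat(i)`` — the expected counts were the ``N`` agents placed uniformly at
  random without overlap: the ``X * (Y - i)`` same-column site pairs at
  separation ``i`` times the probability ``N (N-1) / (X Y (X Y - 1))`` that
  both sites of a given pair are occupied.
* ``q(i) = c(i) / chat(i)`` — the pair correlation function.  ``q > 1`` means
  pairs at that separation are over-represented relative to uniform random
  placement; ``q ~ 1`` everywhere means no spatial structure.

Distances between an observed and a simulated :class:`SummarySet` (statistic
``q``, ``c``, ``N`` or the combination ``K``) are mean absolute differences,
normalized on the observed side so that the components of ``K`` are
commensurate, averaged over the observation times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import LatticeState

__all__ = [
    "PairCounts",
    "PairCorrelation",
    "SummarySet",
    "count_pairs_y",
    "expected_counts",
    "pair_correlation",
    "summarize",
    "map_coordinates_to_lattice",
    "distance",
    "STATISTICS",
]

STATISTICS = ("q", "N", "c", "K")


@dataclass
class PairCounts:
    """Same-column pair counts ``c[i-1]`` for separations ``i = 1 .. Y-1``."""

    c: np.ndarray
    N: int
    X: int
    Y: int

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=np.int64)
        if self.c.shape != (self.Y - 1,):
            raise ValueError(f"c must have length Y-1={self.Y - 1}, got {self.c.shape}")
        if (self.c < 0).any():
            raise ValueError("pair counts must be non-negative")


@dataclass
class PairCorrelation:
    """Pair correlation ``q[i-1] = c(i) / chat(i)`` and density ``rho = N/(XY)``."""

    q: np.ndarray
    N: int
    X: int
    Y: int

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (self.Y - 1,):
            raise ValueError(f"q must have length Y-1={self.Y - 1}, got {self.q.shape}")

    @property
    def rho(self) -> float:
        return self.N / (self.X * self.Y)


class SummarySet:
    """Per-time-point summaries {c(i), q(i), N} of one realization.

    Parameters
    ----------
    times : sequence of float
        Strictly increasing observation times (h).
    counts : sequence of PairCounts
        One per time, all sharing lattice dimensions.
    """

    def __init__(self, times, counts) -> None:
        times = [float(t) for t in times]
        if len(times) != len(counts):
            raise ValueError("times and counts must have equal length")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        if len({(pc.X, pc.Y) for pc in counts}) > 1:
            raise ValueError("all time points must share lattice dimensions")
        self.times = times
        self.counts = list(counts)
        self.X = counts[0].X
        self.Y = counts[0].Y

    @property
    def N(self) -> np.ndarray:
        return np.array([pc.N for pc in self.counts], dtype=np.int64)

    @property
    def c(self) -> np.ndarray:
        """(n_times, Y-1) array of pair counts."""
        return np.stack([pc.c for pc in self.counts])

    @property
    def q(self) -> np.ndarray:
        """(n_times, Y-1) array of pair correlations (requires N >= 2)."""
        return np.stack([pair_correlation(pc).q for pc in self.counts])

    def __len__(self) -> int:
        return len(self.times)


def count_pairs_y(state: LatticeState) -> PairCounts:
    """Count occupied same-column site pairs for each separation i = 1..Y-1.

    Only the y direction (perpendicular to the scratch) is counted: a pair of
    agents at (x, y1) and (x, y2) contributes to ``c(|y1 - y2|)``.
    """
    occ = state.occupancy.astype(bool)
    Y = state.Y
    c = np.array(
        [np.count_nonzero(occ[:, :-i] & occ[:, i:]) for i in range(1, Y)],
        dtype=np.int64,
    )
    return PairCounts(c, state.N, state.X, Y)


def expected_counts(N: int, X: int, Y: int) -> np.ndarray:
    """Expected pair counts ``chat(i)`` under uniform random placement of N
    agents on an X-by-Y lattice without overlap, for i = 1..Y-1.

    ``chat(i) = X (Y - i) N (N - 1) / (X Y (X Y - 1))``; zero for N < 2.
    """
    if not (0 <= N <= X * Y):
        raise ValueError(f"N must lie in [0, X*Y], got N={N}")
    i = np.arange(1, Y)
    if N < 2:
        return np.zeros(Y - 1)
    M = X * Y
    return X * (Y - i) * (N * (N - 1)) / (M * (M - 1))


def pair_correlation(counts: PairCounts) -> PairCorrelation:
    """Normalize pair counts into the pair correlation ``q(i) = c(i)/chat(i)``."""
    if counts.N < 2:
        raise ValueError(
            f"pair correlation undefined for N={counts.N} < 2: no pairs exist"
        )
    chat = expected_counts(counts.N, counts.X, counts.Y)
    return PairCorrelation(counts.c / chat, counts.N, counts.X, counts.Y)


def summarize(states: list[LatticeState]) -> SummarySet:
    """Reduce simulator snapshots to a :class:`SummarySet`."""
    return SummarySet([s.t for s in states], [count_pairs_y(s) for s in states])


def map_coordinates_to_lattice(
    points: np.ndarray, delta: float, X: int, Y: int
) -> LatticeState:
    """Discretize cell centroid coordinates (um) onto the simulation lattice.

    Each centroid is assigned to the lattice site whose centre
    ``((x - 1/2) delta, (y - 1/2) delta)`` is nearest.  Volume exclusion is
    enforced: points are processed in input order, and a point whose site is
    already taken is displaced to the vacant site nearest to the point's own
    continuous position (ties broken by smaller x, then smaller y), so the
    agent count is preserved.

    Parameters
    ----------
    points : (n, 2) array
        Centroid (x, y) positions in um, inside [0, X*delta] x [0, Y*delta].
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    out = (pts[:, 0] < 0) | (pts[:, 0] > X * delta) | (pts[:, 1] < 0) | (pts[:, 1] > Y * delta)
    if out.any():
        bad = pts[out][0]
        raise ValueError(f"point ({bad[0]}, {bad[1]}) um lies outside the {X * delta} x {Y * delta} um field")
    if pts.shape[0] > X * Y:
        raise ValueError(f"{pts.shape[0]} points cannot fit on an {X}x{Y} lattice")
    occ = np.zeros((X, Y), dtype=np.uint8)
    cx = (np.arange(X) + 0.5) * delta  # site centres, 0-based index k -> site k+1
    cy = (np.arange(Y) + 0.5) * delta
    for px, py in pts:
        ix = min(X - 1, int(px // delta))
        iy = min(Y - 1, int(py // delta))
        if not occ[ix, iy]:
            occ[ix, iy] = 1
            continue
        # collision: nearest vacant site to the point's continuous position
        d2 = (cx[:, None] - px) ** 2 + (cy[None, :] - py) ** 2
        d2 = np.where(occ.astype(bool), np.inf, d2)
        vx, vy = np.unravel_index(np.lexsort(
            (np.arange(X * Y) % Y, np.arange(X * Y) // Y, d2.ravel())
        )[0], (X, Y))
        if not np.isfinite(d2[vx, vy]):
            raise ValueError(f"no vacant site left for point ({px}, {py}) um")
        occ[vx, vy] = 1
    return LatticeState(occ, int(pts.shape[0]), 0.0)


def _check_compatible(a: SummarySet, b: SummarySet) -> None:
    if a.times != b.times:
        raise ValueError(f"observation times differ: {a.times} vs {b.times}")
    if (a.X, a.Y) != (b.X, b.Y):
        raise ValueError(
            f"lattice dimensions differ: {(a.X, a.Y)} vs {(b.X, b.Y)}"
        )


def distance(summary_obs: SummarySet, summary_sim: SummarySet, statistic: str) -> float:
    """Average distance between observed and simulated summaries.

    Per observation time t (then averaged over times):

    * ``q``: mean over i of |q_obs(i) - q_sim(i)|
    * ``c``: mean over i of |c_obs(i) - c_sim(i)|, divided by
      max(1, mean_i c_obs(i)) so the distance is scale-free
    * ``N``: |N_obs - N_sim| / N_obs
    * ``K``: (d[q] + d[N]) / 2 — the combined statistic

    Normalization uses the observed side, so the distance is deliberately
    asymmetric in its arguments.
    """
    _check_compatible(summary_obs, summary_sim)
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}, got {statistic!r}")
    if statistic == "K":
        return 0.5 * (
            distance(summary_obs, summary_sim, "q")
            + distance(summary_obs, summary_sim, "N")
        )
    if statistic == "N":
        n_obs = summary_obs.N.astype(float)
        n_sim = summary_sim.N.astype(float)
        return float(np.mean(np.abs(n_obs - n_sim) / n_obs))
    if statistic == "q":
        return float(np.mean(np.abs(summary_obs.q - summary_sim.q)))
    # statistic == "c"
    c_obs = summary_obs.c.astype(float)
    c_sim = summary_sim.c.astype(float)
    per_time = np.abs(c_obs - c_sim).mean(axis=1) / np.maximum(1.0, c_obs.mean(axis=1))
    return float(np.mean(per_time))
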