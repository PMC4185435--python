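"""Plain-text serialization: lattice states, centroid tables, summaries,
chains and configs.  Every writer has a reader that round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .lattice import LatticeState
from .pairstats import PairCounts, SummarySet, expected_counts, pair_correlation

__all__ = [
    "write_state_csv",
    "read_state_csv",
    "write_state_matrix",
    "read_state_matrix",
    "write_coords_csv",
    "read_coords_csv",
    "states_to_coords",
    "write_summary_set",
    "read_summary_set",
    "write_chain_csv",
    "read_config",
    "write_config",
]


# -- lattice states ---------------------------------------------------------

def write_state_csv(state: LatticeState, path, delta: float = 25.0) -> None:
    """Occupied-site list: metadata header (t, X, Y, delta) then 1-based x,y."""
    coords = state.coordinates()
    with open(path, "w") as fh:
        fh.write("t,X,Y,delta\n")
        fh.write(f"{state.t!r},{state.X},{state.Y},{delta!r}\n")
        fh.write("x,y\n")
        for x, y in coords:
            fh.write(f"{x},{y}\n")


def read_state_csv(path) -> tuple[LatticeState, float]:
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if header != ["t", "X", "Y", "delta"]:
            raise ValueError(f"unexpected state-CSV header in {path}: {header}")
        t_s, x_s, y_s, d_s = fh.readline().strip().split(",")
        t, X, Y, delta = float(t_s), int(x_s), int(y_s), float(d_s)
        cols = fh.readline().strip().split(",")
        if cols != ["x", "y"]:
            raise ValueError(f"unexpected coordinate columns in {path}: {cols}")
        occ = np.zeros((X, Y), dtype=np.uint8)
        n = 0
        for line in fh:
            line = line.strip()
            if not line:
                continue
            xs, ys = line.split(",")
            occ[int(xs) - 1, int(ys) - 1] = 1
            n += 1
    return LatticeState(occ, n, t), delta


def write_state_matrix(state: LatticeState, path) -> None:
    """Dense 0/1 occupancy matrix, one lattice row y per text line."""
    np.savetxt(path, state.occupancy.T, fmt="%d", header=f"t={state.t!r}")


def read_state_matrix(path, t: float | None = None) -> LatticeState:
    with open(path) as fh:
        first = fh.readline()
    if t is None:
        t = float(first.lstrip("# ").strip().split("=", 1)[1]) if "=" in first else 0.0
    occ = np.loadtxt(path, dtype=np.uint8, ndmin=2).T
    return LatticeState(occ, int(occ.sum()), t)


# -- centroid coordinate tables --------------------------------------------

def states_to_coords(states: list[LatticeState], delta: float) -> pd.DataFrame:
    """Centroid table (time_h, x_um, y_um) with agents at site centres."""
    frames = []
    for s in states:
        xy = s.coordinates().astype(float)
        frames.append(
            pd.DataFrame(
                {
                    "time_h": s.t,
                    "x_um": (xy[:, 0] - 0.5) * delta,
                    "y_um": (xy[:, 1] - 0.5) * delta,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_coords_csv(coords: pd.DataFrame, path) -> None:
    coords.to_csv(path, index=False)


def read_coords_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"time_h", "x_um", "y_um"} - set(df.columns)
    if missing:
        raise ValueError(f"coordinate CSV {path} lacks columns {sorted(missing)}")
    return df


# -- summary sets -----------------------------------------------------------

def _time_tag(t: float) -> str:
    return f"{t:g}".replace(".", "p")


def write_summary_set(summary: SummarySet, directory) -> None:
    """One CSV (i, c_i, chat_i, q_i) plus JSON sidecar (N, X, Y, rho, t)
    per observation time, in ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t, pc in zip(summary.times, summary.counts):
        tag = _time_tag(t)
        chat = expected_counts(pc.N, pc.X, pc.Y)
        q = pair_correlation(pc).q if pc.N >= 2 else np.full(pc.Y - 1, np.nan)
        pd.DataFrame(
            {"i": np.arange(1, pc.Y), "c_i": pc.c, "chat_i": chat, "q_i": q}
        ).to_csv(directory / f"summaries_t{tag}.csv", index=False)
        sidecar = {
            "t": t,
            "N": int(pc.N),
            "X": pc.X,
            "Y": pc.Y,
            "rho": pc.N / (pc.X * pc.Y),
        }
        with open(directory / f"summaries_t{tag}.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)


def read_summary_set(directory) -> SummarySet:
    directory = Path(directory)
    sidecars = sorted(directory.glob("summaries_t*.json"))
    if not sidecars:
        raise FileNotFoundError(f"no summaries_t*.json found in {directory}")
    entries = []
    for sc in sidecars:
        with open(sc) as fh:
            meta = json.load(fh)
        df = pd.read_csv(sc.with_suffix(".csv"))
        pc = PairCounts(df["c_i"].to_numpy(np.int64), meta["N"], meta["X"], meta["Y"])
        entries.append((float(meta["t"]), pc))
    entries.sort(key=lambda e: e[0])
    return SummarySet([t for t, _ in entries], [pc for _, pc in entries])


# -- chains and configs ------------------------------------------------------

def write_chain_csv(chain, path) -> None:
    chain.to_frame().to_csv(path, index=False)


def read_config(path) -> dict:
    """Flat YAML (JSON is a YAML subset) key-value config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
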