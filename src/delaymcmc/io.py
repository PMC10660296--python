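"""Readers, writers, configuration and posterior summaries.

All tabular artefacts are plain CSV; configuration is YAML.  Observations,
trajectories and counts use tidy long formats so that any number of
species, reactions and cells fits one schema:

observations / trajectories: ``trajectory_id,time,species,value``
reaction counts:             ``trajectory_id,interval,reaction,count``

The time grid is the closed range 0..T in unit steps; counting intervals
are half-open (i-1, i], indexed by their right endpoint i.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .likelihood import Observations
from .network import (
    DelayDistribution,
    DelayedNetwork,
    ParameterSet,
    Propensity,
    Reaction,
    build_two_step_model,
)

__all__ = [
    "read_observations",
    "write_observations",
    "write_trajectories",
    "write_counts",
    "load_config",
    "summarize_posterior",
    "format_mean_sd",
    "RunManifest",
]


# ---------------------------------------------------------------------------
# observations
# ---------------------------------------------------------------------------


def write_observations(path, yobs: np.ndarray, species: str = "Y") -> None:
    """Write per-cell observation series (n_traj, T+1) as tidy CSV."""
    yobs = np.atleast_2d(np.asarray(yobs, dtype=float))
    n, nt = yobs.shape
    df = pd.DataFrame(
        {
            "trajectory_id": np.repeat(np.arange(n), nt),
            "time": np.tile(np.arange(nt), n),
            "species": species,
            "value": yobs.ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_observations(path) -> tuple[np.ndarray, list[str]]:
    """Read tidy observations; returns (array (n_traj, n_species, T+1), species).

    The grid must be the consecutive integers 0..T, identical for every
    trajectory; a missing time point raises an error naming the trajectory
    and time rather than silently imputing.
    """
    df = pd.read_csv(path)
    required = {"trajectory_id", "time", "species", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observation file lacks columns: {sorted(missing)}")
    times = df["time"].to_numpy()
    if not np.allclose(times, np.round(times)):
        raise ValueError("observation times must be integers on the unit grid")
    df["time"] = np.round(times).astype(int)
    species = sorted(df["species"].unique())
    traj_ids = sorted(df["trajectory_id"].unique())
    T = int(df["time"].max())
    grid = np.arange(T + 1)
    out = np.empty((len(traj_ids), len(species), T + 1))
    for a, tid in enumerate(traj_ids):
        for b, sp in enumerate(species):
            sub = df[(df["trajectory_id"] == tid) & (df["species"] == sp)]
            sub = sub.sort_values("time")
            t = sub["time"].to_numpy()
            if t.size != T + 1 or not np.array_equal(t, grid):
                missing_t = sorted(int(x) for x in set(grid) - set(t))
                raise ValueError(
                    f"trajectory {tid}, species {sp!r}: missing time "
                    f"point(s) {missing_t[:5]} — grids must be complete"
                )
            out[a, b] = sub["value"].to_numpy()
    return out, species


def write_trajectories(path, traj: np.ndarray, species: list[str]) -> None:
    """Write (n_traj, u, T+1) integer trajectories as tidy CSV."""
    traj = np.asarray(traj)
    n, u, nt = traj.shape
    df = pd.DataFrame(
        {
            "trajectory_id": np.repeat(np.arange(n), u * nt),
            "species": np.tile(np.repeat(species, nt), n),
            "time": np.tile(np.arange(nt), n * u),
            "count": traj.ravel(),
        }
    )
    df.to_csv(path, index=False)


def write_counts(path, counts: np.ndarray, reactions: list[str]) -> None:
    """Write (n_traj, v, T) per-interval reaction counts as tidy CSV."""
    counts = np.asarray(counts)
    n, v, T = counts.shape
    df = pd.DataFrame(
        {
            "trajectory_id": np.repeat(np.arange(n), v * T),
            "reaction": np.tile(np.repeat(reactions, T), n),
            "interval": np.tile(np.arange(1, T + 1), n * v),
            "count": counts.ravel(),
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def load_config(path) -> tuple[DelayedNetwork, ParameterSet, float]:
    """Load a network configuration; returns (network, params, sigma_e).

    Two dialects are accepted.  The short form names the two-step model:

        AX: 10.0
        AY: 60.0
        KM: 100.0
        B: 0.05
        tauX: [3.6, 0.6]
        tauY: [3.6, 0.6]
        sigma_e: 10.0
        x0: 0        # optional
        y0: 0        # optional

    The generic form lists species[], reactions[], init_state and
    observed[]; see the README for the schema.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    sigma_e = float(cfg.get("sigma_e", 0.0))
    if "species" not in cfg:
        net, params = build_two_step_model(
            float(cfg["AX"]),
            float(cfg["AY"]),
            float(cfg["KM"]),
            float(cfg["B"]),
            DelayDistribution.gamma(*map(float, cfg["tauX"])),
            DelayDistribution.gamma(*map(float, cfg["tauY"])),
            int(cfg.get("x0", 0)),
            int(cfg.get("y0", 0)),
        )
        return net, params, sigma_e

    species = [s["name"] for s in cfg["species"]]
    observed = [s["name"] for s in cfg["species"] if s.get("observed", False)]
    reactions = []
    for rx in cfg["reactions"]:
        prop = rx["propensity"]
        reactions.append(
            Reaction(
                name=rx.get("name", f"R{len(reactions) + 1}"),
                reactants=rx.get("reactants", {}),
                products=rx.get("products", {}),
                propensity=Propensity(
                    form=prop["form"],
                    rate=prop["rate"],
                    species=prop.get("species"),
                    km=prop.get("km"),
                ),
                delay=_delay_from_config(rx.get("delay")),
            )
        )
    net = DelayedNetwork(
        species=tuple(species),
        observed=tuple(observed),
        reactions=tuple(reactions),
        init_state=cfg.get("init_state", {}),
    )
    params = ParameterSet(cfg.get("params", {}))
    return net, params, sigma_e


def _delay_from_config(d) -> DelayDistribution:
    if not d or d.get("family", "dirac_zero") == "dirac_zero":
        return DelayDistribution.dirac_zero()
    if d["family"] == "gamma":
        return DelayDistribution.gamma(d["shape"], d["rate"])
    if d["family"] == "sum_of_gammas":
        return DelayDistribution.sum_of_gammas(
            [(c["shape"], c["rate"]) for c in d["components"]]
        )
    raise ValueError(f"unknown delay family {d['family']!r}")


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


def format_mean_sd(mean: float, sd: float) -> str:
    """Render an estimate as "12.90±0.14" with two significant sd digits."""
    if sd <= 0 or not np.isfinite(sd):
        return f"{mean:.4g}±0"
    digits = max(0, 1 - int(np.floor(np.log10(sd))))
    return f"{mean:.{digits}f}±{sd:.{digits}f}"


def summarize_posterior(samples, normalize_by: dict | None = None) -> pd.DataFrame:
    """Per-parameter posterior summary table.

    Columns: mean, sd, q2.5, q97.5, ess (bulk effective sample size) and a
    ``mean±sd`` rendering; when ``normalize_by`` supplies ground-truth
    values, normalised rows (draws divided by the true value) are appended
    with a ``/truth`` suffix, the convention used to report recovery of
    known generative parameters.
    """
    draws = samples.draws if hasattr(samples, "draws") else samples
    cols = [c for c in draws.columns if c != "iteration"]
    if not cols or draws.empty:
        raise ValueError("no posterior draws to summarise")
    try:
        import arviz as az

        ess = {c: float(az.ess(draws[c].to_numpy())) for c in cols}
    except Exception:  # pragma: no cover - diagnostic only
        ess = {c: float("nan") for c in cols}
    rows = []
    for c in cols:
        x = draws[c].to_numpy(dtype=float)
        entries = [(c, x)]
        if normalize_by and c in normalize_by and normalize_by[c] != 0:
            entries.append((f"{c}/truth", x / normalize_by[c]))
        for name, vals in entries:
            m, s = float(vals.mean()), float(vals.std(ddof=1))
            rows.append(
                {
                    "parameter": name,
                    "mean": m,
                    "sd": s,
                    "q2.5": float(np.quantile(vals, 0.025)),
                    "q97.5": float(np.quantile(vals, 0.975)),
                    "ess": ess[c],
                    "mean±sd": format_mean_sd(m, s),
                }
            )
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI output."""

    command: str
    config: dict
    seed: int | None
    started: str = field(default_factory=lambda: _time.strftime("%Y-%m-%dT%H:%M:%S"))
    wall_clock_s: float = 0.0
    acceptance: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256

    def add_output(self, path) -> None:
        self.outputs[str(path)] = _sha256(path)

    def write(self, path) -> None:
        from . import __version__

        payload = {
            "command": self.command,
            "version": __version__,
            "config": self.config,
            "seed": self.seed,
            "started": self.started,
            "wall_clock_s": round(self.wall_clock_s, 3),
            "acceptance": self.acceptance,
            "outputs": self.outputs,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
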