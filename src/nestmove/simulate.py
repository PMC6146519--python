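"""Synthetic tag-data generator drawn from the exact generative model.

Emulates the two data streams of a satellite-tagged whale deployment:
irregular Argos fixes with class-dependent location error around a latent
6-hourly switching correlated random walk, and within-interval dive records
whose maximum depths follow the nested traveling/foraging/resting emission
mixture.  Defaults emulate the observed regime of the study system (11
animals, roughly 8 fixes and 24 dives per 6-h interval, a mixed Argos
class distribution); everything is reproducible bit-for-bit from the seed.

Coordinates are planar kilometres in an abstract local projection — the
generator never emits geographic degrees (projection is owned by
preprocessing).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .model import (ARGOS_CLASSES, ARS, DIVE_THRESHOLD_M, FORAGING, TRAVELING,
                    ArgosErrorTable, ModelParameters, ParameterError,
                    default_error_table, default_parameters, process_mean,
                    sub_transition_matrix)
from .tracks import INTERVAL_HOURS, TrackData

DEFAULT_CLASS_PROBS: Mapping[str, float] = {
    "3": 0.05, "2": 0.08, "1": 0.12, "0": 0.15, "A": 0.25, "B": 0.35,
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic deployment set."""

    n_animals: int = 11
    steps_per_animal: int = 100
    true_params: ModelParameters = field(default_factory=default_parameters)
    fixes_per_interval_rate: float = 8.0
    dives_per_interval_rate: float = 24.0
    argos_class_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    missing_interval_prob: float = 0.1
    seed: int = 0
    error_table: ArgosErrorTable = field(default_factory=default_error_table)
    start_time: str = "2016-03-01T00:00:00"
    stagger_days: float = 3.0
    initial_sd_km: float = 100.0
    j_mode: str = "uniform"  # or "midpoint" (deterministic j = 0.5)
    sub_reinit: bool = False  # re-draw S'' from its stationary law on traveling->ARS entry
    duration_log_mean: float = math.log(300.0)
    duration_log_sd: float = 0.4

    def validate(self) -> None:
        if self.n_animals < 1:
            raise ParameterError("n_animals must be >= 1")
        if self.steps_per_animal < 2:
            raise ParameterError("steps_per_animal must be >= 2")
        if self.fixes_per_interval_rate <= 0:
            raise ParameterError("fixes_per_interval_rate must be positive")
        if self.dives_per_interval_rate < 0:
            raise ParameterError("dives_per_interval_rate must be >= 0")
        if not 0.0 <= self.missing_interval_prob < 1.0:
            raise ParameterError("missing_interval_prob must lie in [0, 1)")
        total = sum(self.argos_class_probs.values())
        if abs(total - 1.0) > 1e-12:
            raise ParameterError(f"class probabilities sum to {total}, not 1")
        unknown = set(self.argos_class_probs) - set(ARGOS_CLASSES)
        if unknown:
            raise ParameterError(f"unknown Argos classes {unknown}")
        if self.j_mode not in ("uniform", "midpoint"):
            raise ParameterError("j_mode must be 'uniform' or 'midpoint'")
        self.true_params.validate()

    def animal_ids(self) -> list[str]:
        return [f"sim{i:03d}" for i in range(self.n_animals)]

    def deployment_start(self, animal: int) -> np.datetime64:
        t0 = np.datetime64(self.start_time, "s")
        return t0 + np.timedelta64(int(self.stagger_days * 86400 * animal), "s")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["true_params"] = {k: np.asarray(v).tolist()
                            for k, v in dataclasses.asdict(self.true_params).items()}
        d["error_table"] = {k: float(v) for k, v in self.error_table.sd_km.items()}
        d["argos_class_probs"] = dict(self.argos_class_probs)
        return d


@dataclass
class SyntheticDataset:
    """Observed streams plus the latent truth they were generated from."""

    fixes: pd.DataFrame
    dives: pd.DataFrame
    truth_intervals: pd.DataFrame
    truth_dives: pd.DataFrame
    config: SimulationConfig


def _rng(config: SimulationConfig, animal: int, stream: int) -> np.random.Generator:
    """Independent child generator per (animal, purpose)."""
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(animal, stream))
    return np.random.default_rng(ss)


def simulate_latent_chain(config: SimulationConfig, animal: int
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Draw the top-layer state sequence and grid locations for one animal.

    Returns ``(s_top, y)`` with ``s_top`` of length ``steps_per_animal`` and
    ``y`` holding the ``steps_per_animal + 1`` grid locations (km).  The
    first two locations come from the initial-location prior (a wide normal
    around the origin, then one diffusion step); the initial state is
    uniform; thereafter states follow the logit transition law and locations
    the state-switching correlated walk.
    """
    config.validate()
    p = config.true_params
    T = config.steps_per_animal
    rng = _rng(config, animal, 0)
    s_top = np.empty(T, dtype=np.int64)
    s_top[0] = TRAVELING if rng.random() < 0.5 else ARS
    p_trav = expit(p.alpha_top)
    for t in range(1, T):
        s_top[t] = TRAVELING if rng.random() < p_trav[s_top[t - 1]] else ARS
    y = np.empty((T + 1, 2))
    y[0] = config.initial_sd_km * rng.standard_normal(2)
    y[1] = y[0] + p.process_sd * rng.standard_normal(2)
    # the state of interval t (dive window (t-1, t]) drives the step INTO
    # Y_{t+1}, i.e. the displacement of interval t+1 — the printed index
    # structure ties each state to the onward step
    for t in range(1, T):
        d = process_mean(y[t], y[t - 1], int(s_top[t - 1]), p)
        y[t + 1] = d + p.process_sd * rng.standard_normal(2)
    return s_top, y


def _truncnorm_depths(mu: float, sd: float, size: int,
                      rng: np.random.Generator) -> np.ndarray:
    a = (DIVE_THRESHOLD_M - mu) / sd
    return truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=size, random_state=rng)


def simulate_dives(s_top: np.ndarray, config: SimulationConfig, animal: int = 0
                   ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Draw dive records for one animal given its top-state sequence.

    Dive counts are Poisson per interval; the sub-chain runs over successive
    dives with the transition row selected by the interval's top state, and
    depths come from the truncated-normal component of the emitting state.
    Durations (lognormal) and shape codes (uniform) are schema filler the
    model ignores.

    Returns ``(dives, dive_interval, s_sub)`` — the records plus per-dive
    truth (1-based interval index and sub-state).
    """
    if len(s_top) == 0:
        raise ParameterError("state sequence must be non-empty")
    config.validate()
    p = config.true_params
    rng = _rng(config, animal, 1)
    T = len(s_top)
    counts = rng.poisson(config.dives_per_interval_rate, size=T)
    n = int(counts.sum())
    t0 = config.deployment_start(animal)
    step_s = INTERVAL_HOURS * 3600.0

    dive_interval = np.repeat(np.arange(1, T + 1), counts)
    offsets = (dive_interval - 1) * step_s
    within = np.concatenate([
        np.sort(rng.choice(int(step_s), size=min(c, int(step_s)), replace=False))
        for c in counts]).astype(float) if n else np.zeros(0)
    times = np.datetime64(t0, "s") + (np.round(offsets + within).astype("timedelta64[s]")
                                      if n else np.array([], "timedelta64[s]"))

    s_sub = np.empty(n, dtype=np.int64)
    p_forage = expit(p.alpha_sub)  # [s_top, prev_sub]
    stationary_ars = _stationary_foraging_prob(p)
    for u in range(n):
        s = int(s_top[dive_interval[u] - 1])
        if u == 0:
            prob = 0.5
        elif (config.sub_reinit and s == ARS and _is_first_of_interval(dive_interval, u)
              and s_top[dive_interval[u] - 2] == TRAVELING):
            prob = stationary_ars
        else:
            prob = p_forage[s, s_sub[u - 1]]
        s_sub[u] = FORAGING if rng.random() < prob else 1
    comp = np.where(s_top[dive_interval - 1] == TRAVELING, 0, 1 + s_sub) \
        if n else np.zeros(0, dtype=int)
    depths = np.empty(n)
    for c in range(3):
        mask = comp == c
        if mask.any():
            depths[mask] = _truncnorm_depths(p.dive_mu[c], p.dive_sd[c],
                                             int(mask.sum()), rng)
    durations = rng.lognormal(config.duration_log_mean, config.duration_log_sd, n)
    shapes = rng.integers(0, 4, size=n)
    dives = pd.DataFrame({
        "animal": config.animal_ids()[animal],
        "timestamp": times,
        "depth_m": depths,
        "duration_s": durations,
        "shape": shapes,
    })
    return dives, dive_interval, s_sub


def _is_first_of_interval(dive_interval: np.ndarray, u: int) -> bool:
    return u == 0 or dive_interval[u] != dive_interval[u - 1]


def _stationary_foraging_prob(p: ModelParameters) -> float:
    m = sub_transition_matrix(p, ARS)
    # two-state stationary distribution: pi_F = P(F|R) / (1 - P(F|F) + P(F|R))
    return float(m[1, 0] / (1.0 - m[0, 0] + m[1, 0]))


def degrade_to_argos(y: np.ndarray, config: SimulationConfig, animal: int = 0
                     ) -> pd.DataFrame:
    """Turn a latent location sequence into Argos-style fixes.

    Fix times fall uniformly within each interval (or at the midpoint in
    ``j_mode='midpoint'``); the true position is the chord interpolation of
    the bracketing grid points; observed positions add isotropic normal
    noise with the class-specific sd; whole intervals go dark with
    ``missing_interval_prob``.
    """
    if len(y) < 2:
        raise ParameterError("need at least two grid locations")
    config.validate()
    rng = _rng(config, animal, 2)
    T = len(y) - 1
    t0 = config.deployment_start(animal)
    step_s = INTERVAL_HOURS * 3600.0
    classes = list(config.argos_class_probs)
    probs = np.array([config.argos_class_probs[c] for c in classes])
    sds = np.array([config.error_table.sd(c) for c in classes])

    rows_t, rows_j, rows_cls = [], [], []
    for t in range(1, T + 1):
        if rng.random() < config.missing_interval_prob:
            continue
        c = min(int(rng.poisson(config.fixes_per_interval_rate)), int(step_s))
        if c == 0:
            continue
        if config.j_mode == "midpoint":
            j = np.full(c, 0.5)
        else:
            # unique whole-second offsets, so written timestamps recover j exactly
            j = np.sort(rng.choice(int(step_s), size=c, replace=False)) / step_s
        rows_t.append(np.full(c, t))
        rows_j.append(j)
        rows_cls.append(rng.choice(len(classes), size=c, p=probs))
    if rows_t:
        f_t = np.concatenate(rows_t)
        f_j = np.concatenate(rows_j)
        f_c = np.concatenate(rows_cls)
    else:
        f_t = np.zeros(0, dtype=int)
        f_j = np.zeros(0)
        f_c = np.zeros(0, dtype=int)
    true_xy = (1.0 - f_j)[:, None] * y[f_t - 1] + f_j[:, None] * y[f_t]
    obs = true_xy + sds[f_c][:, None] * rng.standard_normal((len(f_t), 2))
    off_s = np.round((f_t - 1) * step_s + f_j * step_s).astype("timedelta64[s]")
    times = np.datetime64(t0, "s") + off_s
    return pd.DataFrame({
        "animal": config.animal_ids()[animal],
        "timestamp": times,
        "x_km": obs[:, 0],
        "y_km": obs[:, 1],
        "argos_class": [classes[i] for i in f_c],
    })


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full multi-animal dataset with its latent truth."""
    config.validate()
    fixes, dives = [], []
    ti_rows, td_rows = [], []
    for a in range(config.n_animals):
        aid = config.animal_ids()[a]
        s_top, y = simulate_latent_chain(config, a)
        d, d_int, s_sub = simulate_dives(s_top, config, a)
        f = degrade_to_argos(y, config, a)
        fixes.append(f)
        dives.append(d)
        T = config.steps_per_animal
        grid = (np.datetime64(config.deployment_start(a), "s")
                + (np.arange(T + 1) * INTERVAL_HOURS * 3600).astype("timedelta64[s]"))
        ti_rows.append(pd.DataFrame({
            "animal": aid,
            "grid_index": np.arange(T + 1),
            "timestamp": grid,
            "x_km": y[:, 0],
            "y_km": y[:, 1],
            # state of the interval ENDING at this grid point; first point has none
            "s_top": np.concatenate([[-1], s_top]),
        }))
        td_rows.append(pd.DataFrame({
            "animal": aid,
            "timestamp": d["timestamp"].to_numpy(),
            "interval": d_int,
            "s_sub": s_sub,
        }))
        # invariant: every dive falls inside the deployment window
        if len(d):
            lo = np.datetime64(config.deployment_start(a), "s")
            hi = lo + np.timedelta64(int(T * INTERVAL_HOURS * 3600), "s")
            ts = d["timestamp"].to_numpy()
            if ts.min() < lo or ts.max() > hi:
                raise AssertionError("dive outside deployment window")
    return SyntheticDataset(
        fixes=pd.concat(fixes, ignore_index=True),
        dives=pd.concat(dives, ignore_index=True),
        truth_intervals=pd.concat(ti_rows, ignore_index=True),
        truth_dives=pd.concat(td_rows, ignore_index=True),
        config=config,
    )


def dataset_to_tracks(ds: SyntheticDataset) -> list[TrackData]:
    """Build sampler-ready tracks directly on the generator's own grid.

    Bypasses preprocessing (the synthetic grid is already regular), mapping
    fix times back to interval indices and fractions exactly.
    """
    cfg = ds.config
    tracks = []
    step_s = INTERVAL_HOURS * 3600.0
    for a in range(cfg.n_animals):
        aid = cfg.animal_ids()[a]
        t0 = np.datetime64(cfg.deployment_start(a), "s")
        T = cfg.steps_per_animal
        f = ds.fixes[ds.fixes["animal"] == aid]
        rel = (f["timestamp"].to_numpy().astype("datetime64[s]") - t0) \
            .astype(float) / step_s
        f_int = np.minimum(np.floor(rel).astype(np.int64) + 1, T)
        f_j = rel - (f_int - 1)
        d = ds.dives[ds.dives["animal"] == aid]
        d_truth = ds.truth_dives[ds.truth_dives["animal"] == aid]
        tracks.append(TrackData(
            animal=aid, track_id=1, t0=t0, n_intervals=T,
            fix_interval=f_int, fix_j=f_j,
            fix_x=f["x_km"].to_numpy(), fix_y=f["y_km"].to_numpy(),
            fix_sd=np.asarray(cfg.error_table.sd(list(f["argos_class"])), dtype=float),
            dive_interval=d_truth["interval"].to_numpy(),
            dive_depth=d["depth_m"].to_numpy(),
            dive_time=d["timestamp"].to_numpy().astype("datetime64[s]"),
        ))
    return tracks


def true_latents(ds: SyntheticDataset) -> list:
    """Latent truth in sampler layout, aligned with :func:`dataset_to_tracks`."""
    from .model import LatentState

    cfg = ds.config
    out = []
    for aid in cfg.animal_ids():
        ti = ds.truth_intervals[ds.truth_intervals["animal"] == aid]
        td = ds.truth_dives[ds.truth_dives["animal"] == aid]
        out.append(LatentState(
            y=ti[["x_km", "y_km"]].to_numpy(),
            s_top=ti["s_top"].to_numpy()[1:],
            s_sub=td["s_sub"].to_numpy(),
        ))
    return out


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset as delimited text plus a JSON config sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("fixes", ds.fixes), ("dives", ds.dives),
                     ("truth", ds.truth_intervals), ("truth_dives", ds.truth_dives)):
        path = outdir / f"{name}.csv"
        out = df.copy()
        out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
            "%Y-%m-%dT%H:%M:%SZ")
        out.to_csv(path, index=False, float_format="%.6f")
        paths[name] = path
    sidecar = outdir / "config.json"
    payload = ds.config.as_dict()
    payload["n_fixes"] = int(len(ds.fixes))
    payload["n_dives"] = int(len(ds.dives))
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))
    paths["config"] = sidecar
    return paths
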