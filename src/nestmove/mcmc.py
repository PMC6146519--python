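"""Metropolis-within-Gibbs sampler for the nested movement model.

Each iteration executes three blocks:

1. **Discrete states** — both layers are drawn jointly from their exact full
   conditional by forward filtering–backward sampling over an augmented
   chain (top state, carried sub-state), per track.
2. **Locations** — every latent grid location takes one random-walk
   Metropolis step on its local full conditional (process + observation
   terms), with the proposal sd adapted during burn-in toward 20–50 %
   acceptance and frozen afterwards so the retained chain is Markovian.
3. **Parameters** — scalar random-walk Metropolis updates for gamma, theta,
   the process sds, the transition logits and the dive-component mu/sd,
   honoring all support constraints (proposals outside support are
   rejected outright).

Chains are seeded independently from a master seed by a fixed splitting
rule, so adding chains never reshuffles existing ones.  Convergence is
assessed with the classic Gelman-Rubin potential-scale-reduction statistic,
with the conventional < 1.1 threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import kernels
from .model import (ALPHA_PRIOR_SD, ARS, DIVE_MU_BOUNDS, DIVE_SD_PRIOR_SCALE,
                    DIVE_THRESHOLD_M, FORAGING, PROCESS_SD_PRIOR_SCALE,
                    TRAVELING, LatentState, ModelParameters, ParameterError,
                    complete_data_loglik, dive_component_logliks,
                    prior_median_parameters, sub_transition_matrix,
                    top_transition_matrix)
from .tracks import TrackData

RHAT_THRESHOLD = 1.1

_DEFAULT_SCALES = {
    "gamma": 0.05, "theta": 0.2, "process_sd": 0.5,
    "alpha": 0.4, "dive_mu": 5.0, "dive_sd": 3.0,
}


@dataclass
class McmcConfig:
    """Chain protocol.  Defaults follow the study protocol: 2 chains of
    30,000 iterations, 28,000 burn-in, thinning by 4 (500 retained draws
    per chain)."""

    n_chains: int = 2
    n_iter: int = 30_000
    n_burnin: int = 28_000
    thin: int = 4
    seed: int = 0
    adapt_window: int = 100
    location_scale: float = 1.0
    target_accept_location: float = 0.3
    target_accept_scalar: float = 0.44
    store_locations: bool = True
    proposal_scales: dict = field(default_factory=lambda: dict(_DEFAULT_SCALES))

    def validate(self) -> None:
        if self.n_chains < 1:
            raise ParameterError("need at least one chain")
        if not 0 <= self.n_burnin < self.n_iter:
            raise ParameterError("require 0 <= n_burnin < n_iter")
        if self.thin < 1:
            raise ParameterError("thin must be >= 1")
        if self.retained_per_chain < 1:
            raise ParameterError("no retained draws with this iter/burnin/thin")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iter - self.n_burnin + self.thin - 1) // self.thin


@dataclass
class GelmanRubinResult:
    rhat: float
    degenerate: bool = False


def gelman_rubin(chains: np.ndarray) -> GelmanRubinResult:
    """Classic potential-scale-reduction estimate from >= 2 chains.

    ``chains`` has shape (n_chains, n_draws).  Zero within-chain variance is
    reported as degenerate rather than NaN.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ParameterError("gelman_rubin needs >= 2 chains")
    m, n = x.shape
    if n < 10:
        raise ParameterError("gelman_rubin needs >= 10 draws per chain")
    w = float(np.mean(np.var(x, axis=1, ddof=1)))
    b_over_n = float(np.var(np.mean(x, axis=1), ddof=1))
    if w == 0.0:
        return GelmanRubinResult(rhat=float("nan"), degenerate=True)
    var_plus = (n - 1) / n * w + b_over_n
    return GelmanRubinResult(rhat=math.sqrt(var_plus / w))


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws of parameters and latent states."""

    param_names: list[str]
    params: np.ndarray  # (n_draws, n_params)
    s_top: np.ndarray  # (n_draws, total_intervals) int8
    s_sub: np.ndarray  # (n_draws, total_dives) int8
    chain: np.ndarray  # (n_draws,)
    iteration: np.ndarray  # (n_draws,)
    tracks: list[TrackData]
    config: McmcConfig
    acceptance: list[dict]
    y: np.ndarray | None = None  # (n_draws, total_grid_points, 2)

    @property
    def n_draws(self) -> int:
        return self.params.shape[0]

    def interval_slices(self) -> list[slice]:
        out, start = [], 0
        for t in self.tracks:
            out.append(slice(start, start + t.n_intervals))
            start += t.n_intervals
        return out

    def dive_slices(self) -> list[slice]:
        out, start = [], 0
        for t in self.tracks:
            out.append(slice(start, start + t.n_dives))
            start += t.n_dives
        return out

    def params_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.params, columns=self.param_names)
        df.insert(0, "iteration", self.iteration)
        df.insert(0, "chain", self.chain)
        return df

    def rhat_table(self) -> pd.DataFrame:
        rows = []
        chains = np.unique(self.chain)
        for i, name in enumerate(self.param_names):
            per_chain = np.stack([self.params[self.chain == c, i] for c in chains])
            res = gelman_rubin(per_chain)
            rows.append({"parameter": name, "rhat": res.rhat,
                         "degenerate": res.degenerate})
        return pd.DataFrame(rows)

    def max_rhat(self) -> float:
        table = self.rhat_table()
        if table["degenerate"].any():
            return float("inf")
        return float(table["rhat"].max())

    def credible_interval(self, name: str, level: float = 0.95
                          ) -> tuple[float, float]:
        i = self.param_names.index(name)
        lo = 100 * (1 - level) / 2
        return tuple(np.percentile(self.params[:, i], [lo, 100 - lo]))

    # -- persistence (delimited text + JSON metadata) ----------------------

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.params_dataframe().to_csv(outdir / "params.csv", index=False)
        np.savetxt(outdir / "s_top.csv", self.s_top, fmt="%d", delimiter=",")
        np.savetxt(outdir / "s_sub.csv", self.s_sub, fmt="%d", delimiter=",")
        meta = {
            "param_names": self.param_names,
            "chain": self.chain.tolist(),
            "iteration": self.iteration.tolist(),
            "acceptance": self.acceptance,
            "config": {k: v for k, v in vars(self.config).items()
                       if not isinstance(v, dict)},
            "proposal_scales": self.config.proposal_scales,
            "tracks": [
                {
                    "animal": t.animal, "track_id": t.track_id,
                    "t0": str(np.datetime64(t.t0, "s")),
                    "n_intervals": int(t.n_intervals),
                    "dive_interval": t.dive_interval.tolist(),
                    "dive_depth": t.dive_depth.tolist(),
                    "dive_time": [str(x) for x in t.dive_time],
                }
                for t in self.tracks
            ],
        }
        (outdir / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, outdir: str | Path) -> "PosteriorDraws":
        outdir = Path(outdir)
        meta = json.loads((outdir / "meta.json").read_text())
        pdf = pd.read_csv(outdir / "params.csv")
        names = meta["param_names"]
        tracks = [
            TrackData(
                animal=m["animal"], track_id=m["track_id"],
                t0=np.datetime64(m["t0"], "s"), n_intervals=m["n_intervals"],
                fix_interval=np.zeros(0, dtype=np.int64), fix_j=np.zeros(0),
                fix_x=np.zeros(0), fix_y=np.zeros(0), fix_sd=np.zeros(0),
                dive_interval=np.asarray(m["dive_interval"], dtype=np.int64),
                dive_depth=np.asarray(m["dive_depth"], dtype=float),
                dive_time=np.asarray(m["dive_time"], dtype="datetime64[s]"),
            )
            for m in meta["tracks"]
        ]
        cfg = McmcConfig(**{k: v for k, v in meta["config"].items()})
        cfg.proposal_scales = meta["proposal_scales"]
        s_top = np.loadtxt(outdir / "s_top.csv", dtype=np.int8, delimiter=",", ndmin=2)
        s_sub = np.loadtxt(outdir / "s_sub.csv", dtype=np.int8, delimiter=",", ndmin=2)
        total_dives = sum(t.n_dives for t in tracks)
        if total_dives == 0:
            s_sub = np.zeros((len(pdf), 0), dtype=np.int8)
        return cls(
            param_names=names, params=pdf[names].to_numpy(),
            s_top=s_top, s_sub=s_sub,
            chain=np.asarray(meta["chain"]), iteration=np.asarray(meta["iteration"]),
            tracks=tracks, config=cfg, acceptance=meta["acceptance"],
        )


# ---------------------------------------------------------------------------
# likelihood pieces on sampled latents
# ---------------------------------------------------------------------------

def _process_ll(latents: Sequence[LatentState], gamma: np.ndarray,
                theta: np.ndarray, sd: np.ndarray) -> float:
    total = 0.0
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    for lat in latents:
        y, st = lat.y, lat.s_top
        T = st.size
        if T < 2:
            continue
        disp = y[1:] - y[:-1]
        s = st[: T - 1]
        dx, dy = disp[: T - 1, 0], disp[: T - 1, 1]
        mx = y[1:T, 0] + gamma[s] * (cos_t[s] * dx - sin_t[s] * dy)
        my = y[1:T, 1] + gamma[s] * (sin_t[s] * dx + cos_t[s] * dy)
        rx = (y[2:, 0] - mx) / sd[0]
        ry = (y[2:, 1] - my) / sd[1]
        total += float(np.sum(-0.5 * (rx * rx + ry * ry)))
        total += (T - 1) * (-math.log(sd[0]) - math.log(sd[1]))
    return total


def _bernoulli_ll(logits: np.ndarray, success: np.ndarray) -> float:
    # log expit(a) = -log(1 + e^-a); log(1 - expit(a)) = -log(1 + e^a)
    return float(np.sum(np.where(success, -np.logaddexp(0.0, -logits),
                                 -np.logaddexp(0.0, logits))))


def _top_ll(latents: Sequence[LatentState], alpha_top: np.ndarray) -> float:
    total = 0.0
    for lat in latents:
        st = lat.s_top
        if st.size < 2:
            continue
        total += _bernoulli_ll(alpha_top[st[:-1]], st[1:] == TRAVELING)
    return total


def _sub_ll(tracks: Sequence[TrackData], latents: Sequence[LatentState],
            alpha_sub: np.ndarray) -> float:
    total = 0.0
    for track, lat in zip(tracks, latents):
        if track.n_dives < 2:
            continue
        rows = lat.s_top[track.dive_interval[1:] - 1]
        logits = alpha_sub[rows, lat.s_sub[:-1]]
        total += _bernoulli_ll(logits, lat.s_sub[1:] == FORAGING)
    return total


def _dive_ll(depths: np.ndarray, mu: float, sd: float) -> float:
    """Truncated-normal log-likelihood, constants dropped."""
    from scipy.special import log_ndtr

    if depths.size == 0:
        return 0.0
    z = (depths - mu) / sd
    return float(np.sum(-0.5 * z * z) - depths.size * (math.log(sd)
                 + log_ndtr((mu - DIVE_THRESHOLD_M) / sd)))


def _dive_assignments(tracks, latents) -> list[np.ndarray]:
    """Per-dive emission component (0 traveling, 1 foraging, 2 resting)."""
    out = []
    for track, lat in zip(tracks, latents):
        if track.n_dives == 0:
            out.append(np.zeros(0, dtype=np.int64))
            continue
        trav = lat.s_top[track.dive_interval - 1] == TRAVELING
        out.append(np.where(trav, 0, 1 + lat.s_sub))
    return out


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def initial_latents(tracks: Sequence[TrackData]) -> list[LatentState]:
    """Deterministic starts: interpolated fixes for Y, a step-length median
    split for the top states, a 50-m depth split for the sub states."""
    out = []
    for track in tracks:
        y = track.initial_locations()
        step = np.hypot(*(y[1:] - y[:-1]).T)
        thr = np.median(step) if step.size else 0.0
        s_top = np.where(step > thr, TRAVELING, ARS).astype(np.int64)
        s_sub = np.where(track.dive_depth > 50.0, FORAGING, 1).astype(np.int64)
        out.append(LatentState(y=y, s_top=s_top, s_sub=s_sub))
    return out


# ---------------------------------------------------------------------------
# sampler blocks
# ---------------------------------------------------------------------------

def sample_states_ffbs(track: TrackData, lat: LatentState,
                       params: ModelParameters, rng: np.random.Generator
                       ) -> float:
    """Draw (S', S'') for one track from the exact full conditional.

    Updates ``lat.s_top`` / ``lat.s_sub`` in place and returns the marginal
    log-likelihood over all discrete paths (a free by-product of the
    forward pass).
    """
    from .model import movement_logliks

    T = track.n_intervals
    log_ptop = np.log(top_transition_matrix(params))
    log_psub = np.log(np.stack([sub_transition_matrix(params, s)
                                for s in range(2)]))
    move_ll = movement_logliks(lat.y, params)
    log_e = (dive_component_logliks(track.dive_depth, params)
             if track.n_dives else np.zeros((0, 3)))
    u_top = rng.random(T)
    u_sub = rng.random(max(track.n_dives, 1))
    return float(kernels.ffbs_track(
        log_ptop, move_ll, track.dive_offsets, log_e, log_psub,
        u_top, u_sub, lat.s_top, lat.s_sub))


def sample_locations(track: TrackData, lat: LatentState,
                     params: ModelParameters, scale: float,
                     rng: np.random.Generator) -> int:
    """One Metropolis sweep over the track's grid locations (in place);
    returns the number of accepted moves."""
    n = track.n_intervals + 1
    eps = rng.standard_normal((n, 2))
    u = rng.random(n)
    return int(kernels.metropolis_locations(
        lat.y, lat.s_top, params.gamma, np.cos(params.theta),
        np.sin(params.theta), params.process_sd[0], params.process_sd[1],
        track.fix_offsets, track.fix_j, track.fix_x, track.fix_y, track.fix_sd,
        scale, eps, u))


class _Accumulator:
    """Acceptance bookkeeping + burn-in-only scale adaptation."""

    def __init__(self, scales: dict[str, float], target: dict[str, float]):
        self.scales = scales
        self.target = target
        self.prop = {k: 0 for k in scales}
        self.acc = {k: 0 for k in scales}
        self.total_prop = {k: 0 for k in scales}
        self.total_acc = {k: 0 for k in scales}

    def record(self, name: str, accepted: bool) -> None:
        self.prop[name] += 1
        self.total_prop[name] += 1
        if accepted:
            self.acc[name] += 1
            self.total_acc[name] += 1

    def adapt(self) -> None:
        for k in self.scales:
            if self.prop[k] == 0:
                continue
            rate = self.acc[k] / self.prop[k]
            self.scales[k] *= math.exp(np.clip(rate - self.target[k], -0.9, 0.9))
            self.scales[k] = float(np.clip(self.scales[k], 1e-4, 1e4))
            self.prop[k] = 0
            self.acc[k] = 0

    def rates(self) -> dict[str, float]:
        return {k: self.total_acc[k] / self.total_prop[k]
                for k in self.scales if self.total_prop[k]}


def _wrap_angle(x: float) -> float:
    w = (x + math.pi) % (2.0 * math.pi) - math.pi
    return math.pi if w == -math.pi else w


def _half_normal_lp(x: float, scale: float) -> float:
    return -0.5 * (x / scale) ** 2


def sample_parameters(tracks: Sequence[TrackData],
                      latents: Sequence[LatentState],
                      params: ModelParameters, acc: _Accumulator,
                      rng: np.random.Generator) -> None:
    """Scalar Metropolis-within-Gibbs updates of all model parameters,
    holding states and locations fixed.  Mutates ``params`` in place."""
    sc = acc.scales

    # movement block: gamma, theta, process_sd share one likelihood
    cur_ll = _process_ll(latents, params.gamma, params.theta, params.process_sd)
    for i in range(2):
        prop = params.gamma.copy()
        prop[i] += sc[f"gamma_{i}"] * rng.standard_normal()
        ok = 0.0 <= prop[i] <= 1.0 and prop[TRAVELING] > prop[ARS]
        if ok:
            new_ll = _process_ll(latents, prop, params.theta, params.process_sd)
            if math.log(rng.random()) < new_ll - cur_ll:
                params.gamma = prop
                cur_ll = new_ll
                acc.record(f"gamma_{i}", True)
                continue
        acc.record(f"gamma_{i}", False)
    for i in range(2):
        prop = params.theta.copy()
        prop[i] = _wrap_angle(prop[i] + sc[f"theta_{i}"] * rng.standard_normal())
        new_ll = _process_ll(latents, params.gamma, prop, params.process_sd)
        if math.log(rng.random()) < new_ll - cur_ll:
            params.theta = prop
            cur_ll = new_ll
            acc.record(f"theta_{i}", True)
        else:
            acc.record(f"theta_{i}", False)
    for i in range(2):
        prop = params.process_sd.copy()
        prop[i] += sc[f"process_sd_{i}"] * rng.standard_normal()
        if prop[i] > 0:
            new_ll = _process_ll(latents, params.gamma, params.theta, prop)
            dprior = (_half_normal_lp(prop[i], PROCESS_SD_PRIOR_SCALE)
                      - _half_normal_lp(params.process_sd[i], PROCESS_SD_PRIOR_SCALE))
            if math.log(rng.random()) < new_ll - cur_ll + dprior:
                params.process_sd = prop
                cur_ll = new_ll
                acc.record(f"process_sd_{i}", True)
                continue
        acc.record(f"process_sd_{i}", False)

    # top-layer transition logits
    cur_ll = _top_ll(latents, params.alpha_top)
    for i in range(2):
        prop = params.alpha_top.copy()
        prop[i] += sc[f"alpha_top_{i}"] * rng.standard_normal()
        new_ll = _top_ll(latents, prop)
        dprior = -0.5 * (prop[i] ** 2 - params.alpha_top[i] ** 2) / ALPHA_PRIOR_SD ** 2
        if math.log(rng.random()) < new_ll - cur_ll + dprior:
            params.alpha_top = prop
            cur_ll = new_ll
            acc.record(f"alpha_top_{i}", True)
        else:
            acc.record(f"alpha_top_{i}", False)

    # dive components
    comps = _dive_assignments(tracks, latents)
    for c in range(3):
        depths = np.concatenate([
            track.dive_depth[comp == c]
            for track, comp in zip(tracks, comps)
        ]) if tracks else np.zeros(0)
        lo, hi = DIVE_MU_BOUNDS[c]
        cur = _dive_ll(depths, params.dive_mu[c], params.dive_sd[c])
        prop_mu = params.dive_mu[c] + sc[f"dive_mu_{c}"] * rng.standard_normal()
        if lo <= prop_mu <= hi:
            new = _dive_ll(depths, prop_mu, params.dive_sd[c])
            if math.log(rng.random()) < new - cur:
                params.dive_mu[c] = prop_mu
                cur = new
                acc.record(f"dive_mu_{c}", True)
            else:
                acc.record(f"dive_mu_{c}", False)
        else:
            acc.record(f"dive_mu_{c}", False)
        prop_sd = params.dive_sd[c] + sc[f"dive_sd_{c}"] * rng.standard_normal()
        if prop_sd > 0:
            new = _dive_ll(depths, params.dive_mu[c], prop_sd)
            dprior = (_half_normal_lp(prop_sd, DIVE_SD_PRIOR_SCALE)
                      - _half_normal_lp(params.dive_sd[c], DIVE_SD_PRIOR_SCALE))
            if math.log(rng.random()) < new - cur + dprior:
                params.dive_sd[c] = prop_sd
                acc.record(f"dive_sd_{c}", True)
            else:
                acc.record(f"dive_sd_{c}", False)
        else:
            acc.record(f"dive_sd_{c}", False)


def _sub_marginal_ll(tracks: Sequence[TrackData],
                     latents: Sequence[LatentState], alpha_sub: np.ndarray,
                     log_es: Sequence[np.ndarray]) -> float:
    """Dive-sequence log-likelihood with the sub-states integrated out."""
    p_forage = expit(alpha_sub)
    log_psub = np.log(np.stack([
        np.column_stack([p_forage[s], 1.0 - p_forage[s]]) for s in range(2)]))
    total = 0.0
    for track, lat, log_e in zip(tracks, latents, log_es):
        if track.n_dives == 0:
            continue
        rows = lat.s_top[track.dive_interval - 1]
        total += float(kernels.dive_chain_marginal(rows, log_e, log_psub))
    return total


def update_alpha_sub_collapsed(tracks: Sequence[TrackData],
                               latents: Sequence[LatentState],
                               params: ModelParameters, acc: _Accumulator,
                               rng: np.random.Generator) -> None:
    """Metropolis update of the sub-layer logits with S'' marginalized out.

    Dives inside traveling intervals carry no emission information about the
    sub-state, so conditioning the logit update on sampled sub-states mixes
    pathologically slowly (the states are themselves generated by the
    logits).  Proposing against the marginal dive-chain likelihood breaks
    that coupling; validity requires the sub-states to be redrawn from their
    full conditional immediately after, which the state block at the top of
    each iteration does.
    """
    sc = acc.scales
    log_es = [dive_component_logliks(t.dive_depth, params)
              if t.n_dives else np.zeros((0, 3)) for t in tracks]
    cur_ll = _sub_marginal_ll(tracks, latents, params.alpha_sub, log_es)
    for r in range(2):
        for c in range(2):
            prop = params.alpha_sub.copy()
            prop[r, c] += sc[f"alpha_sub_{r}{c}"] * rng.standard_normal()
            new_ll = _sub_marginal_ll(tracks, latents, prop, log_es)
            dprior = (-0.5 * (prop[r, c] ** 2 - params.alpha_sub[r, c] ** 2)
                      / ALPHA_PRIOR_SD ** 2)
            if math.log(rng.random()) < new_ll - cur_ll + dprior:
                params.alpha_sub = prop
                cur_ll = new_ll
                acc.record(f"alpha_sub_{r}{c}", True)
            else:
                acc.record(f"alpha_sub_{r}{c}", False)


def _scalar_scale_names() -> dict[str, str]:
    """Scalar proposal names -> default-scale group."""
    names = {}
    for i in range(2):
        names[f"gamma_{i}"] = "gamma"
        names[f"theta_{i}"] = "theta"
        names[f"process_sd_{i}"] = "process_sd"
        names[f"alpha_top_{i}"] = "alpha"
    for r in range(2):
        for c in range(2):
            names[f"alpha_sub_{r}{c}"] = "alpha"
    for c in range(3):
        names[f"dive_mu_{c}"] = "dive_mu"
        names[f"dive_sd_{c}"] = "dive_sd"
    return names


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _run_chain(tracks: Sequence[TrackData], config: McmcConfig, chain_id: int,
               init_params: ModelParameters | None):
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(chain_id,))
    rng = np.random.default_rng(ss)
    params = (init_params.copy() if init_params is not None
              else prior_median_parameters())
    latents = initial_latents(tracks)

    ll0 = complete_data_loglik(tracks, latents, params)
    if not np.isfinite(ll0):
        raise RuntimeError(
            f"non-finite posterior at initialization (loglik={ll0}); "
            "check for dives at/below the 10-m threshold or bad fixes")

    groups = _scalar_scale_names()
    scales = {name: float(config.proposal_scales.get(
        grp, _DEFAULT_SCALES[grp])) for name, grp in groups.items()}
    targets = {name: config.target_accept_scalar for name in scales}
    for k in range(len(tracks)):
        scales[f"loc_{k}"] = config.location_scale
        targets[f"loc_{k}"] = config.target_accept_location
    acc = _Accumulator(scales, targets)

    n_keep = config.retained_per_chain
    n_params = len(ModelParameters.names())
    total_T = sum(t.n_intervals for t in tracks)
    total_D = sum(t.n_dives for t in tracks)
    total_N = sum(t.n_intervals + 1 for t in tracks)
    out_params = np.empty((n_keep, n_params))
    out_stop = np.empty((n_keep, total_T), dtype=np.int8)
    out_ssub = np.empty((n_keep, total_D), dtype=np.int8)
    out_y = (np.empty((n_keep, total_N, 2)) if config.store_locations else None)
    out_iter = np.empty(n_keep, dtype=np.int64)
    kept = 0

    for it in range(config.n_iter):
        # collapsed logit update first: the FFBS that follows redraws the
        # marginalized sub-states before anything else conditions on them
        update_alpha_sub_collapsed(tracks, latents, params, acc, rng)
        for k, (track, lat) in enumerate(zip(tracks, latents)):
            sample_states_ffbs(track, lat, params, rng)
        for k, (track, lat) in enumerate(zip(tracks, latents)):
            n_grid = track.n_intervals + 1
            n_acc = sample_locations(track, lat, params, acc.scales[f"loc_{k}"], rng)
            # count the sweep as n_grid proposals
            acc.prop[f"loc_{k}"] += n_grid
            acc.total_prop[f"loc_{k}"] += n_grid
            acc.acc[f"loc_{k}"] += n_acc
            acc.total_acc[f"loc_{k}"] += n_acc
        sample_parameters(tracks, latents, params, acc, rng)

        if it < config.n_burnin:
            if (it + 1) % config.adapt_window == 0:
                acc.adapt()
        elif (it - config.n_burnin) % config.thin == 0:
            out_params[kept] = params.to_vector()
            out_stop[kept] = np.concatenate([lat.s_top for lat in latents]) \
                if total_T else np.zeros(0, dtype=np.int8)
            out_ssub[kept] = np.concatenate([lat.s_sub for lat in latents]) \
                if total_D else np.zeros(0, dtype=np.int8)
            if out_y is not None:
                out_y[kept] = np.concatenate([lat.y for lat in latents])
            out_iter[kept] = it
            kept += 1

    return (out_params[:kept], out_stop[:kept], out_ssub[:kept],
            out_y[:kept] if out_y is not None else None,
            out_iter[:kept], acc.rates())


def run_mcmc(tracks: Sequence[TrackData], config: McmcConfig | None = None,
             init_params: ModelParameters | None = None) -> PosteriorDraws:
    """Run the full sampler and return thinned post-burn-in draws.

    Chains run sequentially with independently split seeds.  Identical
    configs (and seed) give bit-identical draws.
    """
    config = config or McmcConfig()
    config.validate()
    if not tracks:
        raise ParameterError("no tracks to fit")
    all_params, all_stop, all_ssub, all_y, all_iter, all_chain = [], [], [], [], [], []
    acceptance = []
    for chain_id in range(config.n_chains):
        p, st, sb, y, its, rates = _run_chain(tracks, config, chain_id, init_params)
        all_params.append(p)
        all_stop.append(st)
        all_ssub.append(sb)
        all_y.append(y)
        all_iter.append(its)
        all_chain.append(np.full(len(its), chain_id))
        acceptance.append(rates)
    return PosteriorDraws(
        param_names=ModelParameters.names(),
        params=np.concatenate(all_params),
        s_top=np.concatenate(all_stop),
        s_sub=np.concatenate(all_ssub),
        y=(np.concatenate(all_y) if config.store_locations else None),
        chain=np.concatenate(all_chain),
        iteration=np.concatenate(all_iter),
        tracks=list(tracks), config=config, acceptance=acceptance,
    )
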