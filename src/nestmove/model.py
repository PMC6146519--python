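"""Core densities of the nested switching correlated-random-walk model.

The model has two behavioral layers.  The top layer is a two-state switching
correlated random walk on a 6-hour grid: the latent planar location ``Y_t``
(km) evolves as

    Y_{t+1} ~ Normal( Y_t + gamma_s R(theta_s) (Y_t - Y_{t-1}), diag(sigma^2) )

where ``s`` is the behavioral state of interval ``t`` (traveling or
area-restricted search, "ARS"), ``gamma_s`` is the step autocorrelation,
``R(theta_s)`` a rotation by the mean turning angle, and ``sigma`` a shared
per-coordinate process sd.  States follow a Markov chain on the logit scale,
``logit P(traveling | prev) = alpha_top[prev]``.

Irregular satellite fixes observe the straight-line interpolation of the two
grid locations bracketing the fix, with a fixed per-error-class sd.

The second layer splits ARS into foraging and resting through a higher
frequency Markov chain over successive dives: ``logit P(foraging | S',
prev S'') = alpha_sub[S', prev S'']``, and a dive's maximum depth is drawn
from a normal component (traveling / foraging / resting) truncated below at
the 10-m dive-definition threshold.

Everything the sampler needs — process, observation, transition and emission
log-densities, the joint prior, the complete-data log-likelihood, and the
forward recursion that marginalizes the discrete states exactly — lives here.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import yaml
from scipy.special import expit, log_ndtr, logsumexp

if TYPE_CHECKING:  # pragma: no cover
    from .tracks import TrackData

# Top-layer states
TRAVELING, ARS = 0, 1
TOP_STATE_NAMES = ("traveling", "ars")
# Sub-layer states (defined within ARS)
FORAGING, RESTING = 0, 1
SUB_STATE_NAMES = ("foraging", "resting")
# Dive emission components, in storage order
DIVE_COMPONENT_NAMES = ("traveling", "foraging", "resting")

#: dive-definition depth threshold (m); emissions are truncated below here
DIVE_THRESHOLD_M = 10.0

#: prior support of the component mean depths (m): traveling, foraging, resting
DIVE_MU_BOUNDS = ((0.0, 30.0), (50.0, 250.0), (0.0, 30.0))

# weakly-informative prior scales
PROCESS_SD_PRIOR_SCALE = 10.0  # km, half-normal
DIVE_SD_PRIOR_SCALE = 50.0  # m, half-normal
ALPHA_PRIOR_SD = 2.0  # logits, normal(0, 2)

LOG_HALF = math.log(0.5)

ARGOS_CLASSES = ("3", "2", "1", "0", "A", "B")


class ParameterError(ValueError):
    """Raised when model parameters violate their support constraints."""


@dataclass
class ModelParameters:
    """All unknowns of the nested model (latent states and locations aside).

    Attributes
    ----------
    gamma : (2,) step autocorrelation per top state, in [0, 1].
    theta : (2,) mean turning angle per top state, in (-pi, pi].
    process_sd : (2,) process sd per planar coordinate (km), shared across states.
    alpha_top : (2,) logit P(traveling at t | state at t-1), indexed by previous state.
    alpha_sub : (2, 2) logit P(foraging at dive u | S' of the interval, S'' at dive u-1).
    dive_mu : (3,) mean depth (m) of the traveling/foraging/resting components.
    dive_sd : (3,) sd (m) of those components.
    """

    gamma: np.ndarray
    theta: np.ndarray
    process_sd: np.ndarray
    alpha_top: np.ndarray
    alpha_sub: np.ndarray
    dive_mu: np.ndarray
    dive_sd: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.process_sd = np.asarray(self.process_sd, dtype=float)
        self.alpha_top = np.asarray(self.alpha_top, dtype=float)
        self.alpha_sub = np.asarray(self.alpha_sub, dtype=float).reshape(2, 2)
        self.dive_mu = np.asarray(self.dive_mu, dtype=float)
        self.dive_sd = np.asarray(self.dive_sd, dtype=float)

    def validate(self) -> None:
        """Raise :class:`ParameterError` on any support violation."""
        for name in ("gamma", "theta", "process_sd", "alpha_top", "alpha_sub",
                     "dive_mu", "dive_sd"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ParameterError(f"non-finite values in {name}")
        if np.any(self.gamma < 0.0) or np.any(self.gamma > 1.0):
            raise ParameterError("gamma must lie in [0, 1]")
        if np.any(self.process_sd <= 0.0):
            raise ParameterError("process_sd must be positive")
        if np.any(self.dive_sd <= 0.0):
            raise ParameterError("dive_sd must be positive")

    # -- flat-vector view (used by diagnostics and posterior storage) ------

    @staticmethod
    def names() -> list[str]:
        return [
            "gamma_traveling", "gamma_ars",
            "theta_traveling", "theta_ars",
            "process_sd_x", "process_sd_y",
            "alpha_top_prev_traveling", "alpha_top_prev_ars",
            "alpha_sub_traveling_prev_foraging", "alpha_sub_traveling_prev_resting",
            "alpha_sub_ars_prev_foraging", "alpha_sub_ars_prev_resting",
            "dive_mu_traveling", "dive_mu_foraging", "dive_mu_resting",
            "dive_sd_traveling", "dive_sd_foraging", "dive_sd_resting",
        ]

    def to_vector(self) -> np.ndarray:
        return np.concatenate([
            self.gamma, self.theta, self.process_sd, self.alpha_top,
            self.alpha_sub.ravel(), self.dive_mu, self.dive_sd,
        ])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "ModelParameters":
        v = np.asarray(v, dtype=float)
        if v.shape != (18,):
            raise ParameterError(f"expected 18 parameters, got shape {v.shape}")
        return cls(gamma=v[0:2], theta=v[2:4], process_sd=v[4:6],
                   alpha_top=v[6:8], alpha_sub=v[8:12].reshape(2, 2),
                   dive_mu=v[12:15], dive_sd=v[15:18])

    def copy(self) -> "ModelParameters":
        return ModelParameters.from_vector(self.to_vector())

    # -- serialization -----------------------------------------------------

    def to_yaml(self) -> str:
        payload = {
            "gamma": self.gamma.tolist(),
            "theta": self.theta.tolist(),
            "process_sd": self.process_sd.tolist(),
            "alpha_top": self.alpha_top.tolist(),
            "alpha_sub": self.alpha_sub.tolist(),
            "dive_mu": self.dive_mu.tolist(),
            "dive_sd": self.dive_sd.tolist(),
        }
        return yaml.safe_dump(payload, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelParameters":
        payload = yaml.safe_load(io.StringIO(text))
        return cls(**{k: np.asarray(v, dtype=float) for k, v in payload.items()})


def default_parameters() -> ModelParameters:
    """Generative defaults: well-separated traveling vs ARS regimes.

    Movement: traveling is strongly autocorrelated with small turning angles,
    ARS weakly autocorrelated with large turns.  Transition logits match the
    probability-scale persistence reported for Antarctic humpback whales
    (self-transition around 0.85 on the movement layer, 0.95/0.88 for
    foraging/resting on the dive layer).  The foraging mean depth of 194.3 m
    is the reported field estimate; traveling and resting components are
    shallow (within their [0, 30] m prior support).
    """
    return ModelParameters(
        gamma=np.array([0.8, 0.2]),
        theta=np.array([0.0, 2.0]),
        process_sd=np.array([4.0, 4.0]),
        alpha_top=np.array([1.734601, -1.734601]),  # logit(0.85), logit(0.15)
        alpha_sub=np.array([[0.0, 0.0],
                            [2.944439, -1.992430]]),  # logit(0.95), logit(0.12)
        dive_mu=np.array([25.0, 194.3, 25.1]),
        dive_sd=np.array([15.0, 40.0, 10.0]),
    )


@dataclass
class LatentState:
    """Latent variables of one track: grid locations and both state layers.

    ``y`` has one row per grid point (``n_intervals + 1``); ``s_top`` one
    entry per interval; ``s_sub`` one entry per dive (defined for every dive,
    but only emission-relevant inside ARS intervals).
    """

    y: np.ndarray
    s_top: np.ndarray
    s_sub: np.ndarray

    def copy(self) -> "LatentState":
        return LatentState(self.y.copy(), self.s_top.copy(), self.s_sub.copy())


@dataclass
class ArgosErrorTable:
    """Per-error-class location sd (km per coordinate), defining tau_argos."""

    sd_km: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [c for c in ARGOS_CLASSES if c not in self.sd_km]
        if missing:
            raise ParameterError(f"error table missing classes {missing}")
        sds = [float(self.sd_km[c]) for c in ARGOS_CLASSES]
        if any(s <= 0 for s in sds):
            raise ParameterError("Argos sds must be positive")
        if any(b < a for a, b in zip(sds, sds[1:])):
            raise ParameterError("Argos sds must not decrease from class 3 to B")

    def sd(self, cls: str | Sequence[str]) -> np.ndarray | float:
        if isinstance(cls, str):
            try:
                return float(self.sd_km[cls])
            except KeyError:
                raise ParameterError(f"unknown Argos error class {cls!r}") from None
        return np.array([self.sd(c) for c in cls])

    @classmethod
    def from_yaml(cls, text: str) -> "ArgosErrorTable":
        payload = yaml.safe_load(io.StringIO(text))
        return cls(sd_km={str(k): float(v) for k, v in payload["sd_km"].items()})


def default_error_table() -> ArgosErrorTable:
    """Load the per-class sds shipped as package configuration."""
    from importlib.resources import files

    text = (files("nestmove") / "data" / "argos_errors.yaml").read_text()
    return ArgosErrorTable.from_yaml(text)


# ---------------------------------------------------------------------------
# Eq.-level building blocks
# ---------------------------------------------------------------------------

def rotation_matrix(theta: float) -> np.ndarray:
    """2x2 counter-clockwise rotation by ``theta`` radians."""
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def process_mean(y_t: np.ndarray, y_prev: np.ndarray, state: int,
                 params: ModelParameters) -> np.ndarray:
    """Expected next location d = Y_t + gamma_s R(theta_s) (Y_t - Y_{t-1})."""
    y_t = np.asarray(y_t, dtype=float)
    y_prev = np.asarray(y_prev, dtype=float)
    if not (np.all(np.isfinite(y_t)) and np.all(np.isfinite(y_prev))):
        raise ParameterError("non-finite locations")
    g = params.gamma[state]
    r = rotation_matrix(params.theta[state])
    return y_t + g * (r @ (y_t - y_prev))


def transition_prob(alpha_logit: float) -> float:
    """Logistic inverse of a transition logit; strictly inside (0, 1)."""
    if not np.isfinite(alpha_logit):
        raise ParameterError("transition logit must be finite")
    return float(expit(alpha_logit))


def top_transition_matrix(params: ModelParameters) -> np.ndarray:
    """P[prev, next] over the movement layer; rows sum to 1."""
    p_trav = expit(params.alpha_top)
    return np.column_stack([p_trav, 1.0 - p_trav])


def sub_transition_matrix(params: ModelParameters, s_top: int) -> np.ndarray:
    """P[prev_sub, next_sub] for the dive layer, given the interval's S'."""
    p_forage = expit(params.alpha_sub[s_top])
    return np.column_stack([p_forage, 1.0 - p_forage])


def _normal_logpdf(x: np.ndarray, mu: np.ndarray, sd: float | np.ndarray) -> np.ndarray:
    z = (np.asarray(x, dtype=float) - mu) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * math.log(2.0 * math.pi)


def observation_loglik(fix_xy: np.ndarray, y_prev: np.ndarray, y_t: np.ndarray,
                       j: float, sd_km: float) -> float:
    """Log-density of one fix around the chord point (1-j) Y_{t-1} + j Y_t.

    Coordinates are independent with the same per-class sd, so the bivariate
    normal factorizes into two univariate terms.
    """
    if not 0.0 <= j <= 1.0:
        raise ParameterError(f"interpolation fraction j={j} outside [0, 1]")
    zhat = (1.0 - j) * np.asarray(y_prev, dtype=float) + j * np.asarray(y_t, dtype=float)
    return float(np.sum(_normal_logpdf(np.asarray(fix_xy, dtype=float), zhat, sd_km)))


def dive_loglik(depth: float | np.ndarray, component: int, params: ModelParameters,
                truncated: bool = True) -> float | np.ndarray:
    """Log-density of a maximum dive depth under one emission component.

    ``component`` indexes (traveling, foraging, resting).  By default the
    normal is truncated below at the 10-m dive-definition threshold and
    renormalized; ``truncated=False`` gives the plain normal for sensitivity
    checks.
    """
    mu = params.dive_mu[component]
    sd = params.dive_sd[component]
    if sd <= 0:
        raise ParameterError("dive sd must be positive")
    ll = _normal_logpdf(depth, mu, sd)
    if truncated:
        # log P(X > threshold) = log Phi((mu - thr) / sd), via log_ndtr for stability
        log_tail = log_ndtr((mu - DIVE_THRESHOLD_M) / sd)
        ll = np.where(np.asarray(depth) > DIVE_THRESHOLD_M, ll - log_tail, -np.inf)
    if np.ndim(depth) == 0:
        return float(ll)
    return ll


def dive_component_logliks(depths: np.ndarray, params: ModelParameters,
                           truncated: bool = True) -> np.ndarray:
    """(n_dives, 3) log emission of every depth under every component."""
    depths = np.asarray(depths, dtype=float)
    out = np.empty((depths.size, 3))
    for c in range(3):
        out[:, c] = dive_loglik(depths, c, params, truncated=truncated)
    return out


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

def _half_normal_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return math.log(2.0) + float(_normal_logpdf(x, 0.0, scale))


def log_prior(params: ModelParameters, ordered_gamma: bool = True) -> float:
    """Joint log prior density; -inf outside the support.

    gamma ~ Uniform(0, 1) with the identifiability ordering
    gamma_traveling > gamma_ars; theta ~ Uniform(-pi, pi]; process and dive
    sds half-normal; transition logits Normal(0, 2); component mean depths
    uniform on their biological bounds (traveling and resting shallow,
    foraging deep).  The ordering indicator is left unnormalized.
    """
    g, th = params.gamma, params.theta
    if np.any(g < 0) or np.any(g > 1):
        return -np.inf
    if ordered_gamma and not g[TRAVELING] > g[ARS]:
        return -np.inf
    if np.any(th <= -math.pi) or np.any(th > math.pi):
        return -np.inf
    lp = -2.0 * math.log(2.0 * math.pi)  # two uniform angles
    for sd in params.process_sd:
        lp += _half_normal_logpdf(float(sd), PROCESS_SD_PRIOR_SCALE)
    for sd in params.dive_sd:
        lp += _half_normal_logpdf(float(sd), DIVE_SD_PRIOR_SCALE)
    if not np.isfinite(lp):
        return -np.inf
    for a in np.concatenate([params.alpha_top, params.alpha_sub.ravel()]):
        lp += float(_normal_logpdf(a, 0.0, ALPHA_PRIOR_SD))
    for c, (lo, hi) in enumerate(DIVE_MU_BOUNDS):
        mu = params.dive_mu[c]
        if not lo <= mu <= hi:
            return -np.inf
        lp += -math.log(hi - lo)
    return lp


def prior_median_parameters() -> ModelParameters:
    """Deterministic initialization point: componentwise prior medians.

    gamma is set to (0.75, 0.25) — the medians of the order statistics of two
    uniforms — so the ordering constraint holds at the start.
    """
    # median of half-normal(scale) = 0.6744898 * scale
    hn = 0.6744897501960817
    return ModelParameters(
        gamma=np.array([0.75, 0.25]),
        theta=np.array([0.0, 0.0]),
        process_sd=np.array([hn * PROCESS_SD_PRIOR_SCALE] * 2),
        alpha_top=np.zeros(2),
        alpha_sub=np.zeros((2, 2)),
        dive_mu=np.array([(lo + hi) / 2.0 for lo, hi in DIVE_MU_BOUNDS]),
        dive_sd=np.array([hn * DIVE_SD_PRIOR_SCALE] * 3),
    )


# ---------------------------------------------------------------------------
# Track-level likelihood pieces
# ---------------------------------------------------------------------------

def movement_logliks(y: np.ndarray, params: ModelParameters) -> np.ndarray:
    """(T, 2) movement log-likelihood contribution of each candidate state.

    Row ``t-1`` (interval t) holds, for each state s, the log-density of
    Y_{t+1} around d_t computed with s.  The last interval has no onward
    location and contributes 0.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    T = n - 1
    out = np.zeros((T, 2))
    if T < 2:
        return out
    disp = y[1:] - y[:-1]  # displacement of interval t at index t-1
    sx, sy = params.process_sd
    for s in range(2):
        r = rotation_matrix(params.theta[s])
        pred = y[1:T] + params.gamma[s] * (disp[: T - 1] @ r.T)
        resid = y[2:] - pred
        out[: T - 1, s] = (
            _normal_logpdf(resid[:, 0], 0.0, sx) + _normal_logpdf(resid[:, 1], 0.0, sy)
        )
    return out


def observation_loglik_track(track: "TrackData", y: np.ndarray) -> float:
    """Sum of fix log-densities for one track given grid locations."""
    t = track.fix_interval
    zhat = (1.0 - track.fix_j)[:, None] * y[t - 1] + track.fix_j[:, None] * y[t]
    ll = _normal_logpdf(track.fix_x, zhat[:, 0], track.fix_sd)
    ll = ll + _normal_logpdf(track.fix_y, zhat[:, 1], track.fix_sd)
    return float(np.sum(ll))


def _sub_chain_terms(track: "TrackData", s_top: np.ndarray, s_sub: np.ndarray,
                     params: ModelParameters) -> float:
    """Initial + transition log-probability of the dive sub-chain."""
    d = track.dive_interval
    if d.size == 0:
        return 0.0
    lp = LOG_HALF  # uniform initial sub-state at the track's first dive
    if d.size > 1:
        rows = s_top[d[1:] - 1]  # S' of the interval of dive u
        p_forage = expit(params.alpha_sub[rows, s_sub[:-1]])
        target = np.where(s_sub[1:] == FORAGING, p_forage, 1.0 - p_forage)
        lp += float(np.sum(np.log(target)))
    return lp


def complete_data_loglik(tracks: Sequence["TrackData"],
                         latents: Sequence[LatentState],
                         params: ModelParameters,
                         include_observation: bool = True,
                         truncated_dives: bool = True) -> float:
    """Joint log-density of data and latent variables given parameters.

    Sums, over tracks: the uniform initial top state, top-layer transitions,
    movement process terms, the uniform initial sub-state with sub-layer
    transitions, dive emissions, and (optionally) the Argos observation
    terms.  The flat initial-location prior contributes no term.
    """
    if len(tracks) != len(latents):
        raise ParameterError("tracks and latent states must align")
    total = 0.0
    for track, lat in zip(tracks, latents):
        T = track.n_intervals
        if lat.s_top.shape != (T,) or lat.y.shape != (T + 1, 2):
            raise ParameterError("latent dimensions do not match track")
        if lat.s_sub.shape != track.dive_depth.shape:
            raise ParameterError("one sub-state per dive required")
        total += LOG_HALF  # initial top state
        if T > 1:
            p_trav = expit(params.alpha_top[lat.s_top[:-1]])
            target = np.where(lat.s_top[1:] == TRAVELING, p_trav, 1.0 - p_trav)
            total += float(np.sum(np.log(target)))
        mv = movement_logliks(lat.y, params)
        total += float(np.sum(mv[np.arange(T), lat.s_top]))
        total += _sub_chain_terms(track, lat.s_top, lat.s_sub, params)
        if track.dive_depth.size:
            comp = np.where(lat.s_top[track.dive_interval - 1] == TRAVELING,
                            0, 1 + lat.s_sub)
            e = dive_component_logliks(track.dive_depth, params,
                                       truncated=truncated_dives)
            total += float(np.sum(e[np.arange(comp.size), comp]))
        if include_observation:
            total += observation_loglik_track(track, lat.y)
    return total


def forward_loglik(track: "TrackData", y: np.ndarray, params: ModelParameters,
                   truncated_dives: bool = True) -> float:
    """Exact marginal log-likelihood over both discrete state layers.

    Runs a forward recursion over the augmented chain z_t = (S'_t, K_t),
    where K_t is the sub-state after the last dive at or before interval t.
    Within-interval dive sequences are folded into 2x2 log-space transfer
    matrices, so the sum over all 2^T x 2^D paths is computed in O(T + D).
    Observation terms are excluded (they do not depend on the states).
    """
    T = track.n_intervals
    mv = movement_logliks(y, params)
    log_ptop = np.log(top_transition_matrix(params))
    log_psub = np.log(np.stack([sub_transition_matrix(params, s) for s in range(2)]))
    log_e = (dive_component_logliks(track.dive_depth, params, truncated=truncated_dives)
             if track.dive_depth.size else np.zeros((0, 3)))
    offs = track.dive_offsets

    # within-interval transfer matrices M[t, s, k_in, k_out]
    M = np.zeros((T, 2, 2, 2))
    for t in range(T):
        for s in range(2):
            mat = np.where(np.eye(2, dtype=bool), 0.0, -np.inf)
            for u in range(offs[t], offs[t + 1]):
                if u == 0:
                    trans = np.full((2, 2), LOG_HALF)  # track's first dive: uniform init
                else:
                    trans = log_psub[s]
                emis = np.full(2, log_e[u, 0]) if s == TRAVELING else log_e[u, 1:3]
                step = trans + emis[None, :]
                mat = logsumexp(mat[:, :, None] + step[None, :, :], axis=1)
            M[t, s] = mat

    alpha = np.full((T, 2, 2), -np.inf)  # [t, s, k]
    for s in range(2):
        # entering sub-state uniform; top initial state uniform
        alpha[0, s] = LOG_HALF + mv[0, s] + logsumexp(LOG_HALF + M[0, s], axis=0)
    for t in range(1, T):
        prev = alpha[t - 1]  # [s', k']
        for s in range(2):
            # sum over s', k' of prev + log P(s|s') + M[t, s, k', k]
            inner = prev[:, :, None] + log_ptop[:, s][:, None, None] + M[t, s][None, :, :]
            alpha[t, s] = logsumexp(inner, axis=(0, 1)) + mv[t, s]
    return float(logsumexp(alpha[T - 1]))
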