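"""Posterior decoding and the behavioral summaries reported for tag studies.

Decoding follows the most-likely-state rule: an interval is labeled
traveling when its posterior probability of traveling exceeds 0.5 (a tie
goes to area-restricted search, since the rule names traveling strictly);
each dive gets the plurality label among traveling / foraging / resting
across posterior draws.  Time-in-state proportions are computed over dive
observations — the only layer where all three behaviors exist — per
individual, then averaged across individuals.  Temporal profiles bin dives
by UTC calendar month or UTC hour of day, with uncertainty bands from a
fixed number of posterior draws of the latent labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import PosteriorDraws
from .model import TRAVELING, ParameterError

BEHAVIOR_NAMES = ("traveling", "foraging", "resting")


@dataclass
class DecodedSequence:
    """Modal behavior labels with posterior probabilities.

    ``intervals``: one row per (track, interval) with the posterior
    probability of traveling and the modal top state.  ``dives``: one row
    per dive with per-behavior posterior probabilities and the plurality
    label.
    """

    intervals: pd.DataFrame
    dives: pd.DataFrame


def dive_behavior_draws(draws: PosteriorDraws) -> np.ndarray:
    """(n_draws, total_dives) behavior code per dive per posterior draw.

    0 = traveling (the dive's interval is in the traveling state),
    1 = foraging, 2 = resting.
    """
    out = np.empty((draws.n_draws, draws.s_sub.shape[1]), dtype=np.int8)
    for track, isl, dsl in zip(draws.tracks, draws.interval_slices(),
                               draws.dive_slices()):
        if track.n_dives == 0:
            continue
        st = draws.s_top[:, isl][:, track.dive_interval - 1]
        ss = draws.s_sub[:, dsl]
        out[:, dsl] = np.where(st == TRAVELING, 0, 1 + ss)
    return out


def decode(draws: PosteriorDraws) -> DecodedSequence:
    """Modal states under the phi' > 0.5 rule (top) and plurality (dives)."""
    if draws.n_draws < 1:
        raise ParameterError("need at least one retained draw")
    irows = []
    for track, isl in zip(draws.tracks, draws.interval_slices()):
        p_trav = (draws.s_top[:, isl] == TRAVELING).mean(axis=0)
        grid = track.grid_times
        irows.append(pd.DataFrame({
            "animal": track.animal, "track": track.track_id,
            "interval": np.arange(1, track.n_intervals + 1),
            "start": grid[:-1],
            "p_traveling": p_trav,
            # tie at 0.5 -> ARS: "traveling" requires strict majority
            "state": np.where(p_trav > 0.5, "traveling", "ars"),
        }))
    intervals = pd.concat(irows, ignore_index=True)

    beh = dive_behavior_draws(draws)
    drows = []
    for track, dsl in zip(draws.tracks, draws.dive_slices()):
        if track.n_dives == 0:
            continue
        sub = beh[:, dsl]
        probs = np.stack([(sub == b).mean(axis=0) for b in range(3)], axis=1)
        modal = probs.argmax(axis=1)
        drows.append(pd.DataFrame({
            "animal": track.animal, "track": track.track_id,
            "interval": track.dive_interval,
            "timestamp": track.dive_time,
            "depth_m": track.dive_depth,
            "p_traveling": probs[:, 0],
            "p_foraging": probs[:, 1],
            "p_resting": probs[:, 2],
            "p_modal": probs[np.arange(len(modal)), modal],
            "behavior": [BEHAVIOR_NAMES[b] for b in modal],
        }))
    dives = (pd.concat(drows, ignore_index=True) if drows
             else pd.DataFrame(columns=["animal", "track", "interval", "timestamp",
                                        "depth_m", "p_traveling", "p_foraging",
                                        "p_resting", "p_modal", "behavior"]))
    return DecodedSequence(intervals=intervals, dives=dives)


def state_time_proportions(decoded: DecodedSequence
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual percent time per behavior (over dive observations),
    plus the across-individual mean and sd.

    Returns ``(per_individual, summary)``.  The summary reports the sd on
    both the percentage and the proportion scale; an individual with zero
    dives is excluded, and single-individual sds are reported as 0 with
    ``n = 1``.
    """
    d = decoded.dives
    if d.empty:
        raise ParameterError("no decoded dives")
    rows = []
    for animal, g in d.groupby("animal", sort=True):
        n = len(g)
        fr = [float((g["behavior"] == b).sum()) / n for b in BEHAVIOR_NAMES]
        rows.append({"animal": animal, "n_dives": n,
                     **{f"pct_{b}": 100.0 * f for b, f in zip(BEHAVIOR_NAMES, fr)}})
    per_ind = pd.DataFrame(rows)
    summary_rows = []
    n_ind = len(per_ind)
    for b in BEHAVIOR_NAMES:
        vals = per_ind[f"pct_{b}"].to_numpy(float)
        sd_pct = float(np.std(vals, ddof=1)) if n_ind > 1 else 0.0
        summary_rows.append({
            "behavior": b,
            "mean_pct": float(np.mean(vals)),
            "sd_pct": sd_pct,
            "sd_proportion": sd_pct / 100.0,
            "n_individuals": n_ind,
        })
    return per_ind, pd.DataFrame(summary_rows)


def depth_distribution_summary(decoded: DecodedSequence, draws: PosteriorDraws,
                               level: float = 0.95) -> pd.DataFrame:
    """Per-behavior depth summary: posterior mean and credible interval of
    the component mean depth, plus empirical quartiles (linear interpolation
    of order statistics) and maximum of the dives assigned to the behavior.

    Behaviors with no assigned dives have their empirical stats reported as
    missing.
    """
    mu_cols = {b: f"dive_mu_{b}" for b in BEHAVIOR_NAMES}
    rows = []
    for b in BEHAVIOR_NAMES:
        i = draws.param_names.index(mu_cols[b])
        mu_draws = draws.params[:, i]
        lo, hi = draws.credible_interval(mu_cols[b], level)
        depths = decoded.dives.loc[decoded.dives["behavior"] == b,
                                   "depth_m"].to_numpy(float)
        if depths.size:
            q25, q75 = np.percentile(depths, [25, 75])  # type-7 interpolation
            dmax = float(depths.max())
        else:
            q25 = q75 = dmax = float("nan")
        rows.append({
            "behavior": b,
            "mu_posterior_mean": float(mu_draws.mean()),
            "mu_ci_low": lo, "mu_ci_high": hi,
            "n_dives": int(depths.size),
            "depth_q25": float(q25), "depth_q75": float(q75),
            "depth_max": dmax,
        })
    return pd.DataFrame(rows)


def temporal_frequency(decoded: DecodedSequence, draws: PosteriorDraws,
                       resolution: str = "month",
                       n_uncertainty_draws: int = 50) -> pd.DataFrame:
    """Behavior frequency by calendar month or hour of day (UTC), with
    uncertainty bands from posterior draws of the latent labels.

    The point estimate is the posterior-mean fraction of dives in each
    behavior per bin; the band is the min–max spread of that fraction
    recomputed under ``n_uncertainty_draws`` evenly spaced retained draws.
    Empty bins are reported with count 0 and no fraction.
    """
    if resolution not in ("month", "hour"):
        raise ParameterError("resolution must be 'month' or 'hour'")
    times = pd.DatetimeIndex(np.concatenate(
        [t.dive_time for t in draws.tracks if t.n_dives]))
    bins = times.month if resolution == "month" else times.hour
    bins = np.asarray(bins)
    all_bins = np.arange(1, 13) if resolution == "month" else np.arange(24)

    beh = dive_behavior_draws(draws)
    n = draws.n_draws
    k = min(max(int(n_uncertainty_draws), 1), n)
    pick = np.unique(np.linspace(0, n - 1, k).astype(int))

    rows = []
    for bin_val in all_bins:
        sel = bins == bin_val
        count = int(sel.sum())
        for b, name in enumerate(BEHAVIOR_NAMES):
            if count == 0:
                rows.append({"bin": int(bin_val), "behavior": name,
                             "n_dives": 0, "frequency": float("nan"),
                             "band_low": float("nan"), "band_high": float("nan")})
                continue
            per_draw = (beh[:, sel] == b).mean(axis=1)
            sub = per_draw[pick]
            rows.append({"bin": int(bin_val), "behavior": name,
                         "n_dives": count,
                         "frequency": float(per_draw.mean()),
                         "band_low": float(sub.min()),
                         "band_high": float(sub.max())})
    out = pd.DataFrame(rows)
    out.insert(0, "resolution", resolution)
    return out


def deep_dive_count(decoded: DecodedSequence, threshold_m: float) -> dict:
    """Count of observed dives strictly deeper than ``threshold_m``,
    overall and per modal behavior."""
    if threshold_m < 10.0:
        raise ParameterError("threshold must be >= the 10-m dive definition")
    d = decoded.dives
    deep = d["depth_m"].to_numpy(float) > threshold_m
    per = {b: int((deep & (d["behavior"] == b).to_numpy()).sum())
           for b in BEHAVIOR_NAMES}
    return {"threshold_m": float(threshold_m), "total": int(deep.sum()), **per}


def mean_per_individual(total_count: float, n_individuals: int) -> float:
    """Average count per individual — e.g. total recorded dives over the
    number of tagged animals."""
    if n_individuals < 1:
        raise ParameterError("need at least one individual")
    return float(total_count) / n_individuals


def tag_metadata() -> pd.DataFrame:
    """Deployment metadata of the reference 11-animal tagging campaign.

    One row per tag: raw Argos and dive-record counts and the deployment
    window.  Ships as package data; useful as a realistic template when
    configuring the synthetic generator.
    """
    from importlib.resources import files

    with (files("nestmove") / "data" / "tag_metadata.csv").open() as fh:
        return pd.read_csv(fh, dtype={"animal": str},
                           parse_dates=["start", "end"])
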