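"""Shared fixtures: a toy track small enough for brute-force enumeration."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from nestmove.model import LatentState, complete_data_loglik, default_parameters
from nestmove.tracks import TrackData


@pytest.fixture
def params():
    return default_parameters()


def make_toy_track(T: int = 4, dive_intervals=(1, 1, 2, 4),
                   depths=(30.0, 200.0, 25.0, 150.0),
                   n_fixes: int = 2, seed: int = 0) -> tuple[TrackData, np.ndarray]:
    """A hand-sized track plus plausible grid locations."""
    rng = np.random.default_rng(seed)
    y = rng.normal(0.0, 5.0, (T + 1, 2))
    fix_interval = np.sort(rng.integers(1, T + 1, size=n_fixes))
    track = TrackData(
        animal="toy", track_id=1, t0=np.datetime64("2016-03-01T00:00", "s"),
        n_intervals=T,
        fix_interval=fix_interval,
        fix_j=rng.random(n_fixes),
        fix_x=rng.normal(0, 5, n_fixes), fix_y=rng.normal(0, 5, n_fixes),
        fix_sd=np.full(n_fixes, 1.0),
        dive_interval=np.asarray(dive_intervals, dtype=np.int64),
        dive_depth=np.asarray(depths, dtype=float),
    )
    return track, y


@pytest.fixture
def toy_track():
    return make_toy_track()


def enumerate_state_paths(track: TrackData, y: np.ndarray, params):
    """Brute-force posterior over all (S', S'') paths of a toy track.

    Returns ``(keys, logliks)`` where each key is the concatenated state
    tuple and logliks are complete-data log-densities without observation
    terms.  This is the independent oracle the forward recursion and the
    FFBS draws are checked against.
    """
    T = track.n_intervals
    D = track.n_dives
    keys, lls = [], []
    for st in itertools.product([0, 1], repeat=T):
        for ss in itertools.product([0, 1], repeat=D):
            lat = LatentState(y, np.asarray(st), np.asarray(ss, dtype=np.int64))
            keys.append(st + ss)
            lls.append(complete_data_loglik([track], [lat], params,
                                            include_observation=False))
    return keys, np.asarray(lls)


def enumerated_marginal(track, y, params) -> float:
    _, lls = enumerate_state_paths(track, y, params)
    return float(logsumexp(lls))
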