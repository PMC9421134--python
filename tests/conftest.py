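import numpy as np
import pandas as pd
import pytest

from hrvstress.hrv import RRSeries


def make_activity(minutes, met=1.3, supine=0.0, worn=True):
    """Uniform activity table over the given minute indices."""
    minutes = np.asarray(minutes, dtype=int)
    return pd.DataFrame(
        {
            "minute": minutes,
            "met": np.full(minutes.size, float(met)),
            "supine_fraction": np.full(minutes.size, float(supine)),
            "worn": np.full(minutes.size, bool(worn)),
        }
    )


def constant_rr_series(n_minutes, rr=1000.0, start_minute=0):
    """Strictly periodic beats covering n_minutes whole minutes."""
    n = int(n_minutes * 60000 / rr)
    t = start_minute * 60 + np.arange(1, n + 1) * rr / 1000.0
    keep = t < (start_minute + n_minutes) * 60
    return RRSeries(t[keep], np.full(keep.sum(), rr))


def minute_table_from_rmssd(rmssd_per_minute, met=1.3, supine=0.0, worn=True,
                            n_beats=70, mean_rr=850.0, start_minute=0):
    """Minute records with exact per-minute pooled RMSSD values.

    Builds the sufficient statistics directly: each minute gets
    ``n_beats - 1`` successive pairs whose mean squared difference is
    rmssd^2, so any 5-min pooled window has RMSSD equal to the
    root-mean-square of the five per-minute values weighted by pairs.
    """
    vals = np.asarray(rmssd_per_minute, dtype=float)
    n = vals.size
    minutes = np.arange(start_minute, start_minute + n)
    pairs = n_beats - 1
    return pd.DataFrame(
        {
            "minute": minutes,
            "met": np.full(n, float(met)),
            "supine_fraction": np.full(n, float(supine)),
            "worn": np.full(n, bool(worn)) if np.isscalar(worn) else np.asarray(worn, bool),
            "n_valid_beats": np.full(n, n_beats),
            "sum_rr": np.full(n, n_beats * mean_rr),
            "sum_sq_succ_diff": pairs * vals**2,
            "n_succ_pairs": np.full(n, pairs),
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
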