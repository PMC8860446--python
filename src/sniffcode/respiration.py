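"""Respiration-event detection, trial alignment and phototag identification.

Inhalation onsets are detected as descending zero-crossings of the
smoothed, mean-subtracted pressure signal with hysteresis; every trial is
then re-referenced to the first inhalation at or after odor onset (t0),
which is the zero point of all downstream analyses.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .types import AlignedRaster, RespirationTrace

logger = logging.getLogger(__name__)

__all__ = [
    "detect_inhalation_onsets",
    "align_trials",
    "build_raster",
    "identify_phototagged",
]


def detect_inhalation_onsets(trace: RespirationTrace,
                             smoothing_ms: float = 5.0,
                             hysteresis: float | None = None) -> np.ndarray:
    """Inhalation-onset times from a pressure trace.

    The pressure is Gaussian-smoothed (``smoothing_ms`` sd) and
    mean-subtracted; onsets are descending zero-crossings, accepted only
    after the signal has re-armed by exceeding ``hysteresis`` (default 10%
    of the signal SD) since the previous accepted onset.  Crossing times
    are linearly interpolated between samples.  A constant trace yields an
    empty array.
    """
    if len(trace.pressure) == 0:
        raise ValueError("empty trace")
    sigma = smoothing_ms / 1000.0 * trace.fs
    s = gaussian_filter1d(trace.pressure, sigma) if sigma > 0 else trace.pressure
    s = s - s.mean()
    sd = s.std()
    if sd == 0:
        return np.array([])
    h = 0.1 * sd if hysteresis is None else float(hysteresis)

    down = np.flatnonzero((s[:-1] > 0) & (s[1:] <= 0))
    if len(down) == 0:
        return np.array([])
    # max of the signal between consecutive candidate crossings, used to
    # decide whether the detector re-armed (rose above +h) since the last
    # accepted onset
    bounds = np.concatenate([[0], down + 1])
    seg_max = np.maximum.reduceat(s, bounds[:-1])

    dt = trace.times[1] - trace.times[0] if len(trace.times) > 1 else 1.0
    accepted = []
    run_max = -np.inf
    for k, i in enumerate(down):
        run_max = max(run_max, seg_max[k])
        if run_max >= h:
            frac = s[i] / (s[i] - s[i + 1])
            accepted.append(trace.times[i] + frac * dt)
            run_max = -np.inf
    return np.asarray(accepted)


def align_trials(trials: pd.DataFrame, onsets: np.ndarray,
                 odor_duration: float = 1.0) -> pd.DataFrame:
    """Attach t0 (first inhalation at/after odor onset) to each trial.

    ``t0_s`` is the earliest onset with ``odor_on_s <= t0 < odor_on_s +
    odor_duration``; trials without one are flagged invalid rather than
    raising.
    """
    onsets = np.asarray(onsets, dtype=float)
    if np.any(np.diff(onsets) < 0):
        raise ValueError("onsets must be sorted")
    out = trials.copy()
    odor_on = out["odor_on_s"].to_numpy(dtype=float)
    idx = np.searchsorted(onsets, odor_on, side="left")
    has = idx < len(onsets)
    t0 = np.full(len(out), np.nan)
    t0[has] = onsets[np.clip(idx, 0, max(len(onsets) - 1, 0))][has]
    valid = has & (t0 < odor_on + odor_duration)
    t0[~valid] = np.nan
    out["t0_s"] = t0
    out["valid"] = valid
    return out


def build_raster(spikes: pd.DataFrame, trials: pd.DataFrame,
                 window: tuple[float, float] = (-0.10, 0.30)) -> AlignedRaster:
    """Aligned raster: spike times relative to t0 inside half-open window.

    Invalid trials are skipped (logged); spikes outside the window are
    dropped; per-trial counts are conserved within the window.
    """
    w_lo, w_hi = window
    if w_lo >= w_hi:
        raise ValueError("window must satisfy w_lo < w_hi")
    if "t0_s" not in trials.columns:
        raise ValueError("trials must be aligned first (missing t0_s)")
    valid = trials[trials.get("valid", True) & trials["t0_s"].notna()]
    n_skipped = len(trials) - len(valid)
    if n_skipped:
        logger.info("build_raster: skipping %d invalid trials", n_skipped)

    times = spikes["spike_time_s"].to_numpy(dtype=float)
    order = np.argsort(times, kind="stable")
    times = times[order]
    unit = spikes["unit_id"].to_numpy()[order]

    rows_unit, rows_trial, rows_rel = [], [], []
    for tid, t0 in zip(valid["trial_id"].to_numpy(),
                       valid["t0_s"].to_numpy(dtype=float)):
        a = np.searchsorted(times, t0 + w_lo, side="left")
        b = np.searchsorted(times, t0 + w_hi, side="left")
        rows_unit.append(unit[a:b])
        rows_trial.append(np.full(b - a, tid))
        rows_rel.append(times[a:b] - t0)
    if rows_unit:
        out = pd.DataFrame({
            "unit_id": np.concatenate(rows_unit),
            "trial_id": np.concatenate(rows_trial),
            "rel_time_s": np.concatenate(rows_rel),
        })
    else:
        out = pd.DataFrame(columns=["unit_id", "trial_id", "rel_time_s"])
    units = np.unique(spikes["unit_id"]) if len(spikes) else np.array([])
    return AlignedRaster(spikes=out, trials=valid.reset_index(drop=True),
                         window=window, units=units)


def identify_phototagged(spikes: pd.DataFrame, pulse_times: np.ndarray,
                         window_ms: float = 5.0, alpha: float = 0.01,
                         jitter_max_ms: float = 2.0,
                         baseline_ms: float = 10.0) -> pd.DataFrame:
    """Tag units with short-latency, low-jitter responses to light pulses.

    A unit is tagged iff (i) its firing rate in ``[0, window_ms)`` after
    pulse onset significantly exceeds the rate in ``[-baseline_ms, 0)``
    before it (one-sided paired t-test across pulses, p < alpha) and (ii)
    the SD of its first-spike latency across pulses is at most
    ``jitter_max_ms``.  Requires at least 20 pulses.
    """
    pulse_times = np.asarray(pulse_times, dtype=float)
    if len(pulse_times) == 0:
        raise ValueError("no pulses")
    if len(pulse_times) < 20:
        raise ValueError("phototagging requires >= 20 pulses")
    w = window_ms / 1000.0
    b = baseline_ms / 1000.0

    rows = []
    for uid, g in spikes.groupby("unit_id", sort=True):
        t = np.sort(g["spike_time_s"].to_numpy(dtype=float))
        post = (np.searchsorted(t, pulse_times + w)
                - np.searchsorted(t, pulse_times))
        pre = (np.searchsorted(t, pulse_times)
               - np.searchsorted(t, pulse_times - b))
        diff = post / w - pre / b  # paired rate differences (spikes/s)
        m = diff.mean()
        sd = diff.std(ddof=1)
        if sd == 0:
            p = 0.0 if m > 0 else 1.0
        else:
            tstat = m / (sd / np.sqrt(len(diff)))
            p = float(stats.t.sf(tstat, df=len(diff) - 1))
        # first-spike latency per pulse within the response window
        first_idx = np.searchsorted(t, pulse_times)
        has = (first_idx < len(t)) & (post > 0)
        lat = (t[np.clip(first_idx, 0, max(len(t) - 1, 0))] - pulse_times)[has]
        lat_ms = lat * 1000.0
        lat_sd = float(np.std(lat_ms, ddof=1)) if len(lat_ms) > 1 else np.nan
        tagged = bool(m > 0 and p < alpha and np.isfinite(lat_sd)
                      and lat_sd <= jitter_max_ms)
        rows.append((uid, tagged, p, float(np.mean(lat_ms)) if len(lat_ms) else np.nan,
                     lat_sd, int(has.sum())))
    return pd.DataFrame(rows, columns=[
        "unit_id", "tagged", "p_value", "latency_mean_ms", "latency_sd_ms",
        "n_pulses_with_spike"])
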