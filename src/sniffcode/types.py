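"""Shared container types for sniff-aligned analyses.

Time is in seconds throughout, with t = 0 at the first inhalation of odor
(``t0``) for all aligned quantities, and every analysis window half-open
``[a, b)``.  Tables are tidy pandas DataFrames so they serialize losslessly
to CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class RespirationTrace:
    """Uniformly sampled single-channel pressure signal.

    Downward deflections are inhalation, upward exhalation.  When produced
    by the generator, ``true_onsets`` carries the ground-truth inhalation
    onset times.
    """

    times: np.ndarray  # s, uniform
    pressure: np.ndarray  # arbitrary units
    fs: float  # Hz
    true_onsets: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.times.shape != self.pressure.shape:
            raise ValueError("times and pressure must have equal length")
        if not np.all(np.isfinite(self.pressure)):
            raise ValueError("pressure must be finite")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("sampling must be uniform")


@dataclass
class GroundTruth:
    """Latent draws of the generator, kept for parameter-recovery tests.

    ``responses``: unit_id, class_label, odor_id, responsive, amplitude.
    ``latencies``: unit_id, odor_id, concentration, latency_s, amplitude_s
    (per-concentration latency and effective bump amplitude).
    ``trials``: the trial table plus the true first-inhalation time.
    """

    units: pd.DataFrame
    responses: pd.DataFrame
    latencies: pd.DataFrame
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.latencies) and (self.latencies["latency_s"] < 0).any():
            raise ValueError("latencies must be >= 0")
        bad = self.responses.loc[~self.responses["responsive"], "amplitude"]
        if len(bad) and (bad != 0).any():
            raise ValueError("nonresponsive pairs must have amplitude 0")


@dataclass
class AlignedRaster:
    """Spike times re-referenced to the first odor inhalation.

    ``spikes``: long table (unit_id, trial_id, rel_time_s) with every
    relative time inside the half-open ``window``; ``trials`` holds the
    aligned (valid) trials with their condition labels and ``t0_s``.
    """

    spikes: pd.DataFrame
    trials: pd.DataFrame
    window: tuple[float, float]
    units: np.ndarray

    def __post_init__(self) -> None:
        lo, hi = self.window
        if lo >= hi:
            raise ValueError("window must satisfy w_lo < w_hi")
        if len(self.spikes):
            rel = self.spikes["rel_time_s"].to_numpy()
            if rel.min() < lo or rel.max() >= hi:
                raise ValueError("relative spike times outside window")


@dataclass
class SpikeDensity:
    """Trial-averaged Gaussian-kernel firing-rate estimates.

    ``rate`` has one row per group in ``index`` (typically unit x odor x
    concentration) evaluated at the bin centers ``grid``.
    """

    grid: np.ndarray  # s, bin centers
    rate: np.ndarray  # spikes/s, (n_groups, n_bins)
    index: pd.DataFrame  # group keys aligned with rate rows
    sigma: float  # s
    step: float  # s

    def __post_init__(self) -> None:
        if self.rate.ndim != 2 or self.rate.shape[0] != len(self.index):
            raise ValueError("rate rows must match index")
        if np.any(self.rate < -1e-9):
            raise ValueError("rates must be >= 0")


@dataclass
class ResponseTensor:
    """Pseudopopulation response array: units x condition x trial x bin.

    ``conditions`` is a DataFrame (odor_id, concentration) aligned with
    axis 1; ``grid`` gives bin centers (s, relative to t0).  ``meta``
    optionally carries per-unit metadata (class/recording labels).
    """

    data: np.ndarray  # spikes/s
    units: np.ndarray
    conditions: pd.DataFrame
    grid: np.ndarray
    meta: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("tensor must be units x condition x trial x bin")
        if self.data.shape[0] != len(self.units):
            raise ValueError("unit axis mismatch")
        if self.data.shape[1] != len(self.conditions):
            raise ValueError("condition axis mismatch")
        if self.data.shape[3] != len(self.grid):
            raise ValueError("bin axis mismatch")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("tensor values must be finite")

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def select(self, odor_id=None, concentration=None) -> "ResponseTensor":
        """Sub-tensor restricted to the given odor(s)/concentration(s)."""
        mask = np.ones(len(self.conditions), dtype=bool)
        if odor_id is not None:
            vals = [odor_id] if np.isscalar(odor_id) else list(odor_id)
            mask &= self.conditions["odor_id"].isin(vals).to_numpy()
        if concentration is not None:
            vals = ([concentration] if np.isscalar(concentration)
                    else list(concentration))
            mask &= self.conditions["concentration"].isin(vals).to_numpy()
        return ResponseTensor(self.data[:, mask], self.units,
                              self.conditions.loc[mask].reset_index(drop=True),
                              self.grid, self.meta)


@dataclass
class PCATrajectory:
    """Per-condition trajectories in the first K principal components."""

    scores: np.ndarray  # (n_cond, n_bins, K)
    explained_variance_ratio: np.ndarray  # (K,)
    components: np.ndarray  # (K, n_units), orthonormal rows
    grid: np.ndarray  # s
    conditions: pd.DataFrame

    def __post_init__(self) -> None:
        evr = self.explained_variance_ratio
        if np.any(evr < -1e-12) or np.any(evr > 1 + 1e-12):
            raise ValueError("explained-variance fractions must be in [0, 1]")
        if np.any(np.diff(evr) > 1e-9):
            raise ValueError("explained variance must be non-increasing")


@dataclass
class DecodingResult:
    """Accuracy of a linear decoder at one window position."""

    window: tuple[float, float]  # s
    feature_mode: str  # 'rate' | 'binary'
    label_type: str  # 'identity' | 'intensity' | ...
    accuracies: np.ndarray  # per repeat
    n_classes: int

    def __post_init__(self) -> None:
        a = np.asarray(self.accuracies, dtype=float)
        if len(a) and (a.min() < 0 or a.max() > 1):
            raise ValueError("accuracies must be in [0, 1]")
        self.accuracies = a

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sem_accuracy(self) -> float:
        a = self.accuracies
        return float(np.std(a, ddof=1) / np.sqrt(len(a))) if len(a) > 1 else float("nan")

    @property
    def chance(self) -> float:
        return 1.0 / self.n_classes


@dataclass
class TrendResult:
    """Spearman rank-correlation summary."""

    rho: float
    p_value: float
    n: int
    undefined: bool = False

    def __post_init__(self) -> None:
        if not self.undefined and not -1 - 1e-9 <= self.rho <= 1 + 1e-9:
            raise ValueError("rho must be in [-1, 1]")


@dataclass
class BehaviorSession:
    """One 2AFC session.

    ``trials``: trial_id, stim ('A'/'B'), led, lick_time_s (NaN when the
    subject did not respond), side (chosen port, None when unresponded),
    correct.
    """

    trials: pd.DataFrame
    session_id: str = "s00"

    def __post_init__(self) -> None:
        df = self.trials
        responded = df["lick_time_s"].notna()
        if (responded != df["side"].notna()).any():
            raise ValueError("chosen side must be present iff lick time present")


@dataclass
class DPrimeCurve:
    """d' of cumulative 2AFC responses over time."""

    t: np.ndarray  # s
    dprime: np.ndarray
    hits: np.ndarray  # cumulative A-side responses among class-A trials
    false_alarms: np.ndarray  # cumulative A-side responses among class-B trials
    n_signal: int
    n_noise: int
    session_id: str = "s00"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.dprime)):
            raise ValueError("d' must be finite after rate correction")
        if np.any(np.diff(self.hits) < 0) or np.any(np.diff(self.false_alarms) < 0):
            raise ValueError("cumulative counts must be non-decreasing")
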