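"""Synthetic session generator for sniff-aligned odor-coding analyses.

Emulates the statistical structure of awake head-fixed recordings during
odor presentation: a quasi-periodic respiration pressure signal, odor
delivery triggered at the exhalation phase, spike trains of several
principal-cell classes firing as inhomogeneous Poisson processes with
odor-specific Gaussian rate bumps, and two-alternative forced-choice
(2AFC) behavioral sessions with lick latencies.

All distributional choices for firing rates are stand-ins: the experiments
this generator emulates do not come with a published rate model.  The
generator's role is to provide ground-truth-tagged data on which every
downstream statistic (activation tests, sparseness, decoding, peak-time
trends, d') can be validated by parameter recovery.

Concentration laws are log-linear with per-doubling parameters, referenced
to the highest concentration delivered:

    latency(c)   = latency_mean + latency_shift_per_doubling * log2(c / c_ref)
    amplitude(c) = amplitude * max(0, 1 + rate_gain_per_doubling * log2(c / c_ref))

so ``latency_mean`` is the class latency at the reference (highest)
concentration and negative shift parameters move responses *earlier* as
concentration increases.  The across-cell latency scatter likewise follows

    sd(c) = latency_sd + latency_sd_shift_per_doubling * log2(c / c_ref)

with a negative shift producing tighter (more synchronous) latencies at
high concentration.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .types import BehaviorSession, GroundTruth, RespirationTrace

__all__ = [
    "ClassParams",
    "GeneratorConfig",
    "BehaviorConfig",
    "simulate_respiration",
    "simulate_session",
    "simulate_behavior",
    "simulate_phototag_block",
]

BLANK = "blank"


class ClassParams(BaseModel):
    """Per-cell-class generator parameters.

    ``latency_mean`` is the mean response latency (s) at the reference
    concentration; ``latency_shift_per_doubling`` (s, negative = earlier at
    higher concentration) and ``rate_gain_per_doubling`` (dimensionless)
    set the concentration laws.  ``response_prob`` overrides the global
    per-odor response probability when given (0 makes the class untuned).
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_units: int
    latency_mean: float = 0.075
    latency_shift_per_doubling: float = 0.0
    rate_gain_per_doubling: float = 0.0
    response_prob: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "ClassParams":
        if self.n_units < 0:
            raise ValueError("n_units must be >= 0")
        if self.latency_mean < 0:
            raise ValueError("latency_mean must be >= 0")
        if self.response_prob is not None and not 0 <= self.response_prob <= 1:
            raise ValueError("response_prob must be in [0, 1]")
        return self


def _default_classes() -> dict[str, ClassParams]:
    # Latency means follow the reported class ordering: fan cells earliest
    # and concentration invariant, pyramidal cells slightly later and
    # shifting earlier with concentration, CA1 latest with a purely
    # temporal concentration code (zero rate gain).
    return {
        "fan": ClassParams(
            n_units=122, latency_mean=0.072, latency_shift_per_doubling=0.0,
            rate_gain_per_doubling=0.2,
        ),
        "pyramidal": ClassParams(
            n_units=98, latency_mean=0.078, latency_shift_per_doubling=-0.010,
            rate_gain_per_doubling=0.2,
        ),
    }


class GeneratorConfig(BaseModel):
    """Study-condition parameters for a simulated recording session.

    Defaults mirror the emulated protocol: 11 odors at four relative
    concentrations (0.25/0.33/0.50/1.00), 25 repetitions of each odor at
    each concentration plus blank trials, ~300-ms respiration cycles, and
    1-s odor delivery triggered at the exhalation phase.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    classes: dict[str, ClassParams] = None  # type: ignore[assignment]
    n_odors: int = 11
    concentrations: tuple[float, ...] = (0.25, 0.33, 0.50, 1.00)
    trials_per_condition: int = 25
    n_blank_trials: Optional[int] = None  # default: trials_per_condition
    respiration_period_mean: float = 0.30  # s
    respiration_period_sd: float = 0.02  # s
    respiration_noise_sd: float = 0.01  # fraction of unit signal amplitude
    sample_rate: float = 1000.0  # Hz
    odor_duration: float = 1.0  # s
    inter_trial_interval: float = 4.0  # s
    baseline_rate: float = 3.0  # spikes/s
    response_prob: float = 0.15  # per unit-odor; ~51% of units respond to >=2 of 11 odors
    amplitude_mean: float = 20.0  # spikes/s at reference concentration
    amplitude_sd: float = 8.0  # spikes/s (gamma-distributed amplitudes)
    response_width: float = 0.020  # s, Gaussian bump sd
    latency_sd: float = 0.012  # s, across-cell scatter at reference concentration
    latency_sd_shift_per_doubling: float = -0.005  # s per doubling
    reference_concentration: Optional[float] = None  # default: max(concentrations)

    @model_validator(mode="before")
    @classmethod
    def _fill_classes(cls, data):
        if isinstance(data, dict) and data.get("classes") is None:
            data = dict(data)
            data["classes"] = _default_classes()
        return data

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if self.n_odors < 1:
            raise ValueError("n_odors must be >= 1")
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size < 1 or np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be positive and strictly increasing")
        if self.trials_per_condition < 2:
            raise ValueError("trials_per_condition must be >= 2")
        if self.respiration_period_mean <= 0:
            raise ValueError("respiration period must be > 0")
        if self.sample_rate < 100:
            raise ValueError("sample_rate must be >= 100 Hz")
        for name in ("baseline_rate", "amplitude_mean", "amplitude_sd",
                     "respiration_period_sd", "respiration_noise_sd",
                     "latency_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.response_prob <= 1:
            raise ValueError("response_prob must be in [0, 1]")
        if self.response_width <= 0:
            raise ValueError("response_width must be > 0")
        if self.odor_duration <= 0:
            raise ValueError("odor_duration must be > 0")
        if sum(p.n_units for p in self.classes.values()) < 1:
            raise ValueError("at least one unit required")
        return self

    @property
    def c_ref(self) -> float:
        return (self.reference_concentration
                if self.reference_concentration is not None
                else max(self.concentrations))

    @property
    def odor_ids(self) -> list[str]:
        return [f"odor{i + 1:02d}" for i in range(self.n_odors)]


class BehaviorConfig(BaseModel):
    """Parameters of a simulated 2AFC session.

    Stimulus delivery lasts 1 s and the subject may report within 2 s of
    odor onset.  ``accuracy`` / ``led_accuracy`` are the programmed
    probabilities of a correct choice without / with optogenetic silencing
    (LED); ``decision_latency`` is the earliest first-lick time relative to
    the first odor inhalation, jittered by a half-normal tail.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_trials: int = 300
    accuracy: float = 0.80
    led_accuracy: float = 0.50
    led_fraction: float = 0.25
    decision_latency: float = 0.200  # s
    lick_jitter_sd: float = 0.025  # s
    lick_prob: float = 1.0  # probability the subject responds at all
    response_window: float = 2.0  # s

    @model_validator(mode="after")
    def _check(self) -> "BehaviorConfig":
        for name in ("accuracy", "led_accuracy", "led_fraction", "lick_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.decision_latency < 0 or self.lick_jitter_sd < 0:
            raise ValueError("latency parameters must be >= 0")
        return self


# ---------------------------------------------------------------------------
# respiration

def _draw_cycles(config: GeneratorConfig, rng: np.random.Generator,
                 duration: float) -> np.ndarray:
    """Cycle period draws covering ``duration`` seconds; clipped positive."""
    n = int(math.ceil(duration / max(config.respiration_period_mean
                                     - 4 * config.respiration_period_sd, 1e-3))) + 2
    periods = rng.normal(config.respiration_period_mean,
                         config.respiration_period_sd, size=n)
    periods = np.clip(periods, 0.2 * config.respiration_period_mean, None)
    while periods.sum() < duration:
        extra = rng.normal(config.respiration_period_mean,
                           config.respiration_period_sd, size=n)
        periods = np.concatenate([periods, np.clip(
            extra, 0.2 * config.respiration_period_mean, None)])
    return periods


def simulate_respiration(config: GeneratorConfig, seed: int,
                         duration: float = 10.0) -> RespirationTrace:
    """Quasi-periodic pressure signal with known inhalation onsets.

    Each cycle has a period drawn around ``respiration_period_mean``; the
    pressure is ``-sin(2*pi*phase)`` so inhalation (downward deflection)
    occupies the first half-cycle and exhalation (upward) the second.
    Cycle starts are descending zero-crossings and are returned as the true
    inhalation-onset times.
    """
    rng = np.random.default_rng(seed)
    periods = _draw_cycles(config, rng, duration)
    starts = np.concatenate([[0.0], np.cumsum(periods)])
    fs = config.sample_rate
    t = np.arange(int(round(duration * fs))) / fs
    idx = np.searchsorted(starts, t, side="right") - 1
    phase = (t - starts[idx]) / periods[idx]
    pressure = -np.sin(2 * np.pi * phase)
    if config.respiration_noise_sd > 0:
        pressure = pressure + rng.normal(0.0, config.respiration_noise_sd,
                                         size=pressure.shape)
    onsets = starts[(starts >= 0) & (starts < duration)]
    return RespirationTrace(times=t, pressure=pressure, fs=fs,
                            true_onsets=onsets)


# ---------------------------------------------------------------------------
# ground truth

def _draw_ground_truth(config: GeneratorConfig,
                       rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw per unit-odor responsiveness, amplitudes and per-concentration
    latencies.  Returns (units, responses, latencies) tables."""
    unit_rows = []
    uid = 0
    for cls_name, params in config.classes.items():
        for _ in range(params.n_units):
            unit_rows.append((f"u{uid:04d}", cls_name))
            uid += 1
    units = pd.DataFrame(unit_rows, columns=["unit_id", "class_label"])

    conc = np.asarray(config.concentrations, dtype=float)
    doublings = np.log2(conc / config.c_ref)

    resp_rows, lat_rows = [], []
    for _, (unit_id, cls_name) in units.iterrows():
        params = config.classes[cls_name]
        p = (params.response_prob if params.response_prob is not None
             else config.response_prob)
        for odor in config.odor_ids:
            responsive = bool(rng.random() < p)
            if responsive and config.amplitude_mean > 0:
                if config.amplitude_sd > 0:
                    shape = (config.amplitude_mean / config.amplitude_sd) ** 2
                    scale = config.amplitude_sd ** 2 / config.amplitude_mean
                    amp = float(rng.gamma(shape, scale))
                else:
                    amp = config.amplitude_mean
            else:
                amp = 0.0
            responsive = responsive and amp > 0
            z = float(rng.standard_normal())
            resp_rows.append((unit_id, cls_name, odor, responsive, amp))
            if responsive:
                sd_c = np.clip(config.latency_sd
                               + config.latency_sd_shift_per_doubling * doublings,
                               0.0, None)
                lat = np.clip(params.latency_mean
                              + params.latency_shift_per_doubling * doublings
                              + z * sd_c, 0.0, None)
                gain = np.clip(1.0 + params.rate_gain_per_doubling * doublings,
                               0.0, None)
                for c, l, g in zip(conc, lat, gain):
                    lat_rows.append((unit_id, odor, c, float(l), amp * float(g)))
    responses = pd.DataFrame(
        resp_rows, columns=["unit_id", "class_label", "odor_id", "responsive",
                            "amplitude"])
    latencies = pd.DataFrame(
        lat_rows, columns=["unit_id", "odor_id", "concentration", "latency_s",
                           "amplitude_s"])
    return units, responses, latencies


# ---------------------------------------------------------------------------
# full session

def simulate_session(config: GeneratorConfig, seed: int):
    """Simulate one recording session.

    Returns ``(trace, trials, spikes, ground_truth)`` where ``trials`` and
    ``spikes`` are tidy tables (spikes sorted by time) and
    ``ground_truth`` records every latent draw for parameter-recovery
    tests.

    Spike trains are exact inhomogeneous Poisson samples obtained by
    superposition: a homogeneous baseline process at ``baseline_rate``
    plus, for responsive unit-odor pairs, an independent bump process
    whose event count is Poisson with mean ``amplitude * width *
    sqrt(2*pi)`` and whose event times are Gaussian around the programmed
    latency (events falling outside the simulated trial window are
    dropped, which is exactly the window-truncated process).
    """
    if config.trials_per_condition < 1:
        raise ValueError("zero trials requested")
    n_units_total = sum(p.n_units for p in config.classes.values())
    if n_units_total < 1:
        raise ValueError("zero units requested")

    ss = np.random.SeedSequence(seed)
    rng_resp, rng_truth, rng_sched, rng_spk = (
        np.random.default_rng(s) for s in ss.spawn(4))

    n_blank = (config.n_blank_trials if config.n_blank_trials is not None
               else config.trials_per_condition)
    conditions = [(o, c) for o in config.odor_ids for c in config.concentrations]
    trial_defs = [(o, c) for (o, c) in conditions
                  for _ in range(config.trials_per_condition)]
    trial_defs += [(BLANK, 0.0)] * n_blank
    order = rng_sched.permutation(len(trial_defs))
    trial_defs = [trial_defs[i] for i in order]
    n_trials = len(trial_defs)

    duration = n_trials * config.inter_trial_interval + 2.0
    trace = simulate_respiration(
        config, seed=int(rng_resp.integers(2 ** 31)), duration=duration)
    onsets = trace.true_onsets
    periods = np.diff(np.append(onsets, duration))
    exh_mid = onsets + 0.75 * periods  # odor valve opens mid-exhalation

    nominal = 1.0 + np.arange(n_trials) * config.inter_trial_interval
    oi = np.searchsorted(exh_mid, nominal, side="left")
    oi = np.clip(oi, 0, len(exh_mid) - 1)
    odor_on = exh_mid[oi]
    ti = np.searchsorted(onsets, odor_on, side="left")
    t0_true = np.where(ti < len(onsets), onsets[np.clip(ti, 0, len(onsets) - 1)],
                       np.nan)

    trials = pd.DataFrame({
        "trial_id": np.arange(n_trials),
        "odor_id": [d[0] for d in trial_defs],
        "concentration": [d[1] for d in trial_defs],
        "odor_on_s": odor_on,
        "led": False,
    })

    units, responses, latencies = _draw_ground_truth(config, rng_truth)
    unit_ids = units["unit_id"].to_numpy()
    n_units = len(unit_ids)

    # simulation window around each trial
    w_lo, w_hi = -0.5, config.odor_duration + 0.5
    T = w_hi - w_lo

    # baseline: homogeneous Poisson for every unit on every trial
    counts = rng_spk.poisson(config.baseline_rate * T, size=(n_units, n_trials))
    total = int(counts.sum())
    base_times = rng_spk.uniform(w_lo, w_hi, size=total)
    flat = counts.ravel()
    pair_idx = np.repeat(np.arange(n_units * n_trials), flat)
    base_unit = pair_idx // n_trials
    base_trial = pair_idx % n_trials
    base_abs = base_times + odor_on[base_trial]

    # bump component for responsive unit-odor pairs
    lat_idx = latencies.set_index(["unit_id", "odor_id", "concentration"])
    uix = {u: i for i, u in enumerate(unit_ids)}
    bump_unit_l, bump_trial_l, bump_time_l = [], [], []
    w = config.response_width
    area_factor = w * math.sqrt(2 * math.pi)
    if len(latencies):
        lat_tab = latencies.copy()
        lat_tab["uix"] = lat_tab["unit_id"].map(uix)
        grouped = {k: g for k, g in lat_tab.groupby(["odor_id", "concentration"])}
        for tr in range(n_trials):
            key = (trials["odor_id"].iat[tr], trials["concentration"].iat[tr])
            g = grouped.get(key)
            if g is None or np.isnan(t0_true[tr]):
                continue
            mean_counts = g["amplitude_s"].to_numpy() * area_factor
            n_ev = rng_spk.poisson(mean_counts)
            tot = int(n_ev.sum())
            if tot == 0:
                continue
            mu = np.repeat(g["latency_s"].to_numpy(), n_ev)
            uu = np.repeat(g["uix"].to_numpy(), n_ev)
            tt = t0_true[tr] + mu + rng_spk.normal(0.0, w, size=tot)
            keep = (tt >= odor_on[tr] + w_lo) & (tt < odor_on[tr] + w_hi)
            bump_unit_l.append(uu[keep])
            bump_trial_l.append(np.full(int(keep.sum()), tr))
            bump_time_l.append(tt[keep])

    if bump_unit_l:
        all_unit = np.concatenate([base_unit] + bump_unit_l)
        all_time = np.concatenate([base_abs] + bump_time_l)
    else:
        all_unit, all_time = base_unit, base_abs
    order = np.lexsort((all_unit, all_time))
    spikes = pd.DataFrame({
        "unit_id": unit_ids[all_unit[order]],
        "spike_time_s": all_time[order],
    })

    gt_trials = trials.copy()
    gt_trials["t0_true_s"] = t0_true
    ground_truth = GroundTruth(units=units, responses=responses,
                               latencies=latencies, trials=gt_trials)
    return trace, trials, spikes, ground_truth


# ---------------------------------------------------------------------------
# behavior

def simulate_behavior(config: BehaviorConfig, seed: int,
                      session_id: str = "s00") -> BehaviorSession:
    """Simulate one 2AFC session with programmed accuracy per LED state."""
    rng = np.random.default_rng(seed)
    n = config.n_trials
    stim = np.where(rng.random(n) < 0.5, "A", "B")
    led = rng.random(n) < config.led_fraction
    acc = np.where(led, config.led_accuracy, config.accuracy)
    correct = rng.random(n) < acc
    side = np.where(correct, stim, np.where(stim == "A", "B", "A"))
    responded = rng.random(n) < config.lick_prob
    lick = config.decision_latency + np.abs(
        rng.normal(0.0, config.lick_jitter_sd, size=n))
    responded &= lick <= config.response_window
    df = pd.DataFrame({
        "trial_id": np.arange(n),
        "stim": stim,
        "led": led,
        "lick_time_s": np.where(responded, lick, np.nan),
        "side": np.where(responded, side, None),
        "correct": np.where(responded, correct, None),
    })
    return BehaviorSession(trials=df, session_id=session_id)


# ---------------------------------------------------------------------------
# phototagging block

def simulate_phototag_block(n_pulses: int, n_tagged: int, n_untagged: int,
                            seed: int, latency_ms: float = 2.0,
                            jitter_ms: float = 0.3,
                            tagged_prob: float = 0.9,
                            baseline_rate: float = 5.0,
                            pulse_interval: float = 0.25):
    """Light-pulse train plus spikes of tagged and untagged units.

    Tagged units emit a low-jitter spike ``latency_ms`` after each pulse
    with probability ``tagged_prob`` on top of baseline firing; untagged
    units fire pulse-independent Poisson baseline only.  Returns
    ``(pulse_times, spikes, tagged_flags)``.
    """
    rng = np.random.default_rng(seed)
    pulses = 1.0 + np.arange(n_pulses) * pulse_interval
    duration = pulses[-1] + 1.0
    rows = []
    flags = {}
    for i in range(n_tagged + n_untagged):
        uid = f"u{i:03d}"
        tagged = i < n_tagged
        flags[uid] = tagged
        n_base = rng.poisson(baseline_rate * duration)
        times = list(rng.uniform(0, duration, size=n_base))
        if tagged:
            hit = rng.random(n_pulses) < tagged_prob
            lat = rng.normal(latency_ms, jitter_ms, size=n_pulses) / 1000.0
            times.extend((pulses + lat)[hit])
        for t in sorted(times):
            rows.append((uid, t))
    spikes = pd.DataFrame(rows, columns=["unit_id", "spike_time_s"])
    spikes = spikes.sort_values(["spike_time_s", "unit_id"],
                                ignore_index=True)
    return pulses, spikes, flags
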