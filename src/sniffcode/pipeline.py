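"""Configuration, file formats and end-to-end orchestration.

One global integer seed determines every stochastic stage.  All events and
results are tidy CSV (times in seconds, t = 0 at the first odor
inhalation, half-open windows); each output file carries the hash of the
config that produced it as a leading ``# config_hash=`` comment line, and
a ``manifest.json`` records config, seed and library versions.  The run
log (``log.txt``) carries wall-clock stage timings and is the only output
excluded from the byte-identity determinism contract.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import behavior as beh
from . import decoding as dec
from . import geometry as geo
from . import metrics as met
from . import respiration as resp
from . import temporal as tem
from .synth import (BehaviorConfig, GeneratorConfig, simulate_behavior,
                    simulate_session)
from .types import AlignedRaster, BehaviorSession, RespirationTrace

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "DecodeConfig",
    "RunConfig",
    "write_events",
    "read_events",
    "run_pipeline",
]


class AnalysisConfig(BaseModel):
    """Windows and test parameters for the single-unit analysis stages."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    raster_window: tuple[float, float] = (-0.10, 0.30)
    early_window: tuple[float, float] = (0.050, 0.100)
    late_window: tuple[float, float] = (0.200, 0.300)
    peak_search_window: tuple[float, float] = (0.0, 0.300)
    sigma: float = 0.010
    sdf_step: float = 0.001
    alpha: float = 0.05
    smoothing_ms: float = 5.0
    pca_components: int = 3
    pca_step: float = 0.001


class DecodeConfig(BaseModel):
    """Linear-decoder settings (fixed-window by default)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    window: tuple[float, float] = (0.050, 0.100)
    tensor_step: float = 0.005
    n_repeats: int = 20
    test_size: float = 0.2


class RunConfig(BaseModel):
    """Fully serialized run description; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    seed: int = 0
    out: str = "results"
    verbose: bool = False
    generator: GeneratorConfig = GeneratorConfig()
    behavior: BehaviorConfig = BehaviorConfig()
    behavior_sessions: int = 6
    analysis: AnalysisConfig = AnalysisConfig()
    decode: DecodeConfig = DecodeConfig()

    def config_hash(self) -> str:
        # hash covers the scientific parameters, not where results land
        dump = self.model_dump(mode="json", exclude={"out", "verbose"})
        blob = json.dumps(dump, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# events IO

def write_events(path, table: pd.DataFrame, config_hash: str | None = None) -> Path:
    """Write a tidy event/result table as CSV with an optional hash header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        table.to_csv(fh, index=False)
    return path


def read_events(path, required: list[str] | None = None,
                time_column: str | None = None,
                sort: bool = False) -> pd.DataFrame:
    """Read a CSV event table, validating schema and time ordering.

    Malformed rows raise with the offending line; with a ``time_column``,
    out-of-order times either raise or are sorted per the ``sort`` flag.
    """
    df = pd.read_csv(path, comment="#")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
    if time_column is not None and len(df):
        t = df[time_column].to_numpy()
        if np.any(np.diff(t) < 0):
            if sort:
                df = df.sort_values(time_column, kind="stable",
                                    ignore_index=True)
            else:
                raise ValueError(f"{path}: {time_column} not sorted")
    return df


# ---------------------------------------------------------------------------
# stages (file-based so CLI subcommands and run_pipeline share one path)

def _load_raster(cfg: RunConfig, out: Path) -> AlignedRaster:
    spikes = read_events(out / "aligned_spikes.csv",
                         required=["unit_id", "trial_id", "rel_time_s"])
    trials = read_events(out / "aligned_trials.csv",
                         required=["trial_id", "odor_id", "concentration",
                                   "t0_s", "valid"])
    units = read_events(out / "units.csv")["unit_id"].to_numpy()
    return AlignedRaster(spikes=spikes, trials=trials,
                         window=cfg.analysis.raster_window, units=units)


def stage_simulate(cfg: RunConfig, out: Path) -> None:
    h = cfg.config_hash()
    trace, trials, spikes, gt = simulate_session(cfg.generator, cfg.seed)
    write_events(out / "respiration.csv",
                 pd.DataFrame({"time_s": trace.times,
                               "pressure": trace.pressure}), h)
    write_events(out / "spikes.csv", spikes, h)
    write_events(out / "trials.csv", trials, h)
    write_events(out / "units.csv", gt.units, h)
    write_events(out / "gt_responses.csv", gt.responses, h)
    write_events(out / "gt_latencies.csv", gt.latencies, h)
    write_events(out / "gt_trials.csv", gt.trials, h)


def stage_events(cfg: RunConfig, out: Path) -> None:
    h = cfg.config_hash()
    rdf = read_events(out / "respiration.csv",
                      required=["time_s", "pressure"], time_column="time_s")
    fs = 1.0 / float(np.median(np.diff(rdf["time_s"].to_numpy()[:1000])))
    trace = RespirationTrace(times=rdf["time_s"].to_numpy(),
                             pressure=rdf["pressure"].to_numpy(), fs=fs)
    trials = read_events(out / "trials.csv",
                         required=["trial_id", "odor_id", "odor_on_s"])
    spikes = read_events(out / "spikes.csv",
                         required=["unit_id", "spike_time_s"],
                         time_column="spike_time_s")
    onsets = resp.detect_inhalation_onsets(trace, cfg.analysis.smoothing_ms)
    aligned = resp.align_trials(trials, onsets,
                                odor_duration=cfg.generator.odor_duration)
    raster = resp.build_raster(spikes, aligned,
                               window=cfg.analysis.raster_window)
    write_events(out / "onsets.csv",
                 pd.DataFrame({"onset_s": onsets}), h)
    write_events(out / "aligned_trials.csv", raster.trials, h)
    write_events(out / "aligned_spikes.csv", raster.spikes, h)


def stage_metrics(cfg: RunConfig, out: Path) -> None:
    h = cfg.config_hash()
    raster = _load_raster(cfg, out)
    ana = cfg.analysis
    rates = met.window_rate(raster, ana.early_window)
    activation = met.activated_units(rates, raster.trials, alpha=ana.alpha)
    write_events(out / "activation.csv", activation, h)
    write_events(out / "sparseness.csv", met.sparseness_table(activation), h)
    hist, per_odor = met.responsive_count_histogram(activation)
    write_events(out / "responsive_hist.csv",
                 pd.DataFrame({"n_odors": np.arange(len(hist)),
                               "n_units": hist}), h)
    write_events(out / "pct_activated_per_odor.csv", per_odor, h)
    act_early = met.activated_units(
        met.window_rate(raster, (0.0, 0.100)), raster.trials, alpha=ana.alpha)
    act_late = met.activated_units(
        met.window_rate(raster, ana.late_window), raster.trials,
        alpha=ana.alpha)
    write_events(out / "early_late.csv",
                 met.early_late_fractions(act_early, act_late), h)


def stage_geometry(cfg: RunConfig, out: Path) -> None:
    h = cfg.config_hash()
    raster = _load_raster(cfg, out)
    ana = cfg.analysis
    tensor = geo.build_response_tensor(raster, step=ana.pca_step,
                                       sigma=ana.sigma)
    traj = geo.pca_trajectories(tensor, k=ana.pca_components)
    rows = []
    for ci, (odor, conc) in enumerate(zip(traj.conditions["odor_id"],
                                          traj.conditions["concentration"])):
        for bi, t in enumerate(traj.grid):
            rows.append((odor, conc, t, *traj.scores[ci, bi]))
    cols = ["odor_id", "concentration", "bin_s"] + \
        [f"pc{k + 1}" for k in range(ana.pca_components)]
    write_events(out / "pca_trajectories.csv",
                 pd.DataFrame(rows, columns=cols), h)
    write_events(out / "pca_variance.csv",
                 pd.DataFrame({"component": np.arange(1, ana.pca_components + 1),
                               "explained_variance_ratio":
                                   traj.explained_variance_ratio}), h)
    dist = geo.euclidean_distance_timecourse(traj)
    write_events(out / "pca_distance.csv",
                 dist[["bin_s", "distance"]], h)


def stage_decode(cfg: RunConfig, out: Path) -> None:
    h = cfg.config_hash()
    raster = _load_raster(cfg, out)
    d = cfg.decode
    tensor = geo.build_response_tensor(raster, step=d.tensor_step)
    rows = []
    specs = [("identity", tensor.conditions["odor_id"].to_numpy()),
             ("intensity", tensor.conditions["concentration"].to_numpy())]
    for label_type, labels in specs:
        if len(np.unique(labels)) < 2:
            logger.info("decode: %s has <2 classes, skipped", label_type)
            continue
        for mode in ("rate", "binary"):
            res = dec.decode_fixed(tensor, labels, d.window,
                                   feature_mode=mode, n_repeats=d.n_repeats,
                                   test_size=d.test_size, seed=cfg.seed,
                                   label_type=label_type)
            rows.append((label_type, mode, d.window[0], d.window[1],
                         res.mean_accuracy, res.sem_accuracy, res.chance,
                         res.n_classes))
    write_events(out / "decoding.csv", pd.DataFrame(rows, columns=[
        "label_type", "feature_mode", "window_lo_s", "window_hi_s",
        "mean_accuracy", "sem_accuracy", "chance", "n_classes"]), h)


def stage_temporal(cfg: RunConfig, out: Path) -> None:
    h = cfg.config_hash()
    raster = _load_raster(cfg, out)
    ana = cfg.analysis
    sdf = met.condition_sdf(raster, sigma=ana.sigma, step=ana.sdf_step)
    activation = read_events(out / "activation.csv")
    blank = sdf.index["odor_id"] == "blank"
    sdf.index, sdf.rate = (sdf.index[~blank].reset_index(drop=True),
                           sdf.rate[~blank.to_numpy()])
    peaks = tem.peak_stats(sdf, search_window=ana.peak_search_window,
                           activation=activation)
    write_events(out / "peaks.csv", peaks, h)

    trend_rows = []
    act_peaks = peaks[peaks["activated"]]
    subset = act_peaks if len(act_peaks) >= 10 else peaks
    subset_name = "activated" if len(act_peaks) >= 10 else "all"
    for var in ("peak_time_s", "peak_rate"):
        try:
            tr = tem.concentration_trend(subset, variable=var)
            trend_rows.append((var, subset_name, tr.rho, tr.p_value, tr.n,
                               tr.undefined))
        except ValueError as e:
            logger.info("temporal: trend for %s not computed (%s)", var, e)
    write_events(out / "trends.csv", pd.DataFrame(trend_rows, columns=[
        "variable", "subset", "rho", "p", "n", "undefined"]), h)

    sync_rows = []
    for conc in sorted(peaks["concentration"].unique()):
        mean, tab = tem.pairwise_peak_time_diff(peaks, conc)
        sync_rows.append((conc, mean, int(tab["n_cells"].sum()) if len(tab) else 0))
    write_events(out / "synchrony.csv", pd.DataFrame(sync_rows, columns=[
        "concentration", "mean_pairwise_diff_s", "n_cells"]), h)


def stage_behavior(cfg: RunConfig, out: Path) -> None:
    h = cfg.config_hash()
    ss = np.random.SeedSequence([cfg.seed, 0x2AFC])
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
             ss.spawn(cfg.behavior_sessions)]
    sessions = [simulate_behavior(cfg.behavior, seed=s, session_id=f"s{i:02d}")
                for i, s in enumerate(seeds)]
    write_events(out / "behavior_sessions.csv",
                 pd.concat([s.trials.assign(session_id=s.session_id)
                            for s in sessions], ignore_index=True), h)
    write_events(out / "behavior_pc.csv",
                 pd.concat([beh.percent_correct(s) for s in sessions],
                           ignore_index=True), h)
    curves = [beh.dprime_timecourse(s) for s in sessions]
    write_events(out / "dprime.csv",
                 pd.concat([pd.DataFrame({"session_id": c.session_id,
                                          "t_s": c.t, "dprime": c.dprime,
                                          "hits": c.hits,
                                          "false_alarms": c.false_alarms})
                            for c in curves], ignore_index=True), h)
    onset = beh.dprime_onset(sessions, seed=cfg.seed) \
        if cfg.behavior_sessions >= 3 else None
    led = beh.led_comparison(sessions) if cfg.behavior.led_fraction > 0 else {}
    summary = {"dprime_onset_s": onset, **led}
    write_events(out / "behavior_summary.csv",
                 pd.DataFrame([summary]), h)


STAGES = [
    ("simulate", stage_simulate),
    ("events", stage_events),
    ("metrics", stage_metrics),
    ("geometry", stage_geometry),
    ("decode", stage_decode),
    ("temporal", stage_temporal),
    ("behavior", stage_behavior),
]


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage in order, writing all outputs plus a manifest.

    A stage failure stops the run and preserves completed outputs.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []
    for name, fn in STAGES:
        t0 = time.perf_counter()
        fn(config, out)
        dt = time.perf_counter() - t0
        log_lines.append(f"stage={name} elapsed_s={dt:.3f}")
        logger.info("stage %s done in %.3f s", name, dt)
    manifest = {
        "config": config.model_dump(mode="json"),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _versions(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return out


def _versions() -> dict:
    import scipy
    import sklearn
    from . import __version__
    return {"sniffcode": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__,
            "sklearn": sklearn.__version__}
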