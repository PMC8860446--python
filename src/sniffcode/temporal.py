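"""Peak-time statistics and spike-timing synchrony across concentrations.

Peak time is the earliest time of the maximum of the trial-averaged SDF in
a search window (default [0, 0.300) s after the first odor inhalation).
Concentration trends use Spearman rank correlation (invariant to the
log/raw concentration scale); synchrony is the mean absolute pairwise
peak-time difference of activated cell-odor pairs, computed within odor
and averaged across odors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import SpikeDensity, TrendResult

__all__ = [
    "peak_stats",
    "concentration_trend",
    "pairwise_peak_time_diff",
    "cross_population_synchrony",
    "latency_shift_regression",
]


def peak_stats(sdf: SpikeDensity,
               search_window: tuple[float, float] = (0.0, 0.300),
               activation: pd.DataFrame | None = None,
               activated_only: bool = False) -> pd.DataFrame:
    """Peak time and rate per cell-odor-concentration group.

    Ties at the SDF maximum resolve to the earliest time.  When an
    activation matrix is supplied its ``activated`` flags are attached;
    with ``activated_only`` rows are restricted to activated pairs.
    """
    lo, hi = search_window
    if lo >= hi:
        raise ValueError("empty search window")
    sel = (sdf.grid >= lo) & (sdf.grid < hi)
    if not sel.any():
        raise ValueError("search window outside SDF grid")
    sub_grid = sdf.grid[sel]
    sub = sdf.rate[:, sel]
    peak_idx = np.argmax(sub, axis=1)  # argmax returns first (earliest) max
    out = sdf.index.copy()
    out["peak_time_s"] = sub_grid[peak_idx]
    out["peak_rate"] = sub[np.arange(len(sub)), peak_idx]
    if activation is not None:
        out = out.merge(
            activation[["unit_id", "odor_id", "concentration", "activated"]],
            on=["unit_id", "odor_id", "concentration"], how="left")
        out["activated"] = out["activated"].fillna(False).astype(bool)
        if activated_only:
            out = out[out["activated"]].reset_index(drop=True)
    return out


def concentration_trend(peaks: pd.DataFrame,
                        variable: str = "peak_time_s") -> TrendResult:
    """Spearman correlation of a peak statistic with concentration.

    Pools all cell-odor pairs; ranks are identical for raw and log
    concentration.  A constant variable gives an undefined (flagged)
    result rather than rho = 0.
    """
    conc = peaks["concentration"].to_numpy(dtype=float)
    var = peaks[variable].to_numpy(dtype=float)
    n = len(var)
    if np.unique(conc).size < 2:
        raise ValueError("need at least 2 concentrations")
    if n < 10:
        raise ValueError("need at least 10 cell-odor pairs")
    if np.all(var == var[0]):
        return TrendResult(rho=float("nan"), p_value=float("nan"), n=n,
                           undefined=True)
    rho, p = stats.spearmanr(conc, var)
    return TrendResult(rho=float(rho), p_value=float(p), n=n)


def _mean_abs_pairwise(x: np.ndarray) -> float:
    """Mean |xi - xj| over unordered pairs; O(n log n) via sorting."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 2:
        return float("nan")
    i = np.arange(n)
    total = np.sum((2 * i - n + 1) * x)
    return float(total / (n * (n - 1) / 2))


def pairwise_peak_time_diff(peaks: pd.DataFrame, concentration: float,
                            activated_only: bool = True,
                            pool: str = "within_odor") -> tuple[float, pd.DataFrame]:
    """Mean absolute pairwise peak-time difference at one concentration.

    An inverse synchrony measure: smaller values mean more synchronized
    firing.  ``pool='within_odor'`` (default) averages the per-odor mean
    pairwise |difference| across odors; ``'pooled'`` pools all pairs.
    Returns ``(mean_diff_s, per_odor_table)``; NaN (flagged via empty
    table) when no odor has two responses.
    """
    sel = peaks[peaks["concentration"] == concentration]
    if activated_only and "activated" in sel.columns:
        sel = sel[sel["activated"]]
    if pool == "pooled":
        v = _mean_abs_pairwise(sel["peak_time_s"].to_numpy())
        tab = pd.DataFrame({"odor_id": ["__pooled__"], "mean_diff_s": [v],
                            "n_cells": [len(sel)]})
        return v, tab
    rows = []
    for odor, g in sel.groupby("odor_id"):
        if len(g) >= 2:
            rows.append((odor, _mean_abs_pairwise(g["peak_time_s"].to_numpy()),
                         len(g)))
    tab = pd.DataFrame(rows, columns=["odor_id", "mean_diff_s", "n_cells"])
    mean = float(tab["mean_diff_s"].mean()) if len(tab) else float("nan")
    return mean, tab


def cross_population_synchrony(peaks_a: pd.DataFrame,
                               peaks_b: pd.DataFrame,
                               activated_only: bool = True) -> pd.DataFrame:
    """Between-class mean |peak-time difference| per concentration.

    Pairs take one cell from each class responding to the same odor;
    per-odor means are averaged across odors.  Returns a table
    (concentration, mean_diff_s, n_pairs); concentrations where either
    class is empty are flagged with NaN.
    """
    def prep(df):
        if activated_only and "activated" in df.columns:
            df = df[df["activated"]]
        return df
    a, b = prep(peaks_a), prep(peaks_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both populations must have responses")
    concs = sorted(set(a["concentration"]) | set(b["concentration"]))
    rows = []
    for c in concs:
        ac = a[a["concentration"] == c]
        bc = b[b["concentration"] == c]
        per_odor, n_pairs = [], 0
        for odor in set(ac["odor_id"]) & set(bc["odor_id"]):
            ta = ac.loc[ac["odor_id"] == odor, "peak_time_s"].to_numpy()
            tb = bc.loc[bc["odor_id"] == odor, "peak_time_s"].to_numpy()
            d = np.abs(ta[:, None] - tb[None, :])
            per_odor.append(d.mean())
            n_pairs += d.size
        rows.append((c, float(np.mean(per_odor)) if per_odor else np.nan,
                     n_pairs))
    return pd.DataFrame(rows, columns=["concentration", "mean_diff_s",
                                       "n_pairs"])


def latency_shift_regression(peaks: pd.DataFrame) -> tuple[float, float]:
    """Peak-time shift per concentration doubling (s), with its SE.

    Least-squares regression of peak time on log2(concentration) pooled
    over cell-odor pairs; recovers the generator's programmed
    latency-shift-per-doubling parameter.
    """
    x = np.log2(peaks["concentration"].to_numpy(dtype=float))
    y = peaks["peak_time_s"].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 concentrations")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.stderr)
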