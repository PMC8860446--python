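"""Single-unit response quantification.

Spike-density functions (Gaussian kernel, sigma = 10 ms by default),
windowed firing rates, activated-unit detection against blank trials,
lifetime sparseness, responsive-odor histograms, and the odd/even-trial
cross-validated rank-ordered peak map.

The default early analysis window is [0.050, 0.100) s after the first
odor inhalation, where odor-evoked firing peaks; a late window
[0.200, 0.300) s captures the tail of the sniff cycle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .types import AlignedRaster, SpikeDensity

__all__ = [
    "EARLY_WINDOW",
    "LATE_WINDOW",
    "single_trial_sdf",
    "condition_sdf",
    "window_rate",
    "paired_increase_test",
    "activated_units",
    "lifetime_sparseness",
    "sparseness_table",
    "responsive_count_histogram",
    "rank_order_crossval",
    "early_late_fractions",
]

EARLY_WINDOW = (0.050, 0.100)
LATE_WINDOW = (0.200, 0.300)
CA1_WINDOW = (0.081, 0.131)


def _grid(window: tuple[float, float], step: float) -> np.ndarray:
    """Bin centers of the half-open window at the given step."""
    n = int(round((window[1] - window[0]) / step))
    return window[0] + (np.arange(n) + 0.5) * step


def single_trial_sdf(rel_times: np.ndarray, window: tuple[float, float],
                     sigma: float = 0.010, step: float = 0.001) -> tuple[np.ndarray, np.ndarray]:
    """SDF of one spike train: unit-area Gaussian per spike.

    Returns ``(grid, rate)``.  Spikes are binned at ``step`` and convolved
    with a Gaussian of sd ``sigma``; kernel mass falling outside the
    window is truncated (not renormalized), so the integral over an
    extended grid equals the spike count.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    grid = _grid(window, step)
    edges = np.append(grid - step / 2, grid[-1] + step / 2)
    counts, _ = np.histogram(np.asarray(rel_times, dtype=float), bins=edges)
    rate = gaussian_filter1d(counts / step, sigma / step, mode="constant")
    return grid, rate


def condition_sdf(raster: AlignedRaster, sigma: float = 0.010,
                  step: float = 0.001, split: str | None = None) -> SpikeDensity:
    """Trial-averaged SDF per unit x odor x concentration.

    ``split='odd'`` / ``'even'`` restricts each condition to its 1st,3rd,...
    or 2nd,4th,... trials (by trial order) for cross-validated peak maps.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    w_lo, w_hi = raster.window
    grid = _grid(raster.window, step)
    n_bins = len(grid)

    trials = raster.trials.sort_values("trial_id")
    if split is not None:
        if split not in ("odd", "even"):
            raise ValueError("split must be 'odd', 'even' or None")
        offset = 0 if split == "odd" else 1
        keep = (trials.groupby(["odor_id", "concentration"], sort=False)
                .cumcount() % 2 == offset)
        trials = trials[keep.to_numpy()]

    conds = (trials[["odor_id", "concentration"]].drop_duplicates()
             .sort_values(["odor_id", "concentration"]).reset_index(drop=True))
    cond_key = {(o, c): i for i, (o, c) in
                enumerate(zip(conds["odor_id"], conds["concentration"]))}
    trial_cond = {t: cond_key[(o, c)] for t, o, c in
                  zip(trials["trial_id"], trials["odor_id"],
                      trials["concentration"])}
    n_trials_per_cond = trials.groupby(["odor_id", "concentration"]).size()
    n_per_cond = np.array([n_trials_per_cond[(o, c)] for o, c in
                           zip(conds["odor_id"], conds["concentration"])])

    units = np.asarray(raster.units)
    uix = {u: i for i, u in enumerate(units)}

    counts = np.zeros((len(units), len(conds), n_bins))
    spk = raster.spikes
    if len(spk):
        sel = spk["trial_id"].isin(trial_cond).to_numpy()
        s_unit = spk["unit_id"].to_numpy()[sel]
        s_trial = spk["trial_id"].to_numpy()[sel]
        s_rel = spk["rel_time_s"].to_numpy()[sel]
        ui = np.fromiter((uix[u] for u in s_unit), int, count=len(s_unit))
        ci = np.fromiter((trial_cond[t] for t in s_trial), int,
                         count=len(s_trial))
        bi = np.floor((s_rel - w_lo) / step).astype(int)
        bi = np.clip(bi, 0, n_bins - 1)
        np.add.at(counts, (ui, ci, bi), 1.0)

    rate = counts / (n_per_cond[None, :, None] * step)
    rate = gaussian_filter1d(rate, sigma / step, axis=-1, mode="constant")

    index = pd.DataFrame({
        "unit_id": np.repeat(units, len(conds)),
        "odor_id": np.tile(conds["odor_id"].to_numpy(), len(units)),
        "concentration": np.tile(conds["concentration"].to_numpy(), len(units)),
    })
    return SpikeDensity(grid=grid, rate=rate.reshape(-1, n_bins), index=index,
                        sigma=sigma, step=step)


def window_rate(raster: AlignedRaster,
                window: tuple[float, float]) -> pd.DataFrame:
    """Per-trial mean firing rate (spikes/s) in a half-open window.

    Returns a tidy table (unit_id, trial_id, rate) covering every unit x
    valid trial, zeros included.
    """
    a, b = window
    if not b > a:
        raise ValueError("zero-length window")
    if a < raster.window[0] or b > raster.window[1]:
        raise ValueError("window must lie within the raster window")
    spk = raster.spikes
    sel = spk[(spk["rel_time_s"] >= a) & (spk["rel_time_s"] < b)]
    counts = sel.groupby(["unit_id", "trial_id"]).size()
    full = pd.MultiIndex.from_product(
        [np.asarray(raster.units), raster.trials["trial_id"].to_numpy()],
        names=["unit_id", "trial_id"])
    rate = counts.reindex(full, fill_value=0).astype(float) / (b - a)
    return rate.rename("rate").reset_index()


def paired_increase_test(odor_rates: np.ndarray,
                         blank_rates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sided paired t-test for rate increases, vectorized over rows.

    ``odor_rates`` and ``blank_rates`` are (n, n_trials) arrays paired by
    trial order.  Returns ``(delta, p)`` where delta is the mean rate
    change and p the one-sided (increase) p-value.  Zero-variance
    differences give p = 0 for a positive shift and p = 1 otherwise.
    """
    d = np.asarray(odor_rates, float) - np.asarray(blank_rates, float)
    n = d.shape[1]
    if n < 3:
        raise ValueError("need >= 3 paired trials")
    m = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    p = np.empty_like(m)
    zero = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    p[~zero] = stats.t.sf(t[~zero], df=n - 1)
    p[zero] = np.where(m[zero] > 0, 0.0, 1.0)
    return m, p


def activated_units(rates: pd.DataFrame, trials: pd.DataFrame,
                    alpha: float = 0.05,
                    blank_label: str = "blank") -> pd.DataFrame:
    """Activation matrix: odor vs blank paired t-test per unit-condition.

    ``rates`` is the per-trial table from :func:`window_rate`; trials are
    paired with blank trials by presentation order.  A unit-condition is
    activated iff its mean rate increased and p < alpha (one-sided).
    Conditions with fewer than 3 pairable trials are flagged invalid.
    """
    merged = rates.merge(trials[["trial_id", "odor_id", "concentration"]],
                         on="trial_id")
    mat = merged.pivot_table(index="unit_id", columns="trial_id",
                             values="rate", fill_value=0.0)
    units = mat.index.to_numpy()
    tinfo = trials.set_index("trial_id")

    blank_ids = [t for t in mat.columns if tinfo.loc[t, "odor_id"] == blank_label]
    if not blank_ids:
        raise ValueError("no blank trials to pair against")
    blank = mat[sorted(blank_ids)].to_numpy()

    rows = []
    conds = (trials.loc[trials["odor_id"] != blank_label,
                        ["odor_id", "concentration"]]
             .drop_duplicates().sort_values(["odor_id", "concentration"]))
    for odor, conc in conds.itertuples(index=False):
        ids = sorted(t for t in mat.columns
                     if tinfo.loc[t, "odor_id"] == odor
                     and tinfo.loc[t, "concentration"] == conc)
        n = min(len(ids), blank.shape[1])
        if n < 3:
            for u in units:
                rows.append((u, odor, conc, np.nan, np.nan, False, False))
            continue
        od = mat[ids[:n]].to_numpy()
        delta, p = paired_increase_test(od, blank[:, :n])
        act = (delta > 0) & (p < alpha)
        for i, u in enumerate(units):
            rows.append((u, odor, conc, float(p[i]), float(delta[i]),
                         bool(act[i]), True))
    return pd.DataFrame(rows, columns=[
        "unit_id", "odor_id", "concentration", "p", "delta_rate",
        "activated", "test_valid"])


def lifetime_sparseness(r, n_odors: int | None = None) -> float:
    """Lifetime sparseness of a response vector.

    S = (1 - (sum(r)/N)^2 / (sum(r^2)/N)) / (1 - 1/N) with negative
    responses clipped to zero first.  1 = completely selective (responds
    to a single odor), 0 = nonselective (uniform).  Returns NaN when all
    clipped responses are zero (undefined).
    """
    r = np.clip(np.asarray(r, dtype=float), 0.0, None)
    n = len(r) if n_odors is None else n_odors
    if n < 2:
        raise ValueError("need responses to at least 2 odors")
    if len(r) != n:
        raise ValueError("response vector length must equal n_odors")
    ss = np.sum(r * r)
    if ss == 0:
        return float("nan")
    return float((1.0 - (r.sum() / n) ** 2 / (ss / n)) / (1.0 - 1.0 / n))


def sparseness_table(activation: pd.DataFrame) -> pd.DataFrame:
    """Per-unit (and per-concentration) lifetime sparseness from the mean
    firing-rate changes across odors of the activation matrix."""
    rows = []
    for (u, c), g in activation.groupby(["unit_id", "concentration"]):
        r = g["delta_rate"].to_numpy(dtype=float)
        if len(r) < 2 or np.any(~np.isfinite(r)):
            s = np.nan
        else:
            s = lifetime_sparseness(r)
        rows.append((u, c, s, len(r)))
    return pd.DataFrame(rows, columns=["unit_id", "concentration",
                                       "sparseness", "n_odors"])


def responsive_count_histogram(activation: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Units activated by 0..N odors, and percent activated per odor.

    Returns ``(hist, per_odor)`` where ``hist[k]`` counts units activated
    by exactly k odors (summing to the unit count) and ``per_odor`` gives
    the percentage of units activated for each odor.
    """
    n_odors = activation["odor_id"].nunique()
    per_unit = activation.groupby("unit_id")["activated"].sum().astype(int)
    hist = np.bincount(per_unit.to_numpy(), minlength=n_odors + 1)
    per_odor = (activation.groupby("odor_id")["activated"].mean() * 100.0)
    per_odor = per_odor.rename("pct_activated").reset_index()
    return hist, per_odor


def rank_order_crossval(raster: AlignedRaster, sigma: float = 0.010,
                        step: float = 0.001,
                        search_window: tuple[float, float] = (0.0, 0.300),
                        min_trials: int = 2) -> dict:
    """Cross-validated rank-ordered peak map.

    Peak times are computed on odd trials' SDFs; rows (cell-odor pairs)
    are sorted by that peak, and the plotted matrix comes from even
    trials, row-normalized to its maximum.  Pairs whose condition has
    fewer than ``min_trials`` trials are excluded.

    Returns dict with ``pairs`` (sorted index), ``peak_time_odd``,
    ``peak_time_even``, ``matrix`` (even-trial rows in sorted order) and
    ``grid``.
    """
    n_per = raster.trials.groupby(["odor_id", "concentration"]).size()
    ok_conds = set(n_per[n_per >= min_trials].index)

    odd = condition_sdf(raster, sigma=sigma, step=step, split="odd")
    even = condition_sdf(raster, sigma=sigma, step=step, split="even")
    # align rows (both use the same unit x condition enumeration)
    if not odd.index.equals(even.index):
        merged = odd.index.reset_index().merge(
            even.index.reset_index(), on=["unit_id", "odor_id", "concentration"],
            suffixes=("_o", "_e"))
        oi, ei = merged["index_o"].to_numpy(), merged["index_e"].to_numpy()
        idx = odd.index.iloc[oi].reset_index(drop=True)
        odd_rate, even_rate = odd.rate[oi], even.rate[ei]
    else:
        idx, odd_rate, even_rate = odd.index, odd.rate, even.rate

    keep = np.array([(o, c) in ok_conds for o, c in
                     zip(idx["odor_id"], idx["concentration"])])
    idx = idx[keep].reset_index(drop=True)
    odd_rate, even_rate = odd_rate[keep], even_rate[keep]

    lo, hi = search_window
    sel = (odd.grid >= lo) & (odd.grid < hi)
    if not sel.any():
        raise ValueError("search window outside SDF grid")
    sub = odd.grid[sel]
    peak_odd = sub[np.argmax(odd_rate[:, sel], axis=1)]
    peak_even = sub[np.argmax(even_rate[:, sel], axis=1)]

    order = np.argsort(peak_odd, kind="stable")
    mat = even_rate[order]
    mx = mat.max(axis=1, keepdims=True)
    mat = np.divide(mat, mx, out=np.zeros_like(mat), where=mx > 0)
    return {
        "pairs": idx.iloc[order].reset_index(drop=True),
        "peak_time_odd": peak_odd[order],
        "peak_time_even": peak_even[order],
        "matrix": mat,
        "grid": odd.grid,
    }


def early_late_fractions(activation_early: pd.DataFrame,
                         activation_late: pd.DataFrame) -> pd.DataFrame:
    """Percent activated cells per odor in early vs late sniff phases."""
    _, early = responsive_count_histogram(activation_early)
    _, late = responsive_count_histogram(activation_late)
    out = early.rename(columns={"pct_activated": "early_pct"}).merge(
        late.rename(columns={"pct_activated": "late_pct"}), on="odor_id")
    return out
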