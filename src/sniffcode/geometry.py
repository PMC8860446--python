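"""Pseudopopulation assembly, PCA trajectories, and distance time courses.

Units recorded in separate sessions are pooled into one pseudopopulation
by matching trials within each condition (seed-controlled random pairing).
PCA is fitted over the unit dimension with per-unit mean centering and no
variance scaling, preserving rate-magnitude information; discriminability
is summarized as the mean pairwise Euclidean distance between condition
trajectories in the first K (default 3) components, per 1-ms bin.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.decomposition import PCA

from .types import AlignedRaster, PCATrajectory, ResponseTensor

logger = logging.getLogger(__name__)

__all__ = [
    "build_response_tensor",
    "build_pseudopopulation",
    "pca_trajectories",
    "euclidean_distance_timecourse",
]


def build_response_tensor(raster: AlignedRaster, step: float = 0.005,
                          sigma: float | None = None,
                          include_blank: bool = False,
                          blank_label: str = "blank") -> ResponseTensor:
    """Bin an aligned raster into units x condition x trial x bin rates.

    Trial counts are equalized across conditions by truncating to the
    minimum count (in presentation order).  ``sigma`` optionally smooths
    rates along time with a Gaussian kernel (for trajectory analyses).
    """
    trials = raster.trials.sort_values("trial_id")
    if not include_blank:
        trials = trials[trials["odor_id"] != blank_label]
    if trials.empty:
        raise ValueError("no trials for tensor")
    w_lo, w_hi = raster.window
    n_bins = int(round((w_hi - w_lo) / step))
    grid = w_lo + (np.arange(n_bins) + 0.5) * step

    conds = (trials[["odor_id", "concentration"]].drop_duplicates()
             .sort_values(["odor_id", "concentration"]).reset_index(drop=True))
    per_cond = [g["trial_id"].to_numpy() for _, g in
                trials.groupby(["odor_id", "concentration"], sort=True)]
    n_rep = min(len(ids) for ids in per_cond)
    trial_slot = {}
    for ci, ids in enumerate(per_cond):
        for ri, t in enumerate(ids[:n_rep]):
            trial_slot[t] = (ci, ri)

    units = np.asarray(raster.units)
    uix = {u: i for i, u in enumerate(units)}
    data = np.zeros((len(units), len(conds), n_rep, n_bins))
    spk = raster.spikes
    if len(spk):
        sel = spk["trial_id"].isin(trial_slot).to_numpy()
        s_unit = spk["unit_id"].to_numpy()[sel]
        s_trial = spk["trial_id"].to_numpy()[sel]
        s_rel = spk["rel_time_s"].to_numpy()[sel]
        ui = np.fromiter((uix[u] for u in s_unit), int, count=len(s_unit))
        slots = [trial_slot[t] for t in s_trial]
        ci = np.fromiter((s[0] for s in slots), int, count=len(slots))
        ri = np.fromiter((s[1] for s in slots), int, count=len(slots))
        bi = np.clip(np.floor((s_rel - w_lo) / step).astype(int), 0, n_bins - 1)
        np.add.at(data, (ui, ci, ri, bi), 1.0)
    data /= step
    if sigma is not None and sigma > 0:
        data = gaussian_filter1d(data, sigma / step, axis=-1, mode="constant")
    return ResponseTensor(data=data, units=units, conditions=conds, grid=grid)


def build_pseudopopulation(tensors: list[ResponseTensor],
                           seed: int = 0) -> ResponseTensor:
    """Pool units across recordings into one pseudopopulation tensor.

    Conditions of the first recording define the reference; recordings
    missing any reference condition are excluded (logged).  Within each
    condition, trials are matched across recordings by seeded random
    pairing; the pooled trial count is the minimum across recordings.
    """
    if not tensors:
        raise ValueError("no recordings")
    rng = np.random.default_rng(seed)
    ref = tensors[0].conditions
    ref_keys = list(zip(ref["odor_id"], ref["concentration"]))

    usable: list[tuple[int, ResponseTensor, np.ndarray]] = []
    for k, t in enumerate(tensors):
        keys = {(o, c): i for i, (o, c) in
                enumerate(zip(t.conditions["odor_id"],
                              t.conditions["concentration"]))}
        if not all(key in keys for key in ref_keys):
            logger.info("pseudopopulation: recording %d missing conditions, "
                        "excluded", k)
            continue
        order = np.array([keys[key] for key in ref_keys])
        usable.append((k, t, t.data[:, order]))
    if not usable:
        raise ValueError("no recording covers the reference conditions")

    n_rep = min(d.shape[2] for _, _, d in usable)
    n_bins = usable[0][2].shape[3]
    if any(d.shape[3] != n_bins for _, _, d in usable):
        raise ValueError("recordings must share the time grid")

    blocks, unit_blocks = [], []
    for k, t, d in usable:
        if len(usable) == 1:
            out = d[:, :, :n_rep]  # single recording: pairing is identity
        else:
            out = np.empty((d.shape[0], len(ref_keys), n_rep, n_bins))
            for ci in range(len(ref_keys)):
                perm = rng.permutation(d.shape[2])[:n_rep]
                out[:, ci] = d[:, ci, perm]
        blocks.append(out)
        prefix = "" if len(usable) == 1 else f"r{k}:"
        unit_blocks.append(np.array([f"{prefix}{u}" for u in t.units]))
    data = np.concatenate(blocks, axis=0)
    units = np.concatenate(unit_blocks)
    return ResponseTensor(data=data, units=units,
                          conditions=ref.reset_index(drop=True),
                          grid=usable[0][1].grid)


def pca_trajectories(tensor: ResponseTensor, k: int = 3,
                     mode: str = "trial_mean") -> PCATrajectory:
    """Fit PCA over units and project per-condition mean trajectories.

    ``mode='trial_mean'`` fits on condition-averaged time-bin vectors
    (one observation per condition x bin); ``'per_trial'`` fits on
    single-trial vectors.  Observations are centered per unit (the PCA
    mean); no variance scaling is applied.
    """
    n_units = tensor.data.shape[0]
    if n_units < k:
        raise ValueError(f"need at least {k} units for {k} components")
    cond_mean = tensor.data.mean(axis=2)  # units x cond x bins
    if mode == "trial_mean":
        X = cond_mean.reshape(n_units, -1).T
    elif mode == "per_trial":
        X = tensor.data.reshape(n_units, -1).T
    else:
        raise ValueError("mode must be 'trial_mean' or 'per_trial'")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(X)
    scores = pca.transform(cond_mean.reshape(n_units, -1).T)
    n_cond, n_bins = cond_mean.shape[1], cond_mean.shape[2]
    scores = scores.reshape(n_cond, n_bins, k)
    return PCATrajectory(scores=scores,
                         explained_variance_ratio=pca.explained_variance_ratio_,
                         components=pca.components_, grid=tensor.grid,
                         conditions=tensor.conditions)


def euclidean_distance_timecourse(traj: PCATrajectory,
                                  condition_pairs: list[tuple[int, int]] | None = None
                                  ) -> pd.DataFrame:
    """Mean pairwise Euclidean distance between trajectories per bin.

    ``condition_pairs`` are index pairs into ``traj.conditions``; by
    default all unordered pairs are used.  Returns a tidy frame
    (bin_s, distance) plus per-pair distances in wide columns.
    """
    n_cond = traj.scores.shape[0]
    if condition_pairs is None:
        condition_pairs = list(itertools.combinations(range(n_cond), 2))
    if len(condition_pairs) == 0:
        raise ValueError("empty condition-pair set")
    cols = {}
    acc = np.zeros(traj.scores.shape[1])
    for i, j in condition_pairs:
        d = np.linalg.norm(traj.scores[i] - traj.scores[j], axis=-1)
        cols[f"pair_{i}_{j}"] = d
        acc += d
    out = pd.DataFrame({"bin_s": traj.grid,
                        "distance": acc / len(condition_pairs)})
    for name, d in cols.items():
        out[name] = d
    return out
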