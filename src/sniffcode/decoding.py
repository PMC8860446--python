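"""Linear-classifier decoding of odor identity and intensity.

A linear support-vector machine (one-vs-one, C = 1) is trained on
pseudopopulation window features with repeated stratified 20% holdout
validation.  Features are per-unit mean firing rates in a window ('rate')
or a 0/1 activation mark ('binary', thresholded at the unit's training-
split mean so no test information leaks into the feature construction).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.svm import SVC

from .types import DecodingResult, ResponseTensor

logger = logging.getLogger(__name__)

__all__ = [
    "window_features",
    "decode_fixed",
    "decode_sliding",
    "ensemble_size_curve",
    "decode_identity_per_concentration",
    "decode_intensity_per_odor",
]


def window_features(tensor: ResponseTensor,
                    window: tuple[float, float]) -> np.ndarray:
    """Per-trial feature matrix: mean rate per unit in a half-open window.

    Returns (n_cond * n_trials, n_units); samples ordered condition-major
    to match :func:`condition_labels`.
    """
    a, b = window
    sel = (tensor.grid >= a) & (tensor.grid < b)
    if not sel.any():
        raise ValueError("window does not overlap the tensor grid")
    feat = tensor.data[..., sel].mean(axis=-1)  # units x cond x trial
    n_units = feat.shape[0]
    return feat.reshape(n_units, -1).T


def condition_labels(tensor: ResponseTensor, labels) -> np.ndarray:
    """Expand per-condition labels over trials (condition-major order)."""
    labels = np.asarray(labels)
    if len(labels) != len(tensor.conditions):
        raise ValueError("one label per condition required")
    return np.repeat(labels, tensor.n_trials)


def _equalize_classes(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices subsampling every class to the minimum class count."""
    classes, counts = np.unique(y, return_counts=True)
    n = counts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if len(idx) > n:
            idx = rng.choice(idx, size=n, replace=False)
        keep.append(np.sort(idx))
    return np.concatenate(keep)


def _binarize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    thr = train.mean(axis=0, keepdims=True)
    return (train > thr).astype(float), (test > thr).astype(float)


def _holdout_accuracies(X: np.ndarray, y: np.ndarray, feature_mode: str,
                        n_repeats: int, test_size: float,
                        seed: int) -> np.ndarray:
    splitter = StratifiedShuffleSplit(n_splits=n_repeats, test_size=test_size,
                                      random_state=seed % (2 ** 31))
    accs = np.empty(n_repeats)
    for r, (tr, te) in enumerate(splitter.split(X, y)):
        Xtr, Xte = X[tr], X[te]
        if feature_mode == "binary":
            Xtr, Xte = _binarize(Xtr, Xte)
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(Xtr, y[tr])
        accs[r] = float(np.mean(clf.predict(Xte) == y[te]))
    return accs


def decode_fixed(tensor: ResponseTensor, labels, window: tuple[float, float],
                 feature_mode: str = "rate", n_repeats: int = 50,
                 test_size: float = 0.2, seed: int = 0,
                 label_type: str = "identity") -> DecodingResult:
    """Decode labels from rates in one fixed window (e.g. 50-100 ms).

    ``labels`` has one entry per tensor condition; conditions sharing a
    label pool their trials as one class.  Classes are equalized by
    seeded subsampling; each of ``n_repeats`` repeats uses a fresh
    stratified 20% holdout split.
    """
    if feature_mode not in ("rate", "binary"):
        raise ValueError("feature_mode must be 'rate' or 'binary'")
    rng = np.random.default_rng(seed)
    X = window_features(tensor, window)
    y = condition_labels(tensor, labels).astype(str)  # discrete classes
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to decode")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 trials")
    keep = _equalize_classes(y, rng)
    X, y = X[keep], y[keep]
    accs = _holdout_accuracies(X, y, feature_mode, n_repeats, test_size,
                               seed=int(rng.integers(2 ** 31)))
    return DecodingResult(window=window, feature_mode=feature_mode,
                          label_type=label_type, accuracies=accs,
                          n_classes=len(classes))


def decode_sliding(tensor: ResponseTensor, labels, window: float = 0.050,
                   step: float = 0.005, feature_mode: str = "rate",
                   n_repeats: int = 50, test_size: float = 0.2,
                   seed: int = 0,
                   label_type: str = "identity") -> list[DecodingResult]:
    """Decode in a sliding window over the tensor's time span.

    Window positions are ``floor((T - window)/step) + 1`` with T the
    tensor span; each position is an independent :func:`decode_fixed`.
    """
    bin_step = float(tensor.grid[1] - tensor.grid[0])
    t_lo = tensor.grid[0] - bin_step / 2
    t_hi = tensor.grid[-1] + bin_step / 2
    n_pos = int(np.floor((t_hi - t_lo - window) / step + 1e-9)) + 1
    if n_pos < 1:
        raise ValueError("window longer than tensor span")
    results = []
    for k in range(n_pos):
        a = t_lo + k * step
        results.append(decode_fixed(tensor, labels, (a, a + window),
                                    feature_mode=feature_mode,
                                    n_repeats=n_repeats, test_size=test_size,
                                    seed=seed + k, label_type=label_type))
    return results


def ensemble_size_curve(tensor: ResponseTensor, labels, sizes,
                        window: tuple[float, float], n_draws: int = 10,
                        feature_mode: str = "rate", n_repeats: int = 10,
                        seed: int = 0) -> pd.DataFrame:
    """Decoding accuracy as a function of ensemble (unit-subset) size."""
    n_units = tensor.data.shape[0]
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size < 1 or size > n_units:
            raise ValueError(f"ensemble size {size} out of range")
        draws = 1 if size == n_units else n_draws
        for d in range(draws):
            idx = np.sort(rng.choice(n_units, size=size, replace=False))
            sub = ResponseTensor(tensor.data[idx], tensor.units[idx],
                                 tensor.conditions, tensor.grid)
            res = decode_fixed(sub, labels, window, feature_mode=feature_mode,
                               n_repeats=n_repeats,
                               seed=int(rng.integers(2 ** 31)))
            rows.append((size, d, res.mean_accuracy))
    return pd.DataFrame(rows, columns=["size", "draw", "accuracy"])


def decode_identity_per_concentration(tensor: ResponseTensor,
                                      window: tuple[float, float],
                                      **kwargs) -> dict[float, DecodingResult]:
    """Odor-identity decoding separately at each concentration."""
    out = {}
    for conc in sorted(tensor.conditions["concentration"].unique()):
        sub = tensor.select(concentration=conc)
        if sub.conditions["odor_id"].nunique() < 2:
            logger.info("identity decode: concentration %s has <2 odors, "
                        "skipped", conc)
            continue
        out[conc] = decode_fixed(sub, sub.conditions["odor_id"].to_numpy(),
                                 window, label_type="identity", **kwargs)
    return out


def decode_intensity_per_odor(tensor: ResponseTensor,
                              window: tuple[float, float],
                              **kwargs) -> dict[str, DecodingResult]:
    """Odor-intensity (concentration) decoding separately for each odor."""
    out = {}
    for odor in sorted(tensor.conditions["odor_id"].unique()):
        sub = tensor.select(odor_id=odor)
        if sub.conditions["concentration"].nunique() < 2:
            logger.info("intensity decode: odor %s has <2 concentrations, "
                        "skipped", odor)
            continue
        out[odor] = decode_fixed(sub,
                                 sub.conditions["concentration"].to_numpy(),
                                 window, label_type="intensity", **kwargs)
    return out
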