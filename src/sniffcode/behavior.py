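"""2AFC behavioral analysis: percent correct, cumulative d', onset, LED.

Discriminability d'(t) = z(HR(t)) - z(FAR(t)) is computed from cumulative
responses: a trial counts toward time t once its first lick occurred at or
before t, with the hit rate taken over class-A trials (responses on the A
side) and the false-alarm rate over class-B trials.  Unresponded-by-t
trials stay in the denominators, so rates are cumulative response
probabilities.  A log-linear correction (add 0.5 to counts, 1 to totals)
keeps d' finite at rates of 0 or 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .types import BehaviorSession, DPrimeCurve

logger = logging.getLogger(__name__)

__all__ = [
    "percent_correct",
    "dprime",
    "dprime_timecourse",
    "dprime_onset",
    "led_comparison",
]


def percent_correct(session: BehaviorSession,
                    stratify_by_led: bool = True) -> pd.DataFrame:
    """Fraction correct among responded trials, per LED state.

    Strata with no responded trials are flagged NaN (undefined).
    """
    df = session.trials
    responded = df[df["lick_time_s"].notna()]
    groups = responded.groupby("led") if stratify_by_led else [(None, responded)]
    rows = []
    for led, g in groups:
        n = len(g)
        pct = 100.0 * g["correct"].astype(bool).mean() if n else np.nan
        rows.append((session.session_id, led, n, pct))
    out = pd.DataFrame(rows, columns=["session_id", "led", "n_responded",
                                      "pct_correct"])
    if not stratify_by_led:
        out = out.drop(columns="led")
    return out


def dprime(hit_rate: float, fa_rate: float) -> float:
    """Signal-detection d' = z(HR) - z(FAR)."""
    return float(stats.norm.ppf(hit_rate) - stats.norm.ppf(fa_rate))


def _corrected_rate(k: np.ndarray, n: int) -> np.ndarray:
    return (k + 0.5) / (n + 1.0)


def dprime_timecourse(session: BehaviorSession, step: float = 0.025,
                      t_max: float = 2.0,
                      signal_class: str = "A") -> DPrimeCurve:
    """d' of cumulative responses over time since first odor inhalation."""
    df = session.trials
    classes = set(df["stim"])
    other = ({"A", "B"} - {signal_class}).pop() if signal_class in ("A", "B") \
        else None
    if signal_class not in classes or (classes - {signal_class}) == set():
        raise ValueError("both stimulus classes must be present")
    sig = df[df["stim"] == signal_class]
    noi = df[df["stim"] != signal_class]
    t = np.arange(step, t_max + step / 2, step)

    def cum_toward_signal(g):
        lick = g["lick_time_s"].to_numpy(dtype=float)
        side = g["side"].to_numpy()
        resp = np.isfinite(lick) & (side == signal_class)
        times = np.sort(lick[resp])
        return np.searchsorted(times, t, side="right")

    hits = cum_toward_signal(sig)
    fas = cum_toward_signal(noi)
    hr = _corrected_rate(hits, len(sig))
    far = _corrected_rate(fas, len(noi))
    d = stats.norm.ppf(hr) - stats.norm.ppf(far)
    return DPrimeCurve(t=t, dprime=d, hits=hits, false_alarms=fas,
                       n_signal=len(sig), n_noise=len(noi),
                       session_id=session.session_id)


def _shuffled_null_curve(session: BehaviorSession, step: float, t_max: float,
                         n_shuffles: int, rng: np.random.Generator) -> np.ndarray:
    """Mean d' curve across stimulus-label shuffles of one session."""
    df = session.trials
    acc = None
    for _ in range(n_shuffles):
        shuf = df.copy()
        shuf["stim"] = rng.permutation(df["stim"].to_numpy())
        curve = dprime_timecourse(BehaviorSession(shuf, session.session_id),
                                  step=step, t_max=t_max)
        acc = curve.dprime if acc is None else acc + curve.dprime
    return acc / n_shuffles


def dprime_onset(sessions: list[BehaviorSession], step: float = 0.025,
                 t_max: float = 2.0, alpha: float = 0.05, k_consec: int = 3,
                 n_shuffles: int = 20, seed: int = 0) -> float | None:
    """Earliest time d' departs from the label-shuffled null.

    At each time step, session d' values are compared to their own
    shuffled-null curves with a one-sided paired t-test; the onset is the
    first step opening a run of at least ``k_consec`` significant steps.
    Returns None when never significant.
    """
    if len(sessions) < 3:
        raise ValueError("need at least 3 sessions")
    rng = np.random.default_rng(seed)
    real = np.array([dprime_timecourse(s, step=step, t_max=t_max).dprime
                     for s in sessions])
    null = np.array([_shuffled_null_curve(s, step, t_max, n_shuffles, rng)
                     for s in sessions])
    diff = real - null
    n = diff.shape[0]
    m = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = m / (sd / np.sqrt(n))
    p = stats.t.sf(tstat, df=n - 1)
    p = np.where(sd == 0, np.where(m > 0, 0.0, 1.0), p)
    sig = p < alpha
    t_grid = np.arange(step, t_max + step / 2, step)
    run = 0
    for i, s in enumerate(sig):
        run = run + 1 if s else 0
        if run >= k_consec:
            return float(t_grid[i - k_consec + 1])
    return None


def led_comparison(sessions: list[BehaviorSession]) -> dict:
    """Paired t-test of percent correct, LED off vs on, across sessions.

    Sessions missing either LED state are dropped (logged).  Returns
    means +/- SEM per state and the paired two-sided test.
    """
    offs, ons = [], []
    for s in sessions:
        pc = percent_correct(s, stratify_by_led=True).set_index("led")
        if (True not in pc.index or False not in pc.index
                or pc["pct_correct"].isna().any()):
            logger.info("led_comparison: session %s lacks a LED state, "
                        "dropped", s.session_id)
            continue
        offs.append(pc.loc[False, "pct_correct"])
        ons.append(pc.loc[True, "pct_correct"])
    if len(offs) < 3:
        raise ValueError("need at least 3 sessions with both LED states")
    offs, ons = np.asarray(offs), np.asarray(ons)
    d = offs - ons
    if np.all(d == d[0]):
        if d[0] == 0:
            t, p = 0.0, 1.0
        else:
            t, p = np.inf * np.sign(d[0]), 0.0
    else:
        t, p = stats.ttest_rel(offs, ons)
    sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(len(x)))
    return {
        "mean_off": float(offs.mean()), "sem_off": sem(offs),
        "mean_on": float(ons.mean()), "sem_on": sem(ons),
        "t": float(t), "p": float(p), "n_sessions": len(offs),
    }
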