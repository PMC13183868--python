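"""Sleep/wake-history statistics.

The central question: how does slow-wave activity (SWA) right after a
micro-arousal depend on the preceding sleep/wake history, compared with SWA
of the surrounding NREM sleep?  For each eligible event we collect a
HistoryPoint — the fraction of the previous 6 h spent in NREM sleep, the
post-arousal SWA (3-8 s after onset, percent of a baseline), and the
surrounding SWA (1 min before to 1 min after, same scale).  Ordinary
least-squares lines of each SWA measure on prior NREM time are compared via
the interaction term of a stacked regression (the ANCOVA equal-slopes test).
Also here: the SWA decline rate across recovery sleep, its correlation with
NREM amount or arousal frequency, prior-sleep binning with paired
comparisons, and repeated-measures one-way ANOVA with Greenhouse-Geisser
correction plus Tukey pairwise tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import EventSet, Interval, SignalTrace
from .hypnogram import Hypnogram, NREM, fraction_in_state, state_bouts
from .spectral import SWA, BandDefinition, SignalTrace as _Trace, band_power, post_ma_swa, spectrogram

__all__ = [
    "HistoryPoint",
    "RegressionResult",
    "SlopeComparison",
    "RMANOVAResult",
    "build_history_points",
    "fit_history_regression",
    "compare_slopes",
    "swa_decline_rate",
    "correlate_decline",
    "bin_by_prior_sleep",
    "rm_anova_gg_tukey",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HistoryPoint:
    """One event's sleep/wake-history record.

    ``prior_nrem_fraction`` is the fraction (0-1) of the 6-h lookback spent
    in NREM; ``post_swa_pct`` the SWA 3-8 s after onset and
    ``surround_swa_pct`` the SWA from 1 min before to 1 min after, both as
    percent of the recording's baseline NREM SWA.
    """

    event_id: int
    prior_nrem_fraction: float
    post_swa_pct: float
    surround_swa_pct: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.prior_nrem_fraction <= 1.0):
            raise ValueError("prior_nrem_fraction must be in [0, 1]")


@dataclass(frozen=True)
class RegressionResult:
    """OLS line with Pearson correlation: slope per percent-NREM, intercept,
    r, two-sided p, 95% CI of the slope, and n."""

    slope: float
    intercept: float
    r: float
    p: float
    slope_ci: tuple
    n: int


@dataclass(frozen=True)
class SlopeComparison:
    """Difference between two regression slopes with the interaction-term
    (ANCOVA) p-value."""

    slope_a: float
    slope_b: float
    difference: float
    p: float


def build_history_points(
    events: EventSet,
    hyp: Hypnogram,
    lfp: SignalTrace,
    baseline_swa: float,
    lookback_s: float = 21600.0,
    post_window: Interval = Interval(3.0, 5.0),
    surround_pre_s: float = 60.0,
    surround_post_s: float = 60.0,
    band: BandDefinition = SWA,
) -> list:
    """Collect one HistoryPoint per eligible event.

    Events without a full ``lookback_s`` of history or without the +/-1 min
    surround context are skipped (logged).  Duration filtering (the < 5 s
    criterion for the sleep-pressure analysis) is applied by the caller.
    """
    if baseline_swa <= 0:
        raise ValueError("baseline_swa must be positive")
    points = []
    for k, ev in enumerate(events):
        if ev.onset - lookback_s < hyp.start_time:
            log.info("event %d at %.1f s: insufficient lookback, skipped", k, ev.onset)
            continue
        t0 = ev.onset - surround_pre_s
        t1 = ev.onset + max(surround_post_s, post_window.offset)
        if t0 < 0 or t1 * lfp.sampling_rate > lfp.n_samples:
            log.info("event %d at %.1f s: insufficient surround context, skipped", k, ev.onset)
            continue
        frac = fraction_in_state(hyp, Interval(ev.onset - lookback_s, lookback_s), NREM)
        post_pct = post_ma_swa(lfp, ev, baseline_swa, window=post_window, band=band)
        seg = lfp.segment(ev.onset - surround_pre_s, ev.onset + surround_post_s)
        spec = spectrogram(_Trace(seg, lfp.sampling_rate), window_s=0.5)
        surround_pct = 100.0 * float(band_power(spec, band, mode="mean").mean()) / baseline_swa
        points.append(
            HistoryPoint(
                event_id=k,
                prior_nrem_fraction=frac,
                post_swa_pct=post_pct,
                surround_swa_pct=surround_pct,
            )
        )
    return points


def _xy(points: Sequence[HistoryPoint], response: str):
    x = np.array([p.prior_nrem_fraction * 100.0 for p in points])
    if response not in ("post_swa_pct", "surround_swa_pct"):
        raise ValueError(f"unknown response {response!r}")
    y = np.array([getattr(p, response) for p in points])
    return x, y


def fit_history_regression(
    points: Sequence[HistoryPoint],
    response: str = "post_swa_pct",
) -> RegressionResult:
    """OLS line of an SWA response on prior NREM time (percent).

    Slope units: percent-of-baseline SWA per percent NREM in the lookback.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    x, y = _xy(points, response)
    if np.ptp(x) == 0:
        raise ValueError("zero predictor variance")
    res = stats.linregress(x, y)
    n = len(points)
    tcrit = stats.t.ppf(0.975, n - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p=float(res.pvalue),
        slope_ci=ci,
        n=n,
    )


def compare_slopes(
    points: Sequence[HistoryPoint],
    response_a: str = "post_swa_pct",
    response_b: str = "surround_swa_pct",
) -> SlopeComparison:
    """Equal-slopes (ANCOVA) test between two responses on the same points.

    The two responses are stacked into one regression
    ``y ~ x + group + x:group``; the interaction coefficient equals
    ``slope_a - slope_b`` and its t-test p-value is the reported p.
    Antisymmetric: swapping the responses flips the sign, not the p.
    """
    x, ya = _xy(points, response_a)
    _, yb = _xy(points, response_b)
    n = x.size
    X = np.column_stack(
        [
            np.ones(2 * n),
            np.r_[x, x],
            np.r_[np.ones(n), np.zeros(n)],  # group indicator: a = 1
            np.r_[x, np.zeros(n)],  # interaction
        ]
    )
    y = np.r_[ya, yb]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = 2 * n - X.shape[1]
    s2 = resid @ resid / dof
    tol = 1e-10 * max(float(np.var(y)), 1.0)
    if s2 <= tol:
        # noiseless fit: the interaction either is exactly zero or trivially
        # differs; avoid a 0/0 t-statistic
        p = 1.0 if abs(beta[3]) <= math.sqrt(tol) else 0.0
    else:
        cov = s2 * np.linalg.inv(X.T @ X)
        se = math.sqrt(cov[3, 3])
        tval = beta[3] / se if se > 0 else np.inf
        p = 2.0 * stats.t.sf(abs(tval), dof)
    slope_b = float(beta[1])
    slope_a = float(beta[1] + beta[3])
    return SlopeComparison(
        slope_a=slope_a, slope_b=slope_b, difference=float(beta[3]), p=float(p)
    )


def swa_decline_rate(
    lfp: SignalTrace,
    hyp: Hypnogram,
    recovery_window: Interval,
    min_bout_s: float = 300.0,
    band: BandDefinition = SWA,
) -> float:
    """Percent change of SWA from the first to the last long NREM bout.

    NREM bouts strictly longer than ``min_bout_s`` (5 min) whose span lies
    inside ``recovery_window`` (e.g. the first 6 h of recovery sleep) are
    found; mean SWA is computed from the 500-ms spectrogram of the first and
    of the last such bout, and the decline is
    ``100 * (last - first) / first`` (negative when SWA dissipates).
    """
    bouts = [
        b
        for b in state_bouts(hyp, NREM, min_bout_s)
        if b.onset >= recovery_window.onset and b.offset <= recovery_window.offset
    ]
    if len(bouts) < 2:
        raise ValueError("need at least two qualifying NREM bouts in the window")

    def _bout_swa(b: Interval) -> float:
        seg = lfp.segment(b.onset, b.offset)
        spec = spectrogram(_Trace(seg, lfp.sampling_rate), window_s=0.5)
        return float(band_power(spec, band, mode="mean").mean())

    first, last = _bout_swa(bouts[0]), _bout_swa(bouts[-1])
    if first <= 0:
        raise ValueError("non-positive SWA in first bout")
    return 100.0 * (last - first) / first


def correlate_decline(
    declines: Sequence[float],
    covariate: Sequence[float],
) -> RegressionResult:
    """Pearson correlation of per-subject SWA decline against a covariate
    (NREM duration or micro-arousals per hour)."""
    d = np.asarray(declines, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if d.size != c.size:
        raise ValueError("length mismatch")
    if d.size < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(c) == 0:
        raise ValueError("zero predictor variance")
    res = stats.linregress(c, d)
    tcrit = stats.t.ppf(0.975, d.size - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p=float(res.pvalue),
        slope_ci=ci,
        n=d.size,
    )


def bin_by_prior_sleep(
    points: Sequence[HistoryPoint],
    edges: Sequence[float] = (0.0, 20.0, 40.0, 60.0),
) -> list:
    """Paired post-vs-surround SWA comparison per prior-sleep bin.

    Events are binned by percent NREM in the lookback using the half-open
    bins ``[edges[i], edges[i+1])``.  Each nonempty bin with n >= 2 gets a
    paired two-sided t-test of post vs surround SWA; bins with one point are
    marked ``insufficient n`` and empty bins are reported absent.
    Returns a list of dicts, one per bin.
    """
    x = np.array([p.prior_nrem_fraction * 100.0 for p in points])
    post = np.array([p.post_swa_pct for p in points])
    surround = np.array([p.surround_swa_pct for p in points])
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (x >= lo) & (x < hi)
        entry = {"bin": (lo, hi), "n": int(sel.sum())}
        if entry["n"] == 0:
            entry["status"] = "absent"
        elif entry["n"] == 1:
            entry["status"] = "insufficient n"
            entry["mean_difference"] = float(post[sel][0] - surround[sel][0])
        else:
            diff = post[sel] - surround[sel]
            entry["mean_difference"] = float(diff.mean())
            if np.allclose(diff, diff[0]) and diff.std(ddof=1) == 0:
                # zero variance: identical differences, report no-difference
                entry["t"] = 0.0 if diff[0] == 0 else float("inf")
                entry["p"] = 1.0 if diff[0] == 0 else 0.0
            else:
                t, p = stats.ttest_rel(post[sel], surround[sel])
                entry["t"], entry["p"] = float(t), float(p)
            entry["status"] = "ok"
        out.append(entry)
    return out


@dataclass(frozen=True)
class RMANOVAResult:
    """Repeated-measures one-way ANOVA with Greenhouse-Geisser correction.

    ``p`` uses the epsilon-corrected degrees of freedom; ``pairwise`` maps
    condition index pairs to Tukey-adjusted p-values (studentized range on
    the RM error term)."""

    F: float
    df1: float
    df2: float
    epsilon: float
    p: float
    p_uncorrected: float
    pairwise: dict


def rm_anova_gg_tukey(values: np.ndarray) -> RMANOVAResult:
    """RM one-way ANOVA (Greenhouse-Geisser) with Tukey pairwise tests.

    ``values`` is a complete subjects x conditions matrix (no missing
    cells).  The omnibus F is the within-subjects condition effect tested
    against the subject x condition interaction; its p-value uses
    Greenhouse-Geisser epsilon-corrected degrees of freedom.  Pairwise
    comparisons use the studentized range with the RM error mean square, the
    Tukey procedure applied after repeated-measures ANOVA.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be subjects x conditions")
    n, k = values.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 conditions")
    if not np.all(np.isfinite(values)):
        raise ValueError("missing cells are not supported")
    grand = values.mean()
    subj_means = values.mean(axis=1)
    cond_means = values.mean(axis=0)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((values - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0:
        # identical columns up to a subject offset: no within-subject effect
        return RMANOVAResult(
            F=0.0, df1=df_cond, df2=df_err, epsilon=1.0, p=1.0,
            p_uncorrected=1.0, pairwise={},
        )
    F = ms_cond / ms_err

    # Greenhouse-Geisser epsilon from the double-centered covariance matrix
    S = np.cov(values, rowvar=False, ddof=1)
    H = np.eye(k) - np.ones((k, k)) / k
    Sc = H @ S @ H
    eps = np.trace(Sc) ** 2 / ((k - 1) * np.sum(Sc * Sc))
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))

    p_unc = float(stats.f.sf(F, df_cond, df_err))
    p = float(stats.f.sf(F, df_cond * eps, df_err * eps))

    pairwise = {}
    se = math.sqrt(ms_err / n)
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(cond_means[i] - cond_means[j]) / se
            pairwise[(i, j)] = float(stats.studentized_range.sf(q, k, df_err))
    return RMANOVAResult(
        F=float(F),
        df1=df_cond * eps,
        df2=df_err * eps,
        epsilon=eps,
        p=p,
        p_uncorrected=p_unc,
        pairwise=pairwise,
    )
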