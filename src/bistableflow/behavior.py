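"""Behavioral statistics: percept segmentation, bias tests, reliability.

Button presses segment each presentation into half-open percept periods
(the stretches before the first and after the last press are unknown and
dropped).  Perceptual bias is quantified with Wilcoxon signed-rank tests --
across participants on percentage-time, and within a participant on paired
dominance durations -- and test-retest reliability of individual bias with
a one-way intraclass correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import (
    PERCEPT_A,
    PERCEPT_B,
    PERCEPT_UNSURE,
    EventLog,
    PerceptPeriod,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BiasResult",
    "segment_percepts",
    "percept_time_fractions",
    "wilcoxon_signed_rank",
    "group_bias_test",
    "individual_bias",
    "icc_oneway",
]


@dataclass(frozen=True)
class BiasResult:
    """Signed-rank bias test outcome.

    ``statistic`` is the sum of ranks of positive differences (W+); ``z``
    is its tie-corrected normal deviate, whose sign identifies the
    preferred percept.
    """

    statistic: float
    z: float
    p: float
    preferred_code: str | None
    n_pairs: int


def segment_percepts(events: EventLog, presentation_length: float | None = None
                     ) -> list[PerceptPeriod]:
    """Split each presentation into percept periods between successive presses.

    Period i spans [press_i, press_{i+1}) and carries press_i's percept code.
    Time before the first press and after the last press is excluded.
    Presentations with fewer than two presses yield no periods.
    """
    if presentation_length is None:
        presentation_length = events.presentation_length
    periods: list[PerceptPeriod] = []
    for pid in events.presentation_ids:
        g = events.presses(pid)
        times = g["time_s"].to_numpy()
        codes = g["percept_code"].to_numpy()
        if len(times) < 2:
            logger.info("presentation %d has <2 presses: no periods", pid)
            continue
        for i in range(len(times) - 1):
            periods.append(
                PerceptPeriod(int(pid), float(times[i]), float(times[i + 1]), str(codes[i]))
            )
    return periods


def percept_time_fractions(periods: list[PerceptPeriod]) -> dict[str, float]:
    """Percentage of labeled time spent in each percept (sums to 100)."""
    if not periods:
        raise ValueError("no percept periods")
    totals: dict[str, float] = {}
    for p in periods:
        totals[p.percept_code] = totals.get(p.percept_code, 0.0) + p.duration
    grand = sum(totals.values())
    return {code: 100.0 * t / grand for code, t in totals.items()}


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, int]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Returns (W+, z, p, n) where W+ is the positive-rank sum of x - y after
    discarding zero differences (classic Wilcoxon zero handling), z is the
    tie-corrected normal deviate of W+ (positive when x tends to exceed y),
    and p is exact for small untied samples, normal-approximate otherwise.
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 0.0, 1.0, 0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4
    # tie correction to the variance of W+
    _, tie_counts = np.unique(ranks, return_counts=True)
    var_w = n * (n + 1) * (2 * n + 1) / 24 - np.sum(tie_counts ** 3 - tie_counts) / 48
    z = 0.0 if var_w == 0 else (w_pos - mean_w) / np.sqrt(var_w)
    try:
        p = float(stats.wilcoxon(d, zero_method="wilcox", correction=False,
                                 alternative="two-sided").pvalue)
    except ValueError:
        p = 1.0
    return w_pos, float(z), p, n


def group_bias_test(
    fractions_a: np.ndarray,
    fractions_b: np.ndarray,
    code_pair: tuple[str, str] = (PERCEPT_A, PERCEPT_B),
) -> BiasResult:
    """Group-level bias: signed-rank on paired per-participant percentages."""
    fractions_a = np.asarray(fractions_a, float)
    fractions_b = np.asarray(fractions_b, float)
    if len(fractions_a) != len(fractions_b):
        raise ValueError("paired samples must have equal length")
    if len(fractions_a) < 5:
        raise ValueError("need at least 5 participants")
    w, z, p, n = wilcoxon_signed_rank(fractions_a, fractions_b)
    if n == 0 or z == 0:
        preferred = None
    else:
        preferred = code_pair[0] if z > 0 else code_pair[1]
    return BiasResult(statistic=w, z=z, p=p, preferred_code=preferred, n_pairs=n)


def _pair_durations(
    periods: list[PerceptPeriod],
    code_pair: tuple[str, str],
    pairing: str,
) -> tuple[np.ndarray, np.ndarray]:
    a_code, b_code = code_pair
    xs: list[float] = []
    ys: list[float] = []
    by_pid: dict[int, list[PerceptPeriod]] = {}
    for p in periods:
        by_pid.setdefault(p.presentation_id, []).append(p)
    for pid, plist in by_pid.items():
        plist = sorted(plist, key=lambda p: p.start_s)
        if pairing == "kth":
            da = [p.duration for p in plist if p.percept_code == a_code]
            db = [p.duration for p in plist if p.percept_code == b_code]
            k = min(len(da), len(db))
            xs.extend(da[:k])
            ys.extend(db[:k])
        elif pairing == "successive":
            plist = [p for p in plist if p.percept_code in code_pair]
            for p1, p2 in zip(plist[:-1], plist[1:]):
                if p1.percept_code == a_code and p2.percept_code == b_code:
                    xs.append(p1.duration)
                    ys.append(p2.duration)
        else:
            raise ValueError("pairing must be 'kth' or 'successive'")
    return np.asarray(xs), np.asarray(ys)


def individual_bias(
    periods: list[PerceptPeriod],
    code_pair: tuple[str, str] = (PERCEPT_A, PERCEPT_B),
    pairing: str = "kth",
    min_pairs: int = 5,
) -> BiasResult:
    """Individual-level bias from paired dominance durations.

    Within each presentation the k-th period of one percept is paired with
    the k-th period of the other (default), or each period with its
    immediate successor of the other percept (``pairing='successive'``).
    Unsure periods are excluded.  The preferred percept is the one with
    longer durations (sign of z).
    """
    xs, ys = _pair_durations(periods, code_pair, pairing)
    if len(xs) < min_pairs:
        return BiasResult(statistic=np.nan, z=np.nan, p=np.nan,
                          preferred_code=None, n_pairs=len(xs))
    w, z, p, n = wilcoxon_signed_rank(xs, ys)
    preferred = None if z == 0 else (code_pair[0] if z > 0 else code_pair[1])
    return BiasResult(statistic=w, z=z, p=p, preferred_code=preferred, n_pairs=n)


def icc_oneway(matrix: np.ndarray) -> tuple[float, float, tuple[int, int], float]:
    """One-way intraclass correlation ICC(1) for participants x sessions.

    ICC(1) = (MSB - MSW) / (MSB + (k-1) MSW) from a one-way ANOVA with
    subjects as the grouping factor; F = MSB/MSW on (n-1, n(k-1)) degrees
    of freedom.  Zero within-subject variance gives ICC = 1.
    """
    m = np.asarray(matrix, float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError("need >= 3 participants and >= 2 sessions")
    if np.any(np.isnan(m)):
        raise ValueError("missing cells are not supported")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    ssb = k * np.sum((row_means - grand) ** 2)
    ssw = np.sum((m - row_means[:, None]) ** 2)
    df_b, df_w = n - 1, n * (k - 1)
    msb = ssb / df_b
    msw = ssw / df_w
    if msw == 0:
        return 1.0, np.inf, (df_b, df_w), 0.0
    icc = (msb - msw) / (msb + (k - 1) * msw)
    f = msb / msw
    p = float(stats.f.sf(f, df_b, df_w))
    return float(icc), float(f), (df_b, df_w), p
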