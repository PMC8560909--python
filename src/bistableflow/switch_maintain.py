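"""Switch/maintain electrode classification and its group-level tests.

Around each button press the percept is in transition ('switching',
+/-0.5 s of the press); between presses, once 1 s clear of either press,
the percept is stable ('maintain').  Each switching window is paired with
the subsequent maintain window and a channel's mean log high-gamma envelope
in the two windows compared with a paired t-test: significantly higher
during switching -> 'switch' electrode, higher during maintenance ->
'maintain' electrode, otherwise not significant.

Group-level follow-ups: a chi-squared test of whether a channel's category
for one ambiguous image is independent of its category for the other, and
a rank-sum test on dorsoventral (Z) coordinates of switch vs. maintain
channels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import EventLog
from .preprocess import EnvelopeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "PeriodSet",
    "ElectrodeClassification",
    "build_periods",
    "classify_channel",
    "classify_recording",
    "overlap_test",
    "dorsoventral_test",
]

LABELS = ("switch", "maintain", "ns")


@dataclass
class PeriodSet:
    """Paired switching/maintain windows on the continuous-recording clock.

    ``switch_windows[i]`` is (press - 0.5 s, press + 0.5 s) and is paired
    with ``maintain_windows[i]``, the window (press + 1 s, next press - 1 s)
    that follows it.  Pairs whose maintain window is shorter than
    ``min_maintain_s`` are dropped.
    """

    switch_windows: np.ndarray  # (n_pairs, 2) start/end seconds
    maintain_windows: np.ndarray  # (n_pairs, 2)


def build_periods(
    events: EventLog,
    switch_half_width_s: float = 0.5,
    maintain_margin_s: float = 1.0,
    min_maintain_s: float = 0.25,
    include_unsure: bool = True,
) -> PeriodSet:
    """Construct paired switching and maintain windows from button presses."""
    sw: list[tuple[float, float]] = []
    mw: list[tuple[float, float]] = []
    for pid in events.presentation_ids:
        onset = events.presentation_onsets[int(pid)]
        g = events.presses(pid)
        if not include_unsure:
            g = g[g["percept_code"] != "unsure"]
        times = onset + g["time_s"].to_numpy()
        for i in range(len(times) - 1):
            s0, s1 = times[i] - switch_half_width_s, times[i] + switch_half_width_s
            m0, m1 = times[i] + maintain_margin_s, times[i + 1] - maintain_margin_s
            if m1 - m0 < min_maintain_s:
                continue
            sw.append((s0, s1))
            mw.append((m0, m1))
    return PeriodSet(
        switch_windows=np.asarray(sw).reshape(-1, 2),
        maintain_windows=np.asarray(mw).reshape(-1, 2),
    )


@dataclass(frozen=True)
class ElectrodeClassification:
    channel: int
    label: str  # 'switch' | 'maintain' | 'ns'
    t: float
    p: float
    n_pairs: int


def classify_channel(
    env: EnvelopeSeries,
    periods: PeriodSet,
    channel: int,
    alpha: float = 0.05,
    min_pairs: int = 5,
) -> ElectrodeClassification:
    """Label one channel from paired window means of its log envelope."""
    x = env.log_amplitude[channel]
    fs = env.fs
    sw_means, mt_means = [], []
    for (s0, s1), (m0, m1) in zip(periods.switch_windows, periods.maintain_windows):
        a, b = int(round(s0 * fs)), int(round(s1 * fs))
        c, d = int(round(m0 * fs)), int(round(m1 * fs))
        if a < 0 or d > len(x) or b <= a or d <= c:
            continue
        sw_means.append(x[a:b].mean())
        mt_means.append(x[c:d].mean())
    n = len(sw_means)
    if n < min_pairs:
        logger.info("channel %d: only %d window pairs, marked ns", channel, n)
        return ElectrodeClassification(channel, "ns", np.nan, np.nan, n)
    diffs = np.asarray(sw_means) - np.asarray(mt_means)
    if np.allclose(diffs.std(ddof=1), 0.0):
        return ElectrodeClassification(channel, "ns", np.nan, np.nan, n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_rel(sw_means, mt_means)
    if not np.isfinite(t) or p >= alpha:
        label = "ns"
    else:
        label = "switch" if t > 0 else "maintain"
    return ElectrodeClassification(channel, label, float(t), float(p), n)


def classify_recording(
    env: EnvelopeSeries, periods: PeriodSet, alpha: float = 0.05
) -> list[ElectrodeClassification]:
    return [classify_channel(env, periods, ch, alpha=alpha) for ch in range(env.n_channels)]


def overlap_test(
    labels_img1: list[str], labels_img2: list[str]
) -> tuple[float, int, float, np.ndarray, np.ndarray]:
    """Chi-squared test of independence of a channel's category across images.

    Returns (chi2, df, p, observed 3x3 table, expected counts) with rows
    indexing image-1 categories and columns image-2 categories, both ordered
    (switch, maintain, ns).  df = 4.  Warns when expected counts drop
    below 1.
    """
    if len(labels_img1) != len(labels_img2):
        raise ValueError("label lists must cover the same channel set")
    idx = {lab: i for i, lab in enumerate(LABELS)}
    table = np.zeros((3, 3))
    for l1, l2 in zip(labels_img1, labels_img2):
        table[idx[l1], idx[l2]] += 1
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        # degenerate margins: chi2 on the full 3x3 is undefined; report df=4 anyway
        warnings.warn("empty category margin in contingency table")
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / max(table.sum(), 1)
        return 0.0, 4, 1.0, table, expected
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    if np.any(expected < 1):
        warnings.warn("expected cell count below 1 in overlap test")
    return float(chi2), int(df), float(p), table, expected


def dorsoventral_test(
    classifications: list[ElectrodeClassification],
    coordinates: dict[int, tuple[float, float, float] | None],
) -> tuple[float, float]:
    """Rank-sum test comparing Z-coordinates of switch vs. maintain channels.

    Positive z means switch channels sit more dorsally (larger Z).  Channels
    without coordinates are excluded with a log message.
    """
    zs = {"switch": [], "maintain": []}
    for c in classifications:
        if c.label not in zs:
            continue
        coord = coordinates.get(c.channel)
        if coord is None:
            logger.info("channel %d lacks coordinates: excluded", c.channel)
            continue
        zs[c.label].append(coord[2])
    if not zs["switch"] or not zs["maintain"]:
        raise ValueError("both switch and maintain groups must be nonempty")
    z, p = stats.ranksums(zs["switch"], zs["maintain"])
    return float(z), float(p)
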