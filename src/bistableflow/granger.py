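"""Permutation-calibrated directed-influence statistics.

This layer turns pairwise Granger causality into the study-level inference
chain: maintain-trial extraction, trial-count equalization between
percepts, feedforward/feedback asymmetry tests against an
electrode-label-shuffle null, preferred/non-preferred difference tests
against a trial-label-shuffle null, lobe-level binomial (sign-test)
aggregation, and cluster-based correction of the frequency-domain results.

Permutation nulls reuse per-trial moment matrices from :mod:`.varfit`:
shuffling the electrode labels is realized as an independent per-trial swap
of the two channels' roles (a fixed index permutation of the trial's Gram
matrix), and shuffling the trial condition labels as re-summation of the
per-trial moments, so a thousand permutations cost one pass over the data
plus small batched linear algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .containers import Recording
from .varfit import (
    default_freq_grid,
    gc_from_moments,
    spectral_gc_from_params,
    swap_permutation_index,
    trial_moments,
    var_params_from_moments,
)

__all__ = [
    "TrialSet",
    "Hierarchy",
    "GCPairResult",
    "PerceptDiffResult",
    "LobeBiasResult",
    "FreqCluster",
    "extract_trials",
    "equalize_counts",
    "asymmetry_test",
    "asymmetry_spectra",
    "percept_difference_test",
    "percept_difference_spectra",
    "sign_test",
    "group_bias",
    "spectral_cluster_test",
]


# ---------------------------------------------------------------------------
# Trials and hierarchy
# ---------------------------------------------------------------------------

@dataclass
class TrialSet:
    """Fixed-length maintain-period windows labeled by percept condition.

    ``data`` has shape (n_trials, n_channels, trial_len); trials are
    non-overlapping, lie wholly inside maintain periods, and are demeaned
    per trial and channel.
    """

    data: np.ndarray
    conditions: np.ndarray  # condition label per trial
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.conditions = np.asarray(self.conditions)
        if len(self.conditions) != self.data.shape[0]:
            raise ValueError("one condition label per trial required")

    def select(self, condition: str) -> np.ndarray:
        return self.data[self.conditions == condition]

    def pair(self, ch_a: int, ch_b: int) -> "TrialSet":
        return TrialSet(self.data[:, [ch_a, ch_b], :], self.conditions.copy(), self.fs)


def extract_trials(
    rec: Recording,
    maintain_periods: Sequence[tuple[float, float, str]],
    trial_len_s: float = 0.25,
) -> TrialSet:
    """Tile maintain periods with non-overlapping fixed-length trials.

    ``maintain_periods`` holds (start_s, end_s, condition) on the
    continuous-recording clock.  Windows tile each period from its start;
    a leftover tail shorter than a trial is discarded.  Trials are demeaned
    per channel.
    """
    w = int(round(trial_len_s * rec.fs))
    chunks, labels = [], []
    for start, end, cond in maintain_periods:
        a = int(round(start * rec.fs))
        b = int(round(end * rec.fs))
        a, b = max(a, 0), min(b, rec.n_samples)
        for t0 in range(a, b - w + 1, w):
            chunks.append(rec.data[:, t0:t0 + w])
            labels.append(cond)
    if not chunks:
        data = np.empty((0, rec.n_channels, w))
    else:
        data = np.stack(chunks)
        data = data - data.mean(axis=-1, keepdims=True)
    return TrialSet(data=data, conditions=np.asarray(labels, dtype=object), fs=rec.fs)


def equalize_counts(
    set_a: np.ndarray, set_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Drop equally spaced trials from the larger set to equalize counts.

    From the larger set of size n, the d = n - m nominal drop indices are
    floor((i + 0.5) * n / d); collisions advance to the next free index.
    """
    a, b = np.asarray(set_a), np.asarray(set_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both trial sets must be nonempty")
    if len(a) == len(b):
        return a, b
    big, small = (a, b) if len(a) > len(b) else (b, a)
    n, m = len(big), len(small)
    drop = equal_spaced_drop_indices(n, n - m)
    keep = np.setdiff1d(np.arange(n), drop)
    big = big[keep]
    return (big, small) if len(set_a) > len(set_b) else (small, big)


def equal_spaced_drop_indices(n: int, d: int) -> np.ndarray:
    """Indices of d equally spaced drops from a list of length n."""
    taken: set[int] = set()
    for i in range(d):
        idx = int(np.floor((i + 0.5) * n / d))
        while idx in taken:
            idx += 1
            if idx >= n:
                idx = 0
        taken.add(idx)
    return np.sort(np.fromiter(taken, dtype=int))


@dataclass(frozen=True)
class Hierarchy:
    """Cortical-group to hierarchy-level map for feedforward designation.

    Feedforward is lower-to-higher level; ordered pairs within a level are
    'lateral' and excluded from feedforward/feedback designation.
    """

    levels: dict = field(
        default_factory=lambda: {"occipital": 1, "temporal": 2, "parietal": 2, "frontal": 3}
    )

    def direction(self, src_group: str, dst_group: str) -> str:
        try:
            a, b = self.levels[src_group], self.levels[dst_group]
        except KeyError as e:
            raise KeyError(f"group {e} not in hierarchy") from None
        if a < b:
            return "ff"
        if a > b:
            return "fb"
        return "lateral"


# ---------------------------------------------------------------------------
# Percentile calls
# ---------------------------------------------------------------------------

def _two_sided_call(observed: float, null: np.ndarray, labels: tuple[str, str]
                    ) -> tuple[str, float]:
    """Strict-percentile two-sided call and its permutation p-equivalent."""
    hi = np.percentile(null, 97.5)
    lo = np.percentile(null, 2.5)
    if observed > hi:
        call = labels[0]
    elif observed < lo:
        call = labels[1]
    else:
        call = "ns"
    n = len(null)
    p = 2 * min(np.mean(null >= observed), np.mean(null <= observed))
    return call, float(min(max(p, 1.0 / n), 1.0))


# ---------------------------------------------------------------------------
# Electrode-label shuffle: feedforward/feedback asymmetry
# ---------------------------------------------------------------------------

@dataclass
class GCPairResult:
    """Asymmetry test outcome for one inter-level electrode pair."""

    gc_ff: float
    gc_fb: float
    asymmetry: float
    order: int
    null_asymmetry: np.ndarray
    call: str  # 'ff' | 'fb' | 'ns'
    p: float


def _swap_moment_sums(
    moments: np.ndarray, order: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Pooled moments for ``n_perm`` independent per-trial channel swaps."""
    perm_idx = swap_permutation_index(order)
    swapped = moments[:, perm_idx][:, :, perm_idx]
    delta = swapped - moments  # (n_trials, d, d)
    base = moments.sum(axis=0)
    masks = rng.random((n_perm, moments.shape[0])) < 0.5
    return base[None] + np.einsum("pn,nij->pij", masks.astype(float), delta)


def asymmetry_test(
    pair_trials: np.ndarray,
    order: int,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    direction: str = "ff",
) -> GCPairResult:
    """Feedforward/feedback asymmetry with an electrode-label-shuffle null.

    ``pair_trials`` has shape (n_trials, 2, T) with channel 0 at the lower
    hierarchy level (``direction='ff'`` means channel0 -> channel1 is
    feedforward; pass ``'fb'`` if channel 0 is the higher one).  The null
    swaps the two channels' roles independently per trial with probability
    1/2.  Significant feedforward bias: asymmetry above the 97.5th
    percentile of the null; feedback: below the 2.5th.
    """
    if direction not in ("ff", "fb"):
        raise ValueError("lateral (same-level) pairs have no ff/fb designation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    moments = trial_moments(pair_trials, order)
    M = moments.sum(axis=0)
    gc_xy, gc_yx = gc_from_moments(M, order)
    gc_ff, gc_fb = (gc_xy, gc_yx) if direction == "ff" else (gc_yx, gc_xy)
    observed = float(gc_ff - gc_fb)

    M_perm = _swap_moment_sums(moments, order, n_perm, rng)
    g_xy, g_yx = gc_from_moments(M_perm, order)
    null = (g_xy - g_yx) if direction == "ff" else (g_yx - g_xy)
    call, p = _two_sided_call(observed, null, ("ff", "fb"))
    return GCPairResult(
        gc_ff=float(gc_ff), gc_fb=float(gc_fb), asymmetry=observed, order=order,
        null_asymmetry=null, call=call, p=p,
    )


def asymmetry_spectra(
    pair_trials: np.ndarray,
    order: int,
    fs: float,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    direction: str = "ff",
    resolution: float = 0.5,
    freqs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed and permuted feedforward-feedback asymmetry spectra.

    Returns (freqs, spectra) with ``spectra`` of shape (n_perm + 1, F);
    row 0 is the observed asymmetry spectrum, rows 1.. are the
    electrode-label-shuffle permutations (same scheme and the same moment
    bookkeeping as :func:`asymmetry_test`).
    """
    if direction not in ("ff", "fb"):
        raise ValueError("lateral pairs have no ff/fb designation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if freqs is None:
        freqs = default_freq_grid(fs, resolution)
    n_trials, _, T = pair_trials.shape
    n_obs = n_trials * (T - order)
    moments = trial_moments(pair_trials, order)
    M_perm = _swap_moment_sums(moments, order, n_perm, rng)
    M_all = np.concatenate([moments.sum(axis=0)[None], M_perm], axis=0)
    A, Sigma = var_params_from_moments(M_all, order, n_obs)
    f_xy, f_yx = spectral_gc_from_params(A, Sigma, freqs, fs)
    spectra = (f_xy - f_yx) if direction == "ff" else (f_yx - f_xy)
    return freqs, spectra


# ---------------------------------------------------------------------------
# Trial-label shuffle: percept-difference tests
# ---------------------------------------------------------------------------

@dataclass
class PerceptDiffResult:
    """Percept-difference test for one directed connection."""

    direction: str  # 'xy' (ch0 -> ch1) or 'yx'
    gc_pref: float
    gc_nonpref: float
    difference: float
    null: np.ndarray
    call: str  # 'preferred' | 'nonpreferred' | 'ns'
    p: float


def _label_mask_moment_sums(
    moments: np.ndarray, n_pref: int, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled moment sums for permuted condition labels (sizes preserved)."""
    n_total = moments.shape[0]
    flat = moments.reshape(n_total, -1)
    total = flat.sum(axis=0)
    masks = np.zeros((n_perm, n_total))
    for i in range(n_perm):
        idx = rng.permutation(n_total)[:n_pref]
        masks[i, idx] = 1.0
    pref = masks @ flat
    non = total[None] - pref
    d = moments.shape[1]
    return pref.reshape(n_perm, d, d), non.reshape(n_perm, d, d)


def percept_difference_test(
    trials_pref: np.ndarray,
    trials_nonpref: np.ndarray,
    order: int,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[PerceptDiffResult, PerceptDiffResult]:
    """Preferred vs. non-preferred GC difference with a trial-label null.

    Counts must already be equalized (see :func:`equalize_counts`).  The
    statistic per direction is GC(preferred) - GC(non-preferred); the null
    permutes the condition labels over the pooled trials preserving group
    sizes.  Both directions may be significant simultaneously.
    """
    if len(trials_pref) != len(trials_nonpref):
        raise ValueError("equalize trial counts before testing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m_pref = trial_moments(trials_pref, order)
    m_non = trial_moments(trials_nonpref, order)
    gc_p = gc_from_moments(m_pref.sum(axis=0), order)
    gc_n = gc_from_moments(m_non.sum(axis=0), order)

    pooled = np.concatenate([m_pref, m_non], axis=0)
    Mp, Mn = _label_mask_moment_sums(pooled, len(trials_pref), n_perm, rng)
    null_p = gc_from_moments(Mp, order)
    null_n = gc_from_moments(Mn, order)

    out = []
    for d, name in ((0, "xy"), (1, "yx")):
        observed = float(gc_p[d] - gc_n[d])
        null = null_p[d] - null_n[d]
        call, p = _two_sided_call(observed, null, ("preferred", "nonpreferred"))
        out.append(PerceptDiffResult(
            direction=name, gc_pref=float(gc_p[d]), gc_nonpref=float(gc_n[d]),
            difference=observed, null=null, call=call, p=p,
        ))
    return out[0], out[1]


def percept_difference_spectra(
    trials_pref: np.ndarray,
    trials_nonpref: np.ndarray,
    order: int,
    fs: float,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    resolution: float = 0.5,
    freqs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed + permuted percept-difference spectra for both directions.

    Returns (freqs, spec_xy, spec_yx), each (n_perm + 1, F) with row 0
    observed.
    """
    if len(trials_pref) != len(trials_nonpref):
        raise ValueError("equalize trial counts before testing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if freqs is None:
        freqs = default_freq_grid(fs, resolution)
    T = trials_pref.shape[2]
    n_obs = len(trials_pref) * (T - order)
    m_pref = trial_moments(trials_pref, order)
    m_non = trial_moments(trials_nonpref, order)
    pooled = np.concatenate([m_pref, m_non], axis=0)
    Mp, Mn = _label_mask_moment_sums(pooled, len(trials_pref), n_perm, rng)
    Mp = np.concatenate([m_pref.sum(axis=0)[None], Mp], axis=0)
    Mn = np.concatenate([m_non.sum(axis=0)[None], Mn], axis=0)
    Ap, Sp = var_params_from_moments(Mp, order, n_obs)
    An, Sn = var_params_from_moments(Mn, order, n_obs)
    fp_xy, fp_yx = spectral_gc_from_params(Ap, Sp, freqs, fs)
    fn_xy, fn_yx = spectral_gc_from_params(An, Sn, freqs, fs)
    return freqs, fp_xy - fn_xy, fp_yx - fn_yx


# ---------------------------------------------------------------------------
# Lobe-level binomial aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LobeBiasResult:
    """Directional imbalance of significant connections between two groups."""

    group_pair: tuple[str, str]
    n_dir1: int  # e.g. feedforward-significant connections
    n_dir2: int  # e.g. feedback-significant
    z: float
    p: float


def sign_test(k: int, n: int, exact_below: int = 20) -> tuple[float, float]:
    """Two-sided sign test of k successes in n trials against p0 = 1/2.

    Exact binomial tails for n < ``exact_below``; otherwise the
    continuity-corrected normal approximation
    z = (k - n/2 - sgn(k - n/2)/2) / sqrt(n/4).  The documented error of
    the approximation on the two-sided p is below 0.01 for n >= 20.
    Returns (z, p); z's sign encodes the direction of imbalance.
    """
    if n == 0:
        return np.nan, np.nan
    centered = k - n / 2
    z = 0.0 if centered == 0 else (centered - 0.5 * np.sign(centered)) / np.sqrt(n / 4.0)
    if n < exact_below:
        lo = min(k, n - k)
        p = float(min(1.0, 2.0 * stats.binom.cdf(lo, n, 0.5)))
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), p


def group_bias(
    records: Sequence[tuple[tuple[str, str], str]],
    dir1_call: str = "ff",
    dir2_call: str = "fb",
) -> list[LobeBiasResult]:
    """Aggregate per-connection calls into per-group-pair sign tests.

    ``records`` holds (group_pair, call) per connection, where group_pair
    is a canonical (e.g. (lower, higher)) pair of lobe names and call one
    of the two directional calls or 'ns'.  For each group pair, the number
    of ``dir1_call`` connections is tested against the number of
    ``dir2_call`` connections with a two-sided sign test; pairs with no
    significant connection are reported with NaN statistics.
    """
    counts: dict[tuple[str, str], list[int]] = {}
    for pair, call in records:
        c = counts.setdefault(tuple(pair), [0, 0])
        if call == dir1_call:
            c[0] += 1
        elif call == dir2_call:
            c[1] += 1
    out = []
    for pair, (k1, k2) in sorted(counts.items()):
        n = k1 + k2
        z, p = sign_test(k1, n)
        out.append(LobeBiasResult(group_pair=pair, n_dir1=k1, n_dir2=k2, z=z, p=p))
    return out


# ---------------------------------------------------------------------------
# Cluster-based frequency-domain correction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FreqCluster:
    start_hz: float
    end_hz: float
    sign: int
    size: float  # |sum of the per-bin group-bias z| over the cluster
    corrected_p: float
    significant: bool


def _bin_calls(spectra: np.ndarray) -> np.ndarray:
    """Per-dataset, per-bin directional calls against the permutation null.

    ``spectra``: (n_perm + 1, F), row 0 observed.  Each row (including the
    permutation rows, which supply the null of the cluster statistic) is
    compared against the 2.5/97.5 percentiles of the permutation rows.
    Returns an int array (n_perm + 1, F) with +1 / -1 / 0.
    """
    null = spectra[1:]
    hi = np.percentile(null, 97.5, axis=0)
    lo = np.percentile(null, 2.5, axis=0)
    calls = np.zeros(spectra.shape, dtype=int)
    calls[spectra > hi[None, :]] = 1
    calls[spectra < lo[None, :]] = -1
    return calls


def _bias_z_and_sig(calls_by_pair: np.ndarray, alpha: float
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Group-bias z and per-bin significance from stacked pair calls.

    ``calls_by_pair``: (n_pairs, n_datasets, F) of +1/-1/0.  Returns
    (z, significant), each (n_datasets, F).
    """
    k = (calls_by_pair == 1).sum(axis=0)
    m = (calls_by_pair == -1).sum(axis=0)
    n = k + m
    centered = k - n / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(
            n > 0,
            np.where(centered == 0, 0.0,
                     (centered - 0.5 * np.sign(centered)) / np.sqrt(np.maximum(n, 1) / 4.0)),
            0.0,
        )
    # significance: exact binomial for small n, normal approximation otherwise
    small = (n > 0) & (n < 20)
    p = np.ones_like(z, dtype=float)
    p[~small & (n > 0)] = 2.0 * stats.norm.sf(np.abs(z[~small & (n > 0)]))
    if np.any(small):
        lo_counts = np.minimum(k[small], m[small])
        p[small] = np.minimum(1.0, 2.0 * stats.binom.cdf(lo_counts, n[small], 0.5))
    sig = (p < alpha) & (n > 0) & (centered != 0)
    return z, sig


def _clusters_of(z_row: np.ndarray, sig_row: np.ndarray) -> list[tuple[int, int, int, float]]:
    """Maximal runs of significant same-sign bins: (start, end, sign, |sum z|)."""
    out = []
    i, F = 0, len(z_row)
    while i < F:
        if not sig_row[i]:
            i += 1
            continue
        s = int(np.sign(z_row[i]))
        j = i
        while j + 1 < F and sig_row[j + 1] and int(np.sign(z_row[j + 1])) == s:
            j += 1
        out.append((i, j, s, float(abs(z_row[i:j + 1].sum()))))
        i = j + 1
    return out


def spectral_cluster_test(
    spectra_by_pair: Sequence[np.ndarray],
    freqs: np.ndarray,
    alpha: float = 0.05,
) -> list[FreqCluster]:
    """Cluster-corrected frequency-domain group-bias test.

    ``spectra_by_pair`` holds, per connection, the (n_perm + 1, F) array of
    directional-difference spectra (row 0 observed, rows 1.. the same
    permutations used for the connection-level calls).  Per dataset the
    per-bin group bias is a sign test on the connection calls at that bin;
    clusters are maximal contiguous runs of significant same-sign bins with
    size |sum z|; the null is the distribution over permutations of the
    maximum cluster size, and observed clusters are significant above its
    95th percentile.
    """
    calls = np.stack([_bin_calls(s) for s in spectra_by_pair])  # (pairs, n_perm+1, F)
    z, sig = _bias_z_and_sig(calls, alpha)
    n_perm = z.shape[0] - 1
    max_sizes = np.zeros(n_perm)
    for j in range(1, n_perm + 1):
        cl = _clusters_of(z[j], sig[j])
        if cl:
            max_sizes[j - 1] = max(c[3] for c in cl)
    threshold = np.percentile(max_sizes, 95)
    out = []
    for (i0, i1, s, size) in _clusters_of(z[0], sig[0]):
        corr_p = float(np.mean(max_sizes >= size))
        out.append(FreqCluster(
            start_hz=float(freqs[i0]), end_hz=float(freqs[i1]), sign=s,
            size=size, corrected_p=corr_p, significant=bool(size > threshold),
        ))
    return out
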