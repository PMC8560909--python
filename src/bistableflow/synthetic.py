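"""Synthetic study-condition generators.

Real intracranial recordings from this kind of experiment cannot be
redistributed, so every downstream stage of the package is exercised on
synthetic inputs with known ground truth:

* percept report streams with asymmetric, gamma-distributed dominance
  durations (the behavioral phenomenology of bistable perception),
* multichannel signals evolving as a vector autoregression (VAR) whose
  directed inter-group coupling is known exactly and may switch with the
  currently reported percept -- ground truth for Granger-causality recovery,
* event-locked high-gamma (50-120 Hz) amplitude modulation around button
  presses -- ground truth for switch/maintain electrode classification,
* line noise and heartbeat-locked artifacts with a simultaneous ECG
  reference channel -- ground truth for artifact removal.

All generators are deterministic given their seed, and every generator
keeps its ground truth (clean signals, coupling matrices, beat times)
available for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .containers import (
    PERCEPT_A,
    PERCEPT_B,
    PERCEPT_UNSURE,
    ChannelInfo,
    EventLog,
    Recording,
)

__all__ = [
    "PerceptScheduleParams",
    "CouplingSpec",
    "ArtifactParams",
    "ArtifactInjection",
    "gen_percept_schedule",
    "build_coefficients",
    "companion_spectral_radius",
    "gen_var_recording",
    "simulate_var_trials",
    "gen_event_locked_gamma",
    "inject_artifacts",
]


# ---------------------------------------------------------------------------
# Percept schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerceptScheduleParams:
    """Parameters of the simulated percept-report stream.

    Dominance durations are drawn from gamma distributions (right-skewed,
    the classic shape of bistable dominance-duration histograms) with the
    stated means; ``duration_shape`` is the gamma shape parameter shared by
    both percepts.  ``p_unsure`` is the probability that any given dominance
    period is replaced by an 'unsure' report.
    """

    presentation_length: float = 60.0
    n_presentations: int = 6
    mean_duration_preferred: float = 8.0
    mean_duration_nonpreferred: float = 5.0
    duration_shape: float = 4.0
    p_unsure: float = 0.0
    reaction_time_jitter: float = 0.0
    preferred_code: str = PERCEPT_A
    nonpreferred_code: str = PERCEPT_B
    seed: int = 0

    def validate(self) -> None:
        if self.mean_duration_preferred <= 0 or self.mean_duration_nonpreferred <= 0:
            raise ValueError("mean dominance durations must be positive")
        if not (0 <= self.p_unsure < 1):
            raise ValueError("p_unsure must be in [0, 1)")
        if self.duration_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.presentation_length <= 0 or self.n_presentations <= 0:
            raise ValueError("presentation structure must be non-degenerate")


def gen_percept_schedule(params: PerceptScheduleParams) -> EventLog:
    """Draw an alternating percept schedule and return the button-press log.

    Each presentation starts with a short latency to the first press, after
    which percepts alternate with gamma-distributed dominance durations.
    Press times are jittered by ``reaction_time_jitter`` (Gaussian SD) while
    preserving strict monotonicity; no press is emitted at or beyond the
    presentation end.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = params.duration_shape
    means = {
        params.preferred_code: params.mean_duration_preferred,
        params.nonpreferred_code: params.mean_duration_nonpreferred,
    }
    rows: list[tuple[int, float, str]] = []
    for pid in range(params.n_presentations):
        t = float(rng.uniform(0.5, 1.5))
        code = params.preferred_code if rng.random() < 0.5 else params.nonpreferred_code
        prev_t = -np.inf
        while t < params.presentation_length:
            press_t = t
            if params.reaction_time_jitter > 0:
                press_t = t + rng.normal(0.0, params.reaction_time_jitter)
            press_t = float(np.clip(press_t, 0.0, np.nextafter(params.presentation_length, 0)))
            press_t = max(press_t, prev_t + 1e-3)
            if press_t >= params.presentation_length:
                break
            emit_code = code
            if params.p_unsure > 0 and rng.random() < params.p_unsure:
                emit_code = PERCEPT_UNSURE
            rows.append((pid, press_t, emit_code))
            prev_t = press_t
            t += float(rng.gamma(shape, means[code] / shape))
            code = (
                params.nonpreferred_code
                if code == params.preferred_code
                else params.preferred_code
            )
    events = pd.DataFrame(rows, columns=["presentation_id", "time_s", "percept_code"])
    return EventLog(events=events, presentation_length=params.presentation_length)


# ---------------------------------------------------------------------------
# VAR recordings with known directed coupling
# ---------------------------------------------------------------------------

@dataclass
class CouplingSpec:
    """Ground-truth directed coupling for a synthetic multichannel VAR.

    ``directed_gains`` maps a condition name (a percept code, or
    ``"baseline"`` used outside labeled periods) to ``{(src_group,
    dst_group): gain}``.  Coupling from group X to group Y adds a lagged
    term ``gain * x_j(t-1)`` (or a band-limited FIR of the source history
    when ``coupling_band`` is set) to every channel of Y, split evenly over
    the source channels.  Unlisted pairs have zero coupling.
    """

    n_channels: int
    channel_groups: Sequence[str]
    directed_gains: Mapping[str, Mapping[tuple[str, str], float]]
    fs: float = 256.0
    var_order: int = 3
    coupling_band: tuple[float, float] | None = None
    innovation_sd: float | Sequence[float] = 1.0
    ar_coeffs: tuple[float, ...] = (0.5, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channel_groups) != self.n_channels:
            raise ValueError("channel_groups must have one entry per channel")
        if self.var_order < len(self.ar_coeffs):
            self.var_order = len(self.ar_coeffs)

    @property
    def innovation_sds(self) -> np.ndarray:
        sd = np.broadcast_to(np.asarray(self.innovation_sd, float), (self.n_channels,))
        return np.array(sd)


def _coupling_taps(spec: CouplingSpec, n_lags: int) -> np.ndarray:
    """Lag profile of a unit-gain coupling path (length ``n_lags``)."""
    if spec.coupling_band is None:
        taps = np.zeros(n_lags)
        taps[0] = 1.0
        return taps
    taps = signal.firwin(n_lags, spec.coupling_band, fs=spec.fs, pass_zero=False)
    # normalize to unit peak magnitude response inside the band
    w, h = signal.freqz(taps, worN=512, fs=spec.fs)
    peak = np.max(np.abs(h))
    return taps / peak


def build_coefficients(spec: CouplingSpec) -> dict[str, np.ndarray]:
    """Assemble per-condition VAR coefficient arrays (n, n, n_lags)."""
    n_lags = spec.var_order
    if spec.coupling_band is not None:
        n_lags = max(n_lags, 12)
    groups = list(spec.channel_groups)
    conditions = set(spec.directed_gains) | {"baseline"}
    out: dict[str, np.ndarray] = {}
    for cond in conditions:
        A = np.zeros((spec.n_channels, spec.n_channels, n_lags))
        for i in range(spec.n_channels):
            for k, c in enumerate(spec.ar_coeffs):
                A[i, i, k] = c
        gains = spec.directed_gains.get(cond, {})
        taps = _coupling_taps(spec, n_lags)
        for (src_g, dst_g), gain in gains.items():
            src = [j for j, g in enumerate(groups) if g == src_g]
            dst = [i for i, g in enumerate(groups) if g == dst_g]
            if not src or not dst:
                raise ValueError(f"unknown group in coupling pair ({src_g}, {dst_g})")
            for i in dst:
                for j in src:
                    A[i, j, :] += gain * taps / len(src)
        out[cond] = A
    return out


def companion_spectral_radius(A: np.ndarray) -> float:
    """Spectral radius of the companion matrix of a VAR coefficient array."""
    n, _, p = A.shape
    comp = np.zeros((n * p, n * p))
    for k in range(p):
        comp[:n, k * n:(k + 1) * n] = A[:, :, k]
    if p > 1:
        comp[n:, :-n] = np.eye(n * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def _condition_per_sample(events: EventLog, fs: float, n_samples: int) -> np.ndarray:
    """Map each sample to the active percept condition ('' outside periods)."""
    cond = np.zeros(n_samples, dtype=object)
    cond[:] = "baseline"
    for pid in events.presentation_ids:
        onset = events.presentation_onsets[int(pid)]
        g = events.presses(pid)
        times = g["time_s"].to_numpy()
        codes = g["percept_code"].to_numpy()
        for i in range(len(times) - 1):
            a = int(round((onset + times[i]) * fs))
            b = int(round((onset + times[i + 1]) * fs))
            cond[max(a, 0):min(b, n_samples)] = codes[i]
    return cond


def gen_var_recording(
    spec: CouplingSpec,
    events: EventLog | None = None,
    n_samples: int | None = None,
    burn_in: int = 200,
) -> Recording:
    """Simulate a multichannel VAR recording with condition-switching coupling.

    The coefficient matrix in force at each sample is selected by the
    percept reported at that time (``baseline`` outside labeled periods, or
    throughout if no event log is given).  Raises if any condition's VAR is
    unstable, reporting the offending companion spectral radius.
    """
    coeffs = build_coefficients(spec)
    for cond, A in coeffs.items():
        rho = companion_spectral_radius(A)
        if rho >= 1.0:
            raise ValueError(
                f"unstable VAR for condition {cond!r}: companion spectral radius {rho:.3f} >= 1"
            )
    if n_samples is None:
        if events is None:
            raise ValueError("need events or n_samples")
        total_t = max(
            events.presentation_onsets[pid] + events.presentation_length
            for pid in events.presentation_ids
        )
        n_samples = int(round(total_t * spec.fs))
    if events is not None:
        cond_per_sample = _condition_per_sample(events, spec.fs, n_samples)
    else:
        cond_per_sample = np.full(n_samples, "baseline", dtype=object)

    n = spec.n_channels
    n_lags = next(iter(coeffs.values())).shape[2]
    # flatten to (n, n * n_lags) for a single matvec per sample
    flat = {c: A.transpose(0, 2, 1).reshape(n, n_lags * n) for c, A in coeffs.items()}
    rng = np.random.default_rng(spec.seed)
    sds = spec.innovation_sds
    noise = rng.normal(size=(n, n_samples + burn_in)) * sds[:, None]
    data = np.zeros((n, n_samples + burn_in))
    lagbuf = np.zeros(n_lags * n)  # [x(t-1), x(t-2), ...] flattened
    first_cond = cond_per_sample[0]
    for t in range(n_samples + burn_in):
        cond = first_cond if t < burn_in else cond_per_sample[t - burn_in]
        x = flat[cond] @ lagbuf + noise[:, t]
        data[:, t] = x
        lagbuf[n:] = lagbuf[:-n]
        lagbuf[:n] = x
    channels = [
        ChannelInfo(label=f"ch{i}", group=spec.channel_groups[i]) for i in range(n)
    ]
    return Recording(data=data[:, burn_in:], fs=spec.fs, channels=channels)


def simulate_var_trials(
    A: np.ndarray,
    n_trials: int,
    n_samples: int,
    rng: np.random.Generator,
    innovation_sd: float | np.ndarray = 1.0,
    burn_in: int = 50,
) -> np.ndarray:
    """Simulate independent fixed-length VAR segments, vectorized over trials.

    Returns an array (n_trials, n_channels, n_samples).  Used to produce
    trial sets with known coupling quickly for Granger-causality validation.
    """
    n = A.shape[0]
    p = A.shape[2]
    sd = np.broadcast_to(np.asarray(innovation_sd, float), (n,))
    total = n_samples + burn_in
    noise = rng.normal(size=(n_trials, n, total)) * sd[None, :, None]
    x = np.zeros((n_trials, n, total))
    for t in range(total):
        acc = noise[:, :, t].copy()
        for k in range(min(p, t)):
            acc += x[:, :, t - 1 - k] @ A[:, :, k].T
        x[:, :, t] = acc
    return x[:, :, burn_in:]


# ---------------------------------------------------------------------------
# Event-locked high-gamma modulation
# ---------------------------------------------------------------------------

def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping, unit variance."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / np.std(x)


def gen_event_locked_gamma(
    events: EventLog,
    fs: float,
    n_channels: int,
    boost_channels: Sequence[int] = (),
    boost_sign: str = "switch",
    boost_factor: float = 2.0,
    window_s: float = 0.5,
    gamma_band: tuple[float, float] = (50.0, 120.0),
    seed: int = 0,
) -> Recording:
    """Pink-noise carrier plus a 50-120 Hz component modulated around presses.

    ``boost_sign='switch'`` multiplies the high-gamma amplitude by
    ``boost_factor`` within +/- ``window_s`` of each button press on the
    designated channels; ``'maintain'`` divides it there instead (so the
    envelope is relatively higher away from presses).  ``boost_factor=1``
    yields a stationary signal.
    """
    if boost_sign not in ("switch", "maintain"):
        raise ValueError("boost_sign must be 'switch' or 'maintain'")
    if fs <= 2 * gamma_band[1]:
        raise ValueError("sampling rate too low for the gamma band")
    rng = np.random.default_rng(seed)
    total_t = max(
        events.presentation_onsets[pid] + events.presentation_length
        for pid in events.presentation_ids
    )
    n_samples = int(round(total_t * fs))
    press_times = events.absolute_press_times()
    mod = np.ones(n_samples)
    factor = boost_factor if boost_sign == "switch" else 1.0 / boost_factor
    half = int(round(window_s * fs))
    for pt in press_times:
        c = int(round(pt * fs))
        a, b = max(0, c - half), min(n_samples, c + half)
        mod[a:b] = factor
    # soften edges to avoid broadband clicks at window boundaries
    edge = signal.windows.hann(int(0.05 * fs) * 2 + 1)
    mod = signal.convolve(mod, edge / edge.sum(), mode="same")

    sos = signal.butter(3, gamma_band, btype="bandpass", fs=fs, output="sos")
    data = np.empty((n_channels, n_samples))
    for ch in range(n_channels):
        carrier = _pink_noise(n_samples, rng)
        hg = signal.sosfiltfilt(sos, rng.normal(size=n_samples))
        hg /= np.std(hg)
        m = mod if ch in set(boost_channels) else 1.0
        data[ch] = carrier + 0.5 * m * hg
    channels = [ChannelInfo(label=f"ch{i}") for i in range(n_channels)]
    return Recording(data=data, fs=fs, channels=channels)


# ---------------------------------------------------------------------------
# Heartbeat and line-noise artifacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArtifactParams:
    """Heartbeat-locked artifact and line-noise injection parameters."""

    heart_rate_bpm: float = 70.0
    heart_rate_jitter: float = 0.03  # fractional SD of inter-beat intervals
    artifact_scale: float = 1.0  # peak amplitude of the beat-locked waveform
    line_freq: float = 60.0
    line_amplitude: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.heart_rate_bpm <= 0:
            raise ValueError("heart rate must be positive")


@dataclass
class ArtifactInjection:
    """Artifact-injection output with ground truth retained for tests."""

    recording: Recording  # contaminated ECoG channels
    ecg: np.ndarray  # simultaneous clean ECG reference channel
    clean: Recording  # the uncontaminated input
    beat_times: np.ndarray  # true beat times in seconds
    artifact_waveform: np.ndarray  # the injected beat-locked waveform


def _beat_waveform(fs: float, scale: float) -> np.ndarray:
    """Low-frequency beat-locked wiggle: Gaussian-windowed 1.5 Hz cosine."""
    t = np.arange(-0.3, 0.3, 1.0 / fs)
    w = scale * np.exp(-(t ** 2) / (2 * 0.1 ** 2)) * np.cos(2 * np.pi * 1.5 * t)
    return w


def inject_artifacts(rec: Recording, params: ArtifactParams) -> ArtifactInjection:
    """Add line noise and a heartbeat-locked artifact; return an ECG channel.

    The beat-locked waveform is identical at every beat (up to sampling
    alignment); beat times carry the configured inter-beat jitter.  The ECG
    reference contains a sharp R-wave at each beat plus weak noise.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = rec.n_samples
    fs = rec.fs
    t = np.arange(n) / fs

    mean_ibi = 60.0 / params.heart_rate_bpm
    beats = []
    bt = float(rng.uniform(0.1, mean_ibi))
    while bt < rec.duration - 0.4:
        beats.append(bt)
        bt += mean_ibi * (1.0 + params.heart_rate_jitter * rng.normal())
    beat_times = np.asarray(beats)

    data = rec.data.copy()
    if params.line_amplitude > 0:
        data += params.line_amplitude * np.sin(2 * np.pi * params.line_freq * t)[None, :]

    wave = _beat_waveform(fs, params.artifact_scale)
    half = len(wave) // 2
    artifact = np.zeros(n)
    for b in beat_times:
        c = int(round(b * fs))
        a0, a1 = c - half, c - half + len(wave)
        s0, s1 = max(0, a0), min(n, a1)
        artifact[s0:s1] += wave[s0 - a0:s1 - a0]
    if params.artifact_scale != 0:
        data += artifact[None, :]

    # ECG: narrow R-wave spikes at the beats
    ecg = 0.02 * rng.normal(size=n)
    rt = np.arange(-0.04, 0.04, 1.0 / fs)
    rwave = np.exp(-(rt ** 2) / (2 * 0.008 ** 2))
    for b in beat_times:
        c = int(round(b * fs))
        a0 = c - len(rwave) // 2
        s0, s1 = max(0, a0), min(n, a0 + len(rwave))
        ecg[s0:s1] += rwave[s0 - a0:s1 - a0]

    contaminated = rec.copy_with(data=data)
    return ArtifactInjection(
        recording=contaminated,
        ecg=ecg,
        clean=rec.copy_with(),
        beat_times=beat_times,
        artifact_waveform=wave,
    )
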