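"""Three-layer hierarchical predictive-coding attractor model.

The network has prior (P), concept (C) and sensory (S) layers, each with
one population tuned to the preferred percept (PP) and one to the
non-preferred percept (NPP).  Rates follow first-order dynamics driven
through a sigmoid input-output function by: spike-frequency adaptation,
Ornstein-Uhlenbeck noise, rectified bottom-up prediction errors
(max(0, delta * (rate_below - rate))), top-down predictions proportional to
the rate above (eta * rate_above), mutual inhibition between the two
concept-layer populations (-beta * other), and, in the prior layer only, a
constant Bias that models a lifelong prior: it excites the preferred and
suppresses the non-preferred population.

Percept alternation emerges from mutual inhibition, adaptation and noise
(the classic attractor-network mechanisms); the Bias makes the preferred
percept's dominance durations longer and, through the predictive-coding
message passing, makes top-down predictions stronger during the preferred
percept and bottom-up prediction errors stronger during the non-preferred
percept.

Integration is Euler-Maruyama at dt = 1 ms.  The default parameters were
calibrated (see docs/methods.md) so that the model alternates spontaneously
with dominance durations of order seconds and shows both asymmetries.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


__all__ = [
    "ModelParams",
    "ModelTrace",
    "FlowSummary",
    "HierarchicalPerceptModel",
    "SimulationResult",
    "sigmoid",
    "label_percepts",
    "duration_stats",
    "flow_summary",
]

# population index order used throughout: P_PP, P_NPP, C_PP, C_NPP, S_PP, S_NPP
POPULATIONS = ("P_PP", "P_NPP", "C_PP", "C_NPP", "S_PP", "S_NPP")


@dataclass(frozen=True)
class ModelParams:
    """Model parameters (time constants in ms; gains dimensionless).

    Defaults are the package's calibrated operating point: spontaneous
    alternations with mean dominance durations of order seconds, longer
    preferred-percept durations under positive ``bias``, and the
    prediction/prediction-error asymmetries between percepts.
    """

    tau_p: float = 10.0  # prior-layer rate time constant
    tau_c: float = 10.0  # concept-layer rate time constant
    tau_s: float = 10.0  # sensory-layer rate time constant
    tau_a: float = 2000.0  # adaptation time constant
    tau_n: float = 100.0  # noise (OU) time constant
    sigma: float = 0.03  # OU noise scale
    phi: float = 0.2  # adaptation gain
    beta: float = 1.5  # concept-layer mutual inhibition gain
    delta_p: float = 1.0  # prediction-error gain into the prior layer
    delta_c: float = 1.0  # prediction-error gain into the concept layer
    delta_s: float = 1.0  # prediction-error gain into the sensory layer
    eta_p: float = 0.7  # prediction gain prior -> concept
    eta_c: float = 0.7  # prediction gain concept -> sensory
    bias: float = 0.08  # constant drive encoding the long-term prior
    i_pp: float = 0.8  # sensory input to the preferred population
    i_npp: float = 0.8  # sensory input to the non-preferred population
    theta: float = 0.2  # sigmoid threshold
    k: float = 0.1  # sigmoid slope
    dt: float = 1.0  # integration step (ms)

    def validate(self) -> None:
        for name in ("tau_p", "tau_c", "tau_s", "tau_a", "tau_n", "k", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


def sigmoid(y: np.ndarray, theta: float = 0.2, k: float = 0.1) -> np.ndarray:
    """Input-output function F(y) = 1 / (1 + exp((theta - y) / k))."""
    if k <= 0:
        raise ValueError("sigmoid slope k must be positive")
    return 1.0 / (1.0 + np.exp((theta - np.asarray(y, float)) / k))


@njit(cache=True)
def _simulate_kernel(n_steps, r0, a0, nz0, noise_seed,
                     tau_p, tau_c, tau_s, tau_a, tau_n, sigma, phi, beta,
                     delta_p, delta_c, delta_s, eta_p, eta_c, bias,
                     i_pp, i_npp, theta, k, dt):  # pragma: no cover - jitted
    np.random.seed(noise_seed)
    rates = np.empty((6, n_steps), dtype=np.float32)
    r = r0.copy()
    a = a0.copy()
    nz = nz0.copy()
    taus = np.array([tau_p, tau_p, tau_c, tau_c, tau_s, tau_s])
    ou_drive = sigma * np.sqrt(2.0 / tau_n) * np.sqrt(dt)
    for t in range(n_steps):
        # adaptation and OU noise (Euler-Maruyama)
        for i in range(6):
            fa = 1.0 / (1.0 + np.exp((theta - r[i]) / k))
            a[i] += dt / tau_a * (-a[i] + fa)
            nz[i] += -dt * nz[i] / tau_n + ou_drive * np.random.normal()
        # layer inputs
        e_cp_pp = delta_p * (r[2] - r[0])
        e_cp_np = delta_p * (r[3] - r[1])
        e_sc_pp = delta_c * (r[4] - r[2])
        e_sc_np = delta_c * (r[5] - r[3])
        e_is_pp = delta_s * (i_pp - r[4])
        e_is_np = delta_s * (i_npp - r[5])
        u = np.empty(6)
        u[0] = -phi * a[0] + bias + max(0.0, e_cp_pp) + nz[0]
        u[1] = -phi * a[1] - bias + max(0.0, e_cp_np) + nz[1]
        u[2] = -phi * a[2] - beta * r[3] + max(0.0, e_sc_pp) + eta_p * r[0] + nz[2]
        u[3] = -phi * a[3] - beta * r[2] + max(0.0, e_sc_np) + eta_p * r[1] + nz[3]
        u[4] = -phi * a[4] + max(0.0, e_is_pp) + eta_c * r[2] + nz[4]
        u[5] = -phi * a[5] + max(0.0, e_is_np) + eta_c * r[3] + nz[5]
        for i in range(6):
            f = 1.0 / (1.0 + np.exp((theta - u[i]) / k))
            r[i] += dt / taus[i] * (-r[i] + f)
            rates[i, t] = r[i]
    return rates, r, a, nz


def _simulate_python(n_steps, r, a, nz, rng, p: "ModelParams"):
    """Pure-numpy fallback used only when numba is unavailable."""
    rates = np.empty((6, n_steps), dtype=np.float32)
    taus = np.array([p.tau_p, p.tau_p, p.tau_c, p.tau_c, p.tau_s, p.tau_s])
    ou = p.sigma * np.sqrt(2.0 / p.tau_n) * np.sqrt(p.dt)
    for t in range(n_steps):
        a += p.dt / p.tau_a * (-a + sigmoid(r, p.theta, p.k))
        nz += -p.dt * nz / p.tau_n + ou * rng.normal(size=6)
        err = np.maximum(0.0, np.array([
            p.delta_p * (r[2] - r[0]), p.delta_p * (r[3] - r[1]),
            p.delta_c * (r[4] - r[2]), p.delta_c * (r[5] - r[3]),
            p.delta_s * (p.i_pp - r[4]), p.delta_s * (p.i_npp - r[5]),
        ]))
        u = err + nz + np.array([
            -p.phi * a[0] + p.bias,
            -p.phi * a[1] - p.bias,
            -p.phi * a[2] - p.beta * r[3] + p.eta_p * r[0],
            -p.phi * a[3] - p.beta * r[2] + p.eta_p * r[1],
            -p.phi * a[4] + p.eta_c * r[2],
            -p.phi * a[5] + p.eta_c * r[3],
        ])
        r += p.dt / taus * (-r + sigmoid(u, p.theta, p.k))
        rates[:, t] = r
    return rates, r, a, nz


@dataclass
class ModelTrace:
    """Simulated firing rates (6 populations x steps) plus final state."""

    rates: np.ndarray  # float32 (6, n_steps); order per POPULATIONS
    params: ModelParams
    final_rates: np.ndarray
    final_adaptation: np.ndarray
    final_noise: np.ndarray

    @property
    def n_steps(self) -> int:
        return self.rates.shape[1]


def label_percepts(
    trace: ModelTrace,
    layer: str = "concept",
    debounce_steps: int = 50,
) -> np.ndarray:
    """Per-step percept label: 1 preferred, 0 non-preferred.

    The percept is the population with the higher firing rate in the chosen
    layer ('concept' by default; 'prior'/'sensory' give similar labels since
    alternation is synchronized across layers).  Exact ties keep the
    previous label (hysteresis); dominance episodes shorter than
    ``debounce_steps`` are merged into the preceding episode.
    """
    base = {"prior": 0, "concept": 2, "sensory": 4}[layer]
    pp = trace.rates[base].astype(float)
    np_ = trace.rates[base + 1].astype(float)
    raw = np.where(pp > np_, 1, np.where(np_ > pp, 0, -1)).astype(np.int8)
    # hysteresis on exact ties
    tie_idx = np.flatnonzero(raw == -1)
    if len(tie_idx):
        lab = raw.copy()
        prev = 1 if raw[0] == -1 else raw[0]
        for i in range(len(lab)):
            if lab[i] == -1:
                lab[i] = prev
            prev = lab[i]
        raw = lab
    labels = raw.astype(np.int8)
    if debounce_steps > 1:
        starts, lengths, values = _runs(labels)
        for j in range(1, len(starts)):
            if lengths[j] < debounce_steps:
                values[j] = values[j - 1]
        out = np.empty_like(labels)
        for s, ln, v in zip(starts, lengths, values):
            out[s:s + ln] = v
        labels = out
    return labels


def _runs(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    return starts, ends - starts, labels[starts].astype(int)


def episodes(labels: np.ndarray, dt_ms: float = 1.0) -> pd.DataFrame:
    """Maximal constant-label runs as a tidy frame with durations in seconds."""
    starts, lengths, values = _runs(labels)
    return pd.DataFrame({
        "start_step": starts,
        "duration_s": lengths * dt_ms / 1000.0,
        "percept": np.where(values == 1, "preferred", "nonpreferred"),
    })


def duration_stats(
    eps: pd.DataFrame, min_episodes: int = 20, drop_censored: bool = True
) -> dict:
    """Dominance-duration distributions and their rank-sum comparison."""
    if drop_censored and len(eps) > 2:
        eps = eps.iloc[1:-1]
    pref = eps.loc[eps["percept"] == "preferred", "duration_s"].to_numpy()
    non = eps.loc[eps["percept"] == "nonpreferred", "duration_s"].to_numpy()
    flag = len(pref) < min_episodes or len(non) < min_episodes
    if len(pref) and len(non):
        z, p = stats.ranksums(pref, non)
    else:
        z, p = np.nan, np.nan
    return {
        "preferred_durations": pref,
        "nonpreferred_durations": non,
        "median_preferred_s": float(np.median(pref)) if len(pref) else np.nan,
        "median_nonpreferred_s": float(np.median(non)) if len(non) else np.nan,
        "ranksum_z": float(z),
        "ranksum_p": float(p),
        "insufficient_episodes": bool(flag),
    }


@dataclass
class FlowSummary:
    """Directed message strengths averaged within each percept state.

    Rows: prediction prior->concept, prediction concept->sensory,
    prediction error sensory->concept, prediction error concept->prior;
    columns: mean during preferred / non-preferred percept.
    """

    table: pd.DataFrame

    def asymmetries(self) -> dict[str, float]:
        """preferred-minus-nonpreferred difference per directed flow."""
        return (self.table["preferred"] - self.table["nonpreferred"]).to_dict()


def flow_summary(trace: ModelTrace, labels: np.ndarray) -> FlowSummary:
    """Compute the four directed flow strengths per percept state.

    Predictions are summed over the two populations (eta * (r_PP + r_NPP));
    prediction errors are the summed rectified differences.  All quantities
    are non-negative by construction.
    """
    p = trace.params
    r = trace.rates.astype(float)
    pred_pc = p.eta_p * (r[0] + r[1])
    pred_cs = p.eta_c * (r[2] + r[3])
    err_sc = np.maximum(0, p.delta_c * (r[4] - r[2])) + np.maximum(0, p.delta_c * (r[5] - r[3]))
    err_cp = np.maximum(0, p.delta_p * (r[2] - r[0])) + np.maximum(0, p.delta_p * (r[3] - r[1]))
    rows = {
        "prediction_prior_to_concept": pred_pc,
        "prediction_concept_to_sensory": pred_cs,
        "error_sensory_to_concept": err_sc,
        "error_concept_to_prior": err_cp,
    }
    mask_pref = labels == 1

    def _mean(v: np.ndarray, m: np.ndarray) -> float:
        # one percept may never occur (e.g. under extreme parameters)
        return float(v[m].mean()) if m.any() else float("nan")

    table = pd.DataFrame({
        "preferred": {k: _mean(v, mask_pref) for k, v in rows.items()},
        "nonpreferred": {k: _mean(v, ~mask_pref) for k, v in rows.items()},
    })
    return FlowSummary(table=table)


class HierarchicalPerceptModel:
    """Simulator front end: build with parameters, ``simulate`` for results."""

    def __init__(self, params: ModelParams | None = None):
        self.params = params or ModelParams()
        self.params.validate()

    def simulate(self, n_steps: int, seed: int = 0) -> "SimulationResult":
        """Run the network for ``n_steps`` Euler-Maruyama steps.

        Reproducible given ``seed``.  Raises if the state goes non-finite.
        """
        p = self.params
        rng = np.random.default_rng(seed)
        r = rng.uniform(0.1, 0.3, size=6)
        a = np.zeros(6)
        nz = np.zeros(6)
        if _HAVE_NUMBA:
            noise_seed = int(rng.integers(0, 2 ** 31 - 1))
            rates, r, a, nz = _simulate_kernel(
                int(n_steps), r, a, nz, noise_seed,
                p.tau_p, p.tau_c, p.tau_s, p.tau_a, p.tau_n, p.sigma, p.phi,
                p.beta, p.delta_p, p.delta_c, p.delta_s, p.eta_p, p.eta_c,
                p.bias, p.i_pp, p.i_npp, p.theta, p.k, p.dt,
            )
        else:
            rates, r, a, nz = _simulate_python(int(n_steps), r, a, nz, rng, p)
        if not np.all(np.isfinite(r)):
            raise FloatingPointError(
                f"non-finite model state after {n_steps} steps: rates={r}"
            )
        trace = ModelTrace(rates=rates, params=p, final_rates=r,
                           final_adaptation=a, final_noise=nz)
        return SimulationResult(trace=trace)

    def fixed_point_residual(self, r: np.ndarray, a: np.ndarray) -> np.ndarray:
        """Deterministic (sigma = 0) stationarity residuals of the 12-dim state.

        Returns the concatenated right-hand sides (dr/dt, da/dt); a fixed
        point satisfies residual = 0.  Used by root-finding oracles.
        """
        p = self.params
        fa = sigmoid(r, p.theta, p.k)
        err = np.maximum(0.0, np.array([
            p.delta_p * (r[2] - r[0]), p.delta_p * (r[3] - r[1]),
            p.delta_c * (r[4] - r[2]), p.delta_c * (r[5] - r[3]),
            p.delta_s * (p.i_pp - r[4]), p.delta_s * (p.i_npp - r[5]),
        ]))
        u = err + np.array([
            -p.phi * a[0] + p.bias,
            -p.phi * a[1] - p.bias,
            -p.phi * a[2] - p.beta * r[3] + p.eta_p * r[0],
            -p.phi * a[3] - p.beta * r[2] + p.eta_p * r[1],
            -p.phi * a[4] + p.eta_c * r[2],
            -p.phi * a[5] + p.eta_c * r[3],
        ])
        taus = np.array([p.tau_p, p.tau_p, p.tau_c, p.tau_c, p.tau_s, p.tau_s])
        dr = (-r + sigmoid(u, p.theta, p.k)) / taus
        da = (-a + fa) / p.tau_a
        return np.concatenate([dr, da])


@dataclass
class SimulationResult:
    """Results wrapper over a simulated trace."""

    trace: ModelTrace

    def labels(self, layer: str = "concept", debounce_steps: int = 50) -> np.ndarray:
        return label_percepts(self.trace, layer=layer, debounce_steps=debounce_steps)

    def episodes(self, **kwargs) -> pd.DataFrame:
        return episodes(self.labels(**kwargs), dt_ms=self.trace.params.dt)

    def duration_stats(self, **kwargs) -> dict:
        return duration_stats(self.episodes(), **kwargs)

    def flow_summary(self) -> FlowSummary:
        return flow_summary(self.trace, self.labels())

    def summary(self) -> str:
        ds = self.duration_stats()
        fs = self.flow_summary()
        asym = fs.asymmetries()
        lines = [
            "Hierarchical predictive-coding attractor model",
            "=" * 50,
            f"steps:                     {self.trace.n_steps} (dt = {self.trace.params.dt} ms)",
            f"episodes (pref/nonpref):   {len(ds['preferred_durations'])}"
            f" / {len(ds['nonpreferred_durations'])}",
            f"median duration pref:      {ds['median_preferred_s']:.2f} s",
            f"median duration nonpref:   {ds['median_nonpreferred_s']:.2f} s",
            f"rank-sum z, p:             {ds['ranksum_z']:.2f}, {ds['ranksum_p']:.2g}",
            "flow asymmetries (preferred - nonpreferred):",
        ]
        for name, v in asym.items():
            lines.append(f"  {name:<32s} {v:+.4f}")
        return "\n".join(lines)
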