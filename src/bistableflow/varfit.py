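"""Bivariate vector-autoregressive fitting and Granger causality.

The estimator is ordinary least squares on trial-pooled lagged regressors:
each fixed-length trial contributes its own lagged design (regressions
never span trial boundaries), trials are demeaned beforehand, and all
sufficient statistics are accumulated as per-trial Gram (moment) matrices.
Working with moments makes permutation schemes cheap -- swapping the two
channels' roles within a trial, or reassigning a trial to a different
condition, is a fixed index permutation or a re-summation of per-trial
moments, so thousands of permutations reuse one pass over the data.

Time-domain Granger causality is the classic log ratio of reduced to full
innovation variance; the frequency-domain decomposition follows Geweke,
evaluated from the fitted VAR transfer function and innovation covariance.
A ``VARPairModel``/``VARPairResults`` pair exposes the fitted coefficients,
innovation covariance, both GC directions and the spectral decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "trial_moments",
    "swap_permutation_index",
    "gc_from_moments",
    "var_params_from_moments",
    "spectral_gc_from_params",
    "gc_time",
    "gc_spectral",
    "select_order",
    "order_to_ms",
    "VARPairModel",
    "VARPairResults",
]


def order_to_ms(order: int, fs: float) -> float:
    """Model order expressed as a temporal history length in milliseconds."""
    return 1000.0 * order / fs


def _demean_trials(trials: np.ndarray) -> np.ndarray:
    trials = np.asarray(trials, float)
    return trials - trials.mean(axis=-1, keepdims=True)


def trial_moments(trials: np.ndarray, order: int, demean: bool = True) -> np.ndarray:
    """Per-trial Gram matrices of the lagged design.

    ``trials`` has shape (n_trials, 2, T).  For each trial the design row at
    time t is ``[x(t-1..t-p), y(t-1..t-p), x(t), y(t)]`` (d = 2p + 2
    columns, T - p rows); the result stacks ``W.T @ W`` per trial into an
    (n_trials, d, d) array.
    """
    trials = _demean_trials(trials) if demean else np.asarray(trials, float)
    n_trials, n_ch, T = trials.shape
    if n_ch != 2:
        raise ValueError("pairwise engine expects exactly 2 channels")
    p = order
    if p < 1 or p >= T:
        raise ValueError("order must be in [1, T)")
    d = 2 * p + 2
    W = np.empty((n_trials, T - p, d))
    for c in range(2):
        for k in range(1, p + 1):
            W[:, :, c * p + (k - 1)] = trials[:, c, p - k:T - k]
    W[:, :, 2 * p] = trials[:, 0, p:]
    W[:, :, 2 * p + 1] = trials[:, 1, p:]
    return np.einsum("nti,ntj->nij", W, W)


def swap_permutation_index(order: int) -> np.ndarray:
    """Column permutation realizing the exchange of the two channels' roles."""
    p = order
    return np.concatenate(
        [np.arange(p, 2 * p), np.arange(0, p), [2 * p + 1, 2 * p]]
    )


def _rss(M: np.ndarray, regs: np.ndarray, target: int) -> np.ndarray:
    """Residual sum of squares of ``target`` regressed on ``regs``.

    ``M`` may carry leading batch dimensions.
    """
    Mzz = M[..., regs[:, None], regs[None, :]]
    Mzt = M[..., regs, target]
    Mtt = M[..., target, target]
    sol = np.linalg.solve(Mzz, Mzt[..., None])[..., 0]
    return Mtt - np.einsum("...i,...i->...", Mzt, sol)


def gc_from_moments(M: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Both GC directions from (batched) pooled moment matrices.

    Returns (gc_xy, gc_yx): the influence of x on y and of y on x, each
    ``ln(rss_reduced / rss_full)`` clipped to be non-negative.
    """
    p = order
    full = np.arange(2 * p)
    x_lags = np.arange(p)
    y_lags = np.arange(p, 2 * p)
    tx, ty = 2 * p, 2 * p + 1
    rss_x_full = _rss(M, full, tx)
    rss_y_full = _rss(M, full, ty)
    rss_x_red = _rss(M, x_lags, tx)
    rss_y_red = _rss(M, y_lags, ty)
    with np.errstate(divide="ignore", invalid="ignore"):
        gc_yx = np.log(rss_x_red / rss_x_full)
        gc_xy = np.log(rss_y_red / rss_y_full)
    return np.maximum(gc_xy, 0.0), np.maximum(gc_yx, 0.0)


def var_params_from_moments(
    M: np.ndarray, order: int, n_obs: int
) -> tuple[np.ndarray, np.ndarray]:
    """Fitted coefficients A (..., 2, 2, p) and innovation covariance Sigma.

    ``M`` may carry leading batch dimensions; ``n_obs`` is the pooled number
    of regression rows (the maximum-likelihood divisor of the residual
    covariance).
    """
    p = order
    full = np.arange(2 * p)
    targets = np.array([2 * p, 2 * p + 1])
    Mzz = M[..., full[:, None], full[None, :]]
    Mzt = M[..., full[:, None], targets[None, :]]
    Mtt = M[..., targets[:, None], targets[None, :]]
    B = np.linalg.solve(Mzz, Mzt)  # (..., 2p, 2)
    Sigma = (Mtt - np.swapaxes(Mzt, -1, -2) @ B) / n_obs
    # B rows: [x lags (p), y lags (p)]; columns: targets (x, y)
    A = np.empty(M.shape[:-2] + (2, 2, p))
    Bt = np.swapaxes(B, -1, -2)  # (..., target, regressor)
    A[..., :, 0, :] = Bt[..., :, 0:p]
    A[..., :, 1, :] = Bt[..., :, p:2 * p]
    return A, Sigma


def spectral_gc_from_params(
    A: np.ndarray, Sigma: np.ndarray, freqs: np.ndarray, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Geweke spectral Granger causality on a frequency grid.

    ``A`` has shape (..., 2, 2, p), ``Sigma`` (..., 2, 2).  Returns
    (f_xy, f_yx) of shape (..., F): the spectral influence of x on y and of
    y on x in nats.  Non-positive denominators at isolated bins (failed
    local spectral factorization) are clipped to zero influence.
    """
    A = np.asarray(A, float)
    Sigma = np.asarray(Sigma, float)
    p = A.shape[-1]
    freqs = np.asarray(freqs, float)
    phase = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, p + 1)) / fs)  # (F, p)
    Abar = np.zeros(A.shape[:-3] + (len(freqs), 2, 2), dtype=complex)
    Abar[..., 0, 0] = 1.0
    Abar[..., 1, 1] = 1.0
    Abar -= np.einsum("...ijk,fk->...fij", A, phase)
    # closed-form 2x2 inverse
    det = Abar[..., 0, 0] * Abar[..., 1, 1] - Abar[..., 0, 1] * Abar[..., 1, 0]
    H = np.empty_like(Abar)
    H[..., 0, 0] = Abar[..., 1, 1] / det
    H[..., 1, 1] = Abar[..., 0, 0] / det
    H[..., 0, 1] = -Abar[..., 0, 1] / det
    H[..., 1, 0] = -Abar[..., 1, 0] / det

    sxx = Sigma[..., 0, 0][..., None]
    syy = Sigma[..., 1, 1][..., None]
    sxy = Sigma[..., 0, 1][..., None]
    S = np.einsum("...fij,...jk,...flk->...fil", H, Sigma, np.conj(H))
    S_xx = S[..., 0, 0].real
    S_yy = S[..., 1, 1].real
    syy_cond = syy - sxy ** 2 / sxx  # innovation variance of y unexplainable by x
    sxx_cond = sxx - sxy ** 2 / syy
    with np.errstate(divide="ignore", invalid="ignore"):
        f_yx = np.log(S_xx / np.maximum(S_xx - syy_cond * np.abs(H[..., 0, 1]) ** 2, 1e-300))
        f_xy = np.log(S_yy / np.maximum(S_yy - sxx_cond * np.abs(H[..., 1, 0]) ** 2, 1e-300))
    return np.maximum(f_xy, 0.0), np.maximum(f_yx, 0.0)


def default_freq_grid(fs: float, resolution: float = 0.5) -> np.ndarray:
    """Frequency grid from 0 to Nyquist at the configured resolution."""
    return np.arange(0.0, fs / 2 + resolution / 2, resolution)


def gc_time(trials: np.ndarray, order: int) -> tuple[float, float]:
    """Time-domain GC in both directions from pooled trials (x->y, y->x)."""
    M = trial_moments(trials, order).sum(axis=0)
    gc_xy, gc_yx = gc_from_moments(M, order)
    return float(gc_xy), float(gc_yx)


def gc_spectral(
    trials: np.ndarray,
    order: int,
    fs: float,
    resolution: float = 0.5,
    freqs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spectral GC in both directions; returns (freqs, f_xy, f_yx)."""
    if freqs is None:
        freqs = default_freq_grid(fs, resolution)
    n_trials, _, T = np.asarray(trials).shape
    M = trial_moments(trials, order).sum(axis=0)
    n_obs = n_trials * (T - order)
    A, Sigma = var_params_from_moments(M, order, n_obs)
    f_xy, f_yx = spectral_gc_from_params(A, Sigma, freqs, fs)
    return freqs, f_xy, f_yx


def bic_for_order(trials: np.ndarray, order: int) -> float:
    """BIC of the full bivariate VAR at the given order on pooled trials."""
    n_trials, m, T = np.asarray(trials).shape
    M = trial_moments(trials, order).sum(axis=0)
    n_obs = n_trials * (T - order)
    _, Sigma = var_params_from_moments(M, order, n_obs)
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("non positive-definite residual covariance")
    return float(logdet + order * m ** 2 * np.log(n_obs) / n_obs)


def select_order(
    trialsets: list[np.ndarray], max_order: int
) -> tuple[int, list[int]]:
    """Dataset-level VAR order: median of per-pair BIC-optimal orders.

    Each element of ``trialsets`` is an (n_trials, 2, T) array for one
    electrode pair.  The per-pair order minimizes the full-model BIC over
    1..max_order; the dataset order is the median across pairs, rounded
    half up.  Pairs with ill-conditioned covariances are skipped.
    """
    T = min(ts.shape[2] for ts in trialsets)
    if max_order >= T / 2:
        raise ValueError("max_order must be below half the trial length")
    per_pair: list[int] = []
    for ts in trialsets:
        bics = []
        for p in range(1, max_order + 1):
            try:
                bics.append(bic_for_order(ts, p))
            except np.linalg.LinAlgError:
                bics.append(np.inf)
        if np.all(np.isinf(bics)):
            continue
        per_pair.append(int(np.argmin(bics)) + 1)
    if not per_pair:
        raise ValueError("no pair yielded a usable model order")
    med = np.median(per_pair)
    return int(np.floor(med + 0.5)), per_pair


class VARPairModel:
    """Bivariate VAR model for one channel pair, built from pooled trials.

    Parameters
    ----------
    trials
        Array (n_trials, 2, T): demeaning is applied per trial and channel.
    order
        Number of lags p.
    fs
        Sampling rate, used for the spectral decomposition grid.
    """

    def __init__(self, trials: np.ndarray, order: int, fs: float = 256.0):
        trials = np.asarray(trials, float)
        if trials.ndim != 2 + 1 or trials.shape[1] != 2:
            raise ValueError("trials must have shape (n_trials, 2, T)")
        self.trials = trials
        self.order = int(order)
        self.fs = float(fs)
        self.n_trials, _, self.trial_len = trials.shape
        self.n_obs = self.n_trials * (self.trial_len - self.order)
        self._moments = trial_moments(trials, self.order)

    @classmethod
    def from_dataframe(cls, df, x: str, y: str, trial_col: str, order: int,
                       fs: float = 256.0) -> "VARPairModel":
        """Build from a tidy frame with one row per sample."""
        groups = [g[[x, y]].to_numpy().T for _, g in df.groupby(trial_col)]
        T = min(g.shape[1] for g in groups)
        trials = np.stack([g[:, :T] for g in groups])
        return cls(trials, order, fs)

    def fit(self) -> "VARPairResults":
        M = self._moments.sum(axis=0)
        A, Sigma = var_params_from_moments(M, self.order, self.n_obs)
        return VARPairResults(model=self, coefs=A, sigma=Sigma)


@dataclass
class VARPairResults:
    """Fit results of a :class:`VARPairModel`."""

    model: VARPairModel
    coefs: np.ndarray  # (2, 2, p)
    sigma: np.ndarray  # (2, 2) innovation covariance

    def gc(self) -> tuple[float, float]:
        """Time-domain Granger causality (x->y, y->x) in nats."""
        gc_xy, gc_yx = gc_from_moments(self.model._moments.sum(axis=0), self.model.order)
        return float(gc_xy), float(gc_yx)

    def spectral_gc(
        self, resolution: float = 0.5, freqs: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Geweke spectral GC; returns (freqs, f_xy, f_yx)."""
        if freqs is None:
            freqs = default_freq_grid(self.model.fs, resolution)
        f_xy, f_yx = spectral_gc_from_params(self.coefs, self.sigma, freqs, self.model.fs)
        return freqs, f_xy, f_yx

    def summary(self) -> str:
        gc_xy, gc_yx = self.gc()
        lines = [
            "Bivariate VAR / Granger causality",
            "=" * 40,
            f"order (lags):        {self.model.order}"
            f" ({order_to_ms(self.model.order, self.model.fs):.1f} ms)",
            f"trials x length:     {self.model.n_trials} x {self.model.trial_len}",
            f"pooled observations: {self.model.n_obs}",
            f"innovation cov:      [[{self.sigma[0, 0]:.4g}, {self.sigma[0, 1]:.4g}],"
            f" [{self.sigma[1, 0]:.4g}, {self.sigma[1, 1]:.4g}]]",
            f"GC x->y:             {gc_xy:.5f} nats",
            f"GC y->x:             {gc_yx:.5f} nats",
        ]
        return "\n".join(lines)
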