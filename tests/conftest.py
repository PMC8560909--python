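"""Shared helpers for the test suite."""

import numpy as np
import pytest

from bistableflow.synthetic import companion_spectral_radius, simulate_var_trials


def random_stable_var(rng, order=2, m=2, scale=0.5, radius=0.95, max_tries=200):
    """Random coefficient array (m, m, order) with companion radius < radius."""
    decay = scale ** np.arange(1, order + 1)
    for _ in range(max_tries):
        A = rng.uniform(-0.8, 0.8, size=(m, m, order)) * decay
        if companion_spectral_radius(A) < radius:
            return A
    raise RuntimeError("could not draw a stable VAR")


def coupled_var2(gain_xy=0.4, gain_yx=0.15):
    """Hand-built stable VAR(2) with nontrivial bidirectional coupling."""
    A = np.zeros((2, 2, 2))
    A[0, 0] = [0.55, -0.2]
    A[1, 1] = [0.45, -0.25]
    A[1, 0, 0] = gain_xy  # x drives y
    A[0, 1, 0] = gain_yx  # y drives x
    assert companion_spectral_radius(A) < 1
    return A


def var_trials(A, n_trials, n_samples, seed=0, innovation_sd=1.0):
    rng = np.random.default_rng(seed)
    x = simulate_var_trials(A, n_trials, n_samples, rng, innovation_sd=innovation_sd)
    return x - x.mean(axis=-1, keepdims=True)


def ols_gc_oracle(trials, order):
    """Independent two-regression OLS Granger causality (x->y, y->x).

    Builds the lagged design explicitly per trial (never crossing trial
    boundaries), stacks it, and solves both full and reduced regressions
    with lstsq.  Serves as the reference implementation for the
    moment-matrix engine.
    """
    trials = np.asarray(trials, float)
    trials = trials - trials.mean(axis=-1, keepdims=True)
    rows_full, rows_x, rows_y, tx, ty = [], [], [], [], []
    for tr in trials:
        x, y = tr
        T = len(x)
        for t in range(order, T):
            lx = x[t - order:t][::-1]
            ly = y[t - order:t][::-1]
            rows_full.append(np.concatenate([lx, ly]))
            rows_x.append(lx)
            rows_y.append(ly)
            tx.append(x[t])
            ty.append(y[t])
    Xf = np.asarray(rows_full)
    Xx = np.asarray(rows_x)
    Xy = np.asarray(rows_y)
    tx = np.asarray(tx)
    ty = np.asarray(ty)

    def rss(X, t):
        beta, *_ = np.linalg.lstsq(X, t, rcond=None)
        r = t - X @ beta
        return float(r @ r)

    gc_xy = np.log(rss(Xy, ty) / rss(Xf, ty))  # does x help predict y?
    gc_yx = np.log(rss(Xx, tx) / rss(Xf, tx))
    return gc_xy, gc_yx


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
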