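"""VAR fitting and Granger causality: oracle equivalence, spectra, order."""

import numpy as np
import pytest

from conftest import coupled_var2, ols_gc_oracle, random_stable_var, var_trials
from bistableflow.varfit import (
    VARPairModel,
    bic_for_order,
    default_freq_grid,
    gc_from_moments,
    gc_spectral,
    gc_time,
    order_to_ms,
    select_order,
    spectral_gc_from_params,
    swap_permutation_index,
    trial_moments,
    var_params_from_moments,
)


def test_order_to_ms():
    assert order_to_ms(14, 256.0) == pytest.approx(54.6875)
    assert order_to_ms(1, 1000.0) == pytest.approx(1.0)


def test_gc_matches_ols_oracle():
    rng = np.random.default_rng(0)
    for i in range(3):
        A = random_stable_var(rng, order=2)
        trials = var_trials(A, 100, 64, seed=i)
        gc_xy, gc_yx = gc_time(trials, 2)
        ref_xy, ref_yx = ols_gc_oracle(trials, 2)
        assert gc_xy == pytest.approx(ref_xy, rel=1e-8)
        assert gc_yx == pytest.approx(ref_yx, rel=1e-8)


def test_gc_zero_for_independent_series():
    rng = np.random.default_rng(1)
    trials = rng.normal(size=(200, 2, 64))
    trials -= trials.mean(-1, keepdims=True)
    gc_xy, gc_yx = gc_time(trials, 3)
    assert 0 <= gc_xy < 0.01 and 0 <= gc_yx < 0.01


def test_gc_detects_planted_direction():
    trials = var_trials(coupled_var2(gain_xy=0.5, gain_yx=0.0), 150, 64, seed=2)
    gc_xy, gc_yx = gc_time(trials, 2)
    assert gc_xy > 5 * max(gc_yx, 0.005)


def test_swap_permutation_index_exchanges_channels():
    """Swapping channels via the moment index equals recomputing from swapped data."""
    rng = np.random.default_rng(3)
    trials = var_trials(coupled_var2(), 40, 48, seed=3)
    order = 2
    m = trial_moments(trials, order).sum(axis=0)
    idx = swap_permutation_index(order)
    m_swapped = m[idx][:, idx]
    swapped_data = trials[:, ::-1, :]
    m_ref = trial_moments(swapped_data, order).sum(axis=0)
    np.testing.assert_allclose(m_swapped, m_ref, rtol=1e-12)


def test_var_params_recover_coefficients():
    A = coupled_var2()
    trials = var_trials(A, 600, 128, seed=4)
    M = trial_moments(trials, 2).sum(axis=0)
    n_obs = trials.shape[0] * (trials.shape[2] - 2)
    A_hat, Sigma = var_params_from_moments(M, 2, n_obs)
    np.testing.assert_allclose(A_hat, A, atol=0.03)
    np.testing.assert_allclose(Sigma, np.eye(2), atol=0.05)


def test_spectral_gc_nonnegative_and_mean_matches_time_gc():
    trials = var_trials(coupled_var2(), 300, 96, seed=5)
    freqs, f_xy, f_yx = gc_spectral(trials, 2, fs=256.0, resolution=0.5)
    assert np.all(f_xy >= 0) and np.all(f_yx >= 0)
    gc_xy, gc_yx = gc_time(trials, 2)
    assert f_xy.mean() == pytest.approx(gc_xy, rel=0.05)
    assert f_yx.mean() == pytest.approx(gc_yx, rel=0.05)


def test_default_freq_grid_spans_to_nyquist():
    f = default_freq_grid(256.0, 0.5)
    assert f[0] == 0.0 and f[-1] == pytest.approx(128.0)
    assert np.allclose(np.diff(f), 0.5)


def test_bic_selects_true_order():
    A = np.zeros((2, 2, 3))
    A[0, 0] = [0.4, 0.0, 0.25]
    A[1, 1] = [0.3, 0.0, 0.2]
    A[1, 0, 0] = 0.3
    hits = 0
    for seed in range(5):
        trials = var_trials(A, 250, 64, seed=seed)
        bics = [bic_for_order(trials, p) for p in range(1, 7)]
        hits += int(np.argmin(bics) + 1 == 3)
    assert hits >= 4


def test_select_order_median_rounds_half_up():
    """Dataset order is the median of per-pair orders, rounded half up."""
    rng = np.random.default_rng(6)
    # craft pairs whose individually optimal orders are {1, 1, 3, 3}
    A1 = coupled_var2(); A1[:, :, 1] = 0.0  # pure order 1
    A3 = np.zeros((2, 2, 3))
    A3[0, 0] = [0.4, 0.0, 0.3]
    A3[1, 1] = [0.35, 0.0, 0.3]
    A3[1, 0, 0] = 0.3
    sets = [var_trials(A1, 300, 64, seed=s) for s in (0, 1)]
    sets += [var_trials(A3, 300, 64, seed=s) for s in (2, 3)]
    order, per_pair = select_order(sets, max_order=5)
    assert all(p <= 2 for p in per_pair[:2])  # order-1 pairs stay low
    assert per_pair[2:] == [3, 3]
    assert order == int(np.floor(np.median(per_pair) + 0.5))  # median, half up
    with pytest.raises(ValueError):
        select_order(sets, max_order=40)


def test_var_pair_model_results_api():
    trials = var_trials(coupled_var2(), 120, 64, seed=7)
    model = VARPairModel(trials, order=2, fs=256.0)
    res = model.fit()
    gc_xy, gc_yx = res.gc()
    assert gc_xy > gc_yx
    freqs, f_xy, f_yx = res.spectral_gc(resolution=1.0)
    assert f_xy.shape == freqs.shape
    text = res.summary()
    assert "GC x->y" in text and "order" in text
    # dataframe constructor produces the same fit
    import pandas as pd

    rows = []
    for i, tr in enumerate(trials[:10]):
        for t in range(tr.shape[1]):
            rows.append({"trial": i, "x": tr[0, t], "y": tr[1, t]})
    df = pd.DataFrame(rows)
    m2 = VARPairModel.from_dataframe(df, "x", "y", "trial", order=2)
    r2 = m2.fit()
    ref = VARPairModel(trials[:10], order=2).fit()
    assert r2.gc() == pytest.approx(ref.gc(), rel=1e-10)


def test_gc_from_moments_batched_consistency():
    trials = var_trials(coupled_var2(), 60, 48, seed=8)
    m = trial_moments(trials, 2)
    stacked = np.stack([m.sum(axis=0)] * 3)
    gx, gy = gc_from_moments(stacked, 2)
    single = gc_from_moments(m.sum(axis=0), 2)
    np.testing.assert_allclose(gx, single[0])
    np.testing.assert_allclose(gy, single[1])
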