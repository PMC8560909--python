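"""Permutation-calibrated directed-flow tests: calls, aggregation, clusters."""

import numpy as np
import pytest
from scipy import stats

from conftest import coupled_var2, var_trials
from bistableflow.containers import Recording
from bistableflow.granger import (
    Hierarchy,
    TrialSet,
    asymmetry_spectra,
    asymmetry_test,
    equal_spaced_drop_indices,
    equalize_counts,
    extract_trials,
    group_bias,
    percept_difference_test,
    sign_test,
    spectral_cluster_test,
)


# ---------------------------------------------------------------------------
# trial extraction and bookkeeping
# ---------------------------------------------------------------------------

def test_extract_trials_tiles_and_demeans():
    rng = np.random.default_rng(0)
    rec = Recording(data=rng.normal(size=(2, 1000)) + 3.0, fs=100.0)
    ts = extract_trials(rec, [(0.0, 2.2, "A"), (5.0, 6.0, "B")], trial_len_s=0.5)
    # 2.2 s tiles into 4 half-second trials (tail dropped); 1 s into 2
    assert ts.data.shape == (6, 2, 50)
    assert list(ts.conditions) == ["A"] * 4 + ["B"] * 2
    np.testing.assert_allclose(ts.data.mean(axis=-1), 0.0, atol=1e-12)
    assert ts.select("A").shape[0] == 4
    pair = ts.pair(1, 0)
    np.testing.assert_allclose(pair.data[:, 0], ts.data[:, 1])


def test_equal_spaced_drop_indices_example():
    np.testing.assert_array_equal(
        equal_spaced_drop_indices(10, 5), [1, 3, 5, 7, 9])


def test_equalize_counts_balances_and_preserves_small_set():
    a = np.arange(10)[:, None, None] * np.ones((1, 2, 4))
    b = np.arange(4)[:, None, None] * np.ones((1, 2, 4))
    a2, b2 = equalize_counts(a, b)
    assert len(a2) == len(b2) == 4
    np.testing.assert_array_equal(b2, b)
    with pytest.raises(ValueError):
        equalize_counts(a[:0], b)


def test_hierarchy_directions():
    h = Hierarchy()
    assert h.direction("occipital", "temporal") == "ff"
    assert h.direction("frontal", "occipital") == "fb"
    assert h.direction("temporal", "parietal") == "lateral"
    with pytest.raises(KeyError):
        h.direction("occipital", "insula")


# ---------------------------------------------------------------------------
# asymmetry test (electrode-label shuffle)
# ---------------------------------------------------------------------------

def test_asymmetry_test_flags_planted_feedforward():
    trials = var_trials(coupled_var2(gain_xy=0.5, gain_yx=0.0), 80, 64, seed=1)
    res = asymmetry_test(trials, order=2, n_perm=300, seed=1)
    assert res.call == "ff" and res.p < 0.05
    assert res.gc_ff > res.gc_fb
    assert res.null_asymmetry.shape == (300,)


def test_asymmetry_test_direction_argument_flips_roles():
    trials = var_trials(coupled_var2(gain_xy=0.5, gain_yx=0.0), 80, 64, seed=2)
    res_fb = asymmetry_test(trials, order=2, n_perm=300, seed=2, direction="fb")
    assert res_fb.call == "fb"  # same coupling, channel 0 declared higher
    with pytest.raises(ValueError, match="lateral"):
        asymmetry_test(trials, order=2, direction="lateral")


def test_asymmetry_spectra_shape_and_row0_observed():
    trials = var_trials(coupled_var2(), 50, 64, seed=3)
    freqs, spec = asymmetry_spectra(trials, 2, fs=256.0, n_perm=50, seed=3,
                                    resolution=2.0)
    assert spec.shape == (51, len(freqs))
    # row 0 integrates to the time-domain asymmetry (Geweke identity)
    res = asymmetry_test(trials, order=2, n_perm=10, seed=3)
    assert spec[0].mean() == pytest.approx(res.asymmetry, abs=0.02)


# ---------------------------------------------------------------------------
# percept-difference test (trial-label shuffle)
# ---------------------------------------------------------------------------

def test_percept_difference_flags_condition_change():
    pref = var_trials(coupled_var2(gain_xy=0.55, gain_yx=0.1), 60, 64, seed=4)
    non = var_trials(coupled_var2(gain_xy=0.1, gain_yx=0.1), 60, 64, seed=5)
    r_xy, r_yx = percept_difference_test(pref, non, order=2, n_perm=300, seed=4)
    assert r_xy.call == "preferred" and r_xy.p < 0.05
    assert r_xy.gc_pref > r_xy.gc_nonpref
    assert r_yx.call == "ns"
    with pytest.raises(ValueError, match="equalize"):
        percept_difference_test(pref, non[:-5], order=2)


def test_percept_difference_null_is_symmetric():
    """Identical conditions give ns calls most of the time (spot check)."""
    hits = 0
    for seed in range(10):
        a = var_trials(coupled_var2(), 40, 48, seed=100 + seed)
        b = var_trials(coupled_var2(), 40, 48, seed=200 + seed)
        r_xy, r_yx = percept_difference_test(a, b, order=2, n_perm=200, seed=seed)
        hits += (r_xy.call != "ns") + (r_yx.call != "ns")
    assert hits <= 4  # 20 calls at alpha 0.05


# ---------------------------------------------------------------------------
# sign test and lobe aggregation
# ---------------------------------------------------------------------------

def test_sign_test_exact_small_n():
    z, p = sign_test(9, 10)
    lo = 1
    p_ref = 2 * sum(stats.binom.pmf(k, 10, 0.5) for k in range(lo + 1))
    assert p == pytest.approx(p_ref, abs=1e-12)
    assert z > 0
    z2, p2 = sign_test(1, 10)
    assert z2 == -z and p2 == p


def test_sign_test_normal_approximation_documented_error():
    z, p = sign_test(30, 40)
    exact = 2 * stats.binom.cdf(10, 40, 0.5)
    assert abs(p - exact) < 0.01
    assert sign_test(0, 0) == (pytest.approx(np.nan, nan_ok=True),) * 2


def test_group_bias_bookkeeping():
    records = (
        [(("occipital", "temporal"), "ff")] * 5
        + [(("occipital", "temporal"), "fb")] * 1
        + [(("occipital", "temporal"), "ns")] * 3
        + [(("temporal", "frontal"), "fb")] * 2
    )
    out = group_bias(records)
    by_pair = {r.group_pair: r for r in out}
    r1 = by_pair[("occipital", "temporal")]
    assert (r1.n_dir1, r1.n_dir2) == (5, 1)
    assert r1.n_dir1 + r1.n_dir2 == 6  # ns calls excluded
    r2 = by_pair[("temporal", "frontal")]
    assert (r2.n_dir1, r2.n_dir2) == (0, 2)


# ---------------------------------------------------------------------------
# cluster-based frequency correction
# ---------------------------------------------------------------------------

def band_limited_pair_trials(seed, gain=0.5, band=(30.0, 50.0), fs=256.0):
    from bistableflow.synthetic import CouplingSpec, build_coefficients
    spec = CouplingSpec(
        n_channels=2, channel_groups=["occipital", "temporal"],
        directed_gains={"baseline": {("occipital", "temporal"): gain}},
        fs=fs, var_order=12, coupling_band=band, seed=seed,
    )
    A = build_coefficients(spec)["baseline"]
    return var_trials(A, 120, 64, seed=seed)


def test_cluster_test_recovers_planted_band():
    rng = np.random.default_rng(9)
    spectra = []
    freqs = None
    for p in range(10):
        trials = band_limited_pair_trials(seed=300 + p)
        freqs, spec = asymmetry_spectra(trials, 12, fs=256.0, n_perm=200,
                                        seed=rng, resolution=2.0)
        spectra.append(spec)
    clusters = spectral_cluster_test(spectra, freqs)
    sig = [c for c in clusters if c.significant]
    assert sig, "no significant cluster found"
    # some significant positive cluster overlaps the driven 30-50 Hz band
    assert any(c.sign > 0 and c.start_hz < 50.0 and c.end_hz > 30.0 for c in sig)


def test_cluster_test_cluster_fields_consistent():
    rng = np.random.default_rng(10)
    spectra = []
    for p in range(6):
        trials = var_trials(coupled_var2(gain_xy=0.5, gain_yx=0.0), 60, 64,
                            seed=400 + p)
        freqs, spec = asymmetry_spectra(trials, 2, fs=256.0, n_perm=100,
                                        seed=rng, resolution=2.0)
        spectra.append(spec)
    clusters = spectral_cluster_test(spectra, freqs)
    for c in clusters:
        assert c.end_hz >= c.start_hz
        assert c.sign in (-1, 1)
        assert c.size > 0
        assert 0.0 <= c.corrected_p <= 1.0
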