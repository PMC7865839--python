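"""Feature formulas against independent oracles: direct statistics, a
brute-force O(N^2) DFT, Parseval's identity, and structural column counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import equispeed as eq
from equispeed.features import (FEATURE_SETS, FREQ_FEATURE_NAMES,
                                N_FEATURES_PER_LOCATION,
                                build_feature_matrix, feature_columns,
                                freq_features, hann_window,
                                spectral_entropy_of_power, time_features)


def brute_force_dft(x):
    """O(N^2) DFT sum, the independent oracle for every frequency feature."""
    n = len(x)
    k = np.arange(n)
    F = np.array([np.sum(x * np.exp(-2j * np.pi * kk * k / n)) for kk in range(n)])
    return F


def oracle_freq_features(x):
    xw = np.asarray(x, float) * hann_window(len(x))
    F = brute_force_dft(xw)
    power = np.abs(F) ** 2
    energy = power.sum()
    one_sided = power[: len(x) // 2 + 1]
    p = one_sided / one_sided.sum()
    ent = -np.sum(p[p > 0] * np.log(p[p > 0]))
    out = {"ent": ent, "enrg": energy}
    n = len(x)
    ns = np.arange(n)
    for kk in range(1, 7):
        out[f"fft{kk}"] = np.abs(F[kk])
        s = np.sum(xw * np.sin(2 * np.pi * kk * ns / n))
        c = np.sum(xw * np.cos(2 * np.pi * kk * ns / n))
        out[f"ang{kk}"] = np.arctan2(s, c)
    return out


def test_time_features_small_vector_by_direct_evaluation():
    f = time_features(np.array([1.0, 2.0, 3.0, 4.0]))
    assert f["max"] == 4.0 and f["min"] == 1.0
    assert f["mean"] == pytest.approx(2.5)
    assert f["mdn"] == pytest.approx(2.5)
    assert f["sd"] == pytest.approx(1.29099, abs=1e-5)  # 1/(N-1) denominator
    assert f["p25"] == pytest.approx(1.75)  # linear interpolation
    assert f["p75"] == pytest.approx(3.25)


def test_skewness_zero_for_symmetric_window():
    x = np.concatenate([np.arange(128.0), -np.arange(128.0)])
    assert time_features(x)["skw"] == pytest.approx(0.0, abs=1e-12)


def test_gaussian_kurtosis_approaches_three():
    """Raw (non-excess) kurtosis of standard normal draws -> 3; Monte-Carlo
    oracle with a 3-SE band (SE of sample kurtosis ~ sqrt(24/n))."""
    rng = np.random.default_rng(123)
    n = 200_000
    x = rng.normal(size=n)
    krt = time_features(x)["krt"]
    assert abs(krt - 3.0) < 3 * np.sqrt(24.0 / n)


def test_zero_variance_window_flagged_degenerate():
    f = time_features(np.full(256, 2.0))
    assert f["krt"] == 0.0 and f["skw"] == 0.0
    assert eq.features.is_degenerate_time(np.full(256, 2.0))


def test_all_zero_window_energy_and_entropy_zero():
    f = freq_features(np.zeros(256))
    assert f["enrg"] == 0.0
    assert f["ent"] == 0.0


def test_single_bin_spectrum_has_zero_entropy():
    p = np.zeros(129)
    p[5] = 3.0
    assert spectral_entropy_of_power(p) == 0.0


def test_cosine_at_bin_five_dominates_fft_magnitudes():
    n = 256
    x = np.cos(2 * np.pi * 5 * np.arange(n) / n)
    f = freq_features(x)
    mags = {k: f[f"fft{k}"] for k in range(1, 7)}
    assert max(mags, key=mags.get) == 5
    oracle = oracle_freq_features(x)
    assert f["fft5"] == pytest.approx(oracle["fft5"], rel=1e-9)


def test_all_frequency_features_match_brute_force_dft_oracle(random_windows):
    """All 14 frequency features agree with the O(N^2) DFT oracle to 1e-9
    relative on 100 seeded random windows."""
    for x in random_windows[:20]:  # subset here; the full 100 run in the
        got = freq_features(x)     # acceptance suite
        want = oracle_freq_features(x)
        for name in FREQ_FEATURE_NAMES:
            assert got[name] == pytest.approx(want[name], rel=1e-9, abs=1e-9), name


def test_parseval_identity_for_hann_windowed_signal(random_windows):
    """sum_k |X_k|^2 = N * sum_n |w_n x_n|^2 pins the DFT normalization
    used for spectral energy."""
    w = hann_window(256)
    for x in random_windows[:20]:
        energy = freq_features(x)["enrg"]
        assert energy == pytest.approx(256 * np.sum((w * x) ** 2), rel=1e-6)


def test_entropy_bounds(random_windows):
    n_bins = 129
    for x in random_windows[:20]:
        ent = freq_features(x)["ent"]
        assert 0.0 <= ent <= np.log(n_bins)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=64))
def test_time_feature_order_invariants(xs):
    f = time_features(np.asarray(xs))
    assert f["min"] <= f["mean"] <= f["max"]
    assert f["p25"] <= f["mdn"] <= f["p75"]


def test_feature_matrix_column_counts(small_windows):
    """138 per location; 966 for All; 552 for Limbs; 11 sets defined."""
    assert N_FEATURES_PER_LOCATION == 138
    assert len(FEATURE_SETS) == 11
    lh = build_feature_matrix(small_windows[:10], "LH")
    assert len(feature_columns(lh)) == 138
    allm = build_feature_matrix(small_windows[:10], "All")
    assert len(feature_columns(allm)) == 966
    limbs = build_feature_matrix(small_windows[:10], "Limbs")
    assert len(feature_columns(limbs)) == 552
    # metadata carried through, row order = window order
    assert list(allm["speed"]) == [w.target_speed for w in small_windows[:10]]


def test_feature_matrix_naming_matches_field_style(small_matrix_lh):
    assert "max_gyrz(LH)" in small_matrix_lh.columns
    assert "ent_accz(LH)" in small_matrix_lh.columns
    assert not small_matrix_lh[feature_columns(small_matrix_lh)].isna().any().any()


def test_missing_location_rejected(small_windows):
    from equispeed.features import FeatureSetDef
    with pytest.raises(ValueError, match="missing location"):
        # windows restricted to LH cannot serve a sacrum set
        wins = [w for w in small_windows[:5]]
        restricted = [type(w)(samples={k: v for k, v in w.samples.items()
                                       if k[0] == "LH"},
                              center_time=w.center_time,
                              target_speed=w.target_speed, gait=w.gait,
                              subject_id=w.subject_id, breed=w.breed)
                      for w in wins]
        build_feature_matrix(restricted, "Sacrum")
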