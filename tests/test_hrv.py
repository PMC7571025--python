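"""HRV feature extraction: worked examples, identities and brute-force oracles."""

import numpy as np
import pytest

import cogload as cg
from cogload.hrv import (apen, dfa, dfa_alpha, entropy_features, extract_all,
                         freq_domain, mfen, peen, poincare, rlhe, sampen,
                         tfc, time_domain)
from cogload.types import EntropyParams, FeatureUndefinedError

CONST = np.full(80, 1000.0)
ALT = np.array([800.0, 820.0, 800.0, 820.0])


# ---------------------------------------------------------------- time domain

def test_time_domain_constant_series():
    td = time_domain(CONST)
    assert td["SDRR"] == td["RMSSD"] == td["MFD"] == 0.0
    assert td["pNN20"] == td["pNN10"] == td["HRVC"] == 0.0
    assert td["Mean"] == 1000.0 and td["Area"] == 80000.0


def test_time_domain_alternating_hand_arithmetic():
    # three successive differences, all |Δ| = 20; pNN20 uses strict '>'
    td = time_domain(ALT)
    assert td["RMSSD"] == pytest.approx(20.0)
    assert td["MFD"] == pytest.approx(20.0)
    assert td["pNN10"] == 1.0
    assert td["pNN20"] == 0.0


def test_hrvc_identity():
    x = np.random.default_rng(0).normal(850, 40, 80)
    td = time_domain(x)
    assert td["HRVC"] * td["Mean"] == pytest.approx(td["SDRR"])


def test_time_domain_rejects_single_interval():
    with pytest.raises(FeatureUndefinedError):
        time_domain([800.0])


# ------------------------------------------------------------ frequency domain

def test_freq_domain_single_tone_concentrates_in_lf():
    t = np.cumsum(np.full(80, 1.0))  # ~1 s beats
    rr = 1000.0 + 50.0 * np.sin(2 * np.pi * 0.1 * t)
    fd = freq_domain(rr)
    assert fd["LF/(LF+HF)"] > 0.95


def test_freq_domain_constant_is_all_zero():
    fd = freq_domain(CONST)
    assert fd["VLF"] == fd["LF"] == fd["HF"] == fd["TOTPWR"] == 0.0


def test_freq_domain_ratio_identity():
    rr = np.random.default_rng(3).normal(800, 50, 80)
    fd = freq_domain(rr)
    assert fd["HF/(LF+HF)"] + fd["LF/(LF+HF)"] == pytest.approx(1.0)


def test_lf_hf_undefined_when_hf_zero():
    with pytest.warns(UserWarning):
        fd = freq_domain(CONST)
    assert np.isnan(fd["LF/HF"])


# ----------------------------------------------------------------- entropies

def brute_apen(x, m, r):
    """Direct definition: Φ(m) − Φ(m+1), Chebyshev distance, self-matches."""
    x = np.asarray(x, float)

    def phi(mm):
        n = len(x) - mm + 1
        tmpl = [x[i:i + mm] for i in range(n)]
        total = 0.0
        for a in tmpl:
            c = sum(1 for b in tmpl if max(abs(a - b)) <= r) / n
            total += np.log(c)
        return total / n

    return phi(m) - phi(m + 1)


def brute_sampen(x, m, r):
    """Direct template-pair counting, no self-matches."""
    x = np.asarray(x, float)
    n = len(x) - m
    a_cnt = b_cnt = 0
    for i in range(n):
        for j in range(i + 1, n):
            if max(abs(x[i:i + m] - x[j:j + m])) <= r:
                b_cnt += 1
            if max(abs(x[i:i + m + 1] - x[j:j + m + 1])) <= r:
                a_cnt += 1
    if a_cnt == 0 or b_cnt == 0:
        return np.inf
    return -np.log(a_cnt / b_cnt)


def test_apen_degenerate_tolerance_on_constant_series():
    with pytest.raises(FeatureUndefinedError):
        apen(CONST, EntropyParams(m=2, r=0.2, r_mode="sdrr"))


def test_sampen_alternating_matches_brute_force():
    x = np.array([1, 2, 1, 2, 1, 2, 1, 2, 1, 2], float)
    z = (x - x.mean()) / x.std()
    expected = brute_sampen(z, 1, 0.3)
    got = sampen(x, EntropyParams(m=1, r=0.3, r_mode="absolute"))
    assert got == pytest.approx(expected)
    assert got == pytest.approx(0.0)  # all matches persist at length 2


@pytest.mark.parametrize("m,r", [(1, 0.3), (2, 0.5)])
def test_apen_sampen_fuzz_corpus_matches_brute_force(m, r):
    rng = np.random.default_rng(42)
    for _ in range(25):
        n = int(rng.integers(m + 3, 13))
        x = rng.normal(0, 1, n)
        z = (x - x.mean()) / x.std()
        p = EntropyParams(m=m, r=r, r_mode="absolute")
        assert apen(x, p) == pytest.approx(brute_apen(z, m, r), abs=1e-12)
        expected = brute_sampen(z, m, r)
        if np.isfinite(expected):
            assert sampen(x, p) == pytest.approx(expected, abs=1e-12)


def test_peen_monotone_series_is_zero():
    assert peen(np.arange(80, dtype=float), EntropyParams(m=3)) == pytest.approx(0.0)


def test_peen_bounded_by_one():
    x = np.random.default_rng(5).normal(0, 1, 80)
    assert 0.0 <= peen(x, EntropyParams(m=3)) <= 1.0


def test_mfen_finite_on_random_series_and_coarse_grains():
    x = np.random.default_rng(6).normal(800, 40, 80)
    v5 = mfen(x, EntropyParams(m=1, r=0.1, r_mode="absolute", scale=5))
    v1 = mfen(x, EntropyParams(m=1, r=0.1, r_mode="absolute", scale=1))
    assert np.isfinite(v5) and np.isfinite(v1) and v5 != v1


# ----------------------------------------------------------------------- DFA

def brute_dfa_fluct(x, n):
    """Loop-based DFA-1 fluctuation at one box size."""
    y = np.cumsum(np.asarray(x, float) - np.mean(x))
    n_boxes = len(y) // n
    sq = []
    for b in range(n_boxes):
        seg = y[b * n:(b + 1) * n]
        t = np.arange(n, dtype=float)
        coef = np.polyfit(t, seg, 1)
        sq.extend((seg - np.polyval(coef, t)) ** 2)
    return np.sqrt(np.mean(sq))


def test_dfa_alpha1_matches_brute_force_per_box():
    x = np.random.default_rng(11).normal(800, 50, 80)
    sizes = np.arange(4, 17)
    expected = np.polyfit(np.log(sizes),
                          np.log([brute_dfa_fluct(x, n) for n in sizes]), 1)[0]
    assert dfa_alpha(x, 4, 16) == pytest.approx(expected, abs=1e-10)


def test_dfa_white_noise_alpha1_near_half():
    rng = np.random.default_rng(7)
    a1 = [dfa(rng.normal(0, 1, 80))["DFA_alpha1"] for _ in range(100)]
    assert np.mean(a1) == pytest.approx(0.5, abs=0.15)


def test_dfa_integrated_noise_alpha1_near_three_halves():
    rng = np.random.default_rng(8)
    a1 = [dfa(np.cumsum(rng.normal(0, 1, 80)))["DFA_alpha1"] for _ in range(100)]
    assert np.mean(a1) == pytest.approx(1.5, abs=0.2)


def test_dfa_requires_64_intervals():
    with pytest.raises(FeatureUndefinedError):
        dfa(np.random.default_rng(0).normal(0, 1, 50))


# ------------------------------------------------------------------ Poincaré

def test_poincare_alternating_closed_form():
    assert poincare(ALT)["SD1"] == pytest.approx(20.0 / np.sqrt(2))


def test_poincare_constant_is_zero():
    p = poincare(CONST)
    assert p["SD1"] == 0.0 and p["SD2"] == 0.0


def test_sd1_equals_rmssd_over_sqrt2():
    x = np.random.default_rng(9).normal(800, 60, 80)
    assert poincare(x)["SD1"] == pytest.approx(
        time_domain(x)["RMSSD"] / np.sqrt(2))


# ----------------------------------------------------------------------- TFC

def brute_tfc(x, M=10):
    x = np.asarray(x, float)
    total = 0.0
    for s in range(1, M + 1):
        n = len(x) // s
        cg_series = [np.mean(x[i * s:(i + 1) * s]) for i in range(n)]
        diffs = [abs(cg_series[i + 1] - cg_series[i]) for i in range(n - 1)]
        total += (sum(diffs) / len(diffs)) / np.mean(x)
    return total


def test_tfc_constant_is_zero():
    assert tfc(CONST) == 0.0


def test_tfc_scale_invariance():
    x = np.random.default_rng(12).normal(800, 50, 80)
    assert tfc(2 * x) == pytest.approx(tfc(x))


def test_tfc_matches_loop_oracle():
    x = np.random.default_rng(13).normal(800, 50, 80)
    assert tfc(x) == pytest.approx(brute_tfc(x), abs=1e-12)


# ---------------------------------------------------------------------- RLHE

def test_rlhe_detects_heterogeneous_roughness():
    wins = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        smooth = np.cumsum(rng.normal(0, 1, 40))  # strongly correlated half
        rough = rng.normal(0, np.std(smooth) + 1.0, 40)  # uncorrelated half
        hetero = np.concatenate([smooth, rough]) + 800
        homo = rng.normal(800, 50, 80)
        if rlhe(hetero) > rlhe(homo):
            wins += 1
    assert wins >= 45  # >= 90% of paired comparisons


def test_rlhe_constant_series_undefined():
    with pytest.raises(FeatureUndefinedError):
        rlhe(CONST)


def test_rlhe_nonnegative():
    assert rlhe(np.random.default_rng(14).normal(800, 50, 80)) >= 0.0


# ---------------------------------------------------------------- full vector

def test_full_vector_names_and_completeness():
    x = np.random.default_rng(15).normal(800, 50, 80)
    feats = extract_all(x)
    assert tuple(feats) == cg.HRV_FEATURE_NAMES
    assert len(feats) == 27
    assert all(np.isfinite(v) for v in feats.values())


def test_features_depend_only_on_interval_values():
    x = np.random.default_rng(16).normal(800, 50, 80)
    a = extract_all(cg.RRSeries(x, "S01", "CL"))
    b = extract_all(cg.RRSeries(x, "S99", "BL"))
    assert a == b
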