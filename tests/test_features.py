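"""Unit tests for the five gait features, each checked against an
independent brute-force evaluation of its defining formula."""

import numpy as np
import pytest

from gaitscore.features import (
    FeatureError,
    count_extreme_points,
    count_extreme_points_channel,
    feature_vector,
    harmonic_ratio,
    harmonic_spectrum,
    harmonic_total,
    pearson_channel,
    pearson_total,
    symmetry_channel,
    symmetry_total,
    unbiased_autocorrelation,
    variance_ratio_channel,
    variance_ratio_total,
)
from gaitscore.gait_graph import AverageGaitGraph, CharacteristicGaitGraph, NormalizedCycle
from gaitscore.segmentation import SIX_CHANNELS


def _agg(data):
    return AverageGaitGraph(data=np.asarray(data, float), channels=SIX_CHANNELS,
                            source_cycles=(0, 1, 2))


def _cgg(data):
    return CharacteristicGaitGraph(data=np.asarray(data, float), channels=SIX_CHANNELS)


# ---------------------------------------------------------------------------
# independent brute-force oracles (loop-level, no shared code with features.py)
# ---------------------------------------------------------------------------

def oracle_pearson(x, y):
    m = len(x)
    xbar, ybar = sum(x) / m, sum(y) / m
    sx = (sum((v - xbar) ** 2 for v in x) / (m - 1)) ** 0.5
    sy = (sum((v - ybar) ** 2 for v in y) / (m - 1)) ** 0.5
    return sum((x[i] - xbar) * (y[i] - ybar) / (sx * sy) for i in range(m)) / (m - 1)

def oracle_variance_ratio(rows):
    n, m = len(rows), len(rows[0])
    num = den = 0.0
    grand = sum(sum(r) for r in rows) / (n * m)
    for i in range(m):
        phase_mean = sum(rows[j][i] for j in range(n)) / n
        for j in range(n):
            num += (rows[j][i] - phase_mean) ** 2
            den += (rows[j][i] - grand) ** 2
    return (num / (m * (n - 1))) / (den / (m * n - 1))

def oracle_harmonic_ratio(x):
    m = len(x)
    xc = [v - sum(x) / m for v in x]
    even = odd = 0.0
    for nh in range(1, 21):
        re = sum(xc[i] * np.cos(2 * np.pi * nh * i / m) for i in range(m))
        im = sum(xc[i] * np.sin(2 * np.pi * nh * i / m) for i in range(m))
        c = (re ** 2 + im ** 2) ** 0.5
        if nh % 2 == 0:
            even += c
        else:
            odd += c
    return even / odd

def oracle_symmetry(x):
    m = len(x)
    xc = [v - sum(x) / m for v in x]
    a0 = sum(v * v for v in xc) / m
    lo, hi = int(np.ceil(0.3 * m)), int(np.floor(0.7 * m))
    best = -np.inf
    for lag in range(lo, hi + 1):
        a = sum(xc[i] * xc[i + lag] for i in range(m - lag)) / (m - lag)
        best = max(best, a / a0)
    return best

def oracle_extrema(x):
    xs = [x[0]] + [x[i] for i in range(1, len(x)) if x[i] != x[i - 1]]
    count = 0
    for i in range(1, len(xs) - 1):
        if (xs[i] - xs[i - 1]) * (xs[i + 1] - xs[i]) < 0:
            count += 1
    return count


class TestPearson:
    def test_self_correlation(self, rng):
        x = rng.standard_normal(100)
        assert pearson_channel(x, x) == pytest.approx(1.0)
        assert pearson_channel(x, -x) == pytest.approx(-1.0)

    def test_small_example_matches_oracle(self):
        x, y = [1.0, 2.0, 4.0, 5.0], [1.0, 3.0, 3.0, 6.0]
        assert pearson_channel(np.array(x), np.array(y)) == pytest.approx(
            oracle_pearson(x, y), abs=1e-12)

    def test_constant_channel_warns_and_zeroes(self, rng):
        with pytest.warns(UserWarning, match="constant"):
            assert pearson_channel(np.ones(50), rng.standard_normal(50)) == 0.0

    def test_total_is_sum_and_symmetric(self, rng):
        a, c = rng.standard_normal((2, 6, 100))
        p = pearson_total(_agg(a), _cgg(c))
        expected = sum(oracle_pearson(list(a[i]), list(c[i])) for i in range(6))
        assert p == pytest.approx(expected, abs=1e-9)
        assert p == pytest.approx(pearson_total(_agg(c), _cgg(a)), abs=1e-12)

    def test_identity_ceiling(self, rng):
        x = rng.standard_normal((6, 100))
        assert pearson_total(_agg(x), _cgg(x)) == pytest.approx(6.0, abs=1e-12)

    def test_affine_invariance_per_channel(self, rng):
        a, c = rng.standard_normal((2, 6, 100))
        scaled = 3.0 * a + np.arange(6)[:, None]
        assert pearson_total(_agg(scaled), _cgg(c)) == pytest.approx(
            pearson_total(_agg(a), _cgg(c)), abs=1e-9)


class TestVarianceRatio:
    def test_identical_cycles_zero(self, rng):
        row = rng.standard_normal(100)
        assert variance_ratio_channel(np.tile(row, (3, 1))) == pytest.approx(
            0.0, abs=1e-12)

    def test_hand_matrix_matches_oracle(self):
        rows = [[1.0, 2.0, 0.5, 3.0], [0.5, 2.5, 1.0, 2.0], [1.5, 1.0, 0.0, 4.0]]
        assert variance_ratio_channel(np.array(rows)) == pytest.approx(
            oracle_variance_ratio(rows), abs=1e-12)

    def test_independent_noise_near_one(self):
        vals = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            vals.append(variance_ratio_channel(r.standard_normal((3, 100))))
        assert 0.9 <= np.mean(vals) <= 1.1

    def test_total_additivity(self, rng):
        cycles = [NormalizedCycle(data=rng.standard_normal((6, 100)),
                                  channels=SIX_CHANNELS) for _ in range(3)]
        stack = np.array([c.data for c in cycles])
        expected = sum(oracle_variance_ratio([list(stack[j, c]) for j in range(3)])
                       for c in range(6))
        assert variance_ratio_total(cycles) == pytest.approx(expected, abs=1e-9)

    def test_scale_invariance(self, rng):
        cycles = [NormalizedCycle(data=rng.standard_normal((6, 100)),
                                  channels=SIX_CHANNELS) for _ in range(3)]
        scaled = [NormalizedCycle(data=5.0 * c.data, channels=SIX_CHANNELS)
                  for c in cycles]
        assert variance_ratio_total(scaled) == pytest.approx(
            variance_ratio_total(cycles), abs=1e-9)


class TestExtremePoints:
    def test_monotone_ramp_zero(self):
        agg = _agg(np.tile(np.linspace(0, 1, 100), (6, 1)))
        assert count_extreme_points(agg) == 0

    def test_full_sine_period_two_per_channel(self):
        t = np.arange(100) / 100
        agg = _agg(np.tile(np.sin(2 * np.pi * t), (6, 1)))
        assert count_extreme_points(agg) == 12

    def test_ripple_strictly_increases_count(self):
        t = np.arange(100) / 100
        base = np.sin(2 * np.pi * t)
        clean = _agg(np.tile(base, (6, 1)))
        rippled_data = np.tile(base, (6, 1)).copy()
        rippled_data[0] = base + 0.2 * np.sin(2 * np.pi * 12 * t)
        assert count_extreme_points(_agg(rippled_data)) > count_extreme_points(clean)

    def test_plateau_counts_once(self):
        x = np.array([0.0, 1.0, 1.0, 1.0, 0.0, -1.0, 0.0])
        assert count_extreme_points_channel(x) == 2

    def test_matches_oracle_on_random_input(self, rng):
        for _ in range(20):
            x = rng.standard_normal(50)
            assert count_extreme_points_channel(x) == oracle_extrema(list(x))


class TestHarmonicRatio:
    def test_pure_fundamental_zero(self):
        t = np.arange(100) / 100
        assert harmonic_ratio(np.cos(2 * np.pi * t)) == pytest.approx(0.0, abs=1e-9)

    def test_pure_second_harmonic_capped(self):
        t = np.arange(100) / 100
        with pytest.warns(UserWarning, match="capped"):
            assert harmonic_ratio(np.cos(4 * np.pi * t)) == 1e6

    def test_equal_first_two_harmonics_unity(self):
        t = np.arange(100) / 100
        x = np.cos(2 * np.pi * t) + np.cos(4 * np.pi * t)
        assert harmonic_ratio(x) == pytest.approx(1.0, abs=1e-9)

    def test_matches_dft_oracle(self, rng):
        x = rng.standard_normal(100)
        assert harmonic_ratio(x) == pytest.approx(oracle_harmonic_ratio(list(x)),
                                                  abs=1e-9)

    def test_planted_spectrum(self):
        # C1=2, C2=1, C3=0.5, C4=0.25: h = (1+0.25)/(2+0.5)
        t = np.arange(100) / 100
        x = (2 * np.cos(2 * np.pi * t) + np.cos(4 * np.pi * t)
             + 0.5 * np.cos(6 * np.pi * t) + 0.25 * np.cos(8 * np.pi * t))
        assert harmonic_ratio(x) == pytest.approx(1.25 / 2.5, abs=1e-9)

    def test_total_sums_waist_channels(self):
        t = np.arange(100) / 100
        data = np.tile(np.cos(2 * np.pi * t), (6, 1)).copy()
        i_siw = SIX_CHANNELS.index("SI-W")
        data[i_siw] = np.cos(2 * np.pi * t) + np.cos(4 * np.pi * t)  # h = 1
        assert harmonic_total(_agg(data)) == pytest.approx(1.0, abs=1e-9)

    def test_spectrum_non_negative(self, rng):
        assert np.all(harmonic_spectrum(rng.standard_normal(100)) >= 0)


class TestSymmetry:
    def test_half_stride_periodic_unity(self, rng):
        half = rng.standard_normal(50)
        x = np.concatenate([half, half])
        assert symmetry_channel(x) == pytest.approx(1.0, abs=0.02)

    def test_matches_bruteforce_oracle(self, rng):
        x = rng.standard_normal(100)
        assert symmetry_channel(x) == pytest.approx(oracle_symmetry(list(x)), abs=1e-9)

    def test_asymmetric_steps_lower_symmetry(self, rng):
        half = np.sin(2 * np.pi * np.arange(50) / 50) + 0.1 * rng.standard_normal(50)
        sym = np.concatenate([half, half])
        asym = np.concatenate([half, 0.5 * half])
        assert symmetry_channel(asym) < symmetry_channel(sym)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(100)
        assert symmetry_channel(7.3 * x) == pytest.approx(symmetry_channel(x),
                                                          abs=1e-9)

    def test_total_additivity_on_constructions(self, rng):
        half = np.sin(2 * np.pi * np.arange(50) / 50)
        periodic = np.concatenate([half, half])
        data = np.tile(periodic, (6, 1)).copy()
        s = symmetry_total(_agg(data))
        assert s == pytest.approx(2.0, abs=0.04)
        # replace AP-W with noise: S drops to ~1
        data[SIX_CHANNELS.index("AP-W")] = rng.standard_normal(100)
        s1 = symmetry_total(_agg(data))
        assert 0.7 < s1 < 1.5

    def test_autocorrelation_zero_energy_warns(self):
        with pytest.warns(UserWarning, match="zero-energy"):
            a = unbiased_autocorrelation(np.zeros(100))
        assert np.all(a == 0)


class TestFeatureVector:
    def test_identity_composition(self):
        """AGG == CGG from identical cycles, waist channels pure fundamental
        and step-periodic: (P, V, N, H, S) hits its ceiling values."""
        t = np.arange(100) / 100
        data = np.tile(np.cos(4 * np.pi * t), (6, 1)).copy()   # step-periodic
        i_si, i_ap = SIX_CHANNELS.index("SI-W"), SIX_CHANNELS.index("AP-W")
        # waist: fundamental + step harmonic, still half-stride dominated
        data[i_si] = np.cos(2 * np.pi * t)
        data[i_ap] = np.cos(2 * np.pi * t)
        agg = _agg(data)
        cycles = [NormalizedCycle(data=data.copy(), channels=SIX_CHANNELS)
                  for _ in range(3)]
        fv = feature_vector(agg, cycles, _cgg(data))
        assert fv.P == pytest.approx(6.0, abs=1e-12)
        assert fv.V == pytest.approx(0.0, abs=1e-12)
        assert fv.H == pytest.approx(0.0, abs=1e-9)  # pure fundamental waist
        n0 = count_extreme_points(agg)
        assert fv.N == n0

    def test_deterministic(self, rng):
        data = rng.standard_normal((6, 100))
        cycles = [NormalizedCycle(data=rng.standard_normal((6, 100)),
                                  channels=SIX_CHANNELS) for _ in range(3)]
        cgg = _cgg(rng.standard_normal((6, 100)))
        f1 = feature_vector(_agg(data), cycles, cgg)
        f2 = feature_vector(_agg(data), cycles, cgg)
        assert f1.to_array().tolist() == f2.to_array().tolist()

    def test_channel_mismatch_rejected(self, rng):
        from gaitscore.gait_graph import CharacteristicGaitGraph
        bad = CharacteristicGaitGraph(data=rng.standard_normal((6, 100)),
                                      channels=tuple(reversed(SIX_CHANNELS)))
        with pytest.raises(FeatureError):
            pearson_total(_agg(rng.standard_normal((6, 100))), bad)


class TestPathologyMonotonicity:
    def test_tremor_raises_n_lowers_p(self, cfg, healthy_reference):
        """Two otherwise-identical subjects, one with injected tremor."""
        import gaitscore as gs
        cgg = healthy_reference["cgg"]
        base = gs.SyntheticGaitProfile(seed=3)
        trem = gs.SyntheticGaitProfile(seed=3, tremor_amp=0.3)
        t_base = gs.run_extract(gs.generate_recording(base), cgg, cfg)
        t_trem = gs.run_extract(gs.generate_recording(trem), cgg, cfg)
        assert t_trem["N"].mean() > t_base["N"].mean()
        assert t_trem["P"].mean() < t_base["P"].mean()

    def test_asymmetry_lowers_s(self, cfg, healthy_reference):
        import gaitscore as gs
        cgg = healthy_reference["cgg"]
        sym = gs.SyntheticGaitProfile(seed=5)
        asym = gs.SyntheticGaitProfile(seed=5, asymmetry=0.5)
        t_sym = gs.run_extract(gs.generate_recording(sym), cgg, cfg)
        t_asym = gs.run_extract(gs.generate_recording(asym), cgg, cfg)
        assert t_asym["S"].mean() < t_sym["S"].mean()
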