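"""Separability statistics, thresholds, ensemble regions, normality check."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from shrubspec import (SpectralLibrary, classify_value, ensemble_regions,
                       normality_diagnostic, pairwise_metrics,
                       separability_profile)
from shrubspec.separability import ZeroVarianceError

from conftest import make_spectrum


def bhattacharyya_quadrature(m1, s1, m2, s2):
    """Independent oracle: -ln of the Bhattacharyya coefficient by quadrature.

    sqrt(p1 p2) is itself Gaussian-shaped; the window is centred on its
    peak so tiny overlaps between distant distributions are resolved.
    """
    f = lambda x: np.sqrt(stats.norm.pdf(x, m1, s1) * stats.norm.pdf(x, m2, s2))
    w1, w2 = 1.0 / s1 ** 2, 1.0 / s2 ** 2
    peak = (m1 * w1 + m2 * w2) / (w1 + w2)
    width = 1.0 / np.sqrt((w1 + w2) / 2.0)
    val, _ = integrate.quad(f, peak - 14 * width, peak + 14 * width,
                            limit=300, epsabs=0, epsrel=1e-12)
    return -np.log(val)


def divergence_quadrature(m1, s1, m2, s2):
    """Independent oracle: symmetric KL divergence by quadrature.

    Log-densities are evaluated analytically so tails never hit log(0).
    """
    def f(x):
        lp = -0.5 * ((x - m1) / s1) ** 2 - np.log(s1 * np.sqrt(2 * np.pi))
        lq = -0.5 * ((x - m2) / s2) ** 2 - np.log(s2 * np.sqrt(2 * np.pi))
        return (np.exp(lp) - np.exp(lq)) * (lp - lq)
    lo = min(m1 - 14 * s1, m2 - 14 * s2)
    hi = max(m1 + 14 * s1, m2 + 14 * s2)
    val, _ = integrate.quad(f, lo, hi, limit=500, epsabs=0, epsrel=1e-11)
    return val


def single(mu1, sd1, mu2, sd2):
    return {k: float(v[0]) for k, v in pairwise_metrics(mu1, sd1, mu2, sd2).items()}


class TestPairwiseMetrics:
    def test_identical_distributions_give_zero(self):
        m = single(0.4, 0.1, 0.4, 0.1)
        assert all(v == 0.0 for v in m.values())

    def test_unit_shift_frozen_values(self):
        # oracle values pre-computed by quadrature of the Bhattacharyya
        # coefficient and of the symmetric KL divergence for N(0,1) vs N(1,1)
        m = single(0.0, 1.0, 1.0, 1.0)
        assert m["M"] == pytest.approx(0.5)
        assert m["B"] == pytest.approx(0.125, abs=1e-12)
        assert m["D"] == pytest.approx(1.0, abs=1e-12)
        assert m["TD"] == pytest.approx(2 * (1 - np.exp(-0.125)), abs=1e-12)
        assert m["JM"] == pytest.approx(m["TD"], abs=1e-12)
        assert m["TD"] == pytest.approx(0.2350, abs=1e-4)

    def test_unequal_variance_frozen_values(self):
        m = single(0.0, 1.0, 0.0, 2.0)
        assert m["M"] == 0.0
        assert m["D"] == pytest.approx(1.125, abs=1e-12)
        assert m["B"] == pytest.approx(0.5 * np.log(1.25), abs=1e-12)
        assert m["B"] == pytest.approx(0.1116, abs=1e-4)

    def test_matches_quadrature_oracles(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            m1, m2 = rng.normal(0, 2, 2)
            s1, s2 = rng.uniform(0.2, 3.0, 2)
            m = single(m1, s1, m2, s2)
            assert m["B"] == pytest.approx(
                bhattacharyya_quadrature(m1, s1, m2, s2), abs=1e-8)
            assert m["D"] == pytest.approx(
                divergence_quadrature(m1, s1, m2, s2), rel=1e-7, abs=1e-9)

    def test_equal_variance_identity_td_equals_jm(self):
        rng = np.random.default_rng(1)
        mu1, mu2 = rng.normal(0, 1, 200), rng.normal(0, 1, 200)
        sd = rng.uniform(0.1, 2.0, 200)
        m = pairwise_metrics(mu1, sd, mu2, sd)
        assert np.allclose(m["D"], 8 * m["B"], atol=1e-12)
        assert np.allclose(m["TD"], m["JM"], atol=1e-12)

    def test_monotone_in_mean_separation(self):
        deltas = np.linspace(0.0, 10.0, 50)
        m = pairwise_metrics(np.zeros(50), np.ones(50), deltas, np.ones(50))
        for key in ("M", "B", "D", "TD", "JM"):
            assert np.all(np.diff(m[key]) > 0), key

    def test_bounds_and_saturation(self):
        # strictly below 2 while resolvable; saturates to 2.0 in float64
        m = single(0.0, 1.0, 5.0, 1.0)
        assert m["TD"] < 2.0 and m["JM"] < 2.0
        m = single(0.0, 1.0, 20.0, 1.0)  # |dmu|/sigma = 20
        assert m["TD"] <= 2.0 and m["JM"] <= 2.0
        assert m["TD"] > 1.999 and m["JM"] > 1.999

    def test_symmetric_under_group_swap(self):
        a = single(0.1, 0.5, 0.9, 1.5)
        b = single(0.9, 1.5, 0.1, 0.5)
        assert a == b

    def test_zero_variance_raises(self):
        with pytest.raises(ZeroVarianceError):
            pairwise_metrics(0.0, 0.0, 1.0, 1.0)


class TestSeparabilityProfile:
    def _lib(self, grid, offsets, season="spring", prefix="A"):
        rng = np.random.default_rng(99)
        return SpectralLibrary(
            make_spectrum(grid, np.clip(0.3 + off + rng.normal(0, 0.01, len(grid)), 0, 1),
                          quadrat=f"{prefix}{i}", season=season)
            for i, off in enumerate(offsets))

    def test_group_vs_itself_is_zero(self, tiny_grid):
        lib = self._lib(tiny_grid, [0.0, 0.01, -0.01])
        prof = separability_profile(lib, lib)
        assert np.allclose(prof[["M", "B", "D", "TD", "JM"]].to_numpy(), 0.0)

    def test_group_too_small_rejected(self, tiny_grid):
        one = self._lib(tiny_grid, [0.0])
        two = self._lib(tiny_grid, [0.0, 0.1], prefix="B")
        with pytest.raises(ValueError, match="at least 2"):
            separability_profile(one, two)

    def test_difference_only_in_masked_window_invisible(self, default_grid):
        from shrubspec.spectra import mask_library
        rng = np.random.default_rng(5)
        wl = default_grid.wavelengths
        in_window = (wl >= 1750) & (wl <= 1980)
        base = 0.3 + rng.normal(0, 0.005, (4, len(wl)))
        other = base.copy()
        other[:, in_window] += 0.3  # big contrast, but inside a water window
        lib_a = SpectralLibrary(
            make_spectrum(default_grid, np.clip(base[i], 0, 1), quadrat=f"A{i}")
            for i in range(4))
        lib_b = SpectralLibrary(
            make_spectrum(default_grid, np.clip(other[i], 0, 1), quadrat=f"B{i}")
            for i in range(4))
        prof = separability_profile(mask_library(lib_a), mask_library(lib_b))
        # same noise realisation outside the window -> exact zeros there
        assert np.allclose(prof[["M", "B", "D", "TD", "JM"]].to_numpy(), 0.0)
        assert not np.isin(prof["wavelength_nm"], wl[in_window]).any()

    def test_variance_floor_rescues_degenerate_groups(self, tiny_grid):
        lib_a = SpectralLibrary([make_spectrum(tiny_grid, 0.2, quadrat="A0"),
                                 make_spectrum(tiny_grid, 0.2, quadrat="A1")])
        lib_b = SpectralLibrary([make_spectrum(tiny_grid, 0.6, quadrat="B0"),
                                 make_spectrum(tiny_grid, 0.6, quadrat="B1")])
        with pytest.raises(ZeroVarianceError):
            separability_profile(lib_a, lib_b)
        prof = separability_profile(lib_a, lib_b, variance_floor=1e-8)
        assert (prof["TD"] > 1.999).all()


class TestClassification:
    @pytest.mark.parametrize("metric,value,expected", [
        ("TD", 1.85, "good"), ("TD", 2.0, "good"), ("TD", 1.8, "good"),
        ("JM", 1.6, "moderate"), ("TD", 1.79, "moderate"),
        ("TD", 1.5, "poor"), ("JM", 0.2, "poor"),
        ("M", 1.01, "good"), ("M", 0.99, "poor"), ("M", 1.0, "poor"),
    ])
    def test_threshold_rules(self, metric, value, expected):
        assert classify_value(metric, value) == expected

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="threshold rule"):
            classify_value("XYZ", 1.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_value("TD", float("nan"))


def profile_from(wl, td, jm):
    return pd.DataFrame({"wavelength_nm": wl, "TD": td, "JM": jm})


class TestEnsembleRegions:
    def test_all_poor_gives_empty_list(self):
        wl = np.arange(400.0, 500.0)
        prof = profile_from(wl, np.full(100, 1.2), np.full(100, 1.2))
        assert ensemble_regions(prof) == []

    def test_good_region_extraction(self):
        # layout mirrors a summer NIR window: both metrics good over 718-979
        wl = np.arange(700.0, 1000.0)
        good = (wl >= 718) & (wl <= 979)
        td = np.where(good, 1.9, 1.0)
        jm = np.where(good, 1.85, 1.0)
        regions = ensemble_regions(profile_from(wl, td, jm))
        assert len(regions) == 1
        r = regions[0]
        assert (r.low_nm, r.high_nm, r.klass) == (718.0, 979.0, "good")
        assert r.width_nm == 262.0

    def test_requires_both_metrics_good(self):
        wl = np.arange(700.0, 800.0)
        td = np.full(100, 1.9)
        jm = np.full(100, 1.6)  # only moderate
        regions = ensemble_regions(profile_from(wl, td, jm))
        assert [r.klass for r in regions] == ["moderate"]

    def test_narrow_run_dropped(self):
        wl = np.arange(700.0, 800.0)
        td = np.full(100, 1.0)
        jm = np.full(100, 1.0)
        td[10:18] = jm[10:18] = 1.95  # 8 nm run < 10 nm
        assert ensemble_regions(profile_from(wl, td, jm)) == []

    def test_runs_break_at_masked_gap(self):
        wl = np.concatenate([np.arange(1300.0, 1350.0), np.arange(1431.0, 1481.0)])
        td = np.full(100, 1.9)
        jm = np.full(100, 1.9)
        regions = ensemble_regions(profile_from(wl, td, jm))
        assert [(r.low_nm, r.high_nm) for r in regions] == [
            (1300.0, 1349.0), (1431.0, 1480.0)]

    def test_td_fallback_when_jm_saturates_low(self):
        wl = np.arange(700.0, 800.0)
        td = np.full(100, 1.9)
        jm = np.full(100, 1.4)  # JM finds nothing anywhere
        assert ensemble_regions(profile_from(wl, td, jm)) == []
        regions = ensemble_regions(profile_from(wl, td, jm), td_fallback=True)
        assert len(regions) == 1 and regions[0].metric_basis == "TD"


class TestNormalityDiagnostic:
    def test_normal_group_passes_at_nominal_rate(self):
        rng = np.random.default_rng(2024)
        X = rng.normal(0.4, 0.05, size=(30, 400))
        d = normality_diagnostic(X)
        assert d.attrs["pass_fraction"] == pytest.approx(0.95, abs=0.03)

    def test_heavy_tails_fail_more(self):
        rng = np.random.default_rng(2024)
        X = rng.standard_t(df=2, size=(30, 300))
        d = normality_diagnostic(X)
        assert d.attrs["pass_fraction"] < 0.75

    def test_constant_column_reported_as_undefined(self):
        X = np.column_stack([np.full(10, 0.3), np.random.default_rng(0).normal(size=10)])
        d = normality_diagnostic(X)
        assert not d["passed"].iloc[0]
        assert "zero variance" in d["reason"].iloc[0]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            normality_diagnostic(np.zeros((2, 5)))
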