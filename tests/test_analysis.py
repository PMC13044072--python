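"""Classification, band power, scheme comparison, environmental alignment,
and geometric-ratio estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import geobands as gb
from geobands.scheme import DomainError


class TestClassify:
    @pytest.mark.parametrize(
        "f, label",
        [(9.0, "alpha1"), (10.5, "alpha2"), (25.0, "gamma1"),
         (2.0, "delta"), (100.0, "gamma2")],
    )
    def test_default_scheme_labels(self, default_scheme, f, label):
        assert gb.classify_frequency(f, default_scheme) == label

    def test_boundary_belongs_to_upper_band(self, default_scheme):
        cut = default_scheme.bands[1].upper  # theta/alpha1
        assert gb.classify_frequency(cut, default_scheme) == "alpha1"
        assert gb.classify_frequency(cut - 1e-9, default_scheme) == "theta"

    def test_rejects_nonpositive(self, default_scheme):
        with pytest.raises(DomainError):
            gb.classify_frequency(0.0, default_scheme)

    def test_agrees_with_brute_force_scan(self, default_scheme):
        rng = np.random.default_rng(11)
        cuts = [b.upper for b in default_scheme.bands[:-1]]
        labels = default_scheme.labels()
        for f in rng.uniform(0.01, 200.0, 10_000):
            k = int(np.searchsorted(cuts, f, side="right"))
            assert gb.classify_frequency(f, default_scheme) == labels[k]


class TestBandPower:
    def test_flat_psd_power_equals_bandwidth(self, flat_psd, default_scheme):
        bp = gb.band_power(flat_psd, default_scheme)
        for _, row in bp.iterrows():
            assert row.absolute_power == pytest.approx(
                row.upper - row.lower, rel=1e-9
            )

    def test_relative_powers_sum_to_one(self, alpha_peak_psd, default_scheme):
        bp = gb.band_power(alpha_peak_psd, default_scheme)
        assert bp.relative_power.sum() == pytest.approx(1.0, abs=1e-9)

    def test_conservation_against_total(self, alpha_peak_psd, default_scheme):
        bp = gb.band_power(alpha_peak_psd, default_scheme)
        assert bp.absolute_power.sum() == pytest.approx(
            alpha_peak_psd.total_power(), rel=1e-9
        )

    def test_narrow_peak_lands_in_gamma1(self, default_scheme):
        spec = gb.SynthSpec(
            background_amp=0.5, background_exp=0.3,
            peaks=((30.0, 40.0, 0.8),), noise_sd=0.0,
            grid=(1.0, 45.0, 441), seed=0,
        )
        psd = gb.synth_psd(spec)
        bp = gb.band_power(psd, default_scheme).set_index("label")
        assert bp.relative_power.idxmax() == "gamma1"
        # independent oracle: dense numerical integration over gamma1
        g1 = default_scheme.classify(30.0)
        f_dense = np.linspace(g1.lower, min(g1.upper, 45.0), 20_001)
        dense = np.trapezoid(np.interp(f_dense, psd.freqs, psd.power), f_dense)
        assert bp.loc["gamma1", "absolute_power"] == pytest.approx(dense, rel=1e-4)

    def test_f_max_cap_truncates_open_band(self, flat_psd, default_scheme):
        bp = gb.band_power(flat_psd, default_scheme, f_max_cap=35.0)
        assert bp.set_index("label").loc["gamma2", "absolute_power"] == 0.0

    def test_disjoint_support_rejected(self, default_scheme):
        freqs = np.linspace(200.0, 300.0, 50)
        psd = gb.PSDTable(freqs=freqs, power=np.ones(50))
        with pytest.raises(DomainError):
            gb.band_power(psd, gb.traditional_scheme())


class TestCompareSchemes:
    def test_beta_narrower_under_geometric_scheme(
        self, flat_psd, default_scheme, traditional_scheme
    ):
        cmp = gb.compare_schemes(flat_psd, default_scheme, traditional_scheme)
        beta = cmp.set_index("label").loc["beta"]
        # geometric beta spans ~13.80-23.84 Hz vs traditional 13-30 Hz
        assert beta.relative_power_a < beta.relative_power_b
        assert beta.relative_power_diff < 0

    def test_identical_schemes_give_zero_differences(self, flat_psd, default_scheme):
        cmp = gb.compare_schemes(flat_psd, default_scheme, default_scheme)
        assert (cmp.relative_power_diff == 0).all()

    def test_unmatched_labels_reported_one_sided(
        self, flat_psd, default_scheme, traditional_scheme
    ):
        cmp = gb.compare_schemes(flat_psd, default_scheme, traditional_scheme)
        row = cmp.set_index("label").loc["gamma"]  # traditional-only label
        assert np.isnan(row.relative_power_a) and not np.isnan(row.relative_power_b)

    def test_27hz_reclassified_beta_to_gamma(self, default_scheme, traditional_scheme):
        assert gb.classify_frequency(27.0, traditional_scheme) == "beta"
        assert gb.classify_frequency(27.0, default_scheme) == "gamma1"


class TestAlignment:
    def test_headline_under_tabulated_protocol(self, paper_scheme):
        rep = gb.schumann_alignment(paper_scheme)
        assert rep.theta_alpha_deviation < 2.0
        assert rep.theta_alpha_deviation == pytest.approx(1.96, abs=0.01)

    def test_full_precision_headline_documented_value(self, default_scheme):
        # at strict full precision the boundary is 7.9888 Hz -> 2.03%
        rep = gb.schumann_alignment(default_scheme)
        assert rep.theta_alpha_boundary == pytest.approx(7.9888, abs=5e-4)
        assert rep.theta_alpha_deviation == pytest.approx(2.03, abs=0.01)

    def test_exact_feature_gives_zero_deviation(self, default_scheme):
        cut = default_scheme.bands[1].upper
        rep = gb.schumann_alignment(default_scheme, [cut])
        assert rep.rows[0].percent_deviation == 0.0

    def test_second_mode_vs_alpha_beta_boundary(self, default_scheme):
        rep = gb.schumann_alignment(default_scheme, [14.1])
        row = rep.rows[0]
        # hand oracle: 100*|13.8006 - 14.1|/14.1
        assert row.feature_freq == pytest.approx(13.8006, abs=5e-4)
        assert row.percent_deviation == pytest.approx(
            100 * abs(13.800611 - 14.1) / 14.1, abs=1e-3
        )

    def test_nearest_feature_minimizes_deviation(self, default_scheme):
        feats = [f for _, _, f in default_scheme.features()]
        for mode in gb.SCHUMANN_MODES:
            rep = gb.schumann_alignment(default_scheme, [mode])
            best = min(abs(f - mode) for f in feats)
            assert abs(rep.rows[0].feature_freq - mode) == pytest.approx(best)

    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_rescaling_invariance(self, s):
        scheme = gb.build_scheme()
        base = gb.schumann_alignment(scheme, list(gb.SCHUMANN_MODES))
        scaled = gb.schumann_alignment(
            scheme.scaled(s), [m * s for m in gb.SCHUMANN_MODES]
        )
        for r1, r2 in zip(base.rows, scaled.rows):
            assert r1.percent_deviation == pytest.approx(
                r2.percent_deviation, rel=1e-9, abs=1e-9
            )

    def test_empty_modes_rejected(self, default_scheme):
        with pytest.raises(gb.ConfigurationError):
            gb.schumann_alignment(default_scheme, [])


class TestClassicalDeviation:
    def test_about_six_percent_below_fundamental(self):
        assert round(gb.classical_deviation(10.5, 7.83)) == 6

    def test_zero_when_center_matches_mode(self):
        mode = 7.83
        assert gb.classical_deviation(mode * 10 / 7, mode) == pytest.approx(0.0, abs=1e-9)
        assert gb.classical_deviation(10.5, 7.35) == pytest.approx(0.0, abs=1e-9)

    def test_sign_convention(self):
        # classical theta center above the mode -> negative deviation
        assert gb.classical_deviation(12.0, 7.83) < 0


class TestRatioFit:
    def test_exact_progression_recovers_ratio(self):
        peaks = [10.5 * 1.7275**n for n in range(-2, 3)]
        fit = gb.estimate_geometric_ratio(peaks)
        assert fit.R_hat == pytest.approx(1.7275, abs=1e-6)
        assert fit.residual_rms < 1e-9
        assert fit.f_ref_hat == pytest.approx(10.5, rel=1e-6)

    def test_index_assignment_consecutive(self):
        peaks = [10.5 * 1.7275**n for n in range(-2, 3)]
        fit = gb.estimate_geometric_ratio(peaks)
        ns = [fit.index_assignment[f] for f in sorted(fit.index_assignment)]
        assert np.all(np.diff(ns) == 1)

    def test_jittered_recovery_median_within_one_percent(self):
        rng = np.random.default_rng(99)
        errors = []
        for _ in range(100):
            jitter = rng.uniform(0.98, 1.02, size=5)
            peaks = [10.5 * 1.7275**n * j for n, j in zip(range(-2, 3), jitter)]
            fit = gb.estimate_geometric_ratio(peaks)
            errors.append(abs(fit.R_hat - 1.7275) / 1.7275)
        assert np.median(errors) < 0.01

    def test_arithmetic_progression_fits_worse(self):
        geo = [5.0 * 1.7275**n for n in range(4)]
        arith = [5.0, 10.0, 15.0, 20.0]
        assert (
            gb.estimate_geometric_ratio(arith).residual_rms
            > gb.estimate_geometric_ratio(geo).residual_rms
        )

    def test_too_few_or_degenerate_peaks_rejected(self):
        with pytest.raises(DomainError):
            gb.estimate_geometric_ratio([10.0])
        with pytest.raises(DomainError):
            gb.estimate_geometric_ratio([10.0, 10.0])

    def test_accepts_peakset(self, alpha_peak_psd):
        spec = gb.SynthSpec(
            background_amp=10.0, background_exp=1.0,
            peaks=tuple((10.5 * 1.7275**n, 40.0 * 10.5 * 1.7275**-n, 0.6)
                        for n in (-1, 0, 1)),
            noise_sd=0.0, grid=(1.0, 45.0, 881), seed=3,
        )
        peaks = gb.detect_peaks(gb.synth_psd(spec))
        fit = gb.estimate_geometric_ratio(peaks)
        assert fit.R_hat == pytest.approx(1.7275, rel=0.01)
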