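"""Two-state model, curve fits, Tm-plot analysis and concentration estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psimelt import (
    Baselines,
    MeltCurve,
    MeltFitError,
    Strand,
    TwoStateParams,
    analyze_dataset,
    average_curve_fits,
    fit_curve,
    fit_tm_plot,
    fraction_paired,
    gibbs_at,
    melting_temperature,
    simulate_curve,
    strand_concentration,
    two_state_consistency,
)
from psimelt.extinction import extinction_nn
from psimelt.melt import CELSIUS_OFFSET, R_KCAL, equilibrium_constant
from psimelt.synthetic import DEFAULT_BASELINES, SyntheticSpec, generate_dataset

CORE = TwoStateParams(-77.6, -217.1)


class TestGibbs:
    @pytest.mark.parametrize("dh,ds,expected", [
        (-77.6, -217.1, -10.27),   # prints as 10.26 from pre-rounding inputs
        (-104.9, -291.6, -14.46),  # prints as 14.44
    ])
    def test_printed_rows(self, dh, ds, expected):
        assert gibbs_at(TwoStateParams(dh, ds), 310.15) == pytest.approx(expected, abs=0.005)

    def test_zero_entropy(self):
        p = TwoStateParams(-50.0, 0.0)
        for t in (273.15, 310.15, 360.0):
            assert gibbs_at(p, t) == -50.0

    def test_compensation_enforced(self):
        with pytest.raises(ValueError):
            TwoStateParams(-80.0, 220.0)


class TestFractionPaired:
    def test_half_paired_exactly_at_tm(self):
        for ct in (1e-6, 1e-4, 1e-3):
            tm_k = melting_temperature(CORE, ct) + CELSIUS_OFFSET
            assert fraction_paired(CORE, ct, tm_k) == pytest.approx(0.5, abs=1e-9)

    def test_limits(self):
        assert fraction_paired(CORE, 1e-4, 273.15) > 0.999
        assert fraction_paired(CORE, 1e-4, 372.0) < 1e-3

    def test_matches_bisection_oracle(self):
        """Closed form vs brute-force bisection of K = 2α/((1−α)²CT)."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = TwoStateParams(-rng.uniform(40, 120), -rng.uniform(120, 330))
            ct = 10 ** rng.uniform(-6, -3)
            t_k = rng.uniform(270, 370)
            k = float(equilibrium_constant(p, t_k))
            lo, hi = 0.0, 1.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                # mass balance in product form: K(1−α)²CT − 2α changes sign at the root
                if k * (1 - mid) ** 2 * ct > 2 * mid:
                    lo = mid
                else:
                    hi = mid
            assert fraction_paired(p, ct, t_k) == pytest.approx(0.5 * (lo + hi), abs=1e-10)

    @settings(max_examples=60, derandomize=True)
    @given(
        st.floats(min_value=-120, max_value=-40),
        st.floats(min_value=-330, max_value=-130),
        st.floats(min_value=-6, max_value=-3),
    )
    def test_monotone_decreasing_and_half_at_tm(self, dh, ds, log_ct):
        p = TwoStateParams(dh, ds)
        ct = 10.0 ** log_ct
        grid = np.linspace(270.0, 380.0, 111)
        alpha = fraction_paired(p, ct, grid)
        # non-increasing up to float rounding; strictly decreasing away from saturation
        assert np.all(np.diff(alpha) <= 1e-12)
        interior = (alpha[:-1] < 1 - 1e-12) & (alpha[1:] > 1e-12)
        assert np.all(np.diff(alpha)[interior] < 0)
        try:
            tm_k = melting_temperature(p, ct) + CELSIUS_OFFSET
        except ValueError:
            return
        assert fraction_paired(p, ct, tm_k) == pytest.approx(0.5, abs=1e-9)


class TestMeltingTemperature:
    def test_core_duplex_printed_tm(self):
        assert melting_temperature(CORE, 1e-4) == pytest.approx(52.7, abs=0.05)

    def test_log_term_vanishes_at_ct_4(self):
        p = TwoStateParams(-80.0, -220.0)
        assert melting_temperature(p, 4.0) + CELSIUS_OFFSET == pytest.approx(
            p.dh / (p.ds / 1000.0), abs=1e-9
        )

    def test_nonphysical_rejected(self):
        with pytest.raises(ValueError):
            # entropic term overwhelms ΔH° at absurd concentration: T ≤ 0 K
            melting_temperature(TwoStateParams(-80.0, -20.0), 1e6)
        with pytest.raises(ValueError):
            melting_temperature(CORE, 0.0)


class TestSimulate:
    def test_normalized_curve_is_one_minus_alpha(self):
        grid = np.arange(0.0, 90.0, 1.0)
        c = simulate_curve(CORE, 1e-4, Baselines(0, 0, 0, 1.0), grid)
        alpha = fraction_paired(CORE, 1e-4, grid + CELSIUS_OFFSET)
        assert np.allclose(c.absorbances, 1.0 - alpha)
        assert np.all(np.diff(c.absorbances) > 0)

    def test_midpoint_of_baselines_at_tm(self):
        tm = melting_temperature(CORE, 1e-4)
        bl = DEFAULT_BASELINES
        c = simulate_curve(CORE, 1e-4, bl, np.array([tm - 1e-6, tm, tm + 1e-6]))
        mid = 0.5 * (bl.double(np.array([tm])) + bl.single(np.array([tm])))[0]
        assert c.absorbances[1] == pytest.approx(mid, abs=1e-6)

    def test_derivative_max_near_but_above_tm(self):
        """For a bimolecular melt the derivative maximum sits ~1 °C above the
        α = 1/2 point — close, but systematically offset, which is why Tm
        extraction uses the fitted α = 1/2 point rather than the peak."""
        grid = np.arange(0.0, 90.0, 0.02)
        c = simulate_curve(CORE, 1e-4, Baselines(0, 0, 0, 1.0), grid)
        tm = melting_temperature(CORE, 1e-4)
        t_star = grid[np.argmax(np.gradient(c.absorbances, grid))]
        assert tm < t_star < tm + 2.0


class TestFitCurve:
    def test_noiseless_roundtrip_recovers_parameters(self):
        grid = np.arange(0.0, 91.0, 1.0)
        c = simulate_curve(CORE, 1e-4, DEFAULT_BASELINES, grid)
        fit = fit_curve(c)
        assert abs(fit.dh.value - CORE.dh) / abs(CORE.dh) < 1e-3
        assert abs(fit.ds.value - CORE.ds) / abs(CORE.ds) < 1e-3
        assert fit.dg37.value == pytest.approx(gibbs_at(CORE, 310.15), abs=1e-3)

    def test_noisy_recovery_within_five_percent(self):
        grid = np.arange(0.0, 91.0, 1.0)
        clean = simulate_curve(CORE, 1e-4, DEFAULT_BASELINES, grid)
        rng = np.random.default_rng(7)
        amplitude = clean.absorbances.max() - clean.absorbances.min()
        noisy = MeltCurve(
            grid, clean.absorbances + rng.normal(0, 0.002 * amplitude, len(grid)),
            1e-4,
        )
        fit = fit_curve(noisy)
        assert abs(fit.dh.value - CORE.dh) / abs(CORE.dh) < 0.05

    def test_dg37_identity_between_fields(self):
        grid = np.arange(0.0, 91.0, 1.0)
        fit = fit_curve(simulate_curve(CORE, 1e-4, DEFAULT_BASELINES, grid))
        assert fit.dg37.value == pytest.approx(
            fit.dh.value - 310.15 * fit.ds.value / 1000.0, abs=1e-12
        )

    def test_flat_and_linear_inputs_rejected(self):
        grid = np.arange(0.0, 90.0, 1.0)
        with pytest.raises(MeltFitError, match="no transition"):
            fit_curve(MeltCurve(grid, np.ones_like(grid), 1e-4))
        with pytest.raises(MeltFitError, match="no transition"):
            fit_curve(MeltCurve(grid, 1.0 + 0.002 * grid, 1e-4))


class TestTmPlot:
    def test_exact_on_noiseless_points(self):
        cts = np.geomspace(1e-6, 1e-3, 9)
        pts = [(ct, melting_temperature(CORE, ct) + CELSIUS_OFFSET) for ct in cts]
        fit = fit_tm_plot(pts)
        assert fit.dh.value == pytest.approx(CORE.dh, rel=1e-9)
        assert fit.ds.value == pytest.approx(CORE.ds, rel=1e-9)
        assert fit.tm_1e4_c == pytest.approx(52.7, abs=0.05)

    def test_noisy_points_recovered_within_reported_sd(self):
        rng = np.random.default_rng(11)
        cts = np.geomspace(1e-6, 1e-3, 9)
        pts = [
            (ct, melting_temperature(CORE, ct) + CELSIUS_OFFSET + rng.normal(0, 0.08))
            for ct in cts
        ]
        fit = fit_tm_plot(pts)
        assert abs(fit.dh.value - CORE.dh) < 3 * fit.dh.sd
        assert fit.dg37.sd < fit.dh.sd  # ΔH/ΔS compensation shrinks ΔG° error

    def test_degenerate_inputs_rejected(self):
        tm = melting_temperature(CORE, 1e-4) + CELSIUS_OFFSET
        with pytest.raises(ValueError):
            fit_tm_plot([(1e-6, 330.0), (1e-5, 331.0)])
        with pytest.raises(ValueError):
            fit_tm_plot([(1e-4, tm), (1e-4, tm), (1e-4, tm)])
        with pytest.raises(ValueError):
            fit_tm_plot([(1e-6, tm), (1e-5, tm), (1e-4, tm)])  # zero slope


class TestTwoStateConsistency:
    def test_printed_first_row(self):
        rel, ok = two_state_consistency(-78.5, -71.7)
        assert rel == pytest.approx(0.091, abs=0.002)
        assert ok

    def test_equal_inputs(self):
        assert two_state_consistency(-80.0, -80.0) == (0.0, True)

    def test_footnote_duplex_flagged(self):
        rel, ok = two_state_consistency(-105.9, -76.8)
        assert rel == pytest.approx(0.319, abs=0.002)
        assert not ok

    def test_sign_mismatch_rejected(self):
        with pytest.raises(ValueError):
            two_state_consistency(-80.0, 80.0)


class TestDatasetAnalysis:
    def test_routes_agree_on_synthetic_two_state_data(self):
        res = analyze_dataset(generate_dataset(SyntheticSpec(seed=5)))
        assert res.two_state
        assert res.rel_dh_difference < 0.15
        assert res.curve_average.method == "curve_average"
        assert res.tm_plot.method == "tm_plot"

    def test_average_requires_fits(self):
        with pytest.raises(ValueError):
            average_curve_fits([])


class TestStrandConcentration:
    def test_mononucleotide_base_case(self):
        assert extinction_nn(Strand("A")) == 15400.0
        assert strand_concentration(0.154, Strand("A")) == pytest.approx(1e-5)

    def test_nine_mer_magnitude_realistic(self):
        eps = extinction_nn(Strand("PCAGUCAGU"))
        assert 70000 < eps < 110000  # per-strand ε260 of a 9-mer

    def test_psi_as_u_bias_is_about_two_percent(self):
        """Assigning Ψ the ε of U (vs its ~20% smaller true value) biases the
        concentration of a one-Ψ 9-mer by ≈2%."""
        s = Strand("PCAGUCAGU")
        eps_u = extinction_nn(s)
        eps_psi = extinction_nn(s, overrides={"P": 0.8 * 9900.0})
        shift = eps_u / eps_psi - 1.0
        assert shift == pytest.approx(0.022, abs=0.005)
        # and the same for an internal Ψ
        s2 = Strand("UCAGPCAGU")
        shift2 = extinction_nn(s2) / extinction_nn(s2, overrides={"P": 0.8 * 9900.0}) - 1
        assert shift2 == pytest.approx(0.022, abs=0.005)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            strand_concentration(0.0, Strand("A"))
        with pytest.raises(ValueError):
            strand_concentration(0.1, Strand("A"), pathlength_cm=0.0)
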