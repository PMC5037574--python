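"""Critical |r| cutoff, back-scaled loadings, correlations, metabolite calls."""

import numpy as np
import pandas as pd
import pytest

from metabodisc.biomarker import (
    backscale_loadings,
    call_metabolites,
    coefficient_table,
    correlation_coefficients,
    critical_r,
    render_coefficient_plot,
)
from metabodisc.opls import encode_labels, fit_oplsda, pareto_scale
from metabodisc.pipeline import RunConfig, run_pipeline
from metabodisc.preprocess import BinningConfig
from metabodisc.simulate import CohortScenario, MetaboliteSpec


class TestCriticalR:
    def test_reproduces_printed_cutoff_at_n10(self):
        """n=10 replicates, alpha=0.05 -> the conventional 0.602 cutoff."""
        assert critical_r(10, 0.05) == pytest.approx(0.602, abs=5e-4)

    def test_n3_hand_computed(self):
        # t(0.975, df=2) = 4.30265; 4.30265/sqrt(4.30265^2 + 2) = 0.950
        assert critical_r(3, 0.05) == pytest.approx(0.950, abs=5e-4)

    def test_strictly_decreasing_in_n(self):
        vals = [critical_r(n) for n in range(3, 200, 7)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert critical_r(100000) < 0.01

    def test_smaller_alpha_larger_cutoff(self):
        assert critical_r(10, 0.01) > critical_r(10, 0.05)

    def test_df_override_conventional(self):
        # df = n_total - 2 = 18 gives the textbook two-sample cutoff (~0.444)
        assert critical_r(10, 0.05, df=18) == pytest.approx(0.444, abs=5e-4)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            critical_r(2)


class TestCorrelationCoefficients:
    def test_agrees_with_two_pass_pearson_oracle(self, rng):
        X = rng.normal(size=(15, 40))
        t = rng.normal(size=15)
        r, _ = correlation_coefficients(X, t)
        oracle = np.array([np.corrcoef(X[:, j], t)[0, 1] for j in range(40)])
        assert np.allclose(r, oracle, atol=1e-10)

    def test_column_equal_to_target_r_one(self, rng):
        t = rng.normal(size=10)
        X = np.column_stack([t, -t])
        r, _ = correlation_coefficients(X, t)
        assert r[0] == pytest.approx(1.0, abs=1e-12)
        assert r[1] == pytest.approx(-1.0, abs=1e-12)

    def test_constant_column_zero_and_flagged(self, rng):
        X = np.column_stack([np.full(10, 3.0), rng.normal(size=10)])
        r, const = correlation_coefficients(X, rng.normal(size=10))
        assert r[0] == 0.0
        assert const[0] and not const[1]

    def test_white_noise_rarely_exceeds_cutoff(self):
        """Null |r| at n=20 stays under 0.602 in >= 95% of replicates."""
        rng = np.random.default_rng(123)
        t = rng.normal(size=20)
        X = rng.normal(size=(20, 1000))
        r, _ = correlation_coefficients(X, t)
        assert (np.abs(r) < 0.602).mean() >= 0.95

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            correlation_coefficients(np.ones((2, 3)), np.ones(2))


class TestBackscaleLoadings:
    def _fit(self, X, y, n_orth=0):
        sm = pareto_scale(X)
        return fit_oplsda(sm.values, y, n_orth=n_orth), sm

    def test_unit_scales_identity(self, rng):
        X, y = rng.normal(size=(10, 5)), np.array([-1.0] * 5 + [1.0] * 5)
        X[:, 0] += 2 * y
        model, sm = self._fit(X, y)
        sm.column_scales[:] = 1.0
        assert np.allclose(backscale_loadings(model, sm), model.p_pred)

    def test_backscaled_equals_raw_covariance_loading(self, rng):
        """Back-scaling restores raw-unit loadings: p_j * scale_j equals the
        regression of the centred raw column on the predictive score, so with
        the scores held fixed, doubling a raw column doubles its value."""
        y = np.array([-1.0] * 5 + [1.0] * 5)
        X = rng.normal(size=(10, 4))
        X[:, 0] += 2 * y
        model, sm = self._fit(X, y, n_orth=0)
        t = model.t_pred
        raw = (X - X.mean(axis=0)).T @ t / (t @ t)
        assert np.allclose(backscale_loadings(model, sm), raw, atol=1e-10)
        X2 = X.copy()
        X2[:, 2] *= 2.0
        raw2 = (X2 - X2.mean(axis=0)).T @ t / (t @ t)
        assert raw2[2] == pytest.approx(2 * raw[2], rel=1e-12)

    def test_constant_column_zero(self):
        y = np.array([-1.0] * 4 + [1.0] * 4)
        X = np.column_stack([y + 0.1 * np.arange(8), np.full(8, 7.0)])
        model, sm = self._fit(X, y)
        assert backscale_loadings(model, sm)[1] == 0.0


def _coeff_df(ppm, loading, r):
    r = np.asarray(r, dtype=float)
    return pd.DataFrame(
        {
            "ppm": ppm, "loading": loading, "r": r, "abs_r": np.abs(r),
            "significant": np.abs(r) > 0.602, "constant": False,
        }
    )


class TestCallMetabolites:
    def test_basic_call_and_direction(self):
        coeffs = _coeff_df([1.0, 1.002, 2.0], [0.5, 0.6, -0.4], [0.9, 0.95, -0.8])
        calls = call_metabolites(
            coeffs, {"up": [(0.999, 1.003)], "down": [(1.999, 2.001)]}, 0.602
        )
        d = dict(zip(calls["metabolite"], calls["direction"]))
        assert d == {"up": "increase", "down": "decrease"}

    def test_median_below_cutoff_no_call(self):
        coeffs = _coeff_df([1.0, 1.002, 1.004], [0.5, 0.5, 0.5], [0.9, 0.3, 0.2])
        calls = call_metabolites(coeffs, {"m": [(0.999, 1.005)]}, 0.602)
        assert len(calls) == 0

    def test_conflicting_signs_no_call(self):
        coeffs = _coeff_df([1.0, 1.002], [0.5, -0.5], [0.9, -0.9])
        calls = call_metabolites(coeffs, {"m": [(0.999, 1.003)]}, 0.602)
        assert len(calls) == 0

    def test_tie_at_cutoff_not_significant(self):
        coeffs = _coeff_df([1.0], [0.5], [0.602])
        calls = call_metabolites(coeffs, {"m": [(0.999, 1.001)]}, 0.602)
        assert len(calls) == 0

    def test_empty_window_errors(self):
        coeffs = _coeff_df([1.0], [0.5], [0.9])
        with pytest.raises(ValueError, match="ghost"):
            call_metabolites(coeffs, {"ghost": [(5.0, 5.1)]}, 0.602)


from conftest import small_cohort_calls as _small_cohort_calls  # noqa: E402


class TestRecoveryProperties:
    def test_relabelling_flips_direction_only(self, tiny_scenario, tiny_binning):
        """Reversing sample order swaps which class codes +1: same metabolites
        are called, every direction flips."""
        from metabodisc.opls import encode_labels, fit_oplsda, pareto_scale
        from metabodisc.preprocess import build_matrix
        from metabodisc.simulate import default_assignments, simulate_cohort

        spectra, labels, _ = simulate_cohort(tiny_scenario)
        ids = [f"s{i}" for i in range(len(spectra))]
        m = build_matrix(spectra, ids, labels, tiny_binning)
        assigns = default_assignments(tiny_scenario.library)
        r_crit = critical_r(tiny_scenario.n_per_group)

        def run(values, labs):
            y, coding = encode_labels(labs)
            sm = pareto_scale(values)
            model = fit_oplsda(sm.values, y, n_orth=1)
            ct = coefficient_table(model, sm, m.bin_centers, r_crit)
            pos = next(k for k, v in coding.items() if v == +1)
            return call_metabolites(ct, assigns, r_crit, positive_group=pos)

        a = run(m.values, labels)
        b = run(m.values[::-1], labels[::-1])
        da = dict(zip(a["metabolite"], a["direction"]))
        db = dict(zip(b["metabolite"], b["direction"]))
        assert "B" in da  # the planted metabolite is recovered
        assert set(da) == set(db)
        flip = {"increase": "decrease", "decrease": "increase"}
        assert all(db[k] == flip[v] for k, v in da.items())

    def test_recovery_power_monotone_in_fold_change(self):
        """Fraction of planted metabolites recovered rises with effect size."""
        rates = []
        for fold in (1.1, 1.5, 2.0):
            hits = sum(
                "target" in set(_small_cohort_calls(fold, seed)["metabolite"])
                for seed in range(40)
            )
            rates.append(hits / 40)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] >= 0.9

    def test_null_cohort_rarely_calls(self):
        """With no perturbation and moderate noise, calls are rare."""
        clean = sum(len(_small_cohort_calls(1.0, seed)) == 0 for seed in range(20))
        assert clean >= 18


class TestCoefficientPlot:
    def test_plot_written(self, tmp_path, rng):
        coeffs = _coeff_df(
            np.linspace(1, 3, 50), rng.normal(size=50), np.clip(rng.normal(0, 0.4, 50), -1, 1)
        )
        out = tmp_path / "coeff.png"
        render_coefficient_plot(coeffs, 0.602, str(out))
        assert out.exists() and out.stat().st_size > 0

    def test_single_bin_renders(self, tmp_path):
        out = tmp_path / "one.png"
        render_coefficient_plot(_coeff_df([1.0], [0.5], [0.9]), 0.602, str(out))
        assert out.exists()

    def test_empty_table_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            render_coefficient_plot(_coeff_df([], [], []), 0.602, str(tmp_path / "x.png"))


class TestCoefficientTable:
    def test_y_basis_option(self, rng):
        y = np.array([-1.0] * 6 + [1.0] * 6)
        X = rng.normal(size=(12, 5))
        X[:, 0] += 3 * y
        sm = pareto_scale(X)
        model = fit_oplsda(sm.values, y, n_orth=0)
        ct = coefficient_table(model, sm, np.arange(5.0), 0.602,
                               corr_basis="y", y_coded=y)
        r_direct, _ = correlation_coefficients(sm.values, y)
        assert np.allclose(ct["r"], r_direct, atol=1e-12)
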