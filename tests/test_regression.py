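"""OLS model suite: fit statistics, cross-validation, selection, screening.

Frozen expected values for the reference dataset were computed with an
independent exact-rational-arithmetic solver of the normal equations
(fractions.Fraction end to end), so they are free of floating-point and
library effects.
"""

import numpy as np
import pandas as pd
import pytest

from ledaffinity import (
    LinearDatasetSpec,
    ModelSpec,
    commensurability_screen,
    exclusion_scan,
    fit_mlr,
    led_fraction_table,
    loo_cv,
    make_linear_dataset,
    q2_with_exclusion,
    variable_selection,
)
from ledaffinity.dataset import AffinityDataset, AffinityRecord
from ledaffinity.errors import (
    FoldSingularityError,
    InsufficientDataError,
    SingularDesignError,
)
from ledaffinity.led import LedComponents

# Exact-rational oracle results for the reference dataset, model M3
# (intercept + all five descriptors), frozen to 12 significant digits.
M3_RESIDUALS = {
    "3ZV7": 0.0220723240322,
    "5NAU": 0.0448056812808,
    "1U65": -0.0253110200410,
    "5NAP": -0.0519960503513,
    "1H23": -0.0332416632996,
    "1H22": 0.0312121204349,
    "1E66": 0.0124586079440,
}
M3_SSQ_RESIDUAL = 0.00807339510374
M3_Q2_LOO = 0.912614887923
M3_Q2_NO_HUX = 0.925817360701


def small_dataset(X: np.ndarray, y: np.ndarray) -> AffinityDataset:
    """Wrap a raw design into an AffinityDataset (unused columns zero-padded)."""
    ncols = X.shape[1]
    records = []
    for i in range(len(y)):
        padded = list(X[i]) + [float(i + j) for j in range(5 - ncols)]
        records.append(
            AffinityRecord(
                complex_id=f"P{i:02d}",
                ligand=f"L{i:02d}",
                log_ki=float(y[i]),
                components=LedComponents(*padded),
            )
        )
    return AffinityDataset(tuple(records))


class TestFitMlr:
    def test_single_energy_model_reference_statistics(self, reference_dataset):
        fit = fit_mlr(reference_dataset, ModelSpec.m1())
        assert round(fit.pct_recovered, 1) == 20.0
        assert round(fit.mse, 3) == 1.096
        assert round(float(fit.residuals["3ZV7"]), 3) == 1.768
        assert round(float(fit.residuals["1E66"]), 3) == -1.778

    def test_led_component_model_reference_statistics(self, reference_dataset):
        fit = fit_mlr(reference_dataset, ModelSpec.m2())
        assert round(fit.pct_recovered, 1) == 62.8
        assert round(fit.mse, 3) == 0.509

    def test_full_model_matches_exact_rational_oracle(self, reference_dataset, m3):
        fit = fit_mlr(reference_dataset, m3)
        assert round(fit.pct_recovered, 1) == 99.9
        assert fit.ssq_residual == pytest.approx(M3_SSQ_RESIDUAL, rel=1e-9)
        for cid, expected in M3_RESIDUALS.items():
            assert float(fit.residuals[cid]) == pytest.approx(expected, abs=1e-9)

    def test_total_ssq_about_the_mean(self, reference_dataset):
        fit = fit_mlr(reference_dataset, ModelSpec.m1())
        assert round(fit.ssq_data, 2) == 9.59

    def test_exact_interpolation_of_noiseless_linear_data(self):
        dataset, _ = make_linear_dataset(
            LinearDatasetSpec(
                n=12,
                coefficients={"intercept": 2.0, "binding_energy": -0.01,
                              "e_disp": 0.05},
                seed=42,
            )
        )
        fit = fit_mlr(dataset, ModelSpec.m3())
        assert fit.pct_recovered == pytest.approx(100.0, abs=1e-9)
        assert fit.residuals.abs().max() < 1e-9

    def test_four_point_fit_matches_hand_solved_normal_equations(self, oracle_ols):
        X = np.array([[1.0], [2.0], [3.0], [5.0]])
        y = np.array([1.1, 1.9, 3.2, 4.8])
        dataset = small_dataset(X, y)
        fit = fit_mlr(dataset, ModelSpec(("binding_energy",)))
        design = np.column_stack([np.ones(4), X])
        expected = oracle_ols(design, y)
        assert fit.coefficients.to_numpy() == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_normal_equation_oracle_on_random_data(self, seed, oracle_ols):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 20))
        dataset, _ = make_linear_dataset(
            LinearDatasetSpec(
                n=n,
                coefficients={"intercept": 1.0, "binding_energy": 0.02,
                              "e_elstat": -0.03, "e_ct": 0.2},
                noise_sd=0.5,
                seed=seed,
            )
        )
        spec = ModelSpec.m3()
        fit = fit_mlr(dataset, spec)
        frame = dataset.to_frame()
        design = np.column_stack(
            [np.ones(n), frame[list(spec.predictors)].to_numpy()]
        )
        expected = oracle_ols(design, frame["log_ki"].to_numpy())
        np.testing.assert_allclose(fit.coefficients.to_numpy(), expected, rtol=1e-10)

    def test_residuals_sum_to_zero_and_are_orthogonal_to_predictors(self):
        dataset, _ = make_linear_dataset(
            LinearDatasetSpec(
                n=15, coefficients={"intercept": 1.0, "e_exch": 0.1},
                noise_sd=1.0, seed=3,
            )
        )
        fit = fit_mlr(dataset, ModelSpec.m3())
        scale = dataset.to_frame()["log_ki"].abs().max()
        assert abs(fit.residuals.sum()) < 1e-10 * 15 * scale
        frame = dataset.to_frame()
        for p in fit.spec.predictors:
            dot = float(frame[p].to_numpy() @ fit.residuals.to_numpy())
            assert abs(dot) < 1e-7 * scale * frame[p].abs().max()

    def test_single_predictor_pct_equals_squared_correlation(self, reference_dataset):
        fit = fit_mlr(reference_dataset, ModelSpec.m1())
        frame = reference_dataset.to_frame()
        r = np.corrcoef(frame["binding_energy"], frame["log_ki"])[0, 1]
        assert fit.pct_recovered == pytest.approx(100 * r * r, rel=1e-10)

    def test_too_few_points_raises(self):
        X = np.arange(5, dtype=float).reshape(-1, 1)
        y = np.arange(5, dtype=float)
        dataset = small_dataset(X, y)
        with pytest.raises(InsufficientDataError):
            fit_mlr(dataset, ModelSpec.m3())  # 6 coefficients, 5 points

    def test_duplicated_predictor_is_singular(self, reference_dataset):
        spec = ModelSpec(("binding_energy", "binding_energy"))
        with pytest.raises(SingularDesignError):
            fit_mlr(reference_dataset, spec)


class TestLooCv:
    def test_reference_q2_matches_exact_oracle(self, reference_dataset, m3):
        loo = loo_cv(reference_dataset, m3)
        assert loo.q2 == pytest.approx(M3_Q2_LOO, abs=1e-9)

    def test_noiseless_linear_data_has_unit_q2(self):
        dataset, _ = make_linear_dataset(
            LinearDatasetSpec(
                n=12, coefficients={"intercept": 0.5, "binding_energy": 0.02},
                seed=8,
            )
        )
        loo = loo_cv(dataset, ModelSpec.m3())
        assert loo.q2 == pytest.approx(1.0, abs=1e-9)

    def test_press_equals_explicit_manual_refits(self):
        rng = np.random.default_rng(17)
        X = rng.uniform(0, 10, (5, 1))
        y = 1.0 + 0.5 * X[:, 0] + rng.normal(0, 0.4, 5)
        dataset = small_dataset(X, y)
        loo = loo_cv(dataset, ModelSpec(("binding_energy",)))
        press = 0.0
        design = np.column_stack([np.ones(5), X])
        for i in range(5):
            mask = np.arange(5) != i
            beta = np.linalg.solve(
                design[mask].T @ design[mask], design[mask].T @ y[mask]
            )
            press += (y[i] - design[i] @ beta) ** 2
        assert loo.press == pytest.approx(press, rel=1e-10)


class TestQ2WithExclusion:
    def test_reference_exclusion_value(self, reference_dataset, m3):
        loo = loo_cv(reference_dataset, m3)
        q2x = q2_with_exclusion(loo, reference_dataset, ["1E66"])
        assert q2x == pytest.approx(M3_Q2_NO_HUX, abs=1e-9)

    def test_excluding_nothing_is_identity(self, reference_dataset, m3):
        loo = loo_cv(reference_dataset, m3)
        assert q2_with_exclusion(loo, reference_dataset, []) == pytest.approx(loo.q2)

    def test_excluding_dominant_error_fold_raises_q2(self):
        dataset, _ = make_linear_dataset(
            LinearDatasetSpec(
                n=12, coefficients={"intercept": 0.0, "binding_energy": 0.02},
                noise_sd=0.2, seed=5, outlier_index=4, outlier_offset=5.0,
            )
        )
        loo = loo_cv(dataset, ModelSpec(("binding_energy",)))
        worst = loo.table.loc[loo.table["sq_error"].idxmax(), "complex_id"]
        assert worst == "SYN005"
        # The planted point's squared LOO error dominates its share of SSQ.
        q2x = q2_with_exclusion(loo, dataset, [worst])
        assert q2x > loo.q2

    def test_excluding_everything_is_an_error(self, reference_dataset, m3):
        loo = loo_cv(reference_dataset, m3)
        with pytest.raises(ValueError):
            q2_with_exclusion(loo, reference_dataset, reference_dataset.complex_ids)


class TestVariableSelection:
    def test_backward_retains_all_five_on_reference_data(self, reference_dataset):
        trace = variable_selection(reference_dataset, direction="backward")
        assert set(trace.selected) == {
            "binding_energy", "e_elstat", "e_exch", "e_ct", "e_disp"
        }
        final = fit_mlr(reference_dataset, ModelSpec(trace.selected))
        assert (final.p_values.drop("intercept") < 0.05).all()

    def test_forward_stalls_on_reference_data(self, reference_dataset):
        # No single descriptor is individually significant at alpha = 0.05,
        # so the forward pass legally ends with the empty model.
        trace = variable_selection(reference_dataset, direction="forward")
        assert trace.selected == ()
        assert trace.steps[-1].action == "stop"

    def test_planted_noise_column_is_excluded(self):
        dataset, _ = make_linear_dataset(
            LinearDatasetSpec(
                n=120,
                coefficients={"intercept": 1.0, "binding_energy": 0.05},
                noise_sd=0.5,
                seed=21,
            )
        )
        trace = variable_selection(
            dataset, candidates=("binding_energy", "e_ct"), direction="forward"
        )
        assert trace.selected == ("binding_energy",)

    def test_backward_with_vacuous_threshold_keeps_full_model(self, reference_dataset):
        trace = variable_selection(
            reference_dataset, direction="backward", alpha=0.9999
        )
        assert len(trace.selected) == 5


class TestExclusionScan:
    def test_reference_minimum_drop(self, reference_dataset, m3):
        scan = exclusion_scan(reference_dataset, m3)
        assert len(scan) == 5
        assert scan["pct_drop"].min() >= 27.0

    def test_irrelevant_predictor_costs_nothing(self):
        dataset, _ = make_linear_dataset(
            LinearDatasetSpec(
                n=30, coefficients={"intercept": 1.0, "binding_energy": 0.05},
                seed=2,
            )
        )
        scan = exclusion_scan(
            dataset, ModelSpec(("binding_energy", "e_disp"))
        ).set_index("excluded")
        assert scan.loc["e_disp", "pct_drop"] == pytest.approx(0.0, abs=1e-6)
        assert scan.loc["binding_energy", "pct_drop"] > 50.0


class TestCommensurabilityScreen:
    def make_eight_point(self, outlier: bool):
        return make_linear_dataset(
            LinearDatasetSpec(
                n=8,
                coefficients={"intercept": 1.0, "binding_energy": 0.02,
                              "e_elstat": -0.01},
                seed=13,
                outlier_index=6 if outlier else None,
                outlier_offset=5.0,
            )
        )[0]

    def test_planted_outlier_is_flagged(self):
        dataset = self.make_eight_point(outlier=True)
        report = commensurability_screen(
            dataset, ModelSpec(("binding_energy", "e_elstat"))
        )
        assert report.flagged == ("SYN007",)
        assert len(report.table) == 8

    def test_homogeneous_noiseless_data_flags_nothing(self):
        dataset = self.make_eight_point(outlier=False)
        report = commensurability_screen(
            dataset, ModelSpec(("binding_energy", "e_elstat"))
        )
        assert report.flagged == ()

    def test_insufficient_points_for_subfits(self, reference_dataset, m3):
        # 7 points, 6 coefficients: sub-fits would have zero residual dof.
        with pytest.raises(InsufficientDataError):
            commensurability_screen(reference_dataset, m3)


class TestFractionTable:
    def test_reference_fractions_row(self, reference_dataset):
        table = led_fraction_table(reference_dataset).set_index("complex_id")
        nhg = table.loc["3ZV7", ["f_elstat", "f_exch", "f_ct", "f_disp"]]
        assert tuple(round(float(v), 2) for v in nhg) == (0.62, 0.17, 0.10, 0.18)
        assert round(float(table.loc["1E66", "f_disp"]), 2) == 0.27

    def test_pure_electrostatic_record(self):
        record = AffinityRecord(
            "X", "LX", 1.0, LedComponents(10.0, 10.0, 0.0, 0.0, 0.0)
        )
        table = led_fraction_table(AffinityDataset((record,))).set_index("complex_id")
        assert tuple(table.loc["X", ["f_elstat", "f_exch", "f_ct", "f_disp"]]) == (
            1.0, 0.0, 0.0, 0.0,
        )

    def test_zero_binding_energy_names_complex(self):
        record = AffinityRecord(
            "BAD", "LX", 1.0, LedComponents(0.0, 1.0, 1.0, 1.0, 1.0)
        )
        with pytest.raises(ZeroDivisionError, match="BAD"):
            led_fraction_table(AffinityDataset((record,)))


class TestProperties:
    @pytest.mark.parametrize("seed", range(10))
    def test_nested_models_recover_monotonically_more_ssq(self, seed):
        rng = np.random.default_rng(seed)
        dataset, _ = make_linear_dataset(
            LinearDatasetSpec(
                n=int(rng.integers(8, 25)),
                coefficients={
                    "intercept": float(rng.normal()),
                    "binding_energy": float(rng.normal(0, 0.02)),
                    "e_elstat": float(rng.normal(0, 0.02)),
                    "e_disp": float(rng.normal(0, 0.05)),
                },
                noise_sd=float(rng.uniform(0.1, 1.0)),
                seed=seed + 1000,
            )
        )
        pct = {
            name: fit_mlr(dataset, ModelSpec.named(name)).pct_recovered
            for name in ("m1", "m2", "m3")
        }
        assert pct["m3"] >= pct["m1"] - 1e-9
        assert pct["m3"] >= pct["m2"] - 1e-9

    def test_zero_noise_coefficient_recovery_is_exact(self):
        truth_in = {
            "intercept": -1.5, "binding_energy": 0.013, "e_elstat": -0.021,
            "e_exch": 0.4, "e_ct": -0.15, "e_disp": 0.033,
        }
        dataset, truth = make_linear_dataset(
            LinearDatasetSpec(n=20, coefficients=truth_in, seed=99)
        )
        fit = fit_mlr(dataset, ModelSpec.m3())
        for name, value in truth.items():
            key = "intercept" if name == "intercept" else name
            assert float(fit.coefficients[key]) == pytest.approx(value, abs=1e-10)

    def test_mean_estimates_unbiased_over_replicates(self):
        truth_in = {"intercept": 1.0, "binding_energy": 0.02}
        estimates = []
        ses = []
        for seed in range(200):
            dataset, _ = make_linear_dataset(
                LinearDatasetSpec(n=25, coefficients=truth_in, noise_sd=0.3,
                                  seed=seed)
            )
            fit = fit_mlr(dataset, ModelSpec(("binding_energy",)))
            estimates.append(float(fit.coefficients["binding_energy"]))
        mean = np.mean(estimates)
        se_of_mean = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean - truth_in["binding_energy"]) < 3 * se_of_mean
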