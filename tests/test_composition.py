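"""Composition bookkeeping: variability, thresholds, flagging, rates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nirscreen.composition import (
    DEFAULT_REFERENCE_VARIABILITY,
    MAJOR_SUGARS,
    SUGARS,
    ReferenceVariability,
    ThresholdSet,
    combine_outlier_sets,
    flag_sugar_outliers,
    percent_differences,
    reference_variability,
    thresholds_from_sigma,
    validate_composition,
    validation_rate,
)
from nirscreen.synthsim import SimConfig, simulate_population


def comp_table(rows: dict[str, list[float]], sugars=MAJOR_SUGARS) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(sugars))


class TestReferenceVariability:
    def test_identical_references_give_zero_sigma(self):
        table = comp_table({"r1": [12, 6, 28, 44], "r2": [12, 6, 28, 44]})
        var = reference_variability(table, ["r1", "r2"])
        assert all(v == 0 for v in var.sigma.values())
        assert all(v == 0 for v in var.mu.values())

    def test_symmetric_deviations_absolute_convention(self):
        # Gal deviations +8.5% and -8.5%: mean of |dev| is 8.5, sd is 0
        base = np.array([12.0, 6.0, 28.0, 44.0])
        up = base * np.array([1.0, 1.085, 1.0, 1.0])
        dn = base * np.array([1.0, 0.915, 1.0, 1.0])
        table = comp_table({"r1": up, "r2": dn})
        var = reference_variability(table, ["r1", "r2"])
        assert var.mu["Gal"] == pytest.approx(8.5, abs=1e-9)
        assert var.sigma["Gal"] == pytest.approx(0.0, abs=1e-9)

    def test_small_batches_skipped(self):
        table = comp_table({"r1": [12, 6, 28, 44], "r2": [13, 7, 27, 43], "r3": [12, 6, 28, 44]})
        var = reference_variability(
            table, ["r1", "r2", "r3"], grouping={"r1": "A", "r2": "A", "r3": "B"}
        )
        assert var.n_references == 2  # lone reference in batch B contributes nothing

    def test_recovers_injected_scale_against_half_normal_oracle(self):
        # references are clipped lognormal draws around the batch mean; the
        # sd of |relative deviation| for injected CV c is close to the
        # half-normal value sigma*sqrt(1 - 2/pi), which we compute as the
        # oracle by direct simulation of the same bounded draw
        injected_cv = 0.085
        cfg = SimConfig(
            seed=0,
            lines_per_batch=80,
            samples_per_line=1,
            n_reference_candidates=0,
            outlier_fraction=0.0,
            line_effect_share=0.0,
        )
        cfg.composition_cv["Gal"] = injected_cv
        recovered = []
        for seed in range(20):
            cfg.seed = seed
            _, comp, _ = simulate_population(cfg)
            ids = list(comp.index)
            var = reference_variability(comp, ids)
            recovered.append(var.sigma["Gal"])
        # oracle: bounded-normal |dev| sd under the generator's clip
        rng = np.random.default_rng(123)
        sig = np.sqrt(np.log1p(injected_cv**2))
        z = np.clip(rng.standard_normal(200_000), -2, 2)
        dev = 100 * np.abs(np.exp(sig * z - sig**2 / 2) - 1.0)
        oracle = dev.std(ddof=1)
        assert abs(np.mean(recovered) - oracle) < 0.2 * oracle

    def test_too_few_references(self):
        table = comp_table({"r1": [12, 6, 28, 44]})
        with pytest.raises(ValueError):
            reference_variability(table, ["r1"])


class TestThresholds:
    def test_gal_printed_sigma_reproduces_printed_threshold(self):
        var = ReferenceVariability(mu={"Gal": 12.5}, sigma={"Gal": 8.5})
        thresholds = thresholds_from_sigma(var, k=4)
        assert thresholds["Gal"] == pytest.approx(34.0)

    @pytest.mark.parametrize("sigma, k, expected", [(0.0, 4, 0.0), (2.5, 4, 10.0)])
    def test_arithmetic(self, sigma, k, expected):
        var = ReferenceVariability(mu={"X": 0.0}, sigma={"X": sigma})
        assert thresholds_from_sigma(var, k)["X"] == pytest.approx(expected)

    def test_default_reference_variability_consistency(self):
        # the shipped Gal default threshold equals 4x the shipped sigma
        t = thresholds_from_sigma(DEFAULT_REFERENCE_VARIABILITY, 4)
        assert t["Gal"] == pytest.approx(34.0)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            thresholds_from_sigma(DEFAULT_REFERENCE_VARIABILITY, 0)


class TestPercentDifferences:
    def test_simple_arithmetic(self):
        values = comp_table({"a": [10.0, 13.0, 28, 44]})
        baseline = pd.Series([10.0, 10.0, 28, 44], index=MAJOR_SUGARS)
        diffs = percent_differences(values, baseline)
        assert diffs.loc["a", "Ara"] == pytest.approx(0.0)
        assert diffs.loc["a", "Gal"] == pytest.approx(30.0)

    def test_per_batch_baselines(self):
        values = comp_table({"a": [11, 6, 28, 44], "b": [12, 6, 28, 44]})
        baselines = comp_table({"A": [10, 6, 28, 44], "B": [12, 6, 28, 44]})
        diffs = percent_differences(values, baselines, batch_of={"a": "A", "b": "B"})
        assert diffs.loc["a", "Ara"] == pytest.approx(10.0)
        assert diffs.loc["b", "Ara"] == pytest.approx(0.0)

    def test_reference_vs_predicted_baselines_differ(self):
        # the screen confirms against reference means; the model path uses
        # predicted batch means — same sample, different baseline, known answers
        values = comp_table({"a": [12.0, 6, 28, 44]})
        ref_baseline = pd.Series([10.0, 6, 28, 44], index=MAJOR_SUGARS)
        model_baseline = pd.Series([12.5, 6, 28, 44], index=MAJOR_SUGARS)
        d_ref = percent_differences(values, ref_baseline)
        d_model = percent_differences(values, model_baseline)
        assert d_ref.loc["a", "Ara"] == pytest.approx(20.0)
        assert d_model.loc["a", "Ara"] == pytest.approx(-4.0)

    def test_zero_baseline_rejected(self):
        values = comp_table({"a": [10, 6, 28, 44]})
        baseline = pd.Series([0.0, 6, 28, 44], index=MAJOR_SUGARS)
        with pytest.raises(ValueError, match="Ara"):
            percent_differences(values, baseline)

    @settings(max_examples=50, deadline=None)
    @given(
        value=st.floats(1.0, 100.0),
        baseline=st.floats(1.0, 100.0),
    )
    def test_antisymmetry_identity(self, value, baseline):
        # swapping value and baseline maps delta -> -100*delta/(100+delta)
        v = comp_table({"a": [value, 1, 1, 1]})
        b = pd.Series([baseline, 1, 1, 1], index=MAJOR_SUGARS)
        d = percent_differences(v, b).loc["a", "Ara"]
        v2 = comp_table({"a": [baseline, 1, 1, 1]})
        b2 = pd.Series([value, 1, 1, 1], index=MAJOR_SUGARS)
        d_swapped = percent_differences(v2, b2).loc["a", "Ara"]
        assert d_swapped == pytest.approx(-100 * d / (100 + d), rel=1e-9)


class TestFlagging:
    THRESH = ThresholdSet({"Ara": 9.1, "Gal": 34.0, "Glc": 36.6, "Xyl": 12.1})

    def test_flag_via_single_sugar(self):
        diffs = comp_table({"a": [2.0, 35.0, -5.0, 0.0]})
        report = flag_sugar_outliers(diffs, self.THRESH)
        assert report.flagged == ["a"]
        assert report.triggered["a"] == ["Gal"]

    def test_all_zero_not_flagged(self):
        diffs = comp_table({"a": [0.0, 0.0, 0.0, 0.0]})
        assert flag_sugar_outliers(diffs, self.THRESH).flagged == []

    def test_boundary_is_closed(self):
        diffs = comp_table({"a": [9.1, 0, 0, 0], "b": [-9.1, 0, 0, 0], "c": [9.0999, 0, 0, 0]})
        report = flag_sugar_outliers(diffs, self.THRESH)
        assert report.flagged == ["a", "b"]

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(0)
        diffs = pd.DataFrame(
            rng.normal(0, 15, size=(50, 4)),
            columns=list(MAJOR_SUGARS),
            index=[f"s{i}" for i in range(50)],
        )
        lo = flag_sugar_outliers(diffs, self.THRESH)
        raised = ThresholdSet({s: v * 1.5 for s, v in self.THRESH.thresholds.items()})
        hi = flag_sugar_outliers(diffs, raised)
        assert set(hi.flagged) <= set(lo.flagged)

    def test_report_round_trip_to_disk(self, tmp_path):
        diffs = comp_table({"a": [2.0, 35.0, -5.0, 0.0], "b": [0, 0, 0, 0]})
        report = flag_sugar_outliers(diffs, self.THRESH)
        report.save(tmp_path / "outliers.tsv")
        frame = pd.read_csv(tmp_path / "outliers.tsv", sep="\t", index_col=0)
        assert bool(frame.loc["a", "flagged"]) is True
        assert bool(frame.loc["b", "flagged"]) is False


class TestRatesAndSets:
    @pytest.mark.parametrize(
        "confirmed, analyzed, expected", [(48, 145, 33), (18, 30, 60), (0, 10, 0)]
    )
    def test_validation_rate_rounding(self, confirmed, analyzed, expected):
        assert validation_rate(confirmed, analyzed) == expected

    def test_exact_rate_retained(self):
        assert validation_rate(48, 145, exact=True) == pytest.approx(33.103448, abs=1e-4)

    def test_validation_rate_errors(self):
        with pytest.raises(ValueError):
            validation_rate(1, 0)
        with pytest.raises(ValueError):
            validation_rate(5, 3)

    def test_union_arithmetic(self):
        a = {f"m{i}" for i in range(48)}
        b = set(list(a)[:11]) | {f"p{i}" for i in range(7)}
        out = combine_outlier_sets(a, b)
        assert out == {"n_a": 48, "n_b": 18, "n_intersection": 11, "n_union": 55}

    def test_disjoint_and_subset_cases(self):
        assert combine_outlier_sets({"a", "b", "c"}, {"d", "e", "f", "g"})["n_union"] == 7
        assert combine_outlier_sets({"a", "b", "c"}, {"a"})["n_union"] == 3


class TestValidateComposition:
    def test_sum_window(self):
        good = pd.DataFrame([[0.5, 1.5, 12, 6, 28, 44, 3, 5]], columns=list(SUGARS))
        validate_composition(good)
        bad = good * 2
        with pytest.raises(ValueError, match="95, 105"):
            validate_composition(bad)

    def test_negative_rejected(self):
        bad = pd.DataFrame([[-1, 2, 12, 6, 28, 44, 4, 5]], columns=list(SUGARS))
        with pytest.raises(ValueError, match="negative"):
            validate_composition(bad)
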