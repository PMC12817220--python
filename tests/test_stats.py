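"""Welch comparisons, stars, proportionality and trajectory tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import welch_oracle
from ergdissect.core import AgeClass, ComponentKind, ErgError, Genotype
from ergdissect.pipeline import amplitude_table, fit_table, isolate_cohort
from ergdissect.presets import simulate_cohort
from ergdissect.stats import (
    compare_parameters,
    compare_per_intensity,
    holm_adjust,
    proportionality,
    star_from_p,
    trajectory,
    welch_test,
)

samples = st.lists(
    st.floats(min_value=-100, max_value=100, allow_nan=False), min_size=2, max_size=12
)


class TestWelch:
    def test_hand_computed_example(self):
        # means 2 and 5, both variances 1: t = -3 / sqrt(2/3), df = 4 exactly
        res = welch_test([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.674, abs=5e-4)
        assert res.df == pytest.approx(4.0, abs=1e-12)

    def test_identical_samples(self):
        res = welch_test([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert res.t == 0.0 and res.p == 1.0 and res.star == "ns"

    def test_zero_variance_conventions(self):
        equal = welch_test([2.0, 2.0], [2.0, 2.0])
        assert equal.p == 1.0
        different = welch_test([2.0, 2.0], [5.0, 5.0])
        assert different.p == 0.0 and different.star == "***"

    def test_small_samples_rejected(self):
        with pytest.raises(ErgError):
            welch_test([1.0], [1.0, 2.0])

    @given(samples, samples)
    def test_matches_reference_implementation(self, x, y):
        if np.var(x) == 0 and np.var(y) == 0:
            return
        res = welch_test(x, y)
        t_ref, df_ref, p_ref = welch_oracle(x, y)
        assert res.t == pytest.approx(t_ref, abs=1e-10)
        assert res.df == pytest.approx(df_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)


class TestStars:
    @pytest.mark.parametrize(
        "p,star",
        [
            (0.0005, "***"), (0.004, "**"), (0.03, "*"), (0.2, "ns"),
            # boundary values fall to the less-significant bin
            (0.001, "**"), (0.01, "*"), (0.05, "ns"), (1.0, "ns"),
        ],
    )
    def test_bins(self, p, star):
        assert star_from_p(p) == star

    def test_holm_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 25)
        _, ref, _, _ = multipletests(p, method="holm")
        assert np.allclose(holm_adjust(p), ref, atol=1e-12)


@pytest.fixture(scope="module")
def adult_tables(noisy_adult_cohort):
    amps = amplitude_table(isolate_cohort(noisy_adult_cohort))
    fits = fit_table(amps)
    return amps, fits


class TestGroupComparisons:
    def test_adult_disease_preset_majority_significant_at_mid_high_intensity(
        self, adult_tables
    ):
        amps, _ = adult_tables
        table = compare_per_intensity(amps)
        mid_high = table[table["intensity"] >= 158.0]
        assert not mid_high.empty
        for genotype, group in mid_high.groupby("genotype"):
            assert group["significant"].mean() > 0.5, genotype
        # mutants are reduced, not enhanced
        assert (mid_high["mean"] < mid_high["mean_ref"]).mean() > 0.9

    def test_single_retina_groups_are_skipped(self, caplog):
        rows = []
        for genotype, retinas in [("WT", 3), ("KO", 1)]:
            for r in range(retinas):
                rows.append({
                    "retina_id": f"{genotype}{r}", "genotype": genotype,
                    "component": "MGC", "phase": "NA",
                    "intensity": 50.0, "amplitude": 100.0 + r,
                })
        with caplog.at_level("WARNING"):
            table = compare_per_intensity(pd.DataFrame(rows))
        assert table.empty
        assert "fewer than 2 retinas" in caplog.text

    def test_empty_fit_table_gives_empty_result(self):
        assert compare_parameters(pd.DataFrame()).empty

    def test_parameter_comparison_flags_reduced_r_max(self, adult_tables):
        _, fits = adult_tables
        table = compare_parameters(fits, parameters=("r_max",))
        assert len(table) == 9  # 3 mutants x 3 components
        assert table["significant"].all()
        assert (table["mean"] < table["mean_ref"]).all()


class TestProportionality:
    def test_uniform_scaling_lies_on_the_diagonal(self, noise_free_adult_cohort):
        amps = amplitude_table(isolate_cohort(noise_free_adult_cohort))
        fits = fit_table(amps)
        for pair in [
            (ComponentKind.PHOTORECEPTOR, ComponentKind.ON_BIPOLAR),
            (ComponentKind.PHOTORECEPTOR, ComponentKind.MGC),
        ]:
            points, summary = proportionality(fits, pair, n_boot=100, seed=0)
            assert np.allclose(summary["mean_deviation"], 0.0, atol=1e-9)
            wt = points[points["genotype"] == "WT"]
            assert np.allclose(wt[["x", "y"]], 1.0, atol=1e-9)

    def test_disproportionate_loss_falls_below_diagonal(self):
        rows = []
        for genotype, pr, onb in [("WT", 100.0, 200.0), ("KO", 50.0, 50.0)]:
            for r in range(2):
                rows += [
                    {"retina_id": f"{genotype}{r}", "genotype": genotype,
                     "component": "PHOTORECEPTOR", "r_max": pr},
                    {"retina_id": f"{genotype}{r}", "genotype": genotype,
                     "component": "ON_BIPOLAR", "r_max": onb},
                ]
        points, summary = proportionality(pd.DataFrame(rows), n_boot=50, seed=1)
        ko = summary[summary["genotype"] == "KO"]
        # ON-bipolar at 0.25x of WT vs photoreceptor at 0.5x: below the line
        assert float(ko["mean_deviation"].iloc[0]) < 0

    def test_missing_wildtype_baseline_rejected(self):
        fits = pd.DataFrame([
            {"retina_id": "a", "genotype": "KO", "component": "PHOTORECEPTOR",
             "r_max": 100.0},
        ])
        with pytest.raises(ErgError):
            proportionality(fits)


class TestTrajectory:
    def test_wildtype_photoreceptor_rises_to_eye_opening_then_stabilises(self):
        fits = []
        for offset, age in enumerate(AgeClass):
            cohort = simulate_cohort(
                age, n_retinas=5, seed=31 + offset, genotypes=[Genotype.WT]
            )
            amps = amplitude_table(isolate_cohort(cohort))
            fits.append(fit_table(amps))
        table = trajectory(pd.concat(fits, ignore_index=True))
        pr = table[table["component"] == "PHOTORECEPTOR"].set_index("age_class")
        pre = pr.loc["PRE_EYE_OPENING", "mean_r_max"]
        eye = pr.loc["EYE_OPENING", "mean_r_max"]
        adult = pr.loc["ADULT", "mean_r_max"]
        assert eye > 1.5 * pre
        assert 0.8 < adult / eye < 1.25

    def test_sem_reporting_rules(self):
        fits = pd.DataFrame([
            {"genotype": "WT", "age_class": "ADULT", "component": "MGC", "r_max": 100.0},
            {"genotype": "WT", "age_class": "ADULT", "component": "MGC", "r_max": 100.0},
            {"genotype": "KO", "age_class": "ADULT", "component": "MGC", "r_max": 80.0},
        ])
        table = trajectory(fits).set_index("genotype")
        assert table.loc["WT", "sem_r_max"] == 0.0  # identical retinas
        assert np.isnan(table.loc["KO", "sem_r_max"])  # single retina
        assert table.loc["KO", "mean_r_max"] == 80.0
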