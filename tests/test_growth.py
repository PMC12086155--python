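"""Treatment comparisons and the fresh-weight ~ color ANCOVA."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from leafcolor import (
    InputError,
    InsufficientDataError,
    ModelError,
    WeightColorModel,
    anova_oneway,
    experiment_report,
    fit_weight_model,
    pairwise_treatment_tests,
)
from leafcolor.synthetic import SyntheticExperimentConfig, gen_experiment


def make_records(groups: dict[str, np.ndarray], response: str = "fresh_weight") -> pd.DataFrame:
    rows = []
    for t, values in groups.items():
        for i, v in enumerate(values):
            rows.append({"plant_id": f"{t}{i}", "treatment": t, response: float(v)})
    df = pd.DataFrame(rows)
    if "fresh_weight" not in df.columns:
        df["fresh_weight"] = 1.0
    return df


class TestAnovaOneway:
    def test_two_groups_f_is_t_squared(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        res = anova_oneway(make_records({"C": a, "N": b}), "fresh_weight")
        t, p = st.ttest_ind(a, b, equal_var=True)
        assert res.F == pytest.approx(t**2)
        assert res.p == pytest.approx(p)

    def test_identical_means_small_f(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        res = anova_oneway(make_records({"C": base, "N": base, "LV": base}), "fresh_weight")
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_agrees_with_permutation_oracle(self):
        # exchangeable normal data: the F-distribution p and a label-permutation
        # p target the same null, so they agree closely at n = 30
        r = np.random.default_rng(0)
        groups = {
            "C": r.normal(0.0, 1.0, 10),
            "N": r.normal(0.6, 1.0, 10),
            "LV": r.normal(0.3, 1.0, 10),
        }
        records = make_records(groups)
        res = anova_oneway(records, "fresh_weight")

        values = records["fresh_weight"].to_numpy()
        labels = records["treatment"].to_numpy()
        sizes = [np.sum(labels == t) for t in ("C", "N", "LV")]

        def between_ss(v):
            # F is monotone in the between-group SS at fixed total SS
            out, start = 0.0, 0
            for n_g in sizes:
                seg = v[start : start + n_g]
                out += n_g * (seg.mean() - v.mean()) ** 2
                start += n_g
            return out

        observed = between_ss(values)
        perm_rng = np.random.default_rng(1)
        n_perm = 100_000
        count = 0
        v = values.copy()
        for _ in range(n_perm):
            perm_rng.shuffle(v)
            count += between_ss(v) >= observed - 1e-12
        p_perm = count / n_perm
        assert abs(p_perm - res.p) < 0.01

    def test_degenerate_grouping_raises(self):
        with pytest.raises(InsufficientDataError):
            anova_oneway(make_records({"C": np.arange(5)}), "fresh_weight")

    def test_missing_response_rejected(self):
        with pytest.raises(InputError):
            anova_oneway(make_records({"C": np.arange(4), "N": np.arange(4)}), "height")


class TestPairwiseTests:
    def test_identical_groups_p_near_one(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        table = pairwise_treatment_tests(
            make_records({"C": base, "N": base + 1e-9}), "fresh_weight"
        )
        assert table.loc[0, "p"] > 0.99

    def test_huge_shift_detected(self, rng):
        a = rng.normal(0, 1, 8)
        table = pairwise_treatment_tests(
            make_records({"C": a, "N": a + 10.0}), "fresh_weight"
        )
        assert table.loc[0, "p"] < 0.001

    def test_configured_n_effect_power(self):
        # at the default effect and n, N vs C flags at alpha = .05 nearly always
        flagged = 0
        for seed in range(40):
            rec = gen_experiment(SyntheticExperimentConfig(seed=seed))
            table = pairwise_treatment_tests(rec, "fresh_weight")
            row = table[(table.group_a == "C") & (table.group_b == "N")]
            flagged += float(row["p"].iloc[0]) < 0.05
        assert flagged >= 36  # >= 90% of seeds

    def test_holm_adjustment_monotone(self, rng):
        rec = gen_experiment(SyntheticExperimentConfig(seed=5))
        table = pairwise_treatment_tests(rec, "fresh_weight", adjust="holm")
        assert (table["p_adjusted"] >= table["p"] - 1e-15).all()

    def test_unknown_adjustment_rejected(self):
        rec = gen_experiment(SyntheticExperimentConfig(seed=0))
        with pytest.raises(InputError):
            pairwise_treatment_tests(rec, "fresh_weight", adjust="bonferroni!!")


class TestWeightColorModel:
    def test_exact_line_recovered(self):
        # zero noise: slope and R^2 are exact
        x = np.tile(np.linspace(0.1, 0.8, 8), 2)
        t = np.repeat(["C", "N"], 8)
        df = pd.DataFrame(
            {
                "plant_id": [f"p{i}" for i in range(16)],
                "treatment": t,
                "dark_green_proportion": x,
                "fresh_weight": 30.0 + 150.0 * x,
            }
        )
        res = fit_weight_model(df, "dark_green_proportion")
        assert res.slope == pytest.approx(150.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.r_squared_full == pytest.approx(1.0)
        assert res.per_treatment_intercepts["C"] == pytest.approx(30.0)
        assert res.per_treatment_intercepts["N"] == pytest.approx(30.0)

    def test_treatment_offsets_absorbed_by_intercepts(self):
        cfg = SyntheticExperimentConfig(seed=11)
        rec = gen_experiment(cfg)
        res1 = fit_weight_model(rec, "dark_green_proportion")
        shifted = rec.copy()
        shifted.loc[shifted.treatment == "N", "fresh_weight"] += 500.0
        res2 = fit_weight_model(shifted, "dark_green_proportion")
        assert res2.slope == pytest.approx(res1.slope, abs=1e-8)

    def test_constant_predictor_rejected(self):
        df = pd.DataFrame(
            {
                "plant_id": list("abcd"),
                "treatment": ["C", "C", "N", "N"],
                "dark_green_proportion": [0.3] * 4,
                "fresh_weight": [10.0, 20.0, 30.0, 40.0],
            }
        )
        with pytest.raises(ModelError, match="dark_green_proportion"):
            fit_weight_model(df, "dark_green_proportion")

    def test_single_treatment_rejected(self):
        df = pd.DataFrame(
            {
                "plant_id": list("abcd"),
                "treatment": ["C"] * 4,
                "dark_green_proportion": [0.1, 0.2, 0.3, 0.4],
                "fresh_weight": [10.0, 20.0, 30.0, 40.0],
            }
        )
        with pytest.raises(ModelError, match="2 treatments"):
            fit_weight_model(df, "dark_green_proportion")

    def test_slope_interval_covers_generating_value(self):
        # configured effect beta = 200 g/unit, sigma = 5 g, 32 plants
        cfg_kw = dict(beta=200.0, sigma=5.0, n_per_treatment=8)
        covered, signs = 0, 0
        reps = 120
        for seed in range(reps):
            rec = gen_experiment(SyntheticExperimentConfig(seed=seed, **cfg_kw))
            res = fit_weight_model(rec, "dark_green_proportion")
            covered += res.slope_ci[0] <= 200.0 <= res.slope_ci[1]
            signs += res.slope > 0
        assert signs == reps
        assert covered / reps == pytest.approx(0.95, abs=0.06)

    def test_mixed_variant_pooled_experiments(self):
        recs = pd.concat(
            [
                gen_experiment(SyntheticExperimentConfig(seed=1, experiment_id="e1")),
                gen_experiment(
                    SyntheticExperimentConfig(
                        seed=2,
                        experiment_id="e2",
                        weight_intercepts={"C": 30.0, "LV": 40.0, "N": 45.0, "I": 32.0},
                    )
                ),
            ],
            ignore_index=True,
        )
        res = fit_weight_model(recs, "dark_green_proportion", method="mixed")
        assert res.slope == pytest.approx(150.0, rel=0.25)
        assert 0.0 <= res.r_squared_full <= 1.0

    def test_from_dataframe_alias(self):
        rec = gen_experiment(SyntheticExperimentConfig(seed=3))
        res = WeightColorModel.from_dataframe(rec, "intensity").fit()
        assert res.predictor == "intensity"


class TestExperimentReport:
    def test_empty_records_empty_report(self):
        rep = experiment_report(pd.DataFrame())
        assert rep.empty
        assert "no records" in rep.summary()

    def test_synthetic_experiment_cardinality(self):
        rec = gen_experiment(SyntheticExperimentConfig(seed=4))
        rep = experiment_report(rec)
        assert len(rep.treatment_table) == 4
        assert set(rep.fits) == {"intensity", "dark_green_proportion"}
        assert {"fresh_weight", "leaf_count"} <= set(rep.anova)

    def test_fits_match_direct_calls(self):
        rec = gen_experiment(SyntheticExperimentConfig(seed=4))
        rep = experiment_report(rec)
        direct = fit_weight_model(rec, "dark_green_proportion")
        assert rep.fits["dark_green_proportion"].slope == pytest.approx(direct.slope)
        assert rep.fits["dark_green_proportion"].p_slope == pytest.approx(direct.p_slope)

    def test_summary_mentions_all_sections(self):
        rec = gen_experiment(SyntheticExperimentConfig(seed=4))
        text = experiment_report(rec).summary()
        assert "Treatment means" in text
        assert "One-way ANOVA" in text
        assert "Fresh weight ~ treatment + intensity" in text
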