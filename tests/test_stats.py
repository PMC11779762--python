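import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from funcest.exceptions import InvalidArgumentError, UndefinedCorrelationError
from funcest.stats import (
    condition_means,
    consistency_analysis,
    factorial_anova,
    parameter_anova,
    parameter_correlations,
)
from funcest.stimuli import full_design

EFFECTS = [
    "generator",
    "n_points",
    "scale",
    "generator:n_points",
    "generator:scale",
    "n_points:scale",
    "generator:n_points:scale",
]


def design_frame():
    cells = full_design()
    return pd.DataFrame(
        [
            {"generator": c.generator, "n_points": c.n_points, "scale": c.scale}
            for c in cells
        ]
    )


def records_frame(rng, n_participants=6, value_fn=None):
    rows = []
    for pid in range(n_participants):
        for c in full_design():
            base = value_fn(pid, c, rng) if value_fn else rng.normal()
            rows.append(
                {
                    "participant_id": f"p{pid}",
                    "problem_id": c.problem_id,
                    "generator": c.generator,
                    "n_points": c.n_points,
                    "scale": c.scale,
                    "replicate": c.replicate,
                    "log_lambda": base,
                    "log_signal_var": rng.normal(),
                    "log_noise_var": rng.normal(),
                }
            )
    return pd.DataFrame(rows)


class TestConditionMeans:
    def test_constant_records_give_constant_means_zero_se(self):
        df = records_frame(np.random.default_rng(0), 3)
        df[["log_lambda", "log_signal_var", "log_noise_var"]] = [0.5, -0.2, -3.0]
        out = condition_means(df)
        np.testing.assert_allclose(out["log_lambda_mean"], 0.5)
        np.testing.assert_allclose(out["log_lambda_se"], 0.0)

    def test_invariant_to_record_order_and_reports_missing_cells(self):
        df = records_frame(np.random.default_rng(1), 4)
        out1 = condition_means(df)
        out2 = condition_means(df.sample(frac=1, random_state=2))
        pd.testing.assert_frame_equal(out1, out2)
        partial = condition_means(df[df["scale"] == "large"])
        assert len(partial) == 12
        assert partial.loc[partial["scale"] == "small", "log_lambda_mean"].isna().all()

    def test_scale_linked_length_scale_profile_shows_in_cell_means(self):
        def value_fn(pid, cell, rng):
            lam = 2.0 if cell.scale == "large" else 0.05
            return np.log(lam) + rng.normal(0, 0.1)

        df = records_frame(np.random.default_rng(3), 8, value_fn)
        out = condition_means(df).dropna()
        large = out[out["scale"] == "large"]["log_lambda_mean"]
        small = out[out["scale"] == "small"]["log_lambda_mean"]
        assert large.min() > small.max()


def oracle_factorial(values, design):
    """Brute-force balanced factorial SS from marginal means."""
    df = design.copy()
    df["value"] = values
    grand = df["value"].mean()
    n = len(df)
    ss = {}
    for k in range(1, 4):
        for combo in itertools.combinations(["generator", "n_points", "scale"], k):
            contrib = np.zeros(n)
            for r in range(k + 1):
                for sub in itertools.combinations(combo, r):
                    if sub:
                        m = df.groupby(list(sub), observed=True)["value"].transform("mean")
                    else:
                        m = pd.Series(grand, index=df.index)
                    contrib += ((-1) ** (k - r)) * m.to_numpy()
            ss[":".join(combo)] = float(np.sum(contrib**2))
    cellmean = df.groupby(["generator", "n_points", "scale"], observed=True)[
        "value"
    ].transform("mean")
    ss["Residual"] = float(np.sum((df["value"] - cellmean) ** 2))
    return ss


class TestFactorialAnova:
    def test_agrees_with_marginal_means_oracle_on_random_designs(self):
        design = design_frame()
        rng = np.random.default_rng(0)
        for _ in range(100):
            values = rng.normal(5, 2, 24)
            table = factorial_anova(values, design)
            oracle = oracle_factorial(values, design)
            for effect in EFFECTS + ["Residual"]:
                assert table.table.loc[effect, "SS"] == pytest.approx(
                    oracle[effect], abs=1e-8
                )

    def test_ss_decomposition_and_df_identities(self):
        design = design_frame()
        rng = np.random.default_rng(1)
        for _ in range(20):
            values = rng.normal(0, 3, 24)
            table = factorial_anova(values, design)
            total = np.sum((values - values.mean()) ** 2)
            assert table.ss_total == pytest.approx(total, rel=1e-9)
            assert table.table["df"].sum() == 23

    def test_zero_variance_input_flagged_not_raised(self):
        table = factorial_anova(np.full(24, 3.0), design_frame())
        assert table.zero_variance
        assert table.F("scale") == 0.0 and table.p("scale") == 1.0

    def test_unbalanced_design_rejected(self):
        design = design_frame().iloc[:23]
        with pytest.raises(InvalidArgumentError):
            factorial_anova(np.zeros(23), design)


class TestParameterAnova:
    def test_constant_within_participant_gives_zero_f(self):
        df = records_frame(np.random.default_rng(0), 5)
        df["log_lambda"] = df["participant_id"].str[1:].astype(int).astype(float)
        table = parameter_anova(df, "log_lambda")
        for effect in EFFECTS:
            assert table.F(effect) == 0.0 and table.p(effect) == 1.0

    def test_matches_saturated_ols_decomposition(self):
        df = records_frame(np.random.default_rng(7), 6)
        table = parameter_anova(df, "log_lambda")
        cellmeans = (
            df.groupby(["participant_id", "generator", "n_points", "scale"], observed=True)[
                "log_lambda"
            ]
            .mean()
            .reset_index()
        )
        model = smf.ols(
            "log_lambda ~ C(generator) * C(n_points) * C(scale) * C(participant_id)",
            data=cellmeans,
        ).fit()
        aov = anova_lm(model, typ=1)
        for effect in EFFECTS:
            term = ":".join(f"C({f})" for f in effect.split(":"))
            ss_e = aov.loc[term, "sum_sq"]
            df_e = aov.loc[term, "df"]
            ss_err = aov.loc[f"{term}:C(participant_id)", "sum_sq"]
            df_err = aov.loc[f"{term}:C(participant_id)", "df"]
            f_oracle = (ss_e / df_e) / (ss_err / df_err)
            assert table.F(effect) == pytest.approx(f_oracle, abs=1e-8)

    def test_power_to_detect_additive_scale_effect(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)

            def value_fn(pid, cell, rng=rng):
                return (
                    rng.normal(0, 0.1)
                    + (1.0 if cell.scale == "large" else 0.0)
                )

            df = records_frame(np.random.default_rng(10_000 + seed), 20, value_fn)
            table = parameter_anova(df, "log_lambda")
            hits += table.p("scale") < 0.001
        assert hits >= 95

    def test_incomplete_participants_dropped_listwise(self):
        df = records_frame(np.random.default_rng(2), 4)
        # drop both replicates of one design cell for p0 -> incomplete
        df = df[
            ~(
                (df["participant_id"] == "p0")
                & (df["problem_id"].isin(["L6S-1", "L6S-2"]))
            )
        ]
        table = parameter_anova(df, "log_lambda")
        # 3 complete participants remain -> participant df = 2
        assert table.table.loc["participant", "df"] == 2


class TestParameterCorrelations:
    def test_exact_linear_dependence_gives_unit_r(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "log_lambda": rng.normal(0, 1, 30),
                "log_noise_var": rng.normal(0, 1, 30),
            }
        )
        df["log_signal_var"] = 2.0 * df["log_lambda"]
        out = parameter_correlations(df).set_index("pair")
        assert out.loc["log_lambda~log_signal_var", "r"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_covariance_formula_and_invariances(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            rng.normal(0, 1, (40, 3)),
            columns=["log_lambda", "log_signal_var", "log_noise_var"],
        )
        out = parameter_correlations(df).set_index("pair")
        for a, b in itertools.combinations(df.columns, 2):
            x, y = df[a].to_numpy(), df[b].to_numpy()
            r_direct = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
            )
            assert out.loc[f"{a}~{b}", "r"] == pytest.approx(r_direct, abs=1e-12)
        shifted = parameter_correlations(df.assign(log_lambda=df["log_lambda"] + 5.0))
        shuffled = parameter_correlations(df.sample(frac=1, random_state=3))
        np.testing.assert_allclose(out["r"], shifted.set_index("pair")["r"], atol=1e-12)
        np.testing.assert_allclose(out["r"], shuffled.set_index("pair")["r"], atol=1e-12)

    def test_zero_variance_column_rejected(self):
        df = pd.DataFrame(
            {
                "log_lambda": np.ones(10),
                "log_signal_var": np.arange(10.0),
                "log_noise_var": np.arange(10.0),
            }
        )
        with pytest.raises(UndefinedCorrelationError):
            parameter_correlations(df)


class TestConsistencyAnalysis:
    @staticmethod
    def frame(n_participants, n_problems, between_sd, within_sd, seed):
        rng = np.random.default_rng(seed)
        offsets = rng.normal(0, between_sd, n_participants)
        rows = []
        for i in range(n_participants):
            for t in range(n_problems):
                rows.append(
                    {
                        "participant_id": f"p{i}",
                        "problem_id": f"T{t}",
                        "log_lambda": offsets[i] + rng.normal(0, within_sd),
                        "log_signal_var": rng.normal(),
                        "log_noise_var": rng.normal(),
                    }
                )
        return pd.DataFrame(rows)

    def test_df_convention_counts_trial_pairs(self):
        df = self.frame(10, 24, 1.0, 0.5, seed=0)
        res = consistency_analysis(df, parameters=("log_lambda",))[0]
        assert res.n_pairs == 276 and res.df == 275

    def test_persistent_individual_offsets_detected(self):
        hits = 0
        for seed in range(100):
            df = self.frame(50, 8, 1.0, 0.5, seed=seed)
            res = consistency_analysis(df, parameters=("log_lambda",))[0]
            hits += (res.mean_r > 0) and (res.p < 0.01)
        assert hits >= 95

    def test_no_offsets_give_near_zero_mean_r(self):
        rejections = 0
        mean_rs = []
        for seed in range(100):
            df = self.frame(50, 8, 0.0, 0.5, seed=200 + seed)
            res = consistency_analysis(df, parameters=("log_lambda",))[0]
            mean_rs.append(res.mean_r)
            rejections += res.p < 0.05
        assert abs(np.mean(mean_rs)) < 0.05
        assert rejections <= 10

    def test_identical_values_exercise_undefined_path(self):
        df = self.frame(6, 5, 0.0, 0.0, seed=1)
        df["log_lambda"] = 1.0
        with pytest.raises(UndefinedCorrelationError):
            consistency_analysis(df, parameters=("log_lambda",))
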