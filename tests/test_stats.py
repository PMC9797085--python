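"""Mixed-model fitting: contracts, cross-checks and reporting rules."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from tunel3d import stats
from tunel3d.stats import (
    ConvergenceError,
    condense_stage,
    fit_binary_endpoint,
    fit_count_models,
    fit_ordinal,
    significance_labels,
    summarize_dev,
    summarize_metrics,
)
from tunel3d.synthetic_data import (
    DevSimParams,
    MetricsSimParams,
    generate_dev_table,
    generate_metrics_table,
)


@pytest.fixture(scope="module")
def dev_tables():
    return generate_dev_table(
        DevSimParams(seed=11, odds_ratios={"cleaved": {"PFHxS": 1.8}})
    )


class TestBinaryEndpoint:
    def test_or_ci_consistent_with_wald_interval(self, dev_tables):
        groups, _ = dev_tables
        fit = fit_binary_endpoint(groups, "cleaved")
        for r in fit.terms.itertuples():
            if np.isnan(r.OR):
                continue
            assert r.CI_low <= r.OR <= r.CI_high
            assert r.CI_low == pytest.approx(np.exp(r.estimate - 1.96 * r.se), rel=1e-9)
            assert r.CI_high == pytest.approx(np.exp(r.estimate + 1.96 * r.se), rel=1e-9)

    def test_matches_lme4_glmer_adaptive_quadrature(self, dev_tables, tmp_path):
        """Independent oracle: lme4::glmer with nAGQ=25 on the same table."""
        groups, _ = dev_tables
        csv = tmp_path / "g.csv"
        groups.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$treatment <- relevel(factor(d$treatment), ref="control")
            m <- glmer(cbind(cleaved, n_oocytes-cleaved) ~ treatment + (1|replicate),
                       data=d, family=binomial,
                       control=glmerControl(optimizer="bobyqa"), nAGQ=25)
            co <- summary(m)$coefficients
            cat(co[,1], co[,2], sqrt(unlist(VarCorr(m))), sep="\\n")
        """)
        proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        vals = [float(v) for v in proc.stdout.split()]
        r_beta, r_se, r_sigma = vals[0:3], vals[3:6], vals[6]
        fit = fit_binary_endpoint(groups, "cleaved")
        t = fit.terms.set_index("term")
        ours = [t.loc["intercept", "estimate"], t.loc["PFHxS", "estimate"], t.loc["PFOS", "estimate"]]
        assert np.allclose(ours, r_beta, atol=2e-3)
        ours_se = [t.loc["intercept", "se"], t.loc["PFHxS", "se"], t.loc["PFOS", "se"]]
        assert np.allclose(ours_se, r_se, atol=2e-3)
        assert fit.random_effect_sd == pytest.approx(r_sigma, abs=5e-3)

    def test_joint_blastocyst_model_has_day_term(self, dev_tables):
        groups, _ = dev_tables
        fit = fit_binary_endpoint(groups, "blastocyst")
        assert "day6" in set(fit.terms["term"])
        assert fit.term("day6")["estimate"] > 0  # day-6 rate exceeds day-5

    def test_zero_variance_outcome_raises(self, dev_tables):
        groups, _ = dev_tables
        dead = groups.copy()
        dead["cleaved"] = 0
        with pytest.raises(ConvergenceError):
            fit_binary_endpoint(dead, "cleaved")

    def test_single_replicate_rejected(self, dev_tables):
        groups, _ = dev_tables
        one = groups[groups["replicate"] == 1]
        with pytest.raises(ValueError):
            fit_binary_endpoint(one, "cleaved")

    def test_unknown_endpoint_rejected(self, dev_tables):
        with pytest.raises(ValueError):
            fit_binary_endpoint(dev_tables[0], "hatched")


class TestOrdinal:
    def test_stage_condensation_mapping(self):
        s = pd.Series(["early", "blastocyst", "expanding", "hatching"])
        assert condense_stage(s).tolist() == [1, 1, 2, 2]
        with pytest.raises(ValueError):
            condense_stage(pd.Series(["morula"]))

    def test_single_category_errors(self):
        b = pd.DataFrame(
            {"replicate": [1, 1, 2, 2], "treatment": ["control", "PFOS"] * 2,
             "stage": ["early"] * 4, "grade": [2.0] * 4}
        )
        with pytest.raises(ConvergenceError):
            fit_ordinal(b, "grade")

    def test_matches_ordered_logit_when_clustering_absent(self):
        """With no replicate effect the CLMM collapses to ordered logit."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        _, blasts = generate_dev_table(
            DevSimParams(seed=21, replicate_sd=0.0, n_replicates=40,
                         grade_or={"PFHxS": 2.0})
        )
        fit = fit_ordinal(blasts, "grade")
        exog = pd.get_dummies(blasts["treatment"])[["PFHxS", "PFOS"]].astype(float)
        om = OrderedModel(
            pd.Categorical(blasts["grade"], ordered=True), exog, distr="logit"
        ).fit(method="bfgs", disp=False)
        # shared sign convention: CLMM beta is the shift toward higher categories
        assert fit.term("PFHxS")["estimate"] == pytest.approx(om.params["PFHxS"], abs=0.05)
        assert fit.term("PFOS")["estimate"] == pytest.approx(om.params["PFOS"], abs=0.05)
        assert fit.random_effect_sd < 0.15

    def test_detects_simulated_grade_shift(self):
        _, blasts = generate_dev_table(
            DevSimParams(seed=22, n_replicates=30, grade_or={"PFHxS": 3.0})
        )
        fit = fit_ordinal(blasts, "grade")
        assert fit.term("PFHxS")["p"] < 0.05
        assert fit.term("PFHxS")["estimate"] > 0


class TestCountModels:
    def test_single_treatment_rejected(self):
        m = generate_metrics_table(MetricsSimParams(seed=1))
        with pytest.raises(ValueError):
            fit_count_models(m[m["treatment"] == "control"])

    def test_too_few_embryos_rejected(self):
        m = generate_metrics_table(MetricsSimParams(seed=2)).head(6)
        with pytest.raises(ValueError):
            fit_count_models(m)

    def test_detects_count_increase(self):
        m = generate_metrics_table(
            MetricsSimParams(seed=3, count_effect={"PFHxS": 1.5}, embryos_per_group=12)
        )
        fits = fit_count_models(m)
        assert fits["cell_count"].term("PFHxS")["estimate"] > 0
        assert fits["cell_count"].term("PFHxS")["p"] < 0.05

    def test_size_apoptosis_slope_recovered(self):
        m = generate_metrics_table(
            MetricsSimParams(seed=4, prop_slope_per_nucleus=-0.0013, embryos_per_group=10)
        )
        fits = fit_count_models(m)
        slope = fits["apoptosis_proportion"].term("n_nuclei")["estimate"]
        assert slope < 0
        assert slope == pytest.approx(-0.0013, abs=0.001)

    def test_excluded_rows_are_dropped(self):
        m = generate_metrics_table(MetricsSimParams(seed=5))
        m.loc[m.index[:10], "excluded"] = True
        fits = fit_count_models(m)
        assert fits["cell_count"].n_obs == len(m) - 10


class TestReporting:
    @pytest.mark.parametrize(
        "p,label", [(0.02, "significant"), (0.06, "tendency"), (0.5, "ns"),
                    (0.049, "significant"), (0.05, "tendency")]
    )
    def test_significance_thresholds(self, p, label):
        fit = stats.ModelFit(
            model="m",
            terms=pd.DataFrame(
                [{"term": "t", "estimate": 0.1, "se": 0.1, "OR": 1.1,
                  "CI_low": 0.9, "CI_high": 1.3, "p": p}]
            ),
        )
        assert significance_labels(fit)["label"].iloc[0] == label

    def test_summaries_have_expected_shape(self, dev_tables):
        groups, _ = dev_tables
        s = summarize_dev(groups)
        assert set(s["treatment"]) == {"control", "PFOS", "PFHxS"}
        m = generate_metrics_table(MetricsSimParams(seed=6))
        sm = summarize_metrics(m)
        assert {"mean_n_nuclei", "mean_prop_apoptotic"} <= set(sm.columns)
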