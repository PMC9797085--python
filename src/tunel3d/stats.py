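"""Treatment-effect models for developmental and apoptosis outcomes.

Three model families, mirroring the study's analysis plan:

* binary developmental endpoints (cleavage, blastocyst rates) —
  mixed-effect logistic regression on replicate × treatment binomial
  counts, group size as binomial trials ("weighted for size"), replicate
  as a random intercept; day-5/day-6 blastocyst outcomes can be fitted
  jointly as repeated measurements with day as a covariate;
* ordinal blastocyst stage and quality grade — cumulative-link
  (proportional odds) mixed models with a replicate random intercept,
  stage condensed to {early blastocyst, blastocyst} = 1 vs
  {expanding, hatching} = 2;
* per-embryo counts — linear mixed models on log cell count and
  log(TUNEL count + 1), the latter adjusted for nucleus count, plus a
  secondary model of the raw apoptotic proportion against nucleus count
  (the size–apoptosis association).

Odds ratios are reported so that OR < 1 means a negative treatment
effect; p < 0.05 is labelled significant and 0.05 <= p < 0.1 a tendency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from ._glmm import ConvergenceError, fit_binomial_glmm, fit_cumulative_glmm

logger = logging.getLogger("tunel3d")

BINARY_ENDPOINTS = ("cleaved", "cleaved_gt2", "blastocyst_d5", "blastocyst_d6", "blastocyst")
STAGE_CONDENSATION = {"early": 1, "blastocyst": 1, "expanding": 2, "hatching": 2}

__all__ = [
    "ModelFit",
    "ConvergenceError",
    "fit_binary_endpoint",
    "fit_ordinal",
    "fit_count_models",
    "significance_labels",
    "condense_stage",
    "summarize_metrics",
    "summarize_dev",
]


@dataclass
class ModelFit:
    """A fitted model: per-term estimates with Wald inference.

    ``terms`` columns: term, estimate (link scale), se, OR (exp of the
    estimate where it is a log-odds or log-scale effect, NaN otherwise),
    CI_low, CI_high (on the OR scale when OR is defined, otherwise on
    the estimate scale), p.
    """

    model: str
    terms: pd.DataFrame
    random_effect_sd: float = float("nan")
    loglik: float = float("nan")
    n_obs: int = 0
    notes: dict = field(default_factory=dict)

    def term(self, name: str) -> pd.Series:
        hit = self.terms[self.terms["term"] == name]
        if hit.empty:
            raise KeyError(f"no term {name!r} in model {self.model}")
        return hit.iloc[0]

    def to_frame(self) -> pd.DataFrame:
        out = self.terms.copy()
        out.insert(0, "model", self.model)
        return out


def _wald_terms(names, beta, se, exponentiate, df: float | None = None) -> pd.DataFrame:
    """Wald inference; a finite ``df`` uses a t reference (linear mixed
    models), otherwise the normal reference (GLMM convention)."""
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    z = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    if df is not None and np.isfinite(df) and df > 0:
        p = 2.0 * sps.t.sf(np.abs(z), df)
    else:
        p = 2.0 * sps.norm.sf(np.abs(z))
    lo, hi = beta - 1.96 * se, beta + 1.96 * se
    rows = []
    for i, name in enumerate(names):
        if exponentiate[i]:
            rows.append((name, beta[i], se[i], np.exp(beta[i]), np.exp(lo[i]), np.exp(hi[i]), p[i]))
        else:
            rows.append((name, beta[i], se[i], np.nan, lo[i], hi[i], p[i]))
    return pd.DataFrame(
        rows, columns=["term", "estimate", "se", "OR", "CI_low", "CI_high", "p"]
    )


def _treatment_design(treatments: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = [t for t in ["control"] if t in set(treatments)] + sorted(
        set(treatments) - {"control"}
    )
    if len(levels) < 2:
        raise ValueError("need at least two treatment groups")
    if levels[0] != "control":
        logger.warning("no control group present; %s used as reference", levels[0])
    cols = [(treatments == lv).astype(float).to_numpy() for lv in levels[1:]]
    return np.column_stack(cols), levels[1:]


def fit_binary_endpoint(
    records: pd.DataFrame,
    endpoint: str,
    weighting: str = "trials",
    n_quad: int = 25,
) -> ModelFit:
    """Mixed-effect logistic regression for one developmental endpoint.

    ``records`` holds one row per replicate × treatment with columns
    ``replicate, treatment, n_oocytes`` and the endpoint success counts.
    The denominator of ``cleaved_gt2`` is the cleaved count; all other
    endpoints use the group size. ``endpoint="blastocyst"`` fits day 5
    and day 6 jointly as repeated measurements with a day-6 indicator.
    Raises :class:`ConvergenceError` on a zero-variance outcome.
    """
    if endpoint not in BINARY_ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}; expected one of {BINARY_ENDPOINTS}")
    records = records.reset_index(drop=True)
    if records["replicate"].nunique() < 2:
        raise ValueError("need at least two replicates for a random intercept")

    trt_design, trt_names = _treatment_design(records["treatment"])
    if endpoint == "blastocyst":
        y = np.r_[records["blastocyst_d5"], records["blastocyst_d6"]]
        n = np.r_[records["n_oocytes"], records["n_oocytes"]]
        day6 = np.r_[np.zeros(len(records)), np.ones(len(records))]
        X = np.column_stack(
            [np.ones(2 * len(records)), np.vstack([trt_design, trt_design]), day6]
        )
        names = ["intercept"] + trt_names + ["day6"]
        groups = np.r_[records["replicate"], records["replicate"]]
    else:
        y = records[endpoint].to_numpy()
        n = (records["cleaved"] if endpoint == "cleaved_gt2" else records["n_oocytes"]).to_numpy()
        X = np.column_stack([np.ones(len(records)), trt_design])
        names = ["intercept"] + trt_names
        groups = records["replicate"].to_numpy()

    keep = n > 0
    fit = fit_binomial_glmm(y[keep], n[keep], X[keep], np.asarray(groups)[keep], n_quad=n_quad)
    terms = _wald_terms(names, fit["beta"], fit["se"], [False] + [True] * (len(names) - 1))
    return ModelFit(
        model=f"binary:{endpoint}",
        terms=terms,
        random_effect_sd=fit["sigma"],
        loglik=fit["loglik"],
        n_obs=fit["n_obs"],
        notes={"weighting": weighting, "random_effect": "replicate intercept"},
    )


def condense_stage(stage: pd.Series) -> pd.Series:
    """Condense the four blastocyst stages to the two-level analysis coding."""
    out = stage.map(STAGE_CONDENSATION)
    if out.isna().any():
        bad = sorted(set(stage[out.isna()]))
        raise ValueError(f"unknown stage value(s): {bad}")
    return out


def fit_ordinal(
    records: pd.DataFrame,
    variable: str,
    n_quad: int = 25,
) -> ModelFit:
    """Cumulative-link mixed model for blastocyst stage or grade.

    ``records`` has one row per blastocyst (replicate, treatment, stage,
    grade). Stage is condensed to two levels before fitting; grade uses
    its observed ordered categories. Raises :class:`ConvergenceError`
    when only one category is observed.
    """
    if variable not in ("stage", "grade"):
        raise ValueError("variable must be 'stage' or 'grade'")
    records = records.reset_index(drop=True)
    values = condense_stage(records["stage"]) if variable == "stage" else records[variable]
    cats = np.sort(pd.unique(values))
    codes = pd.Categorical(values, categories=cats, ordered=True).codes
    trt_design, trt_names = _treatment_design(records["treatment"])
    fit = fit_cumulative_glmm(
        codes, trt_design, records["replicate"].to_numpy(), n_categories=len(cats),
        n_quad=n_quad,
    )
    terms = _wald_terms(trt_names, fit["beta"], fit["se"], [True] * len(trt_names))
    return ModelFit(
        model=f"ordinal:{variable}",
        terms=terms,
        random_effect_sd=fit["sigma"],
        loglik=fit["loglik"],
        n_obs=fit["n_obs"],
        notes={"categories": list(cats), "random_effect": "replicate intercept"},
    )


def _mixedlm(endog, exog, names, groups, model_name, exponentiate) -> ModelFit:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(endog, exog, groups=np.asarray(groups))
        try:
            fit = model.fit(reml=True)
        except np.linalg.LinAlgError:
            fit = model.fit(reml=True, method="powell", maxiter=500)
    k = len(names)
    n_groups = len(np.unique(np.asarray(groups)))
    df = max(float(fit.nobs) - k - n_groups, 1.0)  # residual-df t reference
    terms = _wald_terms(names, fit.params[:k], fit.bse[:k], exponentiate, df=df)
    re_sd = float(np.sqrt(np.asarray(fit.cov_re)[0, 0]))
    return ModelFit(
        model=model_name,
        terms=terms,
        random_effect_sd=re_sd,
        loglik=float(fit.llf),
        n_obs=int(fit.nobs),
        notes={"random_effect": "replicate intercept", "estimation": "REML"},
    )


def fit_count_models(metrics: pd.DataFrame) -> dict[str, ModelFit]:
    """Linear mixed models on per-embryo counts and apoptosis.

    Returns three fits:

    * ``cell_count`` — log nucleus count ~ treatment;
    * ``tunel_count`` — log(apoptotic count + 1) ~ treatment +
      log nucleus count (the nucleus-count adjustment);
    * ``apoptosis_proportion`` — raw apoptotic proportion ~ treatment +
      nucleus count; the ``n_nuclei`` coefficient is the size–apoptosis
      slope on the proportion scale.

    Requires >= 10 non-excluded embryos spanning >= 2 treatments.
    """
    data = metrics.loc[~metrics.get("excluded", pd.Series(False, index=metrics.index)).astype(bool)]
    data = data.dropna(subset=["n_nuclei", "n_apoptotic", "prop_apoptotic"])
    if len(data) < 10:
        raise ValueError(f"need >= 10 non-excluded embryos, got {len(data)}")
    trt_design, trt_names = _treatment_design(data["treatment"])
    groups = data["replicate"].to_numpy()
    ones = np.ones(len(data))
    log_n = np.log(data["n_nuclei"].to_numpy(float))

    fits: dict[str, ModelFit] = {}
    fits["cell_count"] = _mixedlm(
        log_n,
        np.column_stack([ones, trt_design]),
        ["intercept"] + trt_names,
        groups,
        "count:cell_count",
        [False] + [True] * len(trt_names),
    )
    fits["tunel_count"] = _mixedlm(
        np.log1p(data["n_apoptotic"].to_numpy(float)),
        np.column_stack([ones, trt_design, log_n]),
        ["intercept"] + trt_names + ["log_n_nuclei"],
        groups,
        "count:tunel_count",
        [False] + [True] * len(trt_names) + [False],
    )
    fits["apoptosis_proportion"] = _mixedlm(
        data["prop_apoptotic"].to_numpy(float),
        np.column_stack([ones, trt_design, data["n_nuclei"].to_numpy(float)]),
        ["intercept"] + trt_names + ["n_nuclei"],
        groups,
        "count:apoptosis_proportion",
        [False] * (len(trt_names) + 2),
    )
    return fits


def significance_labels(fit: ModelFit) -> pd.DataFrame:
    """Label each term significant (p < 0.05), tendency (0.05 <= p < 0.1) or ns."""
    out = fit.to_frame()
    out["label"] = np.select(
        [out["p"] < 0.05, out["p"] < 0.1], ["significant", "tendency"], default="ns"
    )
    return out


# ---------------------------------------------------------------------------
# summary tables


def summarize_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment mean (SD) of nucleus counts and apoptotic proportions."""
    data = metrics.loc[~metrics.get("excluded", pd.Series(False, index=metrics.index)).astype(bool)]
    g = data.groupby("treatment")
    return pd.DataFrame(
        {
            "n_embryos": g.size(),
            "mean_n_nuclei": g["n_nuclei"].mean(),
            "sd_n_nuclei": g["n_nuclei"].std(ddof=1),
            "mean_prop_apoptotic": g["prop_apoptotic"].mean(),
            "sd_prop_apoptotic": g["prop_apoptotic"].std(ddof=1),
        }
    ).reset_index()


def summarize_dev(groups: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment mean (SD) of the developmental proportions."""
    df = groups.copy()
    df["p_cleaved"] = df["cleaved"] / df["n_oocytes"]
    df["p_cleaved_gt2"] = np.where(df["cleaved"] > 0, df["cleaved_gt2"] / df["cleaved"], np.nan)
    df["p_blastocyst_d5"] = df["blastocyst_d5"] / df["n_oocytes"]
    df["p_blastocyst_d6"] = df["blastocyst_d6"] / df["n_oocytes"]
    g = df.groupby("treatment")
    out = {}
    for col in ("p_cleaved", "p_cleaved_gt2", "p_blastocyst_d5", "p_blastocyst_d6"):
        out[f"mean_{col[2:]}"] = g[col].mean()
        out[f"sd_{col[2:]}"] = g[col].std(ddof=1)
    return pd.DataFrame(out).reset_index()
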