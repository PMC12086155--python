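"""Treatment comparisons and the fresh-weight ~ leaf-color model.

The experimental unit is a plant record: treatment (C = untreated control,
N = nitrogen fertilizer, LV = leafy-vegetable compound fertilizer, I =
microelement fertilizer), fresh weight in grams at harvest, leaf count
(leaves >= 2 cm on the longest side), and the device-averaged color metrics.

Two analyses are provided:

* one-way ANOVA across the four treatments for any response, with unadjusted
  pairwise Welch t-tests (Holm adjustment optional);
* an ANCOVA of fresh weight on one color predictor (normalized intensity or
  dark-green proportion) with a separate intercept per treatment and a
  common slope — :class:`WeightColorModel`.  With a single endpoint
  observation per plant and treatment as the only grouping, fixed treatment
  intercepts are the identifiable form of a "within-treatment" relationship;
  a random-intercept-by-experiment variant is available for pooled
  multi-experiment data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .errors import InputError, InsufficientDataError, ModelError

TREATMENTS = ("C", "N", "LV", "I")

RECORD_COLUMNS = (
    "plant_id",
    "experiment_id",
    "treatment",
    "fresh_weight",
    "leaf_count",
    "intensity",
    "dark_green_proportion",
)


def validate_records(records: pd.DataFrame, require_metrics: bool = False) -> pd.DataFrame:
    """Check a plant-record table and coerce treatment to a category."""
    needed = {"plant_id", "treatment", "fresh_weight"}
    if require_metrics:
        needed |= {"intensity", "dark_green_proportion"}
    missing = needed - set(records.columns)
    if missing:
        raise InputError(f"record table lacks columns {sorted(missing)}")
    bad = set(records["treatment"].unique()) - set(TREATMENTS)
    if bad:
        raise InputError(f"unknown treatment code(s) {sorted(bad)}; expected {TREATMENTS}")
    return records


# ---------------------------------------------------------------------------
# Treatment comparisons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreatmentComparison:
    """One-way ANOVA of a response across treatments, with pairwise tests."""

    response: str
    F: float
    p: float
    group_means: dict[str, float]
    pairwise: pd.DataFrame = field(repr=False)

    def summary(self) -> str:
        lines = [
            f"One-way ANOVA: {self.response} ~ treatment",
            f"  F = {self.F:.3f}, p = {self.p:.4g}",
            "  group means: "
            + ", ".join(f"{t}={m:.3f}" for t, m in self.group_means.items()),
            "  pairwise (Welch):",
        ]
        for row in self.pairwise.itertuples():
            lines.append(f"    {row.group_a} vs {row.group_b}: p = {row.p:.4g}")
        return "\n".join(lines)


def _grouped(records: pd.DataFrame, response: str) -> dict[str, np.ndarray]:
    if response not in records.columns:
        raise InputError(f"no column {response!r} in records")
    groups = {
        str(t): g[response].dropna().to_numpy(dtype=float)
        for t, g in records.groupby("treatment", observed=True)
    }
    groups = {t: v for t, v in groups.items() if v.size > 0}
    if len(groups) < 2 or sum(v.size >= 2 for v in groups.values()) < 2:
        raise InsufficientDataError(
            f"ANOVA on {response!r} needs >= 2 groups with >= 2 records each"
        )
    return groups


def pairwise_treatment_tests(
    records: pd.DataFrame, response: str, adjust: str | None = None
) -> pd.DataFrame:
    """Per-pair Welch t-tests of group mean differences.

    Unadjusted p-values by default; ``adjust="holm"`` applies the Holm
    step-down correction.
    """
    groups = _grouped(records, response)
    rows = []
    for a, b in itertools.combinations(sorted(groups), 2):
        t, p = st.ttest_ind(groups[a], groups[b], equal_var=False)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_a": float(np.mean(groups[a])),
                "mean_b": float(np.mean(groups[b])),
                "t": float(t),
                "p": float(p),
            }
        )
    table = pd.DataFrame(rows)
    if adjust is not None:
        if adjust != "holm":
            raise InputError(f"unknown adjustment {adjust!r}; expected None or 'holm'")
        table["p_adjusted"] = multipletests(table["p"], method="holm")[1]
    return table


def anova_oneway(
    records: pd.DataFrame, response: str, adjust: str | None = None
) -> TreatmentComparison:
    """One-way F-test of a response across treatment groups."""
    groups = _grouped(records, response)
    F, p = st.f_oneway(*groups.values())
    return TreatmentComparison(
        response=response,
        F=float(F),
        p=float(p),
        group_means={t: float(np.mean(v)) for t, v in groups.items()},
        pairwise=pairwise_treatment_tests(records, response, adjust=adjust),
    )


# ---------------------------------------------------------------------------
# Fresh weight ~ color ANCOVA
# ---------------------------------------------------------------------------


class WeightColorModel:
    """Fresh weight regressed on one color predictor within treatments.

    The model is ``fresh_weight = a_t + beta * predictor + error`` with a
    fixed intercept ``a_t`` per treatment and one common slope ``beta``
    (grams per unit predictor).  ``method="mixed"`` instead fits a random
    intercept per experiment on top of the treatment fixed effects, for
    data pooled across experiments.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        predictor: str = "dark_green_proportion",
        method: str = "ols",
    ) -> None:
        if predictor not in records.columns:
            raise InputError(f"no predictor column {predictor!r} in records")
        if method not in ("ols", "mixed"):
            raise InputError(f"unknown method {method!r}; expected 'ols' or 'mixed'")
        records = validate_records(records)
        data = records.dropna(subset=["fresh_weight", predictor, "treatment"]).copy()
        if data[predictor].nunique() < 3:
            raise ModelError(
                f"predictor {predictor!r} has fewer than 3 distinct values; "
                "slope is not estimable"
            )
        if data["treatment"].nunique() < 2:
            raise ModelError("at least 2 treatments are required")
        if method == "mixed" and "experiment_id" not in data.columns:
            raise InputError("method='mixed' requires an experiment_id column")
        self.data = data
        self.predictor = predictor
        self.method = method

    # alias matching the dataframe-first construction idiom
    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, predictor: str, **kw) -> "WeightColorModel":
        return cls(records, predictor=predictor, **kw)

    def fit(self) -> "WeightColorResults":
        formula = f"fresh_weight ~ C(treatment) + {self.predictor}"
        if self.method == "ols":
            res = smf.ols(formula, data=self.data).fit()
        else:
            res = smf.mixedlm(
                formula, data=self.data, groups=self.data["experiment_id"]
            ).fit(reml=True)

        params = res.params
        if self.predictor not in params.index:
            raise ModelError(f"slope term {self.predictor!r} dropped from the fit")
        slope = float(params[self.predictor])
        p_slope = float(res.pvalues[self.predictor])
        ci = res.conf_int().loc[self.predictor]
        slope_ci = (float(ci[0]), float(ci[1]))

        # per-treatment intercepts from the treatment-coded terms
        base = float(params.get("Intercept", 0.0))
        intercepts: dict[str, float] = {}
        for t in sorted(self.data["treatment"].unique()):
            term = f"C(treatment)[T.{t}]"
            intercepts[str(t)] = base + float(params.get(term, 0.0))

        # marginal R^2: squared correlation of weight with the predictor alone
        w = self.data["fresh_weight"].to_numpy(dtype=float)
        x = self.data[self.predictor].to_numpy(dtype=float)
        r_marginal = float(np.corrcoef(x, w)[0, 1] ** 2)
        if self.method == "ols":
            r_full = float(res.rsquared)
        else:
            fitted = np.asarray(res.fittedvalues, dtype=float)
            r_full = float(np.corrcoef(fitted, w)[0, 1] ** 2)

        return WeightColorResults(
            model=self,
            slope=slope,
            slope_ci=slope_ci,
            p_slope=p_slope,
            r_squared=r_marginal,
            r_squared_full=r_full,
            per_treatment_intercepts=intercepts,
            nobs=int(len(self.data)),
            _sm_results=res,
        )


@dataclass(frozen=True)
class WeightColorResults:
    """Fitted weight ~ color relationship.

    ``r_squared`` is the marginal (predictor-only) squared correlation with
    fresh weight; ``r_squared_full`` is the coefficient of determination of
    the full treatment + predictor fit.
    """

    model: WeightColorModel
    slope: float
    slope_ci: tuple[float, float]
    p_slope: float
    r_squared: float
    r_squared_full: float
    per_treatment_intercepts: dict[str, float]
    nobs: int
    _sm_results: object = field(repr=False, default=None)

    @property
    def predictor(self) -> str:
        return self.model.predictor

    def as_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "slope": self.slope,
            "slope_ci_lower": self.slope_ci[0],
            "slope_ci_upper": self.slope_ci[1],
            "p_slope": self.p_slope,
            "r_squared": self.r_squared,
            "r_squared_full": self.r_squared_full,
            "nobs": self.nobs,
        }

    def summary(self) -> str:
        lines = [
            f"Fresh weight ~ treatment + {self.predictor} ({self.model.method})",
            f"  n                  {self.nobs:>10d}",
            f"  slope (g/unit)     {self.slope:>10.2f}"
            f"   95% CI ({self.slope_ci[0]:.2f}, {self.slope_ci[1]:.2f})",
            f"  p (slope = 0)      {self.p_slope:>10.4g}",
            f"  R2 (marginal)      {self.r_squared:>10.3f}",
            f"  R2 (full model)    {self.r_squared_full:>10.3f}",
            "  treatment intercepts (g): "
            + ", ".join(f"{t}={a:.1f}" for t, a in self.per_treatment_intercepts.items()),
        ]
        return "\n".join(lines)


def fit_weight_model(
    records: pd.DataFrame, predictor: str = "dark_green_proportion", method: str = "ols"
) -> WeightColorResults:
    """Convenience wrapper: build and fit a :class:`WeightColorModel`."""
    return WeightColorModel(records, predictor=predictor, method=method).fit()


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


@dataclass
class ExperimentReport:
    """Collected endpoint statistics for one experiment."""

    treatment_table: pd.DataFrame
    anova: dict[str, TreatmentComparison]
    fits: dict[str, WeightColorResults]
    agreement: pd.DataFrame | None = None

    @property
    def empty(self) -> bool:
        return self.treatment_table.empty

    def summary(self) -> str:
        if self.empty:
            return "Experiment report: no records"
        parts = ["Treatment means:", self.treatment_table.to_string(index=False), ""]
        for comp in self.anova.values():
            parts.extend([comp.summary(), ""])
        for fit in self.fits.values():
            parts.extend([fit.summary(), ""])
        if self.agreement is not None and not self.agreement.empty:
            parts.extend(["Device agreement:", self.agreement.to_string(index=False)])
        return "\n".join(parts).rstrip() + "\n"


def experiment_report(
    records: pd.DataFrame,
    agreement: pd.DataFrame | None = None,
    responses: tuple[str, ...] = ("fresh_weight", "leaf_count"),
    predictors: tuple[str, ...] = ("intensity", "dark_green_proportion"),
) -> ExperimentReport:
    """Assemble treatment means, ANOVA/pairwise p-values and both color fits.

    Degenerate inputs produce a partial (possibly empty) report rather than
    an error; each analysis is attempted independently.
    """
    if records is None or len(records) == 0:
        return ExperimentReport(pd.DataFrame(), {}, {}, agreement)
    records = validate_records(records)

    present = [c for c in ("fresh_weight", "leaf_count", *predictors) if c in records]
    table = (
        records.groupby("treatment", observed=True)[present]
        .mean()
        .reset_index()
        .rename(columns={c: f"mean_{c}" for c in present})
    )
    table.insert(1, "n", records.groupby("treatment", observed=True).size().values)

    anova: dict[str, TreatmentComparison] = {}
    for resp in responses:
        if resp not in records.columns:
            continue
        try:
            anova[resp] = anova_oneway(records, resp)
        except InsufficientDataError:
            continue

    fits: dict[str, WeightColorResults] = {}
    for pred in predictors:
        if pred not in records.columns:
            continue
        try:
            fits[pred] = fit_weight_model(records, predictor=pred)
        except (ModelError, InsufficientDataError):
            continue

    return ExperimentReport(table, anova, fits, agreement)
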