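"""Exposure preprocessing and single-exposure regression surfaces.

Covers creatinine dilution correction, Ln transforms, quartile encoding,
survey-weighted logistic/linear fits with sandwich standard errors, integer
trend tests, Benjamini-Hochberg FDR, Pearson correlations among Ln metals,
and the missing-covariate policy (missing-indicator for categoricals, median
for continuous).

The default adjustment set is: age (dichotomised at 60), sex, race/ethnicity,
education, family income-to-poverty ratio, marital status, BMI, physical
activity, drinking alcohol status and serum cotinine; education can be
toggled off.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .cohort import (
    CATEGORICAL_COVARIATES,
    CONTINUOUS_COVARIATES,
    METALS,
    DataError,
)

log = logging.getLogger(__name__)


class ModelError(RuntimeError):
    """A regression fit failed (separation or non-convergence)."""


# ---------------------------------------------------------------------------
# Exposure preprocessing
# ---------------------------------------------------------------------------

def creatinine_correct(metal_ugl, creatinine_mgdl):
    """Creatinine-correct a urinary concentration: ug/L -> ug/g creatinine.

    Dividing by creatinine expressed in g/L (mg/dL x 0.01) adjusts spot-urine
    concentrations for dilution.
    """
    metal = np.asarray(metal_ugl, dtype=float)
    creat = np.asarray(creatinine_mgdl, dtype=float)
    if (creat <= 0).any() or np.isnan(creat).any():
        raise DataError("urinary creatinine must be positive; exclude such participants")
    return metal / (creat * 0.01)


def ln_transform(values):
    """Natural log of a strictly positive exposure vector."""
    v = np.asarray(values, dtype=float)
    if (v <= 0).any():
        raise DataError("Ln transform requires strictly positive values")
    return np.log(v)


@dataclass
class ExposureEncoding:
    """A quartile-coded exposure: ordinal codes 1-4 plus the cutpoints."""

    metal: str
    continuous_ln: np.ndarray
    quartile: np.ndarray
    quartile_cutpoints: np.ndarray

    def dummies(self) -> pd.DataFrame:
        """Indicator columns for Q2-Q4 (Q1 is the reference)."""
        return pd.DataFrame(
            {f"{self.metal}_q{k}": (self.quartile == k).astype(float) for k in (2, 3, 4)}
        )


def _weighted_quantile(values: np.ndarray, probs, weights: np.ndarray) -> np.ndarray:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= np.sum(w)
    return np.interp(probs, cw, v)


def quartile_encode(values, weights=None, name: str = "exposure") -> ExposureEncoding:
    """Quartile-code an exposure at the (optionally weighted) 25/50/75 percentiles.

    Intervals are (-inf, c1], (c1, c2], (c2, c3], (c3, inf).  Heavily tied
    data that empties a quartile raises with a suggestion to fall back to
    rank-based coding.
    """
    v = np.asarray(values, dtype=float)
    if len(np.unique(v)) < 8:
        raise DataError("quartile encoding needs at least 8 distinct values")
    if weights is None:
        cut = np.quantile(v, [0.25, 0.50, 0.75])
    else:
        w = np.asarray(weights, dtype=float)
        if (w <= 0).any():
            raise DataError("weights must be positive")
        cut = _weighted_quantile(v, [0.25, 0.50, 0.75], w)
    if not (cut[0] < cut[1] < cut[2]):
        raise DataError(
            "tied values collapse a quartile; consider rank-based encoding of "
            f"{name} (cutpoints {cut})"
        )
    code = 1 + (v > cut[0]).astype(int) + (v > cut[1]).astype(int) + (v > cut[2]).astype(int)
    counts = np.bincount(code, minlength=5)[1:]
    if (counts == 0).any():
        raise DataError(f"empty quartile for {name}; consider rank-based encoding")
    return ExposureEncoding(name, np.log(v) if (v > 0).all() else v, code, cut)


# ---------------------------------------------------------------------------
# Covariate handling
# ---------------------------------------------------------------------------

from .cohort import (  # noqa: E402  (level orders for dummy coding)
    ACTIVITY_LEVELS,
    ALCOHOL_LEVELS,
    EDUCATION_LEVELS,
    MARITAL_LEVELS,
    RACE_LEVELS,
    SEX_LEVELS,
)

_LEVEL_ORDER: dict[str, tuple[str, ...]] = {
    "sex": SEX_LEVELS,
    "race": RACE_LEVELS,
    "education": EDUCATION_LEVELS,
    "marital": MARITAL_LEVELS,
    "activity": ACTIVITY_LEVELS,
    "alcohol": ALCOHOL_LEVELS,
}

DEFAULT_ADJUSTMENT: tuple[str, ...] = (
    "age", "sex", "race", "education", "pir", "marital", "bmi",
    "activity", "alcohol", "cotinine",
)


def impute_covariates(cohort: pd.DataFrame,
                      columns: tuple[str, ...] = CONTINUOUS_COVARIATES + CATEGORICAL_COVARIATES,
                      ) -> pd.DataFrame:
    """Apply the missing-covariate policy.

    Categorical covariates get an explicit ``"missing"`` level; continuous
    covariates are imputed with the median of observed values.  A column with
    no observed values at all is an error.
    """
    out = cohort.copy()
    for col in columns:
        if col not in out.columns:
            continue
        miss = out[col].isna()
        if not miss.any():
            continue
        if miss.all():
            raise DataError(f"covariate {col!r} is entirely missing")
        if col in CATEGORICAL_COVARIATES:
            out[col] = out[col].astype(object).where(~miss, "missing")
            log.info("covariate %s: %d missing coded as indicator level", col, miss.sum())
        else:
            med = out.loc[~miss, col].median()
            out.loc[miss, col] = med
            log.info("covariate %s: %d missing imputed with median %.4g", col, miss.sum(), med)
    return out


def design_matrix(cohort: pd.DataFrame,
                  covariates: tuple[str, ...] = DEFAULT_ADJUSTMENT,
                  include_education: bool = True) -> pd.DataFrame:
    """Build the covariate design (no intercept; fits add their own).

    Chronological age enters as the dichotomy >= 60 years; categorical
    covariates are dummy-coded against their first documented level, with any
    imputed ``"missing"`` level as an extra indicator.
    """
    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov == "education" and not include_education:
            continue
        if cov == "age":
            cols["age_ge60"] = (cohort["age"].to_numpy(dtype=float) >= 60).astype(float)
        elif cov in ("bmi", "pir", "cotinine"):
            cols[cov] = cohort[cov].to_numpy(dtype=float)
        elif cov in CATEGORICAL_COVARIATES:
            series = cohort[cov].astype(object)
            present = set(pd.unique(series.dropna()))
            documented = _LEVEL_ORDER.get(cov, ())
            # documented order first (reference = first documented level),
            # extra levels such as "missing" appended after
            levels = [lv for lv in documented if lv in present]
            levels += sorted(lv for lv in present if lv not in documented)
            for lv in levels[1:]:
                cols[f"{cov}_{lv}"] = (series == lv).astype(float).to_numpy()
        else:
            cols[cov] = cohort[cov].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=cohort.index)


# ---------------------------------------------------------------------------
# Regression results container
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """One term of a fitted association model, on its reporting scale."""

    term: str
    estimate: float          # log-odds or linear coefficient
    or_or_beta: float        # exp(estimate) for logistic, estimate for linear
    ci_low: float
    ci_high: float
    p_value: float
    model_family: str        # "logistic" | "linear"
    weighted: bool
    n_used: int
    p_fdr: float | None = None
    p_trend: float | None = None

    def as_dict(self) -> dict:
        return {
            "term": self.term, "estimate": self.estimate,
            "or_or_beta": self.or_or_beta, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "p_value": self.p_value,
            "p_fdr": self.p_fdr, "p_trend": self.p_trend,
            "n_used": self.n_used, "model_family": self.model_family,
            "weighted": self.weighted,
        }


def _fit_glm(y, X: pd.DataFrame, family: str, weights=None):
    Xc = sm.add_constant(X, has_constant="add")
    weighted = weights is not None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            if family == "logistic":
                fam = sm.families.Binomial()
                if weighted:
                    w = np.asarray(weights, dtype=float)
                    w = w * len(w) / w.sum()
                    model = sm.GLM(y, Xc, family=fam, freq_weights=w)
                    res = model.fit(cov_type="HC0", maxiter=200)
                else:
                    model = sm.GLM(y, Xc, family=fam)
                    res = model.fit(maxiter=200)
            elif family == "linear":
                if weighted:
                    res = sm.WLS(y, Xc, weights=np.asarray(weights, dtype=float)).fit(
                        cov_type="HC0")
                else:
                    res = sm.OLS(y, Xc).fit()
            else:
                raise ValueError(f"unknown family {family!r}")
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise ModelError(f"perfect separation in {family} fit: {exc}") from exc
    if family == "logistic" and not res.converged:
        raise ModelError("logistic fit did not converge")
    return res


def _term_result(res, term: str, family: str, weighted: bool, n: int) -> RegressionResult:
    est = float(res.params[term])
    lo, hi = (float(v) for v in res.conf_int().loc[term])
    p = float(res.pvalues[term])
    if family == "logistic":
        return RegressionResult(term, est, float(np.exp(est)), float(np.exp(lo)),
                                float(np.exp(hi)), p, family, weighted, n)
    return RegressionResult(term, est, est, lo, hi, p, family, weighted, n)


def fit_logistic(outcome, exposure_term, covariates: pd.DataFrame | None = None,
                 weights=None, term_name: str = "exposure") -> list[RegressionResult]:
    """Multivariable (optionally survey-weighted) logistic regression.

    ``exposure_term`` may be a continuous vector (one result) or an
    :class:`ExposureEncoding` (three results: Q2-Q4 vs Q1).  Weighted fits
    use weighted maximum likelihood with HC0 sandwich standard errors;
    unweighted fits use model-based standard errors.
    """
    return _fit_exposure_model(outcome, exposure_term, covariates, weights,
                               term_name, family="logistic")


def fit_linear(marker, exposure_term, covariates: pd.DataFrame | None = None,
               weights=None, term_name: str = "exposure") -> list[RegressionResult]:
    """Multivariable linear regression of an aging marker on an exposure."""
    return _fit_exposure_model(marker, exposure_term, covariates, weights,
                               term_name, family="linear")


def _exposure_frame(exposure_term, term_name: str):
    if isinstance(exposure_term, ExposureEncoding):
        df = exposure_term.dummies()
        return df, list(df.columns)
    arr = np.asarray(exposure_term, dtype=float)
    return pd.DataFrame({term_name: arr}), [term_name]


def _fit_exposure_model(y, exposure_term, covariates, weights, term_name, family):
    y = np.asarray(y, dtype=float)
    if family == "logistic" and not np.isin(y[~np.isnan(y)], [0, 1]).all():
        raise DataError("logistic outcome must be binary")
    exp_df, terms = _exposure_frame(exposure_term, term_name)
    exp_df = exp_df.reset_index(drop=True)
    X = exp_df if covariates is None else pd.concat(
        [exp_df, covariates.reset_index(drop=True)], axis=1)
    res = _fit_glm(y, X, family, weights)
    return [_term_result(res, t, family, weights is not None, len(y)) for t in terms]


def trend_test(outcome, encoding: ExposureEncoding,
               covariates: pd.DataFrame | None = None, weights=None,
               family: str = "logistic") -> float:
    """P for trend: refit with the quartile replaced by its integer score (1-4)."""
    score = encoding.quartile.astype(float)
    results = _fit_exposure_model(outcome, score, covariates, weights,
                                  "trend_score", family)
    return results[0].p_value


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DataError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def pearson_correlation_matrix(ln_metals: np.ndarray | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations among Ln-transformed metals (unit diagonal).

    Zero-variance columns yield NaN entries and a warning.
    """
    if isinstance(ln_metals, pd.DataFrame):
        names = list(ln_metals.columns)
        X = ln_metals.to_numpy(dtype=float)
    else:
        X = np.asarray(ln_metals, dtype=float)
        names = [METALS[j] if X.shape[1] == 9 else f"x{j}" for j in range(X.shape[1])]
    if X.shape[0] < 3:
        raise DataError("correlation requires at least 3 rows")
    sd = X.std(axis=0)
    if (sd == 0).any():
        warnings.warn("zero-variance column(s); correlations undefined (NaN)")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(corr, np.where(sd == 0, np.nan, 1.0))
    return pd.DataFrame(corr, index=names, columns=names)


# ---------------------------------------------------------------------------
# Analysis-surface tables (Fig 2 / Fig 3 / Table 2 layouts)
# ---------------------------------------------------------------------------

def _prepared_exposures(cohort: pd.DataFrame) -> dict[str, np.ndarray]:
    """Creatinine-corrected, per-metal exposures in ug/g creatinine."""
    creat = cohort["creatinine_mgdl"].to_numpy(dtype=float)
    return {m: creatinine_correct(cohort[f"metal_{m}"].to_numpy(dtype=float), creat)
            for m in METALS}


def metal_outcome_table(cohort: pd.DataFrame, outcome_col: str = "oa",
                        family: str = "logistic",
                        covariates: pd.DataFrame | None = None,
                        weights=None) -> pd.DataFrame:
    """Per-metal continuous (Ln) and quartile associations with one outcome.

    One tidy row per term; trend p-values are FDR-adjusted across the nine
    metals (the smallest family consistent with a single results figure).
    """
    y = cohort[outcome_col].to_numpy(dtype=float)
    exposures = _prepared_exposures(cohort)
    rows: list[dict] = []
    trend_ps: list[float] = []
    cont_ps: list[float] = []
    per_metal: list[tuple[str, list[RegressionResult], list[RegressionResult], float]] = []
    for m in METALS:
        ln_x = ln_transform(exposures[m])
        enc = quartile_encode(exposures[m], name=m)
        cont = _fit_exposure_model(y, ln_x, covariates, weights, f"{m}_ln", family)
        quart = _fit_exposure_model(y, enc, covariates, weights, m, family)
        p_tr = trend_test(y, enc, covariates, weights, family)
        per_metal.append((m, cont, quart, p_tr))
        trend_ps.append(p_tr)
        cont_ps.append(cont[0].p_value)
    trend_fdr = fdr_adjust(trend_ps)
    cont_fdr = fdr_adjust(cont_ps)
    for i, (m, cont, quart, p_tr) in enumerate(per_metal):
        cont[0].p_fdr = float(cont_fdr[i])
        for r in quart:
            r.p_trend = float(trend_fdr[i])
        rows.append({"metal": m, **cont[0].as_dict()})
        rows.extend({"metal": m, **r.as_dict()} for r in quart)
    out = pd.DataFrame(rows)
    out.insert(1, "outcome", outcome_col)
    return out


def marker_outcome_table(cohort: pd.DataFrame, outcome_col: str = "oa",
                         markers: tuple[str, ...] = ("biological_age",
                                                     "phenotypic_age",
                                                     "telomere_ts"),
                         covariates: pd.DataFrame | None = None,
                         weights=None) -> pd.DataFrame:
    """Aging markers -> OA associations, continuous and by quartile."""
    y = cohort[outcome_col].to_numpy(dtype=float)
    rows = []
    for mk in markers:
        v = cohort[mk].to_numpy(dtype=float)
        cont = _fit_exposure_model(y, v, covariates, weights, f"{mk}", "logistic")
        enc = quartile_encode(v, name=mk)
        quart = _fit_exposure_model(y, enc, covariates, weights, mk, "logistic")
        p_tr = trend_test(y, enc, covariates, weights, "logistic")
        for r in quart:
            r.p_trend = p_tr
        rows.append({"marker": mk, **cont[0].as_dict()})
        rows.extend({"marker": mk, **r.as_dict()} for r in quart)
    out = pd.DataFrame(rows)
    out.insert(1, "outcome", outcome_col)
    return out
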