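"""Biological-aging markers: Klemera-Doubal biological age, phenotypic age,
telomere pass-through.

Klemera-Doubal biological age (KDM)
-----------------------------------
Each biomarker ``x_j`` is regressed on chronological age (CA) in a training
sample, giving slope ``k_j``, intercept ``q_j``, residual RMSE ``s_j`` and
signed correlation ``r_j``.  The uncorrected estimate is the
inverse-variance-weighted combination

    BA_E = sum_j (x_j - q_j) * k_j / s_j^2  /  sum_j (k_j / s_j)^2

and the CA-corrected estimator shrinks BA_E toward CA:

    BA = [ sum_j (x_j - q_j) k_j / s_j^2 + CA / s_BA^2 ]
         / [ sum_j (k_j / s_j)^2 + 1 / s_BA^2 ]

where ``s_BA^2`` is the variance of (BA_E - CA) in the training sample minus
a correction ``(1 - r_char^2)/r_char^2 * (CA_max - CA_min)^2 / (12 m)`` driven
by the characteristic correlation

    r_char = sum_j r_j^2 / sqrt(1 - r_j^2)  /  sum_j r_j / sqrt(1 - r_j^2).

``s_BA^2`` can be negative in small or weakly informative samples; it is then
clamped to a configurable positive floor (default ``1e-4 * (CA range)^2``)
with a warning, because the corrected estimator requires positivity.

Phenotypic age
--------------
A mortality-score-derived age in years from nine clinical biomarkers plus CA,
through a fixed closed form (coefficients below, units documented per input).

Exposed both as spec-style functions (:func:`fit_kdm`,
:func:`compute_biological_age`, :func:`compute_phenotypic_age`) and as a
model/results pair (:class:`KlemeraDoubal` / :class:`KDMResults`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import KDM_BIOMARKERS, PHENO_BIOMARKERS, DataError, validate_cohort

log = logging.getLogger(__name__)


class FitError(ValueError):
    """Training data cannot support the requested fit."""


# ---------------------------------------------------------------------------
# KDM parameters
# ---------------------------------------------------------------------------

@dataclass
class KDMParameters:
    """Per-biomarker regression constants and the shrinkage variance.

    ``k``, ``q``, ``s``, ``r`` are aligned with ``biomarker_names``;
    ``s`` is the residual RMSE (ddof=2) and ``r`` the signed Pearson
    correlation of biomarker with chronological age (so ``r**2`` is the OLS
    R-squared).
    """

    biomarker_names: tuple[str, ...]
    k: np.ndarray
    q: np.ndarray
    s: np.ndarray
    r: np.ndarray
    r_char: float
    s_ba2: float
    s_ba2_raw: float
    ca_min: float
    ca_max: float
    m: int
    n: int
    clamped: bool = False

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("k", "q", "s", "r"):
            d[key] = np.asarray(d[key]).tolist()
        d["biomarker_names"] = list(self.biomarker_names)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "KDMParameters":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("k", "q", "s", "r"):
            d[key] = np.asarray(d[key], dtype=float)
        d["biomarker_names"] = tuple(d["biomarker_names"])
        return cls(**d)


def fit_kdm(
    training_biomarkers: np.ndarray | pd.DataFrame,
    chronological_age: np.ndarray,
    biomarker_names: tuple[str, ...] | None = None,
    s_ba2_floor_factor: float = 1e-4,
) -> KDMParameters:
    """Fit the per-biomarker regressions and the shrinkage variance.

    Zero-variance biomarkers are dropped with a warning; fewer than 30
    training rows or a degenerate chronological-age range is a fit error.
    """
    if isinstance(training_biomarkers, pd.DataFrame):
        biomarker_names = tuple(training_biomarkers.columns)
        X = training_biomarkers.to_numpy(dtype=float)
    else:
        X = np.asarray(training_biomarkers, dtype=float)
        if biomarker_names is None:
            biomarker_names = tuple(f"x{j}" for j in range(X.shape[1]))
    ca = np.asarray(chronological_age, dtype=float)
    n = len(ca)
    if n < 30:
        raise FitError(f"KDM training requires n >= 30, got {n}")
    if X.shape[0] != n:
        raise FitError("biomarker matrix and age vector disagree in length")
    if np.isnan(X).any() or np.isnan(ca).any():
        raise FitError("missing values in KDM training data; impute first")
    ca_min, ca_max = float(ca.min()), float(ca.max())
    if ca_max == ca_min or np.var(ca) == 0:
        raise FitError("chronological age has zero variance in training sample")

    keep, k_l, q_l, s_l, r_l = [], [], [], [], []
    ca_c = ca - ca.mean()
    var_ca = float(np.sum(ca_c**2))
    for j, name in enumerate(biomarker_names):
        x = X[:, j]
        if np.var(x) == 0:
            warnings.warn(f"biomarker {name!r} has zero variance; dropped from KDM fit")
            continue
        k = float(np.sum(ca_c * (x - x.mean())) / var_ca)
        q = float(x.mean() - k * ca.mean())
        resid = x - (q + k * ca)
        s = float(np.sqrt(np.sum(resid**2) / max(n - 2, 1)))
        if s == 0:
            warnings.warn(f"biomarker {name!r} is an exact linear function of age; "
                          "tiny jitter added to its RMSE")
            s = 1e-12
        r = float(np.corrcoef(x, ca)[0, 1])
        keep.append(name)
        k_l.append(k); q_l.append(q); s_l.append(s); r_l.append(r)
    if not keep:
        raise FitError("no usable biomarkers after dropping degenerate columns")

    k_a, q_a, s_a, r_a = map(np.asarray, (k_l, q_l, s_l, r_l))
    m = len(keep)

    r2 = np.clip(r_a**2, 0.0, 1.0 - 1e-12)
    denom = np.sqrt(1.0 - r2)
    r_char = float(np.sum(r2 / denom) / np.sum(np.abs(r_a) / denom))

    X_keep = X[:, [list(biomarker_names).index(nm) for nm in keep]]
    ba_e = _ba_e(X_keep, k_a, q_a, s_a)
    diff = ba_e - ca
    var_diff = float(np.mean((diff - diff.mean()) ** 2))
    correction = ((1.0 - r_char**2) / r_char**2) * ((ca_max - ca_min) ** 2 / (12.0 * m))
    s_ba2_raw = var_diff - correction

    floor = s_ba2_floor_factor * (ca_max - ca_min) ** 2
    clamped = s_ba2_raw <= floor
    s_ba2 = float(max(s_ba2_raw, floor))
    if clamped:
        log.warning("s_BA^2 = %.4g below floor %.4g; clamped", s_ba2_raw, floor)

    return KDMParameters(
        biomarker_names=tuple(keep), k=k_a, q=q_a, s=s_a, r=r_a,
        r_char=r_char, s_ba2=s_ba2, s_ba2_raw=float(s_ba2_raw),
        ca_min=ca_min, ca_max=ca_max, m=m, n=n, clamped=bool(clamped),
    )


def _ba_e(X: np.ndarray, k: np.ndarray, q: np.ndarray, s: np.ndarray) -> np.ndarray:
    num = (X - q) @ (k / s**2)
    den = float(np.sum((k / s) ** 2))
    return num / den


def compute_biological_age(
    params: KDMParameters,
    biomarkers: np.ndarray | pd.DataFrame,
    ca: np.ndarray | float,
) -> np.ndarray:
    """Corrected Klemera-Doubal biological age for one or many participants.

    Falls back to the uncorrected BA_E (with a warning) if the shrinkage
    variance is non-positive even after clamping.
    """
    if isinstance(biomarkers, pd.DataFrame):
        biomarkers = biomarkers[list(params.biomarker_names)].to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(biomarkers, dtype=float))
    ca_arr = np.atleast_1d(np.asarray(ca, dtype=float))
    if np.isnan(X).any():
        raise DataError("biomarker vector contains missing values")
    k, q, s = params.k, params.q, params.s
    if params.s_ba2 <= 0:
        warnings.warn("s_BA^2 non-positive; falling back to uncorrected BA_E")
        out = _ba_e(X, k, q, s)
    else:
        num = (X - q) @ (k / s**2) + ca_arr / params.s_ba2
        den = float(np.sum((k / s) ** 2)) + 1.0 / params.s_ba2
        out = num / den
    return out


# ---------------------------------------------------------------------------
# Model/results wrapper
# ---------------------------------------------------------------------------

class KlemeraDoubal:
    """Klemera-Doubal biological-age model.

    Parameters
    ----------
    biomarkers : (n, m) array or DataFrame
        Training biomarker panel.
    age : (n,) array
        Chronological age in years.
    """

    def __init__(self, biomarkers, age, biomarker_names=None,
                 s_ba2_floor_factor: float = 1e-4):
        self.biomarkers = biomarkers
        self.age = np.asarray(age, dtype=float)
        self.biomarker_names = biomarker_names
        self.s_ba2_floor_factor = s_ba2_floor_factor

    def fit(self) -> "KDMResults":
        params = fit_kdm(self.biomarkers, self.age, self.biomarker_names,
                         self.s_ba2_floor_factor)
        return KDMResults(self, params)


@dataclass
class KDMResults:
    """Fitted Klemera-Doubal model: parameters plus prediction and summary."""

    model: KlemeraDoubal
    params: KDMParameters
    _fitted: np.ndarray | None = field(default=None, repr=False)

    def predict(self, biomarkers=None, age=None) -> np.ndarray:
        if biomarkers is None:
            biomarkers, age = self.model.biomarkers, self.model.age
        return compute_biological_age(self.params, biomarkers, age)

    @property
    def fittedvalues(self) -> np.ndarray:
        if self._fitted is None:
            self._fitted = self.predict()
        return self._fitted

    def summary(self) -> str:
        p = self.params
        lines = [
            "Klemera-Doubal biological age fit",
            f"  n = {p.n}, biomarkers = {p.m}, CA range = [{p.ca_min:.1f}, {p.ca_max:.1f}]",
            f"  r_char = {p.r_char:.4f}, s_BA^2 = {p.s_ba2:.4f}"
            + (" (clamped)" if p.clamped else ""),
            f"  {'biomarker':<14} {'k':>10} {'q':>10} {'s':>10} {'r':>8}",
        ]
        for j, name in enumerate(p.biomarker_names):
            lines.append(f"  {name:<14} {p.k[j]:>10.4g} {p.q[j]:>10.4g} "
                         f"{p.s[j]:>10.4g} {p.r[j]:>8.3f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Phenotypic age
# ---------------------------------------------------------------------------

#: Linear-predictor coefficients, ordered as PHENO_BIOMARKERS:
#: albumin (g/L), creatinine (umol/L), glucose (mmol/L), Ln-CRP (Ln mg/dL),
#: lymphocyte percent, mean cell volume (fL), red-cell distribution width (%),
#: alkaline phosphatase (U/L), white-cell count (10^9/L).
PHENO_COEFFICIENTS = np.array(
    [-0.0336, 0.0095, 0.1953, 0.0954, -0.0120, 0.0268, 0.3306, 0.00188, 0.0554]
)
PHENO_AGE_COEFFICIENT = 0.0804
PHENO_INTERCEPT = -19.907
# Gompertz-type constants of the two-level log transform.
_PA_OFFSET = 141.50
_PA_G1 = 0.00553
_PA_G2 = 1.51714
_PA_G3 = 0.0076927
_PA_SCALE = 0.09165


def compute_phenotypic_age(
    biomarkers_pheno: np.ndarray | pd.DataFrame,
    ca: np.ndarray | float,
) -> np.ndarray:
    """Phenotypic age (years) from the nine-biomarker mortality score.

    The closed form is ``141.50 + Ln[-0.00553 * Ln(exp(-1.51714*exp(xb)/
    0.0076927))] / 0.09165``; the inner ``Ln(exp(.))`` is evaluated
    analytically (it is the identity), which keeps the expression finite even
    when ``exp(xb)`` underflows.
    """
    if isinstance(biomarkers_pheno, pd.DataFrame):
        biomarkers_pheno = biomarkers_pheno[list(PHENO_BIOMARKERS)].to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(biomarkers_pheno, dtype=float))
    if X.shape[1] != 9:
        raise DataError(f"phenotypic age needs 9 biomarkers, got {X.shape[1]}")
    ca_arr = np.atleast_1d(np.asarray(ca, dtype=float))
    xb = PHENO_INTERCEPT + X @ PHENO_COEFFICIENTS + PHENO_AGE_COEFFICIENT * ca_arr
    if not np.isfinite(xb).all():
        bad = np.where(~np.isfinite(xb))[0]
        raise DataError(f"non-finite phenotypic-age linear predictor for rows {bad[:10]}")
    # log(-G1 * (-G2 * exp(xb) / G3)) = log(G1 * G2 / G3) + xb
    pheno = _PA_OFFSET + (np.log(_PA_G1 * _PA_G2 / _PA_G3) + xb) / _PA_SCALE
    return pheno


def attach_aging_markers(
    cohort: pd.DataFrame,
    params: KDMParameters | None = None,
) -> pd.DataFrame:
    """Append ``biological_age`` and ``phenotypic_age`` columns to a cohort.

    If no externally fitted KDM parameters are supplied, the model is trained
    on the cohort itself (its 8-biomarker panel against exact age in years).
    The telomere T/S column passes through unchanged after validation.
    """
    validate_cohort(cohort)
    kdm_X = cohort[list(KDM_BIOMARKERS)]
    if kdm_X.isna().any().any() or cohort[list(PHENO_BIOMARKERS)].isna().any().any():
        raise DataError("biomarker panels contain missing values; impute first")
    age = cohort["age"].to_numpy(dtype=float)
    if params is None:
        params = fit_kdm(kdm_X, age)
    out = cohort.copy()
    out["biological_age"] = compute_biological_age(params, kdm_X, age)
    out["phenotypic_age"] = compute_phenotypic_age(cohort[list(PHENO_BIOMARKERS)], age)
    for col in ("biological_age", "phenotypic_age", "telomere_ts"):
        s = out[col]
        log.info("%s: mean %.2f, sd %.2f, range [%.2f, %.2f]",
                 col, s.mean(), s.std(), s.min(), s.max())
    return out


# ---------------------------------------------------------------------------
# Unit conversion helpers (survey units -> formula units)
# ---------------------------------------------------------------------------

def albumin_gdl_to_gl(x):
    """Serum albumin g/dL -> g/L."""
    return np.asarray(x, dtype=float) * 10.0


def creatinine_mgdl_to_umol(x):
    """Serum creatinine mg/dL -> umol/L."""
    return np.asarray(x, dtype=float) * 88.42


def glucose_mgdl_to_mmol(x):
    """Serum glucose mg/dL -> mmol/L."""
    return np.asarray(x, dtype=float) / 18.016


def crp_mgl_to_ln_mgdl(x):
    """CRP mg/L -> Ln(mg/dL)."""
    x = np.asarray(x, dtype=float)
    if (x <= 0).any():
        raise DataError("CRP must be positive for the Ln transform")
    return np.log(x / 10.0)
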