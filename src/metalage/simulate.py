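"""Synthetic NHANES-like cohort generator with known mediation structure.

The generator draws the nine urinary metals multivariate-lognormal with a
configurable Ln-scale covariance, left-censors them at per-metal detection
limits, and builds a latent aging chain

    Ln metals --> telomere T/S  --> whole-body age acceleration --> OA
          \\________________________________________________//
                         direct log-odds paths

Clinical biomarker panels are generated by *inverting* the aging scores: each
biomarker is linear in the latent "true" biological age plus independent
noise, so the scoring module recovers the latent mediator up to noise and
parameter recovery for mediation is well defined.  A per-participant truth
record (latent acceleration, latent biological age, linear predictors) is
retained for testing.

Every random draw flows through a single :class:`numpy.random.Generator`
seeded from ``config.seed``; two calls with the same config are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    ACTIVITY_LEVELS,
    ALCOHOL_LEVELS,
    EDUCATION_LEVELS,
    KDM_BIOMARKERS,
    MARITAL_LEVELS,
    METALS,
    RACE_LEVELS,
    SEX_LEVELS,
    DataError,
    validate_cohort,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

#: Ln-scale geometric-mean urinary concentrations (Ln ug/L), loosely matching
#: U.S. adult spot-urine surveys.
DEFAULT_LN_MEAN: dict[str, float] = {
    "ba": 0.41, "cd": -1.20, "co": -1.05, "cs": 1.50, "mo": 3.81,
    "pb": -0.22, "sb": -2.66, "tl": -1.77, "tu": -4.96,
}

#: Ln-scale standard deviations.
DEFAULT_LN_SD: dict[str, float] = {
    "ba": 0.95, "cd": 0.90, "co": 0.80, "cs": 0.65, "mo": 0.75,
    "pb": 0.80, "sb": 0.85, "tl": 0.70, "tu": 1.10,
}

#: Elevated pairwise Ln-scale correlations (all other pairs share a weak
#: background correlation); the three moderate pairs reflect the observed
#: urinary co-excretion pattern.
DEFAULT_CORR_PAIRS: dict[tuple[str, str], float] = {
    ("cs", "tl"): 0.58,
    ("ba", "co"): 0.41,
    ("cd", "pb"): 0.40,
}
DEFAULT_BACKGROUND_CORR = 0.15

#: Detection limits (ug/L) placed near the lower tail so detection rates stay
#: above ~75%, as in the source survey.
DEFAULT_LOD: dict[str, float] = {
    "ba": 0.12, "cd": 0.06, "co": 0.05, "cs": 0.15, "mo": 0.99,
    "pb": 0.10, "sb": 0.015, "tl": 0.02, "tu": 0.002,
}

#: KDM-panel biomarker generator: column -> (slope per year of latent
#: biological age, intercept at age 0, residual SD).  Values give the
#: individually-weak, jointly-informative age signal typical of clinical
#: chemistry.
DEFAULT_KDM_PANEL: dict[str, tuple[float, float, float]] = {
    "kdm_lncrp":   (0.020, -1.50, 0.60),
    "kdm_creat":   (0.004,  0.70, 0.15),
    "kdm_hba1c":   (0.020,  4.50, 0.45),
    "kdm_albumin": (-0.008, 4.60, 0.25),
    "kdm_chol":    (0.700, 160.0, 35.0),
    "kdm_bun":     (0.120,  8.00, 4.00),
    "kdm_alp":     (0.250, 55.00, 18.0),
    "kdm_sbp":     (0.550, 95.00, 12.0),
}

#: Phenotypic-age panel generator in the closed form's units.  lncrp and alp
#: are shared with the KDM panel (same analyte) and are not listed here.
DEFAULT_PHENO_PANEL: dict[str, tuple[float, float, float]] = {
    "pheno_albumin": (-0.080, 47.0, 2.50),
    "pheno_creat":   (0.350, 60.0, 13.0),
    "pheno_glucose": (0.020, 4.30, 0.80),
    "pheno_lymph":   (-0.080, 34.0, 6.00),
    "pheno_mcv":     (0.050, 87.0, 4.00),
    "pheno_rdw":     (0.020, 12.3, 0.80),
    "pheno_wbc":     (0.010, 6.70, 1.60),
}


def default_ln_cov(
    ln_sd: Mapping[str, float] | None = None,
    corr_pairs: Mapping[tuple[str, str], float] | None = None,
    background: float = DEFAULT_BACKGROUND_CORR,
) -> np.ndarray:
    """Build the default 9x9 Ln-scale covariance from SDs and correlations."""
    sd = np.array([(ln_sd or DEFAULT_LN_SD)[m] for m in METALS])
    corr = np.full((9, 9), background)
    np.fill_diagonal(corr, 1.0)
    idx = {m: i for i, m in enumerate(METALS)}
    for (a, b), r in (corr_pairs or DEFAULT_CORR_PAIRS).items():
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    return corr * np.outer(sd, sd)


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator.

    Per-metal mappings are keyed by the lowercase element identifiers in
    :data:`metalage.cohort.METALS`.  Effects are on the latent scale:
    ``beta_metal_to_aging`` in years of age acceleration per Ln(ug/L),
    ``beta_aging_to_oa`` in log-odds per year, ``beta_metal_direct`` in
    log-odds per Ln(ug/L).  ``covariate_effects`` maps a centred covariate
    term (``age_c`` = age-50, ``female``, ``bmi_c`` = BMI-28) to a pair
    (effect on the mediator in years, effect on the outcome log-odds).
    """

    n_participants: int = 12584
    seed: int = 0
    metal_names: tuple[str, ...] = METALS
    ln_metal_mean: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LN_MEAN))
    ln_metal_cov: np.ndarray = field(default_factory=default_ln_cov)
    lod: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOD))
    beta_metal_to_aging: dict[str, float] = field(
        default_factory=lambda: {"cd": 2.2, "co": 1.0, "cs": 1.2, "pb": 0.6, "tl": 0.5}
    )
    beta_aging_to_oa: float = 0.06
    beta_metal_direct: dict[str, float] = field(
        default_factory=lambda: {"cd": 0.10, "co": 0.10, "cs": 0.08}
    )
    # Serial-chain extensions: metals shorten telomeres, telomere deficit
    # feeds whole-body aging, telomeres may also act on OA directly.
    beta_metal_to_telomere: dict[str, float] = field(
        default_factory=lambda: {"cd": -0.03, "cs": -0.03}
    )
    beta_telomere_to_aging: float = -6.0
    beta_telomere_to_oa: float = -0.5
    covariate_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"age_c": (0.0, 0.045), "female": (0.0, 0.5), "bmi_c": (0.0, 0.06)}
    )
    baseline_oa_logit: float = -2.65
    aging_noise_sd: float = 4.0
    telomere_noise_sd: float = 0.15
    weight_distribution: tuple[float, float] = (2.0, 0.5)  # gamma shape, scale
    creatinine_ln_mean: float = 4.70  # Ln mg/dL
    creatinine_ln_sd: float = 0.55
    age_range: tuple[float, float] = (20.0, 80.0)
    kdm_panel: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_KDM_PANEL)
    )
    pheno_panel: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PHENO_PANEL)
    )
    missing_rates: dict[str, float] | None = None  # MCAR injection, default off

    def validate(self) -> "SimulationConfig":
        if self.n_participants < 50:
            raise ConfigError("n_participants must be >= 50 (downstream fits unidentifiable)")
        cov = np.asarray(self.ln_metal_cov, dtype=float)
        if cov.shape != (9, 9):
            raise ConfigError("ln_metal_cov must be 9x9")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ConfigError("ln_metal_cov must be symmetric")
        eig = np.linalg.eigvalsh(cov)
        if eig.min() < -1e-10:
            raise ConfigError("ln_metal_cov must be positive semi-definite")
        if any(self.lod[m] <= 0 for m in self.metal_names):
            raise ConfigError("all LODs must be strictly positive")
        if tuple(self.metal_names) != METALS:
            raise ConfigError(f"metal_names must be {METALS}")
        return self

    # -- plain-text round trip -------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["ln_metal_cov"] = np.asarray(self.ln_metal_cov).tolist()
        d["covariate_effects"] = {k: list(v) for k, v in self.covariate_effects.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["ln_metal_cov"] = np.asarray(d["ln_metal_cov"], dtype=float)
        d["metal_names"] = tuple(d["metal_names"])
        d["covariate_effects"] = {k: tuple(v) for k, v in d["covariate_effects"].items()}
        for key in ("weight_distribution", "age_range"):
            d[key] = tuple(d[key])
        d["kdm_panel"] = {k: tuple(v) for k, v in d["kdm_panel"].items()}
        d["pheno_panel"] = {k: tuple(v) for k, v in d["pheno_panel"].items()}
        return cls(**d)


def censor_below_lod(values: np.ndarray, lod: float | np.ndarray) -> np.ndarray:
    """Replace values below the detection limit by LOD/sqrt(2).

    Values at or above the LOD are unchanged; negative inputs are a data
    error.  Broadcasts a scalar or per-metal LOD across the input.
    """
    values = np.asarray(values, dtype=float)
    lod_arr = np.broadcast_to(np.asarray(lod, dtype=float), values.shape)
    if (lod_arr <= 0).any():
        raise DataError("LOD must be strictly positive")
    if (values < 0).any():
        raise DataError("negative concentrations are not valid")
    return np.where(values < lod_arr, lod_arr / np.sqrt(2.0), values)


def detection_rates(values: np.ndarray, lod: np.ndarray) -> np.ndarray:
    """Fraction of values at or above the detection limit, per column."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return (values >= np.asarray(lod, dtype=float)).mean(axis=0)


def _draw_covariates(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> pd.DataFrame:
    """Demographics with marginals loosely matching the study population."""
    age = rng.uniform(*cfg.age_range, size=n)
    sex = rng.choice(SEX_LEVELS, size=n, p=[0.49, 0.51])
    race = rng.choice(RACE_LEVELS, size=n, p=[0.09, 0.06, 0.68, 0.11, 0.06])
    education = rng.choice(EDUCATION_LEVELS, size=n, p=[0.17, 0.24, 0.59])
    marital = rng.choice(MARITAL_LEVELS, size=n, p=[0.64, 0.17, 0.19])
    activity = rng.choice(ACTIVITY_LEVELS, size=n, p=[0.60, 0.40])
    alcohol = rng.choice(ALCOHOL_LEVELS, size=n, p=[0.76, 0.24])
    bmi = rng.normal(28.4, 5.5, size=n).clip(15, 60)
    pir = rng.gamma(2.2, 1.37, size=n).clip(0, 5)
    cotinine = np.exp(rng.normal(0.5, 2.2, size=n)).clip(0.01, 2000)
    return pd.DataFrame(
        {"age": age, "sex": sex, "race": race, "education": education,
         "marital": marital, "activity": activity, "alcohol": alcohol,
         "bmi": bmi, "pir": pir, "cotinine": cotinine}
    )


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw one cohort table from the configured generative model.

    Returns a validated cohort with ``truth_*`` columns recording the latent
    mediators and linear predictors.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    metals_i = {m: i for i, m in enumerate(METALS)}

    cov_df = _draw_covariates(rng, n, cfg)
    age = cov_df["age"].to_numpy()

    mean = np.array([cfg.ln_metal_mean[m] for m in METALS])
    ln_metals = rng.multivariate_normal(mean, np.asarray(cfg.ln_metal_cov, float), size=n,
                                        method="cholesky")
    metals_raw = np.exp(ln_metals)
    lod = np.array([cfg.lod[m] for m in METALS])
    metals_obs = censor_below_lod(metals_raw, lod)

    creatinine = np.exp(rng.normal(cfg.creatinine_ln_mean, cfg.creatinine_ln_sd, size=n))

    centred = ln_metals - mean  # effects act on centred Ln exposures

    def metal_lp(betas: Mapping[str, float]) -> np.ndarray:
        lp = np.zeros(n)
        for m, b in betas.items():
            lp += b * centred[:, metals_i[m]]
        return lp

    cov_terms = {
        "age_c": age - 50.0,
        "female": (cov_df["sex"] == "female").astype(float).to_numpy(),
        "bmi_c": cov_df["bmi"].to_numpy() - 28.0,
    }

    # telomere: Ln T/S declines with age and metal burden
    ln_ts_mean = 0.10 - 0.0035 * (age - 50.0) + metal_lp(cfg.beta_metal_to_telomere)
    ln_ts = ln_ts_mean + rng.normal(0.0, cfg.telomere_noise_sd, size=n)
    telomere_ts = np.exp(ln_ts)
    # deficit relative to the age-expected level; carries metal signal + noise
    ts_deficit = ln_ts - (0.10 - 0.0035 * (age - 50.0))

    # whole-body age acceleration (years)
    accel = metal_lp(cfg.beta_metal_to_aging) + cfg.beta_telomere_to_aging * ts_deficit
    for name, (b_med, _) in cfg.covariate_effects.items():
        accel += b_med * cov_terms.get(name, 0.0)
    accel = accel + rng.normal(0.0, cfg.aging_noise_sd, size=n)
    ba_true = age + accel

    # outcome
    logit = np.full(n, cfg.baseline_oa_logit)
    logit += cfg.beta_aging_to_oa * accel
    logit += metal_lp(cfg.beta_metal_direct)
    logit += cfg.beta_telomere_to_oa * ts_deficit
    for name, (_, b_out) in cfg.covariate_effects.items():
        logit += b_out * cov_terms.get(name, 0.0)
    oa = rng.binomial(1, 1.0 / (1.0 + np.exp(-logit)))

    # biomarker panels, linear in latent biological age + independent noise
    panels: dict[str, np.ndarray] = {}
    for col, (k, q, s) in cfg.kdm_panel.items():
        panels[col] = q + k * ba_true + rng.normal(0.0, s, size=n)
    for col, (k, q, s) in cfg.pheno_panel.items():
        panels[col] = q + k * ba_true + rng.normal(0.0, s, size=n)
    # shared analytes between the two panels
    panels["pheno_lncrp"] = panels["kdm_lncrp"]
    panels["pheno_alp"] = panels["kdm_alp"]

    weights = rng.gamma(*cfg.weight_distribution, size=n)

    cohort = pd.DataFrame({"participant_id": np.arange(1, n + 1)})
    for m in METALS:
        cohort[f"metal_{m}"] = metals_obs[:, metals_i[m]]
    cohort["creatinine_mgdl"] = creatinine
    cohort["oa"] = oa
    cohort = pd.concat([cohort, cov_df], axis=1)
    for col in KDM_BIOMARKERS:
        cohort[col] = panels[col]
    for col in (
        "pheno_albumin", "pheno_creat", "pheno_glucose", "pheno_lncrp",
        "pheno_lymph", "pheno_mcv", "pheno_rdw", "pheno_alp", "pheno_wbc",
    ):
        cohort[col] = panels[col]
    cohort["telomere_ts"] = telomere_ts
    cohort["survey_weight"] = weights
    cohort["truth_accel"] = accel
    cohort["truth_ba"] = ba_true
    cohort["truth_ts_deficit"] = ts_deficit
    cohort["truth_oa_logit"] = logit

    if cfg.missing_rates:
        for col, rate in cfg.missing_rates.items():
            mask = rng.random(n) < rate
            cohort.loc[mask, col] = np.nan

    return validate_cohort(cohort)


def simulate_chain(
    n: int,
    seed: int,
    *,
    a1: float = 1.0,
    a2: float = 0.0,
    d21: float = 0.0,
    b1: float = 1.0,
    b2: float = 0.0,
    c_direct: float = 0.0,
    sd_m1: float = 1.0,
    sd_m2: float = 1.0,
    sd_y: float = 1.0,
    outcome: str = "linear",
    baseline_logit: float = -1.0,
) -> pd.DataFrame:
    """Minimal linear mediation chain with known path coefficients.

    ``x -> m1`` with slope ``a1``; ``m2 = a2*x + d21*m1``; outcome depends on
    ``c_direct*x + b1*m1 + b2*m2``.  With ``outcome="linear"`` the classical
    product-of-coefficients identities hold exactly: single-mediator indirect
    effect ``a1*b1``, serial path-specific effect ``a1*d21*b2``.  Used as the
    analytic oracle bed for the mediation estimators.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, size=n)
    m1 = a1 * x + rng.normal(0.0, sd_m1, size=n)
    m2 = a2 * x + d21 * m1 + rng.normal(0.0, sd_m2, size=n)
    lp = c_direct * x + b1 * m1 + b2 * m2
    if outcome == "linear":
        y = lp + rng.normal(0.0, sd_y, size=n)
    elif outcome == "logistic":
        y = rng.binomial(1, 1.0 / (1.0 + np.exp(-(baseline_logit + lp)))).astype(float)
    else:
        raise ValueError("outcome must be 'linear' or 'logistic'")
    return pd.DataFrame({"x": x, "m1": m1, "m2": m2, "y": y})
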