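"""Parallel and serial causal mediation by quasi-Bayesian Monte Carlo.

The estimator fits the component regressions by maximum likelihood, draws
``n_sim`` parameter vectors from each fit's asymptotic normal distribution,
and for each draw evaluates potential outcomes on the response scale
(probabilities for a logistic outcome), contrasting the exposure at its
observed mean ``x0`` against ``x0 + delta`` (one Ln-unit or one quantile).

Parallel (single mediator M):

    M ~ exposure + covariates            (linear)
    Y ~ exposure + M + covariates        (logistic or linear)

    IE(t) = E[ Y(x_t, M(x1)) - Y(x_t, M(x0)) ]
    DE(t) = E[ Y(x1, M(x_t)) - Y(x0, M(x_t)) ]

reported as the t-averages, so TE = IE + DE holds exactly and the proportion
mediated is IE/(IE+DE) = IE/TE.

Serial (ordered mediators M1 -> M2):

    M1 ~ exposure + cov;  M2 ~ exposure + M1 + cov;
    Y  ~ exposure + M1 + M2 + cov

The reported IE is the path-specific effect through M1 then M2 (only the M1
input of the M2 model switches between exposure levels); in an all-linear
chain it reduces to the coefficient product a1*d21*b2.  DE is reported as
TE - IE (everything not flowing through the serial path), keeping the
proportion-mediated definition consistent.

Counterfactual mediators include residual noise (common draws across the two
exposure levels within a simulation, a variance-reduction choice that leaves
the estimands untouched); point estimates are means over draws, intervals
are 2.5/97.5 percentiles, p-values two-sided tail proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .cohort import DataError
from .exposure import ModelError

log = logging.getLogger(__name__)


def proportion_mediated(ie: float, de: float, tol: float = 1e-12) -> float:
    """IE / (IE + DE); undefined (error) when the total effect is ~0."""
    total = ie + de
    if abs(total) < tol:
        raise DataError("total effect is zero to tolerance; proportion undefined")
    return ie / total


def _sim_stats(draws: np.ndarray) -> tuple[float, float, float, float]:
    """Point estimate, percentile CI, two-sided tail p from simulation draws."""
    est = float(np.mean(draws))
    lo, hi = (float(v) for v in np.percentile(draws, [2.5, 97.5]))
    p_lo = float(np.mean(draws <= 0))
    p_hi = float(np.mean(draws >= 0))
    p = min(1.0, 2.0 * min(p_lo, p_hi))
    return est, lo, hi, p


@dataclass
class MediationResults:
    """Indirect/direct/total effects on the response scale, with MC intervals."""

    exposure: str
    mediators: tuple[str, ...]
    ie: float
    de: float
    te: float
    prop_mediated: float
    ci: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    n_sim: int
    seed: int
    mode: str                       # "parallel" | "serial"
    outcome_family: str
    contrast: tuple[float, float]   # (x0, x1)
    sims: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def mc_se(self) -> dict[str, float]:
        """Monte-Carlo / quasi-Bayesian standard errors (SD of the draws)."""
        return {k: float(np.std(v)) for k, v in self.sims.items()}

    def summary(self) -> str:
        rows = [
            f"Quasi-Bayesian mediation ({self.mode}), outcome family "
            f"{self.outcome_family}, n_sim={self.n_sim}, seed={self.seed}",
            f"  exposure {self.exposure}: contrast {self.contrast[0]:.3f} -> "
            f"{self.contrast[1]:.3f}; mediators: {', '.join(self.mediators)}",
        ]
        for name, val in (("IE", self.ie), ("DE", self.de), ("TE", self.te),
                          ("prop_mediated", self.prop_mediated)):
            lo, hi = self.ci[name]
            rows.append(f"  {name:<14} {val:10.5f}  (95% CI {lo:.5f}, {hi:.5f})"
                        f"  p={self.p_values[name]:.3g}")
        return "\n".join(rows)

    def as_dict(self) -> dict:
        d = {"exposure": self.exposure, "mediators": "+".join(self.mediators),
             "mode": self.mode, "ie": self.ie, "de": self.de, "te": self.te,
             "prop_mediated": self.prop_mediated, "n_sim": self.n_sim,
             "seed": self.seed}
        for name in ("IE", "DE", "TE", "prop_mediated"):
            d[f"{name.lower()}_ci_low"], d[f"{name.lower()}_ci_high"] = self.ci[name]
            d[f"{name.lower()}_p"] = self.p_values[name]
        return d


def _fit_component(y, X: pd.DataFrame, family: str, weights=None):
    Xc = sm.add_constant(X, has_constant="add")
    if family == "linear":
        res = (sm.WLS(y, Xc, weights=weights).fit() if weights is not None
               else sm.OLS(y, Xc).fit())
        sigma = float(np.sqrt(res.scale))
    else:
        fam = sm.families.Binomial()
        if weights is not None:
            w = np.asarray(weights, dtype=float)
            w = w * len(w) / w.sum()
            res = sm.GLM(y, Xc, family=fam, freq_weights=w).fit(maxiter=200)
        else:
            res = sm.GLM(y, Xc, family=fam).fit(maxiter=200)
        if not res.converged:
            raise ModelError("outcome model did not converge")
        sigma = np.nan
    return res, sigma


def _draw_params(rng, res, n_sim: int) -> np.ndarray:
    mean = np.asarray(res.params, dtype=float)
    cov = np.asarray(res.cov_params(), dtype=float)
    return rng.multivariate_normal(mean, cov, size=n_sim, method="cholesky")


class CausalMediation:
    """Quasi-Bayesian mediation model for one exposure-mediator(s)-outcome triple.

    Parameters
    ----------
    outcome, exposure : (n,) arrays (or column names with ``data``)
    mediators : sequence of 1 (parallel) or 2 (serial, causally ordered) arrays
        or column names.  Mediators must be continuous.
    covariates : DataFrame, optional
        Adjustment set, entered in every component model.
    outcome_family : {"logistic", "linear"}
    delta : float
        Exposure contrast width; the contrast is (mean(x), mean(x) + delta).
    """

    def __init__(self, outcome, exposure, mediators, covariates: pd.DataFrame | None = None,
                 data: pd.DataFrame | None = None, outcome_family: str = "logistic",
                 delta: float = 1.0, weights=None,
                 exposure_name: str = "exposure", mediator_names=None):
        def col(v, default_name):
            if isinstance(v, str):
                if data is None:
                    raise ValueError("column names require a data frame")
                return data[v].to_numpy(dtype=float), v
            return np.asarray(v, dtype=float), default_name

        self.outcome, _ = col(outcome, "outcome")
        self.exposure, self.exposure_name = col(exposure, exposure_name)
        meds, names = [], []
        for i, m in enumerate(mediators):
            v, nm = col(m, f"m{i + 1}")
            meds.append(v)
            names.append(nm)
        if mediator_names is not None:
            names = list(mediator_names)
        if len(meds) not in (1, 2):
            raise ValueError("1 mediator (parallel) or 2 mediators (serial) supported")
        self.mediators = meds
        self.mediator_names = tuple(names)
        self.covariates = covariates
        self.weights = weights
        if outcome_family not in ("logistic", "linear"):
            raise ValueError("outcome_family must be 'logistic' or 'linear'")
        if outcome_family == "logistic" and not np.isin(self.outcome, [0, 1]).all():
            raise DataError("logistic mediation requires a binary outcome")
        for v, nm in zip(meds, names):
            if len(np.unique(v)) <= 2:
                raise DataError(f"mediator {nm!r} must be continuous")
        self.outcome_family = outcome_family
        self.delta = float(delta)
        self.mode = "parallel" if len(meds) == 1 else "serial"

    # -- design helpers --------------------------------------------------
    def _cov_arr(self) -> np.ndarray:
        n = len(self.outcome)
        if self.covariates is None:
            return np.empty((n, 0))
        return self.covariates.to_numpy(dtype=float)

    @staticmethod
    def _stack(*blocks) -> pd.DataFrame:
        arrs, names = [], []
        for name, a in blocks:
            a = np.asarray(a, dtype=float)
            if a.ndim == 1:
                arrs.append(a[:, None])
                names.append(name)
            else:
                arrs.append(a)
                names.extend(f"{name}{i}" for i in range(a.shape[1]))
        X = np.hstack(arrs) if arrs else np.empty((0, 0))
        return pd.DataFrame(X, columns=names)

    def _response(self, lp: np.ndarray) -> np.ndarray:
        return expit(lp) if self.outcome_family == "logistic" else lp

    def fit(self, n_sim: int = 1000, seed: int | None = None) -> MediationResults:
        """Run the quasi-Bayesian Monte-Carlo estimation."""
        if seed is None:
            seed = 0
        rng = np.random.default_rng(seed)
        if self.mode == "parallel":
            return self._fit_parallel(rng, n_sim, seed)
        return self._fit_serial(rng, n_sim, seed)

    # -- parallel --------------------------------------------------------
    def _fit_parallel(self, rng, n_sim, seed) -> MediationResults:
        x, m, y = self.exposure, self.mediators[0], self.outcome
        C = self._cov_arr()
        x0 = float(np.mean(x))
        x1 = x0 + self.delta

        Xm = self._stack(("x", x), ("c", C))
        res_m, sigma_m = _fit_component(m, Xm, "linear", self.weights)
        Xy = self._stack(("x", x), ("m", m), ("c", C))
        res_y, _ = _fit_component(y, Xy, self.outcome_family, self.weights)

        th_m = _draw_params(rng, res_m, n_sim)   # [const, x, covs]
        th_y = _draw_params(rng, res_y, n_sim)   # [const, x, m, covs]
        n = len(y)
        eps = rng.normal(0.0, sigma_m, size=(n_sim, n))

        cov_m = (C @ th_m[:, 2:].T).T if C.size else 0.0   # (n_sim, n)
        covy_t = (C @ th_y[:, 3:].T).T if C.size else 0.0
        a0, a1 = th_m[:, 0], th_m[:, 1]
        g0, gx, gm = th_y[:, 0], th_y[:, 1], th_y[:, 2]

        M0 = (a0 + a1 * x0)[:, None] + cov_m + eps
        M1 = M0 + (a1 * self.delta)[:, None]

        def Y(xv, M):
            lp = g0[:, None] + gx[:, None] * xv + gm[:, None] * M + covy_t
            return self._response(lp)

        ie_draws = 0.5 * ((Y(x1, M1) - Y(x1, M0)) + (Y(x0, M1) - Y(x0, M0))).mean(axis=1)
        de_draws = 0.5 * ((Y(x1, M1) - Y(x0, M1)) + (Y(x1, M0) - Y(x0, M0))).mean(axis=1)
        te_draws = (Y(x1, M1) - Y(x0, M0)).mean(axis=1)
        return self._assemble(ie_draws, de_draws, te_draws, n_sim, seed, (x0, x1))

    # -- serial ----------------------------------------------------------
    def _fit_serial(self, rng, n_sim, seed) -> MediationResults:
        x, (m1, m2), y = self.exposure, self.mediators, self.outcome
        C = self._cov_arr()
        x0 = float(np.mean(x))
        x1 = x0 + self.delta

        X1 = self._stack(("x", x), ("c", C))
        res1, sig1 = _fit_component(m1, X1, "linear", self.weights)
        X2 = self._stack(("x", x), ("m1", m1), ("c", C))
        res2, sig2 = _fit_component(m2, X2, "linear", self.weights)
        Xy = self._stack(("x", x), ("m1", m1), ("m2", m2), ("c", C))
        res_y, _ = _fit_component(y, Xy, self.outcome_family, self.weights)

        th1 = _draw_params(rng, res1, n_sim)     # [const, x, covs]
        th2 = _draw_params(rng, res2, n_sim)     # [const, x, m1, covs]
        thy = _draw_params(rng, res_y, n_sim)    # [const, x, m1, m2, covs]
        n = len(y)
        e1 = rng.normal(0.0, sig1, size=(n_sim, n))
        e2 = rng.normal(0.0, sig2, size=(n_sim, n))

        c1 = (C @ th1[:, 2:].T).T if C.size else 0.0   # (n_sim, n)
        c2 = (C @ th2[:, 3:].T).T if C.size else 0.0
        cy = (C @ thy[:, 4:].T).T if C.size else 0.0

        b10, b1x = th1[:, 0][:, None], th1[:, 1][:, None]
        b20, b2x, b2m1 = th2[:, 0][:, None], th2[:, 1][:, None], th2[:, 2][:, None]
        gy0, gyx = thy[:, 0][:, None], thy[:, 1][:, None]
        gym1, gym2 = thy[:, 2][:, None], thy[:, 3][:, None]

        def M1f(xv):
            return b10 + b1x * xv + c1 + e1

        def M2f(xv, M1v):
            return b20 + b2x * xv + b2m1 * M1v + c2 + e2

        def Yf(xv, M1v, M2v):
            lp = gy0 + gyx * xv + gym1 * M1v + gym2 * M2v + cy
            return self._response(lp)

        M1_0, M1_1 = M1f(x0), M1f(x1)
        # serial path: only the m1 input to the m2 model switches levels
        ie_draws = (Yf(x0, M1_0, M2f(x0, M1_1)) -
                    Yf(x0, M1_0, M2f(x0, M1_0))).mean(axis=1)
        te_draws = (Yf(x1, M1_1, M2f(x1, M1_1)) -
                    Yf(x0, M1_0, M2f(x0, M1_0))).mean(axis=1)
        de_draws = te_draws - ie_draws
        return self._assemble(ie_draws, de_draws, te_draws, n_sim, seed, (x0, x1))

    # -- shared ----------------------------------------------------------
    def _assemble(self, ie_draws, de_draws, te_draws, n_sim, seed, contrast):
        ie, ie_lo, ie_hi, ie_p = _sim_stats(ie_draws)
        de, de_lo, de_hi, de_p = _sim_stats(de_draws)
        te, te_lo, te_hi, te_p = _sim_stats(te_draws)
        with np.errstate(divide="ignore", invalid="ignore"):
            prop_draws = np.where(np.abs(te_draws) > 1e-12, ie_draws / te_draws, np.nan)
        prop_draws = prop_draws[np.isfinite(prop_draws)]
        if prop_draws.size == 0:
            prop, pr_lo, pr_hi, pr_p = np.nan, np.nan, np.nan, np.nan
            log.warning("total effect ~0 in all draws; proportion mediated undefined")
        else:
            prop = proportion_mediated(ie, de) if abs(ie + de) > 1e-12 else np.nan
            pr_lo, pr_hi = (float(v) for v in np.percentile(prop_draws, [2.5, 97.5]))
            pr_p = min(1.0, 2.0 * min(float(np.mean(prop_draws <= 0)),
                                      float(np.mean(prop_draws >= 0))))
        return MediationResults(
            exposure=self.exposure_name, mediators=self.mediator_names,
            ie=ie, de=de, te=te, prop_mediated=prop,
            ci={"IE": (ie_lo, ie_hi), "DE": (de_lo, de_hi), "TE": (te_lo, te_hi),
                "prop_mediated": (pr_lo, pr_hi)},
            p_values={"IE": ie_p, "DE": de_p, "TE": te_p, "prop_mediated": pr_p},
            n_sim=n_sim, seed=seed, mode=self.mode,
            outcome_family=self.outcome_family, contrast=contrast,
            sims={"IE": ie_draws, "DE": de_draws, "TE": te_draws},
        )


def mediate_parallel(exposure, mediator, outcome, covariates=None, n_sim: int = 1000,
                     seed: int | None = None, outcome_family: str = "logistic",
                     delta: float = 1.0, weights=None) -> MediationResults:
    """Single-mediator quasi-Bayesian mediation (functional wrapper)."""
    model = CausalMediation(outcome, exposure, [mediator], covariates,
                            outcome_family=outcome_family, delta=delta, weights=weights)
    return model.fit(n_sim=n_sim, seed=seed)


def mediate_serial(exposure, mediator1, mediator2, outcome, covariates=None,
                   n_sim: int = 1000, seed: int | None = None,
                   outcome_family: str = "logistic", delta: float = 1.0,
                   weights=None) -> MediationResults:
    """Two-mediator serial chain (mediator1 causally prior to mediator2)."""
    model = CausalMediation(outcome, exposure, [mediator1, mediator2], covariates,
                            outcome_family=outcome_family, delta=delta, weights=weights)
    return model.fit(n_sim=n_sim, seed=seed)
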