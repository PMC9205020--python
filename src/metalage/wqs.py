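"""Weighted quantile sum (WQS) regression, implemented from scratch.

WQS collapses a mixture of correlated exposures into a single index

    index_i = sum_j w_j * q_ij,        w_j >= 0,  sum_j w_j = 1,

where ``q_ij`` is exposure j's quantile score (0 .. n_quantiles-1) for
participant i.  Weights are estimated on bootstrap resamples of a training
split by maximising the likelihood of the outcome model

    g(E[y]) = b0 + b1 * index + covariates,

with ``b1`` constrained to the analyst-declared direction, then averaged
across bootstraps; the final inference regresses the outcome on the
fixed-weight index in the held-out validation split, so the reported
confidence interval is not contaminated by weight estimation.

The simplex constraint is handled by a softmax reparameterisation
(``w = softmax(theta)``) and the sign constraint by ``b1 = direction *
exp(eta)``, leaving an unconstrained smooth problem solved with L-BFGS and an
analytic gradient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, softmax

from .cohort import DataError
from .exposure import RegressionResult, _fit_glm, _term_result

log = logging.getLogger(__name__)


class WQSError(RuntimeError):
    """Weight estimation failed (too few converged bootstraps)."""


def quantile_score(metals: pd.DataFrame | np.ndarray, n_quantiles: int = 4) -> np.ndarray:
    """Score each exposure column into 0..n_quantiles-1 by sample quantiles."""
    if n_quantiles < 2:
        raise DataError("n_quantiles must be >= 2")
    X = metals.to_numpy(dtype=float) if isinstance(metals, pd.DataFrame) else np.asarray(
        metals, dtype=float)
    n, p = X.shape
    scores = np.empty((n, p), dtype=int)
    probs = np.arange(1, n_quantiles) / n_quantiles
    for j in range(p):
        col = X[:, j]
        if len(np.unique(col)) < 2 * n_quantiles:
            raise DataError(f"column {j} has too few distinct values to quantile-score")
        cuts = np.quantile(col, probs)
        if not np.all(np.diff(cuts) > 0):
            raise DataError(f"tied quantile cutpoints in column {j}")
        scores[:, j] = np.searchsorted(cuts, col, side="left")
    return scores


def _nll_and_grad(params, y, Q, Z, direction, family):
    """Negative log-likelihood (Bernoulli) or half-RSS (Gaussian) + gradient.

    params = [theta (p weights), eta (index coef), gamma (intercept + covs)].
    """
    p = Q.shape[1]
    theta = params[:p]
    eta = params[p]
    gamma = params[p + 1:]
    w = softmax(theta)
    # clip keeps line-search trial points finite; |b1| <= e^30 is never binding
    b1 = direction * np.exp(np.clip(eta, -30.0, 30.0))
    s = Q @ w
    lp = b1 * s + Z @ gamma
    if family == "logistic":
        mu = expit(lp)
        nll = -np.sum(y * np.log(np.clip(mu, 1e-12, 1)) +
                      (1 - y) * np.log(np.clip(1 - mu, 1e-12, 1)))
        r = mu - y
    else:
        r = lp - y
        nll = 0.5 * np.sum(r**2)
    g_b1 = float(r @ s)
    g_eta = g_b1 * b1
    u = Q.T @ r * b1
    g_theta = w * (u - float(w @ u))
    g_gamma = Z.T @ r
    return nll, np.concatenate([g_theta, [g_eta], g_gamma])


@dataclass
class WQSResults:
    """Fitted WQS model: simplex weights plus validation-split inference."""

    weights: pd.Series
    index_result: RegressionResult
    n_bootstrap: int
    n_quantiles: int
    split_seed: int
    converged_fraction: float
    direction: str
    train_fraction: float
    bootstrap_weights: np.ndarray = field(repr=False)
    validation_index: np.ndarray = field(repr=False)

    @property
    def index_coefficient(self) -> float:
        return self.index_result.estimate

    @property
    def or_or_beta(self) -> float:
        return self.index_result.or_or_beta

    @property
    def ci(self) -> tuple[float, float]:
        return (self.index_result.ci_low, self.index_result.ci_high)

    def summary(self) -> str:
        r = self.index_result
        scale = "OR" if r.model_family == "logistic" else "beta"
        lines = [
            "Weighted quantile sum regression",
            f"  direction={self.direction}, quantiles={self.n_quantiles}, "
            f"bootstraps={self.n_bootstrap} (converged {self.converged_fraction:.0%}), "
            f"train fraction={self.train_fraction}, seed={self.split_seed}",
            f"  index {scale} per one-quantile increase: {r.or_or_beta:.3f} "
            f"(95% CI {r.ci_low:.3f}, {r.ci_high:.3f}), p={r.p_value:.3g}",
            "  weights:",
        ]
        for name, wv in self.weights.sort_values(ascending=False).items():
            lines.append(f"    {name:<6} {wv:8.4f}")
        return "\n".join(lines)

    def weights_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"component": self.weights.index,
                             "weight": self.weights.to_numpy()})


class WQS:
    """Weighted quantile sum regression model.

    Parameters
    ----------
    endog : (n,) array
        Binary outcome (``family="logistic"``) or continuous marker
        (``family="linear"``).
    exposures : DataFrame (n, p)
        Mixture components on their measurement scale (quantile scoring is
        internal); column names label the weights.
    exog : DataFrame, optional
        Covariates, included both in the bootstrap weight-estimation fits and
        in the final validation model.
    direction : {"positive", "negative"}
        Constrained sign of the index coefficient.
    """

    def __init__(self, endog, exposures: pd.DataFrame, exog: pd.DataFrame | None = None,
                 family: str = "logistic", n_quantiles: int = 4,
                 direction: str = "positive"):
        self.endog = np.asarray(endog, dtype=float)
        if not isinstance(exposures, pd.DataFrame):
            exposures = pd.DataFrame(np.asarray(exposures, dtype=float))
        self.exposures = exposures
        self.exog = exog
        if family not in ("logistic", "linear"):
            raise ValueError("family must be 'logistic' or 'linear'")
        if family == "logistic" and not np.isin(self.endog, [0, 1]).all():
            raise DataError("logistic WQS requires a binary outcome")
        self.family = family
        if n_quantiles < 2:
            raise DataError("n_quantiles must be >= 2")
        self.n_quantiles = n_quantiles
        if direction not in ("positive", "negative"):
            raise ValueError("direction must be 'positive' or 'negative'")
        self.direction = direction

    # -- internals -------------------------------------------------------
    def _design(self):
        Q = quantile_score(self.exposures, self.n_quantiles).astype(float)
        n = len(self.endog)
        if self.exog is not None:
            # standardise covariates for the inner optimisation: the weight
            # estimates are invariant to affine rescaling of the adjustment
            # block, and L-BFGS conditioning is not
            C = self.exog.to_numpy(dtype=float)
            sd = C.std(axis=0)
            sd[sd == 0] = 1.0
            Z = np.column_stack([np.ones(n), (C - C.mean(axis=0)) / sd])
        else:
            Z = np.ones((n, 1))
        return Q, Z

    def _fit_one(self, y, Q, Z, dir_sign, x0):
        res = minimize(_nll_and_grad, x0, args=(y, Q, Z, dir_sign, self.family),
                       jac=True, method="L-BFGS-B",
                       options={"maxiter": 300, "ftol": 1e-10})
        converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-2
        p = Q.shape[1]
        return softmax(res.x[:p]), converged

    def fit(self, n_bootstrap: int = 100, train_fraction: float = 0.4,
            seed: int | None = None, aggregation: str = "mean",
            weights=None) -> WQSResults:
        """Estimate weights on bootstraps of the training split, then fit the
        validation model on the fixed-weight index.

        ``aggregation="mean"`` averages weight vectors over all converged
        bootstraps (default); ``"signif_weighted"`` weights each bootstrap's
        vector by the squared z-statistic of its index term.
        """
        if seed is None:
            seed = 0
        rng = np.random.default_rng(seed)
        y = self.endog
        Q, Z = self._design()
        n, p = Q.shape
        dir_sign = 1.0 if self.direction == "positive" else -1.0

        idx = rng.permutation(n)
        n_train = max(int(round(train_fraction * n)), p + Z.shape[1] + 2)
        train, valid = idx[:n_train], idx[n_train:]
        if len(valid) < p + Z.shape[1] + 2:
            raise DataError("validation split too small; reduce train_fraction")

        # warm start: intercept at the marginal mean, equal weights
        x0 = np.zeros(p + 1 + Z.shape[1])
        x0[p] = np.log(0.05)
        if self.family == "logistic":
            pbar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
            x0[p + 1] = np.log(pbar / (1 - pbar))
        else:
            x0[p + 1] = y.mean()

        boot_w = np.empty((n_bootstrap, p))
        boot_ok = np.zeros(n_bootstrap, dtype=bool)
        boot_z2 = np.ones(n_bootstrap)
        for b in range(n_bootstrap):
            bidx = rng.choice(train, size=len(train), replace=True)
            w_b, ok = self._fit_one(y[bidx], Q[bidx], Z[bidx], dir_sign, x0)
            boot_w[b] = w_b
            boot_ok[b] = ok
            if ok and aggregation == "signif_weighted":
                sb = Q[bidx] @ w_b
                Xb = pd.DataFrame(np.column_stack([sb, Z[bidx, 1:]]))
                Xb.columns = ["wqs_index"] + [f"z{i}" for i in range(Z.shape[1] - 1)]
                try:
                    rb = _fit_glm(y[bidx], Xb, self.family)
                    boot_z2[b] = float(rb.tvalues["wqs_index"] ** 2)
                except Exception:
                    boot_ok[b] = False

        conv_frac = float(boot_ok.mean())
        if conv_frac < 0.5:
            raise WQSError(f"only {conv_frac:.0%} of bootstrap fits converged")
        if aggregation == "mean":
            w_final = boot_w[boot_ok].mean(axis=0)
        elif aggregation == "signif_weighted":
            z2 = boot_z2[boot_ok]
            w_final = (boot_w[boot_ok] * z2[:, None]).sum(axis=0) / z2.sum()
        else:
            raise ValueError("aggregation must be 'mean' or 'signif_weighted'")
        w_final = w_final / w_final.sum()

        index_all = Q @ w_final
        Xv = pd.DataFrame({"wqs_index": index_all[valid]})
        cov_v = None
        if self.exog is not None:
            cov_v = self.exog.iloc[valid].reset_index(drop=True)
            Xv = pd.concat([Xv.reset_index(drop=True), cov_v], axis=1)
        wv = None if weights is None else np.asarray(weights, dtype=float)[valid]
        res = _fit_glm(y[valid], Xv, self.family, wv)
        term = _term_result(res, "wqs_index", self.family, wv is not None, len(valid))
        if dir_sign * term.estimate < 0:
            log.warning("validation index coefficient has the opposite sign to the "
                        "declared direction (%s)", self.direction)

        weights_s = pd.Series(w_final, index=list(self.exposures.columns), name="weight")
        assert abs(weights_s.sum() - 1.0) < 1e-8 and (weights_s >= 0).all()
        return WQSResults(
            weights=weights_s, index_result=term, n_bootstrap=n_bootstrap,
            n_quantiles=self.n_quantiles, split_seed=seed,
            converged_fraction=conv_frac, direction=self.direction,
            train_fraction=train_fraction, bootstrap_weights=boot_w[boot_ok],
            validation_index=index_all[valid],
        )


def fit_wqs(outcome, metals: pd.DataFrame, covariates: pd.DataFrame | None = None,
            direction: str = "positive", n_bootstrap: int = 100,
            n_quantiles: int = 4, train_fraction: float = 0.4,
            seed: int | None = None, family: str = "logistic",
            weights=None, aggregation: str = "mean") -> WQSResults:
    """Functional wrapper around :class:`WQS`."""
    model = WQS(outcome, metals, covariates, family=family,
                n_quantiles=n_quantiles, direction=direction)
    return model.fit(n_bootstrap=n_bootstrap, train_fraction=train_fraction,
                     seed=seed, aggregation=aggregation, weights=weights)
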