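"""Logit-scale linear mixed model of smoking prevalence on policy covariates.

The model, fitted separately per (sex, age-group) stratum, is

    logit(y_ct) = b0 + bp*P_{c,t-1} + bw*W_{c,t-1} + be*E_{c,t-1}
                  + br*RIP_{c,t-1} + a_c + d_c*RIP_{c,t-1} + e_ct

with fixed effects for the three achievement scores (numeric 2-5) and the
relative income price (percentage points), a random intercept a_c and a
random RIP slope d_c per country (2x2 unstructured covariance by default),
and i.i.d. residuals.  Estimation is by restricted maximum likelihood
(default; unbiased variance components and better-calibrated Wald
intervals) or plain ML (required by the likelihood-ratio test of the
random effects), through statsmodels' MixedLM.

:class:`PolicyMixedModel` is constructed from a model-ready panel (see
:mod:`tobaccopolicy.panel`); ``fit()`` returns a :class:`PolicyMixedResults`
carrying estimates, their covariance, variance components, diagnostics and a
``summary()`` table.  Counterfactual projection consumes the Results object
(:mod:`tobaccopolicy.counterfactual`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

from .exceptions import DomainError, FitError, MethodError
from .panel import expit, lag_merge, logit_clamped, select_stratum

FIXED_TERMS = ["Intercept", "p_lag", "w_lag", "e_lag", "rip_lag"]
COVARIATES = ["p_lag", "w_lag", "e_lag", "rip_lag"]

#: residual mean square below which a response is treated as exactly linear
_NOISELESS_TOL = 1e-12


class PolicyMixedModel:
    """Mixed model of logit prevalence on lagged policy scores and RIP.

    Parameters
    ----------
    panel : DataFrame
        Model-ready rows with columns ``country, logit_prev, p_lag, w_lag,
        e_lag, rip_lag`` (one stratum; see ``from_tables`` to build and
        subset in one step).
    stratum : tuple, optional
        (sex, age_group) label carried through to results and reports.
    """

    def __init__(self, panel: pd.DataFrame, stratum: tuple[str, str] | None = None):
        required = ["country", "logit_prev", *COVARIATES]
        missing = [c for c in required if c not in panel.columns]
        if missing:
            raise FitError(f"panel is missing column(s) {missing}")
        panel = panel.dropna(subset=required).reset_index(drop=True)
        if len(panel) < 6:
            raise FitError("need at least 6 complete panel rows")
        if panel["country"].nunique() < 2:
            raise FitError("need at least 2 countries to identify random effects")
        for col in COVARIATES:
            if np.ptp(panel[col].to_numpy()) == 0:
                raise FitError(f"covariate {col!r} is constant across the panel")
        self.panel = panel
        self.stratum = tuple(stratum) if stratum is not None else None
        self.endog = panel["logit_prev"].to_numpy()
        self.exog = np.column_stack(
            [np.ones(len(panel)), *(panel[c].to_numpy() for c in COVARIATES)]
        )
        self.groups = panel["country"].to_numpy()
        # random-effects design: intercept and RIP slope
        self.exog_re = np.column_stack([np.ones(len(panel)), panel["rip_lag"].to_numpy()])

    @classmethod
    def from_tables(cls, policies, prevalence, sex: str, age_group: str) -> "PolicyMixedModel":
        """Build the lagged panel from raw tables and select one stratum."""
        panel, _ = lag_merge(policies, prevalence)
        sub = select_stratum(panel, sex, age_group)
        return cls(sub, stratum=(sex, age_group))

    # -- estimation -----------------------------------------------------

    def fit(
        self,
        method: str = "reml",
        re_structure: str = "unstructured",
        maxiter: int = 2000,
    ) -> "PolicyMixedResults":
        """Fit by REML (default) or ML.

        ``re_structure`` is "unstructured" (correlated intercept and slope)
        or "independent" (diagonal covariance).  A response that is exactly
        linear in the covariates (all variance components zero) degenerates
        the mixed likelihood; it is detected and solved exactly by least
        squares with zero variance components.
        """
        method = method.lower()
        if method not in ("ml", "reml"):
            raise MethodError(f"method must be 'ml' or 'reml', got {method!r}")

        ols = sm.OLS(self.endog, self.exog).fit()
        if ols.ssr / len(self.endog) < _NOISELESS_TOL:
            return self._noiseless_results(ols, method)

        mixed = MixedLM(self.endog, self.exog, groups=self.groups, exog_re=self.exog_re)
        free = None
        if re_structure == "independent":
            free = MixedLMParams.from_components(
                fe_params=np.ones(5), cov_re=np.eye(2)
            )
        elif re_structure != "unstructured":
            raise MethodError(f"unknown re_structure {re_structure!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = mixed.fit(
                reml=(method == "reml"), free=free,
                method=["powell", "bfgs"], maxiter=maxiter,
            )
        cov_re = np.asarray(res.cov_re)  # already on the data scale
        sd_int = float(np.sqrt(max(cov_re[0, 0], 0.0)))
        sd_slope = float(np.sqrt(max(cov_re[1, 1], 0.0)))
        corr = float(cov_re[0, 1] / (sd_int * sd_slope)) if sd_int > 0 and sd_slope > 0 else 0.0
        # model-based GLS covariance of the fixed effects, (sum_i X_i' V_i^-1
        # X_i)^-1 with V_i = Z_i Psi Z_i' + s2 I; unlike the numerical
        # Hessian it stays PSD when variance components sit near zero
        vcov = self._fe_covariance(cov_re, float(res.scale))
        params = pd.Series(np.asarray(res.fe_params), index=FIXED_TERMS)
        bse = pd.Series(np.sqrt(np.diag(vcov)), index=FIXED_TERMS)
        z = params / bse
        pvals = pd.Series(2 * scipy.stats.norm.sf(np.abs(z)), index=FIXED_TERMS)
        return PolicyMixedResults(
            model=self, params=params, bse=bse,
            cov_params=pd.DataFrame(vcov, index=FIXED_TERMS, columns=FIXED_TERMS),
            sd_intercept=sd_int, sd_slope=sd_slope,
            re_correlation=max(-1.0, min(1.0, corr)),
            sd_resid=float(np.sqrt(res.scale)),
            llf=float(res.llf), method=method, re_structure=re_structure,
            converged=bool(res.converged), df_method="normal",
            pvalues=pvals,
            n_obs=len(self.endog), n_countries=int(pd.unique(self.groups).size),
        )

    def _fe_covariance(self, cov_re: np.ndarray, scale: float) -> np.ndarray:
        """Kenward-Roger-adjusted covariance of the fixed effects.

        Starts from the model-based GLS expression
        Phi = (sum_i X_i' V_i^-1 X_i)^-1 with V_i = Z_i Psi Z_i' + s2 I
        (unlike the numerical Hessian it stays PSD when variance components
        sit near zero), then adds the Kackar-Harville/Kenward-Roger term
        for the extra variability induced by estimating the variance
        parameters.  V is linear in the four variance parameters
        (psi11, psi12, psi22, s2), so the second-derivative term of the
        adjustment vanishes.
        """
        k = self.exog.shape[1]
        n_theta = 4
        blocks = []
        for g in pd.unique(self.groups):
            idx = self.groups == g
            X, Z = self.exog[idx], self.exog_re[idx]
            n_i = int(idx.sum())
            V = Z @ cov_re @ Z.T + scale * np.eye(n_i)
            Vinv = np.linalg.inv(V)
            z1, z2 = Z[:, :1], Z[:, 1:]
            # dV/dtheta_r for theta = (psi11, psi12, psi22, s2)
            A = [z1 @ z1.T, z1 @ z2.T + z2 @ z1.T, z2 @ z2.T, np.eye(n_i)]
            blocks.append((X, Vinv, A))

        phi_inv = sum(X.T @ Vinv @ X for X, Vinv, _ in blocks)
        phi = np.linalg.inv(phi_inv)

        P = [np.zeros((k, k)) for _ in range(n_theta)]   # X'V^-1 A_r V^-1 X
        Q = [[np.zeros((k, k)) for _ in range(n_theta)] for _ in range(n_theta)]
        T1 = np.zeros((n_theta, n_theta))                # tr(V^-1 A_r V^-1 A_s)
        for X, Vinv, A in blocks:
            G = [Vinv @ a for a in A]
            XtV = X.T @ Vinv
            for r in range(n_theta):
                P[r] += XtV @ A[r] @ Vinv @ X
                for s in range(r, n_theta):
                    T1[r, s] += np.trace(G[r] @ G[s])
                    Q[r][s] += XtV @ A[r] @ G[s] @ Vinv @ X
        for r in range(n_theta):
            for s in range(r):
                T1[r, s] = T1[s, r]
                Q[r][s] = Q[s][r].T

        # expected REML information of the variance parameters
        info_theta = np.zeros((n_theta, n_theta))
        for r in range(n_theta):
            for s in range(n_theta):
                info_theta[r, s] = 0.5 * (
                    T1[r, s]
                    - 2.0 * np.trace(phi @ Q[r][s])
                    + np.trace(phi @ P[r] @ phi @ P[s])
                )
        W = np.linalg.pinv(info_theta)

        adjust = np.zeros((k, k))
        for r in range(n_theta):
            for s in range(n_theta):
                adjust += W[r, s] * (Q[r][s] - P[r] @ phi @ P[s])
        lam = 2.0 * phi @ adjust @ phi
        lam = (lam + lam.T) / 2.0
        # the population adjustment is PSD; clip a numerically indefinite
        # estimate (variance parameters at the boundary) to its PSD part
        vals, vecs = np.linalg.eigh(lam)
        lam = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
        return phi + lam

    def _noiseless_results(self, ols, method: str) -> "PolicyMixedResults":
        k = len(FIXED_TERMS)
        params = pd.Series(ols.params, index=FIXED_TERMS)
        zeros = pd.DataFrame(np.zeros((k, k)), index=FIXED_TERMS, columns=FIXED_TERMS)
        return PolicyMixedResults(
            model=self, params=params,
            bse=pd.Series(np.zeros(k), index=FIXED_TERMS), cov_params=zeros,
            sd_intercept=0.0, sd_slope=0.0, re_correlation=0.0, sd_resid=0.0,
            llf=float("inf"), method=method, re_structure="degenerate",
            converged=True, df_method="exact",
            pvalues=pd.Series(np.zeros(k), index=FIXED_TERMS),
            n_obs=len(self.endog), n_countries=int(pd.unique(self.groups).size),
        )


@dataclass
class PolicyMixedResults:
    """Estimates, uncertainty and diagnostics from one stratum fit."""

    model: PolicyMixedModel
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    sd_intercept: float
    sd_slope: float
    re_correlation: float
    sd_resid: float
    llf: float
    method: str
    re_structure: str
    converged: bool
    df_method: str
    pvalues: pd.Series
    n_obs: int
    n_countries: int

    @property
    def stratum(self):
        return self.model.stratum if self.model is not None else None

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald (normal) confidence intervals for the fixed effects."""
        zc = scipy.stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - zc * self.bse, "upper": self.params + zc * self.bse}
        )

    def slope_params(self) -> np.ndarray:
        """(bp, bw, be, br) — the covariate effects, without the intercept."""
        return self.params[COVARIATES].to_numpy()

    # -- diagnostics ----------------------------------------------------

    def lrt_random_effects(self) -> "LRTResult":
        """Likelihood-ratio test of the country random effects.

        Compares the full ML fit with the fixed-effects-only linear model.
        The reference chi-square uses one df per extra variance parameter
        (3 unstructured, 2 independent); with variances on the boundary of
        the parameter space this is conservative.
        """
        if self.method != "ml":
            raise MethodError("LRT requires an ML fit; refit with method='ml'")
        ols = sm.OLS(self.model.endog, self.model.exog).fit()
        stat = max(0.0, 2.0 * (self.llf - ols.llf))
        df = 2 if self.re_structure == "independent" else 3
        pvalue = float(scipy.stats.chi2.sf(stat, df))
        return LRTResult(statistic=float(stat), df=df, pvalue=pvalue,
                         reference=f"chi-square({df}), boundary-conservative")

    def effect_table(
        self,
        p0: float | None = None,
        deltas: dict | None = None,
        alpha: float = 0.05,
    ) -> pd.DataFrame:
        """Covariate effects as relative percent changes in prevalence.

        Each coefficient is converted to the percent change in prevalence at
        a baseline ``p0`` (default: the observation-weighted mean prevalence
        of the fitted panel) for a covariate increment ``delta`` (default 1
        score unit for P/W/E and 10 RIP percentage points).  Interval bounds
        transform the Wald CI endpoints; the conversion is monotone in the
        coefficient, so coverage is preserved.
        """
        if p0 is None:
            p0 = float(self.model.panel["prevalence"].mean()) \
                if "prevalence" in self.model.panel.columns \
                else float(expit(np.mean(self.model.endog)))
        deltas = deltas or {"p_lag": 1.0, "w_lag": 1.0, "e_lag": 1.0, "rip_lag": 10.0}
        ci = self.conf_int(alpha)
        rows = []
        for term, delta in deltas.items():
            rows.append({
                "stratum": ":".join(self.stratum) if self.stratum else "",
                "predictor": term,
                "delta": delta,
                "relative_change_pct": relative_change(self.params[term], p0, delta),
                "ui_lower_pct": relative_change(ci.loc[term, "lower"], p0, delta),
                "ui_upper_pct": relative_change(ci.loc[term, "upper"], p0, delta),
                # alternative scaled reading: delta times the per-unit change
                # (differs from the logit-scale shift only for large deltas)
                "per_unit_x_delta_pct": delta * relative_change(self.params[term], p0, 1.0),
                "p_value": self.pvalues[term],
            })
        return pd.DataFrame(rows)

    # -- presentation / persistence -------------------------------------

    def summary(self) -> str:
        lines = []
        title = "Logit-prevalence mixed model"
        if self.stratum:
            title += f" — stratum {self.stratum[0]}:{self.stratum[1]}"
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(
            f"method: {self.method.upper()}   n_obs: {self.n_obs}   "
            f"countries: {self.n_countries}   converged: {self.converged}"
        )
        lines.append(f"log-likelihood: {self.llf:.3f}   df method: {self.df_method}")
        lines.append("")
        lines.append(f"{'term':<10}{'coef':>12}{'std err':>12}{'P>|z|':>10}")
        for term in FIXED_TERMS:
            lines.append(
                f"{term:<10}{self.params[term]:>12.5f}"
                f"{self.bse[term]:>12.5f}{self.pvalues[term]:>10.4f}"
            )
        lines.append("")
        lines.append(
            f"random effects: sd(intercept)={self.sd_intercept:.4f}  "
            f"sd(RIP slope)={self.sd_slope:.5f}  corr={self.re_correlation:+.3f}  "
            f"sd(resid)={self.sd_resid:.4f}"
        )
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "stratum": list(self.stratum) if self.stratum else None,
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "cov_params": self.cov_params.to_numpy().tolist(),
            "sd_intercept": self.sd_intercept, "sd_slope": self.sd_slope,
            "re_correlation": self.re_correlation, "sd_resid": self.sd_resid,
            "llf": self.llf, "method": self.method, "re_structure": self.re_structure,
            "converged": self.converged, "df_method": self.df_method,
            "pvalues": self.pvalues.to_dict(),
            "n_obs": self.n_obs, "n_countries": self.n_countries,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PolicyMixedResults":
        import os

        if isinstance(source, os.PathLike) or (
            isinstance(source, (str, bytes)) and not str(source).lstrip().startswith("{")
        ):
            with open(source) as fh:
                data = json.load(fh)
        else:
            data = json.loads(source)
        k = FIXED_TERMS
        return cls(
            model=None,
            params=pd.Series(data["params"]).reindex(k),
            bse=pd.Series(data["bse"]).reindex(k),
            cov_params=pd.DataFrame(np.asarray(data["cov_params"]), index=k, columns=k),
            sd_intercept=data["sd_intercept"], sd_slope=data["sd_slope"],
            re_correlation=data["re_correlation"], sd_resid=data["sd_resid"],
            llf=data["llf"], method=data["method"], re_structure=data["re_structure"],
            converged=data["converged"], df_method=data["df_method"],
            pvalues=pd.Series(data["pvalues"]).reindex(k),
            n_obs=data["n_obs"], n_countries=data["n_countries"],
        )


@dataclass
class LRTResult:
    statistic: float
    df: int
    pvalue: float
    reference: str


def fit_lmm(panel: pd.DataFrame, method: str = "reml", **kwargs) -> PolicyMixedResults:
    """Functional wrapper: construct :class:`PolicyMixedModel` and fit."""
    return PolicyMixedModel(panel).fit(method=method, **kwargs)


def vif(panel: pd.DataFrame, predictors: list[str] | None = None) -> pd.Series:
    """Variance inflation factors for the fixed-effect covariates.

    VIF_j = 1 / (1 - R^2_j) from regressing predictor j on the other
    predictors plus an intercept; perfect collinearity reports inf.
    """
    predictors = predictors or COVARIATES
    if len(predictors) < 2:
        raise DomainError("need at least 2 predictors for VIFs")
    X = panel[predictors].to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(predictors):
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def relative_change(beta: float, p0: float, delta: float = 1.0) -> float:
    """Percent change in prevalence for a covariate increment.

    Shifts the logit of the baseline prevalence ``p0`` by ``beta * delta``
    and returns ``100 * (p1 - p0) / p0``.  As p0 -> 0 this approaches the
    rare-outcome limit ``100 * (exp(beta * delta) - 1)``.
    """
    if not 0.0 < p0 < 1.0:
        raise DomainError("baseline prevalence p0 must lie in (0, 1)")
    if beta * delta == 0.0:
        return 0.0  # exact null effect, no transform roundtrip noise
    p1 = expit(logit_clamped(p0) + beta * delta)
    return 100.0 * (p1 - p0) / p0
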