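"""Simulation studies that score the pipeline against generator ground truth.

These routines close the loop: generate panels from the model's own
generative process with known parameters, run the estimation and projection
stages, and measure recovery, interval calibration and exactness.  They are
used both by the test suite and by the repository's acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import counterfactual as cf
from .model import FIXED_TERMS, fit_lmm
from .panel import POLICY_COLUMNS, expit, lag_merge, logit_clamped, select_stratum
from .simulate import GeneratorConfig, generate_panel_data

#: fixed effects used for recovery studies (logit scale): intercept, P, W, E
#: score effects per unit, RIP effect per percentage point
RECOVERY_BETAS = (-0.3, -0.011, -0.021, -0.019, -0.009)

_STRATUM = ("both", "15plus")


def _replicate_seeds(seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(int(seed) % (2**31))
    return rng.integers(0, 2**31 - 1, size=n)


def _one_panel(rep_seed: int, n_countries: int, **config_overrides):
    kwargs = dict(
        n_countries=n_countries,
        strata=[_STRATUM],
        fixed_effects=RECOVERY_BETAS,
        seed=int(rep_seed),
    )
    kwargs.update(config_overrides)
    config = GeneratorConfig(**kwargs)
    policies, prevalence, truth = generate_panel_data(config)
    panel, _ = lag_merge(policies[POLICY_COLUMNS], prevalence)
    return policies, prevalence, select_stratum(panel, *_STRATUM), truth


@dataclass
class RecoveryStudy:
    """Mean estimates, relative bias and CI coverage over replicates."""

    truth: pd.Series
    mean_estimates: pd.Series
    rel_bias_pct: pd.Series
    coverage_pct: pd.Series
    n_replicates: int
    n_countries: int
    n_converged: int


def recovery_study(
    n_replicates: int = 100,
    n_countries: int = 150,
    seed: int = 0,
    **config_overrides,
) -> RecoveryStudy:
    """Fit the mixed model on replicate synthetic panels and score recovery.

    Each replicate draws a fresh panel (policy trajectories, random effects,
    residuals) at the study's generative settings, fits with the default
    estimator and records the fixed effects and whether each 95% interval
    covers the truth.
    """
    truth = pd.Series(RECOVERY_BETAS, index=FIXED_TERMS)
    estimates, covered, n_conv = [], [], 0
    for rep_seed in _replicate_seeds(seed, n_replicates):
        _, _, panel, _ = _one_panel(rep_seed, n_countries, **config_overrides)
        res = fit_lmm(panel)
        n_conv += int(res.converged)
        estimates.append(res.params)
        ci = res.conf_int()
        covered.append((ci["lower"] <= truth) & (truth <= ci["upper"]))
    est = pd.DataFrame(estimates)
    cov = pd.DataFrame(covered)
    mean_est = est.mean()
    return RecoveryStudy(
        truth=truth,
        mean_estimates=mean_est,
        rel_bias_pct=100.0 * (mean_est - truth) / truth,
        coverage_pct=100.0 * cov.mean(),
        n_replicates=n_replicates,
        n_countries=n_countries,
        n_converged=n_conv,
    )


def noiseless_exactness(seed: int = 0, n_countries: int = 40) -> dict:
    """Zero-noise limit: exact coefficient recovery and identity scenario.

    With all random-effect and residual SDs at zero the generated logit
    prevalence is an exact linear function of the covariates, so the fit
    must return the generating coefficients to solver precision, and the
    identity scenario must reproduce observed prevalence and smoker counts
    with zero change.
    """
    policies, prevalence, panel, truth = _one_panel(
        seed, n_countries, sd_intercept=0.0, sd_slope=0.0, sd_resid=0.0,
        missing_rate=0.0,
    )
    res = fit_lmm(panel)
    max_abs_err = float(
        (res.params - pd.Series(RECOVERY_BETAS, index=FIXED_TERMS)).abs().max()
    )
    projector = cf.ScenarioProjector({_STRATUM: res}, policies, prevalence)
    table = projector.run([cf.identity_scenario()], n_draws=10, seed=seed)
    return {
        "max_abs_coef_error": max_abs_err,
        "identity_max_abs_rel_change_pct": float(table["rel_change_pct"].abs().max()),
        "identity_max_abs_smoker_change_m": float(table["change_smokers_m"].abs().max()),
        "n_obs": res.n_obs,
    }


def ui_calibration_study(
    n_replicates: int = 200,
    n_countries: int = 150,
    n_draws: int = 1000,
    seed: int = 0,
    **config_overrides,
) -> dict:
    """Coverage of the draw-based 95% UI for global counterfactual prevalence.

    Per replicate: generate a panel with known coefficients, fit the
    mixed model, apply the top-score scenario to the balanced countries, and check
    whether the 2.5-97.5 percentile interval over coefficient draws covers
    the counterfactual computed with the true coefficients (same observed
    anchor, so only coefficient uncertainty matters).
    """
    scenario = cf.Scenario(name="3_max_policy", score_override={"p": 5, "w": 5, "e": 5})
    beta_true = np.asarray(RECOVERY_BETAS[1:])
    hits = 0
    for rep_seed in _replicate_seeds(seed, n_replicates):
        policies, prevalence, panel, _ = _one_panel(
            rep_seed, n_countries, **config_overrides
        )
        res = fit_lmm(panel)
        countries = cf.restrict_balanced_countries(policies)
        prev17 = prevalence[
            (prevalence["sex"] == _STRATUM[0])
            & (prevalence["age_group"] == _STRATUM[1])
            & (prevalence["year"] == 2017)
        ].set_index("country")
        countries = [c for c in countries if c in prev17.index]
        obs16 = cf._covariate_frame(policies, 2016, countries)
        cfcov = pd.DataFrame(
            [cf.apply_scenario(obs16.loc[c], None, scenario) for c in countries],
            index=countries,
        )
        D = cfcov[list(cf.COVAR_KEYS)].to_numpy() - obs16[list(cf.COVAR_KEYS)].to_numpy()
        obs_prev = prev17.loc[countries, "prevalence"].to_numpy(dtype=float)
        wts = prev17.loc[countries, "population"].to_numpy(dtype=float)
        logit_obs = logit_clamped(obs_prev)
        true_val = float(np.average(expit(logit_obs + D @ beta_true), weights=wts))
        draws = cf.draw_coefficients(res, n_draws, int(rep_seed))
        cf_prev_d = expit(logit_obs[:, None] + D @ draws.slopes().T)
        wprev_d = wts @ cf_prev_d / wts.sum()
        lo, hi = cf.summarize_ui(wprev_d)
        hits += int(lo <= true_val <= hi)
    return {
        "coverage_pct": 100.0 * hits / n_replicates,
        "n_replicates": n_replicates,
        "n_countries": n_countries,
        "n_draws": n_draws,
    }
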