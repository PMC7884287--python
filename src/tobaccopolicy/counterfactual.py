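"""Counterfactual 2017 prevalence and smoker counts under policy scenarios.

Four headline scenarios ask what 2017 smoking prevalence would have been if
(1) policy scores and cigarette affordability had stayed at their 2008
levels, (2) every pack had cost at least I$7.73 (the 90th percentile of
observed country-year prices), (3) every country had top (score 5)
smoke-free, warning and advertising laws, and (4) both price floor and top
scores together.

Prediction uses fixed effects only: each country's observed 2017 prevalence
is shifted on the logit scale by the coefficient-weighted change in
covariates (counterfactual minus observed 2016), leaving country random
effects untouched.  Results aggregate to population-weighted global
prevalence and smoker counts, with 95% uncertainty intervals taken as
2.5/97.5 percentiles over multivariate-normal draws of the coefficient
vector.  Age-group smoker counts are proportionally rescaled so that they
sum to the sex-specific 15-plus envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import affordability
from .exceptions import (
    AlignmentError,
    ConfigurationError,
    DomainError,
    EmptyInputError,
)
from .panel import SCORE_COLUMNS, apply_missingness_rules, expit, logit_clamped

#: I$ price floor used by the headline scenarios (90th percentile of
#: observed country-year pack prices in the study data)
DEFAULT_PRICE_FLOOR = 7.73

_SCORE_KEYS = ("p", "w", "e")
COVAR_KEYS = ("p", "w", "e", "rip")


@dataclass(frozen=True)
class Scenario:
    """One counterfactual covariate rule set.

    ``score_override`` maps policy letters ("p", "w", "e") to a target score
    set exactly (not only upward).  ``price_floor`` raises pack price to
    ``max(observed, floor)`` before RIP is recomputed with the same-year
    GDP.  ``use_reference_year`` replaces 2016 covariates with the 2008
    values verbatim.
    """

    name: str
    score_override: Mapping[str, int] | None = None
    price_floor: float | None = None
    use_reference_year: bool = False

    def __post_init__(self):
        if self.score_override is None and self.price_floor is None \
                and not self.use_reference_year and self.name != "identity":
            raise ConfigurationError(f"scenario {self.name!r} sets no rule")
        if self.score_override is not None:
            for k, v in self.score_override.items():
                if k not in _SCORE_KEYS:
                    raise ConfigurationError(f"unknown score key {k!r}")
                if not 2 <= int(v) <= 5:
                    raise ConfigurationError("score overrides must lie in {2,...,5}")
        if self.price_floor is not None and self.price_floor <= 0:
            raise ConfigurationError("price_floor must be positive")


def identity_scenario() -> Scenario:
    """A scenario with no rules: covariates unchanged (zero effect)."""
    return Scenario(name="identity")


def default_scenarios(price_floor: float = DEFAULT_PRICE_FLOOR) -> list[Scenario]:
    """The four headline scenarios, in reporting order."""
    top = {"p": 5, "w": 5, "e": 5}
    return [
        Scenario(name="1_status_quo_2008", use_reference_year=True),
        Scenario(name="2_price_floor", price_floor=price_floor),
        Scenario(name="3_max_policy", score_override=top),
        Scenario(name="4_combined", score_override=top, price_floor=price_floor),
    ]


def compute_price_floor(policies: pd.DataFrame, q: float = 90.0) -> float:
    """q-th percentile of pooled country-year pack prices (linear interp.)."""
    prices = policies["price"].dropna().to_numpy()
    if prices.size == 0:
        raise EmptyInputError("no observed prices")
    return float(np.percentile(prices, q))


def restrict_balanced_countries(
    policies: pd.DataFrame, years: tuple[int, int] = (2008, 2016)
) -> list[str]:
    """Countries with complete P/W/E scores, price and GDP in both years."""
    pol = apply_missingness_rules(policies)
    needed = [*SCORE_COLUMNS, "price", "gdp_pc"]
    keep = None
    for year in years:
        sub = pol[pol["year"] == year].dropna(subset=needed)
        cs = set(sub["country"])
        keep = cs if keep is None else keep & cs
    if not keep:
        raise EmptyInputError(f"no country has complete indicators in both {years}")
    return sorted(keep)


def _covariate_frame(policies: pd.DataFrame, year: int, countries) -> pd.DataFrame:
    pol = apply_missingness_rules(policies)
    sub = pol[pol["year"] == year].set_index("country").loc[list(countries)]
    out = pd.DataFrame({
        "p": sub["p_score"].astype(float),
        "w": sub["w_score"].astype(float),
        "e": sub["e_score"].astype(float),
        "price": sub["price"].astype(float),
        "gdp_pc": sub["gdp_pc"].astype(float),
    })
    out["rip"] = affordability.compute_rip(out["price"].to_numpy(), out["gdp_pc"].to_numpy())
    return out


def apply_scenario(obs_2016: Mapping, obs_2008: Mapping | None, scenario: Scenario) -> dict:
    """Counterfactual (P, W, E, RIP) for one country.

    ``obs_2016``/``obs_2008`` need keys p, w, e, price, gdp_pc (rip optional;
    recomputed).  Returns a dict with keys p, w, e, rip.
    """
    if scenario.use_reference_year:
        if obs_2008 is None:
            raise EmptyInputError("scenario requires 2008 covariates, none supplied")
        src = obs_2008
        return {
            "p": float(src["p"]), "w": float(src["w"]), "e": float(src["e"]),
            "rip": float(affordability.compute_rip(src["price"], src["gdp_pc"])),
        }
    out = {k: float(obs_2016[k]) for k in _SCORE_KEYS}
    price = float(obs_2016["price"])
    if scenario.score_override:
        for k, v in scenario.score_override.items():
            out[k] = float(v)
    if scenario.price_floor is not None:
        price = max(price, float(scenario.price_floor))
    out["rip"] = float(affordability.compute_rip(price, obs_2016["gdp_pc"]))
    return out


def predict_counterfactual_prevalence(beta, obs_prev_2017, delta) -> float | np.ndarray:
    """Shift observed prevalence on the logit scale by the covariate change.

    ``beta`` is the (bp, bw, be, br) coefficient vector; ``delta`` the
    counterfactual-minus-observed covariate change in matching order.
    Country random effects are part of the observed anchor and cancel.
    """
    beta = np.asarray(beta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(delta))):
        raise DomainError("non-finite coefficients or covariate deltas")
    shift = delta @ beta if delta.ndim > 0 and delta.shape[-1] == beta.shape[0] \
        else float(np.dot(delta, beta))
    return expit(logit_clamped(obs_prev_2017) + shift)


def aggregate_global(prevalence, population) -> tuple[float, float]:
    """Population-weighted mean prevalence and total smokers.

    Inputs are aligned pandas Series keyed by country (or equal-length
    arrays).  Returns ``(sum(p*w)/sum(w), sum(p*w))``.
    """
    p = pd.Series(prevalence, dtype=float)
    w = pd.Series(population, dtype=float)
    if isinstance(prevalence, (pd.Series, dict)) or isinstance(population, (pd.Series, dict)):
        if not p.index.equals(w.index):
            if set(p.index) != set(w.index):
                raise AlignmentError("prevalence and population keys do not match")
            w = w.reindex(p.index)
    elif len(p) != len(w):
        raise AlignmentError("prevalence and population lengths differ")
    if (w <= 0).any():
        raise DomainError("populations must be strictly positive")
    smokers = float((p * w).sum())
    return smokers / float(w.sum()), smokers


def redistribute_age_counts(age_counts: Mapping[str, float], envelope: float) -> dict:
    """Scale age-group smoker counts so they sum exactly to the envelope."""
    counts = {k: float(v) for k, v in age_counts.items()}
    if any(v < 0 for v in counts.values()):
        raise DomainError("age counts must be non-negative")
    if envelope <= 0:
        raise DomainError("envelope must be positive")
    total = sum(counts.values())
    if total == 0:
        raise DomainError("cannot redistribute a positive envelope over all-zero counts")
    scale = envelope / total
    return {k: v * scale for k, v in counts.items()}


@dataclass
class DrawSet:
    """Sampled fixed-effect vectors from the estimate's distribution."""

    values: np.ndarray  # n_draws x 5, columns in FIXED_TERMS order
    columns: tuple
    seed: int

    @property
    def n_draws(self) -> int:
        return self.values.shape[0]

    def slopes(self) -> np.ndarray:
        """n_draws x 4 covariate-effect draws (drop the intercept)."""
        return self.values[:, 1:]


def _nearest_psd(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2.0)
    return (vecs * np.clip(vals, 0.0, None)) @ vecs.T


def draw_coefficients(results, n_draws: int, seed: int) -> DrawSet:
    """Multivariate-normal draws of the fixed effects.

    Centered at the point estimates with the fitted covariance; a
    numerically non-PSD covariance is repaired by eigenvalue clipping with
    a warning.  Reproducible by seed.
    """
    if n_draws < 2:
        raise DomainError("n_draws must be >= 2")
    mean = results.params.to_numpy(dtype=float)
    cov = results.cov_params.to_numpy(dtype=float)
    eig_min = float(np.linalg.eigvalsh((cov + cov.T) / 2.0).min())
    if eig_min < -1e-10 * max(1.0, float(np.abs(cov).max())):
        warnings.warn("fixed-effect covariance not PSD; repaired by eigenvalue clipping")
        cov = _nearest_psd(cov)
    rng = np.random.default_rng([int(seed) % (2**31), 23])
    values = rng.multivariate_normal(mean, cov, size=int(n_draws), method="svd")
    return DrawSet(values=values, columns=tuple(results.params.index), seed=int(seed))


def summarize_ui(values) -> tuple[float, float]:
    """Empirical 95% uncertainty interval (2.5th and 97.5th percentiles).

    Percentiles use NumPy's default linear interpolation between order
    statistics.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise EmptyInputError("need at least 2 draws to summarize an interval")
    lo, hi = np.percentile(arr, [2.5, 97.5])
    return float(lo), float(hi)


class ScenarioProjector:
    """Project scenarios through fitted per-stratum models.

    Parameters
    ----------
    results_by_stratum : mapping
        (sex, age_group) -> :class:`~tobaccopolicy.model.PolicyMixedResults`.
    policies, prevalence : DataFrame
        Raw input tables; the projector restricts itself to countries with
        complete indicators in both reference years and prevalence in the
        outcome year.
    outcome_year : int
        Year whose observed prevalence anchors the prediction (2017).
    """

    def __init__(
        self,
        results_by_stratum: Mapping,
        policies: pd.DataFrame,
        prevalence: pd.DataFrame,
        outcome_year: int = 2017,
        reference_years: tuple[int, int] = (2008, 2016),
    ):
        self.results = {tuple(k): v for k, v in results_by_stratum.items()}
        self.policies = policies
        self.prevalence = prevalence
        self.outcome_year = int(outcome_year)
        self.reference_years = reference_years
        self.balanced = restrict_balanced_countries(policies, reference_years)

    def _stratum_inputs(self, sex: str, age: str):
        prev = self.prevalence[
            (self.prevalence["sex"] == sex)
            & (self.prevalence["age_group"] == age)
            & (self.prevalence["year"] == self.outcome_year)
        ].set_index("country")
        countries = [c for c in self.balanced if c in prev.index]
        if not countries:
            raise EmptyInputError(
                f"no balanced country has {self.outcome_year} prevalence for {sex}:{age}"
            )
        obs16 = _covariate_frame(self.policies, self.reference_years[1], countries)
        obs08 = _covariate_frame(self.policies, self.reference_years[0], countries)
        return (
            countries,
            prev.loc[countries, "prevalence"].astype(float),
            prev.loc[countries, "population"].astype(float),
            obs16,
            obs08,
        )

    def run(
        self,
        scenarios: Sequence[Scenario] | None = None,
        n_draws: int = 1000,
        seed: int = 0,
        redistribute: bool = True,
    ) -> pd.DataFrame:
        """One row per stratum and scenario, Table-style.

        Columns: observed prevalence (%) and smokers (millions),
        counterfactual prevalence (%), relative % change in prevalence with
        95% UI, change in smokers (millions) with 95% UI, countries used.
        """
        scenarios = list(scenarios) if scenarios is not None else default_scenarios()
        point_counts: dict = {}
        draw_counts: dict = {}
        rows = []
        for (sex, age), res in self.results.items():
            countries, prev_obs, pop, obs16, obs08 = self._stratum_inputs(sex, age)
            draws = draw_coefficients(res, n_draws, seed)
            beta = res.slope_params()
            B = draws.slopes()  # n_draws x 4
            logit_obs = logit_clamped(prev_obs.to_numpy())
            obs_wprev, obs_smokers = aggregate_global(prev_obs, pop)
            wts = pop.to_numpy()
            for sc in scenarios:
                cf = pd.DataFrame(
                    [apply_scenario(obs16.loc[c], obs08.loc[c], sc) for c in countries],
                    index=countries,
                )
                D = (cf[list(COVAR_KEYS)].to_numpy()
                     - obs16[list(COVAR_KEYS)].to_numpy())
                cf_prev = expit(logit_obs + D @ beta)
                cf_wprev = float(np.average(cf_prev, weights=wts))
                cf_smokers = float(np.sum(cf_prev * wts))
                # draws: countries x n_draws
                cf_prev_d = expit(logit_obs[:, None] + D @ B.T)
                cf_smokers_d = wts @ cf_prev_d
                cf_wprev_d = cf_smokers_d / wts.sum()
                rel_d = 100.0 * (cf_wprev_d - obs_wprev) / obs_wprev
                rel_lo, rel_hi = summarize_ui(rel_d)
                point_counts[(sex, age, sc.name)] = (obs_smokers, cf_smokers)
                draw_counts[(sex, age, sc.name)] = cf_smokers_d
                rows.append({
                    "sex": sex, "age_group": age, "scenario": sc.name,
                    "n_countries": len(countries),
                    "observed_prev_pct": 100.0 * obs_wprev,
                    "observed_smokers_m": obs_smokers / 1e6,
                    "cf_prev_pct": 100.0 * cf_wprev,
                    "rel_change_pct": 100.0 * (cf_wprev - obs_wprev) / obs_wprev,
                    "rel_change_lo": rel_lo, "rel_change_hi": rel_hi,
                    "_cf_smokers": cf_smokers,
                })
        out = pd.DataFrame(rows)
        out = self._attach_smoker_changes(out, point_counts, draw_counts, redistribute)
        return out

    def _attach_smoker_changes(self, out, point_counts, draw_counts, redistribute):
        """Smoker-count changes, envelope-redistributed across age groups."""
        ages = [a for a in ("15-29", "30-49", "50plus") if (out["age_group"] == a).any()]
        changes, los, his = [], [], []
        for _, row in out.iterrows():
            sex, age, sc = row["sex"], row["age_group"], row["scenario"]
            obs_s, cf_s = point_counts[(sex, age, sc)]
            env_key = (sex, "15plus", sc)
            if redistribute and age != "15plus" and env_key in point_counts and ages:
                obs_env, cf_env = point_counts[env_key]
                obs_ages = {a: point_counts[(sex, a, sc)][0] for a in ages}
                cf_ages = {a: point_counts[(sex, a, sc)][1] for a in ages}
                obs_adj = redistribute_age_counts(obs_ages, obs_env)[age]
                cf_adj = redistribute_age_counts(cf_ages, cf_env)[age]
                change = cf_adj - obs_adj
                cf_age_d = np.vstack([draw_counts[(sex, a, sc)] for a in ages])
                env_d = draw_counts[env_key]
                idx = ages.index(age)
                cf_adj_d = cf_age_d[idx] * env_d / cf_age_d.sum(axis=0)
                lo, hi = summarize_ui(cf_adj_d - obs_adj)
            else:
                change = cf_s - obs_s
                lo, hi = summarize_ui(draw_counts[(sex, age, sc)] - obs_s)
            changes.append(change / 1e6)
            los.append(lo / 1e6)
            his.append(hi / 1e6)
        out = out.drop(columns="_cf_smokers")
        out["change_smokers_m"] = changes
        out["change_smokers_lo"] = los
        out["change_smokers_hi"] = his
        return out
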