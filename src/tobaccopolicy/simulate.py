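"""Synthetic country-year panels with the generative structure of the model.

The generator emulates the study's data layout: biennial policy waves
(achievement scores 2-5 for smoke-free/warning/advertising legislation, pack
price and per-capita GDP, both I$) and annual smoking prevalence one year
after each wave, drawn from the logit-scale linear mixed model

    logit(y_ct) = b0 + bp*P + bw*W + be*E + br*RIP + a_c + d_c*RIP + e_ct

with a country random intercept a_c, a country random slope d_c on RIP
(jointly normal, optionally correlated) and i.i.d. residual noise e_ct.
Ground-truth parameters are returned so downstream fits can be scored
against them.

Policy scores follow a capped step-up Markov chain: each score, per wave
transition, moves up one level with probability ``score_drift`` until it
reaches 5, mirroring the real-world strengthening of legislation over time.
Missingness is observational: the latent true score still drives prevalence,
but the recorded score is set to 1 ("no known data").
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import affordability
from .exceptions import ConfigurationError, GenerationError
from .panel import POLICY_COLUMNS, PREVALENCE_COLUMNS, SCORE_COLUMNS, expit

SEXES = ("male", "female", "both")
AGE_GROUPS = ("15-29", "30-49", "50plus", "15plus")
ALL_STRATA = tuple((s, a) for s in SEXES for a in AGE_GROUPS)

#: slope coefficients shared across strata by default (logit scale,
#: per score unit for P/W/E and per RIP percentage point)
DEFAULT_SLOPES = {"beta_p": -0.011, "beta_w": -0.021, "beta_e": -0.019, "beta_r": -0.009}

#: stratum intercepts anchored so typical prevalence sits near the observed
#: 2017 global levels (men ~37%, women ~7%, both in between; young lower,
#: middle-aged higher)
DEFAULT_INTERCEPTS = {
    ("male", "15plus"): -0.30, ("male", "15-29"): -0.63,
    ("male", "30-49"): -0.01, ("male", "50plus"): -0.31,
    ("female", "15plus"): -2.30, ("female", "15-29"): -2.51,
    ("female", "30-49"): -2.21, ("female", "50plus"): -2.23,
    ("both", "15plus"): -1.02, ("both", "15-29"): -1.30,
    ("both", "30-49"): -0.82, ("both", "50plus"): -1.02,
}

_BETA_KEYS = ("beta0", "beta_p", "beta_w", "beta_e", "beta_r")

#: share of the 15+ population in each modelled age band
_AGE_FRACTIONS = {"15-29": 0.35, "30-49": 0.37, "50plus": 0.28}


def _stratum_key(stratum) -> tuple[str, str]:
    if isinstance(stratum, str):
        sex, age = stratum.split(":")
        return sex, age
    return tuple(stratum)


@dataclass
class GeneratorConfig:
    """Settings for one synthetic panel.

    ``fixed_effects`` may be a single (b0, bp, bw, be, br) sequence applied
    to every stratum, or a mapping from stratum to such a sequence; by
    default slopes are shared and intercepts vary by stratum.
    """

    n_countries: int = 175
    policy_years: Sequence[int] = (2008, 2010, 2012, 2014, 2016)
    strata: Sequence[tuple[str, str]] = ALL_STRATA
    fixed_effects: Mapping | Sequence | None = None
    sd_intercept: float = 0.5
    sd_slope: float = 0.002
    re_correlation: float = 0.0
    sd_resid: float = 0.05
    score_drift: float = 0.3
    # log-scale (location, cross-country scale) for 2008 pack price and GDP
    price_params: tuple[float, float] = (math.log(3.1), 0.55)
    gdp_params: tuple[float, float] = (math.log(12000.0), 0.9)
    # per-wave drift on the log scale (prices rise faster than income)
    price_trend: float = 0.14
    gdp_trend: float = 0.04
    missing_rate: float = 0.06
    seed: int = 0

    def __post_init__(self):
        if not isinstance(self.n_countries, (int, np.integer)) or self.n_countries < 2:
            raise ConfigurationError("n_countries must be an integer >= 2")
        if len(self.policy_years) == 0:
            raise ConfigurationError("policy_years must be non-empty")
        if len(self.strata) == 0:
            raise ConfigurationError("strata must be non-empty")
        for name in ("sd_intercept", "sd_slope", "sd_resid"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("score_drift", "missing_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not -1.0 <= self.re_correlation <= 1.0:
            raise ConfigurationError("re_correlation must lie in [-1, 1]")
        self.strata = tuple(_stratum_key(s) for s in self.strata)

    def stratum_betas(self, stratum) -> dict[str, float]:
        """Resolve the five fixed effects for one stratum."""
        key = _stratum_key(stratum)
        fe = self.fixed_effects
        if fe is None:
            b0 = DEFAULT_INTERCEPTS.get(key, -1.0)
            return {"beta0": b0, **DEFAULT_SLOPES}
        if isinstance(fe, Mapping) and not set(fe.keys()) <= set(_BETA_KEYS):
            resolved = {_stratum_key(k): v for k, v in fe.items()}
            if key not in resolved:
                raise ConfigurationError(f"fixed_effects has no entry for stratum {key}")
            fe = resolved[key]
        if isinstance(fe, Mapping):
            missing = set(_BETA_KEYS) - set(fe.keys())
            if missing:
                raise ConfigurationError(f"fixed_effects missing keys {sorted(missing)}")
            return {k: float(fe[k]) for k in _BETA_KEYS}
        vals = list(fe)
        if len(vals) != 5:
            raise ConfigurationError("fixed_effects sequence must have 5 entries")
        return dict(zip(_BETA_KEYS, map(float, vals)))


@dataclass
class SyntheticTruth:
    """Realized ground-truth parameters of one generated panel."""

    fixed_effects: dict = field(default_factory=dict)  # "sex:age" -> {beta0..beta_r}
    alpha: dict = field(default_factory=dict)          # country -> random intercept
    delta: dict = field(default_factory=dict)          # country -> random RIP slope
    sd_intercept: float = 0.0
    sd_slope: float = 0.0
    re_correlation: float = 0.0
    sd_resid: float = 0.0
    seed: int = 0

    def betas(self, stratum) -> np.ndarray:
        sex, age = _stratum_key(stratum)
        fe = self.fixed_effects[f"{sex}:{age}"]
        return np.array([fe[k] for k in _BETA_KEYS])

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SyntheticTruth":
        import os

        if isinstance(source, os.PathLike) or (
            isinstance(source, (str, bytes)) and not str(source).lstrip().startswith("{")
        ):
            with open(source) as fh:
                data = json.load(fh)
        else:
            data = json.loads(source)
        return cls(**data)


def _country_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"C{i:0{width}d}" for i in range(n)]


def generate_policy_trajectories(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the policy table: scores, prices and GDP per country-wave.

    Returns the public columns plus latent ``p_true/w_true/e_true`` columns
    holding the pre-missingness scores that drive prevalence generation.
    """
    rng = np.random.default_rng([int(config.seed) % (2**31), 11])
    n, waves = config.n_countries, list(config.policy_years)
    countries = _country_names(n)

    # initial 2008-wave scores: most countries start weak
    init_levels, init_probs = np.array([2, 3, 4, 5]), np.array([0.45, 0.30, 0.15, 0.10])
    scores = {c: rng.choice(init_levels, size=3, p=init_probs).astype(int) for c in countries}

    price_off = rng.normal(0.0, config.price_params[1], size=n)
    gdp_off = rng.normal(0.0, config.gdp_params[1], size=n)

    rows = []
    for w, year in enumerate(waves):
        for i, c in enumerate(countries):
            if w > 0:
                step = rng.random(3) < config.score_drift
                scores[c] = np.minimum(scores[c] + step.astype(int), 5)
            true = scores[c].copy()
            observed = true.copy()
            if config.missing_rate > 0 and rng.random() < config.missing_rate:
                observed[rng.integers(0, 3)] = 1
            price = math.exp(
                config.price_params[0] + price_off[i]
                + config.price_trend * w + rng.normal(0.0, 0.05)
            )
            gdp = math.exp(
                config.gdp_params[0] + gdp_off[i]
                + config.gdp_trend * w + rng.normal(0.0, 0.02)
            )
            rows.append((c, year, *observed, price, gdp, *true))

    df = pd.DataFrame(rows, columns=[*POLICY_COLUMNS, "p_true", "w_true", "e_true"])
    return df.sort_values(["country", "year"], ignore_index=True)


def _population_table(config: GeneratorConfig, countries: list[str]) -> dict:
    """Deterministic stratum populations (persons aged 15+ and its age bands)."""
    rng = np.random.default_rng([int(config.seed) % (2**31), 13])
    total15 = np.exp(rng.normal(math.log(2.0e7), 1.5, size=len(countries)))
    pops = {}
    for c, t in zip(countries, total15):
        for age, frac in {**_AGE_FRACTIONS, "15plus": 1.0}.items():
            male = 0.5 * t * frac
            pops[(c, "male", age)] = male
            pops[(c, "female", age)] = male
            pops[(c, "both", age)] = 2 * male
    return pops


def generate_prevalence(
    policies: pd.DataFrame, config: GeneratorConfig
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw prevalence one year after each policy wave from the mixed model.

    Uses the latent true scores when present (``p_true`` columns), so
    observational score-1 missingness does not distort the outcome process.
    """
    if policies.empty:
        raise GenerationError("policies table is empty")
    rng = np.random.default_rng([int(config.seed) % (2**31), 17])
    countries = sorted(policies["country"].unique())
    n = len(countries)

    cov = np.array([
        [config.sd_intercept**2,
         config.re_correlation * config.sd_intercept * config.sd_slope],
        [config.re_correlation * config.sd_intercept * config.sd_slope,
         config.sd_slope**2],
    ])
    # svd factorization tolerates semidefinite covariances (zero variances)
    re = rng.multivariate_normal(np.zeros(2), cov, size=n, method="svd")
    alpha = dict(zip(countries, re[:, 0]))
    delta = dict(zip(countries, re[:, 1]))

    score_cols = (
        ["p_true", "w_true", "e_true"] if "p_true" in policies.columns else SCORE_COLUMNS
    )
    pol = policies.copy()
    pol["rip"] = affordability.compute_rip(pol["price"].to_numpy(), pol["gdp_pc"].to_numpy())
    pops = _population_table(config, countries)

    truth = SyntheticTruth(
        sd_intercept=config.sd_intercept, sd_slope=config.sd_slope,
        re_correlation=config.re_correlation, sd_resid=config.sd_resid,
        seed=int(config.seed),
        alpha={c: float(v) for c, v in alpha.items()},
        delta={c: float(v) for c, v in delta.items()},
    )

    rows = []
    for sex, age in config.strata:
        betas = config.stratum_betas((sex, age))
        truth.fixed_effects[f"{sex}:{age}"] = betas
        b = np.array([betas[k] for k in _BETA_KEYS])
        scores = pol[score_cols].to_numpy(dtype=float)
        rip = pol["rip"].to_numpy()
        a = pol["country"].map(alpha).to_numpy()
        d = pol["country"].map(delta).to_numpy()
        lp = (
            b[0] + scores @ b[1:4] + b[4] * rip + a + d * rip
            + rng.normal(0.0, config.sd_resid, size=len(pol))
        )
        if not np.all(np.isfinite(lp)):
            raise GenerationError("linear predictor produced non-finite values")
        prev = expit(lp)
        for (c, year), p in zip(pol[["country", "year"]].itertuples(index=False), prev):
            rows.append((c, int(year) + 1, sex, age, p, pops[(c, sex, age)]))

    df = pd.DataFrame(rows, columns=PREVALENCE_COLUMNS)
    df = df.sort_values(["sex", "age_group", "country", "year"], ignore_index=True)
    return df, truth


def generate_panel_data(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Convenience wrapper: policy table, prevalence table and ground truth."""
    policies = generate_policy_trajectories(config)
    prevalence, truth = generate_prevalence(policies, config)
    return policies, prevalence, truth
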