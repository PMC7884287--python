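"""Read input tables, apply missing-data rules, and build the model panel.

Two delimited-text schemas are consumed:

* policy table — one row per country and policy wave:
  ``country, year, p_score, w_score, e_score, price, gdp_pc``
  Scores are the WHO ordinal achievement grades 1-5 for smoke-free (P),
  warning (W) and advertising (E) legislation; a score of 1 means "no known
  or no recent data" and is treated as missing, not as a level.
* prevalence table — one row per country, year, sex and age group:
  ``country, year, sex, age_group, prevalence, population``
  Prevalence is age-standardized current smoking as a proportion in (0, 1).

The model-ready panel joins logit prevalence in year *t* to the policy
covariates of year *t − 1* (scores and RIP), dropping country-years with any
missing covariate (listwise deletion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.special

from . import affordability
from .exceptions import DomainError, SchemaError

logger = logging.getLogger(__name__)

POLICY_COLUMNS = ["country", "year", "p_score", "w_score", "e_score", "price", "gdp_pc"]
PREVALENCE_COLUMNS = ["country", "year", "sex", "age_group", "prevalence", "population"]
PANEL_COLUMNS = [
    "country", "outcome_year", "sex", "age_group",
    "prevalence", "population", "logit_prev",
    "p_lag", "w_lag", "e_lag", "rip_lag",
]

SCORE_COLUMNS = ["p_score", "w_score", "e_score"]

#: default clamping width for the logit transform
LOGIT_EPS = 1e-6


def logit_clamped(p, eps: float = LOGIT_EPS):
    """log(p / (1-p)) with p clamped into [eps, 1-eps] first.

    Raises DomainError for p outside [0, 1]; NaN propagates.
    """
    arr = np.asarray(p, dtype=float)
    finite = arr[~np.isnan(arr)]
    if np.any(finite < 0) or np.any(finite > 1):
        raise DomainError("prevalence must lie in [0, 1]")
    clamped = np.clip(arr, eps, 1.0 - eps)
    out = scipy.special.logit(clamped)
    return float(out) if out.ndim == 0 else out


def expit(x):
    """Inverse logit, 1 / (1 + exp(-x))."""
    out = scipy.special.expit(np.asarray(x, dtype=float))
    return float(out) if out.ndim == 0 else out


def _read_table(path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        logger.warning("%s: empty data section", path)
        return df[required]
    bad_rows = []
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = coerced.isna() & df[col].notna()
        if newly_bad.any():
            # +2: one for the header line, one for 1-based numbering
            bad_rows.extend((int(i) + 2, col) for i in df.index[newly_bad])
        df[col] = coerced
    if bad_rows:
        detail = ", ".join(f"line {ln} ({col})" for ln, col in bad_rows[:10])
        raise SchemaError(f"{path}: unparseable numeric values at {detail}")
    return df[required]


def _apply_aliases(df: pd.DataFrame, aliases) -> pd.DataFrame:
    if aliases:
        df = df.copy()
        df["country"] = df["country"].map(lambda c: aliases.get(c, c))
    return df


def read_policy_table(path, aliases=None) -> pd.DataFrame:
    """Read and validate a policy CSV; scores of 1 are retained as read.

    ``aliases`` optionally maps raw country labels onto canonical ones;
    otherwise identifiers are opaque strings matched exactly.
    """
    df = _read_table(path, POLICY_COLUMNS, ["year", *SCORE_COLUMNS, "price", "gdp_pc"])
    return _apply_aliases(df, aliases)


def read_prevalence_table(path, aliases=None) -> pd.DataFrame:
    """Read and validate a prevalence CSV (see read_policy_table on aliases)."""
    df = _read_table(path, PREVALENCE_COLUMNS, ["year", "prevalence", "population"])
    df = _apply_aliases(df, aliases)
    if not df.empty:
        bad = df[(df["prevalence"] <= 0) | (df["prevalence"] >= 1)]
        if not bad.empty:
            raise SchemaError(
                f"{path}: prevalence outside (0, 1) for {len(bad)} row(s), "
                f"first at line {int(bad.index[0]) + 2}"
            )
    return df


def write_table(df: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    """Write a CSV, optionally preceded by '#'-prefixed provenance lines."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def apply_missingness_rules(policies: pd.DataFrame) -> pd.DataFrame:
    """Convert achievement scores of 1 (no known data) to missing values."""
    out = policies.copy()
    for col in SCORE_COLUMNS:
        out[col] = out[col].where(out[col] != 1, np.nan)
    return out


@dataclass
class ExclusionLog:
    """Row accounting for the panel join, for n-style sample audits."""

    missing_covariate: int = 0
    no_policy_match: int = 0
    detail: dict = field(default_factory=dict)

    def total(self) -> int:
        return self.missing_covariate + self.no_policy_match


def lag_merge(
    policies: pd.DataFrame,
    prevalence: pd.DataFrame,
    eps: float = LOGIT_EPS,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Assemble the lagged, logit-transformed panel.

    One row per (country, sex, age_group, outcome year t) such that a policy
    record exists at t − 1 with P, W, E and RIP all non-missing and a
    prevalence record exists at t.  Score-1 missingness is applied here, so
    raw tables can be passed directly.

    Returns the panel and an ExclusionLog counting dropped rows.
    """
    if policies.empty or prevalence.empty:
        raise SchemaError("lag_merge requires non-empty policy and prevalence tables")
    pol = apply_missingness_rules(policies)
    if "rip" not in pol.columns:
        pol = affordability.add_rip(pol)

    log = ExclusionLog()
    covars = [*SCORE_COLUMNS, "rip"]
    complete = pol.dropna(subset=covars)
    log.missing_covariate = len(pol) - len(complete)
    log.detail["policy_rows_missing_covariate"] = log.missing_covariate

    lagged = complete[["country", "year", *covars]].copy()
    lagged["outcome_year"] = lagged["year"].astype(int) + 1
    lagged = lagged.rename(
        columns={"p_score": "p_lag", "w_score": "w_lag", "e_score": "e_lag", "rip": "rip_lag"}
    ).drop(columns="year")

    merged = prevalence.merge(
        lagged, left_on=["country", "year"], right_on=["country", "outcome_year"], how="inner"
    )
    # prevalence rows with no complete policy record the year before
    log.no_policy_match = len(prevalence) - len(merged)
    log.detail["prevalence_rows_without_lagged_policy"] = log.no_policy_match

    merged["logit_prev"] = logit_clamped(merged["prevalence"].to_numpy(), eps=eps)
    panel = merged[PANEL_COLUMNS].sort_values(
        ["sex", "age_group", "country", "outcome_year"], ignore_index=True
    )
    logger.info(
        "panel: %d rows (%d policy rows dropped for missing covariates, "
        "%d prevalence rows without a lagged policy match)",
        len(panel), log.missing_covariate, log.no_policy_match,
    )
    return panel, log


def select_stratum(panel: pd.DataFrame, sex: str, age_group: str) -> pd.DataFrame:
    """Subset a panel to one (sex, age_group) stratum."""
    out = panel[(panel["sex"] == sex) & (panel["age_group"] == age_group)]
    return out.reset_index(drop=True)
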