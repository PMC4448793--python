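"""Outcome-level statistics: binomial GLMs, Wald and likelihood-ratio tests,
and the exact binomial test.

These are the preliminary, per-participant analyses: the proportion choosing
the shortest route, P(shortest route), and the proportion changing their
mind mid-evacuation, P(change), are modelled with logit-link binomial GLMs
on the treatment flags (S, W, M), age and gender.  Single-parameter effects
are assessed with Wald z-tests; age-by-treatment interactions with
likelihood-ratio tests against the main-effects fit; and a single
condition's shortest-route count against chance with the two-sided exact
binomial test (minimum-likelihood method).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "OutcomeTable",
    "GLMFit",
    "FitFailure",
    "SeparationError",
    "fit_binomial_glm",
    "wald_single_parameter_test",
    "likelihood_ratio_test",
    "exact_binomial_test",
    "outcome_proportions",
    "glm_results_table",
    "DEFAULT_TERMS",
]

DEFAULT_TERMS = ("S", "W", "M", "age", "gender")
OUTCOMES = ("chose_shortest", "changed_mind")
#: absolute log-odds beyond which a coefficient is treated as diverging
SEPARATION_COEF_LIMIT = 15.0


class FitFailure(RuntimeError):
    """GLM fit did not converge."""


class SeparationError(FitFailure):
    """Perfect separation: a coefficient diverges and the MLE is not finite."""


@dataclass
class OutcomeTable:
    """One row per participant: condition flags, demographics, outcomes.

    ``frame`` columns: S, W, M (bool), age (years), gender (0/1),
    chose_shortest (bool), changed_mind (bool).  Conditions span the 8-cell
    factorial design; no missing outcomes.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"S", "W", "M", "age", "gender", *OUTCOMES}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"OutcomeTable missing columns: {sorted(missing)}")
        if self.frame[list(required)].isna().any().any():
            raise ValueError("OutcomeTable has missing values")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class GLMFit:
    """A converged binomial GLM fit on the log-odds scale."""

    outcome: str
    terms: tuple
    coefficients: pd.Series  # includes "const"
    standard_errors: pd.Series
    log_likelihood: float
    deviance: float
    converged: bool
    n_obs: int

    def z_value(self, term: str) -> float:
        return float(self.coefficients[term] / self.standard_errors[term])


def _design_matrix(table: OutcomeTable, terms) -> pd.DataFrame:
    """Design matrix with intercept; age is centred at the sample median,
    treatments and gender coded {0, 1} (reference: treatment absent,
    gender code 0)."""
    df = table.frame
    X = pd.DataFrame(index=df.index)
    for term in terms:
        if term == "age":
            X["age"] = df["age"] - df["age"].median()
        elif ":" in term:  # interaction, e.g. "age:M"
            a, b = term.split(":")
            a_col = df[a] - df[a].median() if a == "age" else df[a].astype(float)
            b_col = df[b] - df[b].median() if b == "age" else df[b].astype(float)
            X[term] = a_col * b_col
        else:
            X[term] = df[term].astype(float)
    return sm.add_constant(X, has_constant="add")


def fit_binomial_glm(
    table: OutcomeTable,
    outcome: str = "chose_shortest",
    terms=DEFAULT_TERMS,
) -> GLMFit:
    """Logit-link binomial GLM fit by iteratively reweighted least squares.

    Raises :class:`SeparationError` when the outcome is (quasi-)separable —
    including the degenerate constant-outcome case — and
    :class:`FitFailure` when IRLS does not converge.  Only converged fits
    are returned.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    y = table.frame[outcome].astype(float)
    X = _design_matrix(table, terms)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with np.errstate(all="ignore"):
        try:
            res = model.fit(maxiter=100)
        except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
            raise SeparationError(f"GLM fit failed for {outcome}: {exc}") from exc
    if not res.converged:
        raise FitFailure(f"IRLS did not converge for outcome {outcome}")
    if np.any(np.abs(res.params.to_numpy()) > SEPARATION_COEF_LIMIT) or not np.all(
        np.isfinite(res.bse.to_numpy())
    ):
        raise SeparationError(
            f"separation detected for outcome {outcome}: diverging coefficient"
        )
    return GLMFit(
        outcome=outcome,
        terms=tuple(terms),
        coefficients=res.params,
        standard_errors=res.bse,
        log_likelihood=float(res.llf),
        deviance=float(res.deviance),
        converged=bool(res.converged),
        n_obs=int(res.nobs),
    )


def wald_single_parameter_test(fit: GLMFit, term: str) -> float:
    """Two-sided normal-approximation p-value for one coefficient."""
    if term not in fit.coefficients.index:
        raise KeyError(f"term {term!r} not in fit {fit.terms}")
    z = fit.z_value(term)
    return float(2.0 * stats.norm.sf(abs(z)))


def likelihood_ratio_test(fit_full: GLMFit, fit_reduced: GLMFit):
    """LRT of nested GLM fits: (statistic, df, p-value).

    statistic = 2 (ll_full - ll_reduced); df = difference in term counts;
    p from the chi-square upper tail.
    """
    if fit_full.outcome != fit_reduced.outcome or fit_full.n_obs != fit_reduced.n_obs:
        raise ValueError("LRT requires the same outcome and data")
    if not set(fit_reduced.terms) < set(fit_full.terms):
        raise ValueError("reduced model's terms must be a strict subset of the full model's")
    statistic = 2.0 * (fit_full.log_likelihood - fit_reduced.log_likelihood)
    df = len(fit_full.terms) - len(fit_reduced.terms)
    p = float(stats.chi2.sf(statistic, df))
    return float(statistic), int(df), p


def exact_binomial_test(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value, minimum-likelihood method.

    Sums the probabilities of all outcomes whose point mass does not exceed
    that of the observed count ``k`` under Binomial(n, p0).
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly between 0 and 1")
    return float(stats.binomtest(k, n, p0).pvalue)


def outcome_proportions(table: OutcomeTable) -> pd.Series:
    """P(shortest route) and P(change) over the whole table."""
    return pd.Series(
        {
            "p_shortest_route": float(table.frame["chose_shortest"].mean()),
            "p_change": float(table.frame["changed_mind"].mean()),
        }
    )


def glm_results_table(table: OutcomeTable, terms=DEFAULT_TERMS) -> pd.DataFrame:
    """Tidy single-parameter test results for both outcomes.

    One row per (outcome, term): estimate, se, z, p, test_type — the shape
    of the headline treatment-effect table.
    """
    rows = []
    for outcome in OUTCOMES:
        fit = fit_binomial_glm(table, outcome=outcome, terms=terms)
        for term in terms:
            rows.append(
                {
                    "outcome": outcome,
                    "term": term,
                    "estimate": float(fit.coefficients[term]),
                    "se": float(fit.standard_errors[term]),
                    "z": fit.z_value(term),
                    "p": wald_single_parameter_test(fit, term),
                    "test_type": "wald_z",
                }
            )
    return pd.DataFrame(rows)


def age_interaction_lrts(table: OutcomeTable, outcome: str = "chose_shortest"):
    """Three separate age-by-treatment LRTs (age:M, age:S, age:W), each
    comparing main effects + one interaction against main effects only."""
    base = fit_binomial_glm(table, outcome=outcome, terms=DEFAULT_TERMS)
    out = {}
    for treatment in ("M", "S", "W"):
        extended = fit_binomial_glm(
            table, outcome=outcome, terms=DEFAULT_TERMS + (f"age:{treatment}",)
        )
        out[treatment] = likelihood_ratio_test(extended, base)
    return out
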