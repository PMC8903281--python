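"""Bayesian ANOVA model-comparison bookkeeping.

A Bayesian ANOVA compares a set of candidate linear models (null,
single-factor, additive, full with interaction) on one dependent variable.
Each model carries:

* ``P(M)`` — prior model probability (uniform by default),
* ``BF_10`` — Bayes factor versus the null model,
* ``P(M|data)`` — posterior model probability,
  ``P(M)·BF_10 / Σ P(M')·BF_10'``,
* ``BF_M`` — change from prior to posterior odds,
  ``[P(M|data)/(1−P(M|data))] / [P(M)/(1−P(M))]``.

The bookkeeping (posteriors, BF_M, evidence bands) is exact arithmetic and
works with externally supplied BF_10 values — including published tables.
Computing BF_10 from data uses the BIC approximation to the Bayes factor,
``BF_10 ≈ exp((BIC_null − BIC_1)/2)``, which corresponds to a unit-
information prior and will not numerically match Bayes factors computed
under other default priors; it preserves the ordering and order of magnitude
of the evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "BayesModelRow",
    "FitSummary",
    "bic",
    "bf10_from_fits",
    "posterior_model_probs",
    "bf_m",
    "classify_evidence",
    "bayes_anova",
    "comparison_frame",
    "EVIDENCE_BANDS",
]


@dataclass(frozen=True)
class BayesModelRow:
    """One candidate model in a comparison table."""

    model_terms: tuple[str, ...]  # empty tuple = null (intercept-only) model
    prior_prob: float
    bf10: float
    posterior_prob: float | None = None
    bf_m: float | None = None

    @property
    def name(self) -> str:
        return " + ".join(self.model_terms) if self.model_terms else "null"


@dataclass(frozen=True)
class FitSummary:
    """Minimal fitted-model summary needed for BIC Bayes factors."""

    model_terms: tuple[str, ...]
    loglik: float
    n_params: int
    n_obs: int


def bic(fit: FitSummary) -> float:
    return fit.n_params * np.log(fit.n_obs) - 2.0 * fit.loglik


def bf10_from_fits(fits: Sequence[FitSummary]) -> list[float]:
    """BIC-approximate Bayes factors of each model against the null.

    The candidate set must include the null (no-terms) model, whose BF_10 is
    1 by construction.
    """
    null = [f for f in fits if not f.model_terms]
    if not null:
        raise ValueError("candidate set must include the null model")
    bic_null = bic(null[0])
    return [float(np.exp((bic_null - bic(f)) / 2.0)) for f in fits]


def posterior_model_probs(rows: Sequence[BayesModelRow]) -> list[BayesModelRow]:
    """Fill in posterior model probabilities from priors and BF_10.

    ``P(M|data)_i = P(M)_i·BF_10,i / Σ_j P(M)_j·BF_10,j``.  Priors must sum
    to 1; BF_10 must be nonnegative with at least one positive numerator.
    """
    priors = np.array([r.prior_prob for r in rows], dtype=float)
    bfs = np.array([r.bf10 for r in rows], dtype=float)
    if abs(priors.sum() - 1.0) > 1e-9:
        raise ValueError(f"prior probabilities must sum to 1 (got {priors.sum()})")
    if np.any(bfs < 0):
        raise ValueError("BF_10 values must be >= 0")
    weights = priors * bfs
    total = weights.sum()
    if total <= 0:
        raise ValueError("all prior-weighted Bayes factors are zero")
    posts = weights / total
    out = []
    for r, post in zip(rows, posts):
        updated = replace(r, posterior_prob=float(post))
        updated = replace(updated, bf_m=_bf_m_safe(updated))
        out.append(updated)
    return out


def _bf_m_safe(row: BayesModelRow) -> float | None:
    try:
        return bf_m(row)
    except ValueError:
        return None


def bf_m(row: BayesModelRow) -> float:
    """Posterior odds over prior odds for one model against all others."""
    post, prior = row.posterior_prob, row.prior_prob
    if post is None:
        raise ValueError("posterior_prob not set; run posterior_model_probs first")
    if not 0.0 < post < 1.0 or not 0.0 < prior < 1.0:
        raise ValueError("BF_M undefined for degenerate prior/posterior (0 or 1)")
    return (post / (1.0 - post)) / (prior / (1.0 - prior))


#: (label, lower, upper) partition of BF_10 in (0, inf).  Boundary values fall
#: in the weaker-evidence band (e.g. exactly 3 counts as "insufficient").
EVIDENCE_BANDS = (
    ("strong_null", 0.0, 0.1),
    ("moderate_null", 0.1, 1.0 / 3.0),
    ("insufficient", 1.0 / 3.0, 3.0),
    ("moderate_alt", 3.0, 10.0),
    ("strong_alt", 10.0, np.inf),
)


def classify_evidence(bf10: float) -> str:
    """Qualitative evidence label for a BF_10 value.

    BF_10 below 0.1 is strong and below 1/3 moderate support for the null;
    above 3 moderate and above 10 strong support for the alternative; in
    between the data are insufficient to favor either.
    """
    if bf10 <= 0:
        raise ValueError("BF_10 must be positive")
    if bf10 < 0.1:
        return "strong_null"
    if bf10 < 1.0 / 3.0:
        return "moderate_null"
    if bf10 <= 3.0:
        return "insufficient"
    if bf10 <= 10.0:
        return "moderate_alt"
    return "strong_alt"


def _candidate_terms(factors: Sequence[str]) -> list[tuple[str, ...]]:
    if len(factors) == 1:
        return [(), (factors[0],)]
    if len(factors) == 2:
        a, b = factors
        return [(), (a,), (b,), (a, b), (a, b, f"{a}:{b}")]
    raise ValueError("bayes_anova supports 1 or 2 factors")


def bayes_anova(
    table: pd.DataFrame,
    dv: str,
    factors: Sequence[str],
    priors: Sequence[float] | None = None,
) -> list[BayesModelRow]:
    """BIC-approximate Bayesian ANOVA over the standard candidate set.

    For two factors the candidates are: null, each main effect alone, both
    main effects, and both plus their interaction — the layout of a JASP-style
    model-comparison table.  Uniform model priors by default.
    """
    data = table[[dv, *factors]].dropna()
    if data.empty:
        raise ValueError("no complete observations")
    candidates = _candidate_terms(factors)
    fits = []
    for terms in candidates:
        if terms:
            rhs = " + ".join(
                ":".join(f"C({part})" for part in t.split(":")) for t in terms
            )
        else:
            rhs = "1"
        fit = smf.ols(f"Q('{dv}') ~ {rhs}", data=data).fit()
        fits.append(
            FitSummary(terms, float(fit.llf), int(fit.df_model) + 2, int(fit.nobs))
        )
    bfs = bf10_from_fits(fits)
    if priors is None:
        priors = [1.0 / len(candidates)] * len(candidates)
    rows = [
        BayesModelRow(model_terms=t, prior_prob=pr, bf10=bf)
        for t, pr, bf in zip(candidates, priors, bfs)
    ]
    return posterior_model_probs(rows)


def comparison_frame(rows: Sequence[BayesModelRow]) -> pd.DataFrame:
    """Tidy table of a model comparison (one row per candidate model)."""
    return pd.DataFrame(
        {
            "model": [r.name for r in rows],
            "prior_prob": [r.prior_prob for r in rows],
            "posterior_prob": [r.posterior_prob for r in rows],
            "bf_m": [r.bf_m for r in rows],
            "bf10": [r.bf10 for r in rows],
            "evidence": [classify_evidence(r.bf10) if r.bf10 > 0 else "strong_null"
                         for r in rows],
        }
    )
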