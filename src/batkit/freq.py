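"""Group-level frequentist analyses for BAT scores.

The study design crosses participant group (young / older / Parkinson's) with
binary training history (0-2 vs 3+ years of music or dance training).  Cells
are unbalanced, so factorial ANOVAs use Type III sums of squares with
sum-to-zero factor coding; effect sizes are partial eta squared,
SS_effect / (SS_effect + SS_error).  Follow-ups are simple main effects
(one factor analyzed within each level of the other), Bonferroni-corrected
pairwise comparisons, Welch's unequal-variance t test, and ordinary
least-squares models of score on age.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "AnovaEffect",
    "InestimableEffectError",
    "categorize_training",
    "add_training_bins",
    "factorial_anova",
    "simple_main_effects",
    "bonferroni_pairwise",
    "welch_t",
    "welch_t_from_stats",
    "age_score_model",
]


@dataclass(frozen=True)
class AnovaEffect:
    """One line of an ANOVA table: F(df_num, df_den), p, partial eta squared."""

    name: str
    F: float
    df_num: int
    df_den: int
    p: float
    eta_p2: float


class InestimableEffectError(ValueError):
    """Raised when an empty design cell makes an effect inestimable."""


def categorize_training(years: float, cutoff: int = 3) -> str:
    """Bin years of training at ``cutoff``: below -> "0-{cutoff-1}", else "{cutoff}+".

    The standard cut is 3 (bins "0-2" / "3+"); a stricter dance-training cut
    of 6 ("0-5" / "6+") is supported the same way.
    """
    if years < 0:
        raise ValueError("training years must be >= 0")
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    return f"0-{cutoff - 1}" if years < cutoff else f"{cutoff}+"


def add_training_bins(
    table: pd.DataFrame,
    music_cutoff: int = 3,
    dance_cutoff: int = 3,
) -> pd.DataFrame:
    """Add ``music_bin`` / ``dance_bin`` columns derived from training years."""
    out = table.copy()
    if "music_years" in out:
        out["music_bin"] = [categorize_training(y, music_cutoff) for y in out["music_years"]]
    if "dance_years" in out:
        out["dance_bin"] = [categorize_training(y, dance_cutoff) for y in out["dance_years"]]
    return out


def _check_cells(table: pd.DataFrame, factors: Sequence[str]) -> None:
    for f in factors:
        if table[f].nunique() < 2:
            raise InestimableEffectError(f"factor {f!r} has fewer than 2 levels")
    if len(factors) > 1:
        counts = table.groupby(list(factors), observed=True).size()
        full = np.prod([table[f].nunique() for f in factors])
        if len(counts) < full:
            present = set(counts.index)
            levels = [table[f].unique() for f in factors]
            from itertools import product
            missing = [c for c in product(*levels) if c not in present]
            raise InestimableEffectError(
                f"empty design cell(s) {missing}: interaction inestimable"
            )


def factorial_anova(
    table: pd.DataFrame,
    dv: str,
    factors: Sequence[str],
    covariates: Sequence[str] = (),
) -> list[AnovaEffect]:
    """Full-factorial fixed-effects ANOVA (Type III SS, sum-to-zero coding).

    Rows missing the dependent variable, a factor, or a covariate are dropped
    listwise.  Continuous ``covariates`` enter additively (no interactions
    with factors), turning the model into an ANCOVA.  Returns one
    :class:`AnovaEffect` per main effect and interaction (covariates included,
    intercept and residual omitted).
    """
    cols = [dv, *factors, *covariates]
    data = table[cols].dropna()
    if data.empty:
        raise ValueError("no complete observations for this ANOVA")
    _check_cells(data, factors)
    terms = " * ".join(f"C({f}, Sum)" for f in factors)
    if covariates:
        terms += " + " + " + ".join(covariates)
    model = smf.ols(f"Q('{dv}') ~ {terms}", data=data).fit()
    if np.allclose(data[dv].var(ddof=0), 0.0):
        # constant dv: anova_lm divides 0/0; report zero effects directly
        df_den = int(model.df_resid)
        out = []
        for name, df_num in _term_dfs(model).items():
            out.append(AnovaEffect(name, 0.0, df_num, df_den, 1.0, 0.0))
        return out
    aov = anova_lm(model, typ=3)
    ss_resid = float(aov.loc["Residual", "sum_sq"])
    df_den = int(aov.loc["Residual", "df"])
    effects = []
    for row_name, row in aov.iterrows():
        if row_name in ("Intercept", "Residual"):
            continue
        ss = float(row["sum_sq"])
        effects.append(
            AnovaEffect(
                name=_clean_term(row_name),
                F=float(row["F"]),
                df_num=int(row["df"]),
                df_den=df_den,
                p=float(row["PR(>F)"]),
                eta_p2=ss / (ss + ss_resid),
            )
        )
    return effects


def _clean_term(term: str) -> str:
    """``C(group, Sum):C(music_bin, Sum)`` -> ``group:music_bin``."""
    return term.replace("C(", "").replace(", Sum)", "")


def _term_dfs(model) -> dict[str, int]:
    dfs: dict[str, int] = {}
    for term, cols in model.model.data.design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        dfs[_clean_term(term)] = cols.stop - cols.start
    return dfs


def simple_main_effects(
    table: pd.DataFrame,
    dv: str,
    within_factor: str,
    across_factor: str,
) -> dict[str, list[AnovaEffect]]:
    """One-way ANOVA of ``across_factor`` within each level of ``within_factor``.

    The standard follow-up to a significant interaction: e.g. the effect of
    music training tested separately within the young, older and Parkinson's
    groups, each on its own error term and degrees of freedom.
    """
    out: dict[str, list[AnovaEffect]] = {}
    for level, sub in table.groupby(within_factor, observed=True, sort=False):
        out[str(level)] = factorial_anova(sub, dv, [across_factor])
    return out


def bonferroni_pairwise(
    table: pd.DataFrame,
    dv: str,
    cells: str | Sequence[str],
) -> pd.DataFrame:
    """All pairwise cell-mean comparisons with Bonferroni-adjusted p values.

    ``cells`` names one column (or several, combined) whose levels define the
    groups.  Each pair is compared with a two-sample pooled-variance t test;
    ``p_adj = min(1, p * m)`` over the m comparisons.  Returns a tidy frame
    with one row per pair, adjusted p monotone in (and never below) raw p.
    """
    if isinstance(cells, str):
        labels = table[cells].astype(str)
    else:
        labels = table[list(cells)].astype(str).agg(" x ".join, axis=1)
    data = pd.DataFrame({"dv": table[dv], "cell": labels}).dropna()
    levels = list(dict.fromkeys(data["cell"]))
    if len(levels) < 2:
        raise ValueError("need at least 2 cells for pairwise comparisons")
    pairs = list(combinations(levels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        xa = data.loc[data["cell"] == a, "dv"].to_numpy()
        xb = data.loc[data["cell"] == b, "dv"].to_numpy()
        t, p = stats.ttest_ind(xa, xb, equal_var=True)
        rows.append(
            {
                "cell_a": a,
                "cell_b": b,
                "mean_diff": float(xa.mean() - xb.mean()),
                "t": float(t),
                "p_raw": float(p),
                "p_adj": float(min(1.0, p * m)),
            }
        )
    return pd.DataFrame(rows)


def welch_t(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t test: ``(t, df, p)``.

    Degrees of freedom by the Welch-Satterthwaite approximation; two-sided p.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def welch_t_from_stats(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> tuple[float, float, float]:
    """Welch's t from summary statistics (mean, SD, n) of each sample."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each sample needs n >= 2")
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=False
    )
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def age_score_model(table: pd.DataFrame, dv: str) -> dict[str, float]:
    """OLS of a score on age: slope, its p value, and R squared."""
    data = table[[dv, "age"]].dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 observations")
    if np.allclose(data["age"].var(ddof=0), 0.0):
        raise ValueError("age has no variance; slope is not identified")
    X = sm.add_constant(data["age"].to_numpy())
    fit = sm.OLS(data[dv].to_numpy(), X).fit()
    return {
        "slope": float(fit.params[1]),
        "p": float(fit.pvalues[1]),
        "r2": float(fit.rsquared),
        "n": int(len(data)),
    }
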