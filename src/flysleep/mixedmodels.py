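"""Random-intercept linear mixed models with LRT model comparison.

The model family is ``response ~ fixed factors + (1 | fly)`` fit by maximum
likelihood (ML rather than REML, so likelihood-ratio tests on fixed effects
are valid).  Nested models are compared by a chi-square LRT; the winning
model's fixed terms get Wald F tests with a residual degrees-of-freedom
approximation, and pairwise level contrasts are adjusted with the
studentized-range (Tukey) distribution.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf


@dataclass
class ModelFit:
    formula: str
    result: object                 # statsmodels MixedLMResults
    data: pd.DataFrame
    group_col: str
    log_likelihood: float
    n_params: int                  # fixed params + variance components
    fixed_effects: pd.Series
    random_intercept_var: float
    residual_var: float
    boundary: bool                 # random-effect variance at zero


@dataclass
class LRTResult:
    chi2: float
    delta_df: int
    p: float
    winner: str                    # 'null' | 'alt'


@dataclass
class PosthocTable:
    factor: str
    table: pd.DataFrame            # level_a, level_b, estimate, SE, p_adj


def _parse_dummies(name: str) -> list[tuple[str, str]]:
    """(factor, level) pairs from a patsy dummy name, robust to levels
    containing ':' (e.g. 'C(time_label)[T.-2:-1]')."""
    return re.findall(r"C\(([^)]+)\)\[T\.([^\]]*)\]", name)


def fit_random_intercept(table: pd.DataFrame, response: str,
                         fixed_factors: list[str] | None = None,
                         group: str = "fly_id",
                         interaction: bool = False) -> ModelFit:
    """ML fit of ``response ~ factors + (1 | group)``.

    ``fixed_factors`` empty/None gives the null (intercept-only) model;
    ``interaction=True`` adds the two-way interaction of two factors.
    """
    if table[group].nunique() < 2:
        raise ValueError("need at least 2 groups (flies)")
    fixed_factors = fixed_factors or []
    if interaction and len(fixed_factors) != 2:
        raise ValueError("interaction requires exactly two factors")
    terms = [f"C({f})" for f in fixed_factors]
    if interaction:
        terms.append(f"C({fixed_factors[0]}):C({fixed_factors[1]})")
    rhs = " + ".join(terms) if terms else "1"
    formula = f"{response} ~ {rhs}"
    model = smf.mixedlm(formula, table, groups=table[group])
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("singular fixed-effect design")
    res = None
    for method in (None, "powell", "cg"):
        try:
            kw = {} if method is None else {"method": method}
            cand = model.fit(reml=False, **kw)
            if np.isfinite(cand.llf):
                res = cand
                break
        except Exception:
            continue
    if res is None:
        raise RuntimeError("mixed-model fit failed to converge")
    re_var = float(res.cov_re.iloc[0, 0])
    boundary = re_var <= 1e-4 * (re_var + float(res.scale))
    k = res.k_fe + 2               # + random-intercept var + residual var
    return ModelFit(formula, res, table, group, float(res.llf), k,
                    res.fe_params, re_var, float(res.scale), boundary)


def compare_lrt(null_fit: ModelFit, alt_fit: ModelFit,
                alpha: float = 0.05) -> LRTResult:
    """Likelihood-ratio chi-square between nested ML fits on the same data."""
    if len(alt_fit.data) != len(null_fit.data):
        raise ValueError("fits must use the same data")
    dd = alt_fit.n_params - null_fit.n_params
    if dd < 1:
        raise ValueError("models are not nested (alt must add parameters)")
    chi2 = max(2.0 * (alt_fit.log_likelihood - null_fit.log_likelihood), 0.0)
    p = float(stats.chi2.sf(chi2, dd))
    winner = "alt" if (p < alpha
                       and alt_fit.log_likelihood > null_fit.log_likelihood) \
        else "null"
    return LRTResult(float(chi2), int(dd), p, winner)


def anova_main_effects(fit: ModelFit) -> pd.DataFrame:
    """Wald F test per fixed term (and interaction).

    Denominator df uses the residual approximation
    ``n_obs - n_fixed_params``.
    """
    res = fit.result
    names = list(res.fe_params.index)
    terms: dict[str, list[int]] = {}
    for i, nm in enumerate(names):
        if nm == "Intercept":
            continue
        # 'C(epoch)[T.x]:C(channel)[T.y]' -> term id 'epoch:channel'
        base = ":".join(f for f, _ in _parse_dummies(nm))
        terms.setdefault(base, []).append(i)
    if not terms:
        return pd.DataFrame(columns=["term", "F", "df_num", "df_den", "p"])
    cov = np.asarray(res.cov_params())[:len(names), :len(names)]
    beta = res.fe_params.to_numpy()
    df_den = len(fit.data) - len(names)
    rows = []
    for term, idx in terms.items():
        L = np.zeros((len(idx), len(names)))
        for r, i in enumerate(idx):
            L[r, i] = 1.0
        v = L @ beta
        V = L @ cov @ L.T
        w = float(v @ np.linalg.solve(V, v))
        F = w / len(idx)
        p = float(stats.f.sf(F, len(idx), df_den))
        rows.append((term, F, len(idx), df_den, p))
    return pd.DataFrame(rows, columns=["term", "F", "df_num", "df_den", "p"])


def posthoc_tukey(fit: ModelFit, factor: str) -> PosthocTable:
    """All pairwise level contrasts of ``factor`` with Tukey-adjusted p.

    Contrasts are differences of estimated marginal means (other factors
    averaged over their levels); p values come from the studentized-range
    distribution with k = number of levels and residual df.
    """
    res = fit.result
    names = list(res.fe_params.index)
    beta = res.fe_params.to_numpy()
    cov = np.asarray(res.cov_params())[:len(names), :len(names)]
    levels = sorted(fit.data[factor].astype(str).unique())
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 levels")
    k = len(levels)
    df_den = len(fit.data) - len(names)

    def level_vec(level: str) -> np.ndarray:
        """EMM contrast row for one level: its own dummies at 1, dummies of
        other factors averaged."""
        v = np.zeros(len(names))
        for i, nm in enumerate(names):
            if nm == "Intercept":
                v[i] = 1.0
                continue
            weight = 1.0
            for fac, lev in _parse_dummies(nm):
                if fac == factor:
                    weight *= 1.0 if lev == level else 0.0
                else:
                    n_lev = fit.data[fac].astype(str).nunique()
                    weight *= 1.0 / n_lev
            v[i] = weight
        return v

    rows = []
    for a, b in itertools.combinations(levels, 2):
        c = level_vec(a) - level_vec(b)
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        q = abs(est) / se * np.sqrt(2.0)
        p_adj = float(stats.studentized_range.sf(q, k, df_den))
        rows.append((a, b, est, se, min(p_adj, 1.0)))
    return PosthocTable(factor, pd.DataFrame(
        rows, columns=["level_a", "level_b", "estimate", "SE", "p_adj"]))


def model_family_comparison(table: pd.DataFrame, response: str,
                            factors: list[str],
                            group: str = "fly_id") -> dict:
    """The null/factor/interaction model-family harness.

    Fits the null model, each single-factor model, and (for two factors)
    the two-factor-with-interaction model; each alternative is LRT-tested
    against the null and the winner is the highest-log-likelihood model
    whose LRT beats the null (ties -> the simpler model).
    """
    fits = {"null": fit_random_intercept(table, response, [], group)}
    for f in factors:
        fits[f] = fit_random_intercept(table, response, [f], group)
    if len(factors) == 2:
        fits["_".join(factors)] = fit_random_intercept(
            table, response, factors, group, interaction=True)
    lrts = {name: compare_lrt(fits["null"], fit)
            for name, fit in fits.items() if name != "null"}
    winner = "null"
    best_ll = fits["null"].log_likelihood
    for name, fit in fits.items():
        if name == "null":
            continue
        if lrts[name].winner == "alt" and fit.log_likelihood > best_ll:
            winner, best_ll = name, fit.log_likelihood
    return {"fits": fits, "lrts": lrts, "winner": winner}
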