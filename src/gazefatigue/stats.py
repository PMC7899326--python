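"""Manipulation checks and association analyses.

Pearson correlations with Fisher-z confidence intervals, the exact
Wilcoxon signed-rank test (the paired test whose statistic V is the sum of
positive-difference ranks), and linear mixed-model effect summaries with
likelihood-ratio chi-square tests, Nakagawa-Schielzeth semi-partial R2 and
Bonferroni correction over the per-feature family of fixed effects.

The signed-rank null distribution is computed natively by subset-sum
dynamic programming over the (tie-averaged) ranks, which stays exact in
the presence of tied absolute differences; a normal approximation with
tie-corrected variance takes over for n > 25.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    r: float
    ci95: tuple[float, float]
    p: float
    n: int


@dataclass(frozen=True)
class WilcoxonResult:
    v: float
    p: float
    n: int  # non-zero differences used
    method: str  # "exact" | "approx"


@dataclass(frozen=True)
class EffectEstimate:
    term: str
    beta: float
    se: float
    chi2: float
    eta_sq: float
    p: float
    p_adj: float
    converged: bool = True
    random_slopes: bool = False


# ---------------------------------------------------------------------------


def pearson_with_ci(
    x, y, feature: str = "", conf: float = 0.95
) -> CorrelationResult:
    """Pearson r with Fisher-z CI and a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need >= 4 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    zcrit = sps.norm.ppf(0.5 + conf / 2)
    if abs(r) < 1.0:
        z = np.arctanh(r)
        hw = zcrit / np.sqrt(n - 3)
        ci = (float(np.tanh(z - hw)), float(np.tanh(z + hw)))
        tstat = r * np.sqrt((n - 2) / (1 - r**2))
        p = float(2 * sps.t.sf(abs(tstat), n - 2))
    else:
        ci = (r, r)
        p = 0.0
    return CorrelationResult(feature=feature, r=r, ci95=ci, p=p, n=n)


# ---------------------------------------------------------------------------


def _signed_rank_exact_p(v2: int, ranks2: np.ndarray) -> float:
    """Two-sided exact p for doubled statistic v2 given doubled ranks.

    Subset-sum DP: the null assigns each rank a +/- sign with probability
    one half; counts[s] is the number of sign patterns whose positive-rank
    (doubled) sum equals s.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        counts[r:] = counts[r:] + counts[:-r] if r else counts[r:] * 2
    counts /= counts.sum()
    cdf = float(counts[: v2 + 1].sum())
    sf = float(counts[v2:].sum())
    return min(1.0, 2.0 * min(cdf, sf))


def wilcoxon_signed_rank(deltas) -> WilcoxonResult:
    """Paired signed-rank test; V = sum of ranks of positive differences.

    Zero differences are dropped (Wilcoxon convention).  Exact two-sided p
    (tie-safe) for n <= 25; tie-corrected normal approximation with
    continuity correction otherwise.
    """
    d = np.asarray(deltas, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero: no information")
    ranks = sps.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    if n <= 25:
        ranks2 = np.round(2 * ranks).astype(int)
        p = _signed_rank_exact_p(int(round(2 * v)), ranks2)
        return WilcoxonResult(v=v, p=p, n=n, method="exact")
    mu = n * (n + 1) / 4.0
    sigma = np.sqrt(np.sum(ranks**2) / 4.0)  # tie-corrected
    z = (v - mu - 0.5 * np.sign(v - mu)) / sigma
    p = float(2 * sps.norm.sf(abs(z)))
    return WilcoxonResult(v=v, p=min(p, 1.0), n=n, method="approx")


def fatigue_level_tests(day_reports: pd.DataFrame) -> dict[str, WilcoxonResult]:
    """Signed-rank tests of the three fatigue-level contrasts.

    ``day_reports`` carries one row per participant-day with columns
    ``fatigue_initial``, ``fatigue_intermediate``, ``fatigue_terminal``.
    """
    out = {}
    pairs = {
        "intermediate_vs_initial": ("fatigue_intermediate", "fatigue_initial"),
        "terminal_vs_intermediate": ("fatigue_terminal", "fatigue_intermediate"),
        "terminal_vs_initial": ("fatigue_terminal", "fatigue_initial"),
    }
    for name, (a, b) in pairs.items():
        out[name] = wilcoxon_signed_rank(
            day_reports[a].to_numpy() - day_reports[b].to_numpy()
        )
    return out


# ---------------------------------------------------------------------------


def _marginal_r2(result) -> float:
    """Nakagawa-Schielzeth marginal R2 of a fitted MixedLM."""
    fe = np.asarray(result.model.exog) @ np.asarray(result.fe_params)
    var_f = float(np.var(fe))
    cov_re = np.atleast_2d(np.asarray(result.cov_re))
    exog_re = result.model.exog_re
    if exog_re is None:
        var_r = float(cov_re[0, 0]) if cov_re.size else 0.0
    else:
        zr = np.asarray(exog_re)
        var_r = float(np.mean(np.einsum("ij,jk,ik->i", zr, cov_re, zr)))
    var_e = float(result.scale)
    denom = var_f + var_r + var_e
    return var_f / denom if denom > 0 else 0.0


def _fit_mixedlm(data, formula, group_col, re_formula=None, reml=False):
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            formula, data, groups=data[group_col], re_formula=re_formula
        )
        last_err = None
        for method in (None, "powell", "nm"):
            try:
                kwargs = {"method": method} if method else {}
                return model.fit(reml=reml, maxiter=200, **kwargs)
            except (np.linalg.LinAlgError, ValueError) as err:
                last_err = err
        raise last_err


def mixed_model_effects(
    table: pd.DataFrame,
    feature: str,
    fixed_effects: tuple[str, ...] = ("perceived_effort", "trial", "day", "language"),
    group_col: str = "participant",
    random_slope_for: str = "perceived_effort",
    alpha: float = 0.05,
) -> list[EffectEstimate]:
    """Mixed-model main effects of the fixed terms on one feature.

    Random intercepts per participant always; a random slope for the
    perceived-effort term is added when a likelihood-ratio test at
    ``alpha`` favours it and the fit converges.  For each fixed effect:
    beta and SE from a REML refit of the chosen structure (lmerTest-style;
    ML variance components understate SEs), chi-square and p from the
    likelihood-ratio test against the fit without that term, semi-partial
    R2 as the drop in Nakagawa-Schielzeth marginal R2, and Bonferroni
    adjustment over the feature's family of fixed-effect tests.
    """
    terms = [
        f"C({t})" if table[t].dtype == object else t for t in fixed_effects
    ]
    data = table.dropna(subset=[feature, group_col, *fixed_effects]).copy()
    formula = f"{feature} ~ " + " + ".join(terms)

    full = _fit_mixedlm(data, formula, group_col)
    use_slopes = False
    if random_slope_for in fixed_effects:
        try:
            slope_fit = _fit_mixedlm(
                data, formula, group_col, re_formula=f"~{random_slope_for}"
            )
            if slope_fit.converged:
                lr = 2 * (slope_fit.llf - full.llf)
                # 2 extra variance parameters (slope var + covariance)
                if lr > 0 and sps.chi2.sf(lr, 2) < alpha:
                    full = slope_fit
                    use_slopes = True
        except Exception:
            pass
    converged = bool(getattr(full, "converged", True))
    r2_full = _marginal_r2(full)
    # coefficients and SEs are reported from a REML refit of the chosen
    # structure (ML variance components are biased low with few groups,
    # shrinking the SEs); ML fits are kept for the likelihood-ratio tests
    try:
        report = _fit_mixedlm(
            data, formula, group_col,
            re_formula=f"~{random_slope_for}" if use_slopes else None,
            reml=True,
        )
    except Exception:
        report = full

    out: list[EffectEstimate] = []
    n_tests = len(fixed_effects)
    for raw, term in zip(fixed_effects, terms):
        reduced_terms = [t for t in terms if t != term] or ["1"]
        red_formula = f"{feature} ~ " + " + ".join(reduced_terms)
        re_f = (
            f"~{random_slope_for}"
            if use_slopes and raw != random_slope_for
            else None
        )
        try:
            red = _fit_mixedlm(data, red_formula, group_col, re_formula=re_f)
            chi2 = max(2 * (full.llf - red.llf), 0.0)
            df = 1 if not term.startswith("C(") else max(
                data[raw].nunique() - 1, 1
            )
            p = float(sps.chi2.sf(chi2, df))
            eta = float(np.clip(r2_full - _marginal_r2(red), 0.0, 1.0))
        except Exception:
            chi2, p, eta = np.nan, np.nan, np.nan
        # beta/SE from the REML fit (first matching parameter for factors)
        beta = se = np.nan
        for pname in report.fe_params.index:
            if pname == term or pname.startswith(f"{term}["):
                beta = float(report.fe_params[pname])
                se = float(report.bse[pname])
                break
        out.append(
            EffectEstimate(
                term=raw,
                beta=beta,
                se=se,
                chi2=chi2,
                eta_sq=eta,
                p=p,
                p_adj=float(min(p * n_tests, 1.0)) if np.isfinite(p) else np.nan,
                converged=converged,
                random_slopes=use_slopes,
            )
        )
    return out


def effects_table(estimates: list[EffectEstimate]) -> pd.DataFrame:
    """Tidy frame of mixed-model effects (term, beta, SE, chi2, eta2, p)."""
    return pd.DataFrame(
        [
            {
                "term": e.term,
                "beta": e.beta,
                "se": e.se,
                "chi2": e.chi2,
                "eta_sq": e.eta_sq,
                "p": e.p,
                "p_adj": e.p_adj,
                "random_slopes": e.random_slopes,
            }
            for e in estimates
        ]
    )
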