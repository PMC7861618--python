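"""Statistical procedures over tidy trial/session tables.

The central tool is the linear mixed-effects model: response (a session
mean or normalized score) against fixed effects of laser, session number,
group and their interactions, with random intercepts per rat and optionally
per-rat laser or session slopes.  Normalized count/rate responses take the
inverse hyperbolic sine first (asinh is defined at zero, unlike log).
Companion nonparametric procedures: per-trial Wilcoxon rank-sum between
groups at a raw p < 0.01 cutoff (no multiplicity correction), Kruskal-
Wallis across groups, paired t-tests within extent bins, and sign tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import TestResult

__all__ = [
    "LmmSpec", "LmmFit", "asinh_transform", "fit_lmm", "contrast_test",
    "trialwise_ranksum", "kruskal_wallis", "paired_t", "paired_t_by_bin",
    "sign_test",
]


def asinh_transform(values: np.ndarray | pd.Series) -> np.ndarray:
    """Elementwise inverse hyperbolic sine, asinh(x) = ln(x + sqrt(x^2+1)).

    Used before mixed-model fits on normalized scores to accommodate exact
    zeroes (asinh(0) = 0) while compressing large values like a log.
    """
    return np.arcsinh(np.asarray(values, dtype=float))


@dataclass
class LmmSpec:
    """Specification of one linear mixed-effects analysis.

    ``fixed`` is a patsy right-hand side over columns of the input table
    (e.g. ``"laser * session"``); ``groups`` names the random-grouping
    column (the rat); ``re_formula`` specifies the random structure
    (``"1"`` for random intercepts, ``"1 + laser"`` for per-rat laser
    slopes, ...).  ``transform='asinh'`` applies the inverse hyperbolic
    sine to the response before fitting.
    """

    response: str
    fixed: str
    groups: str = "rat"
    re_formula: str = "1"
    transform: str = "none"

    def __post_init__(self) -> None:
        if self.transform not in ("none", "asinh"):
            raise ValueError("transform must be 'none' or 'asinh'")

    def validate(self, table: pd.DataFrame) -> None:
        if self.response not in table.columns:
            raise ValueError(f"response column {self.response!r} not in table")
        if self.groups not in table.columns:
            raise ValueError(f"grouping column {self.groups!r} not in table")


@dataclass
class LmmFit:
    """Fixed-effect estimates and inference from a mixed-model fit.

    ``df`` is the residual degrees of freedom (observations minus fixed-
    effect rank), the fallback when no Satterthwaite approximation is
    available; p-values use the t distribution on that df.  ``singular``
    flags a (near-)singular random-effects covariance — fixed effects are
    still returned.
    """

    terms: list[str]
    estimates: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    df: float
    pvalues: np.ndarray
    cov: np.ndarray
    singular: bool
    converged: bool
    spec: LmmSpec

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms, "estimate": self.estimates, "se": self.se,
            "df": self.df, "stat": self.tvalues, "p": self.pvalues,
        })

    def __getitem__(self, term: str) -> dict[str, float]:
        i = self.terms.index(term)
        return {"estimate": self.estimates[i], "se": self.se[i],
                "t": self.tvalues[i], "df": self.df, "p": self.pvalues[i]}

    def conf_int(self, term: str, level: float = 0.95) -> tuple[float, float]:
        i = self.terms.index(term)
        half = sps.t.ppf(0.5 + level / 2.0, self.df) * self.se[i]
        return (self.estimates[i] - half, self.estimates[i] + half)


def fit_lmm(table: pd.DataFrame, spec: LmmSpec) -> LmmFit:
    """REML fit of a linear mixed-effects model.

    Requires at least two rats and two sessions' worth of data.  A
    singular random-effects fit is flagged, not fatal.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    spec.validate(table)
    data = table.copy()
    if data[spec.groups].nunique() < 2:
        raise ValueError("need >= 2 grouping units (rats)")
    if spec.transform == "asinh":
        data[spec.response] = asinh_transform(data[spec.response])
    data = data.dropna(subset=[spec.response])

    formula = f"{spec.response} ~ {spec.fixed}"
    model = smf.mixedlm(formula, data, groups=data[spec.groups],
                        re_formula=spec.re_formula)
    k_fe = model.k_fe
    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.simplefilter("ignore")
        res = cov = None
        # near-singular random effects can leave the default optimizer with
        # an indefinite Hessian; fall through progressively sturdier fits
        for kwargs in ({"reml": True, "method": ["lbfgs", "powell"]},
                       {"reml": True, "method": "powell"},
                       {"reml": False, "method": ["lbfgs", "powell"]}):
            try:
                cand = model.fit(**kwargs)
            except (np.linalg.LinAlgError, ValueError):
                continue
            ccov = np.asarray(cand.cov_params().iloc[:k_fe, :k_fe], dtype=float)
            if res is None:
                res, cov = cand, ccov
            if np.isfinite(np.diag(ccov)).all() and (np.diag(ccov) > 0).all():
                res, cov = cand, ccov
                break
        if res is None:
            raise np.linalg.LinAlgError("mixed-model fit failed")

    terms = list(model.exog_names)
    est = np.asarray(res.params[:k_fe], dtype=float)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        tvals = est / se
    df = float(res.nobs - np.linalg.matrix_rank(model.exog))
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df)
    cov_re = np.atleast_2d(np.asarray(res.cov_re, dtype=float))
    try:
        singular = bool(np.linalg.cond(cov_re) > 1e8 or np.any(np.diag(cov_re) <= 1e-10))
    except np.linalg.LinAlgError:
        singular = True
    return LmmFit(terms=terms, estimates=est, se=se, tvalues=tvals, df=df,
                  pvalues=pvals, cov=cov, singular=singular,
                  converged=bool(res.converged), spec=spec)


def contrast_test(fit: LmmFit, contrast: np.ndarray | dict[str, float]) -> TestResult:
    """Test a linear contrast c'beta of the fixed effects.

    ``contrast`` is a vector over ``fit.terms`` or a mapping from term
    names to weights (unnamed terms get 0).  A unit vector reproduces the
    corresponding coefficient's t test; the zero vector gives estimate 0
    and p = 1 by convention.
    """
    if isinstance(contrast, dict):
        unknown = set(contrast) - set(fit.terms)
        if unknown:
            raise ValueError(f"contrast names unfitted terms: {sorted(unknown)}")
        c = np.array([contrast.get(t, 0.0) for t in fit.terms])
    else:
        c = np.asarray(contrast, dtype=float)
        if c.shape != (len(fit.terms),):
            raise ValueError(f"contrast length {c.shape} != {len(fit.terms)} fixed effects")
    est = float(c @ fit.estimates)
    var = float(c @ fit.cov @ c)
    if var <= 0:
        return TestResult(statistic=0.0, p_value=1.0, df=fit.df,
                          estimate=est, se=0.0, name="contrast")
    se = np.sqrt(var)
    t = est / se
    p = float(2.0 * sps.t.sf(abs(t), fit.df))
    return TestResult(statistic=float(t), p_value=p, df=fit.df,
                      estimate=est, se=float(se), name="contrast")


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact for small tie-free samples."""
    if len(np.unique(np.concatenate([a, b]))) == len(a) + len(b) \
            and max(len(a), len(b)) <= 25:
        method = "exact"
    else:
        method = "asymptotic"
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def trialwise_ranksum(group_a: np.ndarray, group_b: np.ndarray,
                      alpha: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial two-sample rank-sum comparison between groups.

    ``group_a``/``group_b`` are ``(n_rats, n_trials)`` carry-forward-
    aligned series.  Returns ``(significant_mask, p_values)`` where the
    mask is ``p < alpha`` with no multiplicity correction (a raw cutoff by
    design).  Trials with fewer than two finite values in either group are
    never significant (p = NaN).
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must be aligned to the same trial axis")
    n_trials = a.shape[1]
    pvals = np.full(n_trials, np.nan)
    for t in range(n_trials):
        av = a[:, t][np.isfinite(a[:, t])]
        bv = b[:, t][np.isfinite(b[:, t])]
        if len(av) < 2 or len(bv) < 2:
            continue
        if np.ptp(np.concatenate([av, bv])) == 0:
            pvals[t] = 1.0
            continue
        pvals[t] = _ranksum_p(av, bv)
    mask = np.where(np.isfinite(pvals), pvals < alpha, False)
    return mask, pvals


def kruskal_wallis(groups: list[np.ndarray]) -> TestResult:
    """Kruskal-Wallis H test across independent groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0:
        return TestResult(statistic=0.0, p_value=1.0,
                          df=float(len(arrays) - 1), name="kruskal-wallis")
    h, p = sps.kruskal(*arrays)
    return TestResult(statistic=float(h), p_value=float(p),
                      df=float(len(arrays) - 1), name="kruskal-wallis")


def paired_t(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-sided paired t test on matched samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must match in shape")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        raise ValueError("need >= 2 complete pairs")
    t, p = sps.ttest_rel(a[ok], b[ok])
    diff = a[ok] - b[ok]
    n = int(ok.sum())
    return TestResult(statistic=float(t), p_value=float(p), df=float(n - 1),
                      estimate=float(diff.mean()),
                      se=float(diff.std(ddof=1) / np.sqrt(n)), name="paired-t")


def paired_t_by_bin(a_by_bin: dict, b_by_bin: dict) -> dict[object, TestResult]:
    """Paired t tests within each extent bin present in both conditions.

    Used to compare grasp measures between stimulation conditions at each
    final reach extent; bins missing from either condition, or with fewer
    than two complete pairs, are skipped.
    """
    out: dict[object, TestResult] = {}
    for key in sorted(set(a_by_bin) & set(b_by_bin)):
        try:
            out[key] = paired_t(np.asarray(a_by_bin[key]), np.asarray(b_by_bin[key]))
        except ValueError:
            continue
    return out


def sign_test(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Exact two-sided sign test on paired differences (ties dropped).

    All-tied differences leave the test undefined (error).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must match in shape")
    diff = (a - b)[np.isfinite(a - b)]
    nonzero = diff[diff != 0]
    if len(nonzero) == 0:
        raise ValueError("all paired differences are tied; sign test undefined")
    n_pos = int((nonzero > 0).sum())
    res = sps.binomtest(n_pos, len(nonzero), 0.5)
    return TestResult(statistic=float(n_pos), p_value=float(res.pvalue),
                      df=float(len(nonzero)), name="sign")
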