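"""Statistical models linking load metrics and heterozygosity to fitness.

Implements the study's model battery: ordinary least squares for lifetime
reproductive success (square-root transformed), longevity (log transformed)
and mean litter size; binomial GLMs for first-year (juvenile) survival;
linear mixed models with rodent-cycle phase (and sex) as fixed effects and
natal den as a random intercept for the ancestry contrasts; Mann-Whitney
U tests for group comparisons of allele-load proportions; Pearson
correlations with Fisher-z intervals; and unadjusted contrasts of printed
group means. A Box-Cox adviser reports the transform the likelihood
supports, but the response transforms used by ``fit_trait_lm`` are frozen to
the study's choices.

No multiple-testing adjustment is applied across the model battery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

__all__ = [
    "ModelResult",
    "BoxCoxAdvice",
    "MannWhitneyResult",
    "CorrelationResult",
    "SeparationError",
    "boxcox_advise",
    "fit_trait_lm",
    "fit_juvenile_survival_glm",
    "fit_ancestry_lmm",
    "mann_whitney_groups",
    "correlate",
    "group_mean_contrast",
    "contrast",
    "pool_ancestry",
    "RESPONSE_TRANSFORMS",
]

# response name -> (underlying column, transform callable, label)
RESPONSE_TRANSFORMS = {
    "lrs_sqrt": ("lrs", np.sqrt, "sqrt"),
    "longevity_log": ("longevity_years", np.log, "log"),
    "litter_size": ("mean_litter_size", lambda x: x, "identity"),
}


class SeparationError(RuntimeError):
    """Perfect separation in a logistic fit; a penalised fit is advised."""


@dataclass
class ModelResult:
    """Inference summary for one fitted model."""

    family: str                  # "ols" | "binomial_glm" | "lmm"
    response: str
    transform: str
    terms: list[str]
    estimates: np.ndarray
    std_errors: np.ndarray
    statistics: np.ndarray       # t (ols/lmm) or z (glm)
    pvalues: np.ndarray
    conf_int: np.ndarray         # (k, 2)
    n: int
    r_squared: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.conf_int[:, 0], self.conf_int[:, 1]
        finite = np.isfinite(lo) & np.isfinite(hi) & np.isfinite(self.estimates)
        ok = (lo[finite] <= self.estimates[finite] + 1e-9) & (
            self.estimates[finite] <= hi[finite] + 1e-9)
        if not np.all(ok):
            raise ValueError("confidence bounds must bracket estimates")

    def term(self, name: str) -> dict:
        """Inference for a single term as a plain dict."""
        i = self.terms.index(name)
        return {
            "estimate": float(self.estimates[i]),
            "se": float(self.std_errors[i]),
            "statistic": float(self.statistics[i]),
            "p": float(self.pvalues[i]),
            "ci": [float(self.conf_int[i, 0]), float(self.conf_int[i, 1])],
        }

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "response": self.response,
            "transform": self.transform,
            "n": self.n,
            "r_squared": self.r_squared,
            "terms": {t: self.term(t) for t in self.terms},
            **({"extra": self.extra} if self.extra else {}),
        }


@dataclass
class BoxCoxAdvice:
    lmbda: float
    transform: str  # "log" | "sqrt" | "identity"
    note: str = ""


def boxcox_advise(values: Sequence[float]) -> BoxCoxAdvice:
    """Advise a response transform from the Box-Cox profile likelihood.

    The profile log-likelihood is maximised on a grid lambda in [-2, 2] with
    step 0.01; |lambda| <= 0.25 maps to log, lambda in (0.25, 0.75] to sqrt,
    anything else to identity. Requires strictly positive data.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1-d sample of at least 3 values")
    if np.any(x <= 0):
        bad = int(np.argmax(x <= 0))
        raise ValueError(f"Box-Cox requires positive values; offending index {bad} "
                         f"(value {x[bad]!r})")
    if np.ptp(x) == 0:
        warnings.warn("constant data: Box-Cox likelihood is flat; "
                      "returning identity", stacklevel=2)
        return BoxCoxAdvice(lmbda=1.0, transform="identity", note="degenerate data")
    grid = np.arange(-2.0, 2.0 + 1e-9, 0.01)
    llf = np.array([sps.boxcox_llf(l, x) for l in grid])
    lam = float(grid[int(np.argmax(llf))])
    if abs(lam) <= 0.25:
        tr = "log"
    elif 0.25 < lam <= 0.75:
        tr = "sqrt"
    else:
        tr = "identity"
    return BoxCoxAdvice(lmbda=lam, transform=tr)


def _design(records: pd.DataFrame, predictors: Sequence[str],
            covariates: Sequence[str]) -> tuple[pd.DataFrame, list[str]]:
    """Build a design matrix with intercept, numeric predictors and
    treatment-coded categorical covariates."""
    cols = {}
    for p in predictors:
        cols[p] = pd.to_numeric(records[p])
    for c in covariates:
        series = records[c]
        if series.dtype.kind in "ifu" and series.nunique() > 2:
            cols[c] = pd.to_numeric(series)
        else:
            dummies = pd.get_dummies(series.astype(str), prefix=c, drop_first=True)
            for name in dummies.columns:
                cols[name] = dummies[name].astype(float)
    X = pd.DataFrame(cols, index=records.index)
    X.insert(0, "intercept", 1.0)
    return X, list(X.columns)


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns involved in the collinearity for the error message
        bad = []
        keep: list[str] = []
        for col in X.columns:
            sub = X[keep + [col]].to_numpy()
            if np.linalg.matrix_rank(sub) == len(keep):
                bad.append(col)
            else:
                keep.append(col)
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")


def fit_trait_lm(records: pd.DataFrame, response: str, predictor: str,
                 covariates: Sequence[str] = ("sex", "rodent_phase")) -> ModelResult:
    """OLS fit of a transformed fitness trait on one load/heterozygosity
    predictor plus covariates; complete cases only.

    ``response`` is one of ``lrs_sqrt`` (square root of LRS; zero LRS legal),
    ``longevity_log`` (log of years; adults only, requires positive values)
    or ``litter_size`` (identity).
    """
    if response not in RESPONSE_TRANSFORMS:
        raise ValueError(f"unknown response {response!r}")
    col, fn, trname = RESPONSE_TRANSFORMS[response]
    needed = [col, predictor, *covariates]
    data = records.dropna(subset=needed)
    y_raw = pd.to_numeric(data[col])
    if trname == "log" and (y_raw <= 0).any():
        raise ValueError("log transform requires positive response values")
    if trname == "sqrt" and (y_raw < 0).any():
        raise ValueError("sqrt transform requires non-negative response values")
    y = fn(y_raw.to_numpy(dtype=float))
    X, terms = _design(data, [predictor], covariates)
    if len(data) <= X.shape[1]:
        raise ValueError(f"n = {len(data)} too small for {X.shape[1]} parameters")
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    ci = np.asarray(res.conf_int())
    return ModelResult(
        family="ols", response=response, transform=trname, terms=terms,
        estimates=np.asarray(res.params), std_errors=np.asarray(res.bse),
        statistics=np.asarray(res.tvalues), pvalues=np.asarray(res.pvalues),
        conf_int=ci, n=int(res.nobs), r_squared=float(res.rsquared),
    )


def fit_juvenile_survival_glm(records: pd.DataFrame, predictor: str | Sequence[str],
                              covariates: Sequence[str] = ("sex", "rodent_phase"),
                              response: str = "juvenile_survival") -> ModelResult:
    """Binomial GLM (logit link) for first-year survival.

    Raises :class:`SeparationError` on (quasi-)complete separation and
    ``ValueError`` for an all-0 or all-1 response.
    """
    predictors = [predictor] if isinstance(predictor, str) else list(predictor)
    needed = [response, *predictors, *covariates]
    data = records.dropna(subset=needed)
    y = pd.to_numeric(data[response]).to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("response must be binary (0/1)")
    if y.min() == y.max():
        raise ValueError("response is constant (all 0 or all 1); GLM undefined")
    X, terms = _design(data, predictors, covariates)
    _check_rank(X)
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    except (PerfectSeparationError, RuntimeWarning) as err:
        raise SeparationError(
            "perfect separation detected; consider a penalised (Firth) "
            "logistic fit") from err
    # scale-aware separation check: a diverged fit drives the linear
    # predictor to +/- infinity (coefficients alone can be legitimately
    # huge when a predictor lives on a tiny scale)
    eta = X.to_numpy() @ np.asarray(res.params)
    if np.abs(eta).max() > 30:
        raise SeparationError(
            "diverging linear predictor indicates separation; consider a "
            "penalised (Firth) logistic fit")
    ci = np.asarray(res.conf_int())
    return ModelResult(
        family="binomial_glm", response=response, transform="logit",
        terms=terms, estimates=np.asarray(res.params),
        std_errors=np.asarray(res.bse), statistics=np.asarray(res.tvalues),
        pvalues=np.asarray(res.pvalues), conf_int=ci, n=int(res.nobs),
        extra={"deviance": float(res.deviance)},
    )


def pool_ancestry(ancestry: pd.Series,
                  pool: Mapping[str, str] | None = None) -> pd.Series:
    """Pool ancestry classes for the individual-level contrasts.

    By default F2, F3 and F4 are pooled into 'F2+F3' (later generations are
    grouped to keep contrasts estimable), immigrants are dropped (coded NaN)
    and native / F1 stay as they are.
    """
    if pool is None:
        pool = {"F2": "F2+F3", "F3": "F2+F3", "F4": "F2+F3",
                "native": "native", "F1": "F1"}
    return ancestry.map(pool)


def fit_ancestry_lmm(records: pd.DataFrame, response: str, group_col: str,
                     fixed: Sequence[str] = ("rodent_phase",),
                     random: str = "natal_den",
                     reference: str | None = None) -> ModelResult:
    """Random-intercept linear mixed model (REML) for ancestry contrasts.

    ``group_col`` is a categorical ancestry term (individual classes or
    litter pair combinations) with treatment coding against ``reference``
    (default: first level in sorted order). Wald t tests use the residual
    (n - rank) degrees-of-freedom approximation. A singular random-effect
    variance is reported as ~0 with a warning, not an error.
    """
    if response in RESPONSE_TRANSFORMS and RESPONSE_TRANSFORMS[response][0] in records.columns:
        col, fn, trname = RESPONSE_TRANSFORMS[response]
    elif response in records.columns:
        col, fn, trname = response, (lambda x: x), "identity"
    else:
        raise ValueError(f"response {response!r} not resolvable in records")
    needed = [col, group_col, random, *fixed]
    data = records.dropna(subset=needed).copy()
    if data[random].nunique() < 2:
        raise ValueError("need >= 2 random-effect groups (dens)")
    levels = sorted(data[group_col].astype(str).unique())
    if reference is not None:
        if reference not in levels:
            raise ValueError(f"reference level {reference!r} not present")
        levels = [reference] + [l for l in levels if l != reference]
    data[group_col] = pd.Categorical(data[group_col].astype(str), categories=levels)
    y = fn(pd.to_numeric(data[col]).to_numpy(dtype=float))

    dummies = pd.get_dummies(data[group_col], prefix=group_col, drop_first=True)
    cols = {name: dummies[name].astype(float) for name in dummies.columns}
    for c in fixed:
        d = pd.get_dummies(data[c].astype(str), prefix=c, drop_first=True)
        for name in d.columns:
            cols[name] = d[name].astype(float)
    X = pd.DataFrame(cols, index=data.index)
    X.insert(0, "intercept", 1.0)
    _check_rank(X)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=data[random].astype(str))
        try:
            res = model.fit(reml=True)
        except np.linalg.LinAlgError:
            res = model.fit(reml=True, method="powell")
    re_var = float(np.asarray(res.cov_re).ravel()[0]) if res.cov_re.size else 0.0
    k = X.shape[1]
    params = np.asarray(res.params)[:k]
    bse = np.asarray(res.bse)[:k]
    if re_var < 1e-8 or not np.isfinite(bse).all():
        # singular random-effect variance: retain the fit, report ~0 variance
        # with a warning; fixed-effect inference falls back to the exactly
        # equivalent OLS fit (whose standard errors are well defined)
        warnings.warn("random-effect variance estimated at the boundary (~0); "
                      "fixed effects equal the OLS fit", stacklevel=2)
        ols = sm.OLS(y, X).fit()
        params = np.asarray(ols.params)
        bse = np.asarray(ols.bse)
        re_var = max(re_var, 0.0)
    tvals = params / bse
    df = max(int(len(data) - k), 1)
    pvals = 2 * sps.t.sf(np.abs(tvals), df)
    crit = sps.t.ppf(0.975, df)
    ci = np.column_stack([params - crit * bse, params + crit * bse])
    return ModelResult(
        family="lmm", response=response, transform=trname,
        terms=list(X.columns), estimates=params, std_errors=bse,
        statistics=tvals, pvalues=pvals, conf_int=ci, n=len(data),
        extra={"random_effect_variance": re_var,
               "residual_variance": float(res.scale),
               "random_group": random, "df": df},
    )


@dataclass
class MannWhitneyResult:
    u: float                 # U statistic for sample A
    pvalue: float
    shift: float             # Hodges-Lehmann estimate of median(B - A)
    ci: tuple[float, float]  # ~95% CI for the location shift
    method: str              # "exact" | "asymptotic"


def mann_whitney_groups(values_a: Sequence[float],
                        values_b: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test with a Hodges-Lehmann shift estimate.

    Exact p-value for combined n <= 20 without ties; otherwise the normal
    approximation with tie correction. The location-shift CI uses the normal
    approximation to the U distribution on the ordered pairwise differences
    (B - A).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) + len(b) <= 20 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    diffs = np.sort(np.subtract.outer(b, a).ravel())
    m = len(diffs)
    shift = float(np.median(diffs))
    mu = m / 2.0
    sigma = np.sqrt(len(a) * len(b) * (len(a) + len(b) + 1) / 12.0)
    k = int(np.floor(mu - 1.959964 * sigma))
    k = max(k, 0)
    ci = (float(diffs[k]), float(diffs[m - 1 - k]))
    return MannWhitneyResult(u=float(res.statistic), pvalue=float(res.pvalue),
                             shift=shift, ci=ci, method=method)


@dataclass
class CorrelationResult:
    r: float
    t: float
    pvalue: float
    ci: tuple[float, float]
    n: int


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    n = len(x)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / max(1.0 - r * r, 1e-300))
    ci = res.confidence_interval(0.95)
    return CorrelationResult(r=r, t=float(t), pvalue=float(res.pvalue),
                             ci=(float(ci.low), float(ci.high)), n=n)


def _decimals(value: float) -> int:
    text = repr(float(value))
    if "e" in text or "E" in text or "." not in text:
        return 0
    return min(len(text.split(".")[1]), 6)


def contrast(means: Mapping[str, float], a: str, b: str) -> float:
    """Difference of printed group means (a - b), rounded to the coarser of
    the two inputs' printed precisions."""
    for g in (a, b):
        if g not in means:
            raise KeyError(f"unknown group label {g!r}; have {sorted(means)}")
    nd = max(_decimals(means[a]), _decimals(means[b]))
    return round(float(means[a]) - float(means[b]), nd)


def group_mean_contrast(means: Mapping[str, float]) -> dict[tuple[str, str], float]:
    """All ordered pairwise differences of printed group means."""
    if len(means) < 2:
        raise ValueError("need at least two groups")
    out = {}
    for a in means:
        for b in means:
            if a != b:
                out[(a, b)] = contrast(means, a, b)
    return out
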