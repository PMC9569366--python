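"""Inference layer: covariate-adjusted standardized regressions (mediation
Paths A-D), Sobel test, ordinal moderation with simple slopes, effect sizes,
dual FDR control, propensity-style site adjustment, and split-sample
validation with CV(RMSE).

Continuous variables are z-scored before fitting, so reported coefficients
are standardized betas; binary and dummy-coded terms are left unscaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests

#: default covariate set mirroring the adjusted models of the analysis
DEFAULT_COVARIATES = [
    "age_months",
    "sex_female",
    "race_white",
    "ethnicity_hispanic",
    "income_bracket",
    "bmi",
    "togetherness",
    "family_size",
]

#: binary / categorical-indicator columns that must not be z-scored
BINARY_COLUMNS = {"sex_female", "race_white", "ethnicity_hispanic"}


@dataclass
class ModelSpec:
    outcome: str
    primary_predictor: str
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    ordinal_coding: str = "linear"  # or "dummy_ref1"

    def validate(self, table: pd.DataFrame) -> "ModelSpec":
        if self.primary_predictor in self.covariates:
            raise ValueError("primary_predictor must not appear among covariates")
        missing = [
            c
            for c in [self.outcome, self.primary_predictor, *self.covariates]
            if c not in table.columns
        ]
        if missing:
            raise KeyError(f"columns missing from table: {missing}")
        if self.ordinal_coding not in {"linear", "dummy_ref1"}:
            raise ValueError(f"unknown ordinal_coding {self.ordinal_coding!r}")
        return self


@dataclass
class FitResult:
    terms: pd.DataFrame  # index: term; columns: beta, se, p, p_fdr
    adj_r2: float
    r2: float
    aic: float
    n_used: int
    condition_number: float
    model: object = None

    def beta(self, term: str) -> float:
        return float(self.terms.loc[term, "beta"])

    def se(self, term: str) -> float:
        return float(self.terms.loc[term, "se"])

    def p(self, term: str) -> float:
        return float(self.terms.loc[term, "p"])


def _is_binary(col: pd.Series) -> bool:
    vals = pd.unique(col.dropna())
    return set(np.asarray(vals).tolist()) <= {0, 1, 0.0, 1.0}


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (x - np.mean(x)) / sd


def _design(
    table: pd.DataFrame, columns: Sequence[str], standardize: bool = True
) -> pd.DataFrame:
    out = {}
    for c in columns:
        col = table[c].astype(float)
        if c in BINARY_COLUMNS or _is_binary(col) or not standardize:
            out[c] = col.to_numpy()
        else:
            out[c] = _zscore(col.to_numpy())
    return pd.DataFrame(out, index=table.index)


def fit_ols_standardized(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """OLS with z-scored continuous outcome and predictors.

    Rows with any missing value among the model columns are dropped
    (listwise deletion); ``n_used`` reports the rows analyzed.  Rank-deficient
    designs raise an error naming the aliased columns; an ill-conditioned but
    full-rank design only sets a large ``condition_number``.
    """
    spec.validate(table)
    cols = [spec.outcome, spec.primary_predictor, *spec.covariates]
    sub = table[cols].dropna()
    n_used = len(sub)
    n_terms = 1 + len(spec.covariates) + 1
    if n_used <= n_terms + 1:
        raise ValueError(f"too few complete rows ({n_used}) for {n_terms} terms")

    y = _zscore(sub[spec.outcome].astype(float).to_numpy())
    x = _design(sub, [spec.primary_predictor, *spec.covariates])
    x = sm.add_constant(x, prepend=True)

    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        # identify aliased columns by incremental rank
        aliased = []
        kept: list[str] = []
        for c in x.columns:
            trial = x[kept + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(c)
            else:
                aliased.append(c)
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")

    res = sm.OLS(y, x).fit()
    terms = pd.DataFrame(
        {
            "beta": res.params,
            "se": res.bse,
            "p": res.pvalues,
            "p_fdr": np.nan,
        }
    )
    return FitResult(
        terms=terms,
        adj_r2=float(res.rsquared_adj),
        r2=float(res.rsquared),
        aic=float(res.aic),
        n_used=n_used,
        condition_number=float(np.linalg.cond(x.to_numpy())),
        model=res,
    )


# ---------------------------------------------------------------------------
# Sobel test and mediation
# ---------------------------------------------------------------------------

def sobel_test(a: float, se_a: float, b: float, se_b: float) -> tuple[float, float]:
    """Normal-theory test of the indirect effect a*b.

    z = a*b / sqrt(b^2 se_a^2 + a^2 se_b^2); two-sided normal p.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    denom = np.sqrt(b**2 * se_a**2 + a**2 * se_b**2)
    if denom == 0:
        return 0.0, 1.0
    z = a * b / denom
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class MediationResult:
    path_a: FitResult  # belief -> score (total effect)
    path_b: FitResult  # belief -> property
    path_c: FitResult  # property -> score
    path_d: FitResult  # score ~ belief + property (full model)
    indirect_ab: float
    sobel_z: float
    sobel_p: float
    direct_p: float
    mediation_class: str  # none | partial | full


def run_mediation(
    table: pd.DataFrame,
    belief: str,
    property_col: str,
    score: str,
    covariates: Optional[list[str]] = None,
    motion_col: str = "motion_censored_fraction",
    alpha: float = 0.05,
) -> MediationResult:
    """Paths A-D mediation with Sobel inference.

    Path A: score ~ belief; Path B: property ~ belief; Path C: score ~
    property; Path D: score ~ belief + property.  All share the covariate
    set; models touching the network property add the motion-censoring
    fraction.  The indirect effect is a*b with a from Path B and b from the
    full model (Path D).  Classification: partial = significant indirect and
    significant direct (c'); full = significant indirect, nonsignificant c'.
    """
    covs = list(DEFAULT_COVARIATES if covariates is None else covariates)
    covs_net = covs + ([motion_col] if motion_col in table.columns else [])

    path_a = fit_ols_standardized(table, ModelSpec(score, belief, covs))
    path_b = fit_ols_standardized(table, ModelSpec(property_col, belief, covs_net))
    path_c = fit_ols_standardized(table, ModelSpec(score, property_col, covs_net))
    path_d = fit_ols_standardized(
        table, ModelSpec(score, belief, covs_net + [property_col])
    )

    a, se_a = path_b.beta(belief), path_b.se(belief)
    b, se_b = path_d.beta(property_col), path_d.se(property_col)
    z, p = sobel_test(a, se_a, b, se_b)
    direct_p = path_d.p(belief)

    if p < alpha and direct_p < alpha:
        klass = "partial"
    elif p < alpha:
        klass = "full"
    else:
        klass = "none"
    return MediationResult(
        path_a=path_a,
        path_b=path_b,
        path_c=path_c,
        path_d=path_d,
        indirect_ab=float(a * b),
        sobel_z=z,
        sobel_p=p,
        direct_p=float(direct_p),
        mediation_class=klass,
    )


# ---------------------------------------------------------------------------
# Moderation with simple slopes
# ---------------------------------------------------------------------------

@dataclass
class ModerationResult:
    interaction_betas: pd.Series  # per belief level 2..5
    interaction_p: float  # joint F-test of all interaction terms
    simple_slopes: pd.DataFrame  # index level 1..5: slope, se, p, n_level
    f_squared: float
    full: FitResult
    reduced: FitResult
    low_count_levels: list[int]


def run_moderation(
    table: pd.DataFrame,
    property_col: str,
    score: str,
    belief: str,
    covariates: Optional[list[str]] = None,
    motion_col: str = "motion_censored_fraction",
    min_level_n: int = 10,
) -> ModerationResult:
    """Ordinal moderation of the property -> score slope by belief level.

    The full model codes belief levels 2-5 as dummies against the "not at
    all" (= 1) reference and includes property x dummy interactions; the
    simple slope at level L is beta_property + beta_interaction(L), with SE
    from the coefficient covariance (delta method).  f^2 compares the full
    model with the no-interaction model.
    """
    covs = list(DEFAULT_COVARIATES if covariates is None else covariates)
    if motion_col in table.columns and motion_col not in covs:
        covs = covs + [motion_col]
    cols = [score, property_col, belief, *covs]
    sub = table[cols].dropna()
    levels_present = sorted(int(v) for v in sub[belief].unique())
    if len(levels_present) < 2:
        raise ValueError(f"belief {belief!r} has fewer than 2 observed levels")

    y = _zscore(sub[score].astype(float).to_numpy())
    zprop = _zscore(sub[property_col].astype(float).to_numpy())
    covx = _design(sub, covs)

    x = {"property": zprop}
    int_terms, dummy_terms = [], []
    for lev in levels_present:
        if lev == 1:
            continue
        d = (sub[belief].to_numpy() == lev).astype(float)
        x[f"level_{lev}"] = d
        x[f"property_x_level_{lev}"] = zprop * d
        dummy_terms.append(f"level_{lev}")
        int_terms.append(f"property_x_level_{lev}")
    xfull = sm.add_constant(
        pd.concat([pd.DataFrame(x, index=sub.index), covx], axis=1), prepend=True
    )
    full = sm.OLS(y, xfull).fit()
    xred = xfull.drop(columns=int_terms)
    reduced = sm.OLS(y, xred).fit()

    # joint F-test on all interaction terms
    ftest = full.f_test([f"{t} = 0" for t in int_terms])
    interaction_p = float(ftest.pvalue)
    f_squared = max(
        float((full.rsquared - reduced.rsquared) / (1.0 - full.rsquared)), 0.0
    )

    cov_params = full.cov_params()
    rows = []
    low = []
    for lev in levels_present:
        n_lev = int((sub[belief] == lev).sum())
        if n_lev < min_level_n:
            low.append(lev)
        if lev == 1:
            slope = full.params["property"]
            var = cov_params.loc["property", "property"]
        else:
            t = f"property_x_level_{lev}"
            slope = full.params["property"] + full.params[t]
            var = (
                cov_params.loc["property", "property"]
                + cov_params.loc[t, t]
                + 2.0 * cov_params.loc["property", t]
            )
        se = float(np.sqrt(var))
        zstat = slope / se
        dfr = full.df_resid
        rows.append(
            {
                "level": lev,
                "slope": float(slope),
                "se": se,
                "p": float(2.0 * sps.t.sf(abs(zstat), dfr)),
                "n_level": n_lev,
            }
        )
    slopes = pd.DataFrame(rows).set_index("level")

    def _fit_result(res, xmat) -> FitResult:
        terms = pd.DataFrame(
            {"beta": res.params, "se": res.bse, "p": res.pvalues, "p_fdr": np.nan}
        )
        return FitResult(
            terms=terms,
            adj_r2=float(res.rsquared_adj),
            r2=float(res.rsquared),
            aic=float(res.aic),
            n_used=len(sub),
            condition_number=float(np.linalg.cond(xmat.to_numpy())),
            model=res,
        )

    return ModerationResult(
        interaction_betas=full.params[int_terms],
        interaction_p=interaction_p,
        simple_slopes=slopes,
        f_squared=f_squared,
        full=_fit_result(full, xfull),
        reduced=_fit_result(reduced, xred),
        low_count_levels=low,
    )


# ---------------------------------------------------------------------------
# Effect sizes and FDR
# ---------------------------------------------------------------------------

def cohens_d(group_ref: np.ndarray, group_cmp: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Cohen's d (cmp minus ref) with df-weighted pooled SD and a 95% CI.

    The pooled SD weights each group's variance by its degrees of freedom,
    which is the standard unequal-sample-size adjustment; the CI uses the
    large-sample normal approximation to the noncentral-t interval.
    """
    x, y = np.asarray(group_ref, float), np.asarray(group_cmp, float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if s2 == 0:
        raise ValueError("zero pooled variance")
    d = (y.mean() - x.mean()) / np.sqrt(s2)
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2 - 2)))
    return float(d), (float(d - 1.96 * se), float(d + 1.96 * se))


def fdr_adjust(pvalues: Sequence[float], mode: str = "independent_BH") -> np.ndarray:
    """Step-up FDR-adjusted p-values.

    ``independent_BH`` is the Benjamini-Hochberg procedure; ``dependent_BY``
    multiplies by the harmonic-sum factor for arbitrary dependence
    (Benjamini-Yekutieli).  Order-preserving and monotone-enforced.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    method = {"independent_BH": "fdr_bh", "dependent_BY": "fdr_by"}.get(mode)
    if method is None:
        raise ValueError(f"unknown FDR mode {mode!r}")
    return multipletests(p, alpha=0.05, method=method)[1]


# ---------------------------------------------------------------------------
# Site adjustment (propensity-style)
# ---------------------------------------------------------------------------

def site_adjustment(
    table: pd.DataFrame,
    site_col: str = "site",
    covariates: Optional[list[str]] = None,
    out_col: str = "site_propensity",
    min_site_n: int = 20,
) -> tuple[pd.DataFrame, list]:
    """Append each subject's predicted probability of their own site.

    A multinomial logistic model predicts site membership from demographics;
    the fitted own-site probability enters downstream models as a covariate
    (the covariate-adjustment variant of propensity correction).  Returns the
    augmented table and a list of sites with fewer than ``min_site_n``
    subjects (a warning condition, not an error).
    """
    covs = covariates or ["age_months", "sex_female", "race_white", "income_bracket"]
    sites = table[site_col].to_numpy()
    uniq, counts = np.unique(sites, return_counts=True)
    if uniq.size < 2:
        raise ValueError("site adjustment requires at least 2 sites")
    small = [s for s, c in zip(uniq, counts) if c < min_site_n]

    x = _design(table, covs).to_numpy()
    model = LogisticRegression(max_iter=2000, C=1.0)
    model.fit(x, sites)
    proba = model.predict_proba(x)
    site_to_col = {s: i for i, s in enumerate(model.classes_)}
    own = proba[np.arange(len(table)), [site_to_col[s] for s in sites]]
    out = table.copy()
    out[out_col] = np.clip(own, 1e-9, 1.0 - 1e-9)
    return out, small


# ---------------------------------------------------------------------------
# Split-sample validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationResult:
    cv_rmse: np.ndarray  # per repeat (NaN where the normalizer degenerated)
    aic: np.ndarray
    median_cv_rmse: float
    median_aic: float
    n_train: int
    n_test: int
    n_repeats: int
    n_undefined: int


def split_sample_validate(
    table: pd.DataFrame,
    spec: ModelSpec,
    train_frac: float = 0.75,
    n_repeats: int = 100,
    seed: int = 0,
) -> ValidationResult:
    """Repeated random-split out-of-sample validation.

    Per repeat: fit the model on ``train_frac`` of subjects, predict the
    held-out remainder, and report CV(RMSE) = RMSE / |mean observed outcome|
    on the held-out raw outcome scale, plus the training AIC.  Deterministic
    under ``seed``.
    """
    spec.validate(table)
    cols = [spec.outcome, spec.primary_predictor, *spec.covariates]
    sub = table[cols].dropna().reset_index(drop=True)
    n = len(sub)
    n_train = int(round(train_frac * n))
    n_test = n - n_train
    n_terms = len(cols) + 1
    if n_test < 2 * n_terms:
        raise ValueError("test split too small for the model size")

    rng = np.random.default_rng(seed)
    cv = np.empty(n_repeats)
    aic = np.empty(n_repeats)
    y_all = sub[spec.outcome].astype(float).to_numpy()
    x_all = _design(sub, [spec.primary_predictor, *spec.covariates])
    x_all = sm.add_constant(x_all, prepend=True).to_numpy()

    for r in range(n_repeats):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        res = sm.OLS(y_all[tr], x_all[tr]).fit()
        pred = x_all[te] @ res.params
        rmse = float(np.sqrt(np.mean((y_all[te] - pred) ** 2)))
        denom = abs(float(np.mean(y_all[te])))
        cv[r] = rmse / denom if denom > 1e-12 else np.nan
        aic[r] = float(res.aic)

    n_undef = int(np.isnan(cv).sum())
    return ValidationResult(
        cv_rmse=cv,
        aic=aic,
        median_cv_rmse=float(np.nanmedian(cv)) if n_undef < n_repeats else float("nan"),
        median_aic=float(np.median(aic)),
        n_train=n_train,
        n_test=n_test,
        n_repeats=n_repeats,
        n_undefined=n_undef,
    )
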