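"""Synthetic cohort generator.

Generates cohorts carrying the statistical structure the downstream analysis
assumes: covariate-dependent ordinal beliefs (latent-normal cut-point model),
belief-modulated block-covariance parcel time series, and cognitive task
scores with planted direct, mediated, and moderated belief effects.

Two modes are supported.  In *matrix mode* the mediator (a network property
stand-in) is emitted directly as a table column, which makes statistics-only
experiments fast.  In *time-series mode* the belief effect enters the
within-network correlation of a targeted resting-state network, so the full
connectivity -> graph-metric path is exercised.

All randomness flows through named substreams of the config seed, so the same
``(config, seed)`` pair is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import (
    BELIEF_ITEMS,
    CohortConfig,
    ConfigError,
    FAMILY_ITEMS,
    RELIGIOUS_ITEMS,
)


class GenerationError(RuntimeError):
    pass


# Substream tags (second entry of the rng seed vector).
_STREAM_COVARIATES = 0
_STREAM_BELIEFS = 1
_STREAM_TOPOLOGY = 2
_STREAM_SCORES = 3
_STREAM_TIMESERIES = 4


def _rng(config: CohortConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *tags])


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

# Income-bracket and caregiver-education margins (6 ordered levels each),
# modelled on a large US adolescent cohort; missing categories renormalized.
_INCOME_MARGINS = np.array([0.0261, 0.0862, 0.1326, 0.2688, 0.2970, 0.1156])
_INCOME_MARGINS = _INCOME_MARGINS / _INCOME_MARGINS.sum()
# education ordinal 1 = did not finish high school ... 6 = advanced degree
_EDU_MARGINS = np.array([0.0539, 0.0967, 0.1642, 0.1229, 0.3085, 0.2530])
_EDU_MARGINS = _EDU_MARGINS / _EDU_MARGINS.sum()
_TOGETHER_MARGINS = np.array([0.02, 0.05, 0.18, 0.35, 0.40])

#: Shared latent socioeconomic loading for income and education.
_SES_LOADING = 0.8


def _cut_ordinal(latent: np.ndarray, margins: np.ndarray, start: int = 1) -> np.ndarray:
    """Map standard-normal latents to ordinal levels with given margins."""
    cuts = sps.norm.ppf(np.cumsum(margins)[:-1])
    return start + np.searchsorted(cuts, latent, side="left").astype(np.int64)


def generate_covariates(config: CohortConfig) -> pd.DataFrame:
    """Demographic and nuisance covariates, one row per subject.

    Income and education load on a shared latent socioeconomic factor, so
    their rank correlation is positive by construction.  Age is centered near
    120 months with an IQR near 13 months; sites are assigned uniformly.
    """
    config.validate()
    rng = _rng(config, _STREAM_COVARIATES)
    n = config.n_subjects

    z_ses = rng.normal(size=n)
    inc_latent = _SES_LOADING * z_ses + np.sqrt(1 - _SES_LOADING**2) * rng.normal(size=n)
    edu_latent = _SES_LOADING * z_ses + np.sqrt(1 - _SES_LOADING**2) * rng.normal(size=n)

    df = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:05d}" for i in range(n)],
            "age_months": rng.normal(120.0, 13.0 / 1.349, size=n),
            "sex_female": (rng.random(n) < 0.52).astype(np.int64),
            "race_white": (rng.random(n) < 0.67).astype(np.int64),
            "ethnicity_hispanic": (rng.random(n) < 0.20).astype(np.int64),
            "income_bracket": _cut_ordinal(inc_latent, _INCOME_MARGINS),
            "education": _cut_ordinal(edu_latent, _EDU_MARGINS),
            "bmi": np.clip(rng.normal(18.5, 3.0, size=n), 12.0, None),
            "family_size": 2 + rng.poisson(2.0, size=n),
            "togetherness": _cut_ordinal(rng.normal(size=n), _TOGETHER_MARGINS),
            "site": rng.integers(0, config.n_sites, size=n),
            "motion_censored_fraction": rng.uniform(0.0, 0.10, size=n),
        }
    )
    return df


# ---------------------------------------------------------------------------
# Ordinal beliefs, practices
# ---------------------------------------------------------------------------

# Cut-point designs (cumulative probabilities between the 5 ordinal levels);
# religious items are bimodal-skewed, family-values items center-heavy.
_RELIGIOUS_CUM = np.array([0.20, 0.30, 0.45, 0.65])
_FAMILY_CUM = np.array([0.15, 0.35, 0.70, 0.85])
_ATTEND_CUM = np.array([0.27, 0.50, 0.64, 0.92])  # levels 0..4
_IMPORTANCE_CUM = np.array([0.18, 0.33, 0.63])  # levels 1..4
#: correlation between the religiosity factor and the family-values factor
_FACTOR_CORR = 0.4


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate_beliefs(df: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Fill ordinal belief items, service attendance, and importance.

    Each ordinal item is a cut of a latent normal with a shared religiosity
    (or family-values) factor plus negative loadings on standardized income
    and education.  Attendance and importance load on the religiosity factor,
    so they are positively associated with religious belief strength.
    """
    config.validate()
    rng = _rng(config, _STREAM_BELIEFS)
    n = len(df)
    df = df.copy()

    z_inc = _zscore(df["income_bracket"].to_numpy())
    z_edu = _zscore(df["education"].to_numpy())
    lam_i = config.income_belief_loading
    lam_e = config.education_belief_loading
    lam_r = config.religiosity_loading

    relig = rng.normal(size=n)
    family = _FACTOR_CORR * relig + np.sqrt(1 - _FACTOR_CORR**2) * rng.normal(size=n)

    for item in BELIEF_ITEMS:
        factor = relig if item in RELIGIOUS_ITEMS else family
        sys = lam_r * factor + lam_i * z_inc + lam_e * z_edu
        unique = np.sqrt(max(1.0 - lam_r**2 - lam_i**2 - lam_e**2, 0.05))
        latent = sys + unique * rng.normal(size=n)
        cum = _RELIGIOUS_CUM if item in RELIGIOUS_ITEMS else _FAMILY_CUM
        # latent variance is ~1 by construction; cut at fixed normal quantiles
        cuts = sps.norm.ppf(cum)
        df[item] = 1 + np.searchsorted(cuts, latent, side="left").astype(np.int64)

    att_latent = 0.75 * relig + np.sqrt(1 - 0.75**2) * rng.normal(size=n)
    imp_latent = 0.75 * relig + np.sqrt(1 - 0.75**2) * rng.normal(size=n)
    df["attendance"] = np.searchsorted(sps.norm.ppf(_ATTEND_CUM), att_latent).astype(np.int64)
    df["importance"] = 1 + np.searchsorted(sps.norm.ppf(_IMPORTANCE_CUM), imp_latent).astype(
        np.int64
    )
    return df


# ---------------------------------------------------------------------------
# Planted topology (true within-network correlation of the targeted network)
# ---------------------------------------------------------------------------

def mediator_column(config: CohortConfig) -> str:
    """Name of the targeted network-property column used as the mediator."""
    return f"net__{config.target_network}__{config.target_hemisphere}__median_conn_in"


def generate_true_topology(df: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Subject-level *true* within-network correlation of the targeted network.

    rho_s = rho_within - Delta * (belief - 1)/4 + eta_s, with
    Delta = belief_topology_d * subject_rho_sd and eta_s ~ N(0, subject_rho_sd).
    Cohen's d between belief levels 5 and 1 on rho_s is therefore the planted
    ``belief_topology_d`` (finite-length estimation adds a small attenuation
    downstream).
    """
    config.validate()
    rng = _rng(config, _STREAM_TOPOLOGY)
    df = df.copy()
    level = df[config.target_belief].to_numpy(dtype=float)
    delta = config.belief_topology_d * config.subject_rho_sd
    eta = rng.normal(0.0, config.subject_rho_sd, size=len(df))
    rho = config.rho_within - delta * (level - 1.0) / 4.0 + eta
    lo = config.rho_between + 0.01
    df["true_within_rho"] = np.clip(rho, lo, 0.95)
    return df


def generate_mediator_matrix_mode(df: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Emit the mediator directly (no signals): a*z(belief) + sqrt(1-a^2)*noise.

    The emitted column is standardized, so ``path_a_effect`` is exactly the
    population standardized belief -> mediator slope.
    """
    config.validate()
    rng = _rng(config, _STREAM_TOPOLOGY)
    df = df.copy()
    a = config.path_a_effect
    zb = _zscore(df[config.target_belief].to_numpy())
    resid_sd = np.sqrt(max(1.0 - a**2, 1e-6))
    df[mediator_column(config)] = a * zb + resid_sd * rng.normal(size=len(df))
    return df


# ---------------------------------------------------------------------------
# Task scores
# ---------------------------------------------------------------------------

def generate_task_scores(
    df: pd.DataFrame, mediator_values: np.ndarray | pd.Series, config: CohortConfig
) -> pd.DataFrame:
    """Fill cognitive task scores with the planted direct/indirect/moderated
    structure.

    flanker_score = center + scale * (c' * z_belief + b * z_med
                    + moderation * z_belief*z_med + income effect + noise).
    With ``noise_sd=None`` the residual SD is chosen so the standardized score
    has unit variance, making the planted coefficients exact population
    standardized betas.  ``cardsort_score`` carries no planted belief effect
    and serves as a negative control.
    """
    config.validate()
    rng = _rng(config, _STREAM_SCORES)
    df = df.copy()
    med = np.asarray(mediator_values, dtype=float)
    if med.shape[0] != len(df):
        raise GenerationError(
            f"expected {len(df)} mediator values, got {med.shape[0]}"
        )
    if np.isnan(med).any():
        bad = df["subject_id"].to_numpy()[np.isnan(med)][0]
        raise GenerationError(f"missing mediator value for subject {bad}")

    zb = _zscore(df[config.target_belief].to_numpy())
    zm = _zscore(med)
    z_inc = _zscore(df["income_bracket"].to_numpy())

    # The belief x mediator product is residualized against the main effects
    # (beliefs are skewed, so the raw product correlates with them); the
    # planted coefficients are then exact *partial* standardized effects.
    inter = zb * zm
    basis = np.column_stack([np.ones_like(zb), zb, zm, z_inc])
    coef, *_ = np.linalg.lstsq(basis, inter, rcond=None)
    inter_orth = inter - basis @ coef
    sd = inter_orth.std(ddof=0)
    if sd > 0:
        inter_orth = inter_orth / sd

    systematic = (
        config.path_cprime_effect * zb
        + config.path_b_effect * zm
        + config.moderation_effect * inter_orth
        + config.income_score_effect * z_inc
    )
    if config.noise_sd is None:
        noise_sd = float(np.sqrt(max(1.0 - np.var(systematic), 0.05)))
    else:
        noise_sd = float(config.noise_sd)
    y = systematic + noise_sd * rng.normal(size=len(df))
    df["flanker_score"] = config.score_center + config.score_scale * y

    null_y = config.income_score_effect * z_inc + rng.normal(size=len(df))
    df["cardsort_score"] = 94.0 + (23.0 / 1.349) * null_y
    return df


# ---------------------------------------------------------------------------
# Parcellation and time series
# ---------------------------------------------------------------------------

def parcellation_map(config: CohortConfig) -> pd.DataFrame:
    """Parcel -> (network, hemisphere) table in generator parcel order."""
    rows = []
    i = 0
    for network, hemisphere, count in config.network_layout:
        for _ in range(int(count)):
            rows.append((f"p{i:04d}", network, hemisphere))
            i += 1
    return pd.DataFrame(rows, columns=["parcel_id", "network", "hemisphere"])


def _block_covariance(config: CohortConfig, target_rho: float) -> np.ndarray:
    """Equicorrelated block covariance; the targeted network's within-block
    correlation is replaced by ``target_rho``."""
    p = config.n_parcels
    cov = np.full((p, p), config.rho_between)
    i = 0
    for network, hemisphere, count in config.network_layout:
        c = int(count)
        rho = (
            target_rho
            if (network == config.target_network and hemisphere == config.target_hemisphere)
            else config.rho_within
        )
        cov[i : i + c, i : i + c] = rho
        i += c
    np.fill_diagonal(cov, 1.0)
    return cov


@dataclass
class SubjectRecord:
    """Typed view of one cohort row (beliefs/scores may be absent early on)."""

    subject_id: str
    true_within_rho: float
    motion_censored_fraction: float

    @classmethod
    def from_row(cls, row: pd.Series) -> "SubjectRecord":
        return cls(
            subject_id=str(row["subject_id"]),
            true_within_rho=float(row.get("true_within_rho", np.nan)),
            motion_censored_fraction=float(row["motion_censored_fraction"]),
        )


def generate_timeseries(row: pd.Series, config: CohortConfig, subject_index: int):
    """Per-run parcel time series for one subject.

    Signals are zero-mean Gaussians with the subject's block covariance.  The
    last run carries an additive common (artifact-like) component shared by
    all parcels, which inflates its pairwise correlations; selecting the run
    with the lowest median connectivity therefore avoids it, making run
    selection non-trivial.
    """
    from .connectivity import ParcelTimeSeries  # local import to avoid cycle

    config.validate()
    rng = _rng(config, _STREAM_TIMESERIES, int(subject_index))
    rho_t = float(row.get("true_within_rho", config.rho_within))
    cov = _block_covariance(config, rho_t)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by clip
        raise GenerationError(
            "belief-dependent decrement produced a non-PSD covariance; "
            "reduce belief_topology_d or subject_rho_sd"
        ) from exc

    pmap = parcellation_map(config)
    parcel_ids = pmap["parcel_id"].tolist()
    runs = []
    t = config.n_timepoints
    for r in range(config.n_runs_per_subject):
        x = chol @ rng.standard_normal((config.n_parcels, t))
        if config.n_runs_per_subject > 1 and r == config.n_runs_per_subject - 1:
            # artifact run: shared global component raises all correlations
            common = rng.standard_normal(t) * config.noisy_run_extra_sd
            x = x + common[None, :]
            motion = rng.uniform(0.05, 0.10)
        else:
            motion = rng.uniform(0.0, 0.08)
        runs.append(
            ParcelTimeSeries(
                parcel_ids=list(parcel_ids),
                data=x,
                motion_censored_fraction=float(motion),
            )
        )
    return runs


# ---------------------------------------------------------------------------
# Convenience: full cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig, mode: str = "matrix"):
    """Generate a complete cohort table (and, in time-series mode, signals).

    Returns ``(table, parcel_map, timeseries)`` where ``timeseries`` is
    ``None`` in matrix mode, else a dict subject_id -> list of runs.
    """
    if mode not in {"matrix", "timeseries"}:
        raise ConfigError(f"unknown cohort mode {mode!r}")
    df = generate_covariates(config)
    df = generate_beliefs(df, config)
    pmap = parcellation_map(config)
    med_col = mediator_column(config)
    if mode == "matrix":
        df = generate_mediator_matrix_mode(df, config)
        df = generate_task_scores(df, df[med_col].to_numpy(), config)
        return df, pmap, None
    df = generate_true_topology(df, config)
    ts = {}
    for i in range(len(df)):
        row = df.iloc[i]
        ts[str(row["subject_id"])] = generate_timeseries(row, config, i)
    # scores are driven by the standardized true topology (the latent mediator)
    df = generate_task_scores(df, df["true_within_rho"].to_numpy(), config)
    return df, pmap, ts
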