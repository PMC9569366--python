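"""Pairwise functional connectivity estimation and thresholding.

Connectivity between parcel BOLD signals is estimated either as the peak
(lagged) cross-correlation or as plug-in mutual information from a 2-D
histogram.  Per subject, the analysis run is the one with the lowest overall
median connectivity; a conservative population-based threshold — the upper
95% confidence bound of the per-subject "moderate outlier" level
(median + 1.5*IQR of the correlation distribution) — converts connectivity
matrices into nonnegative weighted adjacency matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class ParcelTimeSeries:
    """One subject/run: parcels x timepoints signal matrix."""

    parcel_ids: list[str]
    data: np.ndarray
    motion_censored_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D parcels x timepoints matrix")
        if self.data.shape[0] != len(self.parcel_ids):
            raise ValueError(
                f"{len(self.parcel_ids)} parcel ids but {self.data.shape[0]} signal rows"
            )
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 parcels")
        if np.isnan(self.data).any():
            raise ValueError("time series contain missing values")
        if not (0.0 <= self.motion_censored_fraction <= 1.0):
            raise ValueError("motion_censored_fraction must be in [0, 1]")

    @property
    def n_parcels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric pairwise association matrix with zero diagonal."""

    parcel_ids: list[str]
    values: np.ndarray
    method: str
    peak_lags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=0.0):
            raise ValueError("connectivity matrix must be exactly symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) != 0.0:
            raise ValueError("connectivity diagonal must be exactly zero")

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]


@dataclass
class AdjacencyMatrix:
    """Thresholded nonnegative weighted adjacency; binary view derived."""

    parcel_ids: list[str]
    weights: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if not np.allclose(w, w.T, atol=0.0):
            raise ValueError("adjacency must be exactly symmetric")
        if (w < 0).any():
            raise ValueError("adjacency weights must be nonnegative")
        if np.abs(np.diag(w)).max(initial=0.0) != 0.0:
            raise ValueError("adjacency diagonal must be exactly zero")

    @property
    def binarized_view(self) -> np.ndarray:
        return (self.weights > 0).astype(np.int64)

    @property
    def n_edges(self) -> int:
        return int(self.binarized_view.sum() // 2)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _check_variance(ts: ParcelTimeSeries) -> None:
    sd = ts.data.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance signal for parcel {ts.parcel_ids[bad[0]]!r}")


def _lagged_corr(x: np.ndarray, lag: int) -> np.ndarray:
    """Pearson correlation of row i at time t with row j at time t+lag.

    Overlapping segments are mean-centered and renormalized per lag.
    """
    t = x.shape[1]
    if lag == 0:
        a = b = x
    else:
        a = x[:, : t - lag]
        b = x[:, lag:]
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt((a * a).sum(axis=1))
    nb = np.sqrt((b * b).sum(axis=1))
    denom = np.outer(na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (a @ b.T) / denom
    c[~np.isfinite(c)] = 0.0
    return np.clip(c, -1.0, 1.0)


def peak_crosscorr(ts: ParcelTimeSeries, max_lag: int = 5) -> ConnectivityMatrix:
    """Signed cross-correlation at the lag maximizing |rho| in [-L, L].

    Ties are broken toward the smallest |lag|, then negative before positive.
    ``max_lag=0`` reduces to the ordinary Pearson correlation matrix.  The lag
    stored for pair (i, j) with i < j is the shift of parcel j relative to
    parcel i at the peak; storage is symmetric.
    """
    if max_lag < 0:
        raise ValueError("max_lag must be nonnegative")
    if max_lag >= ts.n_timepoints / 2:
        raise ValueError(
            f"max_lag={max_lag} too large for {ts.n_timepoints} timepoints"
        )
    _check_variance(ts)
    x = ts.data
    p = ts.n_parcels

    # candidate order encodes the tie-break: |lag| ascending, negative first
    lags = [0]
    for L in range(1, max_lag + 1):
        lags.extend([-L, L])

    best = np.zeros((p, p))
    best_abs = np.full((p, p), -1.0)
    best_lag = np.zeros((p, p), dtype=np.int64)
    for lag in lags:
        c = _lagged_corr(x, lag) if lag >= 0 else _lagged_corr(x, -lag).T
        mask = np.abs(c) > best_abs + 1e-15
        best[mask] = c[mask]
        best_lag[mask] = lag
        best_abs[mask] = np.abs(c[mask])

    # symmetrize on the upper triangle (lag_ij refers to j relative to i, i<j)
    iu = np.triu_indices(p, k=1)
    values = np.zeros((p, p))
    lagmat = np.zeros((p, p), dtype=np.int64)
    values[iu] = best[iu]
    lagmat[iu] = best_lag[iu]
    values = values + values.T
    lagmat = lagmat + lagmat.T
    return ConnectivityMatrix(
        parcel_ids=list(ts.parcel_ids),
        values=values,
        method="peak_crosscorr",
        peak_lags=lagmat,
    )


def mutual_information(ts: ParcelTimeSeries, n_bins: int = 16) -> ConnectivityMatrix:
    """Plug-in mutual information (nats) from equal-width 2-D histograms."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    _check_variance(ts)
    x = ts.data
    p, t = x.shape

    # precompute per-parcel bin assignments (equal-width over each range)
    digitized = np.empty((p, t), dtype=np.int64)
    for i in range(p):
        lo, hi = x[i].min(), x[i].max()
        edges = np.linspace(lo, hi, n_bins + 1)
        d = np.searchsorted(edges, x[i], side="right") - 1
        digitized[i] = np.clip(d, 0, n_bins - 1)

    values = np.zeros((p, p))
    marg = [np.bincount(digitized[i], minlength=n_bins) / t for i in range(p)]
    for i in range(p):
        for j in range(i + 1, p):
            joint = np.zeros((n_bins, n_bins))
            np.add.at(joint, (digitized[i], digitized[j]), 1.0)
            joint /= t
            outer = np.outer(marg[i], marg[j])
            nz = joint > 0
            mi = float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))
            values[i, j] = values[j, i] = max(mi, 0.0)
    return ConnectivityMatrix(
        parcel_ids=list(ts.parcel_ids), values=values, method="mutual_information"
    )


# ---------------------------------------------------------------------------
# Run selection and thresholding
# ---------------------------------------------------------------------------

def select_run(runs: Sequence[ConnectivityMatrix]) -> int:
    """Index of the run with the lowest median upper-triangle connectivity.

    Ties resolve to the lowest index.
    """
    if len(runs) == 0:
        raise ValueError("select_run requires at least one run")
    medians = [float(np.median(r.upper_triangle())) for r in runs]
    return int(np.argmin(medians))


def subject_outlier_level(conn: ConnectivityMatrix) -> float:
    """median + 1.5*IQR of the subject's upper-triangle connectivity values."""
    u = conn.upper_triangle()
    q1, q3 = np.percentile(u, [25, 75])
    return float(np.median(u) + 1.5 * (q3 - q1))


def population_threshold(
    matrices: Sequence[ConnectivityMatrix], method: str = "normal"
) -> float:
    """Upper 95% confidence bound of the mean per-subject outlier level.

    Per subject, q_s = median + 1.5*IQR over upper-triangle values; the
    returned threshold is mean(q) + 1.96*sd(q)/sqrt(n) (``method="normal"``),
    or the 97.5th percentile of bootstrap means (``method="bootstrap"``).
    """
    n = len(matrices)
    if n < 2:
        raise ValueError(
            "population_threshold requires >= 2 subjects; for a single subject "
            "pass an explicit per-subject threshold override"
        )
    q = np.array([subject_outlier_level(m) for m in matrices])
    if method == "normal":
        sd = float(q.std(ddof=1))
        return float(q.mean() + 1.96 * sd / np.sqrt(n))
    if method == "bootstrap":
        rng = np.random.default_rng(0)
        means = rng.choice(q, size=(2000, n), replace=True).mean(axis=1)
        return float(np.percentile(means, 97.5))
    raise ValueError(f"unknown threshold method {method!r}")


def apply_threshold(
    conn: ConnectivityMatrix, thr: float, on_abs: bool = False
) -> AdjacencyMatrix:
    """Zero out values below the threshold (all negatives drop by default).

    With ``on_abs=True`` the threshold applies to |v| and the retained weight
    is |v|, for sensitivity analyses on the sign convention.
    """
    if not np.isfinite(thr):
        raise ValueError("threshold must be finite")
    v = conn.values
    if on_abs:
        w = np.where(np.abs(v) >= thr, np.abs(v), 0.0)
    else:
        w = np.where(v >= thr, v, 0.0)
    w = np.where(w > 0, w, 0.0)
    np.fill_diagonal(w, 0.0)
    return AdjacencyMatrix(
        parcel_ids=list(conn.parcel_ids), weights=w, threshold_used=float(thr)
    )
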