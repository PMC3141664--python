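"""Concordance diagnostics: Bland-Altman, correlations, CV profiles, and a
logistic model of detection consistency.

The Bland-Altman (mean-difference) analysis plots, for each region, the
difference between two replicates' measurements against their average;
the limits of agreement are bias +/- 1.96 * SD(differences).  On RNA-seq
expression this is done on the natural log of RPKM, restricted to regions
with non-zero measurements in both replicates.

The logistic model asks what drives inconsistent detection: the response
is 1 when a region is *not* present in all technical replicates, modeled
on abundance (mean RPKM across replicates), region length (bp) and their
interaction, among regions observed in at least one replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, stats


@dataclass(frozen=True)
class BlandAltmanResult:
    pairs: pd.DataFrame  # columns: average, difference
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    scale: str
    n_used: int
    n_excluded_zero: int
    smoother: pd.DataFrame  # columns: average, bias (moving-average curve)


@dataclass(frozen=True)
class LogisticFit:
    coefficients: np.ndarray
    standard_errors: np.ndarray
    names: tuple[str, ...]
    n_iterations: int
    converged: bool
    log_likelihood: float


def bland_altman(
    values_a,
    values_b,
    scale: str = "natural_log",
    smoother_window: int = 101,
) -> BlandAltmanResult:
    """Mean-difference agreement analysis of two paired measurement sets.

    On the ``natural_log`` scale, pairs with a zero in either replicate are
    excluded (no pseudocounts) and reported via ``n_excluded_zero``.  The
    smoother is a centered moving average of the differences ordered by the
    pair average, a deterministic stand-in for a loess curve.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    n_total = a.size
    if scale == "natural_log":
        keep = (a > 0) & (b > 0)
        a, b = np.log(a[keep]), np.log(b[keep])
        n_excluded = n_total - int(keep.sum())
    elif scale == "raw":
        n_excluded = 0
    else:
        raise ValueError(f"unknown scale: {scale!r}")
    if a.size < 2:
        raise ValueError("fewer than 2 retained pairs; SD undefined")
    avg = (a + b) / 2.0
    diff = a - b
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    order = np.argsort(avg, kind="stable")
    w = min(smoother_window, a.size)
    kernel = np.ones(w) / w
    bias = np.convolve(diff[order], kernel, mode="same")
    return BlandAltmanResult(
        pairs=pd.DataFrame({"average": avg, "difference": diff}),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        scale=scale,
        n_used=int(a.size),
        n_excluded_zero=n_excluded,
        smoother=pd.DataFrame({"average": avg[order], "bias": bias}),
    )


def correlations(values_a, values_b) -> tuple[float, float]:
    """(Pearson, Spearman) correlation of paired measurements."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or a.shape != b.shape:
        raise ValueError("need >= 3 pairs of equal length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance input")
    pearson = float(stats.pearsonr(a, b).statistic)
    spearman = float(stats.spearmanr(a, b).statistic)
    return pearson, spearman


def cv_profile(
    quants: pd.DataFrame,
    display_apn_max: float = 1000.0,
    spline_smoothing: float | None = None,
) -> pd.DataFrame:
    """Coefficient of variation versus mean depth, per region, for one lane.

    Rows with apn == 0 (undefined CV) are dropped.  ``display`` flags rows
    with apn <= display_apn_max (high-coverage points are customarily
    omitted from the plot but retained in the table).  A cubic smoothing
    spline of CV on APN is evaluated at the observed APN values
    (``cv_smooth``); the spline is deterministic with smoothing factor
    proportional to the number of points unless overridden.
    """
    df = quants.loc[quants.apn > 0, ["region_id", "apn", "cv"]].copy()
    df = df.sort_values("apn", kind="stable").reset_index(drop=True)
    df["display"] = df.apn <= display_apn_max
    if len(df) >= 4:
        x = df.apn.to_numpy()
        y = df.cv.to_numpy()
        # spline requires strictly increasing x: average CV at tied APN
        grouped = pd.DataFrame({"x": x, "y": y}).groupby("x", sort=True).mean()
        xu = grouped.index.to_numpy()
        yu = grouped.y.to_numpy()
        if len(xu) >= 4:
            s = spline_smoothing if spline_smoothing is not None else len(xu)
            spline = interpolate.UnivariateSpline(xu, yu, k=3, s=s)
            df["cv_smooth"] = spline(x)
        else:
            df["cv_smooth"] = np.nan
    else:
        df["cv_smooth"] = np.nan
    return df


def logistic_irls(
    design: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray, int, bool, float]:
    """Newton / iteratively-reweighted-least-squares logistic fit."""
    n, p = design.shape
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = design @ beta
        eta = np.clip(eta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if w.max() < 1e-12:
            raise ValueError(
                "complete separation detected: fitted probabilities are all "
                "0 or 1 and the likelihood is unbounded"
            )
        xtw = design.T * w
        hessian = xtw @ design
        grad = design.T @ (y - mu)
        try:
            step = np.linalg.solve(hessian, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular design matrix") from exc
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(design @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    if np.all(np.abs(mu - y) < 1e-4):
        raise ValueError(
            "complete separation detected: fitted probabilities reproduce "
            "the responses exactly and coefficients diverge"
        )
    w = mu * (1.0 - mu)
    cov = np.linalg.inv((design.T * w) @ design)
    se = np.sqrt(np.diag(cov))
    ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    return beta, se, it, converged, ll


def fit_detection_logistic(records: pd.DataFrame) -> LogisticFit:
    """Model inconsistent detection as a function of abundance and length.

    ``records`` has one row per region with columns ``y`` (1 if the region
    is not present in all technical replicates), ``abundance`` (mean RPKM
    across replicates) and ``length`` (bp); only regions observed in at
    least one replicate should be included.  Fits
    logit P(y=1) = b0 + b1*abundance + b2*length + b3*abundance*length
    by IRLS (convergence: max coefficient change < 1e-8 or 50 iterations).
    Covariates enter on their raw scales.
    """
    required = {"y", "abundance", "length"}
    if not required.issubset(records.columns):
        raise ValueError(f"records needs columns {sorted(required)}")
    if len(records) <= 10:
        raise ValueError("need more than 10 regions to fit")
    y = records.y.to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("response is constant; model is degenerate")
    a = records.abundance.to_numpy(dtype=float)
    l = records.length.to_numpy(dtype=float)
    design = np.column_stack([np.ones_like(a), a, l, a * l])
    beta, se, it, converged, ll = logistic_irls(design, y)
    return LogisticFit(
        coefficients=beta,
        standard_errors=se,
        names=("intercept", "abundance", "length", "abundance:length"),
        n_iterations=it,
        converged=converged,
        log_likelihood=ll,
    )


def coverage_presence_matrix(
    quants: pd.DataFrame, percentile_buckets: int = 10
) -> pd.DataFrame:
    """Per-region presence/absence across lanes with length percentiles.

    Returns one row per region: a ``detected_<lane>`` flag per lane, the
    mean coverage (APN) across lanes, region length, and the length
    percentile bucket (0 = shortest decile by default).  Rows are sorted by
    length (stable for ties).
    """
    pivot_det = quants.pivot(index="region_id", columns="lane_id", values="detected")
    pivot_apn = quants.pivot(index="region_id", columns="lane_id", values="apn")
    lengths = quants.groupby("region_id")["length"].first()
    out = pivot_det.add_prefix("detected_")
    out["mean_apn"] = pivot_apn.mean(axis=1)
    out["length"] = lengths
    out = out.sort_values("length", kind="stable")
    ranks = out["length"].rank(method="first") - 1
    out["length_percentile_bucket"] = (
        ranks * percentile_buckets // len(out)
    ).astype(int)
    return out.reset_index()
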