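"""Logistic cline regression of binary lineage codings on geography or time.

Each analysis codes the lineage patterns as a binary outcome (a sample
does or does not carry a given lineage, or carries exactly lineage C)
and regresses it on a single predictor — latitude across the peninsula,
longitude across the North, or production year within a macro-region.
The fit is a from-scratch maximum-likelihood logistic regression by
iteratively reweighted least squares (IRLS), reporting the slope with
its Wald test and the 1-df likelihood-ratio model chi-square against the
intercept-only model.

Orientation: latitude enters in raw decimal degrees (north-positive), so
a frequency that rises toward the south appears as a *negative* slope on
latitude; likewise an east-rising frequency is a positive slope on
longitude.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .samples import CODINGS

__all__ = [
    "ClineFit",
    "DegenerateFitError",
    "code_outcome",
    "fit_logistic",
    "run_cline_battery",
    "SUBSETS",
]

#: Named macro-region subsets for the latitude analyses.  Longitude
#: analyses are restricted to the North (the single macro-region with a
#: wide continuous longitudinal span bounded by natural barriers).
SUBSETS: dict[str, tuple[str, ...]] = {
    "Peninsula": ("North", "Central", "South"),
    "Peninsula+Sicily": ("North", "Central", "South", "Sicily"),
    "Peninsula+Sicily+Sardinia": ("North", "Central", "South", "Sicily", "Sardinia"),
    "North": ("North",),
    "Central+South": ("Central", "South"),
}


class DegenerateFitError(ValueError):
    """Raised when a logistic fit is undefined (constant outcome or predictor)."""


@dataclass
class ClineFit:
    """One fitted single-predictor logistic model."""

    coding: str
    predictor: str
    subset: str
    year: str  # "all" for the pooled fit, else the literal year
    n: int
    intercept: float
    slope: float
    se_slope: float
    wald_z: float
    wald_p: float
    lr_chi2: float
    lr_p: float
    converged: bool
    separation: bool
    iterations: int


def code_outcome(
    df: pd.DataFrame, coding: str, multi_lineage: str = "include"
) -> tuple[np.ndarray, pd.DataFrame]:
    """Binary outcome vector for a lineage coding.

    ``multi_lineage="include"``: every sample is eligible and ``y = 1``
    iff the pattern contains the lineage (``contains-X`` codings) or is
    exactly the lineage (``only-X`` codings).

    ``multi_lineage="exclude"``: samples with multi-lineage patterns are
    dropped first; on the remaining single-lineage samples a
    ``contains-X`` coding degenerates to pattern == X.  ``only-X``
    codings always retain all samples (that is what "only" means).

    Returns ``(y, retained_samples)``.
    """
    if coding not in CODINGS:
        raise ValueError(f"unknown coding {coding!r}; choose from {sorted(CODINGS)}")
    if multi_lineage not in ("include", "exclude"):
        raise ValueError("multi_lineage must be 'include' or 'exclude'")
    sub = df
    if multi_lineage == "exclude" and coding.startswith("contains-"):
        sub = df[df["pattern"].str.len() == 1]
    y = sub["pattern"].map(CODINGS[coding]).to_numpy(dtype=float)
    return y, sub


def fit_logistic(
    y: np.ndarray,
    x: np.ndarray,
    *,
    tol: float = 1e-8,
    max_iter: int = 25,
    meta: dict | None = None,
) -> ClineFit:
    """Maximum-likelihood fit of ``logit P(y=1) = b0 + b1*x`` by IRLS.

    Convergence when the relative deviance change drops below ``tol`` or
    after ``max_iter`` iterations (the conventional GLM defaults).
    Reports the Wald z/p for the slope and the likelihood-ratio model
    chi-square (1 df) against the intercept-only model.  Complete or
    quasi-separation (the deviance path heading to an unbounded slope)
    is detected and flagged rather than reported as a spurious estimate.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be one-dimensional and the same length")
    n = y.size
    if n < 3:
        raise DegenerateFitError(f"need at least 3 observations, got {n}")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary (0/1)")
    n1 = y.sum()
    if n1 == 0 or n1 == n:
        raise DegenerateFitError("outcome is constant (all 0 or all 1); fit undefined")
    if np.ptp(x) == 0:
        raise DegenerateFitError("predictor is constant; slope undefined")

    X = np.column_stack([np.ones(n), x])
    pbar = n1 / n
    beta = np.array([np.log(pbar / (1 - pbar)), 0.0])
    dev_null = -2.0 * (n1 * np.log(pbar) + (n - n1) * np.log(1 - pbar))
    dev = dev_null
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = np.clip(mu * (1 - mu), 1e-12, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        try:
            beta = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            separation = True
            break
        eta = X @ beta
        with np.errstate(over="ignore"):
            dev_new = 2.0 * np.sum(np.logaddexp(0.0, eta) - y * eta)
        if np.abs(eta).max() > 30.0 and dev_new < 1e-6:
            # fitted probabilities numerically 0/1 everywhere: separation
            separation = True
            dev = dev_new
            break
        if abs(dev_new - dev) / (0.1 + abs(dev_new)) < tol:
            dev = dev_new
            converged = True
            break
        dev = dev_new

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    w = np.clip(mu * (1 - mu), 1e-12, None)
    cov = np.linalg.inv((X.T * w) @ X)
    se = float(np.sqrt(cov[1, 1]))
    slope = float(beta[1])
    if separation:
        wald_z = wald_p = np.nan
    else:
        wald_z = slope / se
        wald_p = 2.0 * stats.norm.sf(abs(wald_z))
    lr_chi2 = max(dev_null - dev, 0.0)
    lr_p = float(stats.chi2.sf(lr_chi2, df=1))
    meta = meta or {}
    return ClineFit(
        coding=meta.get("coding", ""),
        predictor=meta.get("predictor", ""),
        subset=meta.get("subset", ""),
        year=meta.get("year", "all"),
        n=n,
        intercept=float(beta[0]),
        slope=slope,
        se_slope=se,
        wald_z=float(wald_z),
        wald_p=float(wald_p),
        lr_chi2=float(lr_chi2),
        lr_p=lr_p,
        converged=converged and not separation,
        separation=separation,
        iterations=it,
    )


def _fit_or_skip(y, x, meta) -> ClineFit | None:
    try:
        return fit_logistic(y, x, meta=meta)
    except DegenerateFitError:
        return None


def run_cline_battery(
    df: pd.DataFrame,
    codings: Sequence[str] = ("contains-A", "contains-M", "only-C"),
    latitude_subsets: Sequence[str] = ("Peninsula", "Peninsula+Sicily", "Peninsula+Sicily+Sardinia"),
    per_year: bool = True,
    multi_lineage: str = "include",
    year_cell_min: int = 100,
) -> pd.DataFrame:
    """Run the full battery of single-predictor logistic fits.

    * latitude: one fit per coding x macro-region subset, pooled over
      all years and (optionally) separately per year;
    * longitude: restricted to the North macro-region, pooled and
      per-year;
    * year as predictor: within each macro-region grouping (North and
      Central+South), using only macro-region-by-year cells with more
      than ``year_cell_min`` samples, to limit small-cell sampling bias.

    Degenerate combinations (constant outcome or predictor after
    subsetting) are recorded as skipped rather than failing the run.
    Returns one row per attempted fit; skipped fits carry ``n`` and NaN
    statistics.
    """
    results: list[dict] = []

    def attempt(sub: pd.DataFrame, coding: str, predictor: str, subset: str, year: str):
        y, kept = code_outcome(sub, coding, multi_lineage)
        x = kept[predictor].to_numpy(dtype=float)
        meta = {"coding": coding, "predictor": predictor, "subset": subset, "year": year}
        if len(kept) == 0:
            return
        fit = _fit_or_skip(y, x, meta)
        if fit is None:
            row = {**meta, "n": len(kept), "skipped": True}
        else:
            row = {**asdict(fit), "skipped": False}
        results.append(row)

    years = sorted(df["year"].unique())

    for coding in codings:
        # latitude over peninsular subsets
        for subset in latitude_subsets:
            sub = df[df["macro_region"].isin(SUBSETS[subset])]
            attempt(sub, coding, "latitude", subset, "all")
            if per_year:
                for yr in years:
                    attempt(sub[sub["year"] == yr], coding, "latitude", subset, str(yr))
        # longitude over the North
        north = df[df["macro_region"].isin(SUBSETS["North"])]
        attempt(north, coding, "longitude", "North", "all")
        if per_year:
            for yr in years:
                attempt(north[north["year"] == yr], coding, "longitude", "North", str(yr))
        # year within macro-region groupings, large cells only
        for grouping in ("North", "Central+South"):
            sub = df[df["macro_region"].isin(SUBSETS[grouping])]
            cell_n = sub.groupby("year").size()
            big_years = cell_n[cell_n > year_cell_min].index
            sub = sub[sub["year"].isin(big_years)]
            if sub["year"].nunique() >= 2:
                attempt(sub, coding, "year", grouping, "all")

    out = pd.DataFrame(results)
    # stable column order
    cols = [
        "coding", "predictor", "subset", "year", "n", "intercept", "slope",
        "se_slope", "wald_z", "wald_p", "lr_chi2", "lr_p", "converged",
        "separation", "iterations", "skipped",
    ]
    return out.reindex(columns=cols)
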