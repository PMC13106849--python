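"""Per-beekeeper lineage-diversity series and the Modified Mann-Kendall test.

Each beekeeper contributing honey in several years yields a short time
series of yearly mtDNA lineage diversity: the number of distinct
lineages (1-3) across all of that beekeeper's samples in a year.  A
monotone trend in that series is measured by Kendall's S statistic and
the tie-adjusted rank correlation tau-b; its variance is corrected for
serial autocorrelation with the Hamed-Rao rank-autocorrelation
adjustment (the canonical "Modified Mann-Kendall" test), which is the
appropriate guard for short, potentially dependent series.

Only beekeepers observed in at least four years are trend-eligible.
Kendall statistics depend on order only, so gap years (a beekeeper
skipping a season) are handled simply by calendar-year ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiversitySeries",
    "TauEstimate",
    "MIN_YEARS",
    "build_diversity_series",
    "kendall_S_tau",
    "mmk_corrected_variance",
    "mk_test",
    "trend_table",
]

#: Minimum number of observed years for trend eligibility.
MIN_YEARS = 4

#: Floor applied to the autocorrelation correction factor so the
#: corrected variance stays positive.
CORRECTION_FLOOR = 1e-2


@dataclass(frozen=True)
class DiversitySeries:
    """Yearly lineage-diversity vector of one beekeeper."""

    beekeeper_id: str
    macro_region: str
    years: tuple[int, ...]  # ascending
    values: tuple[int, ...]  # diversity in {1,2,3} per year

    @property
    def n(self) -> int:
        return len(self.years)

    @property
    def trend_eligible(self) -> bool:
        return self.n >= MIN_YEARS


@dataclass
class TauEstimate:
    """Kendall trend statistics for one beekeeper's diversity series."""

    beekeeper_id: str
    macro_region: str
    n: int
    S: int
    tau: float
    var_S: float
    correction: float
    var_S_star: float
    var_tau: float
    z: float
    p: float
    degenerate: bool  # constant series: tau defined as 0


def build_diversity_series(df: pd.DataFrame) -> list[DiversitySeries]:
    """Per-beekeeper yearly diversity: |union of lineages over the year's samples|.

    A beekeeper whose samples in one year are {C} and {A, C} scores 2 for
    that year (the union {A, C}).  All beekeepers are returned (a census);
    filter on :attr:`DiversitySeries.trend_eligible` for trend testing.
    The macro-region attributed to a beekeeper is the most frequent one
    among their samples (ties broken alphabetically).
    """
    series: list[DiversitySeries] = []
    for bk, g in df.groupby("beekeeper_id", sort=True):
        macro = g["macro_region"].mode().sort_values().iloc[0]
        per_year = (
            g.groupby("year")["pattern"]
            .apply(lambda pats: len(set().union(*(set(p) for p in pats))))
            .sort_index()
        )
        series.append(
            DiversitySeries(
                beekeeper_id=str(bk),
                macro_region=str(macro),
                years=tuple(int(y) for y in per_year.index),
                values=tuple(int(v) for v in per_year.values),
            )
        )
    return series


def kendall_S_tau(values: Sequence[float]) -> tuple[int, float, float]:
    """Kendall S, tau-b and the tie-corrected variance of S.

    ``S = sum_{i<j} sign(x_j - x_i)`` over the time-ordered series; tau
    is the tie-adjusted (tau-b) coefficient against time order (time has
    no ties); ``var_S`` uses the standard tie-corrected formula

        var(S) = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18

    over groups of tied values of size ``t``.  A constant series returns
    ``(0, 0.0, 0.0)``: S is zero and tau is defined as 0 by convention.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    diff = np.sign(x[None, :] - x[:, None])
    S = int(np.triu(diff, k=1).sum())

    _, tie_counts = np.unique(x, return_counts=True)
    t = tie_counts.astype(float)
    var_S = (n * (n - 1) * (2 * n + 5) - np.sum(t * (t - 1) * (2 * t + 5))) / 18.0

    D = n * (n - 1) / 2.0
    ties_x = np.sum(t * (t - 1) / 2.0)
    denom = np.sqrt((D - ties_x) * D)  # time order is never tied
    tau = 0.0 if denom == 0 else S / denom
    return S, float(tau), float(var_S)


def _rank_autocorr(ranks: np.ndarray, lag: int) -> float:
    n = ranks.size
    a = ranks[: n - lag] - ranks.mean()
    b = ranks[lag:] - ranks.mean()
    denom = np.sum((ranks - ranks.mean()) ** 2)
    if denom == 0:
        return 0.0
    return float(np.sum(a * b) / denom)


def mmk_corrected_variance(values: Sequence[float], alpha: float = 0.05) -> tuple[float, float]:
    """Hamed-Rao autocorrelation correction of the Mann-Kendall variance.

    Computes lag-i autocorrelations of the rank-transformed series,
    retains the lags significant at level ``alpha`` (two-sided normal
    approximation, SE = 1/sqrt(n)), and inflates/deflates var(S) by

        correction = 1 + 2/(n(n-1)(n-2)) * sum_i (n-i)(n-i-1)(n-i-2) * rho_rank(i)

    over retained lags (only lags <= n-3 carry a nonzero weight).  The
    factor is floored at a small positive value so the corrected
    variance never collapses to zero or below.  Returns
    ``(correction, var_S_star)``.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < MIN_YEARS:
        raise ValueError(f"need at least {MIN_YEARS} observations for the MMK correction")
    _, _, var_S = kendall_S_tau(x)
    if var_S == 0.0:
        return 1.0, 0.0
    ranks = stats.rankdata(x)
    crit = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n)
    acc = 0.0
    for lag in range(1, n - 2):  # weight (n-i)(n-i-1)(n-i-2) vanishes past n-3
        rho = _rank_autocorr(ranks, lag)
        if abs(rho) > crit:
            acc += (n - lag) * (n - lag - 1) * (n - lag - 2) * rho
    correction = 1.0 + 2.0 / (n * (n - 1) * (n - 2)) * acc
    correction = max(correction, CORRECTION_FLOOR)
    return float(correction), float(var_S * correction)


def mk_test(series: DiversitySeries | Sequence[float], *,
            beekeeper_id: str = "", macro_region: str = "",
            tau_variance: str = "untied") -> TauEstimate:
    """Modified Mann-Kendall test on one diversity series.

    Combines the Kendall statistics with the Hamed-Rao variance
    correction; ``z = (S - sign(S)) / sqrt(var_S_star)`` with the
    standard continuity correction.  The variance of tau forwarded to
    the meta-analysis is ``var_S_star / D**2`` with the untied
    denominator ``D = n(n-1)/2`` (default): with heavy ties in short
    1-to-3-valued series the tau-b denominator is unstable.  Pass
    ``tau_variance="tau-b"`` to scale by the tie-adjusted denominator
    instead.

    A constant series is degenerate: tau = 0 and the variance falls back
    to the untied formula ``n(n-1)(2n+5)/18`` so downstream pooling can
    still consume the estimate (with its ``degenerate`` flag set).
    """
    if isinstance(series, DiversitySeries):
        values = series.values
        beekeeper_id = series.beekeeper_id
        macro_region = series.macro_region
    else:
        values = tuple(series)
    n = len(values)
    if n < MIN_YEARS:
        raise ValueError(f"trend testing requires at least {MIN_YEARS} years, got {n}")
    if tau_variance not in ("untied", "tau-b"):
        raise ValueError("tau_variance must be 'untied' or 'tau-b'")

    S, tau, var_S = kendall_S_tau(values)
    D = n * (n - 1) / 2.0
    degenerate = var_S == 0.0
    if degenerate:
        correction = 1.0
        var_S_star = n * (n - 1) * (2 * n + 5) / 18.0  # untied fallback
    else:
        correction, var_S_star = mmk_corrected_variance(values)

    if tau_variance == "untied" or degenerate:
        denom2 = D * D
    else:
        _, tie_counts = np.unique(np.asarray(values, dtype=float), return_counts=True)
        ties = np.sum(tie_counts * (tie_counts - 1) / 2.0)
        denom2 = (D - ties) * D
    var_tau = var_S_star / denom2

    if S == 0:
        z = 0.0
    else:
        z = (S - np.sign(S)) / np.sqrt(var_S_star)
    p = 2.0 * stats.norm.sf(abs(z))
    return TauEstimate(
        beekeeper_id=beekeeper_id,
        macro_region=macro_region,
        n=n,
        S=S,
        tau=tau,
        var_S=var_S,
        correction=correction,
        var_S_star=float(var_S_star),
        var_tau=float(var_tau),
        z=float(z),
        p=float(p),
        degenerate=bool(degenerate),
    )


def trend_table(df: pd.DataFrame, tau_variance: str = "untied") -> pd.DataFrame:
    """Per-beekeeper trend statistics for all trend-eligible beekeepers."""
    rows = [
        asdict(mk_test(s, tau_variance=tau_variance))
        for s in build_diversity_series(df)
        if s.trend_eligible
    ]
    return pd.DataFrame(rows)
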