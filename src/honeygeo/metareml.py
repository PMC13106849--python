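"""Random-effects meta-analysis of per-beekeeper Kendall tau estimates.

Each trend-eligible beekeeper contributes an estimate ``y_i`` (Kendall's
tau of their diversity series) with sampling variance ``v_i``.  The
estimates are pooled per geographic area with a random-effects model

    y_i = x_i' beta + u_i + e_i,   u_i ~ N(0, tau2),  e_i ~ N(0, v_i)

where the moderator is the area coded as dummy variables without an
intercept, so each coefficient is directly its area's pooled mean tau.
The between-beekeeper variance ``tau2`` (named ``tau2_between`` to avoid
colliding with Kendall's tau) is estimated by restricted maximum
likelihood (REML); 95% confidence intervals are normal (Wald) based, with
a Knapp-Hartung t-based adjustment available behind a flag.

Two moderator schemes are supported: the five areas (North, Central,
South, Sicily, Sardinia) or the macro-area grouping that combines
Central and South (North, Central-South, Sicily, Sardinia).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MetaInput",
    "MetaResult",
    "reml_tau2",
    "restricted_loglik",
    "fit_meta",
    "meta_from_trend_table",
    "forest_plot",
]

AREA_SCHEMES = {
    "areas": ("North", "Central", "South", "Sicily", "Sardinia"),
    "macro-areas": ("North", "Central-South", "Sicily", "Sardinia"),
}


@dataclass
class MetaInput:
    """Estimates, sampling variances and one moderator level per estimate."""

    y: np.ndarray
    v: np.ndarray
    level: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if not (self.y.size == self.v.size == len(self.level)):
            raise ValueError("y, v and level must have equal lengths")
        if not np.all(np.isfinite(self.y)) or not np.all(np.isfinite(self.v)):
            raise ValueError("non-finite estimate or variance")
        if np.any(self.v <= 0):
            raise ValueError("all sampling variances must be positive")


@dataclass
class MetaResult:
    """Fitted random-effects model with per-level pooled estimates."""

    scheme: str
    tau2_between: float
    levels: list[str]
    pooled: np.ndarray  # pooled mean tau per level
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    k_per_level: np.ndarray  # contributing-beekeeper counts
    p_per_level: np.ndarray
    k: int
    Q_E: float
    Q_E_df: int
    Q_E_p: float
    singleton_levels: list[str] = field(default_factory=list)

    def forest_rows(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": self.levels,
                "k": self.k_per_level,
                "pooled_tau": self.pooled,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def _design(level: Sequence[str], levels: Sequence[str]) -> np.ndarray:
    X = np.zeros((len(level), len(levels)))
    for i, lv in enumerate(level):
        X[i, levels.index(lv)] = 1.0
    return X


def restricted_loglik(tau2: float, y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """Restricted log-likelihood of the random-effects model at ``tau2``.

    -1/2 [ sum log(v_i + tau2) + log|X' W X| + y' P y ] with
    W = diag(1/(v_i + tau2)) and P the REML projection (constants
    dropped).
    """
    w = 1.0 / (v + tau2)
    XtWX = (X.T * w) @ X
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtWX, (X.T * w) @ y)
    resid = y - X @ beta
    quad = float(np.sum(w * resid**2))
    return -0.5 * (float(np.sum(np.log(v + tau2))) + logdet + quad)


def reml_tau2(
    y: np.ndarray,
    v: np.ndarray,
    X: np.ndarray,
    *,
    tol: float = 1e-12,
) -> float:
    """REML estimate of the between-study variance ``tau2 >= 0``.

    Maximizes the restricted log-likelihood by safeguarded
    one-dimensional search on a bracketing interval, with the boundary
    ``tau2 = 0`` checked explicitly (zero heterogeneity is a frequent
    and perfectly valid solution).
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    X = np.asarray(X, dtype=float)
    k, p = X.shape
    if k <= p:
        raise ValueError(f"need more estimates ({k}) than moderator levels ({p})")
    if np.any(v <= 0) or not np.all(np.isfinite(y)) or not np.all(np.isfinite(v)):
        raise ValueError("invalid inputs: variances must be positive and finite")

    upper = max(10.0 * float(np.var(y)), 10.0 * float(np.max(v)), 1e-3)
    # expand the bracket until the likelihood is decreasing at the top
    while restricted_loglik(upper, y, v, X) > restricted_loglik(0.7 * upper, y, v, X):
        upper *= 4.0
        if upper > 1e8:
            break
    res = optimize.minimize_scalar(
        lambda t2: -restricted_loglik(t2, y, v, X),
        bounds=(0.0, upper),
        method="bounded",
        options={"xatol": tol},
    )
    cand = float(res.x)
    if restricted_loglik(0.0, y, v, X) >= restricted_loglik(cand, y, v, X):
        return 0.0
    return cand


def fit_meta(
    data: MetaInput,
    scheme: str = "macro-areas",
    *,
    knapp_hartung: bool = False,
    conf_level: float = 0.95,
) -> MetaResult:
    """Fit the random-effects model with the area moderator.

    Levels are coded as dummies without intercept, so each coefficient is
    its level's pooled mean tau, weighted by ``1/(v_i + tau2_between)``.
    Confidence intervals are normal (Wald) by default; with
    ``knapp_hartung=True`` the SEs are scaled by the Knapp-Hartung factor
    and t quantiles with ``k - p`` degrees of freedom are used.  Levels
    contributing a single estimate are reported but flagged.
    """
    if scheme not in AREA_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(AREA_SCHEMES)}")
    observed = [lv for lv in AREA_SCHEMES[scheme] if lv in set(data.level)]
    extra = sorted(set(data.level) - set(AREA_SCHEMES[scheme]))
    if extra:
        raise ValueError(f"moderator level(s) {extra} not part of scheme {scheme!r}")
    X = _design(data.level, observed)
    tau2 = reml_tau2(data.y, data.v, X)

    w = 1.0 / (data.v + tau2)
    XtWX = (X.T * w) @ X
    cov = np.linalg.inv(XtWX)
    beta = cov @ (X.T * w) @ data.y
    se = np.sqrt(np.diag(cov))
    k, p = X.shape

    resid = data.y - X @ beta
    if knapp_hartung and k > p:
        s2 = float(np.sum(w * resid**2) / (k - p))
        se = se * np.sqrt(s2)
        q = stats.t.ppf(1 - (1 - conf_level) / 2, df=k - p)
    else:
        q = stats.norm.ppf(1 - (1 - conf_level) / 2)
        s2 = 1.0
    ci_low = beta - q * se
    ci_high = beta + q * se
    if knapp_hartung:
        p_levels = 2 * stats.t.sf(np.abs(beta / se), df=k - p)
    else:
        p_levels = 2 * stats.norm.sf(np.abs(beta / se))

    # residual heterogeneity with fixed-effect weights (standard Q_E)
    w0 = 1.0 / data.v
    XtW0X = (X.T * w0) @ X
    beta0 = np.linalg.solve(XtW0X, (X.T * w0) @ data.y)
    Q_E = float(np.sum(w0 * (data.y - X @ beta0) ** 2))
    df_E = k - p
    Q_E_p = float(stats.chi2.sf(Q_E, df=df_E)) if df_E > 0 else float("nan")

    counts = np.array([sum(lv == obs for lv in data.level) for obs in observed])
    singles = [obs for obs, c in zip(observed, counts) if c == 1]
    return MetaResult(
        scheme=scheme,
        tau2_between=float(tau2),
        levels=observed,
        pooled=beta,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        k_per_level=counts,
        p_per_level=p_levels,
        k=k,
        Q_E=Q_E,
        Q_E_df=df_E,
        Q_E_p=Q_E_p,
        singleton_levels=singles,
    )


def meta_from_trend_table(
    trend: pd.DataFrame,
    scheme: str = "macro-areas",
    *,
    include_degenerate: bool = True,
    knapp_hartung: bool = False,
) -> MetaResult:
    """Pool a per-beekeeper trend table (see :func:`honeygeo.mktrend.trend_table`).

    Maps sample macro-regions onto the moderator scheme (Central and
    South collapse to "Central-South" under the macro-area scheme).
    Degenerate tau estimates from constant series are included by
    default; ``include_degenerate=False`` drops them.
    """
    t = trend
    if not include_degenerate:
        t = t[~t["degenerate"]]
    if len(t) == 0:
        raise ValueError("no usable trend estimates")
    level = list(t["macro_region"])
    if scheme == "macro-areas":
        level = ["Central-South" if lv in ("Central", "South") else lv for lv in level]
    data = MetaInput(t["tau"].to_numpy(), t["var_tau"].to_numpy(), level)
    return fit_meta(data, scheme, knapp_hartung=knapp_hartung)


def forest_plot(result: MetaResult, path: str) -> None:
    """Render the forest plot of pooled tau per area to an image file.

    Dot size is proportional to the number of contributing beekeepers.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = result.forest_rows()
    fig, ax = plt.subplots(figsize=(6, 0.8 * len(rows) + 1.5))
    ypos = np.arange(len(rows))[::-1]
    sizes = 40.0 * rows["k"] / max(rows["k"].max(), 1)
    ax.errorbar(
        rows["pooled_tau"], ypos,
        xerr=np.vstack([rows["pooled_tau"] - rows["ci_low"], rows["ci_high"] - rows["pooled_tau"]]),
        fmt="none", ecolor="0.3", capsize=3,
    )
    ax.scatter(rows["pooled_tau"], ypos, s=20 + sizes**2 / 4, zorder=3, color="tab:blue")
    ax.axvline(0.0, color="0.7", lw=1, ls="--")
    ax.set_yticks(ypos)
    ax.set_yticklabels([f"{lv} (k={k})" for lv, k in zip(rows["level"], rows["k"])])
    ax.set_xlabel("pooled Kendall's tau (95% CI)")
    ax.set_title(f"Random-effects pooling ({result.scheme}), tau2 = {result.tau2_between:.4f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
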