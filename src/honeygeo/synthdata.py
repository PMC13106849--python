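"""Seeded generator of synthetic beekeepers, colonies and honey samples.

The generator reproduces the statistical structure the analyses assume,
so every downstream stage can be exercised without any external data:

* a synthetic "Italy" of five macro-regions (a three-band peninsula plus
  two islands) divided into 20 regions;
* beekeepers with fixed locations, multi-year participation and one to
  nine samples per active year;
* colony-level lineage frequencies following a multinomial-logit surface
  with latitudinal and longitudinal clines and optional yearly drift;
* honey patterns formed as the union of lineages over a pool of
  colonies (default 10-30 per sample), each colony contributing
  independently with probability ``d``.

Colonies are mono-mitotype (one queen, maternal inheritance), so a
colony is simply a categorical lineage label and the individual-bee
lineage frequency equals the colony-level frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .samples import LINEAGES

__all__ = [
    "MacroBox",
    "SimConfig",
    "lineage_frequencies",
    "simulate_honey_sample",
    "simulate_dataset",
    "config_from_yaml",
    "marginal_cline_slope",
    "peninsula_config",
]


@dataclass(frozen=True)
class MacroBox:
    """Coordinate box of one macro-region, split into longitude-strip regions."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    n_regions: int


def _default_geography() -> dict[str, MacroBox]:
    # A stylised Italy: three latitude bands on the peninsula and two
    # offshore boxes; 8 + 4 + 6 + 1 + 1 = 20 regions.
    return {
        "North": MacroBox(44.0, 47.0, 7.0, 14.0, 8),
        "Central": MacroBox(41.5, 44.0, 10.0, 14.0, 4),
        "South": MacroBox(38.0, 41.5, 13.0, 18.0, 6),
        "Sicily": MacroBox(36.5, 38.0, 12.0, 15.5, 1),
        "Sardinia": MacroBox(38.8, 41.3, 8.0, 9.8, 1),
    }


def _default_redundancy() -> tuple[float, ...]:
    # Samples per beekeeper-year, support 1-9.  Mean about 1.4, matching
    # a survey where roughly three-quarters of beekeepers send a single
    # sample and the rest up to nine.
    return (0.75, 0.13, 0.05, 0.03, 0.015, 0.01, 0.008, 0.004, 0.003)


def _default_participation() -> tuple[float, ...]:
    # Number of active years per beekeeper over a six-year survey;
    # roughly a third participate four or more years, which feeds the
    # trend analyses.
    return (0.33, 0.20, 0.15, 0.12, 0.10, 0.10)


def _default_eta_boost() -> dict[str, dict[str, float]]:
    # Island deviations from the continental cline surface: the
    # A-lineage island (an A. m. siciliana analogue) and a second island
    # whose frequencies resemble the North.
    return {"Sicily": {"A": 4.5}, "Sardinia": {"A": -1.5, "M": -1.5}}


@dataclass
class SimConfig:
    """Parameters of the synthetic survey.

    Cline coefficients are on the logit scale of colony-level lineage
    frequency, with lineage C as the reference category (its linear
    predictor is identically zero): ``eta_L = alpha_L + beta_lat_L*lat +
    beta_lon_L*lon + gamma_L*(year - year0)`` and ``(p_A, p_C, p_M) =
    softmax(eta_A, 0, eta_M)``.  Defaults emulate a peninsula where the
    A and M lineages rise southward and westward from low northern
    frequencies, plus a high-A island.
    """

    n_beekeepers: int = 600
    year_min: int = 2018
    year_max: int = 2023
    geography: dict[str, MacroBox] = field(default_factory=_default_geography)
    macro_weights: dict[str, float] = field(
        default_factory=lambda: {
            "North": 0.50,
            "Central": 0.18,
            "South": 0.22,
            "Sicily": 0.05,
            "Sardinia": 0.05,
        }
    )
    # cline coefficients per non-reference lineage
    alpha: dict[str, float] = field(default_factory=lambda: {"A": 7.31, "M": 8.82})
    beta_lat: dict[str, float] = field(default_factory=lambda: {"A": -0.25, "M": -0.28})
    beta_lon: dict[str, float] = field(default_factory=lambda: {"A": -0.10, "M": -0.10})
    gamma: dict[str, float] = field(default_factory=lambda: {"A": 0.0, "M": 0.0})
    #: macro-regions where the yearly drift gamma applies (None = everywhere)
    drift_macros: tuple[str, ...] | None = None
    eta_boost: dict[str, dict[str, float]] = field(default_factory=_default_eta_boost)
    year0: int | None = None  # drift origin; None = year_min
    # pooled-detection law
    k_min: int = 10
    k_max: int = 30
    d: float = 1.0
    redundancy_probs: tuple[float, ...] = field(default_factory=_default_redundancy)
    participation_probs: tuple[float, ...] = field(default_factory=_default_participation)
    #: SD of a beekeeper-level random intercept on the logit scale
    #: (apiary clustering); 0 = colonies i.i.d. given location.
    beekeeper_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("require 1 <= k_min <= k_max")
        if not 0 < self.d <= 1:
            raise ValueError("d must be in (0, 1]")
        if self.year_max < self.year_min:
            raise ValueError("year_max < year_min")
        for name, probs in (
            ("redundancy_probs", self.redundancy_probs),
            ("participation_probs", self.participation_probs),
        ):
            probs = tuple(probs)
            if not probs or any(p < 0 for p in probs) or abs(sum(probs) - 1) > 1e-9:
                raise ValueError(f"{name} must be a probability vector")
        if len(self.participation_probs) > self.year_max - self.year_min + 1:
            raise ValueError("participation support exceeds the simulated year span")

    @property
    def years(self) -> range:
        return range(self.year_min, self.year_max + 1)

    @property
    def drift_origin(self) -> int:
        return self.year_min if self.year0 is None else self.year0


def config_from_yaml(path: str) -> SimConfig:
    """Load a :class:`SimConfig` from a YAML file (missing keys keep defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "geography" in raw:
        raw["geography"] = {m: MacroBox(**box) for m, box in raw["geography"].items()}
    for key in ("redundancy_probs", "participation_probs", "drift_macros"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return SimConfig(**raw)


def _eta(config: SimConfig, lineage: str, lat: float, lon: float, year: int,
         macro: str | None) -> float:
    e = (
        config.alpha.get(lineage, 0.0)
        + config.beta_lat.get(lineage, 0.0) * lat
        + config.beta_lon.get(lineage, 0.0) * lon
    )
    if config.drift_macros is None or macro in config.drift_macros:
        e += config.gamma.get(lineage, 0.0) * (year - config.drift_origin)
    if macro is not None:
        e += config.eta_boost.get(macro, {}).get(lineage, 0.0)
    return e


def lineage_frequencies(
    config: SimConfig,
    latitude: float,
    longitude: float,
    year: int,
    macro_region: str | None = None,
    extra_logit: float = 0.0,
) -> np.ndarray:
    """Colony-level lineage probability vector ``(p_A, p_C, p_M)``.

    Softmax of the per-lineage linear predictors, with C as the reference
    (``eta_C = 0``).  ``extra_logit`` shifts the A and M predictors
    jointly and implements the optional beekeeper-level random intercept.
    Deterministic given its inputs.
    """
    eta = np.array(
        [
            _eta(config, "A", latitude, longitude, year, macro_region) + extra_logit,
            0.0,
            _eta(config, "M", latitude, longitude, year, macro_region) + extra_logit,
        ]
    )
    eta -= eta.max()  # numerical stability
    w = np.exp(eta)
    return w / w.sum()


def simulate_honey_sample(
    config: SimConfig,
    latitude: float,
    longitude: float,
    year: int,
    rng: np.random.Generator,
    macro_region: str | None = None,
    extra_logit: float = 0.0,
) -> str:
    """Simulate one honey sample's lineage pattern (canonical string).

    Draws a pool size ``k ~ DiscreteUniform(k_min, k_max)``, then ``k``
    colony lineages i.i.d. from the local lineage frequencies; each
    colony contributes its lineage to the pooled pattern independently
    with probability ``d``.  An empty union (possible only when
    ``d < 1``) is resolved by redrawing the contribution step, since an
    observed sample always amplifies at least one lineage.
    """
    p = lineage_frequencies(config, latitude, longitude, year, macro_region, extra_logit)
    k = int(rng.integers(config.k_min, config.k_max + 1))
    counts = rng.multinomial(k, p)
    if config.d >= 1.0:
        contrib = counts
    else:
        contrib = rng.binomial(counts, config.d)
        while contrib.sum() == 0:
            contrib = rng.binomial(counts, config.d)
    return "".join(l for l, c in zip(LINEAGES, contrib) if c > 0)


def _region_of(box: MacroBox, macro: str, lon: float) -> str:
    if box.n_regions == 1:
        return macro
    width = (box.lon_max - box.lon_min) / box.n_regions
    i = min(int((lon - box.lon_min) / width), box.n_regions - 1)
    return f"{macro}-{i + 1}"


def simulate_dataset(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Simulate a full survey table with the standard sample schema.

    Beekeepers are placed uniformly inside their macro-region's box and
    keep the same location in every year (geocoding by municipality, no
    transhumance).  Each beekeeper is active in a contiguous run of
    years drawn from the participation law, and sends a number of
    samples per active year drawn from the redundancy law.  Fully
    reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    macros = list(config.geography)
    weights = np.array([config.macro_weights.get(m, 0.0) for m in macros], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("macro_weights assign no mass to the configured macro-regions")
    weights = weights / weights.sum()
    n_years = config.year_max - config.year_min + 1

    rows: list[dict[str, object]] = []
    sample_no = 0
    for b in range(config.n_beekeepers):
        bk_id = f"BK{b:05d}"
        macro = macros[rng.choice(len(macros), p=weights)]
        box = config.geography[macro]
        lat = float(rng.uniform(box.lat_min, box.lat_max))
        lon = float(rng.uniform(box.lon_min, box.lon_max))
        region = _region_of(box, macro, lon)
        bk_effect = (
            float(rng.normal(0.0, config.beekeeper_sigma)) if config.beekeeper_sigma > 0 else 0.0
        )
        n_active = int(rng.choice(len(config.participation_probs), p=config.participation_probs)) + 1
        start = int(rng.integers(0, n_years - n_active + 1))
        for year in range(config.year_min + start, config.year_min + start + n_active):
            n_samples = int(rng.choice(len(config.redundancy_probs), p=config.redundancy_probs)) + 1
            for _ in range(n_samples):
                pattern = simulate_honey_sample(
                    config, lat, lon, year, rng, macro_region=macro, extra_logit=bk_effect
                )
                rows.append(
                    {
                        "sample_id": f"H{sample_no:06d}",
                        "beekeeper_id": bk_id,
                        "year": year,
                        "latitude": round(lat, 5),
                        "longitude": round(lon, 5),
                        "region": region,
                        "macro_region": macro,
                        "pattern": pattern,
                    }
                )
                sample_no += 1
    columns = [
        "sample_id",
        "beekeeper_id",
        "year",
        "latitude",
        "longitude",
        "region",
        "macro_region",
        "pattern",
    ]
    return pd.DataFrame(rows, columns=columns)


def marginal_cline_slope(
    config: SimConfig,
    lat_lo: float,
    lat_hi: float,
    longitude: float = 11.0,
    lineage: str = "A",
    n_grid: int = 2001,
) -> tuple[float, float]:
    """Population-level logistic slope of a pooled contains-lineage cline.

    The probability that a honey sample contains a lineage is the pooled
    detection probability, which is not exactly logistic in latitude even
    when the colony-level frequency is.  This computes the KL projection
    of the generator's true detection curve (over a uniform latitude
    distribution) onto the single-predictor logistic family — the
    parameter a logistic fit converges to as the sample grows — by
    minimizing the expected negative log-likelihood on a fine grid.
    Returns ``(intercept, slope)``.
    """
    from scipy import optimize

    from . import poolmodel

    idx = LINEAGES.index(lineage)
    lats = np.linspace(lat_lo, lat_hi, n_grid)
    law = poolmodel.uniform_pool_law(config.k_min, config.k_max)
    q = np.array(
        [
            poolmodel.expected_detect_prob(
                lineage_frequencies(config, la, longitude, config.year_min)[idx], law, config.d
            )
            for la in lats
        ]
    )

    def nll(b: np.ndarray) -> float:
        eta = b[0] + b[1] * lats
        return float(np.mean(np.logaddexp(0.0, eta) - q * eta))

    res = optimize.minimize(nll, x0=np.zeros(2), method="BFGS")
    return float(res.x[0]), float(res.x[1])


def peninsula_config(**overrides) -> SimConfig:
    """Convenience configuration restricted to the three peninsular bands.

    Useful for calibration experiments on the latitudinal cline where
    islands would only add off-surface deviations.
    """
    geo = {m: b for m, b in _default_geography().items() if m in ("North", "Central", "South")}
    weights = {"North": 0.5, "Central": 0.2, "South": 0.3}
    cfg = SimConfig(geography=geo, macro_weights=weights, eta_boost={})
    return replace(cfg, **overrides) if overrides else cfg
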