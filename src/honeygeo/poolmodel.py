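"""Analytic model of pooled-eDNA lineage detection.

Honey is a pooled sample: it carries DNA from every colony that
contributed to it, so a lineage present in *any* contributing colony can
amplify.  If a lineage is carried by a fraction ``p`` of colonies, each
pool draws ``k`` colonies independently, and each carrier amplifies with
probability ``d``, the probability that the pooled pattern contains the
lineage is

    P(detect) = 1 - (1 - p * d) ** k

which always exceeds the per-colony (equivalently per-bee, for
mono-mitotype colonies) frequency ``p * d``.  The ratio of pooled to
individual detection frequency is the *inflation factor* that makes
honey a more sensitive monitor of rare lineages than sampling individual
bees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .samples import round_half_up

__all__ = [
    "PoolDetection",
    "detect_prob",
    "expected_detect_prob",
    "inflation_factor",
    "uniform_pool_law",
]


@dataclass(frozen=True)
class PoolDetection:
    """Detection probability of one lineage in one pooled sample."""

    p: float  # colony-level lineage frequency
    k: int  # pool size (number of contributing colonies)
    d: float  # per-colony detection probability
    detect_prob: float


def _check_prob(x: float, name: str, *, positive: bool = False) -> float:
    x = float(x)
    lo_ok = x > 0 if positive else x >= 0
    if not (lo_ok and x <= 1) or not np.isfinite(x):
        bound = "(0, 1]" if positive else "[0, 1]"
        raise ValueError(f"{name} must be in {bound}, got {x}")
    return x


def detect_prob(p: float, k: int, d: float = 1.0) -> float:
    """Probability that a pool of ``k`` colonies contains the lineage.

    ``p`` is the colony-level lineage frequency and ``d`` the per-colony
    detection (amplification) probability.  ``k`` must be a positive
    integer: a pool of zero colonies is not a sample.
    """
    p = _check_prob(p, "p")
    d = _check_prob(d, "d", positive=True)
    if isinstance(k, bool) or int(k) != k or k < 1:
        raise ValueError(f"pool size k must be a positive integer, got {k!r}")
    return 1.0 - (1.0 - p * d) ** int(k)


def uniform_pool_law(k_min: int = 10, k_max: int = 30) -> dict[int, float]:
    """Discrete-uniform pool-size distribution on ``{k_min, ..., k_max}``.

    The default 10-30 range reflects the number of colonies a typical
    commercial honey sample draws on.
    """
    if k_min < 1 or k_max < k_min:
        raise ValueError("require 1 <= k_min <= k_max")
    n = k_max - k_min + 1
    return {k: 1.0 / n for k in range(k_min, k_max + 1)}


def expected_detect_prob(p: float, pool_law: Mapping[int, float], d: float = 1.0) -> float:
    """Detection probability averaged over a pool-size distribution.

    ``pool_law`` maps pool sizes to probabilities and must sum to one over
    positive integers.
    """
    p = _check_prob(p, "p")
    d = _check_prob(d, "d", positive=True)
    if not pool_law:
        raise ValueError("pool_law is empty")
    total = float(sum(pool_law.values()))
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"pool_law probabilities sum to {total}, not 1")
    acc = 0.0
    for k, w in pool_law.items():
        if w < 0:
            raise ValueError("pool_law has a negative probability")
        acc += w * detect_prob(p, k, d)
    return acc


def inflation_factor(honey_freq: float, bee_freq: float) -> float:
    """Ratio of honey-sample to individual-bee detection frequency.

    Quantifies the extra sensitivity of the pooled matrix: a lineage at
    individual-bee frequency ``bee_freq`` appears in a larger fraction
    ``honey_freq`` of honey samples.  Reported rounded to two decimals,
    the convention used when comparing honey and bee surveys.
    """
    if bee_freq <= 0:
        raise ValueError("bee_freq must be positive; the ratio is undefined at 0")
    if honey_freq < 0:
        raise ValueError("honey_freq must be non-negative")
    return round_half_up(honey_freq / bee_freq, 2)
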