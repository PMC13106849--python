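"""Within-year consistency of the samples a beekeeper provides.

Beekeepers who send several honey samples in the same production year
give a replicate view of their apiaries.  Each such beekeeper-year is
classified by whether every sample shows the same exact lineage pattern
("consistent") or not ("different patterns"); consistent beekeeper-years
are further labelled by the shared pattern, with "all only-C" the
dominant category in practice.  Consistency means identical exact
patterns, not merely overlapping lineages.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

__all__ = ["BeekeeperYearSummary", "classify_consistency", "consistency_by_year"]

DIFFERENT = "different patterns"


@dataclass(frozen=True)
class BeekeeperYearSummary:
    """Classification of one beekeeper-year with at least two samples."""

    beekeeper_id: str
    year: int
    n_samples: int
    classification: str  # "different patterns" or "all <pattern>"


def classify_consistency(df: pd.DataFrame) -> list[BeekeeperYearSummary]:
    """Classify every beekeeper-year with >= 2 samples.

    Beekeeper-years with a single sample carry no replication signal and
    never enter the denominator.  A beekeeper-year is "different
    patterns" iff at least two distinct exact patterns occur among its
    samples; otherwise it is labelled ``"all only-C"`` when the shared
    pattern is exactly C, else ``"all <pattern>"``.
    """
    out: list[BeekeeperYearSummary] = []
    for (bk, year), g in df.groupby(["beekeeper_id", "year"], sort=True):
        if len(g) < 2:
            continue
        pats = set(g["pattern"])
        if len(pats) > 1:
            label = DIFFERENT
        else:
            (pat,) = pats
            label = "all only-C" if pat == "C" else f"all {pat}"
        out.append(BeekeeperYearSummary(str(bk), int(year), len(g), label))
    return out


def consistency_by_year(df: pd.DataFrame) -> pd.DataFrame:
    """Per-year proportions of each consistency classification.

    One row per (year, classification) with the count and the proportion
    of that year's multi-sample beekeepers; proportions within a year
    sum to one.
    """
    summaries = classify_consistency(df)
    if not summaries:
        return pd.DataFrame(columns=["year", "classification", "count", "proportion"])
    t = pd.DataFrame([asdict(s) for s in summaries])
    counts = (
        t.groupby(["year", "classification"], sort=True).size().rename("count").reset_index()
    )
    totals = counts.groupby("year")["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    return counts
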