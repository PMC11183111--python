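"""Divergence-time age structure of floras and between-landform contrasts.

A flora's mean divergence time (MDT) is the arithmetic mean of its
species' ages; MDT_oldest and MDT_youngest restrict that mean to the
oldest and youngest age quartiles.  Landform groups are compared with
two-sided independent-samples t tests and the usual significance-star
bins.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: star bins, most significant first: (threshold, symbol)
STAR_BINS = ((1e-5, "****"), (1e-4, "***"), (1e-3, "**"), (0.05, "*"))


@dataclass(frozen=True)
class AgeQuartileSpec:
    """Which fraction of the sorted ages enters the tail means.

    ``count = max(1, ceil(fraction * n))`` species are averaged from each
    end, so the tail means are defined for any nonempty flora.
    """

    fraction: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction <= 0.5):
            raise ValueError("fraction must lie in (0, 0.5]")

    def count(self, n: int) -> int:
        return max(1, math.ceil(self.fraction * n))


def mdt_stats(ages, spec: AgeQuartileSpec = AgeQuartileSpec()
              ) -> tuple[float, float, float]:
    """(MDT, MDT_oldest, MDT_youngest) for one flora's species ages."""
    ages = np.asarray(list(ages), dtype=float)
    if ages.size == 0:
        raise ValueError("ages must be nonempty")
    if (ages < 0).any():
        raise ValueError("ages must be nonnegative")
    m = spec.count(ages.size)
    srt = np.sort(ages)  # stable ascending; ties keep input order
    return float(ages.mean()), float(srt[-m:].mean()), float(srt[:m].mean())


def mdt_table(ages_by_site: dict[str, "np.ndarray"],
              spec: AgeQuartileSpec = AgeQuartileSpec()) -> pd.DataFrame:
    """MDT statistics for many floras, one row per site."""
    rows = {site: mdt_stats(a, spec) for site, a in ages_by_site.items()}
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["MDT", "MDT_oldest", "MDT_youngest"]
    )


def stars(p: float) -> str:
    for threshold, symbol in STAR_BINS:
        if p < threshold:
            return symbol
    return "ns"


def pairwise_group_tests(values, groups, welch: bool = False) -> pd.DataFrame:
    """t test every unordered pair of groups on one metric column.

    Pooled-variance (Student) t by default, with ``df = n1 + n2 - 2``;
    ``welch=True`` switches to the unequal-variance test.  Groups with
    fewer than two members are skipped with a warning.  Returns a tidy
    table with columns group1, group2, t, df, p, stars.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    labels = []
    for g in pd.unique(groups):
        if (groups == g).sum() < 2:
            logger.warning("group %r has <2 members; skipped", g)
        else:
            labels.append(g)
    if len(labels) < 2:
        raise ValueError("need at least two groups with >=2 members")
    rows = []
    for g1, g2 in itertools.combinations(labels, 2):
        a, b = values[groups == g1], values[groups == g2]
        res = stats.ttest_ind(a, b, equal_var=not welch)
        df = float(res.df)
        p = float(res.pvalue)
        rows.append({"group1": g1, "group2": g2, "t": float(res.statistic),
                     "df": df, "p": p, "stars": stars(p)})
    return pd.DataFrame(rows)
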