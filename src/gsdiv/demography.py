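"""Demographic parameters: cohort-size ratios, effective number of parents,
and bootstrap confidence intervals.

The effective number of bulls for a selection regime summarises how evenly
sires contribute offspring:

    Ne = 1 / sum_i p_i**2,    p_i = o_i / sum_j o_j,

with o_i the offspring count of bull i.  Ne equals the census number n
under perfectly even use and collapses towards 1 when a single elite bull
dominates; the Ne/n ratio is the usual headline figure.  Uncertainty is
quantified by resampling bulls (rows) with replacement — percentile
bootstrap — and two regimes are called different when their 95% intervals
do not overlap (touching intervals count as overlapping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree

#: birth-year windows of the two selection regimes: progeny testing (PTS)
#: and genomic selection (GS).  The GS window for Ne ends in 2014 (younger
#: bulls have incomplete offspring records), distinct from the 2012-2015
#: trend window.
PTS_YEARS = (2005, 2010)
GS_YEARS_NE = (2012, 2014)


def cohort_ratio(
    counts_by_year: dict[int, int] | pd.Series, reference_year: int = 2005
) -> pd.Series:
    """S_i = N_i / N_reference for every year in ``counts_by_year``."""
    counts = pd.Series(counts_by_year).sort_index()
    if reference_year not in counts.index:
        raise ValueError(f"reference year {reference_year} absent from counts")
    ref = counts[reference_year]
    if ref <= 0:
        raise ValueError(f"reference year {reference_year} has count {ref}")
    out = counts / ref
    out.name = "S_i"
    return out


def contributions_from_pedigree(
    ped: Pedigree,
    group_years: dict[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Offspring counts per sire, grouped by the sire's birth-year regime.

    Counts every pedigree record naming the bull as sire.  ``group_years``
    maps regime label -> inclusive (first, last) birth year of the *sire*;
    defaults to PTS 2005-2010 and GS 2012-2014.  Sires born outside every
    window are dropped.  Columns: id, offspring, group, birth_year.
    """
    if group_years is None:
        group_years = {"PTS": PTS_YEARS, "GS": GS_YEARS_NE}
    n = len(ped)
    counts = np.zeros(n, dtype=np.int64)
    for k in range(n):
        s = ped.sire[k]
        if s != UNKNOWN:
            counts[s] += 1
    years = pd.Series(ped.birth_date).dt.year
    rows = []
    for k in range(n):
        y = years.iloc[k]
        if pd.isna(y):
            continue
        for label, (lo, hi) in group_years.items():
            if lo <= y <= hi:
                rows.append((ped.ids[k], int(counts[k]), label, int(y)))
                break
    return pd.DataFrame(rows, columns=["id", "offspring", "group", "birth_year"])


def effective_number(contrib: pd.DataFrame, group: str | None = None) -> float:
    """Ne = 1 / sum p_i^2 over offspring-contribution proportions p_i."""
    o = _group_counts(contrib, group)
    total = o.sum()
    if total <= 0:
        raise ValueError("all offspring counts are zero; Ne undefined")
    p = o / total
    return float(1.0 / np.sum(p**2))


def _group_counts(contrib: pd.DataFrame, group: str | None) -> np.ndarray:
    df = contrib
    if group is not None:
        df = contrib[contrib["group"] == group]
        if df.empty:
            raise ValueError(f"no rows for group {group!r}")
    return df["offspring"].to_numpy(dtype=float)


@dataclass
class NeEstimate:
    """Point estimate with census count and a bootstrap interval."""

    Ne: float
    n: int
    ratio: float
    ci_low: float
    ci_high: float
    B: int
    seed: int
    statistic: str = "Ne"


def bootstrap_ci(
    contrib: pd.DataFrame,
    group: str | None = None,
    statistic: str = "Ne",
    B: int = 1000,
    seed: int = 0,
) -> NeEstimate:
    """Percentile bootstrap 95% interval for Ne or Ne/n.

    Bulls (rows) are resampled with replacement B times; the statistic is
    recomputed on each resample.  Fully determined by ``seed``.
    """
    if statistic not in ("Ne", "Ne/n"):
        raise ValueError(f"unknown statistic {statistic!r}")
    o = _group_counts(contrib, group)
    n = o.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    res = o[idx]  # (B, n)
    totals = res.sum(axis=1)
    ok = totals > 0
    p = res[ok] / totals[ok, None]
    ne_star = 1.0 / np.sum(p**2, axis=1)
    if statistic == "Ne/n":
        ne_star = ne_star / n
    lo, hi = np.percentile(ne_star, [2.5, 97.5])
    point = effective_number(contrib, group)
    if statistic == "Ne/n":
        point_stat = point / n
    else:
        point_stat = point
    return NeEstimate(
        Ne=point,
        n=n,
        ratio=point / n,
        ci_low=float(lo),
        ci_high=float(hi),
        B=B,
        seed=seed,
        statistic=statistic,
    )


@dataclass
class GroupComparison:
    a: NeEstimate
    b: NeEstimate
    different: bool


def compare_groups(
    contrib: pd.DataFrame,
    statistic: str = "Ne",
    groups: tuple[str, str] = ("PTS", "GS"),
    B: int = 1000,
    seed: int = 0,
) -> GroupComparison:
    """Bootstrap intervals for two regimes and the non-overlap verdict.

    Intervals that merely touch are treated as overlapping (conservative),
    so the verdict is True only for strictly disjoint intervals.
    """
    est_a = bootstrap_ci(contrib, groups[0], statistic, B=B, seed=seed)
    est_b = bootstrap_ci(contrib, groups[1], statistic, B=B, seed=seed + 1)
    different = est_a.ci_high < est_b.ci_low or est_b.ci_high < est_a.ci_low
    return GroupComparison(est_a, est_b, different)
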