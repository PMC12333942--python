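"""Cell-type densities per region and the rank-based comparisons on them.

Densities are counts per mm² of analyzed tissue, one record per
(region, phenotype).  Group comparisons use the two-sided Wilcoxon rank-sum
test (exact enumeration for small untied samples, normal approximation with
tie and continuity correction otherwise) and the Kruskal-Wallis test for
more than two groups.  Density tests apply no multiple-testing correction —
a Benjamini-Hochberg helper is provided for users who want one.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .geometry import RegionSet

logger = logging.getLogger(__name__)

#: switch from exact enumeration to the normal approximation above this n
EXACT_N_MAX = 12


def cell_density(
    cells: pd.DataFrame,
    regions: RegionSet,
    phenotype_col: str = "phenotype",
    phenotypes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-(region, phenotype) densities in cells per mm².

    Every phenotype observed anywhere (or declared via ``phenotypes``)
    appears in every region with count 0 where absent, so per-region counts
    sum to the region's cell total.
    """
    if not set(cells["region_id"]).issubset(set(regions.ids)):
        unknown = set(cells["region_id"]) - set(regions.ids)
        raise ValueError(f"cells reference unknown regions: {sorted(unknown)}")
    observed = set(cells[phenotype_col].astype(str).unique())
    phenotypes = sorted(observed | set(phenotypes or ()))
    counts = (
        cells.groupby(["region_id", phenotype_col], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    records = []
    for region in regions:
        area = region.area_mm2
        if area <= 0:
            raise ValueError(f"region {region.region_id!r} has zero area")
        row = (
            counts.loc[region.region_id]
            if region.region_id in counts.index
            else pd.Series(0, index=phenotypes)
        )
        for ph in phenotypes:
            n = int(row.get(ph, 0))
            records.append(
                {
                    "region_id": region.region_id,
                    "region_class": region.region_class,
                    "phenotype": ph,
                    "count": n,
                    "area_mm2": area,
                    "density": n / area,
                }
            )
    return pd.DataFrame(records)


def density_ratio(
    records: pd.DataFrame, numerator: str, denominator: str
) -> pd.Series:
    """Per-region density ratio of two phenotypes.

    A zero-density denominator yields a missing value (with a logged
    warning), never infinity.
    """
    for ph in (numerator, denominator):
        if ph not in set(records["phenotype"]):
            raise ValueError(f"unknown phenotype {ph!r}")
    wide = records.pivot(index="region_id", columns="phenotype", values="density")
    num = wide[numerator]
    den = wide[denominator]
    zero = den == 0
    if zero.any():
        logger.warning(
            "density_ratio: zero %s density in regions %s — ratio undefined",
            denominator,
            list(wide.index[zero]),
        )
    ratio = num / den.where(~zero)
    ratio.name = f"{numerator}/{denominator}"
    return ratio


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def compare_groups(
    values_by_group: Mapping | Sequence[Sequence[float]],
    test: str = "wilcoxon",
) -> tuple[float, float]:
    """Two-sided rank test between groups of (density) values.

    ``wilcoxon`` (two groups): exact enumeration when both n ≤ 12 and the
    pooled sample has no ties, otherwise the normal approximation with tie
    and continuity correction.  ``kruskal`` (≥ 2 groups): chi-square
    approximation with tie correction.  Returns ``(statistic, p)``; when all
    values coincide the test is degenerate and p = 1.
    """
    if isinstance(values_by_group, Mapping):
        groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    else:
        groups = [np.asarray(v, dtype=float) for v in values_by_group]

    if test == "wilcoxon":
        if len(groups) != 2:
            raise ValueError("wilcoxon compares exactly 2 groups")
        x, y = groups
        if len(x) < 2 or len(y) < 2:
            raise ValueError("need >= 2 observations per group")
        pooled = np.concatenate([x, y])
        if np.all(pooled == pooled[0]):
            return float(len(x) * len(y) / 2), 1.0
        method = (
            "exact"
            if len(x) <= EXACT_N_MAX and len(y) <= EXACT_N_MAX and not _has_ties(pooled)
            else "asymptotic"
        )
        res = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=True
        )
        return float(res.statistic), float(min(res.pvalue, 1.0))

    if test == "kruskal":
        if len(groups) < 2:
            raise ValueError("kruskal needs >= 2 groups")
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            return 0.0, 1.0
        res = scipy.stats.kruskal(*groups)
        return float(res.statistic), float(res.pvalue)

    raise ValueError(f"unknown test {test!r}")


def compare_marker_expression(
    cells: pd.DataFrame,
    marker: str,
    group_labels: Sequence,
) -> tuple[float, float]:
    """Rank-sum comparison of per-cell (transformed) marker intensity.

    Two groups use the Wilcoxon rank-sum; more than two fall back to
    Kruskal-Wallis.  Empty groups are an error.
    """
    if marker not in cells.columns:
        raise ValueError(f"marker {marker!r} not in cell table")
    labels = np.asarray(group_labels)
    values = cells[marker].to_numpy(dtype=float)
    groups = {g: values[labels == g] for g in pd.unique(labels)}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(v) == 0 for v in groups.values()):
        raise ValueError("empty group")
    return compare_groups(groups, test="wilcoxon" if len(groups) == 2 else "kruskal")


def adjust_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (opt-in; density tests default raw)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
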