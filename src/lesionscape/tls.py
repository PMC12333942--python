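"""Lymphoid-aggregate detection, lesion association, and maturity scoring.

Aggregates are detected by density-based clustering of lymphoid cells,
associated to the nearest lesion boundary under a distance rule (250 μm by
default), profiled for lymphoid composition, and classified as mature when
they hold a germinal-centre B-cell core (CD20+CD21+CD23+ cells that are both
numerous enough and interior to the aggregate hull).  Densities of
follicular dendritic cells (DCSIGN+) and high endothelial venules (PDPN+)
are reported as supporting maturity metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Point, Polygon
from sklearn.cluster import DBSCAN

from .geometry import UM2_PER_MM2, RegionSet

logger = logging.getLogger(__name__)

#: phenotype labels counted as lymphoid for aggregate detection/composition
LYMPHOID_PHENOTYPES = frozenset(
    {
        "T", "T_CD4", "T_CD8", "Treg", "T_cytotoxic", "T_exhausted",
        "T_central_memory", "T_memory_CD57",
        "B", "B_GC", "B_proliferating",
    }
)

#: lesion classes a TLS may be associated with
LESION_CLASSES = ("PanIN", "PDAC", "CP")


@dataclass
class TLSRecord:
    """One detected lymphoid aggregate and everything measured on it."""

    tls_id: str
    member_cell_ids: np.ndarray
    hull_vertices: np.ndarray
    hull_area_mm2: float
    lesion_class: str = "unassociated"
    boundary_distance_um: float = float("nan")
    composition: dict = field(default_factory=dict)
    maturity: str = "unclassified"
    metrics: dict = field(default_factory=dict)

    @property
    def hull(self) -> Polygon:
        return Polygon(self.hull_vertices)

    @property
    def n_cells(self) -> int:
        return len(self.member_cell_ids)


def detect_aggregates(
    cells: pd.DataFrame,
    eps_um: float = 40.0,
    min_samples: int = 10,
    min_cells: int = 50,
    lymphoid: frozenset = LYMPHOID_PHENOTYPES,
    phenotype_col: str = "phenotype",
) -> list[TLSRecord]:
    """Density-cluster lymphoid cells into candidate aggregates.

    DBSCAN with core radius ``eps_um`` and ``min_samples`` runs over
    lymphoid cells only; clusters of at least ``min_cells`` become
    aggregates with a convex-hull boundary.  The default 40 μm reach (a 3-4
    lymphocyte neighbourhood) makes the sparsest aggregate the pipeline is
    expected to resolve — roughly 200 cells in a 150 μm disc — carry ~14
    expected neighbours per cell, comfortably above ``min_samples``, so such
    aggregates detect as single clusters; all three thresholds are
    configuration, not biological claims.  Deterministic given input order.
    """
    if eps_um <= 0:
        raise ValueError("eps_um must be > 0")
    lymph = cells[cells[phenotype_col].isin(lymphoid)]
    if len(lymph) == 0:
        logger.info("detect_aggregates: no lymphoid cells")
        return []
    xy = lymph[["x_um", "y_um"]].to_numpy(dtype=float)
    labels = DBSCAN(eps=eps_um, min_samples=min_samples).fit_predict(xy)

    records: list[TLSRecord] = []
    for lab in sorted(set(labels) - {-1}):
        mask = labels == lab
        if mask.sum() < min_cells:
            continue
        members = lymph.loc[mask]
        hull = MultiPoint(xy[mask]).convex_hull
        if not isinstance(hull, Polygon):
            logger.info("skipping degenerate (collinear) aggregate %d", lab)
            continue
        records.append(
            TLSRecord(
                tls_id=f"tls_{len(records):02d}",
                member_cell_ids=members["cell_id"].to_numpy()
                if "cell_id" in members.columns
                else members.index.to_numpy(),
                hull_vertices=np.asarray(hull.exterior.coords)[:-1],
                hull_area_mm2=hull.area / UM2_PER_MM2,
            )
        )
    return records


def associate_tls(
    tls: TLSRecord,
    regions: RegionSet,
    max_dist_um: float = 250.0,
    lesion_classes: tuple[str, ...] = LESION_CLASSES,
) -> TLSRecord:
    """Assign the nearest qualifying lesion within ``max_dist_um``, else exclude.

    Distance is hull boundary to lesion polygon boundary (zero when they
    touch or overlap).  Near-exact ties resolve to the earlier region in the
    region set, with a log note.
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    hull = tls.hull
    best: tuple[float, str] | None = None
    for region in regions:
        if region.region_class not in lesion_classes:
            continue
        d = float(hull.distance(region.polygon))
        if best is None or d < best[0] - 1e-9:
            best = (d, region.region_id, region.region_class)
        elif best is not None and abs(d - best[0]) <= 1e-6:
            logger.info(
                "TLS %s equidistant to %s and %s; keeping %s (region order)",
                tls.tls_id, best[1], region.region_id, best[1],
            )
    if best is None or best[0] > max_dist_um:
        tls.lesion_class = "excluded"
        tls.boundary_distance_um = float("nan") if best is None else best[0]
    else:
        tls.lesion_class = best[2]
        tls.boundary_distance_um = best[0]
    return tls


def tls_composition(
    tls: TLSRecord,
    cells: pd.DataFrame,
    lymphoid: frozenset = LYMPHOID_PHENOTYPES,
    phenotype_col: str = "phenotype",
) -> dict[str, float]:
    """Fraction of each lymphoid phenotype among the aggregate's members.

    Fractions are over lymphoid members only and sum to one; the
    non-lymphoid share of members is reported separately in
    ``tls.metrics['nonlymphoid_frac']``.
    """
    members = _member_table(tls, cells)
    lymph = members[members[phenotype_col].isin(lymphoid)]
    if len(lymph) == 0:
        raise ValueError(f"{tls.tls_id}: no lymphoid members")
    frac = (lymph[phenotype_col].value_counts() / len(lymph)).to_dict()
    tls.composition = frac
    # members come from lymphoid-only clustering, so the non-lymphoid share
    # is measured over all cells falling inside the hull
    inside = _cells_in_hull(tls, cells)
    n_lymph_inside = int(inside[phenotype_col].isin(lymphoid).sum())
    tls.metrics["nonlymphoid_frac"] = (
        1.0 - n_lymph_inside / len(inside) if len(inside) else 0.0
    )
    return frac


def classify_maturity(
    tls: TLSRecord,
    cells: pd.DataFrame,
    gc_min_cells: int = 10,
    gc_phenotype: str = "B_GC",
    dendritic_phenotype: str = "Dendritic",
    hev_phenotype: str = "Endothelial_HEV",
    erosion_frac: float = 0.10,
    phenotype_col: str = "phenotype",
) -> TLSRecord:
    """Mature ⇔ a numerous, interior germinal-centre B-cell population.

    The call requires at least ``gc_min_cells`` germinal-centre B members
    (strict ≥) whose centroid lies inside the hull eroded by
    ``erosion_frac`` of the equivalent hull radius — a computable proxy for
    a distinct germinal-centre zone.  Densities of GC B cells, dendritic
    cells and HEV (per mm² of hull), and a B/T radial separation index, are
    reported regardless of the call.
    """
    members = _member_table(tls, cells)
    hull = tls.hull
    area = tls.hull_area_mm2
    r_eq = float(np.sqrt(hull.area / np.pi))

    gc = members[members[phenotype_col] == gc_phenotype]
    n_gc = len(gc)
    interior = False
    if n_gc > 0:
        centroid = Point(gc["x_um"].mean(), gc["y_um"].mean())
        eroded = hull.buffer(-erosion_frac * r_eq)
        if eroded.is_empty:
            eroded = hull
        interior = bool(shapely.covers(eroded, centroid))

    # dendritic cells and HEV are not lymphoid, hence never clustering
    # members: count them spatially within the hull
    inside = _cells_in_hull(tls, cells)
    tls.maturity = "mature" if (n_gc >= gc_min_cells and interior) else "immature"
    tls.metrics.update(
        {
            "gc_count": n_gc,
            "gc_density_per_mm2": n_gc / area,
            "gc_interior": interior,
            "dendritic_density_per_mm2": int(
                (inside[phenotype_col] == dendritic_phenotype).sum()
            ) / area,
            "hev_density_per_mm2": int(
                (inside[phenotype_col] == hev_phenotype).sum()
            ) / area,
            "bt_separation_index": _bt_separation(members, hull, r_eq, phenotype_col),
        }
    )
    return tls


def _bt_separation(
    members: pd.DataFrame, hull: Polygon, r_eq: float, phenotype_col: str
) -> float:
    """Mean radial position of T minus B members, in equivalent-radius units.

    Positive when T cells sit peripherally around a B core (the mature
    zonation); reported as a metric, never used in the maturity call.
    """
    c = hull.centroid
    xy = members[["x_um", "y_um"]].to_numpy(dtype=float)
    r = np.hypot(xy[:, 0] - c.x, xy[:, 1] - c.y)
    is_b = members[phenotype_col].str.startswith("B").to_numpy()
    is_t = members[phenotype_col].str.startswith("T").to_numpy()
    if not is_b.any() or not is_t.any() or r_eq == 0:
        return float("nan")
    return float((r[is_t].mean() - r[is_b].mean()) / r_eq)


def profile_tls(
    cells: pd.DataFrame,
    regions: RegionSet,
    max_dist_um: float = 250.0,
    **detect_kwargs,
) -> list[TLSRecord]:
    """Detect, associate, profile, and classify every aggregate in one pass."""
    records = detect_aggregates(cells, **detect_kwargs)
    for rec in records:
        associate_tls(rec, regions, max_dist_um=max_dist_um)
        tls_composition(rec, cells)
        classify_maturity(rec, cells)
    return records


def tls_table(records: list[TLSRecord]) -> pd.DataFrame:
    """One row per aggregate with association, composition, and metrics."""
    rows = []
    for r in records:
        row = {
            "tls_id": r.tls_id,
            "n_cells": r.n_cells,
            "hull_area_mm2": r.hull_area_mm2,
            "lesion_class": r.lesion_class,
            "boundary_distance_um": r.boundary_distance_um,
            "maturity": r.maturity,
        }
        row.update({f"metric_{k}": v for k, v in r.metrics.items()})
        row.update({f"frac_{k}": v for k, v in sorted(r.composition.items())})
        rows.append(row)
    return pd.DataFrame(rows)


def _member_table(tls: TLSRecord, cells: pd.DataFrame) -> pd.DataFrame:
    if "cell_id" in cells.columns:
        return cells[cells["cell_id"].isin(tls.member_cell_ids)]
    return cells.loc[tls.member_cell_ids]


def _cells_in_hull(tls: TLSRecord, cells: pd.DataFrame) -> pd.DataFrame:
    hull = tls.hull
    x0, y0, x1, y1 = hull.bounds
    box = cells[
        cells["x_um"].between(x0, x1) & cells["y_um"].between(y0, y1)
    ]
    if len(box) == 0:
        return box
    pts = shapely.points(box[["x_um", "y_um"]].to_numpy())
    return box[shapely.covers(hull, pts)]
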