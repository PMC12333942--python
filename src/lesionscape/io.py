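"""Readers and writers for the on-disk formats the pipeline exchanges.

Cell tables travel as CSV, region boundaries as GeoJSON, spot matrices as
10x-style MatrixMarket triplets (matrix.mtx + genes.tsv + barcodes.tsv +
positions.csv), gene sets as GMT, and ground truth / manifests as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import gseapy
from shapely.geometry import mapping, shape

from .geometry import RegionPolygon, RegionSet


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, index=False)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_regions_geojson(regions: RegionSet, path: str | Path) -> None:
    features = []
    for r in regions:
        from shapely.geometry import Polygon

        features.append(
            {
                "type": "Feature",
                "geometry": mapping(Polygon(r.vertices)),
                "properties": {"region_id": r.region_id, "class": r.region_class},
            }
        )
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_regions_geojson(path: str | Path) -> RegionSet:
    payload = json.loads(Path(path).read_text())
    regions = []
    for feat in payload["features"]:
        geom = shape(feat["geometry"])
        props = feat.get("properties", {})
        regions.append(
            RegionPolygon(
                region_id=str(props.get("region_id", len(regions))),
                region_class=str(props.get("class", "unknown")),
                vertices=np.asarray(geom.exterior.coords)[:-1],
            )
        )
    return RegionSet(regions)


def write_hulls_geojson(hulls: dict[str, np.ndarray], path: str | Path) -> None:
    """Write convex hulls (id -> (n, 2) vertex array) as a FeatureCollection."""
    from shapely.geometry import Polygon

    features = [
        {
            "type": "Feature",
            "geometry": mapping(Polygon(v)),
            "properties": {"tls_id": k},
        }
        for k, v in hulls.items()
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def write_spot_matrix_dir(spots, out_dir: str | Path) -> None:
    """Write a SpotMatrix as matrix.mtx / genes.tsv / barcodes.tsv / positions.csv.

    The counts matrix is written gene × spot.  Composition fractions and
    segment ids ride along in positions.csv.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = scipy.sparse.csr_matrix(np.asarray(spots.counts))
    scipy.io.mmwrite(str(out / "matrix.mtx"), counts)
    pd.Series(spots.genes).to_csv(out / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(spots.barcodes).to_csv(
        out / "barcodes.tsv", sep="\t", index=False, header=False
    )
    pos = spots.positions.copy()
    pos.insert(0, "barcode", spots.barcodes)
    if spots.composition is not None:
        for col in spots.composition.columns:
            pos[f"frac_{col}"] = spots.composition[col].to_numpy()
    if spots.segment_id is not None:
        pos["segment_id"] = np.asarray(spots.segment_id)
    pos.to_csv(out / "positions.csv", index=False)


def read_spot_matrix_dir(in_dir: str | Path):
    """Read a SpotMatrix written by :func:`write_spot_matrix_dir`."""
    from .st_patterns import SpotMatrix

    d = Path(in_dir)
    counts = np.asarray(scipy.io.mmread(str(d / "matrix.mtx")).todense())
    genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    pos = pd.read_csv(d / "positions.csv")
    frac_cols = [c for c in pos.columns if c.startswith("frac_")]
    composition = None
    if frac_cols:
        composition = pos[frac_cols].rename(
            columns={c: c.removeprefix("frac_") for c in frac_cols}
        )
    segment_id = pos["segment_id"] if "segment_id" in pos.columns else None
    return SpotMatrix(
        counts=counts,
        genes=genes,
        barcodes=barcodes,
        positions=pos[["array_row", "array_col", "x_um", "y_um"]].reset_index(drop=True),
        composition=composition,
        segment_id=None if segment_id is None else segment_id.reset_index(drop=True),
    )


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT gene sets (name → member list), via gseapy's parser."""
    return gseapy.read_gmt(str(path))


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path) -> None:
    """Write gene sets in GMT (name, description, members, tab-separated)."""
    lines = [
        "\t".join([name, "lesionscape"] + list(members))
        for name, members in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, set):
        return sorted(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
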