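"""Configuration-driven end-to-end runs of the proteomic and transcriptomic arms.

Each arm reads its inputs (or synthesizes the bundled demo), runs the full
module chain, writes tidy CSV/JSON artifacts into an output directory, and
records a manifest with SHA-256 checksums so reruns at a fixed seed can be
verified bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from . import synthetic
from .density_stats import cell_density, compare_groups, density_ratio
from .geometry import HexLattice, RegionSet
from .phenotyping import load_gates, phenotype_cells
from .spatial_interaction import (
    interaction_matrix,
    interaction_network,
    normalize_contacts,
    top2_neighbor_matrix,
)
from .st_patterns import (
    SpotMatrix,
    compare_tls_classes,
    cp10k_log2,
    filter_spots,
    fit_nmf,
    fractional_expression,
    gsea_preranked,
    label_tls_spots,
    log_transform,
    module_score,
    pattern_marker_scores,
    pattern_vs_module,
)
from .tls import profile_tls, tls_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, thresholds, and seeds for a pipeline run.

    File paths may be omitted, in which case the bundled synthetic demo is
    generated in place.  Defaults match the module-level defaults
    throughout.
    """

    out_dir: str = "lesionscape_out"
    seed: int = 0
    # proteomic inputs
    cells_csv: str | None = None
    regions_geojson: str | None = None
    gates_yaml: str | None = None
    # transcriptomic inputs
    counts_dir: str | None = None
    tls_geojson: str | None = None
    genesets_gmt: str | None = None
    # thresholds
    cofactor: float = 5.0
    band_um: float = 250.0
    min_frac: float = 0.01
    eps_um: float = 30.0
    min_samples: int = 10
    min_cells: int = 50
    gc_min_cells: int = 10
    depth: int = 2
    K: int = 3
    alpha: float = 0.01
    n_perm: int = 200
    positivity_quantile: float = 0.75
    use_model_thresholds: bool = True  # demo runs gate at the generator midpoint

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out: Path, artifacts: list[Path]) -> Path:
    manifest = {
        p.name: {"sha256": _sha256(p), "bytes": p.stat().st_size}
        for p in sorted(artifacts)
    }
    path = out / "manifest.json"
    lio.write_json(manifest, path)
    return path


def simulate(config: RunConfig) -> dict[str, Path]:
    """Write the bundled synthetic demo inputs into ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells, regions, truth = synthetic.generate_cell_map(
        synthetic.demo_tissue_config(config.seed)
    )
    lio.write_cell_table(cells, out / "cells.csv")
    lio.write_regions_geojson(regions, out / "regions.geojson")
    lio.write_json(truth.to_dict(), out / "cell_ground_truth.json")
    spots, hulls, _, gene_sets = _demo_spot_inputs(config)
    lio.write_spot_matrix_dir(spots, out / "spots")
    _, struth = synthetic.generate_spot_data(
        synthetic.default_visium_config(config.seed, K=config.K)
    )
    lio.write_json(struth.to_dict(), out / "spot_ground_truth.json")
    lio.write_hulls_geojson(hulls, out / "tls_hulls.geojson")
    lio.write_gmt(gene_sets, out / "gene_sets.gmt")
    logger.info("simulate: wrote demo inputs to %s", out)
    return {"cells": out / "cells.csv", "spots": out / "spots"}


def run_proteomic_arm(config: RunConfig) -> dict[str, Path]:
    """Phenotyping → densities/tests → interactions → TLS profiling.

    Returns a mapping of artifact names to paths; a ``manifest.json`` with
    checksums accompanies every run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rules = load_gates(config.gates_yaml)

    if config.cells_csv is None:
        cfg = synthetic.demo_tissue_config(config.seed)
        cells, regions, _ = synthetic.generate_cell_map(cfg)
        thresholds = (
            cfg.marker_model.threshold(config.cofactor)
            if config.use_model_thresholds
            else None
        )
    else:
        cells = lio.read_cell_table(config.cells_csv)
        if len(cells) == 0:
            raise ValueError("proteomic arm: empty cell table")
        if config.regions_geojson is None:
            raise ValueError("proteomic arm: cells_csv given without regions_geojson")
        regions = lio.read_regions_geojson(config.regions_geojson)
        thresholds = None
    if len(cells) == 0:
        raise ValueError("proteomic arm: empty cell table")

    cells = phenotype_cells(
        cells,
        rules,
        cofactor=config.cofactor,
        thresholds=thresholds,
        q=config.positivity_quantile,
    )

    artifacts: list[Path] = []

    densities = cell_density(cells, regions)
    p = out / "densities.csv"
    densities.to_csv(p, index=False)
    artifacts.append(p)

    # unadjusted pairwise rank-sum tests of per-region density by lesion class
    rows = []
    for ph, sub in densities.groupby("phenotype"):
        by_class = {
            cls: grp["density"].to_numpy()
            for cls, grp in sub.groupby("region_class")
        }
        for a, b in combinations(sorted(by_class), 2):
            if len(by_class[a]) < 2 or len(by_class[b]) < 2:
                continue
            stat, pval = compare_groups({a: by_class[a], b: by_class[b]})
            rows.append(
                {"phenotype": ph, "group_a": a, "group_b": b,
                 "statistic": stat, "p": pval}
            )
    p = out / "density_tests.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    artifacts.append(p)

    if {"T_CD8", "Treg"}.issubset(set(densities["phenotype"])):
        ratio = density_ratio(densities, "T_CD8", "Treg")
        p = out / "cd8_treg_ratio.csv"
        ratio.to_frame().to_csv(p)
        artifacts.append(p)

    im = interaction_matrix(cells, min_frac=config.min_frac)
    p = out / "interaction_matrix.csv"
    im.M.to_csv(p)
    artifacts.append(p)
    edges, _ = interaction_network(im)
    p = out / "interaction_network_edges.csv"
    edges.to_csv(p, index=False)
    artifacts.append(p)

    contacts = top2_neighbor_matrix(cells, min_frac=config.min_frac)
    p = out / "top2_contacts.csv"
    contacts.N.to_csv(p)
    artifacts.append(p)
    p = out / "top2_contacts_normalized.csv"
    normalize_contacts(contacts, cells).to_csv(p)
    artifacts.append(p)

    records = profile_tls(
        cells,
        regions,
        max_dist_um=config.band_um,
        eps_um=config.eps_um,
        min_samples=config.min_samples,
        min_cells=config.min_cells,
    )
    p = out / "tls_table.csv"
    tls_table(records).to_csv(p, index=False)
    artifacts.append(p)
    if records:
        p = out / "tls_hulls.geojson"
        lio.write_hulls_geojson({r.tls_id: r.hull_vertices for r in records}, p)
        artifacts.append(p)
        members = pd.concat(
            [
                pd.DataFrame(
                    {"tls_id": r.tls_id, "cell_id": r.member_cell_ids}
                )
                for r in records
            ]
        )
        p = out / "tls_members.csv"
        members.to_csv(p, index=False)
        artifacts.append(p)

    manifest = _write_manifest(out, artifacts)
    logger.info("proteomic arm: %d artifacts in %s", len(artifacts), out)
    return {a.name: a for a in artifacts} | {"manifest.json": manifest}


def run_transcriptomic_arm(config: RunConfig) -> dict[str, Path]:
    """Spot QC → TLS labels → NMF → markers → module score → stats → GSEA."""
    if config.depth < 1:
        raise ValueError("neighbor expansion depth must be >= 1")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.counts_dir is None:
        spots, hulls, signature, gene_sets = _demo_spot_inputs(config)
    else:
        spots = lio.read_spot_matrix_dir(config.counts_dir)
        hulls = {}
        if config.tls_geojson:
            rs = lio.read_regions_geojson(config.tls_geojson)
            hulls = {r.region_id: r.vertices for r in rs}
        gene_sets = (
            lio.read_gmt(config.genesets_gmt) if config.genesets_gmt else {}
        )
        signature = next(iter(gene_sets.values()), None)

    if spots.composition is not None:
        spots, removal_log = filter_spots(spots)
        removal_log.to_csv(out / "spot_removals.csv", index=False)
    if spots.n_spots == 0:
        raise ValueError("transcriptomic arm: all spots filtered out")

    lattice = HexLattice(
        int(spots.positions["array_row"].max()) + 1,
        int(spots.positions["array_col"].max()) + 1,
    )
    if hulls:
        spots = label_tls_spots(spots, hulls, lattice, depth=config.depth)
    labels = (
        spots.labels
        if spots.labels is not None
        else pd.Series(["other"] * spots.n_spots)
    )
    label_class = labels.str.replace(r"TLS:.*", "TLS", regex=True)

    artifacts: list[Path] = []

    D = log_transform(spots.counts)
    decomp = fit_nmf(
        D, config.K, alpha=config.alpha, seed=config.seed, n_restarts=3
    )
    weights = pd.DataFrame(
        decomp.P.T,
        index=spots.barcodes,
        columns=[f"pattern_{k}" for k in range(config.K)],
    )
    weights["label"] = labels.to_numpy()
    p = out / "pattern_weights.csv"
    weights.to_csv(p, index_label="barcode")
    artifacts.append(p)

    f, T = fractional_expression(decomp)
    markers = pattern_marker_scores(
        f, T, genes=spots.genes, patterns=list(weights.columns[: config.K])
    )
    p = out / "pattern_markers.csv"
    markers.to_frame().to_csv(p, index=False)
    artifacts.append(p)

    # TLS-coupled pattern = highest mean weight in TLS spots
    tls_mask = label_class.to_numpy() == "TLS"
    if tls_mask.any():
        mean_w = decomp.P[:, tls_mask].mean(axis=1)
        tls_pattern = int(np.argmax(mean_w))
    else:
        tls_pattern = 0

    summary: dict = {"tls_pattern": f"pattern_{tls_pattern}"}
    if signature:
        score = module_score(
            cp10k_log2(spots.counts), spots.genes, signature, seed=config.seed
        )
        p = out / "module_scores.csv"
        pd.DataFrame(
            {"barcode": spots.barcodes, "score": score.scores, "label": labels}
        ).to_csv(p, index=False)
        artifacts.append(p)
        r, r2, pval = pattern_vs_module(decomp.P[tls_pattern], score.scores)
        summary["pattern_vs_module"] = {"pearson_r": r, "R2": r2, "p": pval}

    if label_class.nunique() >= 2 and (label_class.value_counts() >= 2).sum() >= 2:
        kw, pairwise = compare_tls_classes(
            decomp.P[tls_pattern], label_class.to_numpy()
        )
        summary["kruskal_wallis"] = {"statistic": kw[0], "p": kw[1]}
        p = out / "pattern_class_tests.csv"
        pairwise.to_csv(p, index=False)
        artifacts.append(p)

    if gene_sets:
        gsea_all = []
        for k in range(config.K):
            scores = markers.z[f"pattern_{k}"].dropna()
            res = gsea_preranked(
                scores, gene_sets, n_perm=config.n_perm, seed=config.seed
            )
            res.insert(0, "pattern", f"pattern_{k}")
            gsea_all.append(res)
        p = out / "gsea.csv"
        pd.concat(gsea_all).to_csv(p, index=False)
        artifacts.append(p)

    p = out / "summary.json"
    lio.write_json(summary, p)
    artifacts.append(p)

    manifest = _write_manifest(out, artifacts)
    logger.info("transcriptomic arm: %d artifacts in %s", len(artifacts), out)
    return {a.name: a for a in artifacts} | {"manifest.json": manifest}


def _demo_spot_inputs(config: RunConfig):
    """Synthesize demo spot inputs: counts, TLS hulls, signature, gene sets."""
    vcfg = synthetic.default_visium_config(config.seed, K=config.K)
    spots, truth = synthetic.generate_spot_data(vcfg)
    # uniform stroma composition: the QC path is exercised, nothing drops;
    # no segment ids, so segment-level UMI QC (which would discard sparse
    # single-pattern demos wholesale) stays out of the demo's way
    spots.composition = pd.DataFrame(
        {"stroma": np.ones(spots.n_spots), "non_tissue": np.zeros(spots.n_spots)}
    )

    # hulls drawn around the planted TLS spots recover them by point-in-polygon
    from shapely.geometry import MultiPoint

    xy = spots.positions[["x_um", "y_um"]].to_numpy()[truth.tls_spots]
    hull = MultiPoint(xy).convex_hull.buffer(30.0, quad_segs=8)
    hulls = {"demo": np.asarray(hull.exterior.coords)[:-1]}

    rng = np.random.default_rng(config.seed + 1)
    gene_sets = {"planted_signature": list(truth.signature_genes)}
    anchors = [g for g, _ in (truth.gene_patterns or {}).items()]
    for i in range(3):
        gene_sets[f"random_set_{i}"] = list(
            rng.choice([g for g in spots.genes if g not in anchors], 20, replace=False)
        )
    return spots, hulls, list(truth.signature_genes), gene_sets
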