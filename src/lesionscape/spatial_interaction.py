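"""Nearest-neighbour interaction matrices and top-2 contact matrices.

``interaction_matrix`` summarizes, for every ordered phenotype pair (A, B),
the mean distance from a cell of type A to its nearest cell of type B
(self-excluded on the diagonal).  ``top2_neighbor_matrix`` counts, over each
cell's two nearest neighbours, how often each phenotype pair is in contact.
Phenotypes below an abundance fraction (1% by default) are excluded before
computation.  Nearest-neighbour queries use a k-d tree and match the O(n²)
definition exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)


@dataclass
class InteractionMatrix:
    """Mean nearest-neighbour distances (μm) per ordered phenotype pair."""

    M: pd.DataFrame  # rows: focal type A, cols: target type B
    abundance: pd.Series  # retained-type cell counts

    @property
    def phenotypes(self) -> list:
        return list(self.M.index)


@dataclass
class NeighborContactMatrix:
    """Top-2 neighbour contact counts per (focal, neighbour) phenotype pair."""

    N: pd.DataFrame
    abundance: pd.Series
    normalized: pd.DataFrame | None = None


def _retained_types(
    cells: pd.DataFrame, min_frac: float, phenotype_col: str
) -> list:
    if not 0 <= min_frac < 1:
        raise ValueError("min_frac must be in [0, 1)")
    counts = cells[phenotype_col].value_counts()
    frac = counts / counts.sum()
    kept = sorted(frac.index[frac >= min_frac])
    dropped = sorted(set(counts.index) - set(kept))
    if dropped:
        logger.info(
            "excluding %d phenotypes below %.1f%% abundance: %s",
            len(dropped), 100 * min_frac, dropped,
        )
    return kept


def interaction_matrix(
    cells: pd.DataFrame,
    min_frac: float = 0.01,
    phenotype_col: str = "phenotype",
) -> InteractionMatrix:
    """Mean distance from each type-A cell to its nearest type-B cell.

    The diagonal uses the nearest *other* cell of the same type; a retained
    type with a single cell gets a missing diagonal entry (logged).
    """
    if len(cells) < 2:
        raise ValueError("need >= 2 cells")
    types = _retained_types(cells, min_frac, phenotype_col)
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    labels = cells[phenotype_col].to_numpy()

    idx = {t: np.flatnonzero(labels == t) for t in types}
    trees = {t: cKDTree(xy[idx[t]]) for t in types}
    M = pd.DataFrame(np.nan, index=types, columns=types, dtype=float)
    for a in types:
        pts = xy[idx[a]]
        for b in types:
            if a == b:
                if len(idx[a]) < 2:
                    logger.info(
                        "single %r cell: diagonal entry undefined", a
                    )
                    continue
                d, _ = trees[b].query(pts, k=2)
                M.loc[a, b] = float(d[:, 1].mean())
            else:
                d, _ = trees[b].query(pts, k=1)
                M.loc[a, b] = float(d.mean())
    abundance = pd.Series({t: len(idx[t]) for t in types}, name="n_cells")
    return InteractionMatrix(M=M, abundance=abundance)


def interaction_network(
    im: InteractionMatrix,
) -> tuple[pd.DataFrame, nx.Graph]:
    """Undirected network with edge length = symmetrized mean distance.

    Edge length between A and B is ``(M[A][B] + M[B][A]) / 2``; node weight
    is the type's abundance.  Returns a tidy edge list and the graph.
    """
    types = im.phenotypes
    G = nx.Graph()
    for t in types:
        G.add_node(t, weight=int(im.abundance[t]))
    rows = []
    for i, a in enumerate(types):
        for b in types[i:]:
            if a == b:
                length = im.M.loc[a, a]
            else:
                length = (im.M.loc[a, b] + im.M.loc[b, a]) / 2
            if np.isnan(length):
                continue
            rows.append(
                {
                    "source": a,
                    "target": b,
                    "mean_distance_um": float(length),
                    "weight": int(im.abundance[a]),
                }
            )
            G.add_edge(a, b, mean_distance_um=float(length))
    return pd.DataFrame(rows), G


def top2_neighbor_matrix(
    cells: pd.DataFrame,
    min_frac: float = 0.01,
    phenotype_col: str = "phenotype",
) -> NeighborContactMatrix:
    """Contact counts over each cell's two nearest neighbours.

    For every retained cell, its two nearest other retained cells (Euclidean
    distance, ties broken by smaller cell_id) each increment
    ``N[type(cell)][type(neighbour)]``, so the row sum of type A is
    ``2 * n_A``.
    """
    types = _retained_types(cells, min_frac, phenotype_col)
    kept = cells[cells[phenotype_col].isin(types)]
    if len(kept) < 3:
        raise ValueError("need >= 3 cells after abundance exclusion")
    xy = kept[["x_um", "y_um"]].to_numpy(dtype=float)
    labels = kept[phenotype_col].to_numpy()
    cell_ids = (
        kept["cell_id"].to_numpy()
        if "cell_id" in kept.columns
        else np.arange(len(kept))
    )

    tree = cKDTree(xy)
    k = min(len(kept), 8)  # headroom so distance ties can be id-ordered
    dists, nbrs = tree.query(xy, k=k)
    N = pd.DataFrame(0, index=types, columns=types, dtype=int)
    for i in range(len(kept)):
        cand = [
            (dists[i, j], cell_ids[nbrs[i, j]], nbrs[i, j])
            for j in range(k)
            if nbrs[i, j] != i
        ]
        cand.sort(key=lambda t: (t[0], t[1]))
        for _, _, j in cand[:2]:
            N.loc[labels[i], labels[j]] += 1
    abundance = pd.Series(
        {t: int((labels == t).sum()) for t in types}, name="n_cells"
    )
    return NeighborContactMatrix(N=N, abundance=abundance)


def normalize_contacts(
    contacts: NeighborContactMatrix,
    region_cells: pd.DataFrame,
    phenotype_col: str = "phenotype",
    mode: str = "max_phenotype",
) -> pd.DataFrame:
    """Normalize contact counts by the region's dominant phenotype count.

    ``max_phenotype`` (default) divides by the cell count of the most
    abundant phenotype among ``region_cells``; ``max_entry`` divides by the
    largest matrix entry instead.  Either way the entry ranking is preserved.
    """
    if mode == "max_phenotype":
        if len(region_cells) == 0:
            raise ValueError("region has no cells")
        denom = int(region_cells[phenotype_col].value_counts().iloc[0])
    elif mode == "max_entry":
        denom = int(contacts.N.to_numpy().max())
        if denom == 0:
            raise ValueError("contact matrix is all zero")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    normalized = contacts.N / denom
    contacts.normalized = normalized
    return normalized
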