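"""Marker-intensity transforms, positivity gating, and phenotype assignment.

Intensities are variance-stabilized with the mass-cytometry arcsinh
transform, thresholded into a per-cell positivity matrix, and converted to
phenotype labels by ordered boolean gates (e.g. a regulatory T cell is
CD4+FOXP3+PD1-).  A k-means clustering path with gate-based cluster
annotation is provided for panel-level exploration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

#: columns of a cell table that are never marker intensities
RESERVED_COLUMNS = {
    "cell_id", "x_um", "y_um", "region_id", "phenotype", "cluster_id",
    "true_phenotype", "band", "tls_id", "label",
}

UNASSIGNED = "unassigned"


def marker_columns(table: pd.DataFrame) -> list[str]:
    """Marker columns of a cell table (everything non-reserved and numeric)."""
    return [
        c
        for c in table.columns
        if c not in RESERVED_COLUMNS and pd.api.types.is_numeric_dtype(table[c])
    ]


def transform_intensities(
    table: pd.DataFrame, cofactor: float = 5.0, markers: Sequence[str] | None = None
) -> pd.DataFrame:
    """arcsinh(x / cofactor) on every marker column; order-preserving.

    The cofactor default of 5 is the mass-cytometry convention.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be > 0")
    markers = list(markers) if markers is not None else marker_columns(table)
    out = table.copy()
    vals = out[markers].to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative marker intensity")
    out[markers] = np.arcsinh(vals / cofactor)
    return out


def call_positivity(
    table: pd.DataFrame,
    thresholds: Mapping[str, float] | float | None = None,
    q: float = 0.75,
    markers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Boolean positivity matrix: transformed intensity > threshold.

    ``thresholds`` may be a scalar, a per-marker mapping, or None — in which
    case the per-marker threshold is the quantile ``q`` of the intensity over
    all cells (a constant marker column then thresholds at that constant and
    calls every cell negative).
    """
    markers = list(markers) if markers is not None else marker_columns(table)
    vals = table[markers].to_numpy(dtype=float)
    if thresholds is None:
        if not 0 < q < 1:
            raise ValueError("q must be in (0, 1)")
        thr = np.quantile(vals, q, axis=0)
    elif isinstance(thresholds, Mapping):
        missing = [m for m in markers if m not in thresholds]
        if missing:
            raise ValueError(f"no threshold for markers {missing}")
        thr = np.array([thresholds[m] for m in markers], dtype=float)
    else:
        thr = np.full(len(markers), float(thresholds))
    return pd.DataFrame(vals > thr[None, :], index=table.index, columns=markers)


@dataclass(frozen=True)
class GatingRule:
    """A phenotype gate: all ``positive`` markers true, all ``negative`` false."""

    name: str
    positive: frozenset = frozenset()
    negative: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "positive", frozenset(self.positive))
        object.__setattr__(self, "negative", frozenset(self.negative))
        if self.positive & self.negative:
            raise ValueError(f"gate {self.name!r}: positive and negative overlap")

    @property
    def specificity(self) -> int:
        return len(self.positive) + len(self.negative)


def order_gates(rules: Sequence[GatingRule]) -> list[GatingRule]:
    """More-specific gates first; ties keep declaration order (stable sort)."""
    return sorted(rules, key=lambda r: -r.specificity)


def load_gates(path: str | Path | None = None) -> list[GatingRule]:
    """Load gates from YAML (``gates: [{name, positive, negative}, ...]``).

    Without a path, the bundled default panel (every phenotype used in the
    human analysis) is loaded.
    """
    if path is None:
        text = (
            resources.files("lesionscape").joinpath("data/gates.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    payload = yaml.safe_load(text)
    rules = [
        GatingRule(
            name=str(g["name"]),
            positive=frozenset(g.get("positive", [])),
            negative=frozenset(g.get("negative", [])),
        )
        for g in payload["gates"]
    ]
    names = [r.name for r in rules]
    if len(set(names)) != len(names):
        raise ValueError("gate names must be unique")
    return rules


def apply_gates(
    positivity: pd.DataFrame, rules: Sequence[GatingRule]
) -> pd.Series:
    """First matching gate (in the given order) wins; no match → unassigned.

    Labels depend on the boolean matrix only, so row permutations commute
    with labelling.
    """
    for rule in rules:
        unknown = (rule.positive | rule.negative) - set(positivity.columns)
        if unknown:
            raise ValueError(
                f"gate {rule.name!r} references unknown markers {sorted(unknown)}"
            )
    labels = np.full(len(positivity), UNASSIGNED, dtype=object)
    unset = np.ones(len(positivity), dtype=bool)
    vals = positivity.to_numpy(dtype=bool)
    col = {m: i for i, m in enumerate(positivity.columns)}
    for rule in rules:
        match = unset.copy()
        for m in rule.positive:
            match &= vals[:, col[m]]
        for m in rule.negative:
            match &= ~vals[:, col[m]]
        labels[match] = rule.name
        unset &= ~match
    return pd.Series(labels, index=positivity.index, name="phenotype")


def phenotype_cells(
    table: pd.DataFrame,
    rules: Sequence[GatingRule] | None = None,
    cofactor: float = 5.0,
    thresholds: Mapping[str, float] | float | None = None,
    q: float = 0.75,
    markers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Transform → positivity → ordered gates, returning a labelled table."""
    rules = order_gates(rules if rules is not None else load_gates())
    t = transform_intensities(table, cofactor=cofactor, markers=markers)
    pos = call_positivity(t, thresholds=thresholds, q=q, markers=markers)
    out = table.copy()
    out["phenotype"] = apply_gates(pos, rules)
    return out


def cluster_cells(
    table: pd.DataFrame,
    k: int,
    seed: int = 0,
    markers: Sequence[str] | None = None,
    cofactor: float = 5.0,
) -> np.ndarray:
    """k-means over arcsinh-transformed intensities with a fixed seed.

    Stands in for self-organizing-map / graph-based clustering of imaging
    panels; k is typically 50 for the human panel and 30 for mouse.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(table):
        raise ValueError("k exceeds the number of cells")
    markers = list(markers) if markers is not None else marker_columns(table)
    X = np.arcsinh(table[markers].to_numpy(dtype=float) / cofactor)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(X)


def annotate_clusters(
    positivity: pd.DataFrame,
    cluster_ids: np.ndarray,
    rules: Sequence[GatingRule],
) -> dict[int, str]:
    """Gate each cluster on its mean positivity (≥ 50% positive ⇒ positive)."""
    rules = order_gates(rules)
    cluster_ids = np.asarray(cluster_ids)
    rows = []
    clusters = sorted(pd.unique(cluster_ids))
    for c in clusters:
        rows.append(positivity[cluster_ids == c].mean(axis=0) >= 0.5)
    cluster_pos = pd.DataFrame(rows, index=clusters)
    labels = apply_gates(cluster_pos, rules)
    return {int(c): labels.loc[c] for c in clusters}
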