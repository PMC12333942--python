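"""Spot-level transcriptomic analysis: QC, latent patterns, and marker statistics.

The chain implemented here mirrors a spatial-transcriptomics workflow around
tertiary lymphoid structures (TLS):

1. spot filtering by tissue composition and segment quality,
2. TLS / TLS-neighbour labelling on the hex lattice,
3. non-negative factorization of ``log2(counts + 1)`` into gene amplitudes
   ``A`` and spot weights ``P``,
4. the fractional-expression pattern-marker statistic, which lets a gene
   mark several latent patterns at once,
5. expression-bin-matched module scoring of gene signatures,
6. pattern-level statistics (Pearson correlation with a module score,
   Kruskal-Wallis / rank-sum comparisons across TLS classes), and
7. preranked GSEA on pattern-marker scores with BH adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import shapely
from shapely.geometry import Polygon
from statsmodels.stats.multitest import multipletests

from .density_stats import compare_groups
from .geometry import HexLattice, spot_neighbors

logger = logging.getLogger(__name__)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SpotMatrix:
    """Gene × spot counts on a hex lattice with per-spot annotations.

    ``counts`` is dense gene × spot (non-negative integers); ``positions``
    carries ``array_row`` / ``array_col`` / ``x_um`` / ``y_um`` per spot;
    ``composition`` (optional) holds tissue-class fractions per spot;
    ``labels`` (optional) partitions spots into ``TLS:<id>`` /
    ``TLS_neighbor`` / ``other``.
    """

    counts: np.ndarray
    genes: list[str]
    barcodes: list[str]
    positions: pd.DataFrame
    composition: pd.DataFrame | None = None
    segment_id: pd.Series | None = None
    labels: pd.Series | None = None
    tissue_label: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be gene x spot")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError("counts shape does not match genes x barcodes")
        if len(self.positions) != len(self.barcodes):
            raise ValueError("positions must have one row per barcode")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def umi_per_spot(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_spots(self, mask: np.ndarray) -> "SpotMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return SpotMatrix(
            counts=self.counts[:, idx],
            genes=list(self.genes),
            barcodes=[self.barcodes[i] for i in idx],
            positions=self.positions.iloc[idx].reset_index(drop=True),
            composition=None
            if self.composition is None
            else self.composition.iloc[idx].reset_index(drop=True),
            segment_id=None
            if self.segment_id is None
            else self.segment_id.iloc[idx].reset_index(drop=True),
            labels=None
            if self.labels is None
            else self.labels.iloc[idx].reset_index(drop=True),
            tissue_label=None
            if self.tissue_label is None
            else self.tissue_label.iloc[idx].reset_index(drop=True),
        )

    def to_anndata(self):
        """Spots-as-observations AnnData view of the matrix."""
        import anndata

        obs = self.positions.copy()
        obs.index = pd.Index(self.barcodes, name="barcode")
        if self.labels is not None:
            obs["label"] = self.labels.to_numpy()
        if self.segment_id is not None:
            obs["segment_id"] = self.segment_id.to_numpy()
        return anndata.AnnData(
            X=self.counts.T.astype(float),
            obs=obs,
            var=pd.DataFrame(index=pd.Index(self.genes, name="gene")),
        )


@dataclass
class PatternDecomposition:
    """Non-negative factors of the (log-scale) expression matrix.

    ``A`` is gene × K amplitudes, ``P`` is K × spot weights; the
    reconstruction is ``A @ P``.  ``objective`` records the penalized
    least-squares objective at every iteration of the selected restart.
    """

    A: np.ndarray
    P: np.ndarray
    K: int
    objective: np.ndarray
    seed: int

    @property
    def reconstruction(self) -> np.ndarray:
        return self.A @ self.P


@dataclass
class PatternMarkerResult:
    """Per-(gene, pattern) fractional expression, robust scores, marker flags."""

    f: pd.DataFrame  # gene x pattern fractional expression
    total: pd.Series  # per-gene total reconstructed expression T_g
    z: pd.DataFrame  # robust score per gene x pattern
    marker: pd.DataFrame  # boolean flags per gene x pattern
    stratum: pd.Series  # stratum index per gene (-1 = excluded, T_g == 0)

    def markers_of(self, pattern) -> list[str]:
        return list(self.marker.index[self.marker[pattern].to_numpy()])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: gene, pattern, f, z, marker flag."""
        long = (
            self.f.stack().rename("f").to_frame()
            .join(self.z.stack().rename("z"))
            .join(self.marker.stack().rename("marker"))
            .reset_index()
        )
        long.columns = ["gene", "pattern", "f", "z", "marker"]
        return long


@dataclass
class ModuleScoreResult:
    """Per-spot signature score with the control-bin bookkeeping."""

    scores: np.ndarray
    signature: list[str]
    control_bins: dict[str, int]
    seed: int


# ---------------------------------------------------------------------------
# spot QC and labelling
# ---------------------------------------------------------------------------


def filter_spots(
    spots: SpotMatrix,
    min_tissue_frac: float = 0.70,
    drop_classes: Iterable[str] = ("fat",),
    min_segment_median_umi: float = 200,
    non_tissue_class: str = "non_tissue",
) -> tuple[SpotMatrix, pd.DataFrame]:
    """Label spots by predominant tissue class and drop low-quality material.

    A spot is labelled with a tissue class when that class makes up at least
    ``min_tissue_frac`` of it, otherwise ``"mixed"``.  Spots labelled with a
    dropped class (fat by default), spots that are predominantly non-tissue,
    and whole segments whose median UMI falls below
    ``min_segment_median_umi`` are removed.  Returns the filtered matrix and
    a log of removals with reasons.
    """
    if spots.composition is None:
        raise ValueError("filter_spots requires tissue composition")
    comp = spots.composition
    tissue_cols = [c for c in comp.columns if c != non_tissue_class]
    frac = comp[tissue_cols].to_numpy()
    best = np.argmax(frac, axis=1)
    best_frac = frac[np.arange(len(comp)), best]
    label = np.where(
        best_frac >= min_tissue_frac,
        np.asarray(tissue_cols, dtype=object)[best],
        "mixed",
    )

    removals: list[tuple[str, str]] = []
    keep = np.ones(spots.n_spots, dtype=bool)
    drop_classes = set(drop_classes)
    for i, lab in enumerate(label):
        if lab in drop_classes:
            keep[i] = False
            removals.append((spots.barcodes[i], f"tissue class {lab!r} dropped"))
    if non_tissue_class in comp.columns:
        nt = comp[non_tissue_class].to_numpy()
        for i in np.flatnonzero(nt >= min_tissue_frac):
            if keep[i]:
                keep[i] = False
                removals.append((spots.barcodes[i], "predominantly non-tissue"))

    if spots.segment_id is not None:
        umi = spots.umi_per_spot()
        seg = spots.segment_id.to_numpy()
        for s in pd.unique(seg):
            med = float(np.median(umi[seg == s]))
            if med < min_segment_median_umi:
                for i in np.flatnonzero(seg == s):
                    if keep[i]:
                        keep[i] = False
                        removals.append(
                            (
                                spots.barcodes[i],
                                f"segment {s!r} median UMI {med:.0f} < "
                                f"{min_segment_median_umi}",
                            )
                        )

    log = pd.DataFrame(removals, columns=["barcode", "reason"])
    if not keep.any():
        logger.warning("filter_spots removed every spot")
    out = spots.subset_spots(keep)
    out.tissue_label = pd.Series(label[keep], name="tissue_label").reset_index(
        drop=True
    )
    logger.info("filter_spots: kept %d of %d spots", out.n_spots, spots.n_spots)
    return out, log


def label_tls_spots(
    spots: SpotMatrix,
    tls_hulls: Mapping[str, np.ndarray],
    lattice: HexLattice,
    depth: int = 2,
) -> SpotMatrix:
    """Label spots as ``TLS:<id>`` / ``TLS_neighbor`` / ``other``.

    A spot whose centre lies inside a hull belongs to that TLS (overlapping
    hulls resolve to the nearest hull centroid); spots within ``depth`` hex
    steps of any TLS spot, excluding TLS spots themselves, are neighbours.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    polys = {k: Polygon(np.asarray(v)) for k, v in tls_hulls.items()}
    xy = spots.positions[["x_um", "y_um"]].to_numpy()
    pts = shapely.points(xy)
    labels = np.full(spots.n_spots, "other", dtype=object)
    for i, p in enumerate(pts):
        hits = [k for k, poly in polys.items() if shapely.covers(poly, p)]
        if len(hits) > 1:
            hits.sort(key=lambda k: polys[k].centroid.distance(p))
            logger.info(
                "spot %s inside %d hulls; assigned to nearest centroid %s",
                spots.barcodes[i],
                len(hits),
                hits[0],
            )
        if hits:
            labels[i] = f"TLS:{hits[0]}"

    rc = list(
        zip(
            spots.positions["array_row"].astype(int),
            spots.positions["array_col"].astype(int),
        )
    )
    seed = {rc[i] for i in np.flatnonzero(labels != "other")}
    if seed:
        neigh = spot_neighbors(lattice, seed, depth)
        for i, pos in enumerate(rc):
            if labels[i] == "other" and pos in neigh:
                labels[i] = "TLS_neighbor"
    out = replace(spots)
    out.labels = pd.Series(labels, name="label")
    return out


def log_transform(counts: np.ndarray) -> np.ndarray:
    """``log2(counts + 1)`` with a pseudocount of one."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    return np.log2(counts + 1.0)


def cp10k_log2(counts: np.ndarray) -> np.ndarray:
    """``log2`` counts-per-10k normalization, the module-score input."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum(axis=0, keepdims=True)
    total = np.where(total == 0, 1.0, total)
    return np.log2(counts / total * 1e4 + 1.0)


# ---------------------------------------------------------------------------
# NMF and the pattern-marker statistic
# ---------------------------------------------------------------------------


def _nmf_objective(D, A, P, alpha) -> float:
    R = D - A @ P
    return 0.5 * float(np.sum(R * R)) + alpha * (float(A.sum()) + float(P.sum()))


def fit_nmf(
    D: np.ndarray,
    K: int,
    alpha: float = 0.01,
    max_iter: int = 5000,
    tol: float = 1e-6,
    seed: int = 0,
    n_restarts: int = 3,
) -> PatternDecomposition:
    """L1-penalized NMF by multiplicative updates, best of ``n_restarts``.

    Minimizes ``0.5 * ||D - AP||_F^2 + alpha * (||A||_1 + ||P||_1)`` with the
    standard majorize-minimize multiplicative updates, so the recorded
    objective is non-increasing.  On return, rows of ``P`` are rescaled to
    maximum 1 with the inverse scale absorbed into ``A``.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2:
        raise ValueError("D must be a matrix")
    if (D < 0).any():
        raise ValueError("D must be non-negative")
    if not D.any():
        raise ValueError("D is identically zero")
    G, S = D.shape
    if not 1 <= K <= min(G, S):
        raise ValueError(f"K must be in [1, {min(G, S)}]")

    best: tuple[float, np.ndarray, np.ndarray, list[float]] | None = None
    scale0 = np.sqrt(D.mean() / K)
    for r in range(n_restarts):
        rng = np.random.default_rng(seed + r)
        A = rng.uniform(0.1, 1.0, size=(G, K)) * scale0
        P = rng.uniform(0.1, 1.0, size=(K, S)) * scale0
        trace = [_nmf_objective(D, A, P, alpha)]
        for _ in range(max_iter):
            A *= (D @ P.T) / (A @ (P @ P.T) + alpha + _EPS)
            P *= (A.T @ D) / ((A.T @ A) @ P + alpha + _EPS)
            obj = _nmf_objective(D, A, P, alpha)
            trace.append(obj)
            if abs(trace[-2] - obj) <= tol * max(1.0, abs(trace[-2])):
                break
        if best is None or trace[-1] < best[0]:
            best = (trace[-1], A, P, trace)

    _, A, P, trace = best
    scale = np.maximum(P.max(axis=1), _EPS)
    P = P / scale[:, None]
    A = A * scale[None, :]
    return PatternDecomposition(A=A, P=P, K=K, objective=np.asarray(trace), seed=seed)


def fractional_expression(
    decomp: PatternDecomposition,
) -> tuple[np.ndarray, np.ndarray]:
    """Share of each gene's reconstructed expression attributable to a pattern.

    With ``r_k = sum_j P_kj``, a gene's total reconstructed expression is
    ``T_g = sum_k A_gk r_k`` and its fractional expression in pattern ``k``
    is ``f_gk = A_gk r_k / T_g``; rows sum to one wherever ``T_g > 0``.
    Genes with ``T_g = 0`` get NaN rows and are excluded downstream.
    """
    r = decomp.P.sum(axis=1)
    contrib = decomp.A * r[None, :]
    T = contrib.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = contrib / T[:, None]
    f[T == 0] = np.nan
    if (T == 0).any():
        logger.info("fractional_expression: %d genes with T_g = 0", int((T == 0).sum()))
    return f, T


def pattern_marker_scores(
    f: np.ndarray,
    T: np.ndarray,
    genes: Sequence[str] | None = None,
    patterns: Sequence | None = None,
    n_strata: int = 3,
    fence: float = 1.5,
    min_stratum_genes: int = 5,
) -> PatternMarkerResult:
    """Flag pattern markers as upper-fence outliers of fractional expression.

    Genes are stratified into ``n_strata`` quantile bins of total
    reconstructed expression ``T`` (low / medium / high by default).  Within
    each (stratum, pattern) cell, a gene is a marker when its fractional
    expression exceeds the Tukey upper fence ``Q3 + fence * IQR``, and its
    robust score is ``(f - median) / (MAD + 1e-12)``.  Flags are independent
    across patterns, so a gene can mark several patterns.  Strata with fewer
    than ``min_stratum_genes`` genes are merged into their neighbour.
    """
    f = np.asarray(f, dtype=float)
    T = np.asarray(T, dtype=float)
    G, K = f.shape
    if genes is None:
        genes = [f"gene_{i}" for i in range(G)]
    if patterns is None:
        patterns = list(range(K))

    valid = (T > 0) & np.isfinite(f).all(axis=1)
    stratum = np.full(G, -1, dtype=int)
    if valid.sum() > 0:
        ranks = scipy.stats.rankdata(T[valid], method="average")
        stratum[valid] = np.minimum(
            (ranks / (valid.sum() + 1) * n_strata).astype(int), n_strata - 1
        )
        # merge undersized strata into the adjacent (lower, else higher) one
        changed = True
        while changed:
            changed = False
            present = sorted(set(stratum[valid]))
            for s in present:
                if (stratum == s).sum() < min_stratum_genes and len(present) > 1:
                    neighbor = max(x for x in present if x != s) if s == min(
                        present
                    ) else max(x for x in present if x < s)
                    logger.info(
                        "pattern_marker_scores: merging stratum %d (<%d genes) into %d",
                        s,
                        min_stratum_genes,
                        neighbor,
                    )
                    stratum[stratum == s] = neighbor
                    changed = True
                    break

    z = np.full_like(f, np.nan)
    marker = np.zeros_like(f, dtype=bool)
    for s in sorted(set(stratum[stratum >= 0])):
        rows = stratum == s
        for k in range(K):
            vals = f[rows, k]
            q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
            iqr = q3 - q1
            mad = np.median(np.abs(vals - med))
            z[rows, k] = (vals - med) / (mad + _EPS)
            marker[rows, k] = vals > q3 + fence * iqr

    gidx = pd.Index(genes, name="gene")
    return PatternMarkerResult(
        f=pd.DataFrame(f, index=gidx, columns=patterns),
        total=pd.Series(T, index=gidx, name="T"),
        z=pd.DataFrame(z, index=gidx, columns=patterns),
        marker=pd.DataFrame(marker, index=gidx, columns=patterns),
        stratum=pd.Series(stratum, index=gidx, name="stratum"),
    )


# ---------------------------------------------------------------------------
# module score and pattern-level statistics
# ---------------------------------------------------------------------------


def module_score(
    D_norm: np.ndarray,
    genes: Sequence[str],
    signature: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ModuleScoreResult:
    """Signature mean minus expression-bin-matched control mean, per spot.

    Genes are ranked by mean expression across spots and cut into ``n_bins``
    equal-size bins; each signature gene contributes ``n_ctrl`` control genes
    sampled from its own bin (with replacement when the bin is smaller than
    ``n_ctrl``).  The score of a spot is the mean expression of the
    signature minus the mean over the pooled controls.
    """
    D_norm = np.asarray(D_norm, dtype=float)
    genes = list(genes)
    gene_idx = {g: i for i, g in enumerate(genes)}

    sig = list(dict.fromkeys(signature))  # dedup, order-preserving
    missing = [g for g in sig if g not in gene_idx]
    if missing:
        logger.warning("module_score: %d signature genes missing", len(missing))
    sig = [g for g in sig if g in gene_idx]
    if not sig:
        raise ValueError("no signature genes present in the matrix")

    mean_expr = D_norm.mean(axis=1)
    order = np.argsort(mean_expr, kind="stable")
    bin_of = np.empty(len(genes), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b
    bins = {b: np.flatnonzero(bin_of == b) for b in range(n_bins)}

    rng = np.random.default_rng(seed)
    ctrl_rows: list[np.ndarray] = []
    control_bins: dict[str, int] = {}
    for g in sig:
        b = bin_of[gene_idx[g]]
        control_bins[g] = int(b)
        pool = bins[b]
        replace_draw = len(pool) < n_ctrl
        ctrl_rows.append(rng.choice(pool, size=n_ctrl, replace=replace_draw))
    ctrl = np.concatenate(ctrl_rows)

    sig_rows = np.array([gene_idx[g] for g in sig])
    scores = D_norm[sig_rows].mean(axis=0) - D_norm[ctrl].mean(axis=0)
    return ModuleScoreResult(
        scores=scores, signature=sig, control_bins=control_bins, seed=seed
    )


def pattern_vs_module(
    weights: np.ndarray, scores: np.ndarray
) -> tuple[float, float, float]:
    """Pearson correlation of pattern weights with a module score.

    Returns ``(r, R^2, p)``; ``R^2`` is the simple-linear-regression
    goodness of fit, which equals ``r**2``.
    """
    weights = np.asarray(weights, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(weights) != len(scores) or len(weights) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(weights) == 0 or np.std(scores) == 0:
        raise ValueError("zero variance in input")
    res = scipy.stats.pearsonr(weights, scores)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def compare_tls_classes(
    weights: np.ndarray, classes: Sequence
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Kruskal-Wallis across TLS classes plus unadjusted pairwise rank-sums.

    Classes with fewer than 2 spots are excluded with a warning.  Returns the
    Kruskal-Wallis ``(statistic, p)`` and a pairwise table with columns
    ``group_a`` / ``group_b`` / ``statistic`` / ``p``.
    """
    weights = np.asarray(weights, dtype=float)
    classes = np.asarray(classes)
    by_group: dict = {}
    for c in pd.unique(classes):
        v = weights[classes == c]
        if len(v) < 2:
            logger.warning("compare_tls_classes: dropping singleton class %r", c)
            continue
        by_group[c] = v
    if len(by_group) < 2:
        raise ValueError("need >= 2 classes with >= 2 spots each")
    kw = compare_groups(by_group, test="kruskal")
    names = list(by_group)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            stat, p = compare_groups({a: by_group[a], b: by_group[b]}, test="wilcoxon")
            rows.append({"group_a": a, "group_b": b, "statistic": stat, "p": p})
    return kw, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------


def _enrichment_scores(hit: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Signed weighted-KS enrichment score for each row of ``hit``.

    ``hit`` is (n_sets, N) boolean over a ranked gene list, ``w`` the (N,)
    rank weights (|score| ** exponent).  The ES is the running-sum value of
    maximum absolute deviation.
    """
    hw = hit * w[None, :]
    denom = hw.sum(axis=1, keepdims=True)
    denom = np.where(denom == 0, 1.0, denom)
    p_hit = np.cumsum(hw, axis=1) / denom
    miss = ~hit
    n_miss = miss.sum(axis=1, keepdims=True)
    n_miss = np.where(n_miss == 0, 1, n_miss)
    p_miss = np.cumsum(miss, axis=1) / n_miss
    rs = p_hit - p_miss
    idx = np.argmax(np.abs(rs), axis=1)
    return rs[np.arange(len(rs)), idx]


def gsea_preranked(
    scores: pd.Series,
    gene_sets: Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 3,
) -> pd.DataFrame:
    """Preranked GSEA with gene-label permutation and BH adjustment.

    Genes are ranked by ``scores`` descending; the enrichment score is the
    weighted Kolmogorov-Smirnov statistic (weight exponent 1 by default).
    The null permutes gene labels — equivalently, draws random same-size
    gene sets — and the two-sided permutation p-value uses the +1
    convention.  BH adjustment is applied across the reported sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    scores = scores.sort_values(ascending=False, kind="stable")
    ranked = scores.index.to_numpy()
    pos_of = {g: i for i, g in enumerate(ranked)}
    N = len(ranked)
    w = np.abs(scores.to_numpy()) ** weight

    rng = np.random.default_rng(seed)
    rows = []
    for name, members in gene_sets.items():
        members = set(members)
        present = [g for g in members if g in pos_of]
        if len(present) < len(members):
            logger.info(
                "gsea_preranked: set %r — %d of %d genes in universe",
                name,
                len(present),
                len(members),
            )
        m = len(present)
        if m < min_size:
            logger.info("gsea_preranked: skipping %r (%d represented genes)", name, m)
            continue
        hit = np.zeros(N, dtype=bool)
        hit[[pos_of[g] for g in present]] = True
        es = float(_enrichment_scores(hit[None, :], w)[0])

        perm_hit = np.zeros((n_perm, N), dtype=bool)
        draws = np.argsort(rng.random((n_perm, N)), axis=1)[:, :m]
        np.put_along_axis(perm_hit, draws, True, axis=1)
        es_perm = _enrichment_scores(perm_hit, w)

        p = (1 + int(np.sum(np.abs(es_perm) >= abs(es)))) / (n_perm + 1)
        same_sign = es_perm * np.sign(es) > 0
        norm = np.mean(np.abs(es_perm[same_sign])) if same_sign.any() else np.mean(
            np.abs(es_perm)
        )
        nes = es / norm if norm > 0 else np.nan
        rows.append({"set": name, "size": m, "ES": es, "NES": nes, "p": p})

    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out
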