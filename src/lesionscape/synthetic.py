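"""Synthetic tissue and spot-array generators with planted ground truth.

Two generators drive every downstream test without external downloads:

* :func:`generate_cell_map` — a segmented-cell map in the style of
  multiplexed imaging: per-region homogeneous Poisson point processes of
  phenotyped cells, planted lymphoid aggregates (immature = mixed B/T disc;
  mature = germinal-centre B core with a T-cell annulus), and lognormal
  marker intensities.
* :func:`generate_spot_data` — hex-lattice spot counts whose log2 means are
  a product of planted non-negative factors, with an optional TLS-elevated
  gene signature and Poisson (or negative-binomial) noise.

The module also ships default configurations that define the simulated study
conditions (region classes, per-class phenotype densities, TLS layouts, and
the planted latent-pattern architecture).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .geometry import HexLattice, RegionPolygon, RegionSet
from .st_patterns import SpotMatrix

# ---------------------------------------------------------------------------
# marker model and phenotype definitions
# ---------------------------------------------------------------------------

#: full marker panel of the simulated imaging experiment
DEFAULT_MARKERS = [
    "CD3", "CD4", "CD8", "CD20", "CD21", "CD23", "CD45RA", "CD45RO",
    "FOXP3", "PD1", "TOX2", "CCR7", "HLADR", "GZMB", "KI67", "CD57",
    "CD68", "CD16", "CD11c", "DCSIGN", "PDPN", "CK", "COL", "SMA", "VIM",
]

#: positive-marker set per simulated phenotype; all other markers negative
DEFAULT_PHENOTYPE_MARKERS: dict[str, frozenset[str]] = {
    "Treg": frozenset({"CD3", "CD4", "FOXP3"}),
    "T_exhausted": frozenset({"CD4", "CD45RO", "TOX2", "PD1"}),
    "T_central_memory": frozenset({"CD4", "CD45RO", "CCR7", "HLADR"}),
    "T_memory_CD57": frozenset({"CD4", "CD45RO", "CD57"}),
    "T_cytotoxic": frozenset({"CD3", "CD8", "GZMB"}),
    "B_GC": frozenset({"CD20", "CD21", "CD23"}),
    "B_proliferating": frozenset({"CD20", "CD45RA", "KI67"}),
    "B": frozenset({"CD20", "CD45RA"}),
    "T_CD8": frozenset({"CD3", "CD8"}),
    "T_CD4": frozenset({"CD3", "CD4"}),
    "Macrophage": frozenset({"CD68", "CD16", "CD11c"}),
    "Dendritic": frozenset({"DCSIGN"}),
    "Endothelial_HEV": frozenset({"PDPN"}),
    "NK": frozenset({"CD57"}),
    "Epithelial": frozenset({"CK"}),
    "Fibroblast": frozenset({"COL", "SMA", "VIM"}),
}


@dataclass(frozen=True)
class MarkerModel:
    """Lognormal marker-intensity model.

    A marker's raw intensity is ``mu * exp(sigma * Z)`` with median
    ``mu_pos`` when the phenotype expresses the marker and ``mu_neg``
    otherwise; the defaults separate cleanly under midpoint gating.
    """

    markers: tuple[str, ...] = tuple(DEFAULT_MARKERS)
    positive: dict = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_MARKERS)
    )
    mu_pos: float = 2.0
    mu_neg: float = 0.2
    sigma: float = 0.4

    def threshold(self, cofactor: float = 5.0) -> float:
        """Geometric-midpoint positivity threshold on the arcsinh scale."""
        return float(np.arcsinh(np.sqrt(self.mu_pos * self.mu_neg) / cofactor))


# ---------------------------------------------------------------------------
# tissue configuration
# ---------------------------------------------------------------------------

#: composition of a mature aggregate: (fraction, zone); the germinal-centre
#: B core occupies the inner half-radius disc, everything else the annulus
MATURE_TLS_MIX: dict[str, tuple[float, str]] = {
    "B_GC": (0.35, "inner"),
    "B": (0.10, "annulus"),
    "T_CD4": (0.20, "annulus"),
    "T_CD8": (0.15, "annulus"),
    "Treg": (0.05, "annulus"),
    "Dendritic": (0.075, "annulus"),
    "Endothelial_HEV": (0.075, "annulus"),
}

#: immature aggregates: dense but disorganized B/T mixture, no GC B cells,
#: no follicular dendritic cells, no HEV
IMMATURE_TLS_MIX: dict[str, tuple[float, str]] = {
    "B": (0.45, "disc"),
    "T_CD4": (0.30, "disc"),
    "T_CD8": (0.20, "disc"),
    "Treg": (0.05, "disc"),
}

INNER_FRACTION = 0.5  # inner-core radius as a fraction of the TLS radius


@dataclass(frozen=True)
class TLSSpec:
    """A planted lymphoid aggregate.

    ``lesion_class`` / ``lesion_distance_um`` are ground-truth annotations of
    the intended association (``"excluded"`` when farther than the
    association rule allows); the generator does not enforce them.
    """

    center: tuple[float, float]
    radius_um: float
    maturity: str  # "mature" | "immature"
    n_cells: int
    lesion_class: str = "excluded"
    lesion_distance_um: float | None = None

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("TLS radius must be > 0")
        if self.maturity not in ("mature", "immature"):
            raise ValueError(f"unknown maturity {self.maturity!r}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass
class TissueSimConfig:
    """Configuration of a simulated tissue section.

    ``regions`` are (class, rectangle) pairs with rectangles in μm as
    ``(x0, y0, x1, y1)``; ``densities`` gives expected cells per mm² per
    phenotype for each region class; ``density_cv`` adds per-(region,
    phenotype) lognormal heterogeneity with the given coefficient of
    variation around the class mean.
    """

    regions: list[tuple[str, tuple[float, float, float, float]]]
    densities: dict[str, dict[str, float]]
    tls_specs: list[TLSSpec] = field(default_factory=list)
    marker_model: MarkerModel = field(default_factory=MarkerModel)
    density_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, rect in self.regions:
            x0, y0, x1, y1 = rect
            if x1 <= x0 or y1 <= y0:
                raise ValueError(f"region of class {cls!r} has non-positive area")
        for cls, table in self.densities.items():
            for ph, d in table.items():
                if d < 0:
                    raise ValueError(f"negative density for {cls}/{ph}")
        if self.density_cv < 0:
            raise ValueError("density_cv must be >= 0")


@dataclass
class GroundTruth:
    """Planted truth shared by both generators (unused fields stay None)."""

    cell_phenotype: np.ndarray | None = None
    tls: list[dict] | None = None
    gene_patterns: dict[str, int] | None = None
    signature_genes: list[str] | None = None
    tls_spots: list[int] | None = None

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if out["cell_phenotype"] is not None:
            out["cell_phenotype"] = list(map(str, out["cell_phenotype"]))
        return out


# ---------------------------------------------------------------------------
# cell-map generator
# ---------------------------------------------------------------------------


def _region_set(config: TissueSimConfig) -> RegionSet:
    counters: dict[str, int] = {}
    regions = []
    for cls, rect in config.regions:
        i = counters.get(cls, 0)
        counters[cls] = i + 1
        regions.append(RegionPolygon.from_rectangle(f"{cls}_{i}", cls, rect))
    return RegionSet(regions)


def _check_no_overlap(regions: RegionSet) -> None:
    polys = [r.polygon for r in regions]
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            inter = polys[i].intersection(polys[j])
            if inter.area > 0:
                raise ValueError(
                    f"regions {regions.regions[i].region_id!r} and "
                    f"{regions.regions[j].region_id!r} overlap"
                )


def _uniform_disc(
    rng: np.random.Generator, n: int, center, r_lo: float, r_hi: float
) -> np.ndarray:
    """Uniform points in the annulus r in [r_lo, r_hi] around ``center``."""
    u = rng.uniform(r_lo**2, r_hi**2, size=n)
    r = np.sqrt(u)
    theta = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack(
        [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)]
    )


def _split_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Deterministic largest-remainder split of n into len(fractions) parts."""
    raw = np.asarray(fractions, dtype=float) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base.tolist()


def generate_cell_map(
    config: TissueSimConfig,
) -> tuple[pd.DataFrame, RegionSet, GroundTruth]:
    """Generate a phenotyped cell map with planted aggregates.

    Background cells follow homogeneous Poisson point processes per region
    and phenotype; aggregate cells are placed in discs according to the
    maturity recipes.  Marker intensities are lognormal with positive-marker
    medians from the marker model.  Output is bit-for-bit reproducible for a
    fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    regions = _region_set(config)
    _check_no_overlap(regions)
    model = config.marker_model

    xs: list[np.ndarray] = []
    phenotypes: list[str] = []
    region_ids: list[str] = []

    if config.density_cv > 0:
        sigma_ln = float(np.sqrt(np.log1p(config.density_cv**2)))
    else:
        sigma_ln = 0.0

    for region in regions:
        table = config.densities.get(region.region_class, {})
        x0, y0, x1, y1 = region.vertices[:, 0].min(), region.vertices[:, 1].min(), \
            region.vertices[:, 0].max(), region.vertices[:, 1].max()
        area = region.area_mm2
        for ph in sorted(table):
            dens = table[ph]
            if dens == 0:
                continue
            lam = dens * area
            if sigma_ln > 0:
                lam *= float(
                    np.exp(rng.normal(-0.5 * sigma_ln**2, sigma_ln))
                )
            n = int(rng.poisson(lam))
            if n == 0:
                continue
            pts = np.column_stack(
                [rng.uniform(x0, x1, size=n), rng.uniform(y0, y1, size=n)]
            )
            xs.append(pts)
            phenotypes.extend([ph] * n)
            region_ids.extend([region.region_id] * n)

    tls_truth: list[dict] = []
    next_id = sum(len(a) for a in xs)
    for t, spec in enumerate(config.tls_specs):
        disc = Point(spec.center).buffer(spec.radius_um, quad_segs=32)
        if not any(r.polygon.intersects(disc) for r in regions):
            raise ValueError(f"TLS disc {t} lies outside all regions")
        mix = MATURE_TLS_MIX if spec.maturity == "mature" else IMMATURE_TLS_MIX
        names = list(mix)
        counts = _split_counts(spec.n_cells, [mix[k][0] for k in names])
        member_ids: list[int] = []
        for ph, n in zip(names, counts):
            if n == 0:
                continue
            zone = mix[ph][1]
            r_in = INNER_FRACTION * spec.radius_um
            if zone == "inner":
                pts = _uniform_disc(rng, n, spec.center, 0.0, r_in)
            elif zone == "annulus":
                pts = _uniform_disc(rng, n, spec.center, r_in, spec.radius_um)
            else:
                pts = _uniform_disc(rng, n, spec.center, 0.0, spec.radius_um)
            containing = [
                _containing_region(regions, x, y) for x, y in pts
            ]
            xs.append(pts)
            phenotypes.extend([ph] * n)
            region_ids.extend(containing)
            member_ids.extend(range(next_id, next_id + n))
            next_id += n
        tls_truth.append(
            {
                "tls_id": f"tls_{t:02d}",
                "maturity": spec.maturity,
                "lesion_class": spec.lesion_class,
                "lesion_distance_um": spec.lesion_distance_um,
                "center": list(spec.center),
                "radius_um": spec.radius_um,
                "member_cell_ids": member_ids,
            }
        )

    if xs:
        coords = np.vstack(xs)
    else:
        coords = np.empty((0, 2))
    n_cells = len(coords)
    phen = np.asarray(phenotypes, dtype=object)

    markers = list(model.markers)
    mu = np.full((n_cells, len(markers)), model.mu_neg)
    for j, m in enumerate(markers):
        pos = np.array(
            [m in model.positive.get(p, frozenset()) for p in phen], dtype=bool
        ) if n_cells else np.zeros(0, dtype=bool)
        mu[pos, j] = model.mu_pos
    intensities = mu * np.exp(model.sigma * rng.standard_normal(mu.shape))

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "x_um": coords[:, 0] if n_cells else np.array([]),
            "y_um": coords[:, 1] if n_cells else np.array([]),
            "region_id": region_ids,
        }
    )
    for j, m in enumerate(markers):
        cells[m] = intensities[:, j] if n_cells else np.array([])

    truth = GroundTruth(cell_phenotype=phen, tls=tls_truth)
    return cells, regions, truth


def _containing_region(regions: RegionSet, x: float, y: float) -> str:
    for r in regions:
        if r.contains(x, y):
            return r.region_id
    # disc overhangs all rectangles: attach to the nearest region
    dists = [r.polygon.distance(Point(x, y)) for r in regions]
    return regions.regions[int(np.argmin(dists))].region_id


# ---------------------------------------------------------------------------
# spot-array generator
# ---------------------------------------------------------------------------


@dataclass
class VisiumSimConfig:
    """Configuration of a simulated hex-lattice spot experiment.

    ``A_true`` (gene × K) and ``P_true`` (K × spot) define planted
    non-negative factors of the log2 mean expression; ``signature_genes``
    receive a ``delta`` log2 elevation in ``tls_spots``.  Spot counts are
    Poisson around ``s_j * (2**M - 1)`` with lognormal library-size factors
    ``s_j`` (or deterministic rounding with ``noise="none"``, or
    gamma-Poisson with ``noise="nb"``).
    """

    n_rows: int
    n_cols: int
    A_true: np.ndarray
    P_true: np.ndarray
    genes: list[str] | None = None
    signature_genes: list[str] = field(default_factory=list)
    delta: float = 0.0
    tls_spots: list[int] = field(default_factory=list)
    spacing_um: float = 100.0
    libsize_sigma: float = 0.1
    noise: str = "poisson"
    nb_dispersion: float | None = None
    seed: int = 0
    gene_patterns: dict[str, int] | None = None  # ground-truth annotation

    def __post_init__(self) -> None:
        self.A_true = np.asarray(self.A_true, dtype=float)
        self.P_true = np.asarray(self.P_true, dtype=float)
        if self.A_true.ndim != 2 or self.P_true.ndim != 2:
            raise ValueError("A_true and P_true must be matrices")
        if self.A_true.shape[1] != self.P_true.shape[0]:
            raise ValueError("A_true / P_true inner dimensions disagree")
        if self.A_true.shape[1] < 1:
            raise ValueError("K_true must be >= 1")
        if (self.A_true < 0).any() or (self.P_true < 0).any():
            raise ValueError("planted factors must be non-negative")
        if self.noise not in ("poisson", "none", "nb"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.genes is None:
            self.genes = [f"gene_{i:04d}" for i in range(self.A_true.shape[0])]
        if len(self.genes) != self.A_true.shape[0]:
            raise ValueError("genes length must match A_true rows")
        missing = set(self.signature_genes) - set(self.genes)
        if missing:
            raise ValueError(f"signature genes outside universe: {sorted(missing)}")

    @property
    def lattice(self) -> HexLattice:
        return HexLattice(self.n_rows, self.n_cols, self.spacing_um)


def generate_spot_data(
    config: VisiumSimConfig,
) -> tuple[SpotMatrix, GroundTruth]:
    """Generate hex-lattice spot counts from planted non-negative factors."""
    lattice = config.lattice
    positions = lattice.positions()
    S = len(positions)
    if config.P_true.shape[1] != S:
        raise ValueError(
            f"P_true has {config.P_true.shape[1]} spots; lattice has {S}"
        )
    bad = [j for j in config.tls_spots if not 0 <= j < S]
    if bad:
        raise ValueError(f"tls_spots indices off lattice: {bad}")

    M = config.A_true @ config.P_true
    if config.delta < 0 and abs(config.delta) > M.max():
        raise ValueError("negative delta exceeds the dynamic range of M")
    if config.signature_genes and config.tls_spots and config.delta != 0:
        gidx = [config.genes.index(g) for g in config.signature_genes]
        M = M.copy()
        M[np.ix_(gidx, config.tls_spots)] += config.delta
    lam = np.maximum(2.0**M - 1.0, 0.0)

    rng = np.random.default_rng(config.seed)
    if config.noise == "none":
        counts = np.rint(lam).astype(np.int64)
    else:
        s = np.exp(rng.normal(0.0, config.libsize_sigma, size=S))
        mean = lam * s[None, :]
        if config.noise == "poisson":
            counts = rng.poisson(mean).astype(np.int64)
        else:
            if not config.nb_dispersion or config.nb_dispersion <= 0:
                raise ValueError("nb noise requires nb_dispersion > 0")
            shape = 1.0 / config.nb_dispersion
            gamma = rng.gamma(shape, 1.0 / shape, size=mean.shape)
            counts = rng.poisson(mean * gamma).astype(np.int64)

    spots = SpotMatrix(
        counts=counts,
        genes=list(config.genes),
        barcodes=[f"spot_{i:04d}" for i in range(S)],
        positions=positions,
    )
    truth = GroundTruth(
        gene_patterns=config.gene_patterns,
        signature_genes=list(config.signature_genes),
        tls_spots=list(config.tls_spots),
    )
    return spots, truth


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

#: expected cells per mm² per phenotype by region class — a qualitative
#: stand-in for pancreatic tissue: CD4-dominant infiltrates in lesions,
#: Treg/exhausted enrichment in tumor relative to precursor, immune-poor
#: normal parenchyma
DEFAULT_DENSITIES: dict[str, dict[str, float]] = {
    "normal": {
        "Epithelial": 400, "Fibroblast": 150, "T_CD4": 15, "T_CD8": 10,
        "B": 5, "Treg": 2, "Macrophage": 20, "Dendritic": 5, "NK": 5,
    },
    "PanIN": {
        "Epithelial": 300, "Fibroblast": 250, "T_CD4": 120, "T_CD8": 40,
        "Treg": 15, "T_cytotoxic": 10, "B": 30, "Macrophage": 60,
        "Dendritic": 20, "T_central_memory": 10, "T_exhausted": 3, "NK": 8,
    },
    "PDAC": {
        "Epithelial": 250, "Fibroblast": 350, "T_CD4": 100, "T_CD8": 35,
        "Treg": 45, "T_cytotoxic": 15, "B": 60, "Macrophage": 80,
        "Dendritic": 25, "T_central_memory": 40, "T_exhausted": 25,
        "T_memory_CD57": 15, "NK": 10,
    },
    "CP": {
        "Epithelial": 200, "Fibroblast": 300, "T_CD4": 110, "T_CD8": 50,
        "Treg": 25, "B": 60, "Macrophage": 70, "Dendritic": 20,
        "T_central_memory": 30, "T_exhausted": 15, "NK": 10,
    },
}


def demo_tissue_config(seed: int = 0) -> TissueSimConfig:
    """Small demo section: 3 ROIs per class plus 4 planted aggregates."""
    regions = []
    classes = ["normal", "PanIN", "PDAC", "CP"]
    for i, cls in enumerate(classes):
        for j in range(3):
            x0 = j * 1200.0
            y0 = i * 1200.0
            regions.append((cls, (x0, y0, x0 + 1000.0, y0 + 1000.0)))
    # stroma strip below the ROI grid hosting the aggregates
    regions.append(("normal", (0.0, 4800.0, 3400.0, 6400.0)))
    tls = [
        TLSSpec((500.0, 5300.0), 150.0, "immature", 300, "PanIN", 200.0),
        TLSSpec((1300.0, 5300.0), 150.0, "immature", 300, "PanIN", 200.0),
        TLSSpec((2100.0, 5300.0), 150.0, "mature", 300, "PDAC", 200.0),
        TLSSpec((2900.0, 5300.0), 150.0, "mature", 300, "PDAC", 200.0),
    ]
    return TissueSimConfig(
        regions=regions,
        densities=DEFAULT_DENSITIES,
        tls_specs=tls,
        density_cv=0.3,
        seed=seed,
    )


def tls_benchmark_config(seed: int = 0, n_cells: int = 300) -> TissueSimConfig:
    """Twenty planted aggregates, half mature, at known lesion distances.

    Three lesion rectangles (PanIN / PDAC / CP) sit along the top edge; four
    aggregates hang below each at planted boundary distances of 150, 200
    (associated under the 250 μm rule), 300 and 400 μm (excluded); eight
    far-field aggregates are unambiguously excluded.  Maturity alternates to
    give 10 mature / 10 immature.
    """
    lesions = [("PanIN", 1000.0), ("PDAC", 3700.0), ("CP", 6400.0)]
    half_w = 800.0
    regions: list[tuple[str, tuple[float, float, float, float]]] = []
    for cls, cx in lesions:
        regions.append((cls, (cx - half_w, 0.0, cx + half_w, 1500.0)))
    # stroma strips tiling the rest of the section (regions must not overlap)
    strip_edges = [0.0]
    for _, cx in lesions:
        strip_edges += [cx - half_w, cx + half_w]
    strip_edges.append(8000.0)
    for a, b in zip(strip_edges[::2], strip_edges[1::2]):
        if b > a:
            regions.append(("normal", (a, 0.0, b, 1500.0)))
    regions.append(("normal", (0.0, 1500.0, 8000.0, 6400.0)))

    radius = 150.0
    specs: list[TLSSpec] = []
    k = 0
    for cls, cx in lesions:
        for dist, dx in zip((150.0, 200.0, 300.0, 400.0), (-600.0, -200.0, 200.0, 600.0)):
            maturity = "mature" if k % 2 == 0 else "immature"
            assoc = cls if dist <= 250.0 else "excluded"
            specs.append(
                TLSSpec(
                    (cx + dx, 1500.0 + dist + radius),
                    radius,
                    maturity,
                    n_cells,
                    assoc,
                    dist,
                )
            )
            k += 1
    for i, (x, y) in enumerate(
        [(1000.0, 4600.0), (3000.0, 4600.0), (5000.0, 4600.0), (7000.0, 4600.0),
         (1000.0, 5600.0), (3000.0, 5600.0), (5000.0, 5600.0), (7000.0, 5600.0)]
    ):
        maturity = "mature" if i % 2 == 0 else "immature"
        specs.append(TLSSpec((x, y), radius, maturity, n_cells, "excluded", None))

    n_mature = sum(s.maturity == "mature" for s in specs)
    assert n_mature == 10 and len(specs) == 20

    densities = {
        "normal": {"T_CD4": 20, "T_CD8": 10, "B": 10, "Fibroblast": 100},
        "PanIN": {"Epithelial": 400, "T_CD4": 60, "T_CD8": 20},
        "PDAC": {"Epithelial": 400, "T_CD4": 50, "T_CD8": 15, "Treg": 20},
        "CP": {"Epithelial": 300, "T_CD4": 60, "T_CD8": 25},
    }
    return TissueSimConfig(
        regions=regions, densities=densities, tls_specs=specs, seed=seed
    )


#: the classic 12-chemokine TLS signature gene names, used as the planted
#: TLS-elevated signature in the spot generator
CHEMOKINE_SIGNATURE = [
    "CCL2", "CCL3", "CCL4", "CCL5", "CCL8", "CCL18",
    "CCL19", "CCL21", "CXCL9", "CXCL10", "CXCL11", "CXCL13",
]


def default_visium_config(
    seed: int = 0,
    n_genes: int = 600,
    K: int = 3,
    n_rows: int = 24,
    n_cols: int = 25,
    n_anchors: int = 40,
    delta: float = 1.0,
    noise: str = "poisson",
) -> VisiumSimConfig:
    """Planted spot experiment: K spatial patterns, one coupled to TLS spots.

    Spot weights are Gaussian bumps over the lattice (row-max 1); pattern 0
    is a tight bump whose high-weight spots are the planted TLS spots.  Each
    pattern owns ``n_anchors`` exclusive anchor genes; the remaining
    background genes load on all patterns with Dirichlet-distributed shares.
    The 12-chemokine signature genes are background genes additionally
    elevated by ``delta`` log2 units in TLS spots.
    """
    rng = np.random.default_rng(seed)
    lattice = HexLattice(n_rows, n_cols, 100.0)
    pos = lattice.positions()
    xy = pos[["x_um", "y_um"]].to_numpy()
    S = len(pos)

    x_span = xy[:, 0].max()
    y_span = xy[:, 1].max()
    centers = np.array(
        [
            [0.25 * x_span, 0.30 * y_span],
            [0.75 * x_span, 0.35 * y_span],
            [0.50 * x_span, 0.75 * y_span],
        ]
    )
    sigmas = np.array([150.0, 450.0, 500.0])
    if K > 3:
        extra = rng.uniform([0.1 * x_span, 0.1 * y_span], [0.9 * x_span, 0.9 * y_span],
                            size=(K - 3, 2))
        centers = np.vstack([centers, extra])
        sigmas = np.concatenate([sigmas, np.full(K - 3, 400.0)])
    centers, sigmas = centers[:K], sigmas[:K]

    P = np.empty((K, S))
    for k in range(K):
        d2 = ((xy - centers[k]) ** 2).sum(axis=1)
        P[k] = np.exp(-d2 / (2 * sigmas[k] ** 2))
        P[k] /= P[k].max()
    tls_spots = np.flatnonzero(P[0] >= 0.6).tolist()

    n_sig = len(CHEMOKINE_SIGNATURE)
    n_background = n_genes - K * n_anchors
    if n_background < n_sig:
        raise ValueError("n_genes too small for the anchor/background split")
    genes: list[str] = []
    gene_patterns: dict[str, int] = {}
    A = np.zeros((n_genes, K))
    row = 0
    for k in range(K):
        for a in range(n_anchors):
            name = f"ANCHOR{k}_{a:02d}"
            genes.append(name)
            gene_patterns[name] = k
            A[row, k] = rng.uniform(3.0, 6.0)
            row += 1
    for b in range(n_background):
        # signature genes are statistically exchangeable with background
        # genes: their entire TLS elevation is the planted delta, nothing
        # else, so bin-matched controls cancel the baseline exactly
        w = rng.dirichlet([5.0] * K)
        base = rng.uniform(3.0, 6.0)
        name = CHEMOKINE_SIGNATURE[b] if b < n_sig else f"BG_{b:04d}"
        genes.append(name)
        A[row] = base * w
        row += 1

    return VisiumSimConfig(
        n_rows=n_rows,
        n_cols=n_cols,
        A_true=A,
        P_true=P,
        genes=genes,
        signature_genes=list(CHEMOKINE_SIGNATURE),
        delta=delta,
        tls_spots=tls_spots,
        noise=noise,
        seed=seed,
        gene_patterns=gene_patterns,
    )


def flat_signature_config(
    seed: int = 0,
    n_genes: int = 600,
    n_rows: int = 25,
    n_cols: int = 40,
    n_tls_spots: int = 50,
    delta: float = 1.0,
    noise: str = "poisson",
) -> VisiumSimConfig:
    """Spatially flat field with a signature elevated only in TLS spots.

    Every gene has a constant log2 mean across spots (drawn Uniform(2, 6)),
    so the planted ``delta`` is the sole TLS-vs-other difference — the
    unconfounded setting for measuring module-score fidelity.  The default
    lattice carries 500 spots, 50 of them TLS.
    """
    rng = np.random.default_rng(seed)
    lattice = HexLattice(n_rows, n_cols, 100.0)
    S = len(lattice.spots())
    base = rng.uniform(2.0, 6.0, size=n_genes)
    genes = [f"gene_{i:04d}" for i in range(n_genes)]
    n_sig = len(CHEMOKINE_SIGNATURE)
    genes[:n_sig] = list(CHEMOKINE_SIGNATURE)
    tls_spots = rng.choice(S, size=n_tls_spots, replace=False).tolist()
    return VisiumSimConfig(
        n_rows=n_rows,
        n_cols=n_cols,
        A_true=base[:, None],
        P_true=np.ones((1, S)),
        genes=genes,
        signature_genes=list(CHEMOKINE_SIGNATURE),
        delta=delta,
        tls_spots=tls_spots,
        noise=noise,
        seed=seed,
    )
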