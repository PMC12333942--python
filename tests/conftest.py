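import pytest

import lesionscape as ls
from lesionscape import synthetic as syn


@pytest.fixture(scope="session")
def marker_threshold():
    """Midpoint positivity threshold of the default intensity model."""
    return syn.MarkerModel().threshold(5.0)


@pytest.fixture(scope="session")
def demo_cellmap():
    cfg = syn.demo_tissue_config(seed=11)
    cells, regions, truth = syn.generate_cell_map(cfg)
    return cfg, cells, regions, truth


@pytest.fixture(scope="session")
def demo_phenotyped(demo_cellmap, marker_threshold):
    cfg, cells, regions, truth = demo_cellmap
    ph = ls.phenotype_cells(cells, thresholds=marker_threshold)
    return cfg, ph, regions, truth


@pytest.fixture(scope="session")
def tls_benchmark(marker_threshold):
    """20 planted aggregates (half mature) at known lesion distances."""
    cfg = syn.tls_benchmark_config(seed=7)
    cells, regions, truth = syn.generate_cell_map(cfg)
    ph = ls.phenotype_cells(cells, thresholds=marker_threshold)
    records = ls.profile_tls(ph, regions)
    return ph, regions, truth, records


@pytest.fixture(scope="session")
def visium_demo():
    cfg = syn.default_visium_config(seed=0)
    spots, truth = syn.generate_spot_data(cfg)
    return cfg, spots, truth


def match_planted_tls(record, planted):
    """Planted aggregate whose centre is nearest a detected record's hull."""
    c = record.hull.centroid
    return min(
        planted,
        key=lambda t: (t["center"][0] - c.x) ** 2 + (t["center"][1] - c.y) ** 2,
    )
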