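import numpy as np
import pandas as pd
import pytest

from lesionscape import synthetic as syn
from lesionscape.st_patterns import log_transform


def one_region_config(density, seed=0, phenotype="T_CD4", **kw):
    return syn.TissueSimConfig(
        regions=[("PanIN", (0, 0, 1000, 1000))],
        densities={"PanIN": {phenotype: density}},
        seed=seed,
        **kw,
    )


class TestCellMap:
    def test_fixed_seed_bitwise_reproducible(self):
        cfg = syn.demo_tissue_config(seed=42)
        a, _, ta = syn.generate_cell_map(cfg)
        b, _, tb = syn.generate_cell_map(syn.demo_tissue_config(seed=42))
        pd.testing.assert_frame_equal(a, b)
        assert (ta.cell_phenotype == tb.cell_phenotype).all()

    def test_zero_density_zero_rows(self):
        cells, _, _ = syn.generate_cell_map(one_region_config(0.0))
        assert len(cells) == 0

    def test_poisson_count_moments(self):
        # density 100/mm^2 over 1 mm^2: mean count 100, sd 10; check over
        # 100 replicates that the mean sits within 4 sigma of the target
        counts = [
            len(syn.generate_cell_map(one_region_config(100.0, seed=s))[0])
            for s in range(100)
        ]
        assert abs(np.mean(counts) - 100) < 4 * 10 / np.sqrt(100)

    def test_mature_tls_geometry(self):
        cfg = syn.TissueSimConfig(
            regions=[("normal", (0, 0, 2000, 2000))],
            densities={"normal": {}},
            tls_specs=[syn.TLSSpec((1000, 1000), 150.0, "mature", 200)],
            seed=3,
        )
        cells, _, truth = syn.generate_cell_map(cfg)
        gc = cells[truth.cell_phenotype == "B_GC"]
        assert len(gc) >= 1
        r = np.hypot(gc["x_um"] - 1000, gc["y_um"] - 1000)
        assert (r <= 0.5 * 150.0).all()  # GC B confined to the inner disc
        t = cells[np.isin(truth.cell_phenotype, ["T_CD4", "T_CD8"])]
        rt = np.hypot(t["x_um"] - 1000, t["y_um"] - 1000)
        assert (rt >= 0.5 * 150.0).all()  # T cells confined to the annulus

    def test_overlapping_regions_rejected(self):
        cfg = syn.TissueSimConfig(
            regions=[("PanIN", (0, 0, 1000, 1000)), ("PDAC", (500, 500, 1500, 1500))],
            densities={},
        )
        with pytest.raises(ValueError, match="overlap"):
            syn.generate_cell_map(cfg)

    def test_tls_outside_regions_rejected(self):
        cfg = syn.TissueSimConfig(
            regions=[("normal", (0, 0, 1000, 1000))],
            densities={},
            tls_specs=[syn.TLSSpec((5000, 5000), 100.0, "immature", 50)],
        )
        with pytest.raises(ValueError, match="outside"):
            syn.generate_cell_map(cfg)

    def test_intensities_non_negative_and_positive_markers_high(self):
        cells, _, truth = syn.generate_cell_map(one_region_config(200.0, phenotype="Treg"))
        markers = syn.DEFAULT_MARKERS
        assert (cells[markers].to_numpy() >= 0).all()
        assert cells["CD3"].median() > cells["CD8"].median()


class TestSpotData:
    def test_noiseless_rank_one_identity(self):
        rng = np.random.default_rng(0)
        u = rng.uniform(1, 3, 50)
        lat_spots = len(syn.VisiumSimConfig(
            n_rows=10, n_cols=10, A_true=np.ones((1, 1)), P_true=np.ones((1, 50))
        ).lattice.spots())
        v = rng.uniform(0.2, 1.0, lat_spots)
        cfg = syn.VisiumSimConfig(
            n_rows=10, n_cols=10, A_true=u[:, None], P_true=v[None, :], noise="none"
        )
        spots, _ = syn.generate_spot_data(cfg)
        M = np.outer(u, v)
        # counts = round(2^M - 1): the worst rounding error in log2(c + 1)
        # occurs at 2^M - 1 = 1/2 and equals log2(1.5)
        assert np.abs(log_transform(spots.counts) - M).max() <= np.log2(1.5) + 1e-9

    def test_delta_zero_identical_law(self):
        base = dict(
            n_rows=10, n_cols=10,
            A_true=np.full((20, 1), 3.0), P_true=np.ones((1, 50)),
            tls_spots=[0, 1, 2], seed=9,
        )
        a, _ = syn.generate_spot_data(syn.VisiumSimConfig(**base, delta=0.0,
                                                          signature_genes=["gene_0000"]))
        b, _ = syn.generate_spot_data(syn.VisiumSimConfig(**base))
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_poisson_moments(self):
        # mean 2^M - 1 = 10 over ~1000 spots: empirical mean within 3 SE
        n_rows, n_cols = 40, 50  # 1000 occupied spots
        cfg = syn.VisiumSimConfig(
            n_rows=n_rows, n_cols=n_cols,
            A_true=np.array([[np.log2(11.0)]]),
            P_true=np.ones((1, 1000)),
            libsize_sigma=0.0,
            seed=4,
        )
        spots, _ = syn.generate_spot_data(cfg)
        assert abs(spots.counts.mean() - 10) < 3 * np.sqrt(10 / 1000)

    def test_counts_integral_and_lattice_parity(self):
        cfg = syn.default_visium_config(seed=1)
        spots, _ = syn.generate_spot_data(cfg)
        assert spots.counts.dtype.kind == "i"
        assert (spots.counts >= 0).all()
        rc = spots.positions[["array_row", "array_col"]].to_numpy()
        assert ((rc.sum(axis=1) % 2) == 0).all()

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            syn.VisiumSimConfig(
                n_rows=5, n_cols=5, A_true=-np.ones((3, 1)), P_true=np.ones((1, 13))
            )
        cfg = syn.VisiumSimConfig(
            n_rows=5, n_cols=5, A_true=np.full((3, 1), 2.0), P_true=np.ones((1, 13)),
            signature_genes=["gene_0000"], tls_spots=[0], delta=-99.0,
        )
        with pytest.raises(ValueError, match="delta"):
            syn.generate_spot_data(cfg)

    def test_seed_reproducible(self):
        cfg = syn.default_visium_config(seed=5)
        a, _ = syn.generate_spot_data(cfg)
        b, _ = syn.generate_spot_data(syn.default_visium_config(seed=5))
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_ground_truth_complete(self):
        cfg = syn.default_visium_config(seed=0)
        spots, truth = syn.generate_spot_data(cfg)
        assert set(truth.signature_genes) <= set(spots.genes)
        assert len(truth.tls_spots) == len(set(truth.tls_spots))
        anchors = [g for g in spots.genes if g.startswith("ANCHOR")]
        assert set(anchors) == set(truth.gene_patterns)
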