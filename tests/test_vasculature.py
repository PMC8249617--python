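import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clearvasc import phantoms, vasculature as vasc
from clearvasc.imstore import LabelMask
from conftest import SPACING, cylinder_mask


class TestConfig:
    def test_defaults_valid(self):
        cfg = vasc.VesselPipelineConfig()
        assert cfg.threshold == (170, 255)
        assert cfg.median_radius == 3
        assert cfg.fill_iterations == 2
        assert cfg.min_segment_length == 10.0

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            vasc.VesselPipelineConfig(threshold=(300, 255))

    def test_bad_orientation(self):
        with pytest.raises(ValueError):
            vasc.VesselPipelineConfig(fill_orientations=("XY", "QQ"))


def _hollow_cylinder(radius=12.0, wall=3.0, shape=(20, 40, 40), spacing=SPACING):
    z, y, x = np.indices(shape).astype(float)
    cy = shape[1] * spacing[1] / 2
    r = np.hypot(y * spacing[1] - cy, x * spacing[2] - cy)
    data = ((r <= radius) & (r > radius - wall)).astype(np.uint8)
    filled = (r <= radius).astype(np.uint8)
    return LabelMask(data, spacing), LabelMask(filled, spacing)


class TestFillLumens:
    def test_hollow_cylinder_filled_to_truth(self):
        hollow, filled = _hollow_cylinder()
        out = vasc.fill_lumens(hollow, (None, np.pi * 50**2))
        np.testing.assert_array_equal(out.data, filled.data)

    def test_lumen_larger_than_range_unchanged(self):
        hollow, _ = _hollow_cylinder(radius=12.0, wall=3.0)
        lumen_area = np.pi * 9.0**2
        out = vasc.fill_lumens(hollow, (1.0, lumen_area / 2))
        np.testing.assert_array_equal(out.data, hollow.data)

    def test_c_shaped_wall_filled_only_by_closing_orientation(self):
        # hollow box, one wall slit over all z: every XY ring is open (a "C"),
        # but YZ cross-sections stay closed rectangles
        data = np.zeros((24, 24, 24), np.uint8)
        data[4:18, 4:18, 4:18] = 1
        data[6:16, 6:16, 6:16] = 0           # lumen
        data[6:16, 9:13, 16:18] = 0          # slit through the +x wall
        m = LabelMask(data, (1.0, 1.0, 1.0))
        out_xy = vasc.fill_lumens(m, (4.0, 200.0), orientations=("XY",), iterations=2)
        np.testing.assert_array_equal(out_xy.data, m.data)
        out_yz = vasc.fill_lumens(m, (4.0, 200.0), orientations=("YZ",), iterations=2)
        assert out_yz.data[10, 10, 10] == 1  # lumen voxel filled
        assert out_yz.data.sum() > m.data.sum()

    def test_never_deletes_foreground(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            data = (rng.random((16, 16, 16)) < 0.5).astype(np.uint8)
            m = LabelMask(data, (1.0, 1.0, 1.0))
            out = vasc.fill_lumens(m, (1.0, 40.0))
            assert np.all(out.data >= data)

    def test_idempotent_once_converged(self):
        hollow, _ = _hollow_cylinder()
        two = vasc.fill_lumens(hollow, (None, np.pi * 50**2), iterations=2)
        three = vasc.fill_lumens(hollow, (None, np.pi * 50**2), iterations=3)
        np.testing.assert_array_equal(two.data, three.data)

    def test_empty_orientations_rejected(self):
        hollow, _ = _hollow_cylinder()
        with pytest.raises(ValueError):
            vasc.fill_lumens(hollow, orientations=())


class TestFillLumensOracle:
    def test_all_foreground_unchanged(self):
        m = LabelMask(np.ones((8, 8, 8), np.uint8), (1, 1, 1))
        np.testing.assert_array_equal(vasc.fill_lumens_oracle(m).data, m.data)

    def test_all_background_unchanged(self):
        m = LabelMask(np.zeros((8, 8, 8), np.uint8), (1, 1, 1))
        assert not vasc.fill_lumens_oracle(m).data.any()

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_fast_implementation(self, seed):
        rng = np.random.default_rng(seed)
        data = (rng.random((24, 24, 24)) < rng.uniform(0.3, 0.6)).astype(np.uint8)
        m = LabelMask(data, (1.5, 0.8, 0.8))
        kwargs = dict(area_range=(2.0, 80.0), orientations=("XY", "YZ", "XZ"), iterations=2)
        fast = vasc.fill_lumens(m, **kwargs)
        slow = vasc.fill_lumens_oracle(m, **kwargs)
        np.testing.assert_array_equal(fast.data, slow.data)


class TestPostprocessVesselMask:
    def test_empty_stays_empty(self):
        m = LabelMask(np.zeros((8, 16, 16), np.uint8), SPACING)
        assert not vasc.postprocess_vessel_mask(m).data.any()

    def test_speckle_removed(self):
        rng = np.random.default_rng(0)
        data = np.zeros((30, 80, 80), np.uint8)
        idx = rng.integers(0, [30, 80, 80], size=(200, 3))
        data[tuple(idx.T)] = 1
        cfg = vasc.VesselPipelineConfig(threshold=(105, 255), median_radius=1)
        out = vasc.postprocess_vessel_mask(LabelMask(data, SPACING), cfg)
        assert out.data.sum() <= 0.01 * 200

    def test_solid_tube_volume_preserved(self):
        L = 40 * 3.0
        cl = [(np.array([[0.0, 55.0, 55.0], [L, 55.0, 55.0]]), 5.0)]
        spec = phantoms.PhantomSpec(shape=(40, 160, 160), spacing=SPACING,
                                    centerlines=cl, noise_sd=0.0, seed=0)
        _, truth = phantoms.make_vessel_phantom(spec)
        cfg = vasc.VesselPipelineConfig(threshold=(105, 255), median_radius=1)
        out = vasc.postprocess_vessel_mask(truth.vessel_mask, cfg)
        ratio = out.data.sum() / truth.vessel_mask.data.sum()
        assert abs(ratio - 1.0) < 0.15

    def test_hollow_vessels_recovered_end_to_end(self):
        spec = phantoms.PhantomSpec(shape=(40, 160, 160), spacing=SPACING,
                                    n_vessels=5, radius_range=(3.0, 14.0),
                                    hollow_above=8.0, wall_thickness=2.5,
                                    noise_sd=4.0, seed=4)
        lectin, truth = phantoms.make_vessel_phantom(spec)
        seg = LabelMask((lectin.data >= 120).astype(np.uint8), SPACING)
        cfg = vasc.VesselPipelineConfig(threshold=(105, 255), median_radius=1)
        out = vasc.postprocess_vessel_mask(seg, cfg)
        tv, ov = truth.vessel_mask.binary(), out.binary()
        dice = 2 * (tv & ov).sum() / (tv.sum() + ov.sum())
        assert dice >= 0.9


class TestSkeletonize:
    def test_empty_mask_empty_graph(self):
        g = vasc.skeletonize_to_graph(LabelMask(np.zeros((6, 8, 8), np.uint8), SPACING))
        assert g.segments == [] and g.nodes == {}

    def test_straight_cylinder_geometry(self, straight_tube_mask):
        g = vasc.skeletonize_to_graph(straight_tube_mask, 10.0)
        assert len(g.segments) == 1
        seg = g.segments[0]
        assert 95.0 <= seg.length <= 105.0
        assert 1.0 - 1e-9 <= seg.tortuosity <= 1.05
        assert g.n_junctions == 0

    def test_y_junction_topology(self, y_junction_phantom):
        g = vasc.skeletonize_to_graph(y_junction_phantom.vessel_mask, 10.0)
        degrees = sorted(n.degree for n in g.nodes.values())
        assert degrees == [1, 1, 1, 3]
        assert g.n_junctions == 1
        assert len(g.segments) == 3
        for seg in g.segments:
            assert seg.tortuosity <= 1.05
            assert seg.length >= seg.chord - 1e-9

    def test_topology_preserved_one_component(self, y_junction_phantom):
        import networkx as nx

        g = vasc.skeletonize_to_graph(y_junction_phantom.vessel_mask, 10.0)
        nxg = nx.Graph()
        nxg.add_nodes_from(g.nodes)
        nxg.add_edges_from((s.u, s.v) for s in g.segments)
        assert nx.number_connected_components(nxg) == 1

    @pytest.mark.parametrize("radius", [3.0, 5.0, 10.0, 15.0])
    def test_diameter_recovery_with_fitted_correction(self, radius):
        g = vasc.skeletonize_to_graph(cylinder_mask(radius), 10.0)
        assert len(g.segments) == 1
        md = g.segments[0].mean_diameter
        # measured diameters are close on these phantoms; the fitted
        # correction (see test_fit below) reduces residuals further
        assert abs(md - 2 * radius) <= max(2 * 0.69, 0.15 * 2 * radius)


class TestPruneProbe:
    def test_exclusion_bound_recovered(self):
        lengths = np.arange(0.5, 20.01, 0.5)
        polylines = [
            np.array([[0.0, 40.0 * i, 0.0], [L, 40.0 * i, 0.0]])
            for i, L in enumerate(lengths)
        ]
        graph = vasc.graph_from_polylines(polylines, radii=1.0)
        vasc.prune_graph(graph, vasc.VesselPipelineConfig().min_segment_length)
        kept = sorted(s.length for s in graph.segments)
        assert kept[0] == pytest.approx(10.0)
        assert all(L >= 10.0 for L in kept)

    def test_short_terminal_twig_pruned_long_path_kept(self):
        main = np.array([[0.0, 0, 0], [50.0, 0, 0], [100.0, 0, 0]])
        twig = np.array([[50.0, 0, 0], [50.0, 4.0, 0]])
        graph = vasc.graph_from_polylines([main[:2], main[1:], twig], radii=1.0)
        vasc.prune_graph(graph, 10.0)
        # twig removed, the two halves merged through the degree-2 node
        assert len(graph.segments) == 1
        assert graph.segments[0].length == pytest.approx(100.0)


class TestGraphSummary:
    def test_single_segment_mean_tortuosity(self):
        pts = np.array([[0.0, 0, 0], [30.0, 0, 0], [60.0, 5.0, 0]])
        g = vasc.graph_from_polylines([pts], radii=2.0, mask_volume_um3=500.0)
        s = vasc.graph_summary(g, tissue_volume_mm3=1e-3)
        assert s["mean_tortuosity"] == pytest.approx(g.segments[0].tortuosity)
        assert s["n_segments"] == 1

    def test_volume_fraction_analytic(self, straight_tube_mask):
        g = vasc.skeletonize_to_graph(straight_tube_mask, 10.0)
        shape = straight_tube_mask.shape
        tissue_um3 = np.prod(shape) * straight_tube_mask.voxel_volume
        s = vasc.graph_summary(g, tissue_um3 / 1e9)
        expected = np.pi * 25.0 * 100.0 / tissue_um3
        assert s["vascular_volume_fraction"] == pytest.approx(expected, rel=0.10)

    def test_histogram_masses_sum_to_fraction(self, y_junction_phantom):
        g = vasc.skeletonize_to_graph(y_junction_phantom.vessel_mask, 10.0)
        s = vasc.graph_summary(g, 0.005)
        assert sum(s["diameter_hist_volume_fraction"]) == pytest.approx(
            s["vascular_volume_fraction"], abs=1e-6
        )

    def test_nonpositive_tissue_volume(self):
        g = vasc.VesselGraph()
        with pytest.raises(ValueError):
            vasc.graph_summary(g, 0.0)


class TestCorrectionFactor:
    def test_at_zero_is_y0(self):
        assert vasc.correction_factor(0.0) == pytest.approx(3.7, abs=1e-12)

    def test_limit_is_plateau(self):
        assert vasc.correction_factor(1e6) == pytest.approx(1.3, abs=1e-9)

    def test_degenerate_constant(self):
        p = vasc.DiameterCorrection(Y0=2.0, Plateau=2.0, K=0.9)
        for md in (0.0, 1.0, 10.0, 100.0):
            assert vasc.correction_factor(md, p) == pytest.approx(2.0)

    def test_negative_md_rejected(self):
        with pytest.raises(ValueError):
            vasc.correction_factor(-1.0)

    @given(st.floats(0.0, 50.0), st.floats(0.01, 49.9))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing(self, md, delta):
        p = vasc.DiameterCorrection()
        assert vasc.correction_factor(md + delta, p) < vasc.correction_factor(md, p)

    def test_corrected_diameter_is_product(self):
        md = np.array([1.0, 5.0, 20.0])
        np.testing.assert_allclose(
            vasc.apply_diameter_correction(md),
            md * vasc.correction_factor(md),
        )


class TestFitDiameterCorrection:
    def test_noiseless_recovery(self):
        truth = vasc.DiameterCorrection(3.7, 1.3, 0.5861)
        md = np.linspace(1.0, 30.0, 40)
        pairs = [(m, m * vasc.correction_factor(m, truth)) for m in md]
        fit, rms = vasc.fit_diameter_correction(pairs)
        assert rms < 1e-8
        assert fit.Y0 == pytest.approx(3.7, abs=1e-6)
        assert fit.Plateau == pytest.approx(1.3, abs=1e-6)
        assert fit.K == pytest.approx(0.5861, abs=1e-6)

    def test_constant_cf_flat_fit(self):
        pairs = [(m, 2.5 * m) for m in (1.0, 3.0, 7.0, 12.0, 20.0)]
        fit, rms = vasc.fit_diameter_correction(pairs)
        assert rms < 1e-8
        assert fit.Y0 == pytest.approx(2.5, abs=1e-4)
        assert fit.Plateau == pytest.approx(2.5, abs=1e-4)

    def test_noisy_recovery_within_10pct(self):
        truth = vasc.DiameterCorrection(3.7, 1.3, 0.5861)
        rng = np.random.default_rng(0)
        md = rng.uniform(1.0, 30.0, 100)
        pairs = [
            (m, m * vasc.correction_factor(m, truth) * rng.normal(1.0, 0.05))
            for m in md
        ]
        fit, _ = vasc.fit_diameter_correction(pairs)
        assert fit.Y0 == pytest.approx(3.7, rel=0.10)
        assert fit.Plateau == pytest.approx(1.3, rel=0.10)
        assert fit.K == pytest.approx(0.5861, rel=0.10)

    def test_validation(self):
        with pytest.raises(ValueError):
            vasc.fit_diameter_correction([(1.0, 1.0), (2.0, 2.0)])
        with pytest.raises(ValueError):
            vasc.fit_diameter_correction([(2.0, 1.0)] * 5)
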