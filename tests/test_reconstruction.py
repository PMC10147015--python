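"""Detection, nucleus gating, tracing, pruning, diameters, soma import."""

import dataclasses

import networkx as nx
import numpy as np
import pytest

from gliatrace import image_io
from gliatrace.reconstruction import (
    TraceParams,
    detect_seed_points,
    detect_starting_points,
    filter_by_nucleus,
    fit_diameters,
    import_somas,
    remove_disconnected_segments,
    trace_filaments,
)
from gliatrace.skeleton import FilamentGraph
from gliatrace.synthetic import CellSpec, SceneSpec, morphology_preset, rasterize_scene

from conftest import make_graph

VOX = (0.8, 0.25, 0.25)
PARAMS = TraceParams(starting_diameter_um=8.0)


def noise_free(**kw):
    base = dict(
        field_xy_um=48.0, n_slices=30, voxel_xy_um=0.25, voxel_z_um=0.8,
        noise_gaussian_sd=0.0, noise_poisson_scale=0.0,
    )
    base.update(kw)
    return SceneSpec(**base)


def straight_cell(seg=8.0):
    return CellSpec(
        soma_radius_um=3.5, nucleus_radius_um=2.5, n_primary=1, branch_prob=0.0,
        tortuosity=0.0, segment_length_mean_um=seg, segment_length_sd_um=0.0,
        max_order=1, process_radius_um=0.6,
    )


@pytest.fixture(scope="module")
def straight_scene():
    scene = noise_free(n_cells=1, seed=0)
    # 10 um beyond a 3.5 um soma: tip well outside the seed exclusion zone
    stack, gt = rasterize_scene(
        scene, [straight_cell(13.5)], soma_centers=[np.array([12.0, 24.0, 18.0])]
    )
    f = stack.to_float()
    coloc = image_io.colocalization_channel(f.channels["iba1"], f.channels["dapi"])
    return stack, gt, f.channels["iba1"], f.channels["dapi"], coloc


class TestDetectStartingPoints:
    def test_multi_cell_scene_finds_each_soma(self):
        scene = noise_free(
            field_xy_um=80.0, n_cells=5, min_soma_separation_um=17.0, seed=21
        )
        specs = [morphology_preset("ameboid") for _ in range(5)]
        stack, gt = rasterize_scene(scene, specs)
        f = stack.to_float()
        coloc = image_io.colocalization_channel(f.channels["iba1"], f.channels["dapi"])
        pts = detect_starting_points(coloc, PARAMS, stack.voxel_size_um)
        assert len(pts) == 5
        diag = np.linalg.norm(stack.voxel_size_um)
        for c in gt.soma_centers_um:
            err = min(np.linalg.norm(p.position_um - c) for p in pts)
            assert err <= diag

    def test_blank_channel_empty(self):
        pts = detect_starting_points(np.zeros((20, 40, 40)), PARAMS, VOX)
        assert pts == []

    def test_close_somas_suppressed_to_one(self):
        scene = noise_free(n_cells=2, min_soma_separation_um=5.0, seed=3)
        specs = [morphology_preset("ameboid") for _ in range(2)]
        centers = [np.array([12.0, 24.0, 21.0]), np.array([12.0, 24.0, 27.0])]
        stack, _ = rasterize_scene(scene, specs, soma_centers=centers)
        f = stack.to_float()
        coloc = image_io.colocalization_channel(f.channels["iba1"], f.channels["dapi"])
        pts = detect_starting_points(coloc, PARAMS, stack.voxel_size_um)
        assert len(pts) == 1  # 6 um apart < 8 um starting diameter


class TestFilterByNucleus:
    def test_interior_nucleus_kept(self, straight_scene):
        stack, gt, iba1, dapi, coloc = straight_scene
        pts = detect_starting_points(coloc, PARAMS, stack.voxel_size_um)
        kept = filter_by_nucleus(pts, dapi, 0.1, stack.voxel_size_um)
        assert len(kept) == len(pts) == 1

    def test_no_dapi_dropped(self, straight_scene):
        stack, gt, iba1, dapi, coloc = straight_scene
        pts = detect_starting_points(coloc, PARAMS, stack.voxel_size_um)
        assert filter_by_nucleus(pts, np.zeros_like(dapi), 0.1, stack.voxel_size_um) == []

    def test_nucleus_touching_first_slice_dropped(self):
        scene = noise_free(n_cells=1, seed=5)
        # soma so close to z=0 that the nucleus is clipped by the border
        stack, gt = rasterize_scene(
            scene, [straight_cell()], soma_centers=[np.array([1.0, 24.0, 24.0])]
        )
        f = stack.to_float()
        coloc = image_io.colocalization_channel(f.channels["iba1"], f.channels["dapi"])
        pts = detect_starting_points(coloc, PARAMS, stack.voxel_size_um)
        assert len(pts) >= 1
        kept = filter_by_nucleus(pts, f.channels["dapi"], 0.1, stack.voxel_size_um)
        assert kept == []


class TestDetectSeedPoints:
    def test_seeds_line_the_process(self, straight_scene):
        stack, gt, iba1, dapi, coloc = straight_scene
        pts = detect_starting_points(coloc, PARAMS, stack.voxel_size_um)
        seeds = detect_seed_points(iba1, PARAMS, pts, stack.voxel_size_um)
        assert len(seeds) >= 5
        soma = gt.soma_centers_um[0]
        tip_dir = np.array([0.0, 0.0, 1.0])
        for s in seeds:
            rel = s.position_um - soma
            assert np.linalg.norm(rel) >= PARAMS.starting_diameter_um / 2.0
            # on-axis: within the tube radius + a blur margin
            assert np.linalg.norm(rel - (rel @ tip_dir) * tip_dir) < 1.2

    def test_blank_channel_empty(self):
        assert detect_seed_points(np.zeros((10, 20, 20)), PARAMS, [], VOX) == []

    def test_zero_exclusion_factor_superset(self, straight_scene):
        stack, gt, iba1, dapi, coloc = straight_scene
        pts = detect_starting_points(coloc, PARAMS, stack.voxel_size_um)
        default = detect_seed_points(iba1, PARAMS, pts, stack.voxel_size_um)
        p0 = dataclasses.replace(PARAMS, remove_seed_radius_factor=0.0)
        unfiltered = detect_seed_points(iba1, p0, pts, stack.voxel_size_um)
        dpos = {tuple(np.round(s.position_um, 6)) for s in default}
        upos = {tuple(np.round(s.position_um, 6)) for s in unfiltered}
        assert dpos <= upos
        assert len(upos) > len(dpos)


class TestTraceFilaments:
    def test_straight_tube_length_within_5pct(self, straight_scene):
        stack, gt, iba1, dapi, coloc = straight_scene
        pts = detect_starting_points(coloc, PARAMS, stack.voxel_size_um)
        seeds = detect_seed_points(iba1, PARAMS, pts, stack.voxel_size_um)
        graphs = trace_filaments(iba1, pts, seeds, PARAMS, stack.voxel_size_um)
        assert len(graphs) == 1
        from gliatrace.morphometry import total_length

        truth = gt.metrics[0].total_filament_length_um
        assert total_length(graphs[0]) == pytest.approx(truth, rel=0.05)

    def test_no_seeds_soma_only(self, straight_scene):
        stack, gt, iba1, dapi, coloc = straight_scene
        pts = detect_starting_points(coloc, PARAMS, stack.voxel_size_um)
        graphs = trace_filaments(iba1, pts, [], PARAMS, stack.voxel_size_um)
        from gliatrace.morphometry import total_length

        assert len(graphs) == 1
        assert total_length(graphs[0]) == 0.0

    def test_two_disjoint_cells_no_shared_nodes(self):
        scene = noise_free(field_xy_um=64.0, n_cells=2,
                           min_soma_separation_um=30.0, seed=8)
        specs = [straight_cell(), straight_cell()]
        centers = [np.array([12.0, 16.0, 16.0]), np.array([12.0, 48.0, 48.0])]
        stack, gt = rasterize_scene(scene, specs, soma_centers=centers)
        f = stack.to_float()
        coloc = image_io.colocalization_channel(f.channels["iba1"], f.channels["dapi"])
        pts = detect_starting_points(coloc, PARAMS, stack.voxel_size_um)
        seeds = detect_seed_points(f.channels["iba1"], PARAMS, pts, stack.voxel_size_um)
        graphs = trace_filaments(f.channels["iba1"], pts, seeds, PARAMS, stack.voxel_size_um)
        assert len(graphs) == 2
        pos0 = {tuple(np.round(p, 6)) for p in graphs[0].node_positions()}
        pos1 = {tuple(np.round(p, 6)) for p in graphs[1].node_positions()}
        assert not pos0 & pos1
        for g in graphs:
            g.validate()

    def test_requires_starting_points(self, straight_scene):
        stack, gt, iba1, dapi, coloc = straight_scene
        with pytest.raises(ValueError):
            trace_filaments(iba1, [], [], PARAMS, stack.voxel_size_um)


class TestRemoveDisconnectedSegments:
    def _graph_with_leap(self):
        # soma chain plus a 5 um fragment attached across a 12 um dark leap
        pts = [(0.0, 0.0, 0.0), (0.0, 0.0, 2.0), (0.0, 0.0, 14.0), (0.0, 0.0, 19.0)]
        return make_graph(pts, [(0, 1), (1, 2), (2, 3)], radii=[3.0, 0.5, 0.5, 0.5])

    def _image(self):
        # bright only along the first 3 um and around 14-19 um: gap between
        img = np.full((8, 20, 100), 0.02)
        img[3:5, 8:12, 0:13] = 0.5  # x < 3.25 um
        img[3:5, 8:12, 55:80] = 0.5
        return img

    def test_leap_fragment_removed(self):
        fg = self._graph_with_leap()
        out = remove_disconnected_segments(fg, self._image(), PARAMS, VOX)
        assert out.n_nodes() == 2
        assert 0 in out.graph.nodes

    def test_infinite_gap_identity(self):
        fg = self._graph_with_leap()
        p = dataclasses.replace(PARAMS, max_gap_um=np.inf)
        out = remove_disconnected_segments(fg, self._image(), p, VOX)
        assert out.n_nodes() == fg.n_nodes()

    def test_fully_connected_identity(self):
        fg = self._graph_with_leap()
        bright = np.full((8, 20, 100), 0.5)
        out = remove_disconnected_segments(fg, bright, PARAMS, VOX)
        assert out.n_nodes() == fg.n_nodes()


class TestFitDiameters:
    def test_tube_radius_recovered_within_20pct(self):
        # gentler axial PSF so FWHM broadening stays inside the tolerance
        scene = dataclasses.replace(
            noise_free(n_cells=1, seed=0), psf_sigma_um=(0.3, 0.15, 0.15)
        )
        stack, gt = rasterize_scene(
            scene, [straight_cell(13.5)], soma_centers=[np.array([12.0, 24.0, 18.0])]
        )
        f = stack.to_float()
        iba1 = f.channels["iba1"]
        coloc = image_io.colocalization_channel(iba1, f.channels["dapi"])
        pts = detect_starting_points(coloc, PARAMS, stack.voxel_size_um)
        seeds = detect_seed_points(iba1, PARAMS, pts, stack.voxel_size_um)
        graphs = trace_filaments(iba1, pts, seeds, PARAMS, stack.voxel_size_um)
        fitted = fit_diameters(graphs[0], iba1, PARAMS, stack.voxel_size_um)
        soma = gt.soma_centers_um[0]
        radii = [
            fitted.radius(n)
            for n in fitted.graph.nodes
            if n != fitted.soma
            and np.linalg.norm(fitted.pos(n) - soma) > 6.0
            and np.linalg.norm(fitted.pos(n) - soma) < 12.0
        ]
        assert radii
        assert np.mean(radii) == pytest.approx(0.6, rel=0.2)

    def test_radius_clamped_to_starting_radius(self, straight_scene):
        stack, gt, iba1, dapi, coloc = straight_scene
        pts = detect_starting_points(coloc, PARAMS, stack.voxel_size_um)
        seeds = detect_seed_points(iba1, PARAMS, pts, stack.voxel_size_um)
        graphs = trace_filaments(iba1, pts, seeds, PARAMS, stack.voxel_size_um)
        fitted = fit_diameters(graphs[0], np.ones_like(iba1), PARAMS, stack.voxel_size_um)
        r_max = PARAMS.starting_diameter_um / 2.0
        assert all(
            fitted.radius(n) <= r_max + 1e-9 for n in fitted.graph.nodes
        )

    def test_soma_node_radius_untouched(self, straight_scene):
        stack, gt, iba1, dapi, coloc = straight_scene
        pts = detect_starting_points(coloc, PARAMS, stack.voxel_size_um)
        seeds = detect_seed_points(iba1, PARAMS, pts, stack.voxel_size_um)
        graphs = trace_filaments(iba1, pts, seeds, PARAMS, stack.voxel_size_um)
        fitted = fit_diameters(graphs[0], iba1, PARAMS, stack.voxel_size_um)
        assert fitted.radius(fitted.soma) == graphs[0].radius(graphs[0].soma)


class TestImportSomas:
    def test_volume_within_10pct_of_sphere(self):
        scene = noise_free(n_cells=1, seed=6)
        spec = straight_cell()
        # soma-filling nucleus: the coloc body spans the whole soma
        spec.soma_radius_um = 3.0
        spec.nucleus_radius_um = 3.0
        stack, gt = rasterize_scene(scene, [spec], soma_centers=[np.array([12.0, 24.0, 24.0])])
        f = stack.to_float()
        coloc = image_io.colocalization_channel(f.channels["iba1"], f.channels["dapi"])
        pts = detect_starting_points(coloc, PARAMS, stack.voxel_size_um)
        graphs = trace_filaments(f.channels["iba1"], pts, [], PARAMS, stack.voxel_size_um)
        out = import_somas(graphs, coloc, 0.45, stack.voxel_size_um)
        true_vol = 4.0 / 3.0 * np.pi * 27.0
        assert not out[0].soma_volume_is_fallback
        assert out[0].soma_volume_um3 == pytest.approx(true_vol, rel=0.10)

    def test_blank_coloc_falls_back_flagged(self, straight_scene):
        stack, gt, iba1, dapi, coloc = straight_scene
        pts = detect_starting_points(coloc, PARAMS, stack.voxel_size_um)
        graphs = trace_filaments(iba1, pts, [], PARAMS, stack.voxel_size_um)
        out = import_somas(graphs, np.zeros_like(coloc), 0.15, stack.voxel_size_um)
        assert out[0].soma_volume_is_fallback
        r = graphs[0].radius(graphs[0].soma)
        assert out[0].soma_volume_um3 == pytest.approx(4.0 / 3.0 * np.pi * r**3)

    def test_two_components_assigned_by_containment(self):
        scene = noise_free(field_xy_um=64.0, n_cells=2,
                           min_soma_separation_um=30.0, seed=9)
        specs = [straight_cell(), straight_cell()]
        centers = [np.array([12.0, 16.0, 16.0]), np.array([12.0, 48.0, 48.0])]
        stack, gt = rasterize_scene(scene, specs, soma_centers=centers)
        f = stack.to_float()
        coloc = image_io.colocalization_channel(f.channels["iba1"], f.channels["dapi"])
        pts = detect_starting_points(coloc, PARAMS, stack.voxel_size_um)
        graphs = trace_filaments(f.channels["iba1"], pts, [], PARAMS, stack.voxel_size_um)
        out = import_somas(graphs, coloc, 0.15, stack.voxel_size_um)
        assert len(out) == 2
        assert not any(g.soma_volume_is_fallback for g in out)
        # identical cells: volumes close; assignment must not have swapped
        for g in out:
            assert g.soma_volume_um3 > 0


class TestDeterminism:
    def test_identical_graphs_on_reruns(self, straight_scene):
        stack, gt, iba1, dapi, coloc = straight_scene
        pts = detect_starting_points(coloc, PARAMS, stack.voxel_size_um)
        seeds = detect_seed_points(iba1, PARAMS, pts, stack.voxel_size_um)
        g1 = trace_filaments(iba1, pts, seeds, PARAMS, stack.voxel_size_um)
        g2 = trace_filaments(iba1, pts, seeds, PARAMS, stack.voxel_size_um)
        np.testing.assert_array_equal(
            g1[0].node_positions(), g2[0].node_positions()
        )


class TestDebrisMaskingHelpsSeeds:
    def test_masking_reduces_false_seeds(self):
        from gliatrace.debris import (
            DebrisCriteria,
            debris_mask,
            label_surfaces,
            select_debris,
        )

        scene = noise_free(n_cells=1, seed=13)
        scene = dataclasses.replace(scene, n_debris=15)
        stack, gt = rasterize_scene(
            scene, [straight_cell()], soma_centers=[np.array([12.0, 24.0, 24.0])]
        )
        f = stack.to_float()
        iba1 = f.channels["iba1"]
        coloc = image_io.colocalization_channel(iba1, f.channels["dapi"])
        pts = detect_starting_points(coloc, PARAMS, stack.voxel_size_um)
        raw_seeds = detect_seed_points(iba1, PARAMS, pts, stack.voxel_size_um)
        crit = DebrisCriteria()
        objs = label_surfaces(iba1, crit.threshold, stack.voxel_size_um)
        sel = select_debris(objs, crit)
        mask = debris_mask(
            iba1, crit.threshold, sel, voxel_size=stack.voxel_size_um, dilation_um=1.0
        )
        masked = image_io.mask_voxels(iba1, mask, float(np.median(iba1)))
        clean_seeds = detect_seed_points(masked, PARAMS, pts, stack.voxel_size_um)
        assert len(sel) > 0
        assert len(clean_seeds) < len(raw_seeds)
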