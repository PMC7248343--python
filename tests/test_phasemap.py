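import numpy as np
import pytest
from scipy import ndimage

from memphase import synthgen as sg
from memphase.phasemap import (DensityField, difference_field, interface_edges,
                               label_regions, segment_frame,
                               smoothed_species_field)
from memphase.trajio import Frame


def _frame_with_tail_beads(xy, box=(20.0, 20.0, 10.0), species="DPPC"):
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    n = len(xy)
    pos = np.column_stack([xy, np.full(n, box[2] / 2)])
    return Frame(positions=pos, names=["C1A"] * n,
                 molecule_ids=np.arange(1, n + 1),
                 molecule_types=[species] * n, bead_types=["C1A"] * n,
                 charges=np.zeros(n), box=box)


class TestDensityField:
    def test_single_bead_peak_and_normalization(self):
        fr = _frame_with_tail_beads([[10.0, 10.0]])
        f = smoothed_species_field(fr, "DPPC")
        imax = np.unravel_index(np.argmax(f.values), f.values.shape)
        assert np.allclose(np.array(imax) * f.spacing, [10.0, 10.0], atol=0.1)
        assert f.values.sum() * f.spacing ** 2 == pytest.approx(1.0, rel=1e-9)

    def test_periodicity_against_tiled_oracle(self):
        """Wrap-mode smoothing equals explicit 3x3 image tiling."""
        rng = np.random.default_rng(0)
        box = (8.0, 8.0, 5.0)
        pts = np.column_stack([rng.uniform(0, 8, 30), rng.uniform(0, 8, 30)])
        pts[0] = (0.0, 4.0)  # bead exactly on the periodic edge
        fr = _frame_with_tail_beads(pts, box=box)
        f = smoothed_species_field(fr, "DPPC", sigma=1.0, spacing=0.1)

        nx, ny = f.values.shape
        hist = np.zeros((nx, ny))
        ix = np.minimum((pts[:, 0] / 8.0 * nx).astype(int), nx - 1)
        iy = np.minimum((pts[:, 1] / 8.0 * ny).astype(int), ny - 1)
        np.add.at(hist, (ix, iy), 1.0 / f.spacing ** 2)
        tiled = np.tile(hist, (3, 3))
        sm = ndimage.gaussian_filter(tiled, sigma=1.0 / f.spacing,
                                     mode="constant", truncate=4.0)
        oracle = sm[nx:2 * nx, ny:2 * ny]
        assert np.abs(f.values - oracle).max() < 1e-9 * max(1.0, f.values.max())

    def test_absent_species_warns_and_zeroes(self, stripe_system):
        (frame, _), _ = stripe_system
        with pytest.warns(UserWarning, match="no C1A/C1B"):
            f = smoothed_species_field(frame, "POPC")
        assert not f.values.any()

    def test_dense_uniform_field_flattens(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 20, size=(4000, 2))
        fr = _frame_with_tail_beads(pts)
        f = smoothed_species_field(fr, "DPPC")
        cov = f.values.std() / f.values.mean()
        assert cov < 0.25


class TestInterfaceEdges:
    def test_single_species_membrane_has_no_edges(self):
        spec = sg.MembraneSpec(box=(20.0, 8.0, 10.0), stripe_boundaries=(),
                               composition=({"DPPC": 1.0},), seed=0)
        frame, _ = sg.build_stripe_bilayer(spec)
        delta = difference_field(frame)
        assert not interface_edges(delta).any()

    def test_edges_trace_true_boundaries(self, stripe_system):
        (frame, truth), _ = stripe_system
        delta = difference_field(frame)
        edges = interface_edges(delta)
        nx, ny = edges.shape
        xs = (np.flatnonzero(edges.any(axis=1)) + 0.5) * delta.spacing
        bounds = np.asarray(truth["boundaries"])
        box_x = frame.box[0]
        for x in xs:
            d = np.abs((x - bounds + box_x / 2) % box_x - box_x / 2)
            assert d.min() <= 0.2
        # each boundary is traced continuously across the y extent
        for b in bounds:
            cols = np.flatnonzero(
                np.abs(((np.arange(nx) + 0.5) * delta.spacing - b + box_x / 2)
                       % box_x - box_x / 2) <= 0.2)
            assert np.all(edges[cols, :].any(axis=0))

    def test_translation_equivariance(self, stripe_system):
        """Shifting all coordinates shifts the edge mask by the same cells."""
        (frame, _), _ = stripe_system
        edges = interface_edges(difference_field(frame))
        shifted = frame.copy()
        shift = np.array([frame.box[0] / 2, frame.box[1] / 2, 0.0])
        shifted.positions = shifted.positions + shift
        edges2 = interface_edges(difference_field(shifted))
        nx, ny = edges.shape
        assert np.array_equal(np.roll(edges, (nx // 2, ny // 2), axis=(0, 1)),
                              edges2)


class TestLabelRegions:
    def test_two_boundary_interface_fraction(self, stripe_system):
        """Two straight boundaries, radius 1.5 in a 40 nm box: interface
        fraction 2*(2*1.5)/40 = 0.15 up to one grid cell per boundary side."""
        (frame, _), _ = stripe_system
        pm = segment_frame(frame, radius=1.5)
        fr = pm.area_fractions()
        assert fr["interface"] == pytest.approx(0.15, abs=0.01)
        assert sum(pm.areas.values()) == pytest.approx(
            frame.box[0] * frame.box[1], abs=pm.spacing ** 2)

    def test_recovered_stripe_fractions(self, stripe_system):
        """Ld/Lo fractions match the analytic stripe split within 2 pp."""
        (frame, _), _ = stripe_system
        pm = segment_frame(frame, radius=1.5)
        fr = pm.area_fractions()
        assert fr["Ld"] == pytest.approx((20.0 - 3.0) / 40.0, abs=0.02)
        assert fr["Lo"] == pytest.approx((20.0 - 3.0) / 40.0, abs=0.02)

    def test_interface_area_monotone_in_radius(self, stripe_system):
        (frame, _), _ = stripe_system
        delta = difference_field(frame)
        edges = interface_edges(delta)
        areas = [label_regions(edges, delta, radius=r).areas["interface"]
                 for r in (1.2, 1.4, 1.5, 1.7, 2.0)]
        assert np.all(np.diff(areas) >= 0)

    def test_empty_mask_labels_by_sign(self):
        vals = np.fromfunction(lambda i, j: (i - 10.0) / 5.0, (20, 20))
        delta = DensityField(vals, spacing=0.1, species="test")
        pm = label_regions(np.zeros((20, 20), bool), delta, radius=1.5)
        # the tie column i == 10 (20 cells of 0.01 nm^2) goes to interface
        assert pm.areas["interface"] == pytest.approx(0.2)
        assert np.all(pm.labels[vals > 0] == "Ld")
        assert np.all(pm.labels[vals < 0] == "Lo")

    def test_bad_radius_rejected(self):
        delta = DensityField(np.zeros((5, 5)), spacing=0.1, species="t")
        with pytest.raises(ValueError):
            label_regions(np.zeros((5, 5), bool), delta, radius=0.0)

    def test_label_at_half_open_cells(self):
        vals = np.ones((10, 10))
        delta = DensityField(vals, spacing=0.1, species="t")
        pm = label_regions(np.zeros((10, 10), bool), delta, radius=1.5)
        assert pm.label_at([[0.05, 0.05]])[0] == "Ld"
        assert pm.label_at([[1.05, 0.05]])[0] == "Ld"  # wraps periodically


def test_phasemap_text_export_roundtrip(tmp_path, stripe_system):
    (frame, _), _ = stripe_system
    pm = segment_frame(frame)
    stem = tmp_path / "map"
    pm.save(stem)
    import json
    header = json.loads((tmp_path / "map.json").read_text())
    grid = np.loadtxt(tmp_path / "map.labels.txt")
    assert grid.shape == pm.labels.shape
    legend = {int(k): v for k, v in header["legend"].items()}
    assert sum(header["areas"].values()) == pytest.approx(
        frame.box[0] * frame.box[1], abs=0.1)
    recovered = np.vectorize(legend.get)(grid.astype(int))
    assert np.array_equal(recovered, pm.labels.astype(str))


def test_per_leaflet_segmentation_mode(stripe_system):
    """Stripes are in registry, so each leaflet alone gives the same map."""
    (frame, _), _ = stripe_system
    pooled = segment_frame(frame)
    top = segment_frame(frame, leaflet="top")
    agree = (pooled.labels == top.labels).mean()
    assert agree > 0.97
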