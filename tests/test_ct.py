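"""CT segmentation pipeline and electrode placement asymmetry."""

import numpy as np
import pytest

from epgkit.ct import (
    CTVolume,
    SymmetryPlane,
    assign_sides,
    auto_thresholds,
    distance_histograms,
    double_threshold,
    electrode_table,
    estimate_plane,
    label_electrodes,
    load_ct,
    mirror_project,
    refine_cast,
    segment_palate,
    split_wires_electrodes,
)
from epgkit.synthetic import PhantomSpec, build_phantom


def nearest_match_errors(truth_pts, found_pts):
    d = np.linalg.norm(truth_pts[:, None] - found_pts[None, :], axis=2)
    return d.min(axis=1)


class TestDoubleThreshold:
    def test_three_plateau_phantom_recovered_exactly(self):
        vol = np.zeros((10, 10, 10))
        vol[3:6] = 500.0
        vol[7:9] = 2000.0
        ct = CTVolume(vol, (1, 1, 1))
        background, bright = double_threshold(ct, 250.0, 1000.0)
        np.testing.assert_array_equal(background, vol == 0.0)
        np.testing.assert_array_equal(bright, vol == 2000.0)

    def test_threshold_above_max_empty_bright(self):
        ct = CTVolume(np.full((4, 4, 4), 100.0), (1, 1, 1))
        with pytest.warns(UserWarning, match="outside intensity range"):
            _, bright = double_threshold(ct, 50.0, 1e6)
        assert not bright.any()

    def test_voxelwise_brute_force(self):
        rng = np.random.default_rng(0)
        vol = rng.uniform(0, 3000, size=(8, 9, 10))
        ct = CTVolume(vol, (1, 1, 1))
        background, bright = double_threshold(ct, 400.0, 1500.0)
        for idx in np.ndindex(vol.shape):
            assert background[idx] == (vol[idx] < 400.0)
            assert bright[idx] == (vol[idx] > 1500.0)

    def test_inverted_thresholds_rejected(self):
        ct = CTVolume(np.zeros((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError):
            double_threshold(ct, 1000.0, 250.0)


class TestRefineCast:
    def test_embedded_bright_artefact_excluded_from_metal(self):
        """A bright blob inside the cast is swallowed by hole filling and
        therefore discarded from the metal candidates."""
        vol = np.zeros((24, 24, 24))
        vol[6:18, 6:18, 6:18] = 500.0          # cast block
        vol[11:13, 11:13, 11:13] = 2000.0      # artefact inside
        vol[2:4, 2:4, 2:4] = 2000.0            # genuine metal outside
        ct = CTVolume(vol, (1, 1, 1))
        background, bright = double_threshold(ct, 250.0, 1000.0)
        cast = refine_cast(ct, background, bright, radius=2)
        metal = bright & ~cast
        assert cast[12, 12, 12]                 # artefact voxels inside cast
        assert not metal[11:13, 11:13, 11:13].any()
        assert metal[2:4, 2:4, 2:4].all()       # outside metal survives

    def test_internal_air_holes_filled(self):
        vol = np.zeros((20, 20, 20))
        vol[4:16, 4:16, 4:16] = 500.0
        vol[9:11, 9:11, 9:11] = 0.0            # air pocket
        ct = CTVolume(vol, (1, 1, 1))
        background, bright = double_threshold(ct, 250.0, 1000.0)
        cast = refine_cast(ct, background, bright)
        assert cast[10, 10, 10]

    def test_solid_box_preserved_in_interior(self):
        vol = np.zeros((20, 20, 20))
        vol[4:16, 4:16, 4:16] = 500.0
        ct = CTVolume(vol, (1, 1, 1))
        background, bright = double_threshold(ct, 250.0, 1000.0)
        cast = refine_cast(ct, background, bright, radius=2)
        # interior (away from boundary effects of closing/opening) unchanged
        assert cast[7:13, 7:13, 7:13].all()
        assert not cast[:3].any()

    def test_empty_cast_raises(self):
        ct = CTVolume(np.zeros((8, 8, 8)), (1, 1, 1))
        background, bright = double_threshold(ct, 250.0, 1000.0)
        with pytest.raises(ValueError, match="empty"):
            refine_cast(ct, background, bright)


class TestSplitWiresElectrodes:
    def _mask_with_components(self):
        m = np.zeros((20, 40, 20), dtype=bool)
        m[5:8, 2:38, 5:8] = True    # long tube, 972 voxels -> wire
        m[12:15, 3:6, 3:6] = True   # small blob -> electrode
        m[12:15, 10:13, 10:13] = True
        return m

    def test_size_separation(self):
        wires, electrodes = split_wires_electrodes(self._mask_with_components(), 300)
        assert wires.sum() == 3 * 36 * 3
        assert electrodes.sum() == 2 * 27

    def test_component_exactly_at_threshold_is_electrode(self):
        m = np.zeros((10, 10, 10), dtype=bool)
        m[1:4, 1:4, 1:4] = True  # 27 voxels
        wires, electrodes = split_wires_electrodes(m, 27)
        assert not wires.any() and electrodes.sum() == 27
        wires, electrodes = split_wires_electrodes(m, 26)
        assert wires.sum() == 27 and not electrodes.any()

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning, match="no metal"):
            wires, electrodes = split_wires_electrodes(np.zeros((5, 5, 5), bool), 10)
        assert not wires.any() and not electrodes.any()


class TestLabelElectrodes:
    def test_sphere_centroids_recovered(self):
        """Centroids of disjoint voxelised spheres match the analytic centres."""
        vol = np.zeros((30, 30, 30), dtype=bool)
        centres = np.array([[8.0, 9.5, 10.0], [20.0, 15.0, 5.5], [15.0, 24.0, 22.0]])
        zz, yy, xx = np.meshgrid(*[np.arange(30)] * 3, indexing="ij")
        for c in centres:
            vol |= (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= 3.0**2
        es = label_electrodes(vol)
        assert len(es) == 3
        errs = nearest_match_errors(centres, es.centroids())
        assert errs.max() < 0.5

    def test_ids_ordered_anterior_then_left(self):
        vol = np.zeros((10, 20, 20), dtype=bool)
        vol[4:6, 2:4, 12:14] = True   # anterior right
        vol[4:6, 2:4, 3:5] = True     # anterior left
        vol[4:6, 14:16, 3:5] = True   # posterior left
        es = label_electrodes(vol)
        ys = [e.centroid_vox[1] for e in es.electrodes]
        xs = [e.centroid_vox[2] for e in es.electrodes]
        assert ys[0] == ys[1] < ys[2]
        assert xs[0] < xs[1]

    def test_touching_spheres_merge(self):
        vol = np.zeros((10, 10, 20), dtype=bool)
        vol[4:6, 4:6, 3:9] = True
        vol[4:6, 4:6, 9:15] = True  # touching -> one component
        assert len(label_electrodes(vol)) == 1

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            label_electrodes(np.zeros((5, 5, 5), bool))

    def test_mm_centroid_uses_spacing(self):
        vol = np.zeros((10, 10, 10), dtype=bool)
        vol[4, 5, 6] = True
        es = label_electrodes(vol, spacing=(0.3, 0.3, 0.3))
        np.testing.assert_allclose(es.electrodes[0].centroid_mm, (1.2, 1.5, 1.8))


class TestSidesAndPlane:
    def _set(self, xs):
        vol = np.zeros((10, 10, 40), dtype=bool)
        for x in xs:
            vol[4:6, 4:6, x : x + 2] = True
        return label_electrodes(vol)

    def test_side_assignment(self):
        es = self._set([4, 30])
        assign_sides(es, SymmetryPlane(offset=19.5))
        assert [e.side for e in es.electrodes] == ["left", "right"]

    def test_centroid_on_plane_is_error(self):
        es = self._set([10])
        with pytest.raises(ValueError, match="exactly on the symmetry plane"):
            assign_sides(es, SymmetryPlane(offset=10.5))

    def test_all_one_side_warns(self):
        es = self._set([2, 6])
        with pytest.warns(UserWarning, match="one side"):
            assign_sides(es, SymmetryPlane(offset=30.0))

    def test_estimate_plane_on_mirrored_phantom(self, phantom_zero_segmented):
        spec, truth, (masks, es, plane, ma) = phantom_zero_segmented
        est = estimate_plane(es)
        assert abs(est.offset - spec.plane_x) <= 0.5

    def test_single_pair_midpoint(self):
        es = self._set([4, 30])
        plane = estimate_plane(es)
        xs = [e.centroid_vox[2] for e in es.electrodes]
        assert plane.offset == pytest.approx(np.mean(xs))

    def test_degenerate_collinear_falls_back_to_median(self):
        vol = np.zeros((30, 10, 10), dtype=bool)
        for z in (4, 14, 24):
            vol[z : z + 2, 4:6, 4:6] = True
        es = label_electrodes(vol)
        plane = estimate_plane(es)  # all x centroids equal
        assert plane.offset == pytest.approx(4.5)

    def test_reflection_is_involution(self):
        plane = SymmetryPlane(offset=17.25)
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 40, size=(20, 3))
        np.testing.assert_allclose(plane.reflect(plane.reflect(pts)), pts, atol=1e-9)


class TestMirrorProject:
    def test_perfect_mirror_all_distances_zero(self):
        es = TestSidesAndPlane()._set([4, 10, 28, 34])
        plane = SymmetryPlane(offset=19.5)
        assign_sides(es, plane)
        ma = mirror_project(es, plane)
        assert ma.mirror_distances_vox == pytest.approx([0.0, 0.0])
        assert not ma.unmatched

    def test_unbalanced_sides_warn_and_list_unmatched(self):
        es = TestSidesAndPlane()._set([4, 10, 30])
        plane = SymmetryPlane(offset=19.5)
        assign_sides(es, plane)
        with pytest.warns(UserWarning, match="unbalanced"):
            ma = mirror_project(es, plane)
        assert len(ma.pairings) == 1 and len(ma.unmatched) == 1

    def test_mm_distances_scale_with_spacing(self):
        es = TestSidesAndPlane()._set([4, 32])
        es.spacing = (0.3, 0.3, 0.3)
        plane = SymmetryPlane(offset=19.0)
        assign_sides(es, plane)
        ma = mirror_project(es, plane)
        p = ma.pairings[0]
        assert p.distance_mm == pytest.approx(0.3 * p.distance_vox)

    def test_rigid_shift_equivariance(self, phantom_planted):
        """Translating the volume along y/z leaves all distances unchanged."""
        spec, offsets, vol, truth = phantom_planted
        plane = SymmetryPlane(offset=spec.plane_x)

        def analyse(shift):
            from epgkit.ct import ElectrodeSet, Electrode

            es = ElectrodeSet(
                electrodes=[
                    Electrode(
                        id=e.id,
                        centroid_vox=(
                            e.centroid_vox[0] + shift[0],
                            e.centroid_vox[1] + shift[1],
                            e.centroid_vox[2],
                        ),
                        centroid_mm=e.centroid_mm,
                        volume=0,
                    )
                    for e in truth.electrodes
                ],
                spacing=truth.spacing,
            )
            assign_sides(es, plane)
            return mirror_project(es, plane)

        a = analyse((0.0, 0.0))
        b = analyse((3.7, -2.1))
        np.testing.assert_allclose(
            sorted(a.mirror_distances_vox), sorted(b.mirror_distances_vox), atol=1e-9
        )
        np.testing.assert_allclose(
            sorted(a.neighbour_distances_vox), sorted(b.neighbour_distances_vox),
            atol=1e-9,
        )


class TestEndToEndPhantom:
    def test_zero_offset_phantom(self, phantom_zero_segmented):
        spec, truth, (masks, es, plane, ma) = phantom_zero_segmented
        assert len(es) == 62
        errs = nearest_match_errors(truth.centroids(), es.centroids())
        assert errs.max() < 0.5
        assert ma.summaries["mirror_vox"]["max"] < 1e-6
        assert len(es.by_side("left")) == len(es.by_side("right")) == 31

    def test_planted_offsets_recovered(self, phantom_planted_segmented):
        spec, offsets, truth, (masks, es, plane, ma) = phantom_planted_segmented
        planted = np.linalg.norm(offsets, axis=1)
        planted = planted[planted > 1e-12]
        s = ma.summaries["mirror_vox"]
        assert s["n"] == 31
        assert abs(s["mean"] - planted.mean()) <= 0.5
        assert abs(s["sd"] - planted.std(ddof=1)) <= 0.5

    def test_wires_separated_from_electrodes(self, phantom_zero_segmented):
        spec, truth, (masks, es, plane, ma) = phantom_zero_segmented
        assert masks.wires.any()
        assert not (masks.electrodes & masks.cast).any()
        assert not (masks.wires & masks.electrodes).any()

    def test_auto_thresholds_separate_classes(self, phantom_zero):
        spec, vol, truth = phantom_zero
        t_low, t_high = auto_thresholds(vol)
        assert spec.background_intensity < t_low < spec.cast_intensity
        assert spec.cast_intensity < t_high < spec.metal_intensity


class TestHistogramsAndTables:
    def test_no_overlap_when_offsets_small(self):
        spec0 = PhantomSpec.small(seed=11)
        from epgkit.synthetic import planted_offsets

        offs = planted_offsets(spec0, mean_mag=1.0, sd_mag=0.3, seed=5)
        vol, truth = build_phantom(PhantomSpec.small(seed=11, offsets=offs))
        _, es, plane, ma = segment_palate(vol, plane_offset=spec0.plane_x)
        import matplotlib.pyplot as plt

        ax, table = distance_histograms(ma)
        assert ma.overlap_statistic() == 0.0
        assert table.attrs["overlap_statistic"] == 0.0
        assert set(table["set"]) == {"mirror_vox", "mirror_mm", "neighbour_vox"}
        plt.close(ax.figure)

    def test_identical_sets_overlap_one(self):
        from epgkit.ct import MirrorAnalysis, MirrorPairing

        pair = [
            MirrorPairing(1, 2, (0, 0, 0), d, d) for d in (5.0, 6.0, 7.0)
        ]
        ma = MirrorAnalysis(
            pairings=pair,
            neighbour_distances=[(1, 2, 5.0), (2, 1, 6.0), (3, 1, 7.0)],
            summaries={},
        )
        assert ma.overlap_statistic() == pytest.approx(2 / 3)
        ma2 = MirrorAnalysis(
            pairings=[MirrorPairing(1, 2, (0, 0, 0), 9.0, 9.0)],
            neighbour_distances=[(1, 2, 5.0)],
            summaries={},
        )
        assert ma2.overlap_statistic() == 1.0

    def test_empty_distance_sets_raise(self):
        from epgkit.ct import MirrorAnalysis

        ma = MirrorAnalysis(pairings=[], neighbour_distances=[], summaries={})
        with pytest.raises(ValueError):
            ma.overlap_statistic()

    def test_electrode_table_columns(self, phantom_zero_segmented):
        spec, truth, (masks, es, plane, ma) = phantom_zero_segmented
        df = electrode_table(es, ma)
        assert len(df) == 62
        for col in ("id", "x", "y", "z", "volume", "side", "mirror_partner",
                    "mirror_distance_vox", "mirror_distance_mm",
                    "neighbour_distance_vox"):
            assert col in df.columns
        assert df["mirror_partner"].notna().all()


class TestLoadCT:
    def test_npy_with_sidecar(self, tmp_path):
        import json

        arr = np.random.default_rng(0).uniform(0, 100, (5, 6, 7))
        np.save(tmp_path / "v.npy", arr)
        (tmp_path / "v.json").write_text(json.dumps({"spacing": [0.3, 0.3, 0.3]}))
        ct = load_ct(tmp_path / "v.npy")
        np.testing.assert_allclose(ct.intensities, arr)
        assert ct.spacing == (0.3, 0.3, 0.3)

    def test_dicom_series_round_trip(self, tmp_path):
        import pydicom
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        rng = np.random.default_rng(1)
        vol = rng.integers(0, 1000, size=(4, 8, 8)).astype(np.uint16)
        for z in range(4):
            meta = FileMetaDataset()
            meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
            meta.MediaStorageSOPInstanceUID = generate_uid()
            meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds = Dataset()
            ds.file_meta = meta
            ds.SOPClassUID = meta.MediaStorageSOPClassUID
            ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
            ds.Rows, ds.Columns = 8, 8
            ds.BitsAllocated, ds.BitsStored, ds.HighBit = 16, 16, 15
            ds.PixelRepresentation = 0
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.InstanceNumber = z + 1
            ds.ImagePositionPatient = [0.0, 0.0, z * 0.3]
            ds.PixelSpacing = [0.3, 0.3]
            ds.SliceThickness = 0.3
            ds.PixelData = vol[z].tobytes()
            ds.save_as(tmp_path / f"slice{z}.dcm", enforce_file_format=True)
        ct = load_ct(tmp_path)
        assert ct.shape == (4, 8, 8)
        np.testing.assert_allclose(ct.intensities, vol.astype(float))
        np.testing.assert_allclose(ct.spacing, (0.3, 0.3, 0.3))

    def test_unknown_input_rejected(self, tmp_path):
        p = tmp_path / "x.txt"
        p.write_text("nope")
        with pytest.raises(ValueError):
            load_ct(p)
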