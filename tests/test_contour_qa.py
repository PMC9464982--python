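"""The five contour checks, midline estimation and the CSV report."""

from __future__ import annotations

import csv

import numpy as np
import pytest

from rtcurate.contour_qa import (
    CheckVerdict,
    check_empty,
    check_holes,
    check_outside_body,
    check_parts,
    check_sidedness,
    estimate_midline_x,
    run_qa,
    write_qa_report,
)
from rtcurate.errors import GridMismatchError, MidlineError
from rtcurate.phantom import DefectSpec, PhantomConfig, generate, inject
from rtcurate.rtdata_model import (
    ImageGrid,
    PlanarContour,
    Structure,
    StructureSet,
    VolumeMask,
    rasterize,
    structset_from_dataset,
)

from conftest import flood_fill_components, make_mask


def circle(cx, cy, r, n=32):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])


class TestCheckEmpty:
    def test_no_contours_fails(self):
        v = check_empty(Structure("x"))
        assert v.verdict == "FAIL"

    def test_nonempty_passes(self, unit_grid):
        s = Structure("s", [PlanarContour(0.0, circle(10, 10, 5))])
        assert check_empty(s, rasterize(s, unit_grid)).verdict == "PASS"

    def test_degenerate_below_sampling_fails(self, unit_grid):
        # sliver polygon threading between voxel centres
        s = Structure("sliver", [PlanarContour(0.0, np.array(
            [[5.1, 5.1], [5.4, 5.1], [5.4, 5.4]]
        ))])
        v = check_empty(s, rasterize(s, unit_grid))
        assert v.verdict == "FAIL" and "zero voxels" in v.detail


class TestCheckOutsideBody:
    def test_contained_passes(self, unit_grid):
        organ = make_mask(unit_grid, [[5, 5, 0]])
        body = VolumeMask(unit_grid, np.ones(unit_grid.dims, bool))
        assert check_outside_body(organ, body).verdict == "PASS"

    def test_single_protruding_voxel_fails(self, unit_grid):
        organ = make_mask(unit_grid, [[5, 5, 0], [0, 0, 7]])
        body = VolumeMask(unit_grid, np.ones(unit_grid.dims, bool))
        body.voxels[0, 0, 7] = False
        v = check_outside_body(organ, body)
        assert v.verdict == "FAIL" and "1 voxels" in v.detail

    def test_absent_body_is_na(self, unit_grid):
        assert check_outside_body(make_mask(unit_grid), None).verdict == "N/A"

    def test_grid_mismatch_rejected(self, unit_grid):
        other = ImageGrid(origin=(0, 0, 0), spacing=(2, 2, 2), dims=(32, 32, 8),
                          frame_of_reference="other")
        with pytest.raises(GridMismatchError):
            check_outside_body(make_mask(unit_grid), make_mask(other))


class TestCheckHoles:
    def test_solid_cube_passes(self, unit_grid):
        m = make_mask(unit_grid)
        m.voxels[4:12, 4:12, 2:5] = True
        assert check_holes(m).verdict == "PASS"

    def test_cavity_below_threshold_passes(self, unit_grid):
        # 8x8 ring with 2-voxel cavity = 0.002 cc at 1 mm^3 voxels
        m = make_mask(unit_grid)
        m.voxels[4:12, 4:12, 3] = True
        m.voxels[7, 7:9, 3] = False
        v = check_holes(m, threshold_cc=0.003)
        assert v.verdict == "PASS" and "0.0020" in v.detail

    def test_cavity_at_or_above_threshold_fails(self, unit_grid):
        m = make_mask(unit_grid)
        m.voxels[4:16, 4:16, 3] = True
        m.voxels[7:9, 7:12, 3] = False  # 10 voxels = 0.010 cc
        v = check_holes(m, threshold_cc=0.003)
        assert v.verdict == "FAIL" and "0.0100" in v.detail

    def test_filled_mask_always_passes(self, unit_grid):
        from scipy import ndimage

        rng = np.random.default_rng(3)
        m = make_mask(unit_grid)
        m.voxels = rng.random(unit_grid.dims) < 0.4
        for k in range(m.voxels.shape[2]):
            m.voxels[:, :, k] = ndimage.binary_fill_holes(m.voxels[:, :, k])
        assert check_holes(VolumeMask(unit_grid, m.voxels)).verdict == "PASS"

    def test_threshold_monotonicity(self, unit_grid):
        m = make_mask(unit_grid)
        m.voxels[4:16, 4:16, 3] = True
        m.voxels[7:9, 7:9, 3] = False
        verdicts = [
            check_holes(m, threshold_cc=t).verdict for t in (0.001, 0.004, 0.010)
        ]
        # raising the threshold can only go FAIL -> PASS, never back
        assert verdicts == sorted(verdicts, key=lambda v: v == "PASS")


class TestCheckParts:
    def test_single_component_passes(self, unit_grid):
        m = make_mask(unit_grid)
        m.voxels[4:10, 4:10, 2:5] = True
        v = check_parts(m)
        assert v.verdict == "PASS" and "1 3D component" in v.detail

    def test_two_supra_threshold_islands_fail(self, unit_grid):
        m = make_mask(unit_grid)
        m.voxels[2:6, 2:6, 2] = True   # 16 voxels = 0.016 cc
        m.voxels[20:22, 20:24, 6] = True  # 8 voxels = 0.008 cc
        assert check_parts(m, threshold_cc=0.003).verdict == "FAIL"

    def test_sub_threshold_ditzel_warns_but_passes(self, unit_grid):
        m = make_mask(unit_grid)
        m.voxels[2:6, 2:6, 2] = True
        m.voxels[20, 20:22, 6] = True  # 2 voxels = 0.002 cc ditzel
        v = check_parts(m, threshold_cc=0.003)
        assert v.verdict == "PASS" and "ditzel" in v.detail

    def test_matches_flood_fill_oracle_on_random_masks(self, unit_grid):
        """Component structure agrees with an explicit BFS oracle."""
        from scipy import ndimage

        rng = np.random.default_rng(11)
        for _ in range(30):
            voxels = rng.random((16, 16, 6)) < rng.uniform(0.05, 0.4)
            labels, n = ndimage.label(voxels, structure=np.ones((3, 3, 3), bool))
            got = sorted(np.bincount(labels.ravel())[1:], reverse=True)
            assert got == flood_fill_components(voxels)


class TestMidlineAndSidedness:
    def grid(self):
        # grid symmetric about x = 0
        return ImageGrid(
            origin=(-31.5, -31.5, 0.0), spacing=(1, 1, 2), dims=(64, 64, 10),
            frame_of_reference="f",
        )

    def test_centered_cord_gives_zero_midline(self):
        grid = self.grid()
        ss = StructureSet(
            structures=[
                Structure("cord", [PlanarContour(z, circle(0, 0, 4)) for z in (2, 4, 6)])
            ]
        )
        assert estimate_midline_x(ss, grid) == pytest.approx(0.0, abs=1e-9)

    def test_midline_is_mean_of_centroids(self):
        grid = self.grid()
        ss = StructureSet(
            structures=[
                Structure("brain_stem", [PlanarContour(4.0, circle(1.5, 0, 4))]),
                Structure("cord", [PlanarContour(8.0, circle(0.5, 0, 4))]),
            ]
        )
        assert estimate_midline_x(ss, grid) == pytest.approx(1.0, abs=0.1)

    def test_no_midline_structure_raises(self):
        ss = StructureSet(structures=[Structure("brain")])
        with pytest.raises(MidlineError):
            estimate_midline_x(ss, self.grid())

    def test_left_label_on_left_side_passes(self):
        grid = self.grid()
        s = Structure("parotid_l", [PlanarContour(4.0, circle(20, 0, 4))])
        v = check_sidedness(s, rasterize(s, grid), midline_x=0.0)
        assert v.verdict == "PASS"

    def test_left_label_on_right_side_fails(self):
        grid = self.grid()
        s = Structure("parotid_l", [PlanarContour(4.0, circle(-20, 0, 4))])
        assert check_sidedness(s, rasterize(s, grid), 0.0).verdict == "FAIL"

    def test_non_lateral_label_is_na(self):
        grid = self.grid()
        s = Structure("brain", [PlanarContour(4.0, circle(0, 0, 4))])
        assert check_sidedness(s, rasterize(s, grid), 0.0).verdict == "N/A"

    def test_empty_lateral_structure_is_na(self):
        grid = self.grid()
        s = Structure("parotid_l")
        v = check_sidedness(s, rasterize(s, grid), 0.0)
        assert v.verdict == "N/A" and "empty" in v.detail


class TestRunQA:
    def test_defect_free_phantom_all_pass(self, default_phantom):
        report = run_qa(default_phantom)
        assert report.n_failures() == 0
        for verdicts in report.rows.values():
            assert len(verdicts) == 5

    def test_every_structure_reported_once(self, default_phantom):
        report = run_qa(default_phantom)
        ss = structset_from_dataset(default_phantom.objects["curated_rtstruct"])
        assert sorted(report.rows) == sorted(ss.labels())

    def test_sidedness_swap_fails_exactly_the_swapped_pair(self, default_phantom):
        bad = inject(default_phantom, DefectSpec("sidedness_swap", "parotid"))
        report = run_qa(bad)
        assert report.failed_labels() == ["parotid_l", "parotid_r"]
        for label in ("parotid_l", "parotid_r"):
            failing = [v.check_name for v in report.rows[label] if v.verdict == "FAIL"]
            assert failing == ["sidedness"]

    def test_airway_like_cavity_fails_lung_holes(self, default_phantom):
        bad = inject(default_phantom, DefectSpec("hole", "lung_l", 0.010))
        report = run_qa(bad)
        assert report.failed_labels() == ["lung_l"]
        assert report.verdicts("lung_l")["holes"] == "FAIL"

    def test_mirroring_swaps_detected_sides_only(self, fine_phantom):
        """Negating x of every vertex flips every sidedness verdict and
        nothing else."""
        import copy

        mirrored = copy.deepcopy(fine_phantom)
        struct_ds = mirrored.objects["curated_rtstruct"]
        for rc in struct_ds.ROIContourSequence:
            for c in getattr(rc, "ContourSequence", []):
                data = np.array([float(v) for v in c.ContourData]).reshape(-1, 3)
                data[:, 0] *= -1
                c.ContourData = [f"{v:.4f}" for v in data.ravel()]
        base = run_qa(fine_phantom)
        flipped = run_qa(mirrored)
        for label in base.rows:
            for v_base, v_flip in zip(base.rows[label], flipped.rows[label]):
                if v_base.check_name == "sidedness" and v_base.verdict != "N/A":
                    assert {v_base.verdict, v_flip.verdict} == {"PASS", "FAIL"}
                else:
                    assert v_base.verdict == v_flip.verdict


class TestReportCSV:
    def test_csv_shape_and_vocabulary(self, default_phantom, tmp_path):
        report = run_qa(default_phantom)
        path = write_qa_report(report, tmp_path / "qa.csv")
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        header, data = rows[0], rows[1:]
        assert header[:6] == [
            "label", "empty", "outside_body", "holes", "multiple_parts", "sidedness",
        ]
        assert len(data) == 43  # 42 organs + body
        for row in data:
            assert set(row[1:6]) <= {"PASS", "FAIL", "N/A"}

    def test_empty_report_is_header_only(self, tmp_path):
        from rtcurate.contour_qa import QAReport

        path = write_qa_report(
            QAReport(dataset_id="x", threshold_cc=0.003, midline_x=None),
            tmp_path / "empty.csv",
        )
        with open(path, newline="") as fh:
            assert len(list(csv.reader(fh))) == 1

    def test_verdict_vocabulary_enforced(self):
        with pytest.raises(AssertionError):
            CheckVerdict("empty", "MAYBE")
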