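"""Geometry, rasterization and RTSTRUCT round-trip behaviour."""

from __future__ import annotations

import numpy as np
import pytest

from rtcurate.errors import ContourPlaneError, FormatError, ValidationError
from rtcurate.rtdata_model import (
    ImageGrid,
    PlanarContour,
    Structure,
    StructureSet,
    VolumeMask,
    mask_volume_cc,
    rasterize,
    read_rtstruct,
    structset_from_dataset,
    write_rtstruct,
)

from conftest import brute_force_slice_mask


def square(x0, y0, side):
    return np.array(
        [[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]]
    )


class TestImageGrid:
    def test_rejects_nonpositive_spacing(self):
        with pytest.raises(ValidationError):
            ImageGrid(origin=(0, 0, 0), spacing=(1.0, -1.0, 1.0), dims=(4, 4, 4))

    def test_rejects_non_orthonormal_axes(self):
        with pytest.raises(ValidationError):
            ImageGrid(
                origin=(0, 0, 0),
                spacing=(1, 1, 1),
                axes=((0, 1, 0), (1, 0, 0), (0, 1, 0)),
                dims=(4, 4, 4),
            )

    def test_slice_positions_monotone(self, unit_grid):
        zs = unit_grid.slice_zs()
        assert np.all(np.diff(zs) > 0)


class TestRasterize:
    def test_axis_aligned_square_voxel_count(self, unit_grid):
        # 10x10 mm square off-lattice so no centre sits on an edge
        s = Structure("sq", [PlanarContour(0.0, square(0.25, 0.25, 10.0))])
        assert rasterize(s, unit_grid).count() == 100

    def test_no_contours_gives_empty_mask(self, unit_grid):
        assert rasterize(Structure("empty"), unit_grid).count() == 0

    def test_donut_even_odd_rule(self, unit_grid):
        s = Structure(
            "donut",
            [
                PlanarContour(0.0, square(0.25, 0.25, 20.0)),
                PlanarContour(0.0, square(5.25, 5.25, 10.0)),
            ],
        )
        assert rasterize(s, unit_grid).count() == 400 - 100

    def test_contour_far_from_slices_rejected(self, unit_grid):
        s = Structure("far", [PlanarContour(99.0, square(0, 0, 5))])
        with pytest.raises(ContourPlaneError, match="far"):
            rasterize(s, unit_grid)

    def test_contour_snaps_to_nearest_slice(self, unit_grid):
        s = Structure("near", [PlanarContour(3.4, square(0.25, 0.25, 5.0))])
        m = rasterize(s, unit_grid)
        assert m.voxels[:, :, 3].any() and not m.voxels[:, :, 4].any()

    def test_matches_brute_force_oracle_on_random_polygons(self, unit_grid):
        """Rasterizer vs independent even-odd ray-casting point test."""
        rng = np.random.default_rng(42)
        xs, ys = unit_grid.xs(), unit_grid.ys()
        for _ in range(50):
            n_vert = rng.integers(3, 21)
            # star-shaped random polygon: angles sorted, radii random
            angles = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
            radii = rng.uniform(2.0, 14.0, n_vert)
            cx, cy = rng.uniform(8, 24, 2)
            poly = np.column_stack(
                [cx + radii * np.cos(angles), cy + radii * np.sin(angles)]
            )
            s = Structure("rand", [PlanarContour(0.0, poly)])
            got = rasterize(s, unit_grid).voxels[:, :, 0]
            expected = brute_force_slice_mask([poly], xs, ys)
            assert np.array_equal(got, expected)

    def test_area_converges_with_refinement(self):
        """Mean in-plane area error shrinks as voxel spacing shrinks."""
        rng = np.random.default_rng(19)
        polys = []
        for _ in range(10):
            angles = np.sort(rng.uniform(0, 2 * np.pi, 12))
            r = rng.uniform(6.0, 12.0)
            cx, cy = rng.uniform(13, 17, 2)
            polys.append(
                np.column_stack([cx + r * np.cos(angles), cy + r * np.sin(angles)])
            )

        def shoelace(p):
            x, y = p[:, 0], p[:, 1]
            return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

        mean_errors = []
        for spacing in (2.0, 1.0, 0.5):
            n = int(30 / spacing)
            grid = ImageGrid(
                origin=(0, 0, 0),
                spacing=(spacing, spacing, 1.0),
                dims=(n, n, 1),
                frame_of_reference="f",
            )
            errs = [
                abs(
                    rasterize(Structure("p", [PlanarContour(0.0, p)]), grid).count()
                    * spacing**2
                    - shoelace(p)
                )
                for p in polys
            ]
            mean_errors.append(np.mean(errs))
        assert mean_errors[0] > mean_errors[1] > mean_errors[2]


class TestMaskVolume:
    def test_unit_arithmetic(self, unit_grid):
        m = VolumeMask(unit_grid, np.zeros(unit_grid.dims, bool))
        m.voxels[:10, :10, :8] = True  # 800 voxels at 1 mm^3
        assert mask_volume_cc(m) == pytest.approx(0.8)

    def test_empty_mask_zero(self, unit_grid):
        assert mask_volume_cc(VolumeMask(unit_grid, np.zeros(unit_grid.dims, bool))) == 0.0

    def test_single_planning_voxel_exceeds_qa_threshold(self):
        grid = ImageGrid(
            origin=(0, 0, 0), spacing=(1.27, 1.27, 2.0), dims=(2, 2, 2),
            frame_of_reference="f",
        )
        m = VolumeMask(grid, np.zeros((2, 2, 2), bool))
        m.voxels[0, 0, 0] = True
        assert mask_volume_cc(m) == pytest.approx(0.0032258, abs=1e-6)
        assert mask_volume_cc(m) > 0.003

    def test_additive_over_disjoint_masks(self, unit_grid):
        rng = np.random.default_rng(7)
        a = VolumeMask(unit_grid, rng.random(unit_grid.dims) < 0.2)
        b = VolumeMask(unit_grid, (rng.random(unit_grid.dims) < 0.2) & ~a.voxels)
        union = VolumeMask(unit_grid, a.voxels | b.voxels)
        assert mask_volume_cc(union) == pytest.approx(
            mask_volume_cc(a) + mask_volume_cc(b)
        )


class TestRTStructIO:
    def test_round_trip_preserves_geometry(self, fine_phantom, tmp_path):
        ss = structset_from_dataset(fine_phantom.objects["curated_rtstruct"])
        grid = ImageGrid.from_ct_series(fine_phantom.objects["planning_ct"])
        path = write_rtstruct(ss, grid, tmp_path / "rs.dcm")
        back = read_rtstruct(path)
        assert back.labels() == ss.labels()
        for s1, s2 in zip(ss.structures, back.structures):
            assert len(s1.contours) == len(s2.contours)
            for c1, c2 in zip(s1.contours, s2.contours):
                assert np.abs(c1.vertices - c2.vertices).max() < 1e-3
                assert abs(c1.z - c2.z) < 1e-3

    def test_donut_survives_round_trip(self, unit_grid, tmp_path):
        ss = StructureSet(
            structures=[
                Structure(
                    "donut",
                    [
                        PlanarContour(0.0, square(0.25, 0.25, 20.0)),
                        PlanarContour(0.0, square(5.25, 5.25, 10.0)),
                    ],
                )
            ],
            frame_of_reference=unit_grid.frame_of_reference,
        )
        path = write_rtstruct(ss, unit_grid, tmp_path / "donut.dcm")
        back = read_rtstruct(path)
        assert len(back.structures[0].contours) == 2
        assert rasterize(back.structures[0], unit_grid).count() == 300

    def test_empty_structure_set_round_trip(self, unit_grid, tmp_path):
        path = write_rtstruct(
            StructureSet(frame_of_reference=unit_grid.frame_of_reference),
            unit_grid,
            tmp_path / "empty.dcm",
        )
        assert read_rtstruct(path).structures == []

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            StructureSet(structures=[Structure("a"), Structure("a")])

    def test_non_dicom_file_raises_format_error(self, tmp_path):
        bad = tmp_path / "not_dicom.dcm"
        bad.write_text("hello")
        with pytest.raises(FormatError, match="not_dicom"):
            read_rtstruct(bad)

    def test_wrong_modality_raises_format_error(self, default_phantom):
        ct_slice = default_phantom.objects["planning_ct"][0]
        with pytest.raises(FormatError, match="CT"):
            structset_from_dataset(ct_slice)

    def test_roi_without_contour_sequence_reads_as_empty(self, unit_grid, tmp_path):
        ss = StructureSet(
            structures=[Structure("no_contours")],
            frame_of_reference=unit_grid.frame_of_reference,
        )
        path = write_rtstruct(ss, unit_grid, tmp_path / "rs.dcm")
        back = read_rtstruct(path)
        assert back.structures[0].label == "no_contours"
        assert back.structures[0].contours == []
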