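"""Core data model for planning-CT geometry and DICOM-RT structure sets.

Contours live in the DICOM patient coordinate system (LPS: +x patient-left,
+y posterior, +z superior), in millimetres.  Structures are stacks of closed
planar polygons drawn on axial CT slices; every QA check and overlap metric
operates on their rasterization onto the CT voxel lattice (a
:class:`VolumeMask`).

Rasterization uses even-odd (XOR) polygon combination with voxel-centre
sampling, so an outer ring plus an inner ring on the same slice produces a
"doughnut" with a hole — the convention RT planning systems use when they
export structure sets.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pydicom
from matplotlib.path import Path as MplPath
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import (
    ContourPlaneError,
    FormatError,
    GridMismatchError,
    ValidationError,
)

# SOP class UIDs for the DICOM object roles handled by the toolkit
CT_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.2"
RTSTRUCT_STORAGE = "1.2.840.10008.5.1.4.1.1.481.3"
RTPLAN_STORAGE = "1.2.840.10008.5.1.4.1.1.481.5"
RTIONPLAN_STORAGE = "1.2.840.10008.5.1.4.1.1.481.8"
RTDOSE_STORAGE = "1.2.840.10008.5.1.4.1.1.481.2"
SPATIAL_REGISTRATION_STORAGE = "1.2.840.10008.5.1.4.1.1.66.1"

# Curated-dataset role vocabulary (object schema of a curated case)
ROLE_CURATED_STRUCT = "curated_rtstruct"
ROLE_PLANNING_CT = "planning_ct"
ROLE_SFOV_CT = "sfov_ct"
ROLE_CONTRAST_CT = "contrast_ct"
ROLE_CONTRAST_REG = "contrast_reg"
ROLE_CLINICAL_STRUCT = "clinical_rtstruct"
ROLE_PLAN = "rtplan"
ROLE_DOSE = "rtdose"

ALL_ROLES = (
    ROLE_CURATED_STRUCT,
    ROLE_PLANNING_CT,
    ROLE_SFOV_CT,
    ROLE_CONTRAST_CT,
    ROLE_CONTRAST_REG,
    ROLE_CLINICAL_STRUCT,
    ROLE_PLAN,
    ROLE_DOSE,
)
REQUIRED_ROLES = (
    ROLE_CURATED_STRUCT,
    ROLE_PLANNING_CT,
    ROLE_CLINICAL_STRUCT,
    ROLE_PLAN,
    ROLE_DOSE,
)
OPTIONAL_ROLES = (ROLE_SFOV_CT, ROLE_CONTRAST_CT, ROLE_CONTRAST_REG)

_CT_ROLES = (ROLE_PLANNING_CT, ROLE_SFOV_CT, ROLE_CONTRAST_CT)


@dataclass(frozen=True)
class ImageGrid:
    """Geometry of a CT voxel lattice in patient coordinates.

    Parameters
    ----------
    origin
        Patient-space position of the centre of voxel (0, 0, 0), in mm.
    spacing
        Voxel size ``(row, column, slice)`` in mm; all components positive.
    axes
        3x3 array whose rows are the row, column and slice direction unit
        vectors in patient coordinates.  Must be orthonormal.
    dims
        ``(n_rows, n_cols, n_slices)``.
    frame_of_reference
        DICOM Frame-of-Reference UID of the coordinate system.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    axes: tuple[tuple[float, ...], ...] = (
        (0.0, 1.0, 0.0),
        (1.0, 0.0, 0.0),
        (0.0, 0.0, 1.0),
    )
    dims: tuple[int, int, int] = (1, 1, 1)
    frame_of_reference: str = ""

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        if any(d <= 0 for d in self.dims):
            raise ValidationError(f"dims must be positive, got {self.dims}")
        a = np.asarray(self.axes, dtype=float)
        if a.shape != (3, 3) or not np.allclose(a @ a.T, np.eye(3), atol=1e-6):
            raise ValidationError("axes must be mutually orthonormal unit vectors")

    # -- derived geometry -------------------------------------------------
    @property
    def axes_array(self) -> np.ndarray:
        return np.asarray(self.axes, dtype=float)

    @property
    def is_axial(self) -> bool:
        """True when rows/cols/slices align with the patient y/x/z axes."""
        return np.allclose(
            self.axes_array,
            [[0, 1, 0], [1, 0, 0], [0, 0, 1]],
            atol=1e-6,
        )

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def slice_zs(self) -> np.ndarray:
        """Patient-space z coordinate of every slice plane (axial grids)."""
        return self.origin[2] + np.arange(self.dims[2]) * self.spacing[2]

    def xs(self) -> np.ndarray:
        """Voxel-centre x coordinates along the column axis."""
        return self.origin[0] + np.arange(self.dims[1]) * self.spacing[1]

    def ys(self) -> np.ndarray:
        """Voxel-centre y coordinates along the row axis."""
        return self.origin[1] + np.arange(self.dims[0]) * self.spacing[0]

    @classmethod
    def from_ct_series(cls, series: Sequence[Dataset]) -> "ImageGrid":
        """Build the grid of a (sorted) axial CT series."""
        slices = sorted(series, key=lambda d: float(d.ImagePositionPatient[2]))
        first = slices[0]
        iop = [float(v) for v in first.ImageOrientationPatient]
        row_dir = iop[3:]  # direction along increasing row index
        col_dir = iop[:3]  # direction along increasing column index
        slice_dir = np.cross(row_dir, col_dir)
        if slice_dir[2] < 0:
            slice_dir = -slice_dir
        zs = np.array([float(d.ImagePositionPatient[2]) for d in slices])
        dz = float(np.mean(np.diff(zs))) if len(zs) > 1 else float(
            getattr(first, "SliceThickness", 1.0)
        )
        spacing = (
            float(first.PixelSpacing[0]),
            float(first.PixelSpacing[1]),
            abs(dz),
        )
        return cls(
            origin=tuple(float(v) for v in first.ImagePositionPatient),
            spacing=spacing,
            axes=(tuple(row_dir), tuple(col_dir), tuple(slice_dir)),
            dims=(int(first.Rows), int(first.Columns), len(slices)),
            frame_of_reference=str(first.FrameOfReferenceUID),
        )


@dataclass
class PlanarContour:
    """A closed planar polygon on an axial plane at height ``z`` (mm)."""

    z: float
    vertices: np.ndarray  # (n, 2) array of (x, y) mm

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if len(self.vertices) < 3:
            raise ValidationError("a planar contour needs at least 3 vertices")


@dataclass
class Structure:
    """A labelled organ: a list of planar contours (possibly empty)."""

    label: str
    contours: list[PlanarContour] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.label:
            raise ValidationError("structure label must be non-empty")


@dataclass
class StructureSet:
    """Structures sharing a Frame-of-Reference and an annotated CT series."""

    structures: list[Structure] = field(default_factory=list)
    frame_of_reference: str = ""
    referenced_series: str = ""

    def __post_init__(self) -> None:
        labels = [s.label for s in self.structures]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate structure labels: {dupes}")

    def labels(self) -> list[str]:
        return [s.label for s in self.structures]

    def get(self, label: str) -> Structure | None:
        """Case-insensitive label lookup."""
        key = label.strip().lower()
        for s in self.structures:
            if s.label.strip().lower() == key:
                return s
        return None


@dataclass
class VolumeMask:
    """Binary voxel occupancy on an :class:`ImageGrid`."""

    grid: ImageGrid
    voxels: np.ndarray  # bool, shape == grid.dims

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != tuple(self.grid.dims):
            raise ValidationError(
                f"mask shape {self.voxels.shape} != grid dims {self.grid.dims}"
            )

    def count(self) -> int:
        return int(self.voxels.sum())

    def centroid(self) -> np.ndarray:
        """Patient-space (x, y, z) centroid of the set voxels."""
        idx = np.argwhere(self.voxels)
        if len(idx) == 0:
            raise ValidationError("centroid of an empty mask is undefined")
        rows, cols, slcs = idx.mean(axis=0)
        g = self.grid
        return np.array(
            [
                g.origin[0] + cols * g.spacing[1],
                g.origin[1] + rows * g.spacing[0],
                g.origin[2] + slcs * g.spacing[2],
            ]
        )

    def slice_occupancy(self) -> np.ndarray:
        """Boolean per-slice flag: slice has at least one set voxel."""
        return self.voxels.any(axis=(0, 1))


@dataclass
class CuratedDataset:
    """All DICOM objects of one curated case, keyed by role.

    CT roles map to lists of per-slice datasets; every other role maps to a
    single pydicom :class:`~pydicom.dataset.Dataset`.
    """

    deid_or_native_id: str
    objects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.objects) - set(ALL_ROLES)
        if unknown:
            raise ValidationError(f"unknown dataset roles: {sorted(unknown)}")

    def iter_datasets(self) -> Iterable[Dataset]:
        """Yield every pydicom dataset in the case, CT slices included."""
        for role in ALL_ROLES:
            obj = self.objects.get(role)
            if obj is None:
                continue
            if isinstance(obj, (list, tuple)):
                yield from obj
            else:
                yield obj


def ensure_shared_grid(a: VolumeMask, b: VolumeMask) -> None:
    if a.grid != b.grid:
        raise GridMismatchError("masks are defined on different image grids")


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize(
    s: Structure,
    grid: ImageGrid,
    slice_tolerance: float | None = None,
) -> VolumeMask:
    """Rasterize a structure's planar contours onto a CT grid.

    A voxel is set iff its centre lies inside the even-odd union of the
    polygons assigned to its slice; multiple polygons on one slice combine
    by XOR, so inner rings cut holes.  A contour is assigned to the nearest
    slice plane if the distance is at most ``slice_tolerance`` (default half
    the slice spacing); farther contours raise :class:`ContourPlaneError`.
    """
    if not grid.is_axial:
        raise ValidationError("rasterize supports axial grids only")
    if slice_tolerance is None:
        slice_tolerance = 0.5 * grid.spacing[2]
    n_rows, n_cols, n_slices = grid.dims
    voxels = np.zeros((n_rows, n_cols, n_slices), dtype=bool)
    if not s.contours:
        return VolumeMask(grid, voxels)

    zs = grid.slice_zs()
    xs = grid.xs()
    ys = grid.ys()
    for contour in s.contours:
        k = int(np.argmin(np.abs(zs - contour.z)))
        if abs(zs[k] - contour.z) > slice_tolerance + 1e-9:
            raise ContourPlaneError(
                f"contour of '{s.label}' at z={contour.z:.3f} mm is farther "
                f"than {slice_tolerance:.3f} mm from every slice plane"
            )
        voxels[:, :, k] ^= _polygon_mask(contour.vertices, xs, ys)
    return VolumeMask(grid, voxels)


def _polygon_mask(vertices: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Voxel-centre point-in-polygon test restricted to the polygon bbox."""
    out = np.zeros((len(ys), len(xs)), dtype=bool)
    xmin, ymin = vertices.min(axis=0)
    xmax, ymax = vertices.max(axis=0)
    j0, j1 = np.searchsorted(xs, [xmin, xmax])
    i0, i1 = np.searchsorted(ys, [ymin, ymax])
    j1 = min(j1 + 1, len(xs))
    i1 = min(i1 + 1, len(ys))
    if j0 >= j1 or i0 >= i1:
        return out
    gx, gy = np.meshgrid(xs[j0:j1], ys[i0:i1])
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    # explicit closing vertex: Path(..., closed=True) would treat the last
    # input vertex as the CLOSEPOLY placeholder and drop it
    path = MplPath(np.vstack([vertices, vertices[:1]]), closed=True)
    inside = path.contains_points(pts).reshape(gy.shape)
    out[i0:i1, j0:j1] = inside
    return out


def mask_volume_cc(m: VolumeMask) -> float:
    """Volume of the set voxels in cc (1 cc = 1000 mm^3)."""
    return m.count() * m.grid.voxel_volume_mm3 / 1000.0


# ---------------------------------------------------------------------------
# DICOM RTSTRUCT I/O
# ---------------------------------------------------------------------------

def read_rtstruct(path: str | os.PathLike) -> StructureSet:
    """Read a DICOM RT Structure Set into geometric form.

    Every ROI becomes one :class:`Structure`; ROIs without a ContourSequence
    yield structures with zero contours.  Contour coordinates are kept in
    patient-space mm exactly as stored.
    """
    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:  # pydicom raises several error types
        raise FormatError(f"{path}: not a readable DICOM file ({exc})") from exc
    return structset_from_dataset(ds, source=str(path))


def structset_from_dataset(ds: Dataset, source: str = "<dataset>") -> StructureSet:
    """Convert an in-memory RTSTRUCT dataset to a :class:`StructureSet`."""
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise FormatError(
            f"{source}: expected RTSTRUCT, got modality "
            f"{getattr(ds, 'Modality', 'unknown')!r}"
        )
    names = {
        int(roi.ROINumber): str(roi.ROIName)
        for roi in getattr(ds, "StructureSetROISequence", [])
    }
    contours_by_roi: dict[int, list[PlanarContour]] = {n: [] for n in names}
    for rc in getattr(ds, "ROIContourSequence", []):
        num = int(rc.ReferencedROINumber)
        contours_by_roi.setdefault(num, [])
        for c in getattr(rc, "ContourSequence", []):
            data = np.array([float(v) for v in c.ContourData]).reshape(-1, 3)
            contours_by_roi[num].append(
                PlanarContour(z=float(data[0, 2]), vertices=data[:, :2])
            )

    frame_of_reference = ""
    referenced_series = ""
    for fr in getattr(ds, "ReferencedFrameOfReferenceSequence", []):
        frame_of_reference = str(fr.FrameOfReferenceUID)
        for study in getattr(fr, "RTReferencedStudySequence", []):
            for series in getattr(study, "RTReferencedSeriesSequence", []):
                referenced_series = str(series.SeriesInstanceUID)

    structures = [
        Structure(label=names.get(num, f"roi_{num}"), contours=cs)
        for num, cs in sorted(contours_by_roi.items())
    ]
    return StructureSet(
        structures=structures,
        frame_of_reference=frame_of_reference,
        referenced_series=referenced_series,
    )


def build_rtstruct_dataset(
    ss: StructureSet,
    grid: ImageGrid,
    *,
    label: str = "CURATED",
    patient_id: str = "ANON",
    patient_name: str = "ANON",
    study_uid: str | None = None,
    sop_instance_uid: str | None = None,
    series_instance_uid: str | None = None,
    sop_instance_uids: Sequence[str] | None = None,
    slice_tolerance: float | None = None,
    extra_attributes: Mapping[str, object] | None = None,
) -> Dataset:
    """Assemble a standard-conformant RTSTRUCT dataset in memory.

    ``sop_instance_uids`` are the per-slice SOP Instance UIDs of the CT
    series the contours annotate (index-aligned with the grid's slices);
    when given, each contour carries a ContourImageSequence and the
    referenced-series block lists every slice, so downstream referential
    integrity checks can resolve them.
    """
    labels = ss.labels()
    if len(labels) != len(set(labels)):
        raise ValidationError("duplicate labels in structure set")
    if slice_tolerance is None:
        slice_tolerance = 0.5 * grid.spacing[2]

    ds = Dataset()
    ds.SOPClassUID = RTSTRUCT_STORAGE
    ds.SOPInstanceUID = sop_instance_uid or generate_uid()
    ds.Modality = "RTSTRUCT"
    ds.PatientID = patient_id
    ds.PatientName = patient_name
    ds.StudyInstanceUID = study_uid or generate_uid()
    ds.SeriesInstanceUID = series_instance_uid or generate_uid()
    ds.StructureSetLabel = label
    ds.SeriesDescription = label
    for key, value in (extra_attributes or {}).items():
        setattr(ds, key, value)
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    ds.RTROIObservationsSequence = []

    fr = Dataset()
    fr.FrameOfReferenceUID = ss.frame_of_reference or grid.frame_of_reference
    study = Dataset()
    study.ReferencedSOPClassUID = "1.2.840.10008.3.1.2.3.1"  # detached study
    study.ReferencedSOPInstanceUID = ds.StudyInstanceUID
    series = Dataset()
    series.SeriesInstanceUID = ss.referenced_series or ""
    series.ContourImageSequence = []
    if sop_instance_uids is not None:
        for uid in sop_instance_uids:
            img = Dataset()
            img.ReferencedSOPClassUID = CT_IMAGE_STORAGE
            img.ReferencedSOPInstanceUID = uid
            series.ContourImageSequence.append(img)
    study.RTReferencedSeriesSequence = [series]
    fr.RTReferencedStudySequence = [study]
    ds.ReferencedFrameOfReferenceSequence = [fr]

    zs = grid.slice_zs()
    for num, structure in enumerate(ss.structures, start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = structure.label
        roi.ReferencedFrameOfReferenceUID = fr.FrameOfReferenceUID
        roi.ROIGenerationAlgorithm = ""
        ds.StructureSetROISequence.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ROIDisplayColor = [128, 128, 128]
        rc.ContourSequence = []
        for contour in structure.contours:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(contour.vertices)
            pts = np.column_stack(
                [contour.vertices, np.full(len(contour.vertices), contour.z)]
            )
            c.ContourData = [f"{v:.4f}" for v in pts.ravel()]
            if sop_instance_uids is not None:
                k = int(np.argmin(np.abs(zs - contour.z)))
                if abs(zs[k] - contour.z) <= slice_tolerance + 1e-9:
                    img = Dataset()
                    img.ReferencedSOPClassUID = CT_IMAGE_STORAGE
                    img.ReferencedSOPInstanceUID = sop_instance_uids[k]
                    c.ContourImageSequence = [img]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)

        obs = Dataset()
        obs.ObservationNumber = num
        obs.ReferencedROINumber = num
        obs.RTROIInterpretedType = "ORGAN"
        obs.ROIInterpreter = ""
        ds.RTROIObservationsSequence.append(obs)

    attach_file_meta(ds)
    return ds


def write_rtstruct(
    ss: StructureSet,
    grid: ImageGrid,
    path: str | os.PathLike,
    **kwargs,
) -> str:
    """Write a structure set as a part-10 RTSTRUCT file; returns the path."""
    if ss.frame_of_reference and grid.frame_of_reference and (
        ss.frame_of_reference != grid.frame_of_reference
    ):
        raise ValidationError(
            "structure set and grid reference different Frames-of-Reference"
        )
    ds = build_rtstruct_dataset(ss, grid, **kwargs)
    ds.save_as(path, enforce_file_format=True)
    return str(path)


def attach_file_meta(ds: Dataset) -> None:
    """Give an in-memory dataset the file meta needed for part-10 writing."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta = meta


# ---------------------------------------------------------------------------
# Curated-dataset directory I/O (one parent directory per patient)
# ---------------------------------------------------------------------------

_ROLE_FILE_PREFIX = {
    ROLE_CURATED_STRUCT: "RS_curated",
    ROLE_CLINICAL_STRUCT: "RS_clinical",
    ROLE_PLAN: "RP",
    ROLE_DOSE: "RD",
    ROLE_CONTRAST_REG: "RE",
    ROLE_PLANNING_CT: "CT_planning",
    ROLE_SFOV_CT: "CT_sfov",
    ROLE_CONTRAST_CT: "CT_contrast",
}


def save_dataset(ds: CuratedDataset, directory: str | os.PathLike) -> str:
    """Write every object of a curated case into one patient directory."""
    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    for role, obj in ds.objects.items():
        prefix = _ROLE_FILE_PREFIX[role]
        if isinstance(obj, (list, tuple)):
            for i, slice_ds in enumerate(obj):
                slice_ds.save_as(
                    os.path.join(directory, f"{prefix}_{i:04d}.dcm"),
                    enforce_file_format=True,
                )
        else:
            obj.save_as(
                os.path.join(directory, f"{prefix}.dcm"), enforce_file_format=True
            )
    return directory


def load_dataset(directory: str | os.PathLike) -> CuratedDataset:
    """Load a patient directory written by :func:`save_dataset`.

    Objects are classified by DICOM modality; CT series are told apart by
    their SeriesDescription ("PLANNING", "SFOV", "CONTRAST") and structure
    sets by StructureSetLabel ("CURATED" vs anything else = clinical).
    """
    directory = str(directory)
    files = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if f.lower().endswith(".dcm")
    )
    if not files:
        raise FormatError(f"{directory}: no DICOM files found")
    ct_series: dict[str, list[Dataset]] = {}
    objects: dict = {}
    for f in files:
        ds = pydicom.dcmread(f)
        modality = getattr(ds, "Modality", "")
        if modality == "CT":
            ct_series.setdefault(str(ds.SeriesInstanceUID), []).append(ds)
        elif modality == "RTSTRUCT":
            label = str(getattr(ds, "StructureSetLabel", "")).upper()
            role = ROLE_CURATED_STRUCT if "CURATED" in label else ROLE_CLINICAL_STRUCT
            objects[role] = ds
        elif modality in ("RTPLAN", "RTIONPLAN"):
            objects[ROLE_PLAN] = ds
        elif modality == "RTDOSE":
            objects[ROLE_DOSE] = ds
        elif modality == "REG":
            objects[ROLE_CONTRAST_REG] = ds

    for uid, slices in ct_series.items():
        slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))
        desc = str(getattr(slices[0], "SeriesDescription", "")).upper()
        if "SFOV" in desc:
            objects[ROLE_SFOV_CT] = slices
        elif "CONTRAST" in desc:
            objects[ROLE_CONTRAST_CT] = slices
        else:
            objects[ROLE_PLANNING_CT] = slices

    patient_id = ""
    for obj in objects.values():
        first = obj[0] if isinstance(obj, list) else obj
        patient_id = str(getattr(first, "PatientID", "")) or patient_id
        if patient_id:
            break
    return CuratedDataset(deid_or_native_id=patient_id, objects=objects)
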