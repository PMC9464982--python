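"""Synthetic curated-dataset generator with injectable contour defects.

Every other module in the toolkit is testable without patient data because
this module emulates the object schema of a curated case: an axial
planning-CT series on the nominal 1.27 x 1.27 x 2.0 mm grid, a body
outline, midline and bilateral organs drawn as closed planar contours
(64-vertex circle/ellipse cross-sections, so areas and volumes have closed
forms), clinical-structure-set, RT-plan and RT-dose stubs, and optionally
an SFOV reconstruction, a contrast CT and the spatial registration linking
it.  CT pixel content is schematic (soft tissue inside the body ellipse,
air outside); none of the QA machinery reads intensities.

Defects mirror the failure modes curation QA exists to catch: tiny
discontiguous islands ("ditzels"), interior holes, left/right label swaps,
anatomy protruding from the body outline, empty structures, missing DICOM
objects and dangling cross-references.  Each defect kind flips exactly one
intended detector, so the defect/detector matrix can be exercised
exhaustively.  Generation and injection are deterministic given the seed.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
from pydicom.dataset import Dataset

from .errors import ValidationError
from .rtdata_model import (
    CT_IMAGE_STORAGE,
    RTDOSE_STORAGE,
    RTPLAN_STORAGE,
    RTSTRUCT_STORAGE,
    SPATIAL_REGISTRATION_STORAGE,
    ROLE_CLINICAL_STRUCT,
    ROLE_CONTRAST_CT,
    ROLE_CONTRAST_REG,
    ROLE_CURATED_STRUCT,
    ROLE_DOSE,
    ROLE_PLANNING_CT,
    ROLE_SFOV_CT,
    ROLE_PLAN,
    CuratedDataset,
    ImageGrid,
    PlanarContour,
    Structure,
    StructureSet,
    attach_file_meta,
    build_rtstruct_dataset,
)
from .nomenclature import LabelRegistry, sidedness_of

DEFECT_KINDS = (
    "ditzel",
    "hole",
    "sidedness_swap",
    "outside_body",
    "empty_structure",
    "drop_object",
    "stale_reference",
)

_N_VERTICES = 64
_PHANTOM_UID_ROOT = "1.2.826.0.1.3680043.10.511"
_STUDY_DATE = "20210315"


@dataclass(frozen=True)
class OrganSpec:
    """One organ: an analytic shape placed in patient coordinates (mm)."""

    label: str
    shape: str  # ellipsoid | cylinder
    center: tuple[float, float, float]
    radii: tuple[float, float, float]  # (rx, ry, rz half-extent)

    def __post_init__(self) -> None:
        if self.shape not in ("ellipsoid", "cylinder"):
            raise ValidationError(f"unknown organ shape {self.shape!r}")


@dataclass(frozen=True)
class DefectSpec:
    """A single injectable contour or dataset defect."""

    kind: str
    target: str = ""  # structure label, bilateral stem, or dataset role
    magnitude: float = 0.0  # volume in cc (ditzel/hole) or offset in mm

    def __post_init__(self) -> None:
        if self.kind not in DEFECT_KINDS:
            raise ValidationError(f"unknown defect kind {self.kind!r}")


@dataclass
class PhantomConfig:
    """Geometry of a synthetic curated case.

    Bilateral organs are mirrored about the x = 0 sagittal midplane, with
    the ``_l`` member at positive x (LPS: +x is patient-left).
    """

    dims: tuple[int, int, int] = (96, 96, 40)
    spacing: tuple[float, float, float] = (1.27, 1.27, 2.0)  # (row, col, slice)
    body_radii: tuple[float, float] = (58.0, 58.0)
    organs: list[OrganSpec] = field(default_factory=list)
    patient_id: str = "MRN123456"
    patient_name: str = "PHANTOM^CASE"
    seed: int = 0
    include_optional: bool = True

    @property
    def origin(self) -> tuple[float, float, float]:
        # centre the grid on the sagittal/coronal midplanes, z from 0
        n_rows, n_cols, _ = self.dims
        dy, dx, _ = self.spacing
        return (-(n_cols - 1) / 2.0 * dx, -(n_rows - 1) / 2.0 * dy, 0.0)

    def grid(self, frame_of_reference: str = "") -> ImageGrid:
        return ImageGrid(
            origin=self.origin,
            spacing=self.spacing,
            dims=self.dims,
            frame_of_reference=frame_of_reference,
        )

    # -- stock configurations ---------------------------------------------
    @classmethod
    def default(
        cls, registry: LabelRegistry | None = None, seed: int = 0
    ) -> "PhantomConfig":
        """Full head-and-neck layout: every registry organ plus the body.

        Midline organs sit on x = 0; bilateral pairs at x = +/-28 mm.  The
        spinal cord is a long cylinder so several slices carry midline
        anatomy; everything else is a small ellipsoid.  Placement is a
        deterministic function of registry order.
        """
        reg = registry or LabelRegistry.default()
        organs: list[OrganSpec] = []
        mid_i = bil_i = 0
        for entry in reg.entries:
            labels = entry.expand()
            if entry.is_bilateral:
                y = -40.0 + (bil_i % 13) * 6.5
                z = 10.0 + (bil_i % 7) * 8.0
                for label in labels:
                    x = 28.0 if sidedness_of(label) == "left" else -28.0
                    organs.append(
                        OrganSpec(label, "ellipsoid", (x, y, z), (4.0, 4.0, 4.0))
                    )
                bil_i += 1
            else:
                label = labels[0]
                if label == "cord":
                    organs.append(
                        OrganSpec(label, "cylinder", (0.0, 10.0, 40.0), (3.0, 3.0, 28.0))
                    )
                elif label == "brain_stem":
                    organs.append(
                        OrganSpec(label, "ellipsoid", (0.0, 0.0, 60.0), (4.0, 4.0, 4.0))
                    )
                else:
                    y = -36.0 + (mid_i % 12) * 6.0
                    z = 12.0 + (mid_i % 7) * 8.0
                    organs.append(
                        OrganSpec(label, "ellipsoid", (0.0, y, z), (4.0, 4.0, 4.0))
                    )
                mid_i += 1
        return cls(organs=organs, seed=seed)

    @classmethod
    def fine(cls, seed: int = 0) -> "PhantomConfig":
        """Small high-resolution layout on an SFOV-like 0.59 mm grid.

        Used when sub-voxel-of-the-planning-grid volumes matter: on the
        planning grid one voxel is already 0.0032 cc, so the 0.003 cc QA
        threshold can only be probed from below on a finer lattice.
        """
        organs = [
            OrganSpec("brain_stem", "ellipsoid", (0.0, 2.0, 16.0), (4.0, 4.0, 4.0)),
            OrganSpec("cord", "cylinder", (0.0, 8.0, 12.0), (3.0, 3.0, 10.0)),
            OrganSpec("parotid_l", "ellipsoid", (13.0, -8.0, 12.0), (8.0, 8.0, 6.0)),
            OrganSpec("parotid_r", "ellipsoid", (-13.0, -8.0, 12.0), (8.0, 8.0, 6.0)),
        ]
        return cls(
            dims=(96, 96, 24),
            spacing=(0.59, 0.59, 1.0),
            body_radii=(27.0, 27.0),
            organs=organs,
            seed=seed,
            include_optional=False,
        )


class _UidFactory:
    """Sequential UIDs under a fixed root: deterministic given the seed."""

    def __init__(self, seed: int) -> None:
        self._prefix = f"{_PHANTOM_UID_ROOT}.{seed % 10**6}"
        self._n = 0

    def __call__(self) -> str:
        self._n += 1
        return f"{self._prefix}.{self._n}"


# ---------------------------------------------------------------------------
# Analytic contour construction
# ---------------------------------------------------------------------------

def _circle(cx: float, cy: float, rx: float, ry: float) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * math.pi, _N_VERTICES, endpoint=False)
    return np.column_stack([cx + rx * np.cos(theta), cy + ry * np.sin(theta)])


def organ_contours(spec: OrganSpec, slice_zs: np.ndarray) -> list[PlanarContour]:
    """Per-slice cross-section polygons of an analytic organ."""
    cx, cy, cz = spec.center
    rx, ry, rz = spec.radii
    contours = []
    for z in slice_zs:
        dz = (z - cz) / rz
        if abs(dz) > 1.0:
            continue
        s = 1.0 if spec.shape == "cylinder" else math.sqrt(max(0.0, 1.0 - dz * dz))
        if s < 0.1:  # degenerate polar cap: below voxel sampling
            continue
        contours.append(PlanarContour(z=float(z), vertices=_circle(cx, cy, rx * s, ry * s)))
    return contours


def _body_structure(config: PhantomConfig, slice_zs: np.ndarray) -> Structure:
    rx, ry = config.body_radii
    return Structure(
        label="body",
        contours=[
            PlanarContour(z=float(z), vertices=_circle(0.0, 0.0, rx, ry))
            for z in slice_zs
        ],
    )


def _check_inside_body(config: PhantomConfig) -> None:
    brx, bry = config.body_radii
    n_rows, n_cols, n_slices = config.dims
    dy, dx, dz = config.spacing
    half_x = (n_cols - 1) / 2.0 * dx
    half_y = (n_rows - 1) / 2.0 * dy
    z_max = (n_slices - 1) * dz
    for o in config.organs:
        cx, cy, cz = o.center
        rx, ry, rz = o.radii
        if abs(cx) + rx > half_x or abs(cy) + ry > half_y or not (0 <= cz <= z_max):
            raise ValidationError(f"organ {o.label!r} extends outside the grid")
        u = (abs(cx) + rx) / brx
        v = (abs(cy) + ry) / bry
        if u * u + v * v > 1.0:
            raise ValidationError(f"organ {o.label!r} extends outside the body")


# ---------------------------------------------------------------------------
# DICOM object assembly
# ---------------------------------------------------------------------------

def _base_attributes(config: PhantomConfig, study_uid: str) -> dict:
    # identifying attributes are present on purpose: the de-identification
    # module needs realistic material to scrub
    return {
        "PatientID": config.patient_id,
        "PatientName": config.patient_name,
        "PatientBirthDate": "19600102",
        "PatientSex": "O",
        "ReferringPhysicianName": "PHYSICIAN^REFERRING",
        "InstitutionName": "EXAMPLE MEDICAL CENTER",
        "StationName": "CT-SIM-01",
        "AccessionNumber": "ACC0001",
        "StudyID": "S0001",
        "StudyDescription": f"HN planning, mrn {config.patient_id[-6:]}",
        "StudyDate": _STUDY_DATE,
        "StudyTime": "101500",
        "StudyInstanceUID": study_uid,
    }


def _ct_series(
    config: PhantomConfig,
    uids: _UidFactory,
    study_uid: str,
    frame_of_reference: str,
    description: str,
    dims: tuple[int, int, int] | None = None,
    spacing: tuple[float, float, float] | None = None,
) -> list[Dataset]:
    dims = dims or config.dims
    spacing = spacing or config.spacing
    n_rows, n_cols, n_slices = dims
    dy, dx, dz = spacing
    origin = (-(n_cols - 1) / 2.0 * dx, -(n_rows - 1) / 2.0 * dy, 0.0)
    series_uid = uids()

    xs = origin[0] + np.arange(n_cols) * dx
    ys = origin[1] + np.arange(n_rows) * dy
    gx, gy = np.meshgrid(xs, ys)
    brx, bry = config.body_radii
    inside = (gx / brx) ** 2 + (gy / bry) ** 2 <= 1.0
    # stored values with intercept -1024: soft tissue ~40 HU, air -1000 HU
    pixels = np.where(inside, 1064, 24).astype(np.int16)
    rng = np.random.default_rng(config.seed)
    pixels = pixels + rng.integers(-5, 6, size=pixels.shape).astype(np.int16)

    slices = []
    for k in range(n_slices):
        ds = Dataset()
        for key, value in _base_attributes(config, study_uid).items():
            setattr(ds, key, value)
        ds.SOPClassUID = CT_IMAGE_STORAGE
        ds.SOPInstanceUID = uids()
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.SeriesDescription = description
        ds.SeriesNumber = 1
        ds.InstanceNumber = k + 1
        ds.FrameOfReferenceUID = frame_of_reference
        ds.ImagePositionPatient = [origin[0], origin[1], k * dz]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [dy, dx]
        ds.SliceThickness = dz
        ds.Rows = n_rows
        ds.Columns = n_cols
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.RescaleIntercept = -1024.0
        ds.RescaleSlope = 1.0
        ds.PixelData = pixels.tobytes()
        ds["PixelData"].VR = "OW"
        attach_file_meta(ds)
        slices.append(ds)
    return slices


def _rtplan(
    config: PhantomConfig,
    uids: _UidFactory,
    study_uid: str,
    frame_of_reference: str,
    struct_sop_uid: str,
) -> Dataset:
    ds = Dataset()
    for key, value in _base_attributes(config, study_uid).items():
        setattr(ds, key, value)
    ds.SOPClassUID = RTPLAN_STORAGE
    ds.SOPInstanceUID = uids()
    ds.Modality = "RTPLAN"
    ds.SeriesInstanceUID = uids()
    ds.SeriesNumber = 10
    ds.FrameOfReferenceUID = frame_of_reference
    ds.RTPlanLabel = "HN_PLAN"
    ds.RTPlanDate = _STUDY_DATE
    ds.RTPlanGeometry = "PATIENT"
    ref = Dataset()
    ref.ReferencedSOPClassUID = RTSTRUCT_STORAGE
    ref.ReferencedSOPInstanceUID = struct_sop_uid
    ds.ReferencedStructureSetSequence = [ref]
    attach_file_meta(ds)
    return ds


def _rtdose(
    config: PhantomConfig,
    uids: _UidFactory,
    study_uid: str,
    frame_of_reference: str,
    plan_sop_uid: str,
    grid_mm: float = 3.0,
) -> Dataset:
    ds = Dataset()
    for key, value in _base_attributes(config, study_uid).items():
        setattr(ds, key, value)
    ds.SOPClassUID = RTDOSE_STORAGE
    ds.SOPInstanceUID = uids()
    ds.Modality = "RTDOSE"
    ds.SeriesInstanceUID = uids()
    ds.SeriesNumber = 11
    ds.FrameOfReferenceUID = frame_of_reference
    n = 40
    frames = 26
    ds.Rows = n
    ds.Columns = n
    ds.NumberOfFrames = frames
    ds.ImagePositionPatient = [-(n - 1) / 2 * grid_mm, -(n - 1) / 2 * grid_mm, 0.0]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [grid_mm, grid_mm]
    ds.GridFrameOffsetVector = [k * grid_mm for k in range(frames)]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = 1e-4
    ds.PixelData = np.zeros((frames, n, n), dtype=np.uint32).tobytes()
    ds["PixelData"].VR = "OW"
    ref = Dataset()
    ref.ReferencedSOPClassUID = RTPLAN_STORAGE
    ref.ReferencedSOPInstanceUID = plan_sop_uid
    ds.ReferencedRTPlanSequence = [ref]
    attach_file_meta(ds)
    return ds


def _reg_object(
    config: PhantomConfig,
    uids: _UidFactory,
    study_uid: str,
    planning_for: str,
    contrast_for: str,
) -> Dataset:
    ds = Dataset()
    for key, value in _base_attributes(config, study_uid).items():
        setattr(ds, key, value)
    ds.SOPClassUID = SPATIAL_REGISTRATION_STORAGE
    ds.SOPInstanceUID = uids()
    ds.Modality = "REG"
    ds.SeriesInstanceUID = uids()
    ds.SeriesNumber = 20
    ds.FrameOfReferenceUID = planning_for
    item = Dataset()
    item.FrameOfReferenceUID = contrast_for
    mr = Dataset()
    mr.FrameOfReferenceTransformationMatrixType = "RIGID"
    mr.FrameOfReferenceTransformationMatrix = [
        1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1
    ]
    matrix_seq = Dataset()
    matrix_seq.MatrixSequence = [mr]
    item.MatrixRegistrationSequence = [matrix_seq]
    ds.RegistrationSequence = [item]
    attach_file_meta(ds)
    return ds


# ---------------------------------------------------------------------------
# Public generator API
# ---------------------------------------------------------------------------

def generate(config: PhantomConfig | None = None) -> CuratedDataset:
    """Build a complete synthetic curated case (deterministic per seed)."""
    config = config or PhantomConfig.default()
    _check_inside_body(config)
    uids = _UidFactory(config.seed)
    study_uid = uids()
    planning_for = uids()

    planning_ct = _ct_series(
        config, uids, study_uid, planning_for, "HN PLANNING CT"
    )
    grid = ImageGrid.from_ct_series(planning_ct)
    slice_zs = grid.slice_zs()
    ct_sop_uids = [str(s.SOPInstanceUID) for s in planning_ct]
    series_uid = str(planning_ct[0].SeriesInstanceUID)

    structures = [_body_structure(config, slice_zs)]
    structures += [
        Structure(label=o.label, contours=organ_contours(o, slice_zs))
        for o in config.organs
    ]
    curated_ss = StructureSet(
        structures=structures,
        frame_of_reference=planning_for,
        referenced_series=series_uid,
    )
    curated = build_rtstruct_dataset(
        curated_ss,
        grid,
        label="CURATED OARS",
        patient_id=config.patient_id,
        patient_name=config.patient_name,
        study_uid=study_uid,
        sop_instance_uid=uids(),
        series_instance_uid=uids(),
        sop_instance_uids=ct_sop_uids,
        extra_attributes=_base_attributes(config, study_uid),
    )

    # clinical structure set: what RT planning left behind — same anatomy
    # but without carotid arteries, which clinical sets typically lack
    clinical_ss = StructureSet(
        structures=[
            s for s in structures if not s.label.startswith("carotid_artery")
        ],
        frame_of_reference=planning_for,
        referenced_series=series_uid,
    )
    clinical = build_rtstruct_dataset(
        clinical_ss,
        grid,
        label="CLINICAL OARS",
        patient_id=config.patient_id,
        patient_name=config.patient_name,
        study_uid=study_uid,
        sop_instance_uid=uids(),
        series_instance_uid=uids(),
        sop_instance_uids=ct_sop_uids,
        extra_attributes=_base_attributes(config, study_uid),
    )

    plan = _rtplan(config, uids, study_uid, planning_for, str(curated.SOPInstanceUID))
    dose = _rtdose(config, uids, study_uid, planning_for, str(plan.SOPInstanceUID))

    objects: dict = {
        ROLE_PLANNING_CT: planning_ct,
        ROLE_CURATED_STRUCT: curated,
        ROLE_CLINICAL_STRUCT: clinical,
        ROLE_PLAN: plan,
        ROLE_DOSE: dose,
    }
    if config.include_optional:
        objects[ROLE_SFOV_CT] = _ct_series(
            config,
            uids,
            study_uid,
            planning_for,
            "HN SFOV CT",
            dims=(64, 64, 20),
            spacing=(0.59, 0.59, 1.0),
        )
        contrast_for = uids()
        objects[ROLE_CONTRAST_CT] = _ct_series(
            config, uids, study_uid, contrast_for, "HN CONTRAST CT"
        )
        objects[ROLE_CONTRAST_REG] = _reg_object(
            config, uids, study_uid, planning_for, contrast_for
        )
    return CuratedDataset(deid_or_native_id=config.patient_id, objects=objects)


# ---------------------------------------------------------------------------
# Defect injection
# ---------------------------------------------------------------------------

def _roi_items(struct_ds: Dataset, label: str):
    for roi, rc in zip(
        struct_ds.StructureSetROISequence, struct_ds.ROIContourSequence
    ):
        if str(roi.ROIName).strip().lower() == label.strip().lower():
            return roi, rc
    raise ValidationError(f"structure {label!r} not found in curated RTSTRUCT")


def _contour_item(z: float, vertices: np.ndarray) -> Dataset:
    c = Dataset()
    c.ContourGeometricType = "CLOSED_PLANAR"
    c.NumberOfContourPoints = len(vertices)
    pts = np.column_stack([vertices, np.full(len(vertices), z)])
    c.ContourData = [f"{v:.4f}" for v in pts.ravel()]
    return c


def _roi_centroid(rc: Dataset) -> np.ndarray:
    pts = []
    for c in getattr(rc, "ContourSequence", []):
        pts.append(np.array([float(v) for v in c.ContourData]).reshape(-1, 3))
    if not pts:
        raise ValidationError("cannot place a defect on an empty structure")
    allpts = np.vstack(pts)
    return allpts.mean(axis=0)


def _block_polygon(
    n_voxels: int,
    grid: ImageGrid,
    center_xy: tuple[float, float],
) -> tuple[np.ndarray, int]:
    """Compact rectilinear polygon covering exactly ``n_voxels`` centres.

    The region is a near-square staircase: ``full`` complete rows of width
    ``w`` plus a left-aligned partial row, snapped to the voxel lattice with
    0.45-spacing margins so no voxel centre sits on an edge.
    """
    n = int(n_voxels)
    w = max(1, math.ceil(math.sqrt(n)))
    full, r = divmod(n, w)
    n_rows_used = full + (1 if r else 0)
    xs, ys = grid.xs(), grid.ys()
    dy, dx = grid.spacing[0], grid.spacing[1]
    j0 = int(np.clip(np.argmin(np.abs(xs - center_xy[0])) - w // 2, 0, len(xs) - w))
    i0 = int(
        np.clip(
            np.argmin(np.abs(ys - center_xy[1])) - n_rows_used // 2,
            0,
            len(ys) - n_rows_used,
        )
    )
    x_left = xs[j0] - 0.45 * dx
    x_full = xs[j0 + w - 1] + 0.45 * dx
    y_top = ys[i0] - 0.45 * dy
    if full == 0:
        x_part = xs[j0 + r - 1] + 0.45 * dx
        y_bot = ys[i0] + 0.45 * dy
        verts = [[x_left, y_top], [x_part, y_top], [x_part, y_bot], [x_left, y_bot]]
    elif r == 0:
        y_bot = ys[i0 + full - 1] + 0.45 * dy
        verts = [[x_left, y_top], [x_full, y_top], [x_full, y_bot], [x_left, y_bot]]
    else:
        x_part = xs[j0 + r - 1] + 0.45 * dx
        y_mid = ys[i0 + full - 1] + 0.45 * dy
        y_bot = ys[i0 + full] + 0.45 * dy
        verts = [
            [x_left, y_top],
            [x_full, y_top],
            [x_full, y_mid],
            [x_part, y_mid],
            [x_part, y_bot],
            [x_left, y_bot],
        ]
    return np.asarray(verts, dtype=float), n


def inject(
    ds: CuratedDataset, defect: DefectSpec, seed: int = 0
) -> CuratedDataset:
    """Return a copy of the case with one defect realized.

    The curated RTSTRUCT is edited in place on the copy — UIDs and every
    untouched structure are preserved byte-for-byte, so exactly the
    intended detector flips.
    """
    out = CuratedDataset(
        deid_or_native_id=ds.deid_or_native_id,
        objects={
            role: (list(map(copy.deepcopy, obj)) if isinstance(obj, (list, tuple))
                   else copy.deepcopy(obj))
            for role, obj in ds.objects.items()
        },
    )
    rng = np.random.default_rng(seed)

    if defect.kind == "drop_object":
        if defect.target not in out.objects:
            raise ValidationError(f"role {defect.target!r} not present to drop")
        del out.objects[defect.target]
        return out

    struct_ds = out.objects[ROLE_CURATED_STRUCT]
    grid = ImageGrid.from_ct_series(out.objects[ROLE_PLANNING_CT])

    if defect.kind == "stale_reference":
        _, rc = _roi_items(struct_ds, defect.target or "body")
        contours = list(getattr(rc, "ContourSequence", []))
        with_refs = [c for c in contours if "ContourImageSequence" in c]
        if not with_refs:
            raise ValidationError("no contour image references to corrupt")
        victim = with_refs[int(rng.integers(len(with_refs)))]
        victim.ContourImageSequence[0].ReferencedSOPInstanceUID = (
            f"{_PHANTOM_UID_ROOT}.999.{int(rng.integers(10**8))}"
        )
        return out

    if defect.kind == "empty_structure":
        _, rc = _roi_items(struct_ds, defect.target)
        rc.ContourSequence = []
        return out

    if defect.kind == "sidedness_swap":
        stem = defect.target.removesuffix("_l").removesuffix("_r")
        _, rc_l = _roi_items(struct_ds, f"{stem}_l")
        _, rc_r = _roi_items(struct_ds, f"{stem}_r")
        rc_l.ContourSequence, rc_r.ContourSequence = (
            rc_r.ContourSequence,
            rc_l.ContourSequence,
        )
        return out

    if defect.kind == "outside_body":
        _, rc = _roi_items(struct_ds, defect.target)
        shift = defect.magnitude or 55.0
        for c in getattr(rc, "ContourSequence", []):
            data = np.array([float(v) for v in c.ContourData]).reshape(-1, 3)
            data[:, 0] += shift
            c.ContourData = [f"{v:.4f}" for v in data.ravel()]
        return out

    if defect.kind in ("ditzel", "hole"):
        _, rc = _roi_items(struct_ds, defect.target)
        centroid = _roi_centroid(rc)
        zs = grid.slice_zs()
        k = int(np.argmin(np.abs(zs - centroid[2])))
        vol_mm3 = defect.magnitude * 1000.0
        n = max(1, round(vol_mm3 / grid.voxel_volume_mm3))
        if defect.kind == "hole":
            center_xy = (centroid[0], centroid[1])
        else:
            # park the island 12 mm radially inward of the organ so it stays
            # inside the body and clear of its parent structure
            radial = math.hypot(centroid[0], centroid[1])
            if radial < 1e-6:
                center_xy = (0.0, centroid[1] - 12.0)
            else:
                scale = (radial - 12.0) / radial
                center_xy = (centroid[0] * scale, centroid[1] * scale)
        verts, achieved = _block_polygon(n, grid, center_xy)
        rc.ContourSequence.append(_contour_item(float(zs[k]), verts))
        return out

    raise ValidationError(f"unhandled defect kind {defect.kind!r}")
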