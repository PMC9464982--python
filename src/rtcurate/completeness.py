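"""Curated-dataset completeness validation.

A curated case must contain the required DICOM objects (curated and
clinical RTSTRUCT, planning CT, RT plan — photon or ion — and RT dose),
may contain optional ones (SFOV CT, contrast CT, spatial registration),
and the objects must be mutually linked: the SFOV reconstruction always
shares the planning CT's Frame-of-Reference, while a contrast CT is linked
either by a shared Frame-of-Reference or through a Spatial Registration
object.  Image grids must respect the curation voxel-size constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rtdata_model import (
    ALL_ROLES,
    OPTIONAL_ROLES,
    REQUIRED_ROLES,
    ROLE_CLINICAL_STRUCT,
    ROLE_CONTRAST_CT,
    ROLE_CONTRAST_REG,
    ROLE_CURATED_STRUCT,
    ROLE_DOSE,
    ROLE_PLANNING_CT,
    ROLE_SFOV_CT,
    CuratedDataset,
    structset_from_dataset,
)

# Voxel-size constraints in mm: planning/contrast CT in-plane is nominally
# 1.27 mm; SFOV reconstructions are finer; dose grids are coarse but bounded.
PLANNING_INPLANE_MM = 1.27
SFOV_INPLANE_MAX_MM = 0.59
CT_Z_MAX_MM = 2.5
DOSE_MAX_MM = 3.0
RELATIVE_TOL = 0.01  # scanner metadata rounding


@dataclass
class CompletenessReport:
    role_status: dict[str, str] = field(default_factory=dict)
    linkage_findings: list[str] = field(default_factory=list)
    voxel_findings: list[str] = field(default_factory=list)

    @property
    def missing_required(self) -> list[str]:
        return [
            r for r, s in self.role_status.items() if s == "missing-required"
        ]

    @property
    def is_complete(self) -> bool:
        return not self.missing_required

    @property
    def is_clean(self) -> bool:
        return (
            self.is_complete
            and not self.linkage_findings
            and not self.voxel_findings
        )


def check_completeness(ds: CuratedDataset) -> CompletenessReport:
    """Assign a presence status to every dataset role."""
    report = CompletenessReport()
    for role in ALL_ROLES:
        present = ds.objects.get(role) is not None
        if role in REQUIRED_ROLES:
            report.role_status[role] = (
                "present-required" if present else "missing-required"
            )
        else:
            report.role_status[role] = (
                "present-optional" if present else "missing-optional"
            )
    return report


def _frame_of_reference(obj) -> str:
    first = obj[0] if isinstance(obj, (list, tuple)) else obj
    return str(getattr(first, "FrameOfReferenceUID", ""))


def _series_uid(ct_series) -> str:
    return str(ct_series[0].SeriesInstanceUID)


def _reg_links(reg_ds) -> set[str]:
    """Frame-of-Reference UIDs a Spatial Registration object ties together."""
    fors = {str(getattr(reg_ds, "FrameOfReferenceUID", ""))}
    for item in getattr(reg_ds, "RegistrationSequence", []):
        fors.add(str(getattr(item, "FrameOfReferenceUID", "")))
    fors.discard("")
    return fors


def check_linkage(ds: CuratedDataset) -> list[str]:
    """Cross-object Frame-of-Reference and series-reference findings."""
    findings: list[str] = []
    ct = ds.objects.get(ROLE_PLANNING_CT)
    if not ct:
        return ["planning CT absent; linkage cannot be evaluated"]
    plan_for = _frame_of_reference(ct)

    sfov = ds.objects.get(ROLE_SFOV_CT)
    if sfov and _frame_of_reference(sfov) != plan_for:
        findings.append(
            "SFOV CT does not share the planning CT's Frame-of-Reference"
        )

    contrast = ds.objects.get(ROLE_CONTRAST_CT)
    if contrast:
        c_for = _frame_of_reference(contrast)
        if c_for != plan_for:
            reg = ds.objects.get(ROLE_CONTRAST_REG)
            linked = reg is not None and {plan_for, c_for} <= _reg_links(reg)
            if not linked:
                findings.append(
                    "contrast CT has a different Frame-of-Reference and no "
                    "Spatial Registration object links it to the planning CT"
                )

    for role in (ROLE_CURATED_STRUCT, ROLE_CLINICAL_STRUCT):
        struct = ds.objects.get(role)
        if struct is None:
            continue
        ss = structset_from_dataset(struct, source=role)
        if ss.frame_of_reference and ss.frame_of_reference != plan_for:
            findings.append(
                f"{role} references Frame-of-Reference "
                f"{ss.frame_of_reference}, not the planning CT's"
            )
        if role == ROLE_CURATED_STRUCT and ss.referenced_series:
            if ss.referenced_series != _series_uid(ct):
                findings.append(
                    "curated RTSTRUCT does not reference the planning CT series"
                )
    return findings


def _ct_voxel_size(ct_series) -> tuple[float, float, float]:
    first = ct_series[0]
    dy, dx = (float(v) for v in first.PixelSpacing)
    zs = sorted(float(d.ImagePositionPatient[2]) for d in ct_series)
    dz = float(np.mean(np.diff(zs))) if len(zs) > 1 else float(
        getattr(first, "SliceThickness", 0.0)
    )
    return dx, dy, abs(dz)


def _uniform_z(ct_series, rel_tol: float = RELATIVE_TOL) -> bool:
    zs = sorted(float(d.ImagePositionPatient[2]) for d in ct_series)
    if len(zs) < 3:
        return True
    gaps = np.diff(zs)
    return bool(np.ptp(gaps) <= rel_tol * np.mean(gaps))


def _close(value: float, nominal: float) -> bool:
    return abs(value - nominal) <= RELATIVE_TOL * nominal


def check_voxels(ds: CuratedDataset) -> list[str]:
    """Voxel-size findings for every image object present."""
    findings: list[str] = []
    for role, nominal_inplane in (
        (ROLE_PLANNING_CT, PLANNING_INPLANE_MM),
        (ROLE_CONTRAST_CT, PLANNING_INPLANE_MM),
    ):
        series = ds.objects.get(role)
        if not series:
            continue
        dx, dy, dz = _ct_voxel_size(series)
        if not (_close(dx, nominal_inplane) and _close(dy, nominal_inplane)):
            findings.append(
                f"{role}: in-plane voxel ({dx:.3f}, {dy:.3f}) mm, expected "
                f"{nominal_inplane} mm"
            )
        if dz > CT_Z_MAX_MM * (1 + RELATIVE_TOL):
            findings.append(f"{role}: z spacing {dz:.2f} mm exceeds {CT_Z_MAX_MM} mm")
        if not _uniform_z(series):
            findings.append(f"{role}: non-uniform (non-standard) slice spacing")

    sfov = ds.objects.get(ROLE_SFOV_CT)
    if sfov:
        dx, dy, dz = _ct_voxel_size(sfov)
        if dx > SFOV_INPLANE_MAX_MM * (1 + RELATIVE_TOL) or dy > SFOV_INPLANE_MAX_MM * (
            1 + RELATIVE_TOL
        ):
            findings.append(
                f"sfov_ct: in-plane voxel ({dx:.3f}, {dy:.3f}) mm exceeds "
                f"{SFOV_INPLANE_MAX_MM} mm"
            )
        if dz > CT_Z_MAX_MM * (1 + RELATIVE_TOL):
            findings.append(f"sfov_ct: z spacing {dz:.2f} mm exceeds {CT_Z_MAX_MM} mm")
        if not _uniform_z(sfov):
            findings.append("sfov_ct: non-uniform (non-standard) slice spacing")

    dose = ds.objects.get(ROLE_DOSE)
    if dose is not None:
        dy, dx = (float(v) for v in dose.PixelSpacing)
        offsets = [float(v) for v in getattr(dose, "GridFrameOffsetVector", [0.0])]
        dz = abs(float(np.mean(np.diff(offsets)))) if len(offsets) > 1 else 0.0
        for axis, v in (("x", dx), ("y", dy), ("z", dz)):
            if v > DOSE_MAX_MM * (1 + RELATIVE_TOL):
                findings.append(
                    f"rtdose: {axis} grid spacing {v:.2f} mm exceeds {DOSE_MAX_MM} mm"
                )
    return findings


def validate_dataset(ds: CuratedDataset) -> CompletenessReport:
    """Run presence, linkage and voxel checks; one consolidated report."""
    report = check_completeness(ds)
    if ds.objects.get(ROLE_PLANNING_CT):
        report.linkage_findings = check_linkage(ds)
        report.voxel_findings = check_voxels(ds)
    return report
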