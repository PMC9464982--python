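"""Structure-set quality assurance: five checks per labelled structure.

Per structure the report carries a PASS / FAIL / N/A verdict for

1. ``empty``          — no 2D contours, or contours rasterizing to nothing;
2. ``outside_body``   — any voxel outside the body/external outline;
3. ``holes``          — interior cavities (doughnut shapes) at or above a
   volume threshold (default 0.003 cc);
4. ``multiple_parts`` — two or more discontiguous 3-D components each at or
   above the threshold; smaller islands ("ditzels", typically stray mouse
   clicks) are warned about but do not fail;
5. ``sidedness``      — for ``_l``/``_r`` labelled organs, whether the mask
   centroid lies on the labelled side of the anatomical midline, which is
   estimated from midline organs (brainstem and/or spinal cord).

The outside-body check deliberately has *no* volume threshold: a single
protruding voxel fails.  Holes and parts use 26-connected 3-D components so
organs spanning several slices are not split spuriously; the per-slice 2-D
part count is still reported in the detail text.

Known benign failure modes (airway holes in lungs, naturally multi-part
mastoid air cells or brachial plexus) are reported, not suppressed — waiving
them is a human review decision.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import CompletenessError, MidlineError
from .nomenclature import LabelRegistry, sidedness_of
from .rtdata_model import (
    ROLE_CURATED_STRUCT,
    ROLE_PLANNING_CT,
    CuratedDataset,
    ImageGrid,
    Structure,
    StructureSet,
    VolumeMask,
    ensure_shared_grid,
    mask_volume_cc,
    rasterize,
    structset_from_dataset,
)

DEFAULT_THRESHOLD_CC = 0.003
DEFAULT_MIDLINE_LABELS = ("brain_stem", "cord")
BODY_LABELS = ("body", "external")

CHECK_NAMES = ("empty", "outside_body", "holes", "multiple_parts", "sidedness")

PASS, FAIL, NA = "PASS", "FAIL", "N/A"

# 26-connectivity structuring element for 3-D component labelling
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class CheckVerdict:
    check_name: str
    verdict: str
    detail: str = ""

    def __post_init__(self) -> None:
        assert self.verdict in (PASS, FAIL, NA)


@dataclass
class QAReport:
    """Per-structure verdicts for the five checks, plus run parameters."""

    dataset_id: str
    threshold_cc: float
    midline_x: float | None
    rows: dict[str, list[CheckVerdict]] = field(default_factory=dict)
    off_registry: list[str] = field(default_factory=list)

    def verdicts(self, label: str) -> dict[str, str]:
        return {v.check_name: v.verdict for v in self.rows[label]}

    def n_failures(self) -> int:
        return sum(
            1 for vs in self.rows.values() for v in vs if v.verdict == FAIL
        )

    def failed_labels(self) -> list[str]:
        return sorted(
            label
            for label, vs in self.rows.items()
            if any(v.verdict == FAIL for v in vs)
        )


# ---------------------------------------------------------------------------
# The five checks
# ---------------------------------------------------------------------------

def check_empty(s: Structure, m: VolumeMask | None = None) -> CheckVerdict:
    """FAIL when the structure has no contours or rasterizes to no voxels."""
    if not s.contours:
        return CheckVerdict("empty", FAIL, "no 2D contours")
    if m is not None and m.count() == 0:
        return CheckVerdict("empty", FAIL, "zero voxels")
    return CheckVerdict("empty", PASS, f"{len(s.contours)} contours")


def check_outside_body(m: VolumeMask, body: VolumeMask | None) -> CheckVerdict:
    """FAIL when any structure voxel lies outside the body outline."""
    if body is None:
        return CheckVerdict("outside_body", NA, "no body/external structure")
    ensure_shared_grid(m, body)
    outside = m.voxels & ~body.voxels
    n = int(outside.sum())
    if n:
        cc = n * m.grid.voxel_volume_mm3 / 1000.0
        return CheckVerdict(
            "outside_body", FAIL, f"{cc:.4f} cc ({n} voxels) outside body"
        )
    return CheckVerdict("outside_body", PASS, "")


def _hole_voxels(voxels: np.ndarray) -> np.ndarray:
    """Per-slice interior cavities: filled(slice) minus slice."""
    holes = np.zeros_like(voxels)
    for k in range(voxels.shape[2]):
        sl = voxels[:, :, k]
        if sl.any():
            holes[:, :, k] = ndimage.binary_fill_holes(sl) & ~sl
    return holes


def check_holes(
    m: VolumeMask, threshold_cc: float = DEFAULT_THRESHOLD_CC
) -> CheckVerdict:
    """FAIL when any 3-D-grouped interior cavity is >= the volume threshold."""
    holes = _hole_voxels(m.voxels)
    if not holes.any():
        return CheckVerdict("holes", PASS, "no holes")
    labels, n = ndimage.label(holes, structure=_CONN26)
    sizes = np.bincount(labels.ravel())[1:]
    vols_cc = sizes * m.grid.voxel_volume_mm3 / 1000.0
    big = vols_cc[vols_cc >= threshold_cc]
    detail = f"{n} hole component(s), volumes cc: " + ", ".join(
        f"{v:.4f}" for v in sorted(vols_cc, reverse=True)[:5]
    )
    if len(big):
        return CheckVerdict("holes", FAIL, detail)
    return CheckVerdict("holes", PASS, detail + " (all below threshold)")


def _slice_part_counts(voxels: np.ndarray) -> list[int]:
    counts = []
    for k in range(voxels.shape[2]):
        sl = voxels[:, :, k]
        if sl.any():
            _, n = ndimage.label(sl, structure=np.ones((3, 3), dtype=bool))
            counts.append(int(n))
    return counts


def check_parts(
    m: VolumeMask, threshold_cc: float = DEFAULT_THRESHOLD_CC
) -> CheckVerdict:
    """FAIL when >= 2 discontiguous 3-D components each reach the threshold.

    Sub-threshold islands are flagged as ditzel warnings in the detail text
    without failing the check.
    """
    labels, n = ndimage.label(m.voxels, structure=_CONN26)
    if n == 0:
        return CheckVerdict("multiple_parts", PASS, "empty mask")
    sizes = np.bincount(labels.ravel())[1:]
    vols_cc = np.sort(sizes * m.grid.voxel_volume_mm3 / 1000.0)[::-1]
    n_big = int((vols_cc >= threshold_cc).sum())
    n_ditzel = int(n - n_big)
    max_2d = max(_slice_part_counts(m.voxels), default=0)
    detail = (
        f"{n} 3D component(s), volumes cc: "
        + ", ".join(f"{v:.4f}" for v in vols_cc[:5])
        + f"; max 2D parts/slice: {max_2d}"
    )
    if n_ditzel:
        detail += f"; warning: {n_ditzel} sub-threshold ditzel(s)"
    if n_big >= 2:
        return CheckVerdict("multiple_parts", FAIL, detail)
    return CheckVerdict("multiple_parts", PASS, detail)


def estimate_midline_x(
    ss: StructureSet,
    grid: ImageGrid,
    midline_labels: Sequence[str] = DEFAULT_MIDLINE_LABELS,
    masks: dict[str, VolumeMask] | None = None,
) -> float:
    """Anatomical midline x (mm): mean of midline-organ mask centroids.

    Brainstem and spinal cord straddle the sagittal midplane, so their
    x-centroids estimate the patient's left/right divide.
    """
    xs = []
    for label in midline_labels:
        s = ss.get(label)
        if s is None or not s.contours:
            continue
        m = masks.get(s.label) if masks else None
        if m is None:
            m = rasterize(s, grid)
        if m.count():
            xs.append(float(m.centroid()[0]))
    if not xs:
        raise MidlineError(
            f"no non-empty midline structure among {list(midline_labels)}; "
            "sidedness checks must be N/A"
        )
    return float(np.mean(xs))


def check_sidedness(
    s: Structure, m: VolumeMask, midline_x: float | None
) -> CheckVerdict:
    """FAIL when a lateral label sits on the wrong side of the midline.

    In LPS coordinates +x is patient-left, so a centroid with
    ``x > midline_x`` is on the patient's left.
    """
    side = sidedness_of(s.label)
    if side == "none":
        return CheckVerdict("sidedness", NA, "non-lateral label")
    if midline_x is None:
        return CheckVerdict("sidedness", NA, "no midline estimate")
    if m.count() == 0:
        return CheckVerdict("sidedness", NA, "empty")
    cx = float(m.centroid()[0])
    detected = "left" if cx > midline_x else "right"
    detail = f"centroid x={cx:.1f} mm, midline x={midline_x:.1f} mm -> {detected}"
    if detected != side:
        return CheckVerdict("sidedness", FAIL, detail + f", label says {side}")
    return CheckVerdict("sidedness", PASS, detail)


# ---------------------------------------------------------------------------
# Dataset-level runner and CSV report
# ---------------------------------------------------------------------------

def find_body_structure(ss: StructureSet) -> Structure | None:
    for label in BODY_LABELS:
        s = ss.get(label)
        if s is not None:
            return s
    return None


def run_qa(
    ds: CuratedDataset,
    reg: LabelRegistry | None = None,
    threshold_cc: float = DEFAULT_THRESHOLD_CC,
    midline_labels: Sequence[str] = DEFAULT_MIDLINE_LABELS,
) -> QAReport:
    """Run all five checks on every structure of the curated structure set.

    Each structure is rasterized once onto the planning-CT grid; the midline
    is estimated once.  The body/external structure itself is exempt from
    the outside-body and sidedness checks (reported N/A).
    """
    struct_ds = ds.objects.get(ROLE_CURATED_STRUCT)
    ct = ds.objects.get(ROLE_PLANNING_CT)
    if struct_ds is None or not ct:
        raise CompletenessError(
            "run_qa needs a curated RTSTRUCT and a planning CT; run the "
            "completeness check for a full object inventory"
        )
    ss = structset_from_dataset(struct_ds, source="curated RTSTRUCT")
    grid = ImageGrid.from_ct_series(ct)
    masks = {s.label: rasterize(s, grid) for s in ss.structures}

    body_struct = find_body_structure(ss)
    body_mask = masks[body_struct.label] if body_struct is not None else None
    try:
        midline_x = estimate_midline_x(ss, grid, midline_labels, masks=masks)
    except MidlineError:
        midline_x = None

    report = QAReport(
        dataset_id=ds.deid_or_native_id,
        threshold_cc=threshold_cc,
        midline_x=midline_x,
    )
    if reg is not None:
        from .nomenclature import validate_labels

        report.off_registry = validate_labels(ss, reg)
    for s in ss.structures:
        m = masks[s.label]
        is_body = body_struct is not None and s.label == body_struct.label
        verdicts = [
            check_empty(s, m),
            CheckVerdict("outside_body", NA, "body outline itself")
            if is_body
            else check_outside_body(m, body_mask),
            check_holes(m, threshold_cc),
            check_parts(m, threshold_cc),
            CheckVerdict("sidedness", NA, "body outline itself")
            if is_body
            else check_sidedness(s, m, midline_x),
        ]
        report.rows[s.label] = verdicts
    return report


def write_qa_report(r: QAReport, path: str | os.PathLike) -> str:
    """Serialize a QA report as CSV: one row per structure, stable columns."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", *CHECK_NAMES, "detail"])
        for label, verdicts in r.rows.items():
            by_name = {v.check_name: v for v in verdicts}
            detail = "; ".join(
                f"{v.check_name}: {v.detail}" for v in verdicts if v.detail
            )
            writer.writerow(
                [label]
                + [by_name[name].verdict for name in CHECK_NAMES]
                + [detail]
            )
    return str(path)
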