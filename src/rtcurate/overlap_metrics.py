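"""Volumetric overlap metrics between curated and clinical structures.

Two variants of the Dice similarity coefficient are computed on voxel
masks sharing one CT grid:

* ``dsc``: the standard 2|A∩B| / (|A| + |B|), range [0, 1];
* ``overlap_dsc``: the same quantity after restricting both masks to the
  CT slices where *each* structure has at least one voxel.  This removes
  the penalty for differing superior-inferior extent (e.g. how far down an
  esophagus was contoured), isolating in-slice agreement.

Both are ``None`` (undefined, not zero) when the denominator is empty —
conflating "no data" with "no overlap" would corrupt cohort medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rtdata_model import (
    ImageGrid,
    StructureSet,
    VolumeMask,
    ensure_shared_grid,
    rasterize,
)


@dataclass(frozen=True)
class MetricResult:
    label: str
    dsc: float | None
    overlap_dsc: float | None
    shared_slices: int

    def __post_init__(self) -> None:
        for v in (self.dsc, self.overlap_dsc):
            assert v is None or 0.0 <= v <= 1.0


def dsc(a: VolumeMask, b: VolumeMask) -> float | None:
    """Dice similarity coefficient; ``None`` when both masks are empty."""
    ensure_shared_grid(a, b)
    na, nb = a.count(), b.count()
    if na + nb == 0:
        return None
    inter = int((a.voxels & b.voxels).sum())
    return 2.0 * inter / (na + nb)


def overlap_dsc(a: VolumeMask, b: VolumeMask) -> float | None:
    """Dice restricted to slices occupied by both masks; ``None`` if none."""
    ensure_shared_grid(a, b)
    shared = a.slice_occupancy() & b.slice_occupancy()
    if not shared.any():
        return None
    av = a.voxels[:, :, shared]
    bv = b.voxels[:, :, shared]
    denom = int(av.sum()) + int(bv.sum())
    inter = int((av & bv).sum())
    return 2.0 * inter / denom


def shared_slice_count(a: VolumeMask, b: VolumeMask) -> int:
    ensure_shared_grid(a, b)
    return int((a.slice_occupancy() & b.slice_occupancy()).sum())


def compare_sets(
    curated: StructureSet,
    clinical: StructureSet,
    grid: ImageGrid,
) -> tuple[list[MetricResult], list[str]]:
    """Per-label DSC / Overlap-DSC between two structure sets.

    Returns ``(results, skipped)`` where ``skipped`` lists labels present in
    only one of the two sets (clinical sets frequently lack organs that the
    curated standard requires, and vice versa).  Label matching is
    case-insensitive; both sets are rasterized onto the given planning grid.
    """
    cur = {s.label.strip().lower(): s for s in curated.structures}
    cli = {s.label.strip().lower(): s for s in clinical.structures}
    common = [k for k in cur if k in cli]
    skipped = sorted(set(cur) ^ set(cli))
    results = []
    for key in common:
        a = rasterize(cur[key], grid)
        b = rasterize(cli[key], grid)
        results.append(
            MetricResult(
                label=cur[key].label,
                dsc=dsc(a, b),
                overlap_dsc=overlap_dsc(a, b),
                shared_slices=shared_slice_count(a, b),
            )
        )
    return results, skipped


def summarize_cohort(results: list[list[MetricResult]]) -> pd.DataFrame:
    """Per-label distribution statistics over a cohort of cases.

    Only defined metric values contribute; the ``n_dsc`` column records how
    many cases actually had the label (counts per organ vary with what each
    clinical structure set contains).
    """
    rows = []
    labels = sorted({r.label for case in results for r in case})
    for label in labels:
        vals = [r for case in results for r in case if r.label == label]
        d = np.array([r.dsc for r in vals if r.dsc is not None], dtype=float)
        o = np.array(
            [r.overlap_dsc for r in vals if r.overlap_dsc is not None],
            dtype=float,
        )
        row: dict = {"label": label, "n_dsc": len(d), "n_overlap_dsc": len(o)}
        for name, arr in (("dsc", d), ("overlap_dsc", o)):
            if len(arr):
                row[f"median_{name}"] = float(np.median(arr))
                row[f"q1_{name}"] = float(np.percentile(arr, 25))
                row[f"q3_{name}"] = float(np.percentile(arr, 75))
                row[f"min_{name}"] = float(arr.min())
                row[f"max_{name}"] = float(arr.max())
            else:
                for stat in ("median", "q1", "q3", "min", "max"):
                    row[f"{stat}_{name}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
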