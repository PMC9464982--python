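"""Traceable, reproducible DICOM de-identification.

The engine satisfies four requirements:

1. *Policy-driven*: a tag policy maps DICOM attributes to one of four
   actions — remove, replace, redact (regex masking) or keep.
2. *Customizable*: the policy is a plain tabular config file.
3. *UID transformational reproducibility*: every UID-valued attribute and
   every referenced UID is remapped through one persistent
   :class:`UIDMapStore`, so a given original UID always maps to the same
   de-identified UID and object cross-referencing survives translation.
4. *Traceability*: the store records the original-MRN ↔ DeID-MRN pairing,
   queryable one at a time or in batch.

Geometry (contours, pixel arrays, dose grids) is never touched: only
metadata changes.  Standard DICOM UIDs (SOP class, transfer syntax — the
``1.2.840.10008`` root) are left alone; everything else with VR ``UI`` is
remapped.  Dates are shifted by a stored random per-patient offset so
intervals between study events are preserved.
"""

from __future__ import annotations

import copy
import datetime as _dt
import importlib.resources
import json
import os
import random
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from pydicom.datadict import tag_for_keyword
from pydicom.dataset import Dataset
from pydicom.tag import Tag

from .errors import IntegrityError, NotFoundError, ValidationError
from .rtdata_model import CuratedDataset, attach_file_meta

DICOM_STANDARD_UID_ROOT = "1.2.840.10008"
DEFAULT_UID_ROOT = "1.2.826.0.1.3680043.10.424"
_UID_RE = re.compile(r"^[0-9]+(\.[0-9]+)+$")

ACTIONS = ("remove", "replace", "redact", "keep")


# ---------------------------------------------------------------------------
# Tag policy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolicyRule:
    tag: int
    action: str
    parameter: str = ""

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValidationError(
                f"unknown policy action {self.action!r}; expected one of {ACTIONS}"
            )


@dataclass
class TagPolicy:
    """Mapping from DICOM attribute tags to de-identification actions."""

    rules: dict[int, PolicyRule] = field(default_factory=dict)
    shift_dates: bool = True

    def removed_tags(self) -> list[int]:
        return [t for t, r in self.rules.items() if r.action == "remove"]

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "TagPolicy":
        rules: dict[int, PolicyRule] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                keyword, action = parts[0].strip(), parts[1].strip().lower()
                parameter = parts[2] if len(parts) > 2 else ""
                tag = _parse_tag(keyword)
                rules[tag] = PolicyRule(tag=tag, action=action, parameter=parameter)
        return cls(rules=rules)

    @classmethod
    def default(cls) -> "TagPolicy":
        ref = importlib.resources.files("rtcurate.data") / "default_deid_policy.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_file(path)


def _parse_tag(keyword: str) -> int:
    """Accept a DICOM keyword or a (gggg,eeee) literal."""
    m = re.match(r"^\(?([0-9a-fA-F]{4}),\s*([0-9a-fA-F]{4})\)?$", keyword)
    if m:
        return (int(m.group(1), 16) << 16) | int(m.group(2), 16)
    tag = tag_for_keyword(keyword)
    if tag is None:
        raise ValidationError(f"unknown DICOM keyword in policy: {keyword!r}")
    return tag


# ---------------------------------------------------------------------------
# Persistent UID / trace store
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceRecord:
    mrn: str
    deid_mrn: str
    timestamp: str


class UIDMapStore:
    """Single-file persistent store of UID and MRN mappings.

    The store is a JSON document on disk; every mutation is written through
    immediately, so two sessions sharing a store file see identical
    mappings — this is what makes the UID transformation reproducible.
    Generated UIDs are random-suffixed under ``uid_root`` (injective by
    construction: collisions are re-drawn against the recorded codomain).
    """

    def __init__(
        self,
        path: str | os.PathLike,
        uid_root: str = DEFAULT_UID_ROOT,
        mrn_prefix: str = "DEID-",
        seed: int | None = None,
    ) -> None:
        self.path = str(path)
        self.mrn_prefix = mrn_prefix
        self._rng = random.Random(seed)
        if os.path.exists(self.path):
            with open(self.path, encoding="utf-8") as fh:
                self._data = json.load(fh)
        else:
            self._data = {
                "uid_root": uid_root,
                "uids": {},
                "patients": {},
                "deid_ids": [],
            }
            self._flush()

    # -- persistence -------------------------------------------------------
    def _flush(self) -> None:
        tmp = self.path + ".tmp"
        with open(tmp, "w", encoding="utf-8") as fh:
            json.dump(self._data, fh, indent=1)
        os.replace(tmp, self.path)

    @property
    def uid_root(self) -> str:
        return self._data["uid_root"]

    # -- UID mapping -------------------------------------------------------
    def map_uid(self, uid: str) -> str:
        """Return the stable de-identified UID for ``uid`` (create if new)."""
        uid = str(uid)
        if not _UID_RE.match(uid) or len(uid) > 64:
            raise ValidationError(f"malformed DICOM UID: {uid!r}")
        existing = self._data["uids"].get(uid)
        if existing is not None:
            return existing
        taken = set(self._data["uids"].values())
        while True:
            # component must not start with 0: draw from [10^13, 10^14)
            candidate = f"{self.uid_root}.{self._rng.randrange(10**13, 10**14)}"
            if candidate not in taken:
                break
        assert len(candidate) <= 64
        self._data["uids"][uid] = candidate
        self._flush()
        return candidate

    def known_uids(self) -> dict[str, str]:
        return dict(self._data["uids"])

    # -- patient trace -----------------------------------------------------
    def register_patient(self, mrn: str) -> TraceRecord:
        """Assign (or recall) the DeID-MRN and date offset for a patient."""
        mrn = str(mrn)
        rec = self._data["patients"].get(mrn)
        if rec is None:
            seq = len(self._data["patients"]) + 1
            rec = {
                "deid_mrn": f"{self.mrn_prefix}{seq:06d}",
                "date_offset_days": self._rng.randint(-364, -7),
                "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
            }
            self._data["patients"][mrn] = rec
            if rec["deid_mrn"] not in self._data["deid_ids"]:
                self._data["deid_ids"].append(rec["deid_mrn"])
            self._flush()
        return TraceRecord(
            mrn=mrn, deid_mrn=rec["deid_mrn"], timestamp=rec["timestamp"]
        )

    def date_offset_days(self, mrn: str) -> int:
        return int(self._data["patients"][str(mrn)]["date_offset_days"])

    def is_deid_id(self, patient_id: str) -> bool:
        return str(patient_id) in self._data["deid_ids"]


def map_uid(uid: str, store: UIDMapStore) -> str:
    """Functional alias for :meth:`UIDMapStore.map_uid`."""
    return store.map_uid(uid)


def lookup(mrn: str | Sequence[str], store: UIDMapStore):
    """DeID-MRN for one MRN, or a list of ``(mrn, deid_mrn)`` for a batch."""
    if isinstance(mrn, (list, tuple)):
        return [(m, lookup(m, store)) for m in mrn]
    rec = store._data["patients"].get(str(mrn))
    if rec is None:
        raise NotFoundError(f"MRN {mrn!r} has not been de-identified")
    return rec["deid_mrn"]


# ---------------------------------------------------------------------------
# Dataset rewriting
# ---------------------------------------------------------------------------

def _shift_date(value: str, offset_days: int) -> str:
    """Shift a DA (YYYYMMDD) or DT (YYYYMMDD...) value by ``offset_days``."""
    if len(value) < 8 or not value[:8].isdigit():
        return value
    try:
        day = _dt.date(int(value[:4]), int(value[4:6]), int(value[6:8]))
    except ValueError:
        return value
    shifted = day + _dt.timedelta(days=offset_days)
    return shifted.strftime("%Y%m%d") + value[8:]


def _remap_uid_value(value, store: UIDMapStore):
    def one(u):
        u = str(u)
        if not u or u.startswith(DICOM_STANDARD_UID_ROOT):
            return u
        return store.map_uid(u)

    if isinstance(value, (list, tuple)) or getattr(value, "__iter__", None) and not isinstance(value, str):
        try:
            return [one(v) for v in value]
        except TypeError:
            return one(value)
    return one(value)


def _apply_to_dataset(
    ds: Dataset,
    policy: TagPolicy,
    store: UIDMapStore,
    deid_mrn: str,
    offset_days: int,
) -> None:
    for tag in [e.tag for e in ds]:
        elem = ds[tag]
        rule = policy.rules.get(int(tag))
        if rule is not None:
            if rule.action == "remove":
                del ds[tag]
                continue
            if rule.action == "replace":
                elem.value = rule.parameter
                continue
            if rule.action == "redact":
                if elem.value is not None and rule.parameter:
                    elem.value = re.sub(rule.parameter, "X", str(elem.value))
                continue
            # keep: fall through untouched (UIDs under keep still remap)
        if elem.VR == "SQ":
            for item in elem.value:
                _apply_to_dataset(item, policy, store, deid_mrn, offset_days)
        elif elem.VR == "UI":
            elem.value = _remap_uid_value(elem.value, store)
        elif policy.shift_dates and elem.VR in ("DA", "DT") and elem.value:
            if isinstance(elem.value, (list, tuple)):
                elem.value = [_shift_date(str(v), offset_days) for v in elem.value]
            else:
                elem.value = _shift_date(str(elem.value), offset_days)

    if "PatientID" in ds:
        ds.PatientID = deid_mrn
    if "PatientName" in ds:
        ds.PatientName = deid_mrn


def deid_dataset(
    ds: CuratedDataset,
    policy: TagPolicy | None = None,
    store: UIDMapStore | None = None,
) -> tuple[CuratedDataset, TraceRecord]:
    """De-identify every DICOM object of a curated case.

    Returns the rewritten dataset (originals untouched) and the trace
    record pairing the native MRN with the generated DeID-MRN.  Running the
    same case twice against the same store yields byte-identical UID
    fields.  Re-running on already de-identified output is refused.
    """
    if policy is None:
        policy = TagPolicy.default()
    if store is None:
        raise ValidationError("deid_dataset requires a persistent UIDMapStore")
    if store.is_deid_id(ds.deid_or_native_id):
        raise ValidationError(
            f"{ds.deid_or_native_id!r} is already de-identified output of "
            "this store; refusing to double-map"
        )
    trace = store.register_patient(ds.deid_or_native_id)
    offset = store.date_offset_days(ds.deid_or_native_id)

    new_objects: dict = {}
    for role, obj in ds.objects.items():
        if isinstance(obj, (list, tuple)):
            new_list = []
            for item in obj:
                item = copy.deepcopy(item)
                _apply_to_dataset(item, policy, store, trace.deid_mrn, offset)
                attach_file_meta(item)
                new_list.append(item)
            new_objects[role] = new_list
        else:
            item = copy.deepcopy(obj)
            _apply_to_dataset(item, policy, store, trace.deid_mrn, offset)
            attach_file_meta(item)
            new_objects[role] = item
    out = CuratedDataset(deid_or_native_id=trace.deid_mrn, objects=new_objects)
    return out, trace


# ---------------------------------------------------------------------------
# Post-hoc verification
# ---------------------------------------------------------------------------

@dataclass
class IntegrityReport:
    violations: list[str] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not self.violations


def _collect_uid_fields(ds: Dataset, keyword: str) -> list[str]:
    found: list[str] = []
    for elem in ds.iterall():
        if elem.keyword == keyword and elem.value:
            value = elem.value
            if isinstance(value, (list, tuple)):
                found.extend(str(v) for v in value)
            else:
                found.append(str(value))
    return found


def verify_integrity(
    ds: CuratedDataset, policy: TagPolicy | None = None
) -> IntegrityReport:
    """Verify a de-identified case: scrubbing, references, coordinate frames.

    Confirms that (a) no attribute the policy removes survives in any
    object, (b) every referenced SOP instance resolves to an object inside
    the dataset, and (c) every referenced Frame-of-Reference belongs to the
    dataset's own Frame-of-Reference set.
    """
    if policy is None:
        policy = TagPolicy.default()
    report = IntegrityReport()

    removed = set(policy.removed_tags())
    present_sops: set[str] = set()
    present_series: set[str] = set()
    present_fors: set[str] = set()
    for obj in ds.iter_datasets():
        present_sops.add(str(obj.SOPInstanceUID))
        if getattr(obj, "SeriesInstanceUID", None):
            present_series.add(str(obj.SeriesInstanceUID))
        for v in _collect_uid_fields(obj, "FrameOfReferenceUID"):
            present_fors.add(v)

    for obj in ds.iter_datasets():
        name = f"{getattr(obj, 'Modality', '?')}/{obj.SOPInstanceUID}"
        for elem in obj.iterall():
            if int(elem.tag) in removed:
                report.violations.append(
                    f"{name}: policy-removed attribute {elem.keyword or elem.tag} "
                    "survives"
                )
        for ref in _collect_uid_fields(obj, "ReferencedSOPInstanceUID"):
            # study-level references (detached study) have no part-10 object
            if ref not in present_sops and ref not in _collect_uid_fields(
                obj, "StudyInstanceUID"
            ):
                report.violations.append(
                    f"{name}: referenced SOP instance {ref} does not resolve "
                    "within the dataset"
                )
        for ref in _collect_uid_fields(obj, "ReferencedFrameOfReferenceUID"):
            if ref not in present_fors:
                report.violations.append(
                    f"{name}: referenced Frame-of-Reference {ref} is not "
                    "present in the dataset"
                )
        for ref in _nested_series_references(obj):
            if ref and ref not in present_series:
                report.violations.append(
                    f"{name}: referenced series {ref} absent from the dataset"
                )
    return report


def _nested_series_references(obj: Dataset) -> list[str]:
    """SeriesInstanceUID values occurring inside sequence items (references)."""
    refs: list[str] = []

    def walk(ds: Dataset, nested: bool) -> None:
        for elem in ds:
            if elem.VR == "SQ":
                for item in elem.value:
                    walk(item, True)
            elif nested and elem.keyword == "SeriesInstanceUID" and elem.value:
                refs.append(str(elem.value))

    walk(obj, False)
    return refs
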