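"""Standardized organ-at-risk nomenclature.

The registry is a small editable table of label *patterns*; a pattern may
carry the bilateral marker ``[l,r]``, which expands to a ``_l`` and a ``_r``
concrete label (e.g. ``parotid_[l,r]`` -> ``parotid_l``, ``parotid_r``).
The default registry ships with the package and covers the head-and-neck
organs-at-risk used by our curation workflow: 28 patterns, 42 concrete
labels.  Institutions deviate from consensus guidelines, so the registry is
a data file, not code.

"Purview" subsets model the fact that different curator groups segment
different organ subsets: a purview is the expanded registry minus the
expansion of an excluded-pattern list.
"""

from __future__ import annotations

import importlib.resources
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ValidationError
from .rtdata_model import StructureSet

BILATERAL_MARKER = "[l,r]"

#: Labels commonly present in clinical structure sets that are not OARs and
#: should not be reported as off-registry (body outline, targets).
DEFAULT_ALLOWED_EXTRAS = frozenset(
    {"body", "external", "gtv", "ctv", "ptv", "skin"}
)


@dataclass(frozen=True)
class RegistryEntry:
    """One registry row: a label pattern and its anatomic designation."""

    pattern: str
    anatomic_name: str = ""

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValidationError("registry pattern must be non-empty")
        if self.pattern.count(BILATERAL_MARKER) > 1:
            raise ValidationError(
                f"pattern {self.pattern!r} repeats the bilateral marker"
            )

    @property
    def is_bilateral(self) -> bool:
        return BILATERAL_MARKER in self.pattern

    def expand(self) -> list[str]:
        if self.is_bilateral:
            return [
                self.pattern.replace(BILATERAL_MARKER, side) for side in ("l", "r")
            ]
        return [self.pattern]


@dataclass
class LabelRegistry:
    """Ordered collection of registry entries."""

    entries: list[RegistryEntry] = field(default_factory=list)

    def patterns(self) -> list[str]:
        return [e.pattern for e in self.entries]

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "LabelRegistry":
        entries = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                pattern = parts[0].strip()
                name = parts[1].strip() if len(parts) > 1 else ""
                entries.append(RegistryEntry(pattern=pattern, anatomic_name=name))
        reg = cls(entries=entries)
        expand(reg)  # validates uniqueness of the expanded label set
        return reg

    @classmethod
    def default(cls) -> "LabelRegistry":
        """The packaged head-and-neck OAR registry (42 concrete labels)."""
        ref = importlib.resources.files("rtcurate.data") / "hn_oar_registry.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_file(path)


def expand(reg: LabelRegistry) -> list[str]:
    """Expand every pattern to concrete labels, preserving registry order."""
    labels: list[str] = []
    for entry in reg.entries:
        labels.extend(entry.expand())
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValidationError(f"registry expansion has duplicate labels: {dupes}")
    return labels


def sidedness_of(label: str) -> str:
    """Laterality encoded in a concrete label: ``left``/``right``/``none``."""
    key = label.strip().lower()
    if key.endswith("_l"):
        return "left"
    if key.endswith("_r"):
        return "right"
    return "none"


def purview(
    reg: LabelRegistry, excluded_anatomy: Iterable[str] = ()
) -> list[str]:
    """Concrete labels within a curator group's segmentation scope.

    ``excluded_anatomy`` lists registry *patterns* whose expansions the
    group does not segment; an unknown pattern is a validation error.
    """
    known = set(reg.patterns())
    excluded = list(excluded_anatomy)
    unknown = [p for p in excluded if p not in known]
    if unknown:
        raise ValidationError(f"excluded patterns not in registry: {unknown}")
    drop: set[str] = set()
    for entry in reg.entries:
        if entry.pattern in excluded:
            drop.update(entry.expand())
    return [l for l in expand(reg) if l not in drop]


def validate_labels(
    ss: StructureSet,
    reg: LabelRegistry,
    allowed_extras: Iterable[str] = DEFAULT_ALLOWED_EXTRAS,
) -> list[str]:
    """Labels in the structure set that are neither registry nor allow-list.

    Matching is case-insensitive after trimming, because inconsistent label
    casing is a common real-world failure mode.
    """
    registry_keys = {l.lower() for l in expand(reg)}
    allowed = {str(a).strip().lower() for a in allowed_extras}
    off = []
    for label in ss.labels():
        key = label.strip().lower()
        if key not in registry_keys and key not in allowed:
            off.append(label)
    return off
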