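"""File formats: centroid tables, Lenke code lists, JSON reports.

Centroid files are comma-separated with a dot decimal and a mandatory
header ``label,kind,x_mm,y_mm,z_mm[,rot_x,rot_y,rot_z]``, rows ordered
caudal (L5) to cranial (C7).  Rotation columns, when present, are stored as
metadata and never used in any computation.

Lenke files are two-column CSV ``patient_id,lenke_code`` where a code is
``<type 1-6><A|B|C><+|-|N>`` (e.g. ``6BN``, ``5B+``) or the literal
``Normal`` / ``Normal spine``.  The minus modifier is accepted both as the
ASCII hyphen and the Unicode minus sign.

Reports are JSON and round-trip losslessly; undefined indices serialise as
explicit ``null``, never 0.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .classify import Classification
from .curve import ApexRecord
from .errors import FormatError, ValidationError
from .indices import IndexSet, StdVector
from .spine import DEFAULT_LT_LABEL, CentroidSequence, LandmarkPoint

__all__ = [
    "LenkeRecord",
    "read_centroids",
    "write_centroids",
    "parse_lenke_code",
    "read_lenke_labels",
    "write_report",
    "read_report",
]

_HEADER = ["label", "kind", "x_mm", "y_mm", "z_mm"]
_ROT_HEADER = _HEADER + ["rot_x", "rot_y", "rot_z"]

# Unicode minus normalised to ASCII before matching.
_LENKE_RE = re.compile(r"^([1-6])([ABC])([+\-N])$")
NORMAL_TYPE = "Normal"


@dataclass(frozen=True)
class LenkeRecord:
    """One patient's Lenke classification.

    ``curve_type`` is ``"1"``..``"6"`` or ``"Normal"``; a Normal record has
    no modifiers, a typed record has both.  The lumbar modifier (A/B/C,
    apical-vertebra position versus the central sacral vertical line) is
    parsed and carried but consumed by no analysis here — the centroid data
    holds no sacral reference.
    """

    patient_id: str
    curve_type: str
    lumbar_modifier: Optional[str] = None
    sagittal_modifier: Optional[str] = None

    def __post_init__(self) -> None:
        if self.curve_type == NORMAL_TYPE:
            if self.lumbar_modifier is not None or self.sagittal_modifier is not None:
                raise ValidationError(
                    f"patient {self.patient_id!r}: a Normal record carries no modifiers"
                )
        elif self.curve_type in {"1", "2", "3", "4", "5", "6"}:
            if self.lumbar_modifier is None or self.sagittal_modifier is None:
                raise ValidationError(
                    f"patient {self.patient_id!r}: typed record needs both modifiers"
                )
        else:
            raise ValidationError(
                f"patient {self.patient_id!r}: unknown curve type {self.curve_type!r}"
            )


def read_centroids(
    path: Union[str, Path],
    lt_label: str = DEFAULT_LT_LABEL,
    patient_id: Optional[str] = None,
) -> CentroidSequence:
    """Read a centroid CSV into a validated :class:`CentroidSequence`.

    ``patient_id`` defaults to the file stem.  The disc named ``lt_label``
    is taken as the lumbar->thoracic transition.

    Raises
    ------
    FormatError
        On a missing/garbled header or a row with the wrong field count or
        an unparsable number.
    ValidationError
        On domain violations (missing L5/C7, duplicate labels, NaN
        coordinates, non-monotone ordering), naming the offending row.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = [c.strip() for c in rows[0]]
    if header == _HEADER:
        has_rot = False
    elif header == _ROT_HEADER:
        has_rot = True
    else:
        raise FormatError(
            f"{path}: bad header {header!r}; expected {','.join(_HEADER)}"
            f" optionally followed by rot_x,rot_y,rot_z"
        )
    points: list[LandmarkPoint] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(header):
            raise FormatError(f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}")
        label = row[0].strip()
        kind = row[1].strip()
        try:
            coords = np.array([float(v) for v in row[2:5]])
            rot = np.array([float(v) for v in row[5:8]]) if has_rot else None
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        if not np.all(np.isfinite(coords)):
            raise ValidationError(f"{path}:{lineno}: non-finite coordinate for {label!r}")
        try:
            points.append(LandmarkPoint(label=label, kind=kind, position=coords, rotation=rot))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from None
    labels = {p.label for p in points}
    if "L5" not in labels or "C7" not in labels:
        missing = sorted({"L5", "C7"} - labels)
        raise FormatError(f"{path}: missing required vertebra row(s): {', '.join(missing)}")
    return CentroidSequence(
        patient_id=patient_id if patient_id is not None else path.stem,
        points=tuple(points),
        lt_label=lt_label,
    )


def write_centroids(seq: CentroidSequence, path: Union[str, Path]) -> None:
    """Write a centroid sequence in the dialect :func:`read_centroids` reads."""
    has_rot = any(p.rotation is not None for p in seq.points)
    header = _ROT_HEADER if has_rot else _HEADER
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for p in seq.points:
            row = [p.label, p.kind] + [repr(float(v)) for v in p.position]
            if has_rot:
                rot = p.rotation if p.rotation is not None else np.zeros(3)
                row += [repr(float(v)) for v in rot]
            w.writerow(row)


def parse_lenke_code(code: str, patient_id: str = "") -> LenkeRecord:
    """Decompose a Lenke code string into type and modifiers.

    Accepts ``<1-6><A|B|C><+|-|N>`` (Unicode minus tolerated) and the
    literals ``Normal spine`` / ``Normal``.
    """
    raw = code.strip()
    if raw in ("Normal", "Normal spine"):
        return LenkeRecord(patient_id=patient_id, curve_type=NORMAL_TYPE)
    m = _LENKE_RE.match(raw.replace("−", "-"))
    if not m:
        raise FormatError(f"unrecognised Lenke code {code!r}")
    return LenkeRecord(
        patient_id=patient_id,
        curve_type=m.group(1),
        lumbar_modifier=m.group(2),
        sagittal_modifier=m.group(3),
    )


def read_lenke_labels(path: Union[str, Path]) -> list[LenkeRecord]:
    """Read a ``patient_id,lenke_code`` CSV (header optional) into records."""
    path = Path(path)
    records: list[LenkeRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if lineno == 1 and [c.strip().lower() for c in row[:2]] == ["patient_id", "lenke_code"]:
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: expected patient_id,lenke_code")
            pid = row[0].strip()
            if pid in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate patient_id {pid!r}")
            seen.add(pid)
            try:
                records.append(parse_lenke_code(row[1], patient_id=pid))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return records


def write_report(cls: Classification, path: Union[str, Path]) -> None:
    """Serialise a classification as JSON (undefined indices as ``null``)."""
    doc = {
        "patient_id": cls.patient_id,
        "std": cls.std.to_dict(),
        "s": cls.indices.s,
        "v": cls.indices.v,
        "kl": cls.indices.kl,
        "m_t": cls.indices.m_t,
        "m_l": cls.indices.m_l,
        "severity": cls.severity,
        "side": cls.side,
        "vertical": cls.vertical,
        "sagittal": cls.sagittal,
        "description": cls.description,
        "apexes": [a.to_dict() for a in cls.apexes],
        "config_digest": cls.config_digest,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_report(path: Union[str, Path]) -> Classification:
    """Read a report written by :func:`write_report` back into a
    :class:`Classification` (lossless for every serialised field)."""
    doc = json.loads(Path(path).read_text())
    try:
        return Classification(
            patient_id=doc["patient_id"],
            std=StdVector(**doc["std"]),
            indices=IndexSet(
                s=doc["s"], v=doc["v"], kl=doc["kl"], m_t=doc["m_t"], m_l=doc["m_l"]
            ),
            severity=doc["severity"],
            side=doc["side"],
            vertical=doc["vertical"],
            sagittal=doc["sagittal"],
            description=doc["description"],
            apexes=tuple(
                ApexRecord(a["name"], a["label"], a["displacement"]) for a in doc["apexes"]
            ),
            config_digest=doc.get("config_digest", ""),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: report missing key {exc}") from None
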