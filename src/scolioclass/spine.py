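"""Centroid-sequence domain model.

The internal spinal alignment (ISA) is the 3D curve through the centroids of
the vertebral bodies and intervertebral discs from L5 (or L5/S1) up to C7.
A :class:`CentroidSequence` holds those labelled points, ordered caudal to
cranial, in millimetres, in a right-handed patient-anatomical frame:

* +x — patient's right (lateral),
* +y — cranial (up),
* +z — posterior (towards the back surface).

Under this convention a right-convex scoliotic curve has positive lateral
displacement, thoracic kyphosis has a positive sagittal mean and lumbar
lordosis a negative one.

Per-centroid rotation angles, when present in the input, are carried as
metadata only; no computation consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "VERTEBRA_LABELS",
    "DISC_LABELS",
    "CANONICAL_LABELS",
    "DEFAULT_LT_LABEL",
    "disc_label",
    "LandmarkPoint",
    "CentroidSequence",
]

#: Vertebral bodies caudal -> cranial. L5..L1, T12..T1, C7: the span covered
#: by the ISA curve.
VERTEBRA_LABELS: tuple[str, ...] = (
    "L5", "L4", "L3", "L2", "L1",
    "T12", "T11", "T10", "T9", "T8", "T7", "T6", "T5", "T4", "T3", "T2", "T1",
    "C7",
)


def disc_label(lower: str, upper: str) -> str:
    """Label of the disc between two adjacent vertebrae, written cranial/caudal
    (the disc between L1 and T12 is ``"T12/L1"``)."""
    return f"{upper}/{lower}"


#: Discs between consecutive vertebrae, caudal -> cranial.
DISC_LABELS: tuple[str, ...] = tuple(
    disc_label(VERTEBRA_LABELS[i], VERTEBRA_LABELS[i + 1])
    for i in range(len(VERTEBRA_LABELS) - 1)
)

#: Full alternating vertebra/disc label sequence, caudal -> cranial.
CANONICAL_LABELS: tuple[str, ...] = tuple(
    lab
    for pair in zip(VERTEBRA_LABELS, DISC_LABELS + ("",))
    for lab in pair
    if lab
)

#: Disc at the lumbar->thoracic transition (LT disc) by default.
DEFAULT_LT_LABEL = "T12/L1"

# Anatomical rank of every canonical label (vertebrae at integer ranks, the
# disc between two vertebrae halfway between them); used to check ordering.
_RANK: dict[str, float] = {}
for _i, _v in enumerate(VERTEBRA_LABELS):
    _RANK[_v] = float(_i)
for _i, _d in enumerate(DISC_LABELS):
    _RANK[_d] = _i + 0.5


@dataclass(frozen=True)
class LandmarkPoint:
    """One labelled centroid: a vertebral body or an intervertebral disc."""

    label: str
    kind: str  # "vertebra" | "disc"
    position: np.ndarray  # shape (3,), mm
    rotation: Optional[np.ndarray] = None  # shape (3,), degrees; metadata only

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.rotation is not None:
            object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        if self.kind not in ("vertebra", "disc"):
            raise ValidationError(
                f"landmark {self.label!r}: kind must be 'vertebra' or 'disc', got {self.kind!r}"
            )
        if self.position.shape != (3,):
            raise ValidationError(f"landmark {self.label!r}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValidationError(f"landmark {self.label!r}: non-finite coordinate")


@dataclass(frozen=True)
class CentroidSequence:
    """Ordered, labelled 3D centroids of one spine, caudal (L5) to cranial (C7)."""

    patient_id: str
    points: tuple[LandmarkPoint, ...]
    lt_label: str = DEFAULT_LT_LABEL

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        self._validate()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        pts = self.points
        if len(pts) < 4:
            raise ValidationError(
                f"patient {self.patient_id!r}: need at least 4 centroids, got {len(pts)}"
            )
        labels = [p.label for p in pts]
        seen: set[str] = set()
        for i, lab in enumerate(labels):
            if lab in seen:
                raise ValidationError(
                    f"patient {self.patient_id!r}: duplicate label {lab!r} at row {i}"
                )
            seen.add(lab)
        if "L5" not in seen:
            raise ValidationError(f"patient {self.patient_id!r}: missing vertebra 'L5'")
        if "C7" not in seen:
            raise ValidationError(f"patient {self.patient_id!r}: missing vertebra 'C7'")
        if self.lt_label not in seen:
            raise ValidationError(
                f"patient {self.patient_id!r}: LT disc {self.lt_label!r} not present"
            )
        if pts[self.index_of(self.lt_label)].kind != "disc":
            raise ValidationError(
                f"patient {self.patient_id!r}: LT landmark {self.lt_label!r} is not a disc"
            )
        for i in range(1, len(pts)):
            if pts[i].kind == pts[i - 1].kind:
                raise ValidationError(
                    f"patient {self.patient_id!r}: kinds must alternate "
                    f"vertebra/disc; rows {i - 1} ({pts[i - 1].label!r}) and "
                    f"{i} ({pts[i].label!r}) are both {pts[i].kind!r}"
                )
        # Caudal -> cranial order for labels from the canonical vocabulary.
        ranks = [(_RANK[lab], i) for i, lab in enumerate(labels) if lab in _RANK]
        for (r0, i0), (r1, i1) in zip(ranks, ranks[1:]):
            if r1 <= r0:
                raise ValidationError(
                    f"patient {self.patient_id!r}: rows not ordered caudal->cranial "
                    f"(row {i1} {labels[i1]!r} after row {i0} {labels[i0]!r})"
                )

    # -- accessors --------------------------------------------------------

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.points]

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) array of positions in mm, caudal -> cranial."""
        return np.array([p.position for p in self.points], dtype=float)

    def index_of(self, label: str) -> int:
        for i, p in enumerate(self.points):
            if p.label == label:
                return i
        raise KeyError(label)

    @property
    def lt_index(self) -> int:
        return self.index_of(self.lt_label)

    def region_of(self, index: int) -> str:
        """'lumbar' for centroids at or caudal to the LT disc, else 'thoracic'."""
        return "lumbar" if index <= self.lt_index else "thoracic"

    def with_positions(self, positions: np.ndarray) -> "CentroidSequence":
        """Copy of this sequence with positions replaced (labels/kinds kept)."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.points), 3):
            raise ValidationError("positions array shape does not match point count")
        new_pts = tuple(
            replace(p, position=positions[i]) for i, p in enumerate(self.points)
        )
        return replace(self, points=new_pts)
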