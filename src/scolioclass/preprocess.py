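"""Normalisation of a centroid sequence into the canonical analysis frame.

Every spine is expressed in the same frame before any index is computed:
L5 sits at the origin, the straight L5->C7 chord lies on +y, and the chord
length is scaled to 500 mm.  The transform is rigid plus uniform scaling —
translate L5 to the origin, rotate the chord onto +y by the minimal rotation
(axis = chord x y-hat), then scale by 500/|C7 - L5| — so the shape of the
deformity is untouched.  The minimal rotation leaves no residual axial
freedom except when the chord is already vertical, in which case the
identity is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError
from .spine import CentroidSequence

__all__ = ["NormalizedSpine", "normalize", "CHORD_HEIGHT_MM"]

#: Canonical L5->C7 chord height after scaling, mm.
CHORD_HEIGHT_MM = 500.0

_Y = np.array([0.0, 1.0, 0.0])


@dataclass(frozen=True)
class NormalizedSpine:
    """A centroid sequence in the canonical frame plus the applied transform."""

    sequence: CentroidSequence
    scale_factor: float
    applied_rotation: np.ndarray  # 3x3 orthonormal

    # Delegate the accessors downstream stages need.
    @property
    def patient_id(self) -> str:
        return self.sequence.patient_id

    @property
    def positions(self) -> np.ndarray:
        return self.sequence.positions

    @property
    def labels(self) -> list[str]:
        return self.sequence.labels

    @property
    def lt_index(self) -> int:
        return self.sequence.lt_index

    @property
    def points(self):
        return self.sequence.points

    def region_of(self, index: int) -> str:
        return self.sequence.region_of(index)


def _minimal_rotation_to_y(u: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Rotation matrix mapping unit vector ``u`` onto +y about axis u x y-hat.

    Identity when ``u`` is already within ``tol`` of +y; for the antipodal
    case (chord pointing caudally) a half-turn about +x is used.
    """
    c = float(np.dot(u, _Y))
    axis = np.cross(u, _Y)
    s = float(np.linalg.norm(axis))
    if s < tol:
        if c > 0:
            return np.eye(3)
        # u ~ -y: any axis in the xz-plane works; pick +x.
        return np.diag([1.0, -1.0, -1.0])
    axis = axis / s
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    # Rodrigues with sin = s, cos = c.
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def normalize(spine: CentroidSequence) -> NormalizedSpine:
    """Map a centroid sequence into the canonical frame.

    Raises
    ------
    DegenerateGeometryError
        If L5 and C7 coincide (zero chord).
    """
    pos = spine.positions
    p_l5 = pos[spine.index_of("L5")]
    p_c7 = pos[spine.index_of("C7")]
    chord = p_c7 - p_l5
    length = float(np.linalg.norm(chord))
    if length <= 0.0:
        raise DegenerateGeometryError(
            f"patient {spine.patient_id!r}: L5 and C7 coincide; cannot normalise"
        )
    R = _minimal_rotation_to_y(chord / length)
    scale = CHORD_HEIGHT_MM / length
    new_pos = scale * (pos - p_l5) @ R.T
    # Pin the invariants exactly: rounding in the rotation leaves ~1e-13 dust.
    new_pos[spine.index_of("L5")] = 0.0
    return NormalizedSpine(
        sequence=spine.with_positions(new_pos),
        scale_factor=scale,
        applied_rotation=R,
    )
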