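import numpy as np
import pytest

from scolioclass.spine import CANONICAL_LABELS, CentroidSequence, LandmarkPoint
from scolioclass.synthetic import _HEIGHTS


def analytic_sequence(fx=None, fz=None, patient_id="analytic"):
    """Centroid sequence on the 500 mm template with analytic lateral (x)
    and sagittal (z) displacement profiles of height y."""
    fx = fx or (lambda y: 0.0)
    fz = fz or (lambda y: 0.0)
    pts = tuple(
        LandmarkPoint(
            label=lab,
            kind="disc" if "/" in lab else "vertebra",
            position=[float(fx(_HEIGHTS[lab])), _HEIGHTS[lab], float(fz(_HEIGHTS[lab]))],
        )
        for lab in CANONICAL_LABELS
    )
    return CentroidSequence(patient_id=patient_id, points=pts)


@pytest.fixture
def straight_sequence():
    return analytic_sequence(patient_id="straight")


@pytest.fixture
def balanced_sagittal_sequence():
    """No lateral curve; kyphotic thoracic and lordotic lumbar arcs of equal
    depth: the neutral, 'normal spine' geometry."""
    lt = _HEIGHTS["T12/L1"]

    def fz(y):
        if y <= lt:
            return -25.0 * np.sin(np.pi * y / lt)
        return 25.0 * np.sin(np.pi * (y - lt) / (500.0 - lt))

    return analytic_sequence(fz=fz, patient_id="balanced")


def mirror_laterally(seq: CentroidSequence) -> CentroidSequence:
    pos = seq.positions.copy()
    pos[:, 0] *= -1.0
    return seq.with_positions(pos)
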