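"""The four continuous deformity measures.

From the frontal projection, the quadrant dispersion vector
``STD = [std_TL, std_TR, std_LL, std_LR]`` — for each (region, side)
quadrant the RMS lateral displacement of the curve samples about the
vertical reference line, in mm.  A healthy spine projects onto that line,
so dispersion is measured about zero, not about the quadrant mean (a
uniformly offset curve would otherwise score as no deformity); the
conventional mean-centred reading remains available via
``ThresholdConfig.std_about_mean``.  Samples exactly on the line belong to
neither side, and an empty quadrant scores 0.

From the dispersions:

* sidedness  ``s  = ((std_TR + std_LR) - (std_TL + std_LL)) / sum``
* verticality ``v = ((std_TR + std_TL) - (std_LR + std_LL)) / sum``

both in [-1, 1], undefined when every dispersion is zero.

From the sagittal projection, with ``m_T``/``m_L`` the mean posterior
displacement of the thoracic/lumbar samples, the kyphosis-lordosis balance
``kl = (m_T + m_L) / (m_T - m_L)``: 0 for a perfectly balanced sagittal
profile, positive when kyphosis dominates, negative when lordosis does,
undefined when ``m_T = m_L``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .curve import PlanarCurve
from .errors import ContractError

__all__ = [
    "StdVector",
    "IndexSet",
    "std_vector",
    "sidedness_index",
    "vertical_index",
    "kl_index",
    "compute_indices",
]


@dataclass(frozen=True)
class StdVector:
    """Quadrant dispersion of frontal displacements, mm (all >= 0)."""

    tl: float
    tr: float
    ll: float
    lr: float

    @property
    def total(self) -> float:
        return self.tl + self.tr + self.ll + self.lr

    @property
    def max(self) -> float:
        return max(self.tl, self.tr, self.ll, self.lr)

    def as_array(self) -> np.ndarray:
        return np.array([self.tl, self.tr, self.ll, self.lr])

    def to_dict(self) -> dict:
        return {"tl": self.tl, "tr": self.tr, "ll": self.ll, "lr": self.lr}


@dataclass(frozen=True)
class IndexSet:
    """The continuous indices; ``None`` marks an undefined value."""

    s: Optional[float]
    v: Optional[float]
    kl: Optional[float]
    m_t: float  # mean thoracic sagittal displacement, mm (audit)
    m_l: float  # mean lumbar sagittal displacement, mm (audit)


def _dispersion(values: np.ndarray, about_mean: bool) -> float:
    """RMS about zero (default) or population std about the mean; 0 if empty."""
    if values.size == 0:
        return 0.0
    if about_mean:
        return float(np.std(values))
    return float(np.sqrt(np.mean(values * values)))


def std_vector(frontal: PlanarCurve, about_mean: bool = False) -> StdVector:
    """Quadrant dispersions of the frontal projection.

    Sides by the sign of the lateral displacement (x < 0 left, x > 0 right;
    x = 0 samples counted on neither side); regions by the LT-disc split
    carried on the curve.  An empty quadrant scores 0.
    """
    if frontal.plane != "frontal":
        raise ContractError(f"std_vector needs the frontal projection, got {frontal.plane!r}")
    d = frontal.displacement
    lum = frontal.lumbar_mask
    left, right = d < 0, d > 0
    return StdVector(
        tl=_dispersion(d[~lum & left], about_mean),
        tr=_dispersion(d[~lum & right], about_mean),
        ll=_dispersion(d[lum & left], about_mean),
        lr=_dispersion(d[lum & right], about_mean),
    )


def sidedness_index(std: StdVector) -> Optional[float]:
    """Right-vs-left balance of the dispersions; ``None`` when all are zero."""
    denom = std.total
    if denom == 0.0:
        return None
    return ((std.tr + std.lr) - (std.tl + std.ll)) / denom


def vertical_index(std: StdVector) -> Optional[float]:
    """Thoracic-vs-lumbar balance of the dispersions; ``None`` when all are zero."""
    denom = std.total
    if denom == 0.0:
        return None
    return ((std.tr + std.tl) - (std.lr + std.ll)) / denom


def kl_index(sagittal: PlanarCurve) -> tuple[Optional[float], float, float]:
    """Kyphosis-lordosis balance from the sagittal projection.

    Returns ``(kl, m_t, m_l)`` with ``kl = (m_t + m_l) / (m_t - m_l)``;
    ``kl`` is ``None`` when the means coincide.

    Raises
    ------
    ContractError
        If either region has no samples (no mean can be formed).
    """
    if sagittal.plane != "sagittal":
        raise ContractError(f"kl_index needs the sagittal projection, got {sagittal.plane!r}")
    lum = sagittal.lumbar_mask
    if not lum.any() or lum.all():
        raise ContractError("kl_index needs samples in both the lumbar and thoracic regions")
    m_t = float(np.mean(sagittal.displacement[~lum]))
    m_l = float(np.mean(sagittal.displacement[lum]))
    if m_t == m_l:
        return None, m_t, m_l
    return (m_t + m_l) / (m_t - m_l), m_t, m_l


def compute_indices(
    frontal: PlanarCurve, sagittal: PlanarCurve, about_mean: bool = False
) -> tuple[StdVector, IndexSet]:
    """Convenience wrapper: dispersions plus all three indices."""
    std = std_vector(frontal, about_mean=about_mean)
    kl, m_t, m_l = kl_index(sagittal)
    return std, IndexSet(
        s=sidedness_index(std), v=vertical_index(std), kl=kl, m_t=m_t, m_l=m_l
    )
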