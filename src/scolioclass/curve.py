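"""Fine spline interpolation of the spinal curve, projections, curvature, apexes.

The normalised centroid polyline is interpolated with a cubic spline (natural
end conditions) parameterised by cumulative chord length, then resampled at
~1 mm arc-length steps.  Resampling is approximate: the spline is evaluated
on a dense 0.1 mm parameter grid and samples are picked at cumulative 1 mm
arc positions by linear interpolation, which keeps the spacing error well
under 1% without root solving.

Samples are split into lumbar and thoracic regions at the arc position of
the LT disc node (samples at or below it are lumbar), a curve-based rule
that stays robust for decompensated spines that fold back in height.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ContractError, DegenerateGeometryError
from .preprocess import NormalizedSpine

__all__ = [
    "InterpolatedCurve",
    "PlanarCurve",
    "ApexRecord",
    "CurvatureProfile",
    "interpolate",
    "project",
    "curvature_profile",
    "find_apexes",
]

#: Dense parameter step (mm) used before arc-length resampling.
_FINE_STEP_MM = 0.1


@dataclass(frozen=True)
class InterpolatedCurve:
    """Densely sampled 3D spinal curve with region tags.

    ``positions[i]`` is the 3D point at arc length ``arc_s[i]``; ``region[i]``
    is ``"lumbar"`` iff ``arc_s[i] <= lt_arc_s``.
    """

    positions: np.ndarray  # (m, 3) mm
    arc_s: np.ndarray  # (m,) mm, ascending from 0
    lt_arc_s: float  # arc position of the LT disc node
    spacing_mm: float
    node_labels: tuple[str, ...]  # centroid labels, caudal -> cranial
    node_arc_s: np.ndarray  # (n,) arc position of each centroid

    @property
    def region(self) -> np.ndarray:
        """Per-sample region tag, ``"lumbar"`` or ``"thoracic"``."""
        return np.where(self.arc_s <= self.lt_arc_s, "lumbar", "thoracic")

    @property
    def lumbar_mask(self) -> np.ndarray:
        return self.arc_s <= self.lt_arc_s

    def to_csv(self, path: Union[str, Path]) -> None:
        """Debug export: ``arc_s,x,y,z,region`` rows."""
        region = self.region
        with open(path, "w") as fh:
            fh.write("arc_s,x,y,z,region\n")
            for s, (x, y, z), r in zip(self.arc_s, self.positions, region):
                fh.write(f"{s:.6f},{x:.6f},{y:.6f},{z:.6f},{r}\n")


@dataclass(frozen=True)
class PlanarCurve:
    """A projection of the interpolated curve onto one anatomical plane.

    ``displacement`` is the signed offset from the vertical reference line
    (frontal: x, + = patient's right; sagittal: z, + = posterior); for the
    axial plane ``displacement``/``height_or_axis`` hold the (x, z) pairs.
    """

    plane: str  # "frontal" | "sagittal" | "axial"
    displacement: np.ndarray  # (m,) mm
    height_or_axis: np.ndarray  # (m,) mm
    arc_s: np.ndarray  # (m,) mm
    lumbar_mask: np.ndarray  # (m,) bool

    @property
    def region(self) -> np.ndarray:
        return np.where(self.lumbar_mask, "lumbar", "thoracic")


@dataclass(frozen=True)
class ApexRecord:
    """An extreme-displacement centroid: lateral (ApexS) or sagittal (ApexT/L)."""

    name: str  # ApexS_left | ApexS_right | ApexT | ApexL
    label: str  # anatomical label of the extreme centroid
    displacement: float  # signed mm

    def to_dict(self) -> dict:
        return {"name": self.name, "label": self.label, "displacement": self.displacement}


@dataclass(frozen=True)
class CurvatureProfile:
    """Unsigned planar curvature per curve sample, 1/mm."""

    plane: str
    kappa: np.ndarray  # (m,) >= 0
    arc_s: np.ndarray


def interpolate(spine: NormalizedSpine, spacing_mm: float = 1.0) -> InterpolatedCurve:
    """Cubic-spline interpolation of the centroid polyline at ~``spacing_mm`` steps.

    The spline passes through every centroid (interpolating, not smoothing)
    and is parameterised by cumulative chord length through all nodes.

    Raises
    ------
    DegenerateGeometryError
        If two consecutive centroids coincide (zero chord step).
    """
    if spacing_mm <= 0:
        raise ContractError("spacing_mm must be positive")
    pos = spine.positions
    if len(pos) < 4:
        raise ContractError("need at least 4 centroids for cubic interpolation")
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    if np.any(steps <= 0):
        i = int(np.argmin(steps))
        raise DegenerateGeometryError(
            f"coincident consecutive centroids at rows {i} and {i + 1}"
        )
    t = np.concatenate([[0.0], np.cumsum(steps)])
    spl = CubicSpline(t, pos, axis=0, bc_type="natural")

    # Dense evaluation, then cumulative arc length of the fine polyline.
    n_fine = max(int(np.ceil(t[-1] / _FINE_STEP_MM)) + 1, 2)
    t_fine = np.linspace(0.0, t[-1], n_fine)
    p_fine = spl(t_fine)
    seg = np.linalg.norm(np.diff(p_fine, axis=0), axis=1)
    arc_fine = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc_fine[-1]

    targets = np.arange(0.0, total, spacing_mm)
    if total - targets[-1] > 1e-9:  # keep the cranial endpoint
        targets = np.concatenate([targets, [total]])
    t_at = np.interp(targets, arc_fine, t_fine)
    samples = spl(t_at)

    node_arc = np.interp(t, t_fine, arc_fine)
    lt_arc = float(node_arc[spine.lt_index])
    return InterpolatedCurve(
        positions=samples,
        arc_s=targets,
        lt_arc_s=lt_arc,
        spacing_mm=spacing_mm,
        node_labels=tuple(spine.labels),
        node_arc_s=node_arc,
    )


def project(curve: InterpolatedCurve, plane: str) -> PlanarCurve:
    """Project the curve onto the frontal, sagittal, or axial plane.

    Frontal: lateral displacement x against height y.  Sagittal: posterior
    displacement z against height y (the view from the patient's left).
    Axial: the (x, z) footprint viewed along the vertical axis.
    """
    x, y, z = curve.positions.T
    if plane == "frontal":
        disp, axis = x, y
    elif plane == "sagittal":
        disp, axis = z, y
    elif plane == "axial":
        disp, axis = x, z
    else:
        raise ContractError(f"unknown plane {plane!r}")
    return PlanarCurve(
        plane=plane,
        displacement=disp.copy(),
        height_or_axis=axis.copy(),
        arc_s=curve.arc_s.copy(),
        lumbar_mask=curve.lumbar_mask,
    )


def curvature_profile(
    curve: PlanarCurve, smooth_window: Optional[int] = None
) -> CurvatureProfile:
    """Unsigned curvature kappa = |d'h'' - h'd''| / (d'^2 + h'^2)^(3/2).

    Derivatives are taken with respect to arc length by central finite
    differences on the ~1 mm sampling (one-sided at the endpoints).  An
    optional odd-length moving-average window smooths the profile; off by
    default.
    """
    if len(curve.arc_s) < 5:
        raise ContractError("curvature needs at least 5 samples")
    s = curve.arc_s
    d = curve.displacement
    h = curve.height_or_axis
    d1 = np.gradient(d, s)
    h1 = np.gradient(h, s)
    d2 = np.gradient(d1, s)
    h2 = np.gradient(h1, s)
    denom = (d1 * d1 + h1 * h1) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, np.abs(d1 * h2 - h1 * d2) / denom, 0.0)
    if smooth_window:
        if smooth_window % 2 == 0 or smooth_window < 1:
            raise ContractError("smooth_window must be a positive odd integer")
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        kappa = np.convolve(np.pad(kappa, pad, mode="edge"), kernel, mode="valid")
    return CurvatureProfile(plane=curve.plane, kappa=kappa, arc_s=s.copy())


def _extreme_index(values: np.ndarray, indices: np.ndarray) -> int:
    """Index (into the full centroid list) of the max of ``values``; ties go
    to the more caudal centroid (lowest index, i.e. first occurrence)."""
    k = int(np.argmax(values))
    return int(indices[k])


def find_apexes(spine: NormalizedSpine) -> list[ApexRecord]:
    """Extreme-displacement centroids of a normalised spine.

    Lateral apexes (``ApexS_right``/``ApexS_left``) are the centroids of
    maximal positive / minimal negative x and exist only when some centroid
    lies strictly on that side — a spine with no frontal displacement has no
    side apex.  Sagittal apexes ``ApexT`` (thoracic) and ``ApexL`` (lumbar)
    are the centroids of maximal |z| within their region and always exist.
    Ties break to the more caudal centroid.
    """
    pos = spine.positions
    labels = spine.labels
    x, z = pos[:, 0], pos[:, 2]
    records: list[ApexRecord] = []

    if np.any(x > 0):
        i = int(np.argmax(x))
        records.append(ApexRecord("ApexS_right", labels[i], float(x[i])))
    if np.any(x < 0):
        i = int(np.argmin(x))
        records.append(ApexRecord("ApexS_left", labels[i], float(x[i])))

    lt = spine.lt_index
    idx = np.arange(len(labels))
    thoracic = idx[idx > lt]
    lumbar = idx[idx <= lt]
    it = _extreme_index(np.abs(z[thoracic]), thoracic)
    records.append(ApexRecord("ApexT", labels[it], float(z[it])))
    il = _extreme_index(np.abs(z[lumbar]), lumbar)
    records.append(ApexRecord("ApexL", labels[il], float(z[il])))
    return records
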