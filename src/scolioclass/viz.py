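"""Per-patient graphical report.

One composite figure with the three projections of the interpolated curve
(frontal, sagittal, axial), vertebral centroids as large markers and disc
centroids as small ones, the LT disc and the apexes annotated, the curve
coloured and thickened by normalised planar curvature (the "curvature
strain"), an index box with the four quadrant dispersions (thoracic row
above lumbar) and the kl value, and the class-estimation text on a
background shaded by the combined strain.

Colour anchors: frontal green -> yellow (extreme lateral strain), sagittal
green -> magenta (extreme front-back strain); the combined shading blends
both additively, so spines extreme in both planes trend red.  Full
saturation is reached at ``kappa_max`` (default 0.02/mm, a 50 mm osculating
radius); the mapping is monotone in curvature.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .classify import Classification
from .curve import CurvatureProfile, InterpolatedCurve, curvature_profile, project

__all__ = ["StrainColorMap", "render_report"]

_ANCHORS = {
    "frontal": ((0.0, 0.6, 0.0), (1.0, 1.0, 0.0)),  # green -> yellow
    "sagittal": ((0.0, 0.6, 0.0), (1.0, 0.0, 1.0)),  # green -> magenta
}


@dataclass(frozen=True)
class StrainColorMap:
    """Monotone curvature -> colour (and thickness) mapping for one plane."""

    plane: str  # "frontal" | "sagittal"
    kappa_max: float = 0.02  # 1/mm at full saturation
    thickness_scale: float = 4.0  # extra linewidth at full saturation
    base_width: float = 1.2

    def normalized(self, kappa: np.ndarray) -> np.ndarray:
        """Curvature clipped and scaled to [0, 1]."""
        return np.clip(np.asarray(kappa, dtype=float) / self.kappa_max, 0.0, 1.0)

    def colors(self, kappa: np.ndarray) -> np.ndarray:
        """(m, 4) RGBA, linear between the green and the extreme anchor."""
        t = self.normalized(kappa)[:, None]
        lo, hi = (np.array(a) for a in _ANCHORS[self.plane])
        rgb = (1.0 - t) * lo + t * hi
        return np.column_stack([rgb, np.ones(len(rgb))])

    def widths(self, kappa: np.ndarray) -> np.ndarray:
        return self.base_width + self.thickness_scale * self.normalized(kappa)


def _colored_curve(ax, xs, ys, cmap: StrainColorMap, kappa: np.ndarray) -> None:
    from matplotlib.collections import LineCollection

    pts = np.column_stack([xs, ys]).reshape(-1, 1, 2)
    segs = np.concatenate([pts[:-1], pts[1:]], axis=1)
    mid = 0.5 * (kappa[:-1] + kappa[1:])
    lc = LineCollection(segs, colors=cmap.colors(mid), linewidths=cmap.widths(mid))
    ax.add_collection(lc)
    ax.autoscale_view()


def _panel(ax, curve: InterpolatedCurve, cls: Classification, plane: str,
           cmap: StrainColorMap, node_positions: np.ndarray, lt_index: int) -> None:
    planar = project(curve, plane)
    prof = curvature_profile(planar)
    _colored_curve(ax, planar.displacement, planar.height_or_axis, cmap, prof.kappa)

    axes_map = {"frontal": (0, 1), "sagittal": (2, 1), "axial": (0, 2)}
    ix, iy = axes_map[plane]
    is_disc = np.array(["/" in lab for lab in curve.node_labels])
    ax.scatter(node_positions[~is_disc, ix], node_positions[~is_disc, iy],
               s=28, color="tab:blue", zorder=3, label="vertebra")
    ax.scatter(node_positions[is_disc, ix], node_positions[is_disc, iy],
               s=8, color="tab:blue", zorder=3, label="disc")
    ax.scatter([node_positions[lt_index, ix]], [node_positions[lt_index, iy]],
               s=70, facecolors="none", edgecolors="red", zorder=4, label="LT disc")

    label_xy = {lab: (node_positions[i, ix], node_positions[i, iy])
                for i, lab in enumerate(curve.node_labels)}
    wanted = {"frontal": ("ApexS_left", "ApexS_right"), "sagittal": ("ApexT", "ApexL")}
    for apex in cls.apexes:
        if apex.name in wanted.get(plane, ()) and apex.label in label_xy:
            px, py = label_xy[apex.label]
            ax.annotate(f"{apex.name.replace('_', ' ')}\n{apex.label}", (px, py),
                        textcoords="offset points", xytext=(8, 0), fontsize=7,
                        color="darkred")
    ax.set_title(plane)
    ax.set_aspect("equal", adjustable="datalim")
    ax.grid(True, alpha=0.25)


def _blend_background(frontal_norm: float, sagittal_norm: float) -> tuple:
    """Additive blend of the two strain maps; extreme in both planes -> red."""
    lo_f, hi_f = (np.array(a) for a in _ANCHORS["frontal"])
    lo_s, hi_s = (np.array(a) for a in _ANCHORS["sagittal"])
    cf = (1 - frontal_norm) * lo_f + frontal_norm * hi_f
    cs = (1 - sagittal_norm) * lo_s + sagittal_norm * hi_s
    rgb = np.clip(0.5 * (cf + cs) + 0.35, 0.0, 1.0)  # lifted for readable text
    return tuple(rgb)


def render_report(
    cls: Classification,
    curve: InterpolatedCurve,
    path: Union[str, Path],
    kappa_max: float = 0.02,
) -> Path:
    """Render the composite report figure to ``path`` (PNG/SVG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    node_pos = np.array([curve.positions[np.argmin(np.abs(curve.arc_s - s))]
                         for s in curve.node_arc_s])
    lt_index = int(np.argmin(np.abs(curve.node_arc_s - curve.lt_arc_s)))

    fig = plt.figure(figsize=(12, 7))
    gs = fig.add_gridspec(2, 3, height_ratios=[4, 1])
    cmaps = {
        "frontal": StrainColorMap("frontal", kappa_max=kappa_max),
        "sagittal": StrainColorMap("sagittal", kappa_max=kappa_max),
        "axial": StrainColorMap("frontal", kappa_max=kappa_max),
    }
    for i, plane in enumerate(("frontal", "sagittal", "axial")):
        ax = fig.add_subplot(gs[0, i])
        _panel(ax, curve, cls, plane, cmaps[plane], node_pos, lt_index)
        if i == 0:
            ax.legend(loc="upper left", fontsize=7)

    # Index box: thoracic dispersions above lumbar, kl underneath.
    ax_idx = fig.add_subplot(gs[1, 0])
    ax_idx.axis("off")
    kl = cls.indices.kl
    ax_idx.text(
        0.02, 0.5,
        f"std (mm)   TL {cls.std.tl:6.2f}   TR {cls.std.tr:6.2f}\n"
        f"           LL {cls.std.ll:6.2f}   LR {cls.std.lr:6.2f}\n"
        f"kl  {'undefined' if kl is None else format(kl, '+.3f')}",
        family="monospace", fontsize=10, va="center",
    )

    # Class-estimation text on the combined-strain background.
    f_norm = float(np.max(cmaps["frontal"].normalized(
        curvature_profile(project(curve, "frontal")).kappa)))
    s_norm = float(np.max(cmaps["sagittal"].normalized(
        curvature_profile(project(curve, "sagittal")).kappa)))
    ax_txt = fig.add_subplot(gs[1, 1:])
    ax_txt.axis("off")
    ax_txt.text(
        0.5, 0.5, cls.description, ha="center", va="center", fontsize=12,
        bbox=dict(boxstyle="round", facecolor=_blend_background(f_norm, s_norm)),
    )
    fig.suptitle(f"patient {cls.patient_id}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
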