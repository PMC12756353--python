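"""Categorical labels and the natural-language class estimation.

The continuous indices are bucketed through the configurable interpretation
bands (see :class:`~scolioclass.config.ThresholdConfig`):

========================  =====================================================
quantity                  default buckets
========================  =====================================================
max quadrant dispersion   [0,2.5) no scoliosis · [2.5,4) mild · [4,6.5)
                          slightly significant · [6.5,10) very significant ·
                          [10,14.5) severe · [14.5,inf) extremely severe
sidedness s               s < -0.5 left-sided · |s| <= 0.5 both-sided ·
                          s > +0.5 right-sided
verticality v             [-1,-0.6) lumbar · [-0.6,-0.25) mainly lumbar ·
                          [-0.25,0.25] thoraco-lumbar · (0.25,0.6] mainly
                          thoracic · (0.6,1] thoracic
balance kl                [-1,-0.35) extreme lordosis · [-0.35,-0.2)
                          significant lordosis · [-0.2,0) slight lordosis ·
                          [0,0.3] normal spine · (0.3,0.5] slight kyphosis ·
                          (0.5,0.65] significant kyphosis · (0.65,1] extreme
                          kyphosis
========================  =====================================================

Values beyond +-1 (possible for kl on spines whose regional sagittal means
share a sign) fall into the outermost bucket.  The severity gate follows the
largest dispersion: when it stays below the first bound there is no
scoliosis and the side/vertical words are suppressed (labelled ``n/a``),
though the numeric indices are still reported for audit.

The description strings live in a small message catalog so clinics can
re-word labels without touching the index values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .config import ThresholdConfig
from .curve import ApexRecord, curvature_profile, find_apexes, interpolate, project
from .indices import IndexSet, StdVector, compute_indices
from .preprocess import normalize
from .spine import CentroidSequence

__all__ = [
    "SEVERITY_LABELS",
    "SIDE_LABELS",
    "VERTICAL_LABELS",
    "SAGITTAL_LABELS",
    "NA",
    "Classification",
    "severity_class",
    "side_class",
    "vertical_class",
    "sagittal_class",
    "compose_description",
    "classify_patient",
]

NA = "n/a"

SEVERITY_LABELS = (
    "No scoliosis",
    "Mild",
    "Slightly significant",
    "Very significant",
    "Severe",
    "Extremely severe",
)
SIDE_LABELS = ("Left-sided", "Both-sided", "Right-sided")
VERTICAL_LABELS = (
    "Lumbar",
    "Mainly lumbar",
    "Thoraco-lumbar",
    "Mainly thoracic",
    "Thoracic",
)
SAGITTAL_LABELS = (
    "Extreme lordosis",
    "Significant lordosis",
    "Slight lordosis",
    "Normal spine",
    "Slight kyphosis",
    "Significant kyphosis",
    "Extreme kyphosis",
)

#: Lower-case phrases used when a label is embedded in the description text.
DEFAULT_CATALOG: dict[str, str] = {
    "Left-sided": "left-sided",
    "Both-sided": "both-sided",
    "Right-sided": "right-sided",
    "Lumbar": "lumbar",
    "Mainly lumbar": "mainly lumbar",
    "Thoraco-lumbar": "thoraco-lumbar",
    "Mainly thoracic": "mainly thoracic",
    "Thoracic": "thoracic",
    "Extreme lordosis": "extreme lordosis",
    "Significant lordosis": "significant lordosis",
    "Slight lordosis": "slight lordosis",
    "Slight kyphosis": "slight kyphosis",
    "Significant kyphosis": "significant kyphosis",
    "Extreme kyphosis": "extreme kyphosis",
}


@dataclass(frozen=True)
class Classification:
    """Full per-patient result: numbers, labels, text, apexes."""

    patient_id: str
    std: StdVector
    indices: IndexSet
    severity: str
    side: str
    vertical: str
    sagittal: str
    description: str
    apexes: tuple[ApexRecord, ...]
    config_digest: str = ""


def severity_class(std: StdVector, cfg: ThresholdConfig = ThresholdConfig()) -> str:
    """Severity bucket of the largest quadrant dispersion (half-open bands,
    lower bound inclusive)."""
    m = std.max
    for bound, label in zip(cfg.std_severity_bounds, SEVERITY_LABELS):
        if m < bound:
            return label
    return SEVERITY_LABELS[-1]


def side_class(s: Optional[float], cfg: ThresholdConfig = ThresholdConfig()) -> str:
    """Left-/both-/right-sided by the sidedness index; the band |s| <= bound
    (inclusive) reads both-sided."""
    if s is None:
        return NA
    if s < -cfg.s_bound:
        return SIDE_LABELS[0]
    if s > cfg.s_bound:
        return SIDE_LABELS[2]
    return SIDE_LABELS[1]


def vertical_class(v: Optional[float], cfg: ThresholdConfig = ThresholdConfig()) -> str:
    """Vertical localisation by the v index.

    Boundary conventions as published: the transitional band is closed on
    both sides, so the two lumbar bands are lower-inclusive and the two
    thoracic bands upper-inclusive.
    """
    if v is None:
        return NA
    b = cfg.v_bounds
    if v < b[0]:
        return VERTICAL_LABELS[0]
    if v < b[1]:
        return VERTICAL_LABELS[1]
    if v <= b[2]:
        return VERTICAL_LABELS[2]
    if v <= b[3]:
        return VERTICAL_LABELS[3]
    return VERTICAL_LABELS[4]


def sagittal_class(kl: Optional[float], cfg: ThresholdConfig = ThresholdConfig()) -> str:
    """Sagittal-balance bucket of the kl index.

    The lordotic bands are lower-inclusive, the normal band [0, 0.30] is
    closed, and the kyphotic bands are upper-inclusive, so the seven buckets
    partition [-1, 1].
    """
    if kl is None:
        return NA
    b = cfg.kl_bounds
    if kl < b[0]:
        return SAGITTAL_LABELS[0]
    if kl < b[1]:
        return SAGITTAL_LABELS[1]
    if kl < b[2]:
        return SAGITTAL_LABELS[2]
    if kl <= b[3]:
        return SAGITTAL_LABELS[3]
    if kl <= b[4]:
        return SAGITTAL_LABELS[4]
    if kl <= b[5]:
        return SAGITTAL_LABELS[5]
    return SAGITTAL_LABELS[6]


def compose_description(
    severity: str,
    side: str,
    vertical: str,
    sagittal: str,
    catalog: Optional[dict[str, str]] = None,
) -> str:
    """Natural-language class estimation.

    Template: ``"<Severity> <side> <vertical> scoliosis with <sagittal>."``
    with the side/vertical/sagittal phrases in lower case from the message
    catalog.  The sagittal clause is omitted for a normal sagittal profile.
    With no scoliosis the text collapses to ``"Normal spine."`` or, when the
    sagittal profile alone is abnormal, to the sagittal label on its own
    (e.g. ``"Extreme kyphosis."``).
    """
    cat = dict(DEFAULT_CATALOG)
    if catalog:
        cat.update(catalog)
    sagittal_normal = sagittal in ("Normal spine", NA)
    if severity == SEVERITY_LABELS[0]:
        if sagittal_normal:
            return "Normal spine."
        return f"{sagittal}."
    text = f"{severity} {cat[side]} {cat[vertical]} scoliosis"
    if not sagittal_normal:
        text += f" with {cat[sagittal]}"
    return text + "."


def classify_patient(
    spine: CentroidSequence,
    cfg: ThresholdConfig = ThresholdConfig(),
    catalog: Optional[dict[str, str]] = None,
) -> Classification:
    """Run the full deterministic pipeline on one centroid sequence.

    normalise -> interpolate -> project -> dispersions & indices ->
    categorical labels -> description -> apexes.
    """
    cat = dict(catalog) if catalog else {}
    if cfg.vertical_spelling != "thoraco-lumbar":
        cat.setdefault("Thoraco-lumbar", cfg.vertical_spelling)

    norm = normalize(spine)
    curve = interpolate(norm, spacing_mm=cfg.spacing_mm)
    frontal = project(curve, "frontal")
    sagittal = project(curve, "sagittal")
    std, idx = compute_indices(frontal, sagittal, about_mean=cfg.std_about_mean)

    severity = severity_class(std, cfg)
    if severity == SEVERITY_LABELS[0]:
        # Below the scoliosis gate the side/vertical words are suppressed;
        # the numeric s and v stay in the index set for audit.
        side = NA
        vertical = NA
    else:
        side = side_class(idx.s, cfg)
        vertical = vertical_class(idx.v, cfg)
    sagittal_label = sagittal_class(idx.kl, cfg)
    description = compose_description(severity, side, vertical, sagittal_label, cat)
    apexes = tuple(find_apexes(norm))
    return Classification(
        patient_id=spine.patient_id,
        std=std,
        indices=idx,
        severity=severity,
        side=side,
        vertical=vertical,
        sagittal=sagittal_label,
        description=description,
        apexes=apexes,
        config_digest=cfg.digest(),
    )
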