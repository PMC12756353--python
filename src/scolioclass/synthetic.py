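"""Synthetic spine generator.

The clinical centroid data behind the reference study is restricted, so
every pipeline stage is exercised on generated spines with known ground
truth.  A template spine of 18 vertebral bodies (L5..C7) and the 17
intervening discs is laid out on a vertical 500 mm axis with uniform level
spacing (anatomical spacing tables would add realism but no test power),
then deformed:

* **Sagittal profile** — a lordotic lumbar half-sine (anterior, z < 0) of
  configurable depth below the lumbar->thoracic transition, blended to a
  kyphotic thoracic half-sine (posterior, z > 0) above it; zero at L5, the
  transition, and C7.
* **Lateral profile** — an arched bump peaking exactly at the chosen apex
  vertebra: quarter-sine rise and fall over a configurable half-width,
  clipped to the spine, signed by the convexity side.  The peaked-arch form
  keeps the analytic RMS of the bump at amplitude/sqrt(2) over its support
  while guaranteeing the displacement maximum sits at the apex level.  A
  two-curve spine adds a half-amplitude counter-bump of opposite convexity
  centred mid-lumbar.
* **Noise** — independent Gaussian noise per coordinate, reproducible from
  the seed.

Amplitudes in the default cohort mix span 0-60 mm lateral displacement,
covering the whole severity ladder of the classifier, with sagittal depths
around the kyphosis 30 mm / lordosis 25 mm of a normally balanced spine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .errors import ContractError, ValidationError
from .spine import (
    CANONICAL_LABELS,
    DEFAULT_LT_LABEL,
    VERTEBRA_LABELS,
    CentroidSequence,
    LandmarkPoint,
)

__all__ = ["SpineParams", "CohortMix", "generate_spine", "generate_cohort", "write_cohort"]

#: Template chord height, mm (matches the canonical frame, so normalisation
#: of a noise-free template is the identity).
TEMPLATE_HEIGHT_MM = 500.0

#: Apex levels a single structural curve may peak at.
_VALID_APEX = tuple(VERTEBRA_LABELS[VERTEBRA_LABELS.index("L4"): VERTEBRA_LABELS.index("T2") + 1])


def _template_heights() -> dict[str, float]:
    """Height (y, mm) of every canonical landmark on the straight template."""
    n_v = len(VERTEBRA_LABELS)
    y_v = np.linspace(0.0, TEMPLATE_HEIGHT_MM, n_v)
    heights: dict[str, float] = {}
    for i, lab in enumerate(VERTEBRA_LABELS):
        heights[lab] = float(y_v[i])
    for lab in CANONICAL_LABELS:
        if lab not in heights:  # disc between vertebrae i and i+1
            lower, upper = lab.split("/")[1], lab.split("/")[0]
            heights[lab] = 0.5 * (heights[lower] + heights[upper])
    return heights


_HEIGHTS = _template_heights()
_LT_HEIGHT = _HEIGHTS[DEFAULT_LT_LABEL]


@dataclass(frozen=True)
class SpineParams:
    """Generating parameters of one synthetic spine.

    ``lateral_amplitude`` is the peak lateral displacement (mm) at
    ``apex_level``; ``curve_halfwidth_mm`` the half-extent of the lateral
    arch (default 90 mm, a structural curve spanning roughly six levels).
    ``kyphosis_depth``/``lordosis_depth`` are the peak posterior/anterior
    sagittal offsets (mm).  ``noise_sd`` is the per-coordinate Gaussian
    noise, mm.
    """

    lateral_amplitude: float = 15.0
    apex_level: str = "T8"
    convexity: str = "right"
    n_curves: int = 1
    kyphosis_depth: float = 30.0
    lordosis_depth: float = 25.0
    noise_sd: float = 0.5
    seed: int = 0
    curve_halfwidth_mm: float = 90.0
    patient_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.lateral_amplitude < 0 or self.noise_sd < 0:
            raise ValidationError("amplitudes and noise_sd must be >= 0")
        if self.apex_level not in _VALID_APEX:
            raise ValidationError(
                f"apex_level must be a vertebra between L4 and T2, got {self.apex_level!r}"
            )
        if self.convexity not in ("left", "right"):
            raise ValidationError("convexity must be 'left' or 'right'")
        if self.n_curves not in (1, 2):
            raise ValidationError("n_curves must be 1 or 2")
        if self.curve_halfwidth_mm <= 0:
            raise ValidationError("curve_halfwidth_mm must be positive")

    @property
    def apex_is_thoracic(self) -> bool:
        return _HEIGHTS[self.apex_level] > _LT_HEIGHT


def _arch(y: np.ndarray, peak_y: float, halfwidth: float, amplitude: float) -> np.ndarray:
    """Smooth arch peaking at ``peak_y``: quarter-sine rise/fall over the
    support clipped to the template, zero outside, slope 0 at the peak."""
    lo = max(0.0, peak_y - halfwidth)
    hi = min(TEMPLATE_HEIGHT_MM, peak_y + halfwidth)
    out = np.zeros_like(y)
    rise = (y >= lo) & (y <= peak_y)
    fall = (y > peak_y) & (y <= hi)
    if peak_y > lo:
        out[rise] = amplitude * np.sin(0.5 * np.pi * (y[rise] - lo) / (peak_y - lo))
    else:
        out[rise] = amplitude
    if hi > peak_y:
        out[fall] = amplitude * np.cos(0.5 * np.pi * (y[fall] - peak_y) / (hi - peak_y))
    return out


def _sagittal(y: np.ndarray, kyphosis_depth: float, lordosis_depth: float) -> np.ndarray:
    """Lordotic (z<0) lumbar half-sine below the LT height, kyphotic (z>0)
    thoracic half-sine above; zero at both ends and at the transition."""
    z = np.empty_like(y)
    lum = y <= _LT_HEIGHT
    z[lum] = -lordosis_depth * np.sin(np.pi * y[lum] / _LT_HEIGHT)
    span = TEMPLATE_HEIGHT_MM - _LT_HEIGHT
    z[~lum] = kyphosis_depth * np.sin(np.pi * (y[~lum] - _LT_HEIGHT) / span)
    return z


def generate_spine(params: SpineParams) -> CentroidSequence:
    """Generate one labelled centroid sequence from its parameters.

    Deterministic: two calls with equal parameters (including the seed)
    return identical coordinates.
    """
    rng = np.random.default_rng(params.seed)
    y = np.array([_HEIGHTS[lab] for lab in CANONICAL_LABELS])
    sign = 1.0 if params.convexity == "right" else -1.0
    x = sign * _arch(y, _HEIGHTS[params.apex_level], params.curve_halfwidth_mm,
                     params.lateral_amplitude)
    if params.n_curves == 2:
        # Compensatory counter-curve: half amplitude, opposite side, centred
        # mid-lumbar (or mid-thoracic when the main apex is lumbar).
        counter_level = "L3" if params.apex_is_thoracic else "T8"
        x -= sign * _arch(y, _HEIGHTS[counter_level], params.curve_halfwidth_mm,
                          0.5 * params.lateral_amplitude)
    z = _sagittal(y, params.kyphosis_depth, params.lordosis_depth)
    pos = np.column_stack([x, y, z])
    if params.noise_sd > 0:
        pos = pos + rng.normal(0.0, params.noise_sd, size=pos.shape)
    points = tuple(
        LandmarkPoint(
            label=lab,
            kind="vertebra" if "/" not in lab else "disc",
            position=pos[i],
        )
        for i, lab in enumerate(CANONICAL_LABELS)
    )
    return CentroidSequence(patient_id=params.patient_id, points=points)


@dataclass(frozen=True)
class CohortMix:
    """Parameter distributions for a random cohort.

    Amplitudes are drawn uniformly from ``amplitude_range`` (mm), apex
    levels uniformly from ``apex_levels``, convexity left/right with equal
    probability, sagittal depths uniformly from their ranges, and the noise
    level uniformly from ``noise_range``.  Apex levels sit clearly inside
    one region — a curve apexed at the lumbar->thoracic transition has no
    well-defined region ground truth.
    """

    amplitude_range: tuple[float, float] = (0.0, 60.0)
    apex_levels: tuple[str, ...] = ("L3", "L2", "T9", "T8", "T7", "T6", "T5")
    kyphosis_range: tuple[float, float] = (20.0, 40.0)
    lordosis_range: tuple[float, float] = (15.0, 35.0)
    noise_range: tuple[float, float] = (0.0, 1.0)
    n_curves: int = 1

    def draw(self, rng: np.random.Generator, index: int, seed: int) -> SpineParams:
        return SpineParams(
            lateral_amplitude=float(rng.uniform(*self.amplitude_range)),
            apex_level=str(rng.choice(self.apex_levels)),
            convexity="right" if rng.random() < 0.5 else "left",
            n_curves=self.n_curves,
            kyphosis_depth=float(rng.uniform(*self.kyphosis_range)),
            lordosis_depth=float(rng.uniform(*self.lordosis_range)),
            noise_sd=float(rng.uniform(*self.noise_range)),
            seed=int(rng.integers(0, 2**31 - 1)),
            patient_id=f"synthetic-{index:04d}",
        )


def generate_cohort(
    n: int, mix: CohortMix = CohortMix(), seed: int = 0
) -> list[tuple[CentroidSequence, SpineParams]]:
    """Draw ``n`` spines from the mix; returns each spine with its true
    generating parameters for recovery tests.  Deterministic in ``seed``."""
    if n < 1:
        raise ContractError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        params = mix.draw(rng, i, seed)
        out.append((generate_spine(params), params))
    return out


def write_cohort(
    cohort: Sequence[tuple[CentroidSequence, SpineParams]], out_dir: Union[str, Path]
) -> Path:
    """Write one centroid CSV per spine plus ``truth.csv`` of the generating
    parameters; returns the truth-file path."""
    from .io import write_centroids  # local import to avoid a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = out_dir / "truth.csv"
    with open(truth, "w") as fh:
        fh.write(
            "patient_id,lateral_amplitude,apex_level,convexity,n_curves,"
            "kyphosis_depth,lordosis_depth,noise_sd,seed\n"
        )
        for seq, p in cohort:
            write_centroids(seq, out_dir / f"{seq.patient_id}.csv")
            fh.write(
                f"{p.patient_id},{p.lateral_amplitude!r},{p.apex_level},"
                f"{p.convexity},{p.n_curves},{p.kyphosis_depth!r},"
                f"{p.lordosis_depth!r},{p.noise_sd!r},{p.seed}\n"
            )
    return truth
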