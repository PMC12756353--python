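"""Analysis configuration: classification thresholds and numerical options.

The default index thresholds are the published interpretation bands; clinics
may redefine them, so the whole configuration round-trips through YAML/JSON
and its SHA-256 digest is embedded in every report for auditability.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Union

import yaml

from .errors import ValidationError
from .spine import DEFAULT_LT_LABEL

__all__ = ["ThresholdConfig"]


def _ascending(name: str, values: tuple[float, ...]) -> None:
    if any(b <= a for a, b in zip(values, values[1:])):
        raise ValidationError(f"{name} must be strictly ascending, got {values}")


@dataclass(frozen=True)
class ThresholdConfig:
    """Thresholds and numerical options for the classification pipeline.

    Parameters
    ----------
    std_severity_bounds:
        Five ascending positive bounds (mm) separating the six severity
        buckets of the largest quadrant dispersion value.
    s_bound:
        Half-width of the "both-sided" band of the sidedness index.
    v_bounds:
        Four ascending bounds of the vertical index partitioning [-1, 1]
        into lumbar / mainly lumbar / thoraco-lumbar / mainly thoracic /
        thoracic.
    kl_bounds:
        Six ascending bounds of the kyphosis-lordosis index partitioning
        [-1, 1] into the seven sagittal buckets, extreme lordosis through
        extreme kyphosis.
    spacing_mm:
        Arc-length spacing of the interpolated curve samples.
    std_about_mean:
        If True, quadrant dispersions are conventional standard deviations
        about the quadrant mean instead of RMS displacement about the
        vertical reference line (the default reading; see docs/methods.md).
    lt_label:
        Label of the disc at the lumbar->thoracic transition.
    kappa_max:
        Planar curvature (1/mm) mapped to full colour saturation in reports.
    vertical_spelling:
        Canonical spelling of the transitional vertical category in the
        description text ("thoraco-lumbar" or "thoracolumbar").
    """

    std_severity_bounds: tuple[float, ...] = (2.5, 4.0, 6.5, 10.0, 14.5)
    s_bound: float = 0.5
    v_bounds: tuple[float, ...] = (-0.60, -0.25, 0.25, 0.60)
    kl_bounds: tuple[float, ...] = (-0.35, -0.20, 0.0, 0.30, 0.50, 0.65)
    spacing_mm: float = 1.0
    std_about_mean: bool = False
    lt_label: str = DEFAULT_LT_LABEL
    kappa_max: float = 0.02
    vertical_spelling: str = "thoraco-lumbar"

    def __post_init__(self) -> None:
        object.__setattr__(self, "std_severity_bounds", tuple(float(b) for b in self.std_severity_bounds))
        object.__setattr__(self, "v_bounds", tuple(float(b) for b in self.v_bounds))
        object.__setattr__(self, "kl_bounds", tuple(float(b) for b in self.kl_bounds))
        if len(self.std_severity_bounds) != 5:
            raise ValidationError("std_severity_bounds needs exactly 5 values")
        if len(self.v_bounds) != 4:
            raise ValidationError("v_bounds needs exactly 4 values")
        if len(self.kl_bounds) != 6:
            raise ValidationError("kl_bounds needs exactly 6 values")
        _ascending("std_severity_bounds", self.std_severity_bounds)
        _ascending("v_bounds", self.v_bounds)
        _ascending("kl_bounds", self.kl_bounds)
        if any(b <= 0 for b in self.std_severity_bounds):
            raise ValidationError("std_severity_bounds must all be positive")
        if self.s_bound <= 0:
            raise ValidationError("s_bound must be positive")
        if self.spacing_mm <= 0:
            raise ValidationError("spacing_mm must be positive")
        if self.kappa_max <= 0:
            raise ValidationError("kappa_max must be positive")

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("std_severity_bounds", "v_bounds", "kl_bounds"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ThresholdConfig":
        """Load from YAML or JSON (YAML is a superset, so one loader serves both)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def to_file(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        """SHA-256 digest of the canonical JSON form, recorded in reports."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
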