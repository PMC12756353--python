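"""Render the colour-coded geometric report for one synthetic patient.

The figure shows the frontal, sagittal and axial projections of the
interpolated spinal curve, centroid markers (large = vertebrae, small =
discs), the lumbar->thoracic transition disc, the apexes, the curve
coloured and thickened by curvature strain, the index box, and the class
estimation text.
"""

from pathlib import Path

from scolioclass import classify_patient, interpolate, normalize, render_report
from scolioclass.synthetic import SpineParams, generate_spine

spine = generate_spine(
    SpineParams(lateral_amplitude=35.0, apex_level="T7", convexity="left",
                noise_sd=0.4, seed=5, patient_id="demo-report")
)
cls = classify_patient(spine)
curve = interpolate(normalize(spine))
out = render_report(cls, curve, Path("example_output") / "demo-report.png")
print(f"wrote {out}")
print(f"classification: {cls.description}")
# Yellow/magenta segments mark high lateral / front-back curvature strain;
# green segments are within the normal range.
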