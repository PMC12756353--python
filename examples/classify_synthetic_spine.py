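"""Classify one synthetic scoliotic spine and print what the numbers mean.

Builds a right-convex curve peaking at T8 with 22 mm lateral amplitude on a
normally balanced sagittal profile, runs the full pipeline, and prints the
quadrant dispersions, the three indices, and the composed description.
"""

from scolioclass import classify_patient
from scolioclass.synthetic import SpineParams, generate_spine

spine = generate_spine(
    SpineParams(lateral_amplitude=22.0, apex_level="T8", convexity="right",
                noise_sd=0.5, seed=11, patient_id="demo")
)
cls = classify_patient(spine)

print(f"patient          : {cls.patient_id}")
print(f"std TL/TR/LL/LR  : {cls.std.tl:.2f} {cls.std.tr:.2f} "
      f"{cls.std.ll:.2f} {cls.std.lr:.2f} mm")
print(f"s (sidedness)    : {cls.indices.s:+.3f}   (+1 all-right, -1 all-left)")
print(f"v (verticality)  : {cls.indices.v:+.3f}   (+1 thoracic, -1 lumbar)")
print(f"kl (sag. balance): {cls.indices.kl:+.3f}   (0 balanced, + kyphotic)")
print(f"apexes           : " + ", ".join(f"{a.name}={a.label}" for a in cls.apexes))
print(f"description      : {cls.description}")
# The dispersion maximum sets the severity band; s > 0.5 reads right-sided
# and v > 0.6 reads thoracic, matching the construction of the input.
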