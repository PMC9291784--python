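"""Chlorophyll-fluorescence TPU evidence from a PhiII trace.

Classifies the PhiII-vs-CO2 trend of two synthetic curves (one with a TPU
regime, one without) and prints the segments the classifier finds.
"""

from acifit import classify_phi_trend, generate_curve, j_fluorescence, preset

for name in ("tpu_transition", "no_tpu"):
    curve, _ = generate_curve(preset(name, seed=2))
    report = classify_phi_trend(curve)
    print(f"\n{name}:")
    for seg in report.segments:
        lo = curve.points[report.point_indices[seg.start]].ci
        hi = curve.points[report.point_indices[seg.stop - 1]].ci
        print(f"  Ci {lo:6.1f}-{hi:6.1f} Pa  PhiII {seg.trend.value:<10} "
              f"-> {seg.implied_limitation.value}")
    print(f"  TPU evidence: {report.tpu_evidence}")

phi, qin = 0.4, 1500.0
print(f"\nJ_f(PhiII={phi}, Qin={qin}) = {j_fluorescence(phi, qin):.0f} umol m-2 s-1")
print(
    "\nPhiII rises with CO2 while rubisco limits, is flat under RuBP-"
    "regeneration limitation,\nand falls once TPU limits — a terminal "
    "declining segment is independent evidence of TPU."
)
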