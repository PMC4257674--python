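"""Simulate a study and compare the transform families.

Generates the default synthetic skin volume, deforms it the way EM
processing does (5% global shrinkage plus smooth non-uniform bumps),
observes noisy landmark sets in both frames, and fits all four transform
families.  The residual table shows why a rigid overlay cannot absorb the
processing distortion while the Bookstein (thin-plate-spline) warp forces
the paired landmarks to overlap exactly.
"""

from clemdock import (
    default_scenario,
    fit_affine,
    fit_rigid,
    fit_similarity,
    fit_tps,
    residual_report,
)

scenario = default_scenario(seed=1)
pairing = scenario.pairing
print(f"paired landmarks: {pairing.n}  "
      f"(unmatched: {pairing.unmatched_source + pairing.unmatched_target})")

print(f"{'family':<12}{'RMS (µm)':>12}{'max (µm)':>12}")
for name, fitter in [
    ("rigid", fit_rigid),
    ("similarity", fit_similarity),
    ("affine", fit_affine),
    ("tps λ=0", lambda p: fit_tps(p, 0.0)),
]:
    report = residual_report(fitter(pairing), pairing)
    print(f"{name:<12}{report.rms:>12.3f}{report.max:>12.3f}")

sim = fit_similarity(pairing)
print(f"\nsimilarity scale {sim.scale:.4f} -> recovered shrinkage "
      f"{100 * (1 - sim.scale):.1f}% (5% was simulated, plus bumps and noise)")
print("rigid residuals of several µm confirm the distortion is not a "
      "rigid motion; TPS residual ~0 because λ=0 interpolates every landmark.")
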