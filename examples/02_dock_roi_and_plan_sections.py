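"""Dock a cell into the EM block frame and plan the sectioning window.

The region of interest (a cell centroid seen in the in-vivo frame) is
projected through the fitted thin-plate-spline into the block frame.  The
attached accuracy estimate is the median leave-one-out docking error of
the same registration, and the sectioning window adds that margin on both
sides before converting depth to section indices.
"""

import numpy as np

from clemdock import (
    Point3,
    RegionOfInterest,
    default_scenario,
    depth_to_sections,
    dock_roi,
    fit_tps,
    uniform_scheme,
)

scenario = default_scenario(seed=1)
transform = fit_tps(scenario.pairing, 0.0)

roi = RegionOfInterest("CELL1", [Point3.from_array(scenario.roi_true_source)])
result = dock_roi(transform, roi, scenario.pairing)
print(result.summary())

true_target = scenario.roi_true_target
err = np.linalg.norm(result.predicted_points[0].as_array() - true_target)
print(f"\nground-truth docking error (known only in simulation): {err:.2f} µm")

scheme = uniform_scheme(600, 300.0)  # 600 × 300 nm sections for tomography
window = depth_to_sections(result, scheme)
print(f"collect sections {window.first_index}-{window.last_index} "
      f"({window.n_sections} sections of 300 nm) to cover the ROI with its "
      "accuracy margin")
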