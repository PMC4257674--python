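"""Sectioning-scheme arithmetic for the three targeting strategies.

An alternating scheme interleaves thin EM sections with thick LM overview
sections after an approach run; a uniform semi-thick scheme covers a depth
window for tomography.  Depth intervals are half-open (shallow, deep] from
the block face and abut exactly.
"""

from clemdock import alternating_series_scheme, sections_covering

scheme = alternating_series_scheme(approach_count=180)
print(f"approach ends at {scheme.depth_of(180)[1]:.1f} µm "
      "(180 × 500 nm thick sections)")
z0, z1 = scheme.depth_of(181)
print(f"first thin EM section spans ({z0:.2f}, {z1:.2f}] µm")
unit = alternating_series_scheme(0, n_series=1)
print(f"one thin/thick series advances {unit.total_depth:.1f} µm "
      "(10 × 60 nm + 2 × 500 nm)")
print(f"full scheme: {scheme.n_sections} sections, "
      f"{scheme.total_depth:.1f} µm total")

count = sections_covering((73.0, 123.0), 300.0)
print(f"\ncovering a 73-123 µm target window with 300 nm sections needs "
      f"{count} sections (cut a few extra as safety margin)")
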