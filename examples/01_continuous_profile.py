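"""Continuous diameter/area profile along a coarctation phantom.

Builds a candy-cane aorta with a Gaussian narrowing that halves the 24 mm
base diameter at arc length 230 mm, extracts the centerline, and measures
maximum diameter and cross-sectional area on planes every 2 mm — the
continuous alternative to caliper readings at a handful of stations.
"""

import numpy as np

import vesselgauge as vg

spec = vg.preset("coarctation")
mesh, truth = vg.make_open_phantom(spec)
cl = vg.compute_centerline(
    mesh, truth.centerline_points[0], truth.centerline_points[-1]
)
profile = vg.measure_profile(mesh, cl, spacing=2.0)

body = (profile.s > 10) & (profile.s < profile.s[-1] - 10)
idx = np.flatnonzero(body)[np.nanargmin(profile.max_diameter[body])]
print(f"centerline length: {cl.length:.1f} mm over {len(profile.stations)} stations")
print(
    f"profile minimum: {profile.max_diameter[idx]:.2f} mm at s = {profile.s[idx]:.0f} mm"
)
print(f"ground truth:    12.00 mm at s = {spec.coarctation.center_s:.0f} mm")
print(
    "-> the continuous profile pins both the depth and the location of the "
    "narrowing; a discrete station grid could straddle it."
)
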