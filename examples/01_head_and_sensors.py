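"""Build a synthetic head and a dual-axis OPM array on its scalp.

The head is a bumpy-sphere cortex (the source space) inside a spherical
scalp; sensors are packed uniformly on the scalp at a target spacing
and lifted 8.7 mm along the local normal, each carrying one radial and
one tangential channel.
"""

import numpy as np

from opmlesion import build_array, make_head

head = make_head(order=4, seed=1)
r = np.linalg.norm(head.cortex.vertices, axis=1)
print(f"cortex: {head.cortex.n_vertices} vertices, radius {r.min():.1f}-{r.max():.1f} mm")
print(f"scalp-cortex clearance: {head.min_clearance():.1f} mm (must exceed 5 mm)")

for spacing in (32.0, 64.0):
    array = build_array(head.scalp, spacing=spacing, seed=0)
    d = np.linalg.norm(array.positions, axis=1) - 92.0
    print(
        f"spacing {spacing:>4.0f} mm -> {array.n_sensors:3d} OPMs "
        f"({array.n_channels} channels), stand-off {d.mean():.2f} mm"
    )
# The dense (32 mm) and sparse (64 mm) arrays bracket realistic
# whole-head OPM coverage; quartering the density roughly quarters
# the sensor count.
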