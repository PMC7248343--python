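"""Segment the bilayer plane into Ld / Lo / interface regions.

Tail-bead densities of the two phospholipids are smoothed with a 1.0 nm
Gaussian on a 0.1 nm grid; Canny edge detection on the DLiPC-DPPC difference
field finds the phase boundary, and everything within 1.5 nm of it becomes
the interface region.  On the synthetic stripe fixture the analytic answer
is known: boundaries at x = 0 and 20 nm, interface fraction
2*(2*1.5)/40 = 0.15.
"""

import numpy as np

from memphase import synthgen as sg
from memphase.phasemap import difference_field, interface_edges, segment_frame

spec = sg.MembraneSpec(composition=({"DPPC": 1.0}, {"DLiPC": 1.0}), seed=1)
frame, truth = sg.build_stripe_bilayer(spec)

pm = segment_frame(frame, radius=1.5)
delta = difference_field(frame)
edges = interface_edges(delta)

xs = (np.nonzero(edges)[0] + 0.5) * delta.spacing
bounds = np.asarray(truth["boundaries"])
err = np.abs((xs[:, None] - bounds[None, :] + 20.0) % 40.0 - 20.0).min(axis=1)

print("area fractions:",
      {k: round(v, 4) for k, v in pm.area_fractions().items()})
print(f"worst edge-to-true-boundary distance: {err.max():.3f} nm")
print("meaning: the detected interface tracks the built-in stripe "
      "boundaries to half a grid cell, and the 1.5 nm band covers ~15% "
      "of the membrane area as geometry dictates")
# pm.render("phasemap.png") draws the Fig-2-style overlay for visual QA
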