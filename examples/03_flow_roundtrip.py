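"""Masks -> flows -> masks: the instance representation and its inverse.

Encodes a labelled image as center-pointing unit flows plus a cell
probability, then recovers instances by advecting pixels along the flows
and clustering their convergence points, and scores the recovery.
"""

import numpy as np

from cellrestore import generate_cell_image, masks_to_flows, match_and_score
from cellrestore.flows import SegOutput, flows_to_masks

li = generate_cell_image(8, 18, (128, 128), style="nuclei", seed=5)
ft = masks_to_flows(li.masks)

norms = np.hypot(ft.flow_y, ft.flow_x)[li.masks > 0]
print(f"{li.n_instances} instances; flow norm inside masks: "
      f"min {norms.min():.3f}, max {norms.max():.3f} (unit by construction)")

seg = SegOutput(ft.flow_y, ft.flow_x, np.where(li.masks > 0, 5.0, -5.0))
recovered = flows_to_masks(seg, cellprob_threshold=0.0, niter=200, flow_threshold=0.4)

res = match_and_score(recovered, li.masks, iou_threshold=0.5)
print(f"recovered {recovered.max()} instances; "
      f"TP={res.tp} FP={res.fp} FN={res.fn} AP@0.5={res.ap:.3f}")
print("A perfect round-trip recovers every instance with AP 1.0; the flow "
      "representation is lossless up to the 1-px clustering grid.")
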