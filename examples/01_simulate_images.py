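"""Generate a small synthetic labelled dataset and inspect its geometry.

Creates eight cytoplasm-style images (bright membrane ring, dim textured
interior) with ground-truth instance masks, prints the measured mean
object diameter per image, and writes TIFFs plus a JSON manifest.
"""

import numpy as np

from cellrestore import generate_dataset
from cellrestore.simcells import measured_diameter, write_dataset

images = generate_dataset(
    n_images=8, n_cells=8, diameter=20.0, shape=(128, 128), style="cyto", seed=7
)

for i, li in enumerate(images):
    print(
        f"image {i}: {li.n_instances} instances, "
        f"measured mean diameter {measured_diameter(li.masks):.1f} px"
    )

manifest = write_dataset(images, "scratch/simulated")
print(f"\nwrote dataset + manifest to {manifest.parent}")
print(
    "The measured diameters sit within ~15% of the nominal 20 px; "
    "the diameter is what every resizing step downstream is keyed on."
)
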