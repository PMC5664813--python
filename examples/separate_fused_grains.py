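"""Split artifactually fused grains with the distance-based watershed.

Builds a phantom in which 4 of 10 grain pairs are fused by bright
bridges, renders the ideal binary mask, and shows that plain connected
components undercount the grains while the chessboard-distance
watershed recovers every planted grain.
"""

import numpy as np
from scipy import ndimage

from spikect import separate_grains
from spikect.phantom import PhantomSpec, generate_phantom, render_grain_mask

spec = PhantomSpec(
    n_spikelet_pairs=10,
    voxel_pitch_um=137.6,
    volume_shape=(448, 96, 96),
    fused_pair_fraction=0.4,
    bridge_radius_vox=5,
    tube=False,
    rachis=False,
    n_noise_specks=0,
    seed=3,
)
_, truth = generate_phantom(spec)
mask = render_grain_mask(truth)
print(f"planted {len(truth.grains)} grains, "
      f"{len(truth.fusion_links)} fused pairs (bridge radius "
      f"{spec.bridge_radius_vox} voxels)")

_, n_components = ndimage.label(mask.data, structure=np.ones((3, 3, 3)))
print(f"26-connected components before separation: {n_components} "
      "(each fused pair counts as one object)")

labels = separate_grains(mask)
print(f"labels after chessboard-distance watershed: {labels.n_labels}")

centers = np.round([g.center_zyx for g in truth.grains]).astype(int)
at = labels.data[centers[:, 0], centers[:, 1], centers[:, 2]]
print(f"distinct labels at the planted grain centers: "
      f"{len(set(at.tolist()))} — every grain ended up in its own label.")
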