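"""Segment a synthetic spike scan and measure every grain.

Generates a small phantom (a bimodal grey-value volume with ellipsoidal
grains on a rachis inside a holder tube), runs the segmentation chain
and the watershed separation, and prints the per-grain trait table.
"""

import numpy as np

from spikect import measure_all, segment_spike, separate_grains
from spikect.phantom import PhantomSpec, generate_phantom

spec = PhantomSpec(
    n_spikelet_pairs=6,
    voxel_pitch_um=137.6,
    volume_shape=(320, 96, 96),
    seed=5,
)
volume, truth = generate_phantom(spec)
print(f"phantom: {len(truth.grains)} grains planted, "
      f"volume shape {volume.shape}, pitch {spec.voxel_pitch_um} um/px")

masked, mask, thr = segment_spike(volume)
print(f"adaptive grain threshold: {thr.grain_threshold} "
      f"(background mode ~{thr.mode_lo}, plant mode ~{thr.mode_hi})")

labels = separate_grains(mask)
records = measure_all(labels, masked, volume.meta)
print(f"segmented and separated {labels.n_labels} grains "
      f"(planted: {len(truth.grains)})\n")

print(f"{'grain':>5} {'z_mm':>7} {'len_mm':>7} {'wid_mm':>7} "
      f"{'dep_mm':>7} {'vol_mm3':>8} {'psi':>5}")
for r in records:
    print(f"{r.grain_index:>5} {r.z_mm:>7.2f} {r.length_mm:>7.2f} "
          f"{r.width_mm:>7.2f} {r.depth_mm:>7.2f} {r.volume_mm3:>8.2f} "
          f"{r.sphericity:>5.2f}")

planted = np.mean([g.volume_mm3_analytic for g in truth.grains])
measured = np.mean([r.volume_mm3 for r in records])
deficit = 100 * (1 - measured / planted)
print(f"\nmean grain volume: measured {measured:.2f} mm3 vs planted "
      f"{planted:.2f} mm3 ({deficit:.0f}% low — the morphological opening "
      "shaves grain end-caps; the bias shrinks at finer voxel pitch and "
      "cancels in group-ratio comparisons).")
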