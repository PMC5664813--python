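"""Recover planted treatment effects from a phantom cohort.

Plants a two-group cohort — a stressed group with 0.6x the grain count
and 1.3x the grain volume, the classic fewer-but-bigger response to
heat stress — runs the full pipeline on every spike, and checks that
the group ratios and the inverse count/volume relation are recovered.
"""

import numpy as np
import pandas as pd

from spikect import measure_all, segment_spike, separate_grains
from spikect.phantom import PhantomSpec, generate_cohort

base = PhantomSpec(
    n_spikelet_pairs=6,
    voxel_pitch_um=137.6,
    volume_shape=(320, 96, 96),
    n_noise_specks=0,
)
phantoms, planted = generate_cohort(
    4,
    {
        "control": {"count_multiplier": 1.0, "volume_multiplier": 1.0},
        "stress": {"count_multiplier": 0.6, "volume_multiplier": 1.3},
    },
    seed=11,
    base_spec=base,
)

rows = []
for ph in phantoms:
    vol = ph["volume"]
    masked, mask, _ = segment_spike(vol)
    records = measure_all(separate_grains(mask), masked, vol.meta)
    rows.append({
        "spike": vol.meta.sample_id,
        "group": ph["group"],
        "n_grains": len(records),
        "mean_volume_mm3": np.mean([r.volume_mm3 for r in records]),
    })
df = pd.DataFrame(rows)
print(df.to_string(index=False))

g = df.groupby("group").mean(numeric_only=True)
pg = planted.groupby("group").mean(numeric_only=True)
count_ratio = g.loc["stress", "n_grains"] / g.loc["control", "n_grains"]
vol_ratio = (g.loc["stress", "mean_volume_mm3"]
             / g.loc["control", "mean_volume_mm3"])
planted_count = (pg.loc["stress", "planted_count"]
                 / pg.loc["control", "planted_count"])
planted_vol = (pg.loc["stress", "planted_mean_volume_mm3"]
               / pg.loc["control", "planted_mean_volume_mm3"])
corr = np.corrcoef(df["n_grains"], df["mean_volume_mm3"])[0, 1]
print(f"\nrecovered count ratio {count_ratio:.3f} "
      f"(planted {planted_count:.3f}; the nominal 0.6 rounds to whole "
      "spikelet pairs at this small spike size)")
print(f"recovered volume ratio {vol_ratio:.3f} (planted {planted_vol:.3f})")
print(f"count vs mean-volume correlation across spikes: {corr:.2f} — "
      "negative, the fewer-but-bigger signature.")
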