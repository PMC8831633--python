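"""Category breaks and value histogram for a finished index map.

Shows the two colour-ramp schemes: 32 equal intervals, and a
histogram-adjusted scheme whose top category absorbs the sparse right
tail (e.g. everything above 0.71 for a past-style map).
"""

import numpy as np

import climstab as cs

world = cs.make_world(cs.WorldSpec(map_set="past", n_rows=80,
                                   n_cols=120, master_seed=3))
result = cs.compute_past_csi(world.stacks, world.template,
                             n_points=5000, sampling_seed=1,
                             selection_seed=2)
csi = result.csi.csi

hist = cs.histogram(csi, 10)
print("index histogram (10 bins over [0,1]):")
print(hist.to_string(index=False))

equal = cs.categorize(csi, cs.BreakScheme.equal_interval(32))
adjusted = cs.categorize(csi, cs.BreakScheme.with_top_break(32, 0.71))
print(f"equal-interval top class holds "
      f"{int((equal.values == 32).sum())} pixels; "
      f"adjusted (0.71-1) top class holds "
      f"{int((adjusted.values == 32).sum())} pixels")
print(f"a pixel at 0.80 falls in class "
      f"{int(cs.categorize(csi.with_values(np.full(csi.values.shape, 0.8)), cs.BreakScheme.with_top_break(32, 0.71)).values[0, 0])} "
      f"of the adjusted scheme")
# Most pixels sit in the low-index (stable) half; widening the top
# class keeps the rare, highly unstable areas visible on a map.
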