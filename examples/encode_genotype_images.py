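"""Convert one genotype sample into images under the three encoders.

Shows the minimal square side for the SNP count, the color palette in use,
and verifies the color encoding decodes back to the exact genotype codes.
"""

import numpy as np

import genocam as gc

spec = gc.SimulationSpec(n_cases=2, n_controls=2, n_null_snps=1800,
                         n_risk_snps=200, seed=1)
d = gc.simulate_dataset(spec)
print(f"{d.n_snps} SNPs -> image side {gc.side_length(d.n_snps)}")

layout = gc.layout_end_to_end(d.n_snps)
codes = d.genotypes[0]

cc = gc.encode_cc(codes, layout, d.sample_ids[0], int(d.labels[0]))
chen = gc.encode_chen(codes, layout, d.sample_ids[0], int(d.labels[0]))
yue = gc.encode_yue(gc.genotype_pairs(d, 0), layout, d.sample_ids[0], int(d.labels[0]))
print(f"cc image {cc.pixels.shape}, chen {chen.pixels.shape}, yue {yue.pixels.shape}")
print("cc palette:", gc.CC_PALETTE, "padding (0, 0, 0)")

assert np.array_equal(gc.decode(cc, layout), codes)
print("cc decode(encode(x)) == x: lossless")
# Chen's AA code 0 collides with padding, so an all-AA region is
# indistinguishable from blank cells -- the documented weakness of that scheme.
n_aa = int((codes == 0).sum())
print(f"chen renders {n_aa} AA genotypes at gray 0, same as the "
      f"{int(layout.padding_mask.sum())} padding cells")
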