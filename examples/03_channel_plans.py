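"""Decode decision vectors into channel plans and reproduce the reference report.

A candidate architecture is a vector x in [-0.5, 0.5]^43; each coordinate
rescales one convolution layer via l' = l - floor(l * x).  The packaged
reference plan carries the published baseline and optimized channel counts.
"""

import numpy as np

from lodgeseg.encoding import (
    decode_channels,
    reference_base_plan,
    reference_optimized_plan,
    summarize_plan,
)

base = reference_base_plan()
x = np.zeros(43)
x[7] = -0.5  # maximally widen slot DSCL 08 (64 channels)
decoded = decode_channels(x, base)
print(f"DSCL 08: 64 channels, x = -0.5  ->  {decoded.optimized[7]} channels (+50%)")

report = summarize_plan(reference_optimized_plan())
print("\nPublished optimized plan, first rows:")
print("\n".join(report.to_text().splitlines()[:8]))
print("...")
print(report.to_text().splitlines()[-1])
print("\n23 layers widened / 20 narrowed: the search does not shrink uniformly,")
print("it reallocates width toward early feature-extraction layers.")
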