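"""The five-point demonstration: what MI sees that r does not.

Two arrangements of the same five (x, y) points.  On a rough diagonal the
Pearson coefficient is 0.8; permute the y-positions and it collapses to 0,
yet y remains exactly as predictable from x as before — the mutual
information under five fixed bins per axis stays log2(5) = 2.322 bits in
both cases.
"""

import numpy as np

from coexpmi import BinningConfig, pearson_r

x = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
y_diagonal = np.array([0.3, 0.1, 0.5, 0.9, 0.7])
y_permuted = np.array([0.3, 0.9, 0.5, 0.1, 0.7])

fixed5 = BinningConfig(mode="fixed", n_bins=5, range_low=0.0, range_high=1.0)

for label, y in (("diagonal", y_diagonal), ("permuted", y_permuted)):
    r = pearson_r(x, y)
    mi = fixed5.mi(x, y)
    print(f"{label:9s}  r = {r:+.3f}   MI = {mi:.3f} bits")

print()
print("r drops from 0.8 to 0, but MI is unchanged: each x value still")
print("pins down exactly one y value, so the dependency is fully intact —")
print("it is merely no longer linear.")
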