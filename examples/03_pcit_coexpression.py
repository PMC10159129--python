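"""The PCIT filter: which correlations survive their indirect paths.

For every trio of features the three first-order partial correlations set a
tolerance; an edge weaker than the tolerance-scaled indirect legs is
knocked out. A weak direct edge flanked by strong legs disappears; an edge
equal to the product of its legs survives (its own partial is exactly 0 and
pulls the tolerance down).
"""

import numpy as np

from micronet import pcit_significant

weak_direct = np.array(
    [[1.0, 0.2, 0.9],
     [0.2, 1.0, 0.3],
     [0.9, 0.3, 1.0]]
)
sig = pcit_significant(weak_direct)
print("weak direct edge r_xy=0.2 with legs 0.9/0.3:")
print(f"  x-y kept: {bool(sig[0, 1])}, x-z kept: {bool(sig[0, 2])}, y-z kept: {bool(sig[1, 2])}")

product = np.array(
    [[1.0, 0.81, 0.9],
     [0.81, 1.0, 0.9],
     [0.9, 0.9, 1.0]]
)
sig = pcit_significant(product)
print("product structure r_xy = r_xz * r_yz = 0.81:")
print(f"  all edges kept: {bool(sig.sum() == 6)}")
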