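"""Contact occupancies through the rational switching function.

Evaluates s(r) = (1 - x^8)/(1 - x^12), x = r/2.5 Å, at a few
distances, then sums pairwise occupancies into the H-bond count N for
a toy frame.  s(r) is 1 for a fully formed contact, n/m = 2/3 exactly
at r = r0, and decays to 0 beyond; N is the smooth "number of
H-bonds/salt bridges" axis used by the free-energy projection.
"""

import numpy as np

from lvmetad import ContactSet, SwitchingParams, hbond_count, switch

params = SwitchingParams()  # n=8, m=12, d0=0, r0=2.5 Å
for r in (0.0, 1.5, 2.5, 3.5, 5.0):
    print(f"s({r:3.1f} Å) = {switch(r, params):.6f}")

contacts = ContactSet(pairs=(("guest", "siteA"), ("guest", "siteB")), params=params)
frame = {
    "guest": np.array([0.0, 0.0, 0.0]),
    "siteA": np.array([2.0, 0.0, 0.0]),   # strong contact
    "siteB": np.array([0.0, 4.5, 0.0]),   # weak contact
}
n = hbond_count(frame, contacts)
print(f"\nH-bond count N = {n:.4f}  (sum of the two occupancies above)")
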