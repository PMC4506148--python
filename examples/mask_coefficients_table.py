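"""Inspect the fractional mask coefficient lines and their normalization.

Prints the n + 2 coefficients C_{s_-1} .. C_{s_n} of the 5x5 variable-order
mask for a few orders, the diagonal scale 2^(-v/2) and the total-weight
normalization denominator, and exports one line as CSV.
"""

import sys

from fractex import build_directional_masks, mask_coefficients, normalization_denominator

for v in (0.1, 0.5, 0.9, -0.5):
    C = mask_coefficients(v, n=3)
    ms = build_directional_masks(C, m=2)
    D = normalization_denominator(C)
    coeffs = "  ".join(f"{c:+.5f}" for c in C.C)
    print(f"v={v:+.1f}  C(k=-1..3): {coeffs}  diag scale={ms.diag_scale:.4f}  D={D:+.5f}")

print(
    "At v -> 0 only the centre coefficient survives and D -> 8 C_0, so the"
    " normalized operator is the identity; the nonzero coefficient sum is what"
    " distinguishes the fractional mask from an integer-order one."
)
path = sys.argv[1] if len(sys.argv) > 1 else None
if path:
    mask_coefficients(0.5, 3).to_csv(path)
    print(f"wrote coefficient table for v=0.5 to {path}")
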