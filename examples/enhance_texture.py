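"""Adaptive enhancement: sharpening clean texture, smoothing noisy flats.

Runs the adaptive variable-order enhancement with 5x5 masks on two probes:
a clean band-limited texture (where positive orders dominate and the clarity
measure MADC rises) and a flat image with Gaussian noise of variance 0.01
(where the noise indicator flags isolated pixels, negative orders engage and
the interior variance drops).
"""

import numpy as np

from fractex import (
    EnhanceConfig,
    FixtureSpec,
    add_gaussian_noise,
    enhance_grey,
    global_entropy,
    intensity_std,
    madc,
    make_fixture,
)

cfg = EnhanceConfig(mode="vofcd")

texture = make_fixture(FixtureSpec("sinusoid", (128, 128)))
sharp, order = enhance_grey(texture, cfg, return_order=True)
print("clean texture:")
print("  order field:", order.summary())
print(f"  MADC {madc(texture):.6f} -> {madc(sharp):.6f} "
      f"(ratio {madc(sharp) / madc(texture):.3f}; > 1 means crisper texture)")
print(f"  Ent {global_entropy(texture):.4f} -> {global_entropy(sharp):.4f} bits, "
      f"STD {intensity_std(texture):.4f} -> {intensity_std(sharp):.4f}")

flat = make_fixture(FixtureSpec("constant", (128, 128)))
noisy = add_gaussian_noise(flat, seed=0)
smoothed, order_n = enhance_grey(noisy, cfg, return_order=True)
inner = (slice(4, -4), slice(4, -4))
print("noisy flat image:")
print(f"  noise-flagged pixels: {100 * (order_n.R == 1).mean():.1f}%")
print(f"  interior variance {noisy[inner].var():.6f} -> {smoothed[inner].var():.6f} "
      f"(ratio {smoothed[inner].var() / noisy[inner].var():.3f}; < 1 means noise suppressed)")
print(
    "Positive orders act only where local structure is detected; negative"
    " orders smooth pixels whose gradient has no similar neighbour."
)
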