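"""Colour enhancement through the HSI and per-channel RGB pathways.

Builds a synthetic colour image (three phase-shifted textures as R, G, B) and
enhances it both ways at a fixed order.  The HSI route treats hue, saturation
and intensity as separate planes; the RGB route filters each channel
independently.  The printed hue shifts show the trade-off: filtering the hue
plane itself moves colours more on strongly chromatic textures, while the RGB
route moves hue only through channel imbalance.
"""

import numpy as np

from fractex import EnhanceConfig, FixtureSpec, enhance_colour, hsi_to_rgb, make_fixture, rgb_to_hsi

channels = [make_fixture(FixtureSpec("sinusoid", (64, 64), seed=s, period=10 + 2 * s)) for s in range(3)]
rgb = np.stack(channels, axis=-1)

rt = hsi_to_rgb(rgb_to_hsi(rgb))
print(f"HSI round-trip error (no enhancement): {np.abs(rt - rgb).max():.2e}")

out_hsi = enhance_colour(rgb, EnhanceConfig(mode="fixed", fixed_v=0.3, colour_mode="hsi"))
out_rgb = enhance_colour(rgb, EnhanceConfig(mode="fixed", fixed_v=0.3, colour_mode="rgb"))

def report(label, out):
    hue = float(np.abs(rgb_to_hsi(out)[..., 0] - rgb_to_hsi(rgb)[..., 0]).mean())
    dev = float(np.abs(out - rgb).mean())
    print(f"{label}: mean hue shift {hue:.4f}, mean RGB change {dev:.4f}")

report("HSI pathway", out_hsi)
report("RGB pathway", out_rgb)
print(
    "Both pathways apply the identical grey operator; they differ only in the"
    " colour decomposition the operator sees, so the choice is a modelling"
    " decision about which planes should carry the sharpening."
)
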