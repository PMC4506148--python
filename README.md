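# fractex

Adaptive variable-order fractional differential texture enhancement for
grey-scale and colour images, aimed at medical imaging (e.g. susceptibility-
weighted brain MRI), where texture carries diagnostic information but fixed
sharpening filters over-enhance smooth regions and amplify noise.

## The method

The core operator is a discretized symmetric (Riesz-type) fractional
derivative of order *v*. The fractional centered-difference weights

&nbsp;&nbsp;&nbsp;&nbsp;φ<sub>k</sub> = (−1)<sup>k</sup> Γ(v+1) / [Γ(v/2−k+1) Γ(v/2+k+1)]

reduce to the classical second difference [−1, 2, −1] at *v* = 2. Each sample
is additionally shifted by *vh*/2 with a 3-point Lagrange interpolant
(a, b, c) = (v/4 + v²/8, 1 − v²/4, v²/8 − v/4), which blends every node with
its neighbours and enriches texture response. Truncating the half-axis series
gives a sparse coefficient line C<sub>s−1</sub> … C<sub>sn</sub> (n = 2m − 1)
that is laid out along the four axes and four diagonals as eight directional
masks in a (2m+1)×(2m+1) neighbourhood — diagonal lines carry the
step-length factor 2<sup>−v/2</sup> on their non-centre weights. The enhanced
pixel is the sum of the eight responses divided by the total mask weight

&nbsp;&nbsp;&nbsp;&nbsp;D = 4 Σ<sub>k</sub> C<sub>s<sub>k</sub></sub> + 2<sup>(4−v)/2</sup> Σ<sub>k≠0</sub> C<sub>s<sub>k</sub></sub> + 4 C<sub>s<sub>0</sub></sub>,

so constant images are exact fixed points and *v* = 0 is the identity.

What makes the operator adaptive is a per-pixel order field. Three bounded
local features — gradient magnitude ‖∇s‖, local Shannon entropy *H* and local
roughness Q = 1 − 1/(1+σ²) — are min–max normalized and combined as
g = k₁‖∇s‖ + k₂H + k₃Q with k₁+k₂+k₃ = 1. A binary indicator *R* separates
structure from noise: a pixel whose gradient magnitude has no similar value in
its 8-neighbourhood (minimum |Δ| above a threshold *T*) is noise-like (R = 1).
The order is then

&nbsp;&nbsp;&nbsp;&nbsp;v = (−1)<sup>R</sup> max(0, e<sup>αg</sup> − β),&nbsp;&nbsp;&nbsp;&nbsp;α = 1, β = 1.7,

so structure gets a sharpening order in [0, e−1.7] and noise a smoothing
order in [1.7−e, 0]. Image quality is scored by SNR (squared RMS ratio of a
signal region over a background region), histogram entropy, standard
deviation and MADC (a clarity measure from squared neighbour differences),
and a 0.01-step simplex sweep over (k₁, k₂, k₃) finds the weightings that
maximize or minimize each score.

## Worked example

```sh
python examples/enhance_texture.py
```

prints

```
clean texture:
  order field: {'v_min': -0.7828125689361587, 'v_mean': 0.13090248464434728, 'v_max': 0.6792186467820545, 'noise_fraction': 0.24224853515625}
  MADC 0.002433 -> 0.003905 (ratio 1.605; > 1 means crisper texture)
  Ent 2.7595 -> 2.9547 bits, STD 0.2000 -> 0.2190
noisy flat image:
  noise-flagged pixels: 69.6%
  interior variance 0.009945 -> 0.009847 (ratio 0.990; < 1 means noise suppressed)
```

On a clean sinusoidal texture the order field is positive over the textured
pixels and the clarity measure MADC rises by ~60%, along with the histogram
entropy and contrast; on a flat image with variance-0.01 Gaussian noise the
indicator flags ~70% of pixels, negative orders engage and the interior
variance drops. The other scripts in `examples/` walk through the order-field
features, the fixed-order baselines, the weight grid search, the colour
pathways and the raw mask coefficients.

The same pipeline is available from the shell:

```sh
fractex make-fixtures images --size 64
fractex enhance images/sinusoid.png enhanced.png --report-out report.json
fractex weightsearch images/sinusoid.png --out-csv grid.csv --m 1
```

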