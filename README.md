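# cassdetect

Contour detection by **context-adaptive surround suppression** (CASS) with a
**dynamic suppression method** (DSM) — a biologically inspired edge operator
for separating object contours from texture clutter in grayscale images.

## The problem

Gradient-based edge detectors cannot tell a meaningful object boundary from
the thousands of equally strong edges produced by grass, fur, foliage or any
dense texture. Orientation-selective neurons in primary visual cortex solve
this with *surround suppression*: a cell's response to an edge inside its
receptive field is reduced in proportion to similar stimuli in the annular
non-classical surround. Edges packed densely (texture) inhibit each other;
isolated edges (contours) do not.

## The model

For an image *f* at scale σ, the operator computes

* a Gaussian-derivative gradient, magnitude `M_σ` and orientation `θ`;
* an annular distance weighting `w = H(DoG_σ)/‖H(DoG_σ)‖₁`, the positive
  lobe of a difference of Gaussians with scales σ and 4σ (the surround
  extends between radii r₁ and r₂ = 4r₁);
* the suppression term
  `s(x,y) = Σ M_σ(neighbor) · w(offset) · |cos(θ(x,y) − θ(neighbor))|`
  and the classical suppressed response `E = H(M_σ − α·s)`, with `H`
  half-wave rectification and α the inhibition level.

CASS adapts the surround to the local context, measured by a local linear
kernel regression: at each pixel a plane is fitted by weighted least squares
over a disk window, both fully (WRMS_c) and on the two half-windows split
along the local edge direction (WRMS₁, WRMS₂). The jump statistic
`diff = max(WRMS_c − WRMS₁, WRMS_c − WRMS₂)` is large only next to an
intensity jump. Then

* `diff ≤ Thr` (no jump nearby): `s_a = w_t · s`, with
  `w_t = exp(r_m²/2σ_m²)`, `r_m = min(WRMS₁, WRMS₂, WRMS_c)` — suppression
  is *amplified* where the residual level is high, i.e. inside texture;
* `diff > Thr` (jump): `s_a = s_i − s_e`, inhibition restricted to the
  half-surround on the jump's side of the edge minus facilitation from the
  opposite, smoother half.

The DSM replaces one large hand-tuned α with many applications of a small
one: `E^{t+1} = H(E^t − α·s_a'(E^t))`, feeding the evolving response back
into the surround sums (orientations and diagnostics stay frozen). Mutually
suppressing texture decays toward zero over 10–30 iterations while isolated
contours, seeing little surround response, persist. A final non-maximum
suppression and quantile-parameterized hysteresis (`t_high` = the (1−p)
quantile of positive thinned responses, `t_low = t_high/2`) produce the
binary contour map. Defaults: σ = 1.0, p = 0.2, α = 0.1, Thr = 30,
20 iterations.

Detection quality against a ground-truth contour map is scored by
`P = |E|/(|E|+|E_FP|+|E_FN|)` with `E` the correctly detected pixels,
plus the miss rate `e_fn = |E_FN|/|GT|` and the false-positive rate
`e_fp = |E_FP|/|E|`.

## Worked example

Generate a synthetic scene (a weak-contrast disk embedded in strong random
bar clutter, with pixel-exact ground truth), run both detectors, and score
them:

```bash
cassdetect make-fixtures demo -n 2 --seed 7 --size 128 --weak-fraction 1.0
cassdetect detect demo/scene_001.png -o demo/edges_dsm.png --model cass-dsm
cassdetect eval   demo/edges_dsm.png demo/scene_001_gt.png --tolerance 1
cassdetect detect demo/scene_001.png -o demo/edges_ss.png --model ss
cassdetect eval   demo/edges_ss.png demo/scene_001_gt.png --tolerance 1
```

Output (abridged):

```
cass-dsm  P: 0.116  e_fn: 0.000  e_fp: 7.61   (1464 pixels detected, 170/170 GT found)
ss        P: 0.052  e_fn: 0.000  e_fp: 18.18  (3260 pixels detected, 170/170 GT found)
```

Both detectors recover the full contour (`e_fn = 0`), but the dynamic
context-adaptive model rejects more than half of the clutter the classical
single-level model lets through: its false-positive rate `e_fp` drops from
18.2 to 7.6 spurious pixels per correct one, and the combined score `P`
doubles. The same comparison is available in library form via
`cassdetect.detect_array`, `cassdetect.run_dsm` and `cassdetect.evaluate`.

The `sweep` subcommand reruns detection and evaluation over σ and p grids
and writes a CSV of per-image and mean P, e_fn, e_fp.

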