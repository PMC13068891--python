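# Methods

## Model and assumptions

`cimaug` composites annotated lesion instances into normal endoscopic
frames. The underlying assumptions are those of instance-level copy-paste
augmentation: a lesion's diagnostic appearance is carried by its local
texture/colour structure; that structure survives translation to a
*similar-looking* mucosal region; and gradient-domain blending suffices to
reconcile the illumination mismatch between source and target frames. The
method is deliberately model-free — no generative network, no learned
saliency — so every step is deterministic given a seed and auditable.

### Region proposal

Mean shift operates on 5-dimensional features `(row/h_s, col/h_s, Lab/100/h_r)`
with spatial bandwidth `h_s` (default 16 px) and range bandwidth `h_r`
(default 0.12): dividing each block by its bandwidth lets a single
unit-bandwidth flat kernel realise independent spatial and range scales.
CIELAB is used because Euclidean distance there tracks perceived colour
difference; the /100 scaling puts the lightness range near one unit. Modes
are sought from a regular pixel subgrid (at most `ms_max_samples` points,
default 1500) and every pixel is assigned to its nearest mode; spatially
adjacent clusters closer than `h_r` in mean colour are then merged, so flat
regions fragmented by the spatial term collapse to one cluster. All steps
are deterministic for fixed input.

"Biological relevance" is not defined operationally in the source
literature, so it is implemented as explicit rules: cluster mean luminance
(Rec. 601) within `[0.15, 0.92]` — dropping the dark endoscope mount and
specular glare — an optional RGB gamut for the mucosa band, and a minimum
cluster area fraction of 0.05. Out-of-band pixels are excluded regardless of
their cluster. An image where nothing passes raises an explicit
empty-region error and is skipped (and logged) during dataset builds.

SLIC defaults: 64 segments, compactness 10, 10 iterations, masked to the
relevant region, with post-processing that guarantees a consecutive,
non-empty labelling of at most `n_segments` superpixels (smallest fragments
merge into their most similar spatial neighbour).

### Matching, placement, blending

The lesion-to-site match minimises the Euclidean distance between mean RGB
colours, ties to the lowest superpixel id. The lesion-mask centroid is
aligned to the superpixel centroid, rounded to integers, then clamped so
the patch keeps a one-pixel background margin — the Dirichlet boundary of
the Poisson solve must be background everywhere.

The blend solves, per colour channel, the 5-point discrete Poisson equation
on the pasted support Ω with `I = B` on ∂Ω. The guidance field along an
edge is the difference of the guidance image when both endpoints lie in the
placed patch rectangle, and of the background otherwise (so a constant
lesion on a constant background reproduces the background exactly). Modes:

- `import`: `v = ∇L` — classic gradient import;
- `gradient_mix` (default, `α` = 0.8): `v = α∇L + (1−α)∇B`; since both
  fields are image gradients their convex combination is the gradient of
  `αL + (1−α)B`, so one solve suffices. `α = 0` reproduces the background,
  `α = 1` equals import, and the solution is affine in `α` (hence
  continuous);
- `pixel_mix`: the literal pixel-space convex combination `αP + (1−α)B`
  with `P` the import solution — kept because the describing prose admits
  both the gradient-space and pixel-space readings of the mixing weight;
- `hard`: plain replacement, no solve.

A literal summed-gradient field (`v = ∇B + ∇L`) appears in some
descriptions of Poisson compositing but degenerates — a patch cut from the
background and re-blended in place would double its own gradients — so it
is exposed only behind the off-by-default `sum_gradients` flag.

The linear system (SPD, ≤ ~50k unknowns on 224×224 frames) is solved by
sparse LU factorisation, switching to conjugate gradients (`rtol 0`,
`atol = solver_tol/10`, max 10 000 iterations) above 80 000 unknowns. The
residual is verified against `solver_tol` (default 1e-6) and the output is
clipped to `[0, 1]` after compositing.

### Baselines

MixUp draws `λ ~ Beta(β, β)` with `β = 0.2` — the customary setting for the
cited method; the source does not state its value, so it is configurable.
CutMix samples `λ₀ ~ U(0,1)`, sets patch dims `(H√λ₀, W√λ₀)` rounded half
up, centres the patch uniformly, clips to the frame, and recomputes the
label coefficient from the realised area so the area–label identity is
exact by construction. Random copy-paste places the lesion uniformly over
valid offsets with no blending, downscaling by the minimal factor when the
instance exceeds the frame.

### Protocol

Per class: an 80/20 stratified split (test size `round-half-up(0.2·n)`),
5-fold tags cycled over a shuffled training portion, and
`floor(synthesis_ratio · n_normal_train)` synthetic lesion samples per
variant (ratio 1.0 → exact class balance between real normals and
real+synthetic lesions in training). Backgrounds are the normal training
images cycled in shuffled order; lesion sources are restricted to training
lesions carrying the *same* fold tag as the background, so no held-out fold
ever contributed pixels to a training sample. The published split tables
are internally inconsistent with any single rounding rule (370·0.2 = 74
exactly, but 98·0.2 = 19.6 prints as 19), so `explicit_test_counts` pins
per-class test sizes where a printed table must be matched; the rounding
rule applies everywhere else. Geometric lesion augmentation uses right
angles {0°, 90°, 180°, 270°} by default — "rotation" without a stated angle
set is read conservatively, since right angles transform masks without
interpolation; arbitrary angles are available via configuration with
nearest-neighbour masks. Lesions larger than half the shorter frame side
are downscaled to that fraction (never upscaled) to keep whole-frame
lesions implausible.

The variant sweep produces 11 manifests — default (no augmentation), mixup,
cutmix, random_paste, hard paste, and one per α in
{0, 0.2, 0.4, 0.6, 0.8, 1} — all sharing identical real-image splits: the
split and fold substreams depend only on the master seed, and every other
draw flows through substreams named by variant and sample index, so adding
a variant never perturbs another's data. Note the α = 0 sweep point yields
an image identical to its background while carrying the lesion label; it is
generated as specified, and its pathology is a property of the sweep
definition, not of this implementation.

## Randomness and reproducibility

All randomness derives from one integer seed through named CRC-32-hashed
substreams (`split`, `folds`, `backgrounds/<variant>`,
`sample/<variant>/<i>`). Every synthetic sample's provenance records its
derived integer seed plus lesion source, transform, α, mode and superpixel
id — sufficient to regenerate the sample bit-exactly — and every CLI run
echoes its resolved configuration as sorted JSON.

## The fixture generator

Fixtures emulate the qualitative structure of endoscopic frames: Gaussian
band-limited noise mapped into a reddish-pink palette (texture scale 12 px
at 224², scaled with resolution), a radial vignette (strength 0.35), a dark
circular field-of-view border (radius 0.68·min(H,W)), three specular spots,
and — for lesion frames — one irregular blob (48-vertex radial polygon,
smoothed radius perturbation 0.3, radius 10–22% of the frame side) whose
interior is shifted toward a paler hue (−0.15, −0.02, +0.05 in RGB) and
lightly retextured; the mask is the exact blob support. What the fixtures
do **not** model: real mucosal microstructure and vascular patterns,
device-specific optics, motion blur, fluid/debris, multi-lesion frames, or
the actual colour statistics of narrow-band versus white-light imaging.
Tests passing on fixtures therefore validate the algorithmic machinery —
geometry, bookkeeping, solver identities, determinism — not clinical image
quality or downstream classifier gains, which require real data and
training runs that are out of scope here.

## Problem sizes

The protocol-scale runs (tests and `scripts/acceptance.py`) rebuild the
three published dataset splits — 523/167, 370/98 and 200/32 images — at a
48×48 working resolution with a mode-search budget of 600 samples and 32
SLIC segments per frame. The reported quantities (split and synthesis
counts, solver identities, bookkeeping invariants) are independent of
resolution; 48×48 keeps the ~900 full augmentation chains these builds
execute at desk scale. Unit tests use the same resolution; the blending
identity checks run at 96×96.

## Known limitations

- Mean-shift mode finding runs on a pixel subgrid; extremely thin
  structures (below the subsample stride) can be missed by the mode search,
  though pixel assignment still covers them.
- The relevance rules are tuned to endoscopy-like imagery (dark border,
  glare); other domains need their own criteria via configuration.
- Appearance matching uses mean colour only; texture similarity (named as a
  desirable cue in the source description) is not implemented — mean colour
  already determines the published matching rule.
- `pixel_mix` with small α visibly ghosts the lesion; this is inherent to
  the pixel-space reading, not a solver artefact.
- No photometric lesion augmentation (colour jitter) — only geometric.
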