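# Methods

`visnetscenes` models how primate vision finds and then identifies objects in
cluttered scenes by splitting the problem between two streams: a bottom-up
saliency system (dorsal-stream surrogate) that proposes fixation targets, and
a four-layer hierarchical competitive network (ventral-stream model of
V2 → V4 → posterior IT → anterior IT) that identifies the object at each
fixation with combined view and translation invariance.

## Stimuli

The four object classes are procedural stand-ins for two people and two
vehicles: each is a list of superellipsoid parts rendered by orthographic
projection after rotation about the vertical axis, so the silhouette changes
smoothly and substantially over the 135° range of trained views
(270°, 315°, 0°, 45°).  Object tiles are 256×256, intensities 0–255,
background ≈127.  Each class carries a distinctive albedo texture (smooth
mottle or an oriented weave of class-specific orientation and spatial
frequency) standing in for the distinct material statistics of real object
classes; these surface statistics, not just silhouette, are what make the
classes separable in early oriented-energy channels.  Each object's canonical heading
is offset a few degrees from the camera axis so boxy forms are never seen
exactly axis-on at a trained view (an axis-aligned orthographic box view
collapses to a degenerate silhouette).

Training canvases are 512×512 mid-gray; the object centre is displaced on a
centred square grid (16-px spacing, 5×5, spanning ±32 px).  Test scenes are 1024×1024: multi-scale filtered noise (RMS
contrast 6 gray levels) plus two ±45 gray-level distractor blobs, with each
object pasted (foreground pixels only) in one of its trained views at a
jittered quadrant anchor.  The clutter amplitudes are set so a scene's
saliency map carries a couple of non-object peaks alongside the four object
peaks — the regime the whole-system evaluation assumes — while keeping
fixation proposals from being flooded by background regions.  What this
generator does **not** emulate: real photographic background statistics,
lighting/shadow coupling between object and scene, occlusion, and scale
variation.  Passing tests therefore demonstrate the computational mechanism
(saliency-guided fixation + invariance learning), not photographic-level
robustness.

## V1 front-end

A bank of zero-mean, unit-L2 Gabor filters (4 orientations × 3 spatial
frequencies {0.0625, 0.125, 0.25} cycles/px in the test profile, plus
0.5 c/px at full scale; isotropic envelope, σ = 0.4/f) is convolved with the
canvas at native resolution with reflect padding.  Responses are half-wave
rectified into on/off polarity channels and block-averaged onto a square
retinal lattice whose side matches the first network layer (32 in the test
profile, 128 at full scale).  Constant images produce exactly zero output;
responses scale linearly with contrast.

## The hierarchy

Each of the four layers is a grid of neurons with `fan_in` afferents
(272 for layer 1, 100 above) sampled with replacement from a Gaussian around
the topologically corresponding position in the source layer
(σ = 0.25 × source grid).  Sampling with replacement occasionally duplicates
an afferent; at these fan-ins this is immaterial and keeps initialization a
single vectorized draw.  At initialization the union of afferent chains of a
central layer-4 neuron is required to cover ≥95% of the retina (checked, not
assumed; init fails otherwise).

A forward pass per layer:

1. activation `h_i = Σ_j w_ij x_j` over the neuron's afferents;
2. lateral inhibition: convolution with a centre-surround filter (centre
   weight 1, Gaussian surround of total mass `inhib_contrast` = 1.5,
   σ = {1.4, 2.8, 4.5, 6.0} × grid/32).  The filter output is *not*
   rectified here: suppressed neurons go below zero and the sigmoid maps
   them to ≈0.  Rectifying at this point piles a point mass at exactly zero
   that coincides with the percentile threshold whenever most of a layer is
   suppressed, which collapses the activation function to its degenerate
   midpoint and destroys the sparse code;
3. sparseness-controlled sigmoid `y = σ(2·slope·(h' − θ))` with θ at the
   layer's percentile of the h' distribution.  An all-equal input (e.g. a
   blank canvas) is degenerate and maps the layer to a uniform 0.5, logged;
   the degenerate state propagates, so a blank input yields an uninformative
   layer-4 pattern by construction.

Learning is the trace rule: `ȳ(t) = (1−η)·y(t) + η·ȳ(t−1)` with η = 0.8 in
all four layers, `Δw_ij = α·ȳ_i·x_j` on existing synapses only, followed by
L2 renormalization of each neuron's weight vector (norms are unit after
every update; weights stay nonnegative).  Per-layer learning rates are
(0.05, 0.03, 0.005, 0.005), applied uniformly at every presentation; an
optional geometric within-sequence decay factor is exposed (default 1 = no
decay).  All transforms of one object are presented in a freshly permuted
sequence each epoch with the trace reset at the object boundary, so temporal
continuity only ever binds transforms of the same object.

Training diagnostics log the mean |Δw| per layer per epoch; a run aborts if
total weight change grows for five consecutive epochs.

## Saliency (GBVS)

Feature maps use intensity local contrast and Gabor orientation energy (four
orientations; no color, no motion).  Each pyramid level filters the scene at
a working resolution of 4× the graph scale and pools rectified energy down
by block averaging — computing features on the downsampled image instead
makes textured objects (balanced bright/dark parts) average to the scene
mean and vanish.  Graph scales default to 32 and 16 nodes per side: a
fully connected graph is built per map with edge weight
`|log(f_i/f_j)|·exp(−d²/2σ²)` (σ = 0.15 × map width; ε = 10⁻⁶ × map max
added before logs; uniform teleport weight 10⁻⁶ for ergodicity), rows are
normalized into a Markov matrix, and the activation map is its equilibrium
(power iteration, L1 tolerance 10⁻⁸).  A second pass with weights
proportional to the target node's activation concentrates mass at peaks.
An 8×8 level was tried and dropped: at scene scale it carries no
object-sized structure and only adds a centre-biased plateau.  Channel maps
are averaged (after bilinear upsampling and renormalization) into a master
map that is a probability distribution at every stage.

Fixations: the master map is thresholded at 0.1 of its maximum; the
suprathreshold support is segmented into one region per local maximum
(watershed on the inverted map, minimum peak separation 1/16 of the map
side).  Each region's mass and weighted centroid are computed from
background-subtracted saliency within a window of 1.5× the peak separation
around its peak — plain connected components merge every peak on a shared
plateau into one region, and basin-wide mass ranks diffuse background
basins above compact object peaks.  Regions are ranked by mass (ties by
centroid row, col); the top k = 6 become fixations.  384×384 patches are
cut around each fixation (mid-gray padding at scene borders) and embedded
centred in a 512×512 mid-gray canvas, so object scale matches training and
no rescaling is applied.

## Readout and information measures

Layer-4 responses to every trained transform form a (cell, object,
transform) tensor.  Stimulus-specific single-cell information uses 10
equi-spaced bins over each cell's observed range, uniform object priors,
`max_s Σ_r P(r|s) log₂[P(r|s)/P(r)]`; the ceiling is log₂ 4 = 2 bits, a
constant-rate cell carries 0 by definition, and no bias correction is
applied (≥25 transforms per object keep plug-in bias modest; label-shuffle
tests bound it empirically).  Multiple-cell information is the mutual
information of the confusion matrix of a cross-validated (5-fold)
nearest-class-mean decoder with normalized dot products.

The pattern associator takes the 25 most selective cells per object (by
single-cell information, among cells whose best object is that object; ties
by cell index), accumulates unit-normalized response vectors per output
neuron (one per object) in a single Hebbian batch, and then normalizes each
output neuron's weight vector (synaptic scaling) so the output argmax
compares pattern match rather than accumulated mass.  Classification is the
argmax over the four outputs; ties go to the lowest object id and are
logged.

## Run profiles and problem sizes

* `full`: 128×128 neurons per layer (65,536 total), 4 views × 25 locations
  (100 transforms/object), 50 epochs.
* `test`: 32×32 per layer, the same 4 views × 25 locations, 15 epochs;
  all shipped tests and the worked example use this profile so a complete
  train/evaluate cycle stays within minutes on one CPU.  Fifteen epochs sit
  inside the 15–50-epoch convergence band of the learning-rate schedule;
  at this scale longer training slowly degrades the readout.  Layer 1 keeps
  approximately the full-scale *number* of active cells (percentile 0.95 at
  1024 neurons) rather than the full-scale active fraction, which would
  leave only ~8 active cells and starve the upper layers.

Evaluation suites: a translation sweep along the horizontal grid axis
(offsets 0–48 px, trained and intermediate offsets distinguished), a view
sweep with 6 intermediate views per 45° interval on plain backgrounds, and
the whole-scene pipeline (saliency → fixations → patches → classify), where
a ground-truth object with no fixation within 64 px counts as an error and
non-object fixations are reported separately.

## Known limitations

* The procedural objects are far easier for a pixel-space nearest-neighbour
  classifier than real photographs; the interesting claim the tests support
  is about *invariant* recognition from fixation patches on clutter, not raw
  discriminability.
* The scaled-down profile's layer-1 sparse code is only a handful of active
  cells per stimulus; view generalization and single-cell selectivity are
  accordingly noisier than at full scale.
* Only one fixation per object is used; no top-down attention, no recurrent
  dynamics, no color or motion channels.
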