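# Methods

## The problem

Photoreceptor ribbon synapses connect rod/cone terminals to ON-bipolar
dendrites in the outer plexiform layer (OPL) of the retina. In two-channel
immunofluorescence, the pre-synaptic ribbon (RIBEYE/CtBP2) and the
post-synaptic receptor (mGluR6) appear as punctate signals whose pairing
within ~1 um indicates a synapse. Simple colocalization thresholds are
unstable; this package instead assigns every candidate marker pair a
posterior probability of being a synapse from a Naive Bayes model trained
on anatomically defined classes, and layers downstream inference (growth
curves, electrophysiology models, robust comparisons) on the resulting
counts.

## Image processing

Stacks are reduced by averaging the first five z-planes. Three channel
protocols produce ROIs; all measurements are then taken on the unaltered
projected image.

* **Nuclei**: rolling-ball-style background subtraction (grayscale opening,
  disk radius 20 px), difference-of-Gaussians band-pass passing 3-40 px
  structures, a local noise-adaptive threshold, one binary dilation, and
  marker-based watershed splitting on the distance transform (h-maxima
  depth 2 px); components of 30-3000 px^2 are kept.
* **Pre-synaptic marker**: background subtraction, band-pass, 3x3 mean
  smoothing, then a two-stage local-maxima scheme: h-maxima (prominence 6
  intensity units) seed a watershed that tiles the entire image into
  segments, and each segment is flooded from its own maximum down to
  (maximum - tolerance), tolerance 10. The threshold therefore adapts to
  the background around each punctum; a 2x brighter background half-image
  yields identical detections.
* **Post-synaptic marker**: band-pass, a grayscale maximum filter (disk
  radius 2 px) to consolidate the small puncta, then the same
  segment/threshold scheme.

The local threshold is a quadtree reimplementation of robust automatic
threshold selection: blocks whose SD exceeds 1.5x a global robust noise
estimate (median absolute deviation; signal occupies a minority of pixels)
are split down to 32 px blocks; each leaf's threshold is the
gradient-weighted mean intensity of pixels whose squared gradient exceeds
9x the median squared gradient, with an Otsu fallback when no gradients
qualify, a floor of 5x the noise SD, and box smoothing across seams.
Bit-compatibility with any particular plugin is a non-goal; the filter
constants above are all exposed in `SegmentationConfig`.

Coordinates are 0-based, x = column, y = row (downward). Pixel centers sit
at index + 0.5, so brightness-weighted centroids are comparable with the
generator's continuous ground truth without a half-pixel bias.

## Features (34 parameters)

Per marker ROI: 14 *Signal* parameters (mean, median, integer-cast mode
with smallest-value tie-break, min, max, SD, skewness, kurtosis, and the
first six divided by the global background), 14 *Morphology* parameters
(Crofton 4-direction perimeter; bounding-box width/height; the `shape`
offset between brightness-weighted mass center and bounding-box center;
moment-ellipse major/minor/angle; bounding-box aspect ratio; roundness
4A/(pi major^2); circularity 4 pi A/P^2 capped at 1; solidity against the
pixel-center convex hull, clipped at 1; max/min Feret diameters from the
pixel-corner hull with the max-Feret angle), and 2 marker-level *Geometry*
parameters (area, raw integrated density). The remaining four Geometry
parameters -- pair distance, pair angle, and the partner's area/integrated
density -- live on the candidate pair. Skewness and kurtosis of constant
regions are defined as 0 so density fitting never sees NaN. The global
background is the KDE mode of pixel intensities at or above 8 (pixels
below that are treated as empty space).

Digitization choices: circularity of very small regions overshoots the
analytic bound and is capped at 1 (its fitted support allows up to 1.1);
solidity uses the hull of pixel centers, which slightly favors tiny
regions, and is clipped at 1.

## Densities and the classifier

Each parameter's class-conditional density is a Gaussian-kernel KDE
(Silverman bandwidth; evaluation grids sized so the grid step is at most a
third of the bandwidth, which keeps numeric normalization within 1e-3 even
for spiky integer-valued parameters). Parameters with hard support (areas,
lengths, ratios, angles) use reflection-corrected KDE with zero mass
outside; angles wrap. Pair geometry: synapse distance is a parametric
Gaussian, synapse angle a wrapped KDE; noise distance a normalized
second-order polynomial on [0, 1.2] um (chance pairings of uniform points
grow linearly in r), noise angle uniform. Degenerate (zero-variance)
parameters fall back to a narrow Gaussian and are recorded on the model.

Candidates are all pre/post centroid pairs within 1.2 um. The spatial
prior comes from a chance-pairing calibration: two uniform point sets in a
periodic square, cross-pairs counted within d, pair count per unit area
regressed through the origin on the density product. The slope ("random
factor") matches the analytic pi d^2 (~4.52 um^2 at 1.2 um). At
application time marker densities are counted in a 5x5 um window around
the pair midpoint; `random_pairs = slope * rho_pre * rho_post * 25 um^2`,
and the synapse prior is 0.5 when random_pairs < 2, else 1/random_pairs.
Likelihoods multiply the selected per-parameter densities of both markers
(and the pair distance/angle densities when the Geometry category or the
distance-only subset is selected), floored at 1e-12 so a single unseen
value cannot zero a posterior. Candidates with posterior above 50% are
called synapses; an optional greedy one-to-one resolution handles shared
markers. Maturity scoring applies the same machinery with equal priors to
two classes trained from immature-stage and mature-stage synapse sets and
reports per-marker log-likelihoods without a hard call.

## Synthetic scenes

The generator emulates a section through the OPL: synapse midpoints are a
hard-core point process (minimum separation 1.8 um, the rod-spherule
scale) inside a horizontal 10 um band; pre->post displacements have
Gaussian length (defaults 0.51 +- 0.17 um) oriented vertically (wrapped
normal, SD 25 deg, with an 8% flipped minority); puncta render as Gaussian
spots with log-normal peak jitter over five z-planes with plane-wise
intensity jitter, constant background and Gaussian read noise (Poisson
optional). Noise puncta carry roughly constant total flux spread over a
variable footprint (small-and-bright or large-and-faint, never both);
clustered noise (structured staining of other layers) stays outside the
band, diffuse uniform noise may fall anywhere. The nuclei channel renders
two flanking layers of nuclei as flat-core super-Gaussian disks (filled
nuclei, not diffraction-limited points) at 3-sigma spacing, so packed
layers stay resolvable the way real DAPI nuclei are. Everything is
seeded; every rendered punctum has a ground-truth row.

The hard-core spacing matters: at the default density it keeps pre-i to
post-j cross-pairings of neighboring synapses outside the 1.2 um pairing
radius, so the within-band pair distance distribution is dominated by true
partners and moment fitting recovers the displacement Gaussian -- the same
property real training data must have for its clean Gaussian distance
distribution. What the generator does *not* emulate: optics-accurate PSFs,
photobleaching, autofluorescence, the horseshoe substructure of mature
ribbons (a crescent option exists but features are summary statistics), or
rod/cone subtypes. Benchmark results therefore demonstrate the machinery's
correctness and calibration, not field performance on real microscopy.

## The seeded benchmark

Training pools 8 replicate scenes (noise outside the band), mirroring the
multiple-sections-per-mouse structure of real training sets; in-band ROIs
form the synapse class, outside-band ROIs the noise class, pairs formed
per scene. Evaluation pools 8 held-out scenes (uniform noise allowed in
band); candidate midpoints are greedily matched one-to-one to true
midpoints within 1 um and the posterior ROC is computed with a DeLong 95%
CI (bootstrap optional). The held-out count is sized so the CI spans about
+-0.03. Residual errors are dominated by genuinely ambiguous "half-true"
pairs: a real marker paired with a synapse-like noise punctum whose
midpoint loses the one-to-one match.

## Downstream models

All three Bayesian models use the affine-invariant ensemble sampler with
differential-evolution moves, a Nelder-Mead-refined start, weakly
informative priors (half-normal on scales and positive parameters, normal
on locations, Gamma(2, 0.1) on the Student-t normality), 89% highest-
density intervals, and contrasts computed as differences of posterior
draws. Split R-hat above 1.05 on the reported scalars sets a
non-convergence flag (ensemble walkers make this conservative);
divergences are a Hamiltonian-sampler concept and are reported as zero in
the diagnostics structure, with the acceptance fraction given instead.

* **Gompertz synaptogenesis.** Counts follow Poisson(Lambda_mouse) with
  Lambda_mouse ~ Gamma(shape = Lambda_day beta, rate = beta) --
  mean-preserving, so the Zwietering Gompertz curve
  y(t) = A exp(-exp(mu_M e / A (lambda - t) + 1)) is the expected count --
  and the mouse level is marginalized in closed form
  (lgamma(alpha + S) - lgamma(alpha) + alpha log(beta/(beta+m)) -
  S log(beta+m) per mouse-day; verified against quadrature), leaving
  (A, mu_M, lambda) per condition plus shared beta. Per-mouse rates are
  recovered by conjugate Gamma draws. A calibration study on the default
  recovery design (A=320, mu_M=60/day, lambda=11 d, days 7-35, 4 mice x 4
  replicates) showed joint 89% HDI coverage of the three parameters is
  ~85% when between-mouse spread is moderate (beta = 0.5, ~8% CV -- the
  generator default, typical of litter-matched inbred mice) but degrades
  under extreme spread because only one design day falls in the rising
  phase, leaving mu_M weakly identified.
* **mERG Gamma GLM.** Amplitudes ~ Gamma with mu = exp(a0 + a_cond +
  a_mouse), sigma = exp(b0 + b_cond + b_mouse) (shape mu^2/sigma^2, rate
  mu/sigma^2); sum-to-zero condition effects, zero-centered mouse effects
  with half-normal scale hyperpriors. Reported scalars are recentered by
  folding per-condition mouse-effect means into the intercept (a
  likelihood-invariant reparameterization that removes the
  intercept/mouse-mean degeneracy).
* **Robust comparison.** Student-t likelihood with shared scale, group
  means a0 + a_cond + a_mouse, nu ~ Gamma(2, 0.1); same recentering.

mERG traces get a zero-phase (forward-backward) 2nd-order Butterworth
1-50 Hz band-pass -- zero-phase so wave latencies are not shifted --
replicates averaged first; the a-wave is the most negative local minimum
within 55 ms of the stimulus (must dip below the 50 ms pre-stimulus
baseline), the b-wave the most positive local maximum within 150 ms,
referenced to the a-wave trough when one was detected and to baseline
otherwise. The trace renderer calibrates its pulse amplitudes by fixed
point against this extractor, so generated traces *measure* at the
requested amplitudes despite the filter's pulse reshaping.

## Problem sizes

Defaults are desk-scale: 512 px scenes (51.2 um at 0.1 um/px) with 60
synapse pairs, 8 training and 8 evaluation scenes, 2000+ pooled pairs for
geometry recovery, MCMC with 32+ walkers x 2500 steps, 20 seeded
replications for interval-calibration checks. All are parameters.

## Known limitations

Rod vs cone synapses are not distinguished (the training classes pool
them). The Naive Bayes independence assumption double-counts redundant
Signal statistics, which can make the all-parameter classifier locally
overconfident on half-true pairs. The 2-D section geometry discards z
information. Ensemble-sampler R-hat on hierarchical scale parameters is
conservative; summaries should be read alongside the acceptance fraction.
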