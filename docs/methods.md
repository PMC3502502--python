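# Methods

`morphconnect` implements, on fully synthetic data with known ground truth,
the computational chain used to relate cortical activation patterns evoked by
continuously morphing face stimuli to the structural connectivity between the
activated regions.  This note documents the models, the choices that were
genuinely open, and what the synthetic data do and do not establish.

## Stimulus model and psychophysics

A stimulus is a 6-s face morph followed by a 1-s still (7-s stimulus onset
asynchrony).  Facial age moves linearly between a start and a target age
(2–81 years); in half of the stimuli facial gender crosses from one endpoint
sex to the other.

Perception is modelled by Stevens' power law.  For age, the perceived
magnitude of the age gradient spanned by a morph is

    rating = k * |a_target^p - a_start^p|,    p ≈ 0.3,

so a 16-year change early in life (10→26) carries far more perceptual weight
than the same change late in life (64→80).  The **age regressor** is the
unsigned first derivative of the Stevens-transformed age trajectory, binned
at the 24 fps video rate, zero during stills, and scaled once per run to a
relative maximum of 1.

For gender, the perceived level along the morph coordinate `t ∈ [0, 1]` is
the symmetric S-curve

    P(t) = 0.5 * (1 + sign(u) |u|^(1/γ)),   u = 2t - 1,   γ ≈ 3,

which lies above the linear transition (apperceptive categorisation) and
whose discrete derivative peaks at mid-morph, making peak androgyny the
effective stimulus.  The **gender regressor** is |ΔP| per frame; morphs
without a transition contribute an identically zero series.  A direction
ambiguity exists in how a single exponent maps morph position to perceived
level; we implement the above-diagonal curve with the exponent entering as a
reciprocal power per half-morph, which reproduces both the above-linear
rating profile and the mid-morph derivative peak.  The exponent is
configurable throughout.

Exponent fitting minimises the residual sum of squares over a grid of
candidate exponents, with the scale `k` solved in closed form per candidate,
followed by bounded scalar refinement between the best grid point's
neighbours (no analytic gradient; every step is verifiable against an
exhaustive grid scan).  Noiseless round-trips recover the generating
exponent to 1e-6.

Rater competence is summarised by trichotomising per-subject mean rating
errors at the quintile cutoffs: the `ceil(n/5)` lowest-error subjects form
the high-accuracy group, the `ceil(n/5)` highest-error the low-accuracy
group (n = 24 gives 5/14/5).  Ties spanning a cutoff are resolved by a
stable sort on subject id.

The rating generator adds Gaussian noise (default SD = 10% of the rating
range, clipped at zero).  The noise distribution of real raters is unknown;
an optional linear age-dependent noise slope emulates the observed growth of
rating SD with absolute age, but no functional form is asserted.

## Optical flow nuisance

Residual motion energy differs between morph pairs and is regressed out.
Dense flow between successive 1-s keyframes is estimated by the classic
Horn-Schunck method: brightness constancy `Ex·u + Ey·v + Et = 0` plus a
quadratic smoothness penalty weighted by `α²`, iterated from zero
initialisation (default 30 iterations) with derivatives averaged over the
2×2×2 spatio-temporal cube and replicated edges.  The field is binarised at
a small magnitude threshold (default 1e-3 px/frame) and the flow magnitudes
inside the mask are summed, giving one scalar per keyframe interval; the
series is max-normalised.  `α` (default 1.0 for the pipeline, smaller values
appropriate for weak-gradient test images) and the mask threshold are free
parameters of this implementation and exposed in the config.  Estimation at
1 fps rather than frame-by-frame is deliberate: morph motion is smooth and
strongly autocorrelated, and finer binning adds noise without information.

## First-level GLM

Frame-rate regressors are convolved with a gamma HRF parameterised by mean
lag 6 s and SD 3 s (shape `(lag/sd)²`, scale `sd²/lag`, truncated at 32 s,
unit sum), sampled at volume onsets (TR 2.4 s), and paired with their first
temporal derivatives.  High-pass filtering at 100 s is implemented as
projection onto a DCT drift basis — exactly reproducible, unlike a running
line smoother, with an identical cutoff — applied to task and derivative
columns and to the data, not to spike confounds or the intercept.  Spike
confounds are per-volume indicators.

Per-vertex ordinary least squares yields betas; COPE = c'β̂ and
VARCOPE = σ̂² c'(X'X)⁻¹c for unit contrasts on each task column (derivative
columns deliberately excluded from contrasts).  Optional prewhitening is a
single-pass AR(1) two-stage fit (estimate lag-1 residual autocorrelation per
vertex, transform, refit) rather than a full autospectral method; it is off
by default in the simulations, whose noise is mildly autocorrelated and
whose inferences are validated by calibration tests.  A COPE is converted to
mean percent BOLD change as `100 · cope · peak-to-peak(effective convolved
regressor) / mean(Y)`.  Cluster response magnitudes are compared after
dividing by the within-condition minimum (minimum maps to 1.0).

## Group inference

The cortical surface stand-in is an icosphere of radius 50 mm (vertex count
`10·4^s + 2`); graph-edge shortest paths approximate geodesics.  Surface
smoothing is iterative graph-Laplacian diffusion, `x ← x − ε(D − A)x` with
ε = 0.01; the iteration count is calibrated empirically so a point source
spreads to the requested FWHM (width `2.355·sqrt(E[d²]/2)`).  The operator
is symmetric, hence exactly sum-conserving, and mean-preserving on constant
maps.  Defaults: 5 mm for COPE/VARCOPE maps, 2 mm for connectivity counts.

Group maps use a variance-weighted mixed-effects one-sample statistic:
weights `1/(varcope + σ_b²)` with the between-subject variance σ_b²
estimated by method of moments and floored at zero (deterministic, unlike
iterative ML), t on n−1 degrees of freedom.  Family-wise error is controlled
by cluster-mass permutation: connected components of vertices with two-sided
p below the cluster-forming threshold (default 0.01 — the common choice; no
canonical value exists) are scored by the sum of |t|; the null of the
maximum cluster mass is built by sign-flipping subject COPE maps (the
correct exchangeability for within-subject contrasts), and
`cwp = (1 + #{null ≥ observed}) / (n_perm + 1)`, multiplied by the number of
contrasts (Bonferroni) and capped at 1.  The smallest achievable cwp is
therefore `n_contrasts/(n_perm+1)`.  Calibration tests verify 5% vertex-wise
type-I error and 5% ± 2% cluster FWER on fully null data.

## Probabilistic tractography

Orientation fields carry up to two fiber directions per voxel with volume
fractions and an angular dispersion; a Bayesian fit of diffusion data is out
of scope, so dispersion is modelled directly as a Watson-like axial
perturbation (axis plus Gaussian angular noise, default SD 10°).  Each
streamline sample draws a fiber per voxel proportionally to its fraction,
perturbs the axis, picks the sign minimising the turning angle, and advances
0.5 mm; it terminates on leaving the grid, entering a stop mask, turning
more than 80°, or exhausting the step budget.  Isotropic voxels propose a
uniformly random direction, so survival through them decays geometrically —
this is what makes the disconnected phantom's connectivity negligible rather
than exactly zero.  Field lookup is nearest-neighbour for determinism.
Surface seeds are projected 1 mm inward along the patch normal (the entry
geometry is not otherwise constrained).

A sample "connects" when it enters the target mask having visited every
waypoint mask.  Arrivals are assigned to the nearest target-patch vertex;
counts cs are smoothed at 2 mm FWHM (sum-conserving), divided by the ns
samples sent per seed vertex, and log10-transformed.  Vertices still at zero
after smoothing have no defined score and are excluded (recorded); a
pseudo-count floor is available by configuration.  Per-voxel visit counts
thresholded at ≥100 samples give the path-distribution volume.

Phantoms: a straight bundle of x-oriented voxels joining two planar 1-mm
patches; a crossing with an orthogonal arm (0.5/0.5 fractions in the
overlap); and a disconnected control whose bundle is interrupted by ≥5
isotropic voxels.  In the pipeline the bundle tube (radius 3.5 mm) is
deliberately narrower than the 8×8 mm seed/target patches, so connectivity
has genuine spatial structure across the patch.

## Structure-function coupling

The headline statistic: across the vertices of a cluster, Spearman's ρ
between activation likelihood |log10 p| (higher = more likely active) and
connectivity score log10(cs/ns).  Ranks use average ties; the p-value comes
from the t approximation at n−2 degrees of freedom, with an exact
permutation option (automatic at n ≤ 10).  All p-values are Bonferroni
corrected for the number of tests performed.  Results are directed:
the profile seeded in A and evaluated on B's surface is correlated with B's
activation map, and vice versa — k clusters yield k(k−1) directed results.
ρ is always computed on raw vertices; equal-count bins (mean ± SEM
activation per connectivity bin) are produced for display only.

Paired map fixtures use a Gaussian copula: latent Pearson correlation
`2·sin(πρ/6)` gives a population Spearman correlation of exactly ρ, and any
monotone transform of the margins (here onto the |log10 p| and log10(cs/ns)
scales) preserves it.

## Pipeline defaults and problem sizes

The demonstration pipeline uses 36 morphs (252 s, 105 volumes at TR 2.4 s),
8 subjects, a 162-vertex icosphere, 200 permutations, and 2000 streamline
samples per seed vertex; it completes in well under five minutes on one CPU.
The planted effect amplitude (6 a.u. on a baseline of 100, noise SD 1,
AR(1) 0.3) was chosen by design efficiency: a no-rest morphing paradigm
retains little regressor variance after HRF convolution and mean removal,
and this amplitude puts the planted patches at comfortable but not
saturating group t-values.  Reference-scale values (120 morphs/350 volumes,
24 subjects/raters, 10^4 samples per seed) are used where the quantity under
test depends on them — exponent recovery and phantom tractography — and are
the generator defaults.

## Limitations

The synthetic data establish internal validity — that each stage recovers
what its generator planted, at correct error rates — not external validity
on real brains.  In particular: blob surrogates satisfy brightness constancy
almost exactly, unlike rendered faces; the icosphere lacks cortical folding,
so geodesic and smoothing behaviour is more homogeneous than on a real
surface; BOLD noise is AR(1) plus spikes, without physiological or motion
structure; orientation phantoms have known, well-separated fibers, so
tractography here does not probe the hard cases of real diffusion data; and
the planted structure-function link is monotone by construction.  Passing
tests therefore validate the machinery and its calibration, not the
neuroscientific conclusions one might draw from applying it to real data.
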