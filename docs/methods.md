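# Methods

This package reimplements, as a tested pipeline over synthetic data, the
analysis chain used to study how hippocampal CA1 place cells support two
dissociable components of spatial reorientation: **heading retrieval**
(recovering facing direction from the geometry of a rectangular chamber)
and **context recognition** (identifying which of two feature-distinct
chambers one is in). This note documents the models, the defaults and
why, the numerical choices, and what the synthetic data do and do not
show.

## The task being modeled

A disoriented mouse is placed in one of two rectangular chambers
(contexts A and B, 30 × 20 cm) distinguished only by non-geometric
features, and digs for a reward hidden in one of four corner cups. The
corners are labeled relative to the rewarded corner **C**: **G** is its
geometric equivalent (the corner related to C by the rectangle's 180°
rotational symmetry), **N** shares C's short wall, **F** shares its long
wall. Because a disoriented animal using geometry alone cannot tell C
from G, digs concentrate on the C/G diagonal; learning the features
shows up as C > G. Sessions are 12 trials/day alternating contexts, over
3 days.

## Rate maps

Trajectories are binned into 1 × 1 cm pixels (600 for the default
arena). Only movement epochs faster than 2 cm/s are used (forward-
difference speed per sample; events are assigned to the nearest
preceding trajectory sample and inherit its filter decision — events
during sub-threshold epochs are likewise excluded from mean firing
rates, a choice the pipeline makes explicit rather than guesses as
anyone else's). The activity map (summed event weights; unit weights for
spikes, positive weights for deconvolved calcium event likelihoods) is
divided by the time map and then smoothed with an isometric Gaussian
kernel (σ = 3 cm, sampled, truncated at 4σ). Pixels whose *smoothed*
occupancy reaches 0.05 s are sampled; others are NaN, never zero.

Division precedes smoothing; the rate is smoothed by **mask-normalized
convolution** (the kernel renormalized over the visited pixels under
it), so walls and unvisited regions do not bleed zeros inward, while the
occupancy map is smoothed by plain mass-conserving convolution.
Coordinates: origin at the arena's lower-left, x rightward, y upward,
row 0 at the bottom, half-open [k, k+1) cm bins.

## Rotation analysis and alignment

A rectangle has exactly two-fold rotational symmetry, so a disoriented
map can appear in either of two orientations. Two machinery layers deal
with this:

* **Best-match rotation** (per trial pair): each map is compressed to a
  square (bilinear, side = smaller dimension in bins, mask resampled
  fractionally with a 0.5 cutoff) and the rotation of one map among
  {0°, 90°, 180°, 270°} maximizing the pixel-to-pixel Pearson
  correlation wins. Correlations use jointly sampled pixels only;
  zero-filling would manufacture correlation at 180°. Ties break to the
  smallest angle — deterministic and conservative for alignment claims.
* **Rotation sequences** (per cell and day): each context's trial maps
  get a binary sequence (1 = rotated 180°) maximizing the **global sum
  of pairwise correlations** among aligned maps. "Maximal similarity for
  each pairwise comparison" is not achievable pairwise-independently, so
  the global objective is the coherent reading; it is solved exactly by
  enumerating the 2^(T−1) assignments (first trial fixed unrotated) for
  T ≤ 12 and by greedy bit-flip ascent beyond. The two contexts' average
  aligned maps are then registered to each other (context B rotated 180°
  iff that strictly improves its correlation with A, flipping every bit
  of B's sequence).

**Feature sensitivity:** the Pearson correlation between the average
aligned maps of the two contexts is the cell's context similarity; below
0.3 the cell is feature-sensitive (FS — it remaps across contexts),
at or above 0.3 feature-insensitive (FI). The boundary value 0.3 itself
is FI because feature sensitivity is defined strictly as "< 0.3". Cells
with undefined correlations (e.g. silent in one context) are excluded
and reported separately.

## Population and circular statistics

* **Population cosines:** stacking each cell's average aligned map per
  context, every pixel yields an across-cell rate vector per context;
  the cosine (normalized dot product) between the two vectors measures
  population-level context similarity at that pixel. Zero/undefined
  vectors exclude the pixel, counted.
* **Center-out angles:** the CCW angle (0° = +x) from the arena center
  to the rate-weighted center of mass of the full smoothed map. No field
  segmentation is applied by default (none is defined for this
  analysis); a ≥ 50%-of-peak threshold variant is exposed as an option.
  Across-context differences use the feature-anchored frame the
  generator provides and always subtract the context-B map.
* **6° histograms:** difference distributions use 60 bins of 6°
  **centered on multiples of 6°** (the first bin covers [357°, 3°)).
  Centering is this package's choice: modes sit at the geometrically
  meaningful 0° and 180°, and edge-anchored bins would split each mode
  across two bins by construction, halving modal-bin mass.
* **Angle doubling and Rayleigh:** θ → 2θ mod 360° collapses
  180°-bimodal samples into unimodal ones ("folded" is read as exactly
  this doubling; no second fold). The Rayleigh statistic Z = nR̄² uses
  the standard small-sample corrected p-value
  `p = exp(−Z)·(1 + (2Z − Z²)/4n − (24Z − 132Z² + 76Z³ − 9Z⁴)/288n²)`,
  clipped into (0, 1]. The test's type-I error is calibrated at 5% ±
  1.5% under a uniform null in the test suite.

## Decoding

All decoders are leave-one-out cross-validated, deterministic, and built
on a linear max-margin classifier (scikit-learn `SVC`, linear kernel,
C = 1.0 exposed in config). The "empirical prior" is realized by unit
per-sample weights: class influence is proportional to training-fold
class frequency. If a training fold loses a class the held-out trial
receives the fold's majority label, flagged.

* **Heading from rotation sequences:** one feature per cell per trial
  (the rotation bit), labels C vs G dig side; N/F trials are excluded.
  Constant (all-zero) sequences contribute constant columns and are
  retained.
* **Context from firing location:** per held-out trial the per-cell
  context averages are rebuilt without it and the context whose average
  population maps have the higher mean per-pixel cosine with the
  held-out maps wins; exact ties predict context A, flagged.
* **Context/heading from rates:** per-trial mean firing rates feed the
  same SVM; the context variant uses only trials with C or G digs
  (trials in which the animal identified the context). Rate-difference
  matrices (trials × trials, |MFR_i − MFR_j|) summarize rate remapping
  within vs across context.

A caveat documented because it surprises: leave-one-out with
(near-)balanced classes is *pessimistically* biased under the null —
removing the held-out trial makes its class the training minority and
the empirical prior leans the other way — so null accuracies sit below
0.5 (≈ 0.34 at 4+4 trials). Chance-level claims in the tests are
therefore made against permutation nulls, not against a nominal 0.5.

## Behavior: Bayes factors

Per animal and day, dig outcomes are Bernoulli with likelihood
θ^z (1−θ)^(N−z). Two model pairs: the **C model** (success = dig in C;
chance θ₀ = 0.25, learned θ ~ Uniform(0.25, 0.9)) and the **C/G model**
(success = dig on the correct axis, i.e. C or G; chance θ₀ = 0.5,
learned θ ~ Uniform(0.5, 0.9)). The learned model's marginal likelihood
`(1/(b−a)) ∫_a^b θ^z (1−θ)^(N−z) dθ` is evaluated in closed form via the
regularized incomplete beta function
(`B(z+1, N−z+1)·[I_b − I_a]/(b−a)`); adaptive quadrature is retained as
an internal cross-check and the two agree to 1e−8 relative over N ≤ 50.
Animals multiply: the group BF is the product of individual BFs
(accumulated in log space), with natural-log thresholds ±log 3 ≈ ±1.1
for substantial evidence.

## The synthetic-session generator

The generator emulates the statistical structure the analyses assume;
its defaults are the study conditions and are fixed:

| parameter | default | rationale |
|---|---|---|
| arena | 30 × 20 cm | task chamber; 600 pixels at 1 cm |
| days × trials | 3 × 12, alternating A/B | session structure |
| cells | 200 (15% FS) | a typical recorded population; FS minority |
| trial duration | 180 s at 30 Hz | minutes-long foraging trials |
| trajectory | OU velocity, τ = 1 s, σᵥ = 8 cm/s/comp., wall reflection | mean speed ≈ 10 cm/s, ~4% of samples below the 2 cm/s filter, ≥ 80% bin coverage in 120 s |
| fields | Gaussian, σ = 4 cm, peak 12 Hz, baseline 0.1 Hz | CA1-like tuning; ~350 in-field events/trial |
| rate heterogeneity | log-normal, σ_log = 0.3 | realistic rate spread |
| orientation bit | fair coin per trial | disorientation in a 2-fold-symmetric box |
| coupling ρ | 0.8 | orientation predicts dig side well but not perfectly |
| rate remapping | per-cell log-gain ±g_d in context B, g = (0.1, 0.25, 0.4) | across-context rate differences grow with experience |
| dig schedule | day 1 (.40,.38,.12,.10); day 2 (.62,.16,.12,.10); day 3 (.68,.12,.10,.10) | geometry-only digging early, feature use later |

Key structural choices:

* The latent orientation is a **trial property shared by all cells**
  (the whole map rotates coherently), rotating every field 180° about
  the arena center. FI cells share one template across contexts; FS
  cells get an independently placed context-B template, redrawn until
  ≥ 8 cm from both the context-A center and its 180° image — otherwise
  "remapping" could be confounded with a geometric rotation.
* **Dig coupling:** on C/G draws, with probability ρ the latent
  orientation dictates the dig side (orientation 0 → C, 1 → G);
  otherwise the multinomial draw stands. ρ = 0 is independence, ρ = 1
  deterministic coupling; the match probability among C/G digs is
  (1 + ρ)/2 under fair orientations. The chance-decoding check uses
  ρ = 0 together with the day-1 dig schedule on all days, because a
  non-learning animal digs C and G equally — that balance is what makes
  0.5 the chance accuracy.
* Events are an inhomogeneous Poisson process along the trajectory
  (thinning against the peak rate); calcium-like data use Gamma(2, ½)
  event weights (mean 1), spikes unit weights, so one code path serves
  both modalities.
* All randomness derives from one seed through spawned generator
  streams; a fixed seed reproduces the dataset byte-for-byte.

What the generator does **not** emulate: theta phase and temporal
spiking structure, speed/direction tuning, calcium indicator dynamics
and imaging noise, cross-day field drift, behavioral idiosyncrasies
(wall hugging, corner sampling strategies), and inter-animal
variability in neural parameters. Passing recovery tests therefore shows
the *analysis chain* is correct and well-calibrated on data with the
assumed structure — not that real recordings satisfy those assumptions.

## Problem sizes used by the tests and the reproduction script

Parameter-recovery runs use the full default conditions (200 cells,
3 × 12 trials). Oracle equivalences run on deliberately small instances
where brute force is exact: alignment against exhaustive enumeration
over all 2^T assignments (1000 random instances, T ≤ 8), rate maps
against nested-loop convolution on ≤ 10 × 10 grids (1e−10), Bayes
factors against quadrature for every z with N ≤ 50 (1e−8 relative).
Rayleigh calibration uses 2000 replicates of n = 100 uniform angles.
Chance-level decoding is bracketed by 200-permutation nulls.

## Known limitations

* The center-out modal-bin concentration of FI cells is sensitive to
  center-of-mass jitter: with ~350 events/trial the per-map COM jitters
  a few millimeters (2–4° at typical field eccentricities), and fields
  near the arena center have ill-conditioned angles, so the two 6° modal
  bins hold ≈ 58–60% of across-context mass under the default
  conditions rather than a comfortable majority. The bimodality itself
  is unambiguous (Rayleigh on doubled angles, p ≪ 1e−100).
* Location remapping leaks into the rate code: an FS cell's two field
  positions sample the animal's occupancy differently, so its mean
  firing rate differs between contexts even with identical gains. A
  pure rate-code null therefore requires an all-FI population, not just
  zero gain difference; the tests construct it that way.
* The greedy alignment fallback (T > 12) is a local ascent; it can stop
  below the exact optimum (tests verify it never exceeds it).
* `longitudinal_partition` consumes an externally produced cross-day
  registration table; registration quality is outside this package.
* Because the latent orientation is a fair coin on every trial (pure
  disorientation, by design) and strong coupling makes C/G digs follow
  it, the generated dig pattern keeps C ≈ G on later days even though
  the configured corner probabilities favor C; the learning signal in
  the generated behavior is carried by the declining N/F rate and the
  axis preference. Real animals that learn feature-corrected headings
  show C > G, which this generator deliberately does not emulate.
* Decoding accuracies at 10–12 trials/session are coarse-grained
  (steps of ~0.1); session-level comparisons should pool days or
  animals, as the provided helpers do.
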