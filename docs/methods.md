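# Methods

This note documents the models and procedures behind each pipeline stage,
the parameters that matter, what the synthetic generators emulate (and do
not), the numerical choices, and known limitations.

## Synthetic data: what the generators emulate

The generators define the study conditions under which every stage is
validated. They produce the *inputs* the analysis stages consume —
localization tables, trajectory tables, images, voltage traces — never the
analysis outputs, so passing recovery tests demonstrates that the stage
recomputes truth from raw-format data.

**SMLM fields.** Cluster centers uniform in a 10 × 10 µm field; emitters
uniform in discs of radius 20 nm around centers; background emitters a
homogeneous Poisson field (default 0.4 emitters/µm²). Each emitter blinks
for a geometric number of consecutive frames (default mean 2, the simplest
model that exercises blink correction), and each detection is jittered by
isotropic Gaussian localization error (default sd 10 nm, matching the
rendering kernel; the true precision distribution of an SMLM experiment is
instrument-dependent, so it is a parameter rather than an asserted value).
The default of ~60 expected detections per cluster against this background
yields fields in which roughly 85–90 % of detections fall inside DBSCAN
clusters, the regime the cluster-fraction readout operates in. Not
emulated: drift, anisotropic PSFs, emitter re-activation after dark times
longer than one frame, and structured (cell-shaped) background — so the
recovery results bound performance under idealized blinking only.

**Trajectories.** A hidden Markov chain per particle, initialized from the
stationary distribution of the transition matrix (steady-state assumption)
and evolved per 20 ms frame; displacement components are Gaussian with
variance 2·D·dt. Localization noise on positions defaults to 0 because the
inference model treats displacements as pure Brownian steps; a Gaussian
position-noise option exists for robustness experiments (enabling it
correlates successive displacements, which the HMM does not model — a
deliberate mismatch for stress testing). Defaults for multi-state
simulations are D = {0.01, 0.1, 1.0} µm²/s with self-transitions 0.98
(mean dwell 50 frames), i.e. well-separated membrane-bound vs diffusing
regimes at 50 Hz imaging.

**Two-channel images.** Gaussian puncta (σ = 1.5 px, amplitude 26 counts)
on Poisson background (rate 10), giving peak SNR ≈ amplitude/√background ≈
8. `round(overlap_fraction · n_a)` channel-A puncta share centers (≤ 1 px
jitter) with channel-B puncta. Same-channel centers keep a minimum mutual
distance (default 8 px at σ = 1.5) so true puncta are resolvable, and
unpaired cross-channel centers stay ≥ 5σ apart; with these constraints the
generator's overlap fraction is the ground-truth colocalization rate, which
is what lets colocalization recovery be scored to ±0.05. Real fields
violate both constraints (clumped synaptic puncta, chance overlap), so
measured colocalization on real data includes a chance component the
generator deliberately excludes.

**MEA traces.** White Gaussian noise (the recordings' noise spectrum is
not characterized; band-limited noise would only lower the effective
threshold) with homogeneous Poisson spike trains per channel; each spike
adds a biphasic template (1.6 ms, sharp negative lobe then slower positive
rebound) scaled to 12 noise sd by default. Overlapping templates sum
linearly and both spikes stay in the ground truth — the detector's dead
time, not the generator, decides what is resolvable. A forced
`spike_times_s` override supports constructed collision tests. Not
emulated: bursts, electrode cross-talk, amplitude variability, drift.

All generators draw from one local `numpy.random.Generator` per call;
identical seeds give byte-identical outputs.

## SMLM cluster analysis

*Blink correction.* Detections are chained greedily in frame order: a
detection extends an open chain if its frame is within `max_frame_gap`
(default 1, i.e. strictly consecutive) of the chain's last frame and lies
within `merge_radius_nm` (default 20 nm, twice the pointing accuracy) of
the chain's running centroid; each chain collapses to its centroid at its
first frame. The pass repeats to a fixed point, which makes the operation
idempotent even in the rare configurations where a single greedy pass
leaves two mergeable chains.

*DBSCAN.* Density threshold: ≥ 20 detections within 20 nm, with the point
itself counted (the common inclusive formulation). Neighbor search uses a
k-d tree; results are identical to brute force by construction and are
checked against an independent O(n²) oracle in the tests. Determinism and
permutation invariance come from a canonical tie-break: points are ranked
by (frame, x, y), cluster ids follow the rank of each cluster's first core
point, and border points reachable from several clusters join the lowest
id.

*Metrics.* Cluster area is the convex-hull area of member localizations —
the simplest consistent estimator for comparing area distributions;
clusters with < 3 points or collinear points get area 0 with a degeneracy
flag. Field density normalizes by the full field area by default (an ROI
option would be needed for per-cell normalization of real images).

*Rendering.* Localizations are binned at 10 nm/px and convolved with a
normalized Gaussian (σ = 10 nm, truncated at 6σ so per-kernel mass error is
< 10⁻⁸). Total image mass equals the localization count except for edge
truncation, which is flagged when any localization lies within 6σ of the
field border.

## Diffusive-state HMM

Observation model: displacement r_t ∈ ℝ² with components iid
𝒩(0, 1/λ_k) given hidden state k, where 1/λ_k = 2·D_k·dt. Conjugate
priors: Gamma(a₀, b₀) on each λ_k with a₀ = 1 pseudo-displacement and mean
1/(2·D_prior·dt), D_prior = 0.1 µm²/s; Dirichlet on each transition row
with self pseudocount `prior_dwell_frames − 1` = 49 and total off-diagonal
pseudocount 1 split evenly (prior mean dwell 50 frames = 1000 ms at
20 ms/frame); flat Dirichlet on the initial distribution.

Inference is standard mean-field VB-EM: forward–backward with
expected-log ("tilde") parameters exp(E[ln π]), exp(E[ln A]),
E[ln λ] − ln 2π − E[λ]‖r‖²/2, followed by conjugate posterior updates.
The evidence bound is the summed log normalizer of the scaled forward pass
minus the Dirichlet and Gamma KL divergences; it is provably non-decreasing
per iteration and asserted as such in the tests. Sequences are grouped by
length and processed as batched arrays, so cost is linear in total steps.

Numerical choices: convergence when the bound improves < 10⁻⁶ nats per
displacement step (max 500 iterations); responsibilities are initialized
from randomized 1-D k-means on squared step lengths; each of the
`n_restarts` (default 10) initializations runs a 50-iteration pilot and
only the best-bound restart continues to convergence (per-run monotonicity
is unaffected; this cuts the cost dominated by overfit K on simple data).
The reported D_k is 1/E[λ_k] rescaled by 2·dt, which reduces to the
closed-form estimator mean(‖Δr‖²)/(4·dt) as data dominates the prior
(within 2 % at 10⁵ steps, verified). States are sorted by increasing D so
output is invariant to restart label permutations. All-zero displacement
data is flagged degenerate and D floored at 10⁻¹² µm²/s.

Model selection fits K ∈ {1, 2, 3} and picks the largest evidence bound;
differences under 0.1 nat break toward smaller K (parsimony). Occupancy is
reported as mean posterior state mass over all steps (default) alongside
the stationary distribution of the posterior-mean transition matrix; the
two differ when the data are not yet equilibrated. The variational
approach here is derived from the standard conjugate update equations for
this emission family; acceptance is parameter- and model-order recovery on
simulations, not numeric equality to any particular implementation.
Localization error is excluded from the emission variance by default; a
static-error term is a known omission (see limitations).

## Puncta segmentation and colocalization

The à-trous transform smooths with the B3-spline kernel [1,4,6,4,1]/16,
dilated ×2 per scale (reflective boundaries); detail plane j = c_{j−1} −
c_j. Detection uses the scale-2 plane (spot-sized structures for σ ≈ 1.5 px
PSFs), thresholded at k × robust noise sd, with sd = MAD/0.6745 of the
plane. Components are 8-connected; those under 4 px are removed;
per-structure intensity is always summed from the *original* image under
the mask (asserted exact in tests).

The default k = 4.0. On a 512 × 512 field the scale-2 plane is spatially
correlated, so a 3σ threshold leaves ~6–11 supra-threshold noise
components of ≥ 4 px per field; 4σ reduces the expected false-structure
count to ≈ 0 while leaving detection of SNR ≥ 8 spots at 100 %, whose
plane response is far above either threshold. Both k and the scale are
configurable.

Colocalization: an A structure is colocalized iff it shares ≥ 1 pixel with
any B structure (whether 1 shared pixel suffices is recorded in output
metadata as the package's convention); an opt-in "apposition" mode also
counts centroid distances ≤ 2 px. The endocytosis readout is the same
overlap rule: green structures with red (surface-marker) overlap are
surface; green-only structures are internalized; zero green structures
makes the fraction undefined and flagged, and surface + internal always
equals total.

## MEA analysis

High-pass: 4th-order Butterworth at 300 Hz applied forward and backward
(`sosfiltfilt`), i.e. zero-phase, 8th-order magnitude response; verified
against transfer-function oracles (1 Hz attenuated > 100×, 1 kHz passed
within 5 %). Spike detection estimates the noise sd robustly as
median(|x|)/0.6745 — a plain-sd mode exists, but spikes inflate the plain
estimator, which would raise the threshold on active channels — and takes
each contiguous |x| > 6σ excursion as one event timed at its absolute
peak, with a 1 ms dead time (absolute refractory scale) suppressing
follow-on crossings; both polarities merge into one event stream. At
±6 sd the Gaussian tail predicts ≪ 1 false crossing per 10-min channel.

Rates: spike count / 600 s; channels strictly below 0.1 Hz are flagged
nonspiking and excluded from the network mean (exactly 0.1 Hz is kept).
The longitudinal readout is ratio-based and control-anchored: per plate
r = rate(DIV21)/rate(DIV14), normalized by the mean r over control plates,
so controls average 1 by construction; plates with zero baseline are
excluded with a flag. The exact normalization formula is recorded in
output metadata since ratio-of-rates vs difference-based definitions
diverge for large changes.

## Statistics

Group contrasts use the two-sided Mann–Whitney U test: exact null
distribution for min(n) ≤ 8 without ties (verified against exhaustive
enumeration), normal approximation with tie correction otherwise. No
multiple-comparison correction is applied by the utility; callers doing
many contrasts should correct downstream.

## Pipeline reproducibility

Configs are validated in full — unknown stages, unknown parameters, and
non-positive values of strictly positive parameters are rejected — before
any stage runs. One global seed expands to per-stage seeds through
`numpy.random.SeedSequence(seed).spawn(i)` in stage order, so inserting a
stage changes downstream seeds but nothing upstream. The resolved config,
per-stage provenance (package version, seed, parameters), and a log are
written next to the outputs; metric files contain no timestamps and are
byte-identical across reruns of the same config and seed.

## Problem sizes used in validation

Recovery checks run at sizes chosen to make the statistical tolerances
meaningful at desk scale: 50 random fields for the DBSCAN oracle and 50
seeded fields for cluster recovery; 10⁵ displacements for the closed-form
HMM limit; 20 seeds × 5,000 ten-step trajectories for three-state
parameter and model-order recovery (with 5 restarts per fit); 20 seeds ×
100 puncta for segmentation/colocalization; and one 60-channel, 10-min,
10 kHz recording for MEA sensitivity. The acceptance script uses the same
conditions at somewhat smaller seed counts and reports the size (`n`)
beside every value.

## Known limitations

- Blink correction merges distinct emitters that overlap within the merge
  radius in consecutive frames; at the simulated densities this is rare
  but it biases detection counts at very high emitter density.
- The HMM assumes pure Brownian states, no localization error in
  displacements, a shared transition matrix across all trajectories, and
  steady state; anomalous diffusion or per-trajectory heterogeneity will
  be absorbed into extra states or biased D values.
- Segmentation operates on single 2-D planes; axial structure and
  deconvolution are out of scope, and percent-area uses the full field as
  denominator unless an ROI is supplied.
- Spike analysis stops at per-channel rates: no spike sorting, bursting,
  or synchrony measures.
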