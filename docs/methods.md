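# Methods

This note documents the models, estimators, and numerical choices behind
`plinet`, and what the synthetic-data tests do and do not establish about
real recordings.

## Phase lag index

For two narrowband signals with analytic-signal phases φ_a, φ_b, the
phase lag index is PLI = |⟨sign Δφ(t_k)⟩| over the samples of one epoch,
with Δφ wrapped to (−π, π] before the sign and sign(0) = 0.  Wrapping
first makes the statistic symmetric in its arguments; the sign makes it
blind to amplitude and to any phase relation symmetric around zero —
in particular to instantaneous (zero-lag) linear mixtures of a common
source, the usual volume-conduction confound.  Matrices are computed per
epoch and then averaged per subject/condition/band; the estimator is the
epoch-mean of per-epoch PLI, not the PLI of pooled samples.

Under independence the per-epoch PLI is the absolute mean of n sign
values, E|PLI| ≈ √(2/(π n_eff)), where n_eff is the number of effectively
independent signs.  Averaging across epochs shrinks the variance of this
floor but not its mean, so the null level is set by the *within-epoch*
phase decorrelation rate: broadband signals at 2048 samples sit near
0.02–0.07, while a delta-band (0.5–4 Hz) series at 2 s epochs decorrelates
only a handful of times and its null PLI is ~0.2–0.3.  That band-dependent
floor is a property of the statistic at this epoch length, not an
implementation artifact; contrasts between conditions subtract it out.

## Band filters and phase extraction

Band filters are linear-phase Kaiser-window FIRs, identical across
channels, designed with a transition width of 25% of the band width
placed *outside* the nominal band (cutoffs at low − tw/2, high + tw/2)
so band-edge tones pass at near-unity gain.  The default stopband
attenuation is 20 dB, the largest value for which every canonical band —
including low-alpha, 8–10 Hz — fits a 2048-sample epoch; attenuation one
octave outside any band exceeds this by the window's sidelobe decay.
Filtering is single-pass with group-delay compensation (`mode="same"`
with an odd symmetric kernel); because the same kernel is applied to
every channel, phase *differences* are unaffected by this choice, which
is fixed purely for reproducibility.  Half the filter length is trimmed
from each end of the phase series before the PLI so filter edge
transients never enter the statistic.  Instantaneous phase is the angle
of the Hilbert analytic signal, mapped to (−π, π].

The broadband preprocessing filter reproduces a 0.5–45 Hz Kaiser design
(β = 5.65) at 4530 taps, adjusted to 4531 so the kernel is exactly
type-I linear phase.  "Amplitude change" for artifact rejection is
within-epoch peak-to-peak per channel; epoch windows are half-open
[start, end), tiled from the start of the recording.

## Source estimation

The inverse stage is a deliberately minimal standardized minimum-norm
operator on a user-supplied lead field L (scalar dipoles, identity noise
covariance): K = Lᵀ(LLᵀ + λμI)⁻¹ with λ expressed relative to the mean
eigenvalue μ of LLᵀ (default 0.1), standardized per voxel by the square
root of the resolution-matrix diagonal (the sLORETA construction, which
gives zero localization error for noiseless point sources — verified by
brute force in the tests).  With λ = 0 the Moore–Penrose pseudo-inverse
is used and a rank-deficient lead field is an error.  Voxel estimates
are averaged within each ROI.  No head modelling, anatomy, or electrode
geometry is included; the bundled 44-ROI table (2 × 22 labelled parcels
with lobe assignments) carries labels only.  The ROI count is
configurable because the parcel count is a free parameter of the
analysis, with 44 as the default.

## NBS contrast

Edge-wise statistics are paired F values, F = n·mean(d)²/var(d) for the
per-subject condition differences d, identical to the squared paired t.
For each threshold on the F grid (default 3 to 10 in steps of 0.1) the
supra-threshold graph's largest connected component is measured in
edges; the null distribution of the maximal component size is built by
flipping each subject's condition assignment (sign flips of d), either
n_perm random draws or the full 2ⁿ enumeration.  A per-threshold p value
is the proportion of permutation maxima at least as large as the
observed size.

Because a network reported at "the highest threshold that reaches
significance" involves a search over the threshold family, declaring
significance whenever *any* per-threshold p ≤ α would not control the
family-wise error at α.  The reported `p_fwe` is therefore the
Westfall–Young min-p adjustment: the proportion of permutations whose
own minimal per-threshold p is at most the observed minimal p, floored
at 1/n_perm (the resolution of the permutation distribution).  Simulated
at study scale (25 subjects, 20 ROIs, 1000 permutations, 200 null
replicates) this rejects in 2.5% of null datasets and recovers a planted
6-edge component with recall 1.0 — both asserted in the test suite.

"Largest fully connected network" is read as largest connected
component, the standard NBS statistic; a strict clique reading is
available via `ContrastSpec(clique=True)` but off by default, since
sparse tens-of-edges networks over dozens of nodes are not cliques.
Component size is measured in edges; reported networks are truncated to
`max_edges` (default 50) by descending F, ties broken by ROI pair.
Edges with an exactly zero mean difference are assigned to the A>B
subnetwork when splitting by direction (a measure-zero case in
continuous data).  Each band is tested as its own family; no cross-band
correction is applied.

## Behavioral scoring

Responses are assigned to the event with the latest onset among those
whose 0–5000 ms window covers them (a response is most plausibly caused
by the most recent event); window ends are inclusive.  Reaction times
are trimmed at the 5th/95th percentiles of the pooled task-level
distribution — pooling across subjects and conditions, as implied by
task-level cutoffs — rejecting only strictly outside values so
degenerate distributions retain everything.  d′ uses inverse-normal
quantiles with the 1/(2N) correction for rates of 0 or 1.  The
distractor ratio is FA/(FA + other non-target responses); the
alternative literal reading FA/(non-target responses excluding FA) is
available via `denominator="other_only"` because the two definitions
cannot be reconciled from the task description alone.  Recognition
scoring excludes items with pooled accuracy above 95% or below 30%
(chance on 4-alternative items being 25%) and answers attributed to
outside knowledge, then reports percent correct; no surviving items
yields a missing value.

## Correlation with behavior

Network strength is the mean PLI over the significant network's edges,
per subject.  Each behavioral family is tested by permuting the strength
vector jointly against all variables (one shuffle per permutation, which
preserves the inter-variable correlation structure), taking the maximal
absolute Pearson r per permutation, and reporting per-variable
p_fwe = #(max |r| ≥ |r_obs|)/n_perm.  No +1 smoothing is applied by
default (`add_one=True` switches to the (k+1)/(n+1) convention).  The
maxT construction guarantees p_fwe ≥ the unadjusted permutation p and
collapses to it for a family of one.

## Synthetic data generator

Each ROI's band signal is a unit-amplitude cosine whose frequency is
drawn uniformly inside the band (fresh per epoch) with a uniform initial
phase; white Gaussian noise of sd `noise_sd` (default 0.3) is added.
A planted edge (i, j, lag, κ) replaces ROI j's phase by
φ_i(t) + lag + ε(t), where ε is a zero-order hold of i.i.d. von
Mises(0, κ) draws refreshed every `jitter_ms` (default 64 ms).  The hold
preserves the von Mises marginal exactly, so the planted PLI has the
closed form |E sign(sin(lag + ε))| and can be checked against a
brute-force Monte-Carlo oracle, while the jitter stays slow relative to
the carrier and keeps >80% of signal power inside the nominal band.  A
smoothed (filtered) jitter would look more physiological but destroys
the von Mises marginal and with it the analytic check; the hold is the
deliberate trade-off.  If several planted edges name the same follower,
the last edge in list order wins; simple chains (a→b→c) resolve
transitively and accidental cycles are broken at the smallest ROI index.

Seeding is hierarchical: every stream derives from the global seed plus
CRC-32 hashed entity tags (subject, condition, band), so enlarging the
subject list never reshuffles existing subjects, and any run is
bit-reproducible from its config.

Defaults mirror the recording design the pipeline targets: 25 subjects,
44 ROIs, 95 epochs of 2048 ms per condition at 1 kHz.  The generator
exposes a fixed `epochs_per_condition` rather than modelling the
heterogeneous artifact-rejection counts of real sessions; it also omits
speech-envelope entrainment, blinks/line noise, realistic head geometry,
and amplitude dynamics (PLI is amplitude-blind, so amplitude structure
would be untestable through this statistic anyway).  Tests passing on
this generator therefore establish the *statistical* correctness of the
estimators and their error control — not robustness to physiological
artifacts, nor anything about specific cortical systems.

The simulated event logs use a fixed-probability observer (hit rate
0.85, false-alarm rate 0.1, Gaussian RTs truncated at 50 ms), enough to
exercise the scoring rules end to end; behavioral scores correlated with
network strength are generated directly as
r·z(strength) + √(1−r²)·noise, which makes the population correlation
equal to the requested r.

## Problem sizes in the shipped drivers

The `analysis/` drivers run 8 subjects × 8 ROIs × 16 epochs at 500 Hz
with an exact 2⁸ sign-flip null — sized so the full seven-stage chain
reruns in seconds while still recovering its planted network.  The test
suite establishes the statistical guarantees at study scale (n = 25
subjects, 20 ROIs, 1000 permutations, hundreds of replicates).  The
permutation count for simulation studies is 1000 rather than the 10000
used for single confirmatory analyses; with hundreds of replicates the
Monte-Carlo error of a 1000-permutation p value is negligible relative
to the binomial envelope being tested.

## Known limitations

- The delta-band null PLI floor at 2 s epochs (~0.2–0.3) means absolute
  connectivity values are not comparable across bands; only contrasts
  and correlations are interpreted.
- The inverse stage is a linear-algebra stand-in: with a random dense
  lead field it demonstrates the operator algebra and the
  zero-localization property, not anatomical accuracy.
- Permutation p values without +1 smoothing can be marginally
  anti-conservative (≈ +1/n_perm); the smoothed convention is available
  everywhere by flag.
- The event-log observer does not model attention-condition differences
  in behavior; behavioral contrasts are exercised structurally, not
  calibrated to human performance.
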