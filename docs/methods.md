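# Methods

## Event definition

Events are maximal runs of samples strictly above a threshold; samples
equal to the threshold terminate a run ("exceeds" is read strictly).  Size
integrates the excess area by the rectangle rule, s = Δt·Σ(x−θ), in units
of signal value × seconds; duration is Δt × run length.  Runs touching the
recording boundary are kept — discarding them would bias the tail of the
duration distribution — and events whose area is numerically zero are
dropped.  The default threshold is the median of the entire series, which
makes the definition parameter-free and robust to slow drifts in scale.

For model output, group means are computed from integer spike counts and
divided once at the end, so equal counts produce bit-identical floats; a
running weighted average instead leaves ~1e−16 rounding noise that shows up
as spurious sub-threshold "events" sixteen decades below the real ones.

## Power-law range algorithm

1. **Outlier exclusion.** Sizes are sorted; consecutive log10 gaps are
   compared with 3% of the total range in decades.  Extreme samples are
   peeled one at a time, from each end inward, while the gap separating the
   current extreme from its inward neighbour exceeds the threshold (the
   threshold itself is fixed by the raw data's full range).  Interior gaps
   never remove interior samples, and blocks of duplicated values — the
   normal situation at the quantized head of a population-mean size
   distribution — are never treated as outliers because a duplicate's
   adjacent gap is zero.  Note that an *arithmetically* dense head such as
   {1, 2, 3, …} is log-sparse: the 1→2 gap is 0.3 decades and is peeled
   when the total range is short.  This is the intended conservative
   behavior of the rule, not an accident.
2. **Truncation.** s_max is fixed at the largest remaining size; it is not
   a fitting parameter.
3. **Exponent.** τ maximizes the truncated log likelihood on the grid
   0.7–2.0 in steps of 0.02, using the continuous density
   p(s) = C·s^(−τ), C = (1−τ)/(s_max^(1−τ)−s_min^(1−τ)) (log form at τ=1).
   Ties resolve to the smaller exponent.  Sizes are continuous areas, so no
   discrete correction applies.
4. **Goodness-of-fit.** F is the fraction of the real data's empirical CDF,
   resampled at 10 log-spaced points per decade with linear interpolation,
   that falls inside the pointwise min/max envelope of 500 surrogate CDFs
   drawn from the fitted law.  The strict min/max envelope (not a
   percentile band) makes F generous exactly where sample size is small,
   and F = 1 means the whole candidate interval is consistent with a
   perfect power law at this n.
5. **Range.** Candidate s_min values ascend from the smallest size in 10
   log-spaced steps per decade (so r has 0.1-decade resolution); the first
   candidate passing F ≥ 0.8 wins.  Candidates leaving fewer than 30
   in-range samples are skipped — the MLE is unstable below that — and
   degenerate inputs return r = 0 rather than erroring.  The default
   criterion F = 0.8 sits mid-way in the band (0.75–0.9) over which the
   qualitative conclusions should be robust, and is exposed as a parameter.

Surrogate generation uses inverse-CDF sampling.  Internally the surrogate
CDF envelope is built from *sorted* uniforms generated by exponential
spacings in single precision — distributionally identical, avoids 500
per-candidate sorts, and resolves CDFs far below the 1/n level that
matters.  The public sampler returns unsorted double-precision draws.

**Exponent uncertainty.** Surrogate datasets are binned at 10 log bins per
decade; the 10th–90th percentile band of their PDFs gives envelope
boundaries whose least-squares log-log slopes bracket the exponent.  The
reported error bar is half the absolute slope difference; the absolute
value is taken because with finite surrogates either boundary can be the
steeper one.  At n = 1000 over three decades this yields ≈ 0.08, matching
the magnitude of error bars quoted for comparable event counts, and it
shrinks roughly as n grows (0.15 → 0.08 → 0.02 for n = 10², 10³, 10⁴).

## Scaling relations

α is fit by the same truncated MLE applied to the durations of events whose
*sizes* lie inside the size power-law range, with truncation at the min and
max of those durations; β is the ordinary least-squares slope of
log10 S on log10 T for the same events (raw events, not binned means —
binning would weight the sparse tail arbitrarily).  Restricting all three
exponents to one event population keeps the crackling-noise comparison
β vs (α−1)/(τ−1) internally consistent.  The prediction is refused within
|τ−1| ≤ 1e−6, where it diverges.

## Preprocessing

Neural traces are z-scored (population SD, divisor n, so the operation is
exactly idempotent) and then low-pass filtered with a zero-phase 2nd-order
Butterworth at 0.2 Hz (forward–backward, reflective padding of
3·(order+1) samples).  The filter-then-z-score order is available as a
switch; the default follows the order in which the two steps are naturally
listed for calcium data.  Behavioral channels are used raw: their events
are defined relative to the unprocessed median.

## Subset search and time-shift nulls

A subset is the k = 50 neurons most Pearson-correlated with a seed neuron
(seed excluded by default; an `include_seed` switch exists because either
convention is defensible), averaged after per-neuron z-scoring; events are
extracted from that raw average without re-z-scoring.  "Canceling" subsets
take the 25 most correlated plus 25 most anticorrelated neurons.  The
control pipeline applies the identical analysis to a matrix whose rows are
independently cyclically rotated by uniform shifts in [0, T) — single-row
statistics are preserved exactly while cross-row timing is destroyed.  One
surrogate matrix is built per search, mirroring how the controls define a
per-recording null distribution of ranges.

In the event-specific analysis, each behavioral event window (≥ 3 samples)
is correlated with every subset series and with n_controls = 1000 shifted
copies (shifts drawn from [1, T): a zero shift would reproduce the real
window and is no control at all; controls cycle over subsets so each event
gets its own null).  A subset is *strong* for an event when its real
correlation strictly exceeds the ⌈0.999·n_controls⌉-th control order
statistic, making the chance expectation of the strong count 1 per event;
an event is *significant* when the count exceeds 4.  The fraction of
behaviorally-active time inside significant events summarizes the linkage.

## Winner-take-all model

Binary neurons update synchronously with firing probability
clip(η + Σ C_ij s_j, 0, 1) — the activation is "proportional to the summed
input", and clamping to [0,1] is the minimal way to make proportionality a
probability.  Wiring is block-Bernoulli: per ordered group pair the density
is 0, 5% or 50%; nonzero weights are +c from excitatory and −c from
inhibitory sources; the diagonal is zeroed (no self-connections); and the
whole matrix is rescaled so its largest positive real eigenvalue equals Λ.
Runs start all-quiescent and discard a 1000-step burn-in.

The drive η is the model's least constrained parameter.  The package
defines its sweep as η ∈ logspace(−1.5, −0.5): below ≈ 0.01 the network is
too sparsely active for the competitive mode to engage (group correlations
near zero), while within the band the canonical circuit at Λ = 1 shows the
full phenomenology — corr(e+,e−) < −0.5, corr(i+,i−) < −0.5, e-group
power-law range > 3.5 decades, total-population range < 2 — robustly
across seeds.  The canonical operating point is the sweep midpoint
η = 10^(−1.5/2−0.5/2…) = 0.1.  Switching is quantified as sign changes of
the e+ − e− group-mean difference per 10⁴ steps: winnerless competition
flips the sign constantly (rate ~10²), while for Λ ≳ 1.05 the difference
pins to one side and the rate collapses to ~0.  Far above Λ ≈ 1.2 both
groups saturate and the difference is pure noise again; the phase claim is
about crossing the boundary, not the saturated far field.

Ensemble exponents (τ, α, β) are averaged over the 21-point grid
η ∈ logspace(−1.5, −0.5, 7) × Λ ∈ {0.99, 1.0, 1.01}, keeping points whose
e+ range exceeds 3 decades; e+ is the reference group throughout (e+ and e−
are statistically exchangeable).

## Configuration search

Admissibility over the 3^16 block-density assignments requires: nonzero
within-group connectivity for e+ and e−; at least one excitatory→inhibitory
and one inhibitory→excitatory connection; and no disconnected component,
interpreted as weak connectivity of the 4-node block digraph with
self-loops ignored.  Under this reading the exhaustive count is 18,576,000
— computed purely combinatorially by enumerating the 2^16 zero/nonzero
patterns and weighting each admissible pattern by 2^(#nonzero blocks).
Alternative readings of "reachable by at least one connection" (in-degree
≥ 1, or incident-edge ≥ 1) give different totals and were rejected on that
basis.  The shotgun search samples admissible configurations uniformly
without replacement (rejection sampling), simulates each at Λ = 1, and
classifies against the strict criteria (corr_e < −0.5, corr_i < −0.5,
max e-range > 3.5, total range < 2) and the loose ones (corr_i < −0.2 and
max e-range ≥ 1.4 × total range).  The structural motif predicate — dense
within-e+ and within-e−, e+↔e− at most sparse, and dense crossing
inhibition both ways through one or two inhibitory groups — is evaluated
without simulation.  Desk-scale searches (tens to hundreds of samples at
T = 2–5·10⁴ steps) exercise the machinery; the full 873,000-sample search
at long run lengths is cluster-scale and out of scope here.

## Synthetic data generator

`make_event_series` lays half-sine bumps (duration ∝ √size, so β ≈ 2 by
construction at the latent level) on a zero baseline with gaps averaging
1.5× the bump length; areas match prescribed sizes exactly under the
rectangle rule, and ≥ 50% baseline occupancy pins the median to the
baseline so extraction round-trips the sizes.

`make_planted_population` interleaves scale-free bumps (τ = 1.2 over 4
decades — matching the breadth of real behavioral event distributions)
alternately into a signed switching signal x(t); the two latent drivers are
A = max(C + x, 0) and B = max(C − x, 0) with resting level C at the largest
bump peak.  Bumps are disjoint in time, so corr(A, B) = −1 and A + B is
constant: averaging equal-sized groups cancels their fluctuations exactly,
reproducing the mechanism that hides scale-free subsets from the population
mean.  Group neurons are coupling·latent + Gaussian noise with SD 0.4 in
units of the latent SD (within-group pairwise correlations ≈ 0.8, typical
of the most-correlated-50 selections the subset search makes); 800 noise
neurons are pure Gaussian, dominating the population as weakly correlated
neurons dominate real recordings.  Behavior channels reuse the group-A
event times with independent lognormal per-event amplitude jitter
(σ = 0.25) plus a sensor-noise floor at 20% of the smallest event's peak,
so the head of the behavioral size distribution is measurement noise — as
in real behavioral channels — without drowning genuine small events.
Defaults: 1000 neurons (100 + 100 + 800), T = 16384 samples at 3 Hz
(≈ 1.5 h), matching the recording scale the analysis targets.

**What the generator does not emulate.** Calcium indicator kinetics,
deconvolution artifacts, and — importantly — the limited dynamic range of
single-neuron traces: every planted-group neuron carries a verbatim copy of
the full 4-decade latent.  One consequence is that time-shifted control
subsets seeded *inside* a planted group can retain partial power-law range
(occasionally touching the 3.5-decade line), because averaging 50 shifted
full-range rows still leaves isolated large bumps above the diluted noise
floor.  Real recordings dilute per-neuron dynamic range far more, which is
why empirical controls stay well below genuine subsets.  Noise-seeded
controls, canceling subsets, and the whole-population average behave as in
the real analysis.  Passing tests on this generator therefore validate the
pipeline's mechanics and discriminative behavior, not the exact empirical
null distribution of control ranges.

## Problem sizes

Desk-scale defaults used by the tests and the acceptance script: canonical
model runs of 10⁵ kept steps; the exponent ensemble over 21 grid points at
10⁵ steps each; subset searches with tens of seeds on the default planted
population; 500 surrogates per goodness-of-fit evaluation throughout.

## Known limitations

- The F envelope uses strict min/max of surrogates; with very large event
  counts (n ≳ 10⁴) the envelope tightens and model data with mild
  systematic curvature fail earlier, making r conservative at large n.
- Durations are inherently discrete (multiples of Δt); α is fit with the
  continuous likelihood, slightly biasing α for short-duration-dominated
  event sets.
- The eigenvalue normalization targets the largest positive real
  eigenvalue; configurations whose spectrum has none are recorded as
  failures in the configuration search rather than simulated.
- `admissible` and `count_admissible` treat densities as exactly
  {0, 0.05, 0.5}; other values are validation errors by design.
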