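# scalefree

Scale-free dynamics of behavior and cortical population activity: event
statistics, truncated power-law range estimation, correlated-subset
discovery, and a winner-take-all network model of competitive criticality.

## The problem

Spontaneous body movements (running, whisking, pupil fluctuations) and
ongoing cortical activity both show scale-free, avalanche-like fluctuations.
Whether they are two faces of the same process is testable with
single-neuron-resolution recordings: define *events* on each continuous
time series, measure how broadly their sizes are power-law distributed, and
ask which neural subsets carry that structure and how tightly they couple
to behavior.  The catch is that anticorrelated neural subsets cancel in the
population average, hiding scale-free dynamics from the usual whole-population
analysis — a seed-based subset search plus time-shifted controls is needed to
find them, and a four-population winner-take-all circuit model explains why
they exist.

This package implements that entire analysis chain, exercisable end-to-end
on synthetic data with known ground truth, for anyone analyzing slow
population recordings (e.g. deconvolved calcium at a few Hz) together with
behavioral channels.

## The statistics at the core

**Events.** An event of a series x(t) starts when x rises strictly above a
threshold θ (default: the median of the whole series) and ends when it
returns to or below θ.  Its size is the area s = Δt·Σ(x−θ) over the
excursion and its duration T the excursion length — the avalanche
definition appropriate when no empty time bins exist.

**Power-law range r.** Event sizes are fit by a continuous truncated power
law p(s) = C·s^(−τ) on [s_min, s_max], with s_max the largest observed size
and τ estimated by maximum likelihood on a grid τ ∈ [0.7, 2.0] (step 0.02).
Candidate s_min values ascend in 10 log-spaced steps per decade; each
candidate fit is accepted if its goodness-of-fit F — the fraction of
log-resampled empirical CDF points falling inside the min/max envelope of
500 surrogate CDFs drawn from the fitted law — reaches 0.8.  The reported
range is r = log10(s_max/s_min) for the smallest passing s_min, r = 0 if
none passes.  The fit is binning-free and sample-size aware: r only grows
when the data genuinely sustain a power law over that interval.

**Scaling relations.** For events inside the size power-law range, the
duration distribution exponent α and the slope β of log S vs log T are
estimated, and compared against the crackling-noise prediction
β = (α−1)/(τ−1).

**Winner-take-all model.** N = 1000 binary neurons in four groups (e+, e−:
400 each; i+, i−: 100 each) update synchronously,
s_i(t) = 1 with probability clip(η + Σ_j C_ij s_j(t−1), 0, 1),
with block-structured ±c weights normalized so the largest real eigenvalue
of C is Λ.  Dense within-group excitation, sparse e+↔e− coupling and dense
crossing inhibition (e+→i+→e−, e−→i−→e+) produce stochastic winner-take-all
switching at Λ ≈ 1: e+ and e− anticorrelate, each is scale-free over >3.5
decades, and their sum is not.  A constrained shotgun search over all
3^16 block-density configurations (18,576,000 admissible) shows which
wiring motifs produce this behavior.

## Worked example

```python
from scalefree import analyze_run, canonical_config, run_model, switching_rate

cfg = canonical_config(rng_seed=21)          # Lambda=1, eta=0.1
run = run_model(cfg, T=101_000, burn_in=1000, rng_seed=22)
stats = analyze_run(run, rng_seed=23)
print(stats.corr_e, stats.corr_i, stats.r_e, stats.r_total)
```

The analysis drivers under `analysis/` run the same pipeline with printed
narration.  `python analysis/05_model_canonical.py` prints:

```
canonical model (eta=0.1, Lambda=1.0), 100000 steps after burn-in
  corr(e+,e-) = -0.953   corr(i+,i-) = -0.889
  winner switching: 127 per 1e4 steps
  e+   : r = 4.86 decades, tau = 1.36, F = 0.86
  e-   : r = 3.67 decades, tau = 1.28, F = 0.84
  total: r = 0.31 decades, tau = 2.00, F = 1.00
```

The two excitatory groups anticorrelate strongly (corr < −0.5) and each is
power-law distributed in event size over more than 3.5 orders of magnitude,
while the all-neuron average shows no power law at all (r = 0.31 decades):
cancelation of anticorrelated subsets hides the scale-free dynamics.  On
the synthetic behavioral side, `analysis/02_behavior_powerlaw.py` recovers
the planted exponent (fit τ = 1.32 and 1.24 against truth 1.2) over ≈ 4.4
and 4.1 decades for the two behavior channels.

Scripts `01`–`07` cover, in order: synthetic data generation, behavioral
power laws, the shotgun subset search with time-shifted controls,
event-specific behavior–neural linkage, the canonical model, the
(η, Λ) exponent sweep, and the constrained configuration search.

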