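# Methods

`odormix` analyzes single-unit recordings from a head-fixed odor-mixture
categorization task: on every trial a 3-odorant mixture is presented for 2 s
(with a 500-ms response extension and a 10-s intertrial interval) and the
animal licks one of two ports to report whether the mixture is the single
learned *target* combination or anything else.  Besides ordinary nontarget
mixtures (3 distinct draws from a 13-odorant pool) the task includes
session-fixed *repeated* nontargets and *probe* mixtures that share exactly
one component with the target and are rewarded as nontargets.  The package
implements the statistics used to characterize such data — per-neuron
response classification, odor-identity selectivity, population decoding, and
trial-history representational similarity — together with a synthetic session
generator that provides planted ground truth for every stage.

## Data model and conventions

Time is in seconds, zero at odor onset per trial; bins are half-open
`[t, t + Δ)`.  The per-trial analysis epoch is fixed at `[-5, +12]` s around
odor onset: this covers both baseline segments (5–1 s before odor on and
6–10 s after odor off for a 2-s odor) and nothing more.  Sessions live on
disk as a directory of three plain-text files (`trials.csv`, a long-format
`spikes.csv`, `session.json`); the round trip is exact (`float_precision=
"round_trip"`).  The session clock starts 5 s before the first odor onset so
all times are non-negative.

`AnalysisConfig` holds every tunable that matters:

| parameter | default | meaning |
|---|---|---|
| `bin_width` | 0.2 s | PSTH bin used everywhere |
| `onset_window` | (0, 1) s | the five onset bins tested for modulation |
| `familywise_alpha` | 0.05 | family-wise level over the onset bins |
| `per_bin_alpha` | 0.05/5 = 0.01 | Bonferroni per-bin threshold (derived) |
| `baseline_pre` / `baseline_post_off` | (−5, −1) / (+6, +10) s | baseline segments, odor-on / odor-off relative |
| `n_shuffles` | 1000 | jitter / label shuffles per test |
| `min_lick_latency` | 0.5 s | short-latency exclusion for latency & neural summaries |
| `population_window` | (0.1, 0.6) s | spike-count window for population analyses |
| `min_spikes_per_neuron` / `min_neurons_per_session` | 5 / 4 | population exclusions |
| `lookback_L` | 10 | ProbeTNT look-back window |

The invariant `per_bin_alpha = familywise_alpha / n_onset_bins` and the
tiling `n_onset_bins × bin_width = onset window length` are enforced at
construction.

## Response classification

The modulation of a bin against baseline is `m = (bin − baseline)/(bin +
baseline)` (0/0 defined as 0, so `m` is continuous from both sides).
Baseline pools spike counts over both segments and all trials (equivalent in
expectation to averaging per-trial rates for equal-length trials).
Significance comes from a circular-jitter permutation null: each shuffle
draws one uniform offset per trial over the 17-s epoch, rotates that trial's
spikes modulo the epoch, and recomputes the statistic — including the
baseline, which is re-measured on the jittered train.  p-values use the
add-one rule, `p = (1 + #{|null| ≥ |obs|})/(n_shuffles + 1)`, so they are
never exactly zero and are super-uniform under the null.  Jitter conserves
per-trial spike counts exactly, and all statistics are invariant to a global
translation of the session clock.

A neuron is *odor-on up* if any onset bin has `p < 0.01` with `m > 0`,
*odor-on down* if every significant onset bin is negative, and unlabeled
otherwise — or if the lick-contamination screen flags it.

**Lick contamination.**  Only trials whose first lick came ≥ 800 ms after
odor on enter the screen.  Spikes are aligned both to odor on (ten 200-ms
bins over the 2-s odor period) and to the first lick (five 200-ms bins tiling
−400 ms to +600 ms around it), and bins are screened at p < 0.05.  The
lick-aligned null reuses the jitter engine on a fixed wrap domain of
`[-5, +9.5]` s relative to the lick (inside the odor-anchored epoch for any
lick in the response period), with the neuron's odor-aligned baseline as the
fixed reference rate, since the baseline segments are not defined relative to
the lick.  A neuron with a significant positive odor-period bin is
contaminated if a significant lick-adjacent bin exceeds the fastest such bin;
a neuron without one is contaminated if a significant lick-adjacent bin
undercuts its reference (the slowest significant odor-period bin, else
baseline).  In both branches the margin must exceed **twice the lick bin's
Poisson standard error**: without that requirement an odor-locked response
whose rate merely *ties* the odor-period extreme would be flagged on sampling
noise alone — asymptotically ~a quarter of genuine sustained responses —
whereas a genuinely lick-locked response clears the margin easily because
odor alignment smears it.

**Odor-off responses** require all three of: (1) a post-offset bin (five
200-ms bins in the second after odor off) significant against baseline at
the Bonferroni threshold; (2) a significant change between the last 500 ms
of the odor period and 100–600 ms after offset, measured as
`(pre − post)/(pre + post)` against its own jitter null at the two-sided 95th
percentile; and (3) agreement in direction, where criterion 1's direction is
read at its most significant bin and criterion 2's is `sign(post − pre)`.

## Selectivity and trends

The odor-identity test compares two trial groups (target vs nontarget, one
repeated nontarget vs the other nontargets, probe vs nontarget) bin by bin:
the statistic is the unsigned difference of group mean rates, the null is
1,000 group-label shuffles preserving group sizes, and a neuron is selective
if any onset bin has `p < 0.01`.  The preferred group is the one with the
higher mean in the most significant bin; an exact tie leaves it unset.  On
4+4-trial instances the shuffle p agrees with exhaustive enumeration of all
70 assignments to within Monte-Carlo error.

The trial-count-matched comparison draws `⌊2/3 × n_focal⌋` focal trials (and
independently as many target trials) without replacement, 50 times, testing
each subset against the plain nontargets; each neuron is summarized by the
mode of its 50 p-values, resolved by rounding to 3 decimals with a median
fallback when all rounded values are unique (continuous p-values rarely tie
exactly and no canonical mode exists for them).

Cross-session trends (proportion selective, decoder accuracy, behavioral
indices vs training day) are Pearson correlations whose significance comes
from shuffling the day labels (add-one Monte-Carlo, two-sided by default).
Constant inputs yield `r = 0, p = 1` rather than NaN.

## Population decoding

Each trial is a vector of per-neuron spike counts in 100–600 ms after odor
on.  Neurons with fewer than 5 window spikes summed over trials are excluded
(`min_spikes`), as are zero-variance neurons (z-scoring is undefined for
them; the exclusion is logged); sessions retaining fewer than 4 neurons are
rejected.  Columns are z-scored so every neuron contributes equally — which
also makes the decoder invariant to any per-neuron affine rescaling of raw
counts.

Decoding the category (target vs everything else) uses linear discriminant
analysis over 10 *independent* random 90/10 train/test splits (not a
partition; a split missing a class in training is redrawn); a partitioned
10-fold mode, in which every trial is held out exactly once, is available
behind a flag for comparison.  The LDA uses
the least-squares solver with Ledoit–Wolf shrinkage because desk-scale
sessions can have near-singular within-class covariance.  Reported outputs
are the mean split accuracy, a per-trial posterior probability of the true
category averaged over the splits in which that trial was held out, and a
per-trial-type accuracy breakdown.  Chance is calibrated empirically by
re-running the full procedure on category-shuffled labels (classes are
imbalanced, so chance is not assumed to be 0.5).  Day trends use the mean
posterior over correct trials per session, fed to the day-shuffle engine.

## Representational similarity and trial history

Population vectors (the z-scored window counts) are correlated pairwise
across trials.  For cross-session comparability the coefficients are z-scored
once per session over the off-diagonal upper triangle (fewer simultaneously
recorded neurons inflate correlation variability); the raw matrix is kept
alongside, and on strong planted signals both give the same conclusions.
Zero-variance trial vectors produce missing pairs that are excluded from
normalization and averages; the diagonal never enters any average.

A target trial's TNT value is its mean correlation with every nontarget
trial (plain and repeated alike), and vice versa; probe trials carry no TNT.
`ProbeTNT` of a probe is the mean TNT of the **L nearest preceding
TNT-bearing trials** (default L = 10), skipping probes and other undefined
trials; probes with fewer than L usable predecessors are flagged undefined
rather than extrapolated.  A strict positional mode (exactly the L preceding
indices, NaNs ignored) is available for comparison.

ProbeTNT is associated with behavior two ways, pooling probes across
sessions as one would across a full dataset: (1) Pearson correlation with
probe lick latency plus a one-sided index-shuffle Monte-Carlo p (negative
values mean a more differentiated representation, which accompanies slower,
more often correct probe responses); (2) a one-sided comparison of correct
vs incorrect probes — a signed-rank test over per-session median differences
when enough sessions contribute both outcomes, a pooled Mann–Whitney test
otherwise, and a median-difference Monte-Carlo with shuffled outcome labels.
The outcome comparison is swept over look-back windows of 3–50 trials.

## Behavior

The choice index of a trial type is the fraction of right-lick choices.
Variant A scores every trial after truncating the trailing run of no-lick
trials, counting remaining no-lick trials as incorrect; variant B keeps only
decided trials (a lick within the 2.5-s response period — the gate chosen
for "decided", since the task scores responses in that window).  An
accuracy-based index (proportion correct for targets, one minus that for
other types) is reported alongside, because the two published formulations
differ for target trials; the reward-side convention (target = left by
default) is a session attribute.  First licks earlier than 500 ms are
excluded from latency and neural summaries only — never from choice indices
— with the excluded count and fraction reported.

## Synthetic sessions

The generator emulates the task's trial mix (target fraction 0.4, two
repeated nontargets, probe fraction where enabled, all counts deterministic
given the config with shuffled positions), the timeline (12.5-s trial
period), behavior, and six response archetypes: brief (≈0.4 s) and sustained
(2 s) odor-on increases, sustained odor-on decreases (gain < 1 on an
elevated baseline), lick-locked bursts, odor-off bursts, and unmodulated
cells.  Rates are piecewise constant; spikes are inhomogeneous-Poisson by
thinning.  Trials are 12.5 s apart while the analysis epoch spans 17 s, so
each trial generates spikes only on its own 12.5-s tile — active windows sit
well inside it — keeping the session train a single continuous point process
whose epoch overlaps are pure baseline, as in the real intertrial interval.

Selectivity is planted by marking a fraction of odor-responsive neurons
(default gain 2 on the preferred type, split between target and repeat-1
preference); that fraction grows linearly with `day_index` at `session_drift`
per day to emulate overtraining.  Lick latencies are log-normal per trial
type (probe median 1.1 s, others 0.8–0.9 s, shape 0.35, truncated at 0.2 s);
sides follow a Bernoulli accuracy per type (0.93–0.95, probes 0.75); 2% of
trials have no lick.

A slowly varying AR(1) *separation state* `s` (mean 1, ρ = 0.98, innovation
0.06 — stationary SD ≈ 0.3, decorrelation time tens of trials, matching the
look-back scale of the ProbeTNT analysis) scales the planted selectivity
gains trial by trial.  With a positive behavior `coupling`, probe accuracy
gains `coupling × (s − 1)` and the probe latency median is scaled by
`exp(0.5 × coupling × (s − 1))`: a more separated representation makes probe
responses slower and more often correct, which is exactly the joint pattern
the ProbeTNT analysis is designed to detect.  With coupling 0, probe
behavior is independent of the state, giving calibrated nulls.  A separate
`choice_coupling` ties accuracy on the *non-probe* trial types to the same
state, so correct trials carry a cleaner population signal — the condition
under which decoder confidence should differ between correct and incorrect
trials.

All randomness flows from a single seed through `numpy.random.SeedSequence`
spawning (trials, neuron draw, state, behavior, spikes), so sessions are
fully reproducible.

### What the generator does and does not emulate

It reproduces the trial structure, the response archetypes' time courses,
trial-type selectivity, overtraining drift, and the state–behavior coupling.
It does not model refractoriness, spike-waveform or sorting noise,
sniff-locked dynamics, cross-neuron noise correlations beyond the shared
separation state, or session-to-session neuron identity.  Passing tests
therefore certify the *statistics* — calibration, recovery, exactness against
brute force — not the biological fidelity of any particular parameter value;
archetype gains and latencies are free knobs, not estimates.

## Numerical choices and degenerate inputs

Add-one p-values everywhere (never 0); `modulation_index(0, 0) = 0`;
all-zero neurons give all-zero normalized PSTH rows; zero-variance trial
vectors and single-trial categories give flagged missing values rather than
errors; decoding refuses categories with fewer than 2 trials; trend tests
need ≥ 3 sessions; ProbeTNT associations need ≥ 10 defined probes.  Verified
problem sizes: null calibration uses 200 stationary neurons at 200 shuffles;
archetype recovery 100 seeds per archetype at 150 trials; decoding 20–50
seeds at 200 trials × 30 neurons; overtraining 15 days at 150 trials × 40
neurons (drift 0.025/day from 0, so the planted trend spans the whole run
instead of saturating early) with a null calibration over replicate
no-drift datasets at smaller sizes; ProbeTNT pooling 4 sessions of 300
trials.

## Known limitations

The contamination screen's 2×SE margin is this package's resolution of an
underdetermined rule (the reference rate and tie handling are not otherwise
specified); under a pure stationary null it still flags ~6% of neurons, by
design — a significantly lick-locked suppression with no odor response *is*
lick-driven.  The "mode of p-values" definition is likewise a documented
convention.  Whether the preferred group should be read from the minimal-p
bin or averaged over significant bins is undetermined; the minimal-p bin is
used.  The ProbeTNT look-back follows the nearest-L-TNT-bearing-trials
reading (the alternative strict-index mode is provided).  The factorial
ANOVA tables surrounding these analyses in a full study are out of scope;
the package exposes the per-session quantities they would be run on.
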