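# Methods

## Task and data model

The task couples a 30-s pure tone to a 2-s footshock at tone end; a rat
avoids the shock by mounting a platform, at the cost of leaving a food
lever it otherwise presses on a variable-interval schedule. Sessions have
nine tone trials with variable inter-trial intervals averaging 3 min.
Analysis starts from sorted spike timestamps; all times are seconds from
session start and every interval is half-open `[start, end)`, which makes
windowed counts additive and removes double-counting at bin edges.
Recording stops during the 2-s shock, so all analysis windows are
truncated at shock onset and nothing after 28 s of the tone enters any
spike statistic.

Three groups are compared: *avoidance* (tones + shocks + platform),
*naive* (tones, free platform access, never shocked), and *fear*
(tones + shocks, no platform).

## Peri-event response classification

Spike counts in 0.5-s bins from −10 s to +28 s around the alignment
event are converted to trial-averaged rates. The baseline estimate is the
mean μ and sample SD σ (n−1 denominator; the estimator is a package
choice, as only "SD across the 20 pretone bins" is conventionally
specified) of the 20 pretone trial-averaged bin rates, and
z_b = (r_b − μ)/σ. Labels:

- *excited*: z > 2.58 in the first tone bin (two-tailed p < 0.01);
- *inhibited*: z < −1.96 in the first **or second** bin (two-tailed
  p < 0.05) — the extra bin allows for the longer latency of
  multi-synaptic inhibition;
- *none* otherwise; *unclassifiable* when σ = 0 or no qualifying trials
  exist (near-silent units are carried through, never dropped, and appear
  in an explicit output column).

Excitation is evaluated before inhibition, so a (pathological) profile
crossing both thresholds in bin 0 is labeled excited. Tone-onset
classification uses the first five trials of a session. Platform-entry
classification uses every successful-avoidance trial whose entry came at
least 1 s after tone onset (earlier entries would confound the tone
response with the entry response) and z-scores entry-aligned bins against
the pretone baseline of those same trials' tones; baseline bins of the
profile are tone-aligned so heat maps remain interpretable from −10 s.

Inhibited units are split into *brief* versus *sustained* responses:
sustained means inhibited (z < −1.96) in at least half of the bins in the
10–28 s window. The 50% fraction and the window are configuration knobs;
qualitatively, brief responses end by roughly 10 s.

Population views are a per-bin fraction of units beyond each threshold
(denominator = units with a finite z at that bin), and a heat map ordered
by mean z over the first two event bins (a pure permutation, ties broken
by unit id). A unit is a putative projection neuron when spike width
exceeds 225 µs and baseline rate is below 15 Hz, both strict.

## ISI inhibition latency

Per unit and trial, the pretone baseline is the mean and sample SD of the
ISIs between consecutive spikes in the 30 s before tone onset (at least
two ISIs required, SD > 0, else the trial is unscorable with a reason
code). The latency is the start (minus tone onset) of the first ISI whose
starting spike lies in the tone window with (ISI − mean)/SD > 1.65. The
ISI straddling tone onset is excluded — its start is pretone — which keeps
latencies in [0, 30); the gap from the last in-window spike to the window
end is not an ISI. Baselines are per-cell-per-trial (the alternative,
pooling across cells per trial, is a defensible reading; per-cell matches
the per-cell averaging downstream). Per-cell summaries average over
avoided trials with a detection, paired with platform-entry and headturn
latencies; missing headturns propagate as NaN, never zero.

## Behavioral endpoints

Platform and freezing percentages are interval intersections with the
30-s tone window ×100/30; the 3-s timecourse uses the same arithmetic per
bin, so its mean equals the overall percentage exactly. Avoidance latency
is the first platform entry at/after tone onset within the tone; trials
without one report the 30-s cap plus a `never_avoided` flag (rank tests
then treat non-avoiders as ties at ceiling, matching how non-avoiders are
plotted). Suppression of bar pressing is (pretone − tone)/(pretone + tone)
with the pretone rate over the 60 s before onset; it is reported
unit-scaled in [−1, 1] — the dialect in which group values like 0.922 are
conventionally quoted — with a ×100 display option, and defined as 0 when
both rates are 0. Session aggregates never average tones silently; the
per-trial table is the primary output.

## Inferential statistics

- Chi-square: Pearson Σ(O−E)²/E, **no continuity correction** (required
  to reproduce population statistics such as 22.545 from their counts;
  Yates-corrected values differ), df = (r−1)(c−1), zero marginals are
  errors naming the degenerate margin.
- Fisher exact: two-tailed hypergeometric sum over tables at the observed
  margins.
- Mann-Whitney U: exact for ≤ 12 per group (exact U distribution when
  tie-free; full enumeration of group assignments with midranks
  otherwise), tie-corrected normal approximation without continuity
  correction beyond. Two-sided p = min(1, 2·min(P(U ≤ u), P(U ≥ u))).
- Wilcoxon signed-rank: zeros dropped; exact for ≤ 15 nonzero pairs
  (sign enumeration with midranks when |d| ties exist), normal
  approximation beyond; all-zero differences abstain (NaN) rather than
  fabricate a p-value.
- Laser modulation: per 1-s bin index, rates averaged across trials for
  the OFF window immediately preceding each ON interval and for the ON
  interval; the paired OFF/ON bins enter the Wilcoxon test; p < 0.05
  calls the direction by the mean difference. Protocols: constant-light
  silencing (10 s OFF / 10 s ON × 10) and pulsed activation
  (30 s OFF / 30 s ON / 30 s rest × 5 at 2 or 4 Hz).
- Bonferroni correction exists as an explicit helper and is never applied
  implicitly. All p-values are two-tailed; the classifier z-thresholds
  are applied directly as cutoffs, not wrapped in tests.

## Synthetic-data generator

Spike trains are inhomogeneous Poisson processes with piecewise-constant
rate, sampled exactly by thinning a homogeneous process at the segment
maximum. Defaults encode the study conditions: baseline rates log-normal
with median 6 Hz (SD 0.35 log units across units; inhibited cells drop
from ~6 to ~2 Hz); excitation multiplies the first 0.5 s of the tone by 3;
inhibition clamps the rate to 2 Hz from a per-unit onset lag (uniform
0–1 s) for 8 s (brief) or through the tone (sustained); no spikes during
the shock. Sessions: nine 30-s tones, ITIs uniform 180 ± 60 s, shocks in
the last 2 s (avoidance/fear), platform entries with per-trial probability
0.7 (avoidance; 0.5 for free exploration in naive) at log-normal latencies
with median 3.55 s and σ = 0.95 log units — chosen so that ~91% of entries
fall later than 1 s, matching the observed tail — truncated to the tone;
headturns 0.2–1 s before entry; bar presses Poisson at 0.5 Hz (generated
where the metrics read them: the 60-s pretone window and the tone),
thinned to zero during platform occupancy and freezing; freezing one
interval per trial covering ~30/5/60% of the tone in
avoidance/naive/fear. Group compositions default to the recorded cohort
sizes (205/166/191 units with 30/20/25 excited and 22/3/3 inhibited, the
avoidance inhibited units all rostral, 18 brief + 4 sustained).

What the generator does **not** emulate: refractoriness and bursting
(negligible for 500-ms counts below 15 Hz), rate drift, per-rat clustering
— all units of a group share one session, as if recorded simultaneously,
so cross-cell spreads of behavioral latencies are narrower than in real
cohorts and cell-to-behavior correlations on the default cohort are
degenerate by construction (reported as NaN) — platform-entry-specific
responses (entry-aligned excitation arises only via tone responses), and
spike waveforms (width is a metadata scalar). Passing tests therefore
validate the analysis code under the stated statistical structure, not
the biology of real recordings.

One detail worth stating: a homogeneous Poisson unit crosses the
excitation threshold more often than the nominal one-tailed 0.005 — a
one-time 40,000-unit calibration puts the null excited rate at ~0.0146
and the null inhibited rate at ~0.0531 — because the 20-bin baseline SD
estimate gives the z-statistic t-like tails and Poisson counts are
discrete and right-skewed. Tests compare against these calibrated
references, not the Gaussian nominals.

## Pipeline and reproducibility

`run_pipeline` chains data (load or simulate) → classification (both
alignments) → ISI latency → behavior → population statistics, writing
CSV/JSON outputs whose content is fully determined by (inputs, seed,
config); the report carries the seed and a configuration hash, and unit
counts are reconciled across stages. A single seed fans out to stage
seeds via `numpy.random.SeedSequence`. Problem sizes in the acceptance
script (2000 null units, 300 sensitivity units, 200 latency-recovery
units, a reduced 112-unit cohort for the bit-identity check) keep a full
run within a few tens of seconds on one core while leaving binomial CIs
tight enough to be informative.

## Known limitations

- The brief/sustained split is a thresholded convention; borderline
  profiles move between classes with the configuration knob.
- Exact Mann-Whitney enumeration with ties is combinatorial; above 12 per
  group the tie-corrected normal approximation is used by design.
- The interchange format carries one behavioral session per cohort file;
  multi-rat designs are represented as separate group directories.
- Classification of platform-entry responses in groups without platform
  events (fear) is reported as unclassifiable rather than omitted.
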