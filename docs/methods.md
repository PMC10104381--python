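# Methods

This note documents the statistical procedures, the synthetic-data
model, and the numerical choices behind `somnoval`.

## Hypnogram model

A hypnogram is a sequence of stages at a fixed epoch duration (1 s or
30 s), anchored so epoch 0 begins at lights-off and the last epoch ends
at lights-on; explicit clock times are deliberately outside the data
model, since every derived quantity is relative to lights-off. Two
vocabularies exist — raw five-class AASM (W, N1, N2, N3, REM) and the
collapsed four-class set (W, N1+N2, N3, REM) — and are never mixed
within a sequence. Unscored labels are rejected at ingest: the
analyses assume fully scored nights, and silently imputing or skipping
epochs would bias every downstream latency.

Fine (1-s) stagings are merged to 30-s epochs by majority vote; among
stages tied for the maximal count, the stage whose *first occurrence
within the window* is earliest wins. This is the most literal reading
of the merge rule used by cardio-actimetric stagers ("the more
prevalent stage, or the first occurring stage when equally
represented"); a global stage-priority tie-break is a plausible
alternative but is not what the rule says. A trailing remainder
shorter than one full window is dropped, not padded. Paired nights are
truncated to the shorter recording measured from lights-off.

## Sleep parameters

All parameters are derived from the collapsed 30-s hypnogram; stage
minutes are epoch counts × 0.5.

* SL — lights-off to the first non-wake epoch.
* WASO — all wake from sleep onset to lights-on, terminal wake
  included, so wake = SL + WASO holds exactly. (Stopping WASO at the
  final awakening is a recognized variant; the identity with total
  wake is why the inclusive definition is the default here.)
* LPS — lights-off to the start of the first run of ≥ 10 min of
  uninterrupted sleep *of any stages* (20 consecutive non-wake
  epochs). The stricter reading — 10 min within a single stage — is
  available as `lps_single_stage=True`. LPS is non-decreasing in the
  window length and equals SL when the first sleep run already spans
  the window.
* REML — elapsed time from sleep onset to the first REM epoch,
  intervening wake included (pure elapsed time).

SL/LPS/REML are NaN when the defining event never occurs.
Per-subject averaging is field-wise over the nights where a field is
defined (available-case mean); a field undefined on every night stays
undefined. This keeps, e.g., REML usable for a subject with one
REM-free night rather than discarding the subject.

## Epoch-by-epoch agreement

The confusion matrix puts the reference (PSG) in rows and the device
in columns. Sensitivity is the probability of calling a PSG sleep
epoch sleep; specificity the probability of calling a PSG wake epoch
wake; two-class accuracy is their prevalence-weighted mix. Cohen's κ
uses expected agreement from the product of row and column marginals;
in the degenerate case p_e = 1, κ is defined as 1 for perfect observed
agreement and 0 otherwise. The per-stage "accuracy" column shown next
to row-normalized matrices is one-vs-rest binary accuracy
((TP+TN)/total); this definition reproduces the published per-stage
values from the published cells, which is why it is the one
implemented. Metrics are computed per night and summarized by the
unweighted mean over nights (pooled-count matrices are also reported);
nights where a metric is undefined (e.g. specificity without wake
epochs) are dropped from that metric's mean.

All metric functions work on proportions, so a matrix reconstructed
from published row-normalized percentages and prevalences gives the
same metrics as raw tallies. Published cells carry 1-decimal rounding;
reconstructed metrics can therefore differ from published ones by about
one unit in the last printed digit (e.g. two-class accuracy computes to
87.75 where 87.8 is printed).

## Subject-level agreement

**Trimming.** Differences d = device − reference are trimmed two-sided
before reliability estimation: floor(n·f/2) pairs from each tail at
total fraction f = 0.05. Floor-per-tail is used because no rounding
rule is published. Trimming is applied before the ICC only; the
Bland–Altman analysis uses all nights.

**ICC.** The absolute-agreement average-measures ICC(A,k) with k = 2
raters is computed from the two-way mean squares; its 95% lower bound
follows the standard F-interval for the single-measures form with
Satterthwaite denominator degrees of freedom, stepped up via
Spearman–Brown. The estimate matches an explicit sums-of-squares
oracle to 1e-10 and an independent implementation (pingouin ICC(A,k))
to 1e-9 in tests. Zero total variance returns estimate 1 with a
flagged degenerate CI. Degenerate Satterthwaite df (possible for
negative ICC at very small n) is clamped to 1 and the lower bound to
[−1, estimate]. ICC is computed on per-subject means (one point per
subject); Bland–Altman on all nights — two deliberate granularities.

**Bland–Altman with replicates.** For subject i with m_i nights and
differences d_ij (reference − device): bias = mean of the d̄_i;
s_b = SD of the d̄_i; s_w² pools Σ(d_ij − d̄_i)² over Σ(m_i − 1) df;
m_h = n/Σ(1/m_i). The SD of a single difference is
sd² = s_b² + (1 − 1/m_h)·s_w² — with one night per subject this
reduces exactly to classic Bland–Altman. Because E[s_b²] = σ_b² +
σ_w²/m_h, sd² estimates σ_b² + σ_w², the variance of one new
difference; the Monte-Carlo consistency check in the acceptance script
therefore targets √(σ_b² + σ_w²). The bias CI is t-based on s_b/√n
(the per-subject means are the i.i.d. units; their spread already
contains the within-subject contribution, making the interval mildly
conservative under unequal m_i). LoA CIs use MOVER: each variance
component gets a chi-square interval, the interval for the composite
variance recovers the component discrepancies in quadrature, and each
limit's CI combines the bias CI half-width with the half-width of the
CI of 1.96·sd, again in quadrature. Simulation coverage of the bias CI
at n = 200 subjects (1–3 nights, σ_b 20, σ_w 10) is ≈ 94% at nominal
95% over 500 runs. The sign convention (reference − device) makes a
positive bias mean "device underestimates".

## Synthetic cohort

The generator emulates the *structure* of a multi-group validation
study, not sleep physiology:

* **Architecture** — a first-order Markov chain over the four stages
  at 30-s resolution, entered after a geometric initial wake run that
  sets sleep latency. Presets for healthy / OSA / insomnia / MDD are
  calibrated (by a fixed-point solver matching stationary occupancy
  and mean bout lengths) to published group means: time in bed 477–500
  min, sleep latency 11–47 min, WASO 33–92 min, and the corresponding
  stage minutes. Bout lengths (wake 1.5–2 min, NREM/REM 5–12 min,
  patients more fragmented) are plausible choices; no bout statistics
  are published. Real hypnograms have ultradian cycling, REM-period
  ordering and stage-dependent transition asymmetries that a
  first-order chain does not reproduce — so passing tests show the
  statistics behave correctly on realistic *marginal* architecture,
  not that the generator fools a sleep scientist.
* **Device corruption** — each epoch is relabelled independently from
  P(device | PSG); the default matrix is a published device-vs-PSG
  confusion (row-renormalized, since printed rows sum to 1 ± 0.001).
  Independence keeps the generating matrix analytically known, giving
  recovery tests an exact target (max cell error < 1% at 10⁵ epochs).
  Optional run-length smoothing (device hypnograms are typically less
  fragmented than PSG) relabels interior runs shorter than a minimum
  into the longer neighbour until none remain; smoothing biases the
  realized confusion, so recovery tests run with it off. A per-subject
  N(0, σ) perturbation of each row's logit diagonal induces
  subject-level accuracy differences for the reliability analyses.
* **Signals** — 1-Hz heart rate is stage mean + AR(1) noise (defaults:
  W 72, N1+N2 62, N3 56, REM 66 bpm; N3 steadiest, REM most variable;
  AR coefficient 0.95), with a decaying +15 bpm pulse at each
  sleep-to-wake transition (cardiac arousal). Actimetry is zero
  outside wake; wake epochs receive Poisson movement bursts (2/min,
  exponential amplitudes). These series carry the stage-dependence the
  rule-based stager needs and nothing else — no ECG morphology, apnea
  events or circadian drift.

Seeding: one master `SeedSequence`; per-subject and per-night streams
are spawned with fixed keys so any subset is reproducible
independently.

## Rule-based stager

The published classifier this pipeline surrounds is a trained SVM
ensemble with undisclosed expert rules; it cannot be reconstructed
from public information. The `stager` module is therefore an openly
parameterized baseline with the same I/O contract: RR→HR at 1 Hz
(HR = 60/RR, linear interpolation, gaps > 5 s masked and never
bridged), triaxial vector magnitude, threshold-run movement detection,
cardiac-arousal detection (rise ≥ 10 bpm over a 60-s trailing
baseline with return to within 3 bpm inside 60 s), and a 1-s
precedence rule (wake near movement/arousal events; N3 in the lowest
HR band with low local variability; REM at high variability; N1+N2
otherwise) merged to 30 s. The default movement threshold is half the
median nonzero activity count: an adaptive low threshold, chosen on
synthetic data, that keeps short wake bouts detectable (a
high-percentile threshold flags only the amplitude tail and collapses
wake specificity). On the easy synthetic preset the full chain
achieves > 80% two-class accuracy — a pipeline-integrity budget, not a
performance claim.

Eligibility screening mirrors the usual exclusions: time in bed < 5 h,
heart-rate signal loss above a fraction, and a periodic-movement
heuristic (≥ 10 movement events whose inter-event intervals have
coefficient of variation < 0.15 — a documented stand-in for an
undefined criterion). HR/actimetry synchronization is estimated by
FFT cross-correlation of the arousal and movement indicator series
within ±60 s, with a circular-shift permutation null gating
reliability.

## Sizes and determinism

The validation path is fully deterministic given inputs; all
randomness lives in the generator behind explicit seeds. Default
problem sizes — 500 Monte-Carlo runs of 200 subjects for the
Bland–Altman check, 10⁵ epochs for confusion recovery, 1000 nights for
the brute-force oracles, a 246-subject cohort for the end-to-end run —
were chosen so each check's Monte-Carlo error is comfortably below its
tolerance; the whole acceptance script runs in seconds.

## Known limitations

Epoch-independent corruption understates the autocorrelation of real
device errors; the Markov generator has no ultradian structure; the
rule-based stager is a baseline, not a reconstruction of any
commercial classifier; MOVER coverage is verified for the bias CI and
containment/shrinkage for the LoA CIs, not their exact coverage; and
between-group significance testing is intentionally out of scope.
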