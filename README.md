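# somnoval

Validation toolkit for heart-rate + actimetry sleep staging against
polysomnography (PSG).

Wearable and cardio-actimetric sleep stagers are validated against PSG,
the gold standard, with a now-conventional statistical battery:
epoch-by-epoch (EBE) agreement between the paired 30-s hypnograms,
derivation of the clinical sleep parameters from each hypnogram, and
subject-level agreement on those parameters. `somnoval` implements that
battery as a reusable, tested pipeline for researchers validating a
device or algorithm on healthy sleepers and on patients with disturbed
sleep (obstructive sleep apnea, insomnia, major depressive disorder),
together with a synthetic cohort generator and a transparent rule-based
stager so the whole chain can be exercised without access to real
recordings.

## What it computes

Stages are the collapsed four-class vocabulary W / N1+N2 / N3 / REM
(N1 and N2 merged), at 30-s epochs from lights-off to lights-on.

**Epoch by epoch** — confusion matrices (PSG in rows, device in
columns, row-normalized), sensitivity (P(device sleep | PSG sleep)),
specificity (P(device wake | PSG wake)), two- and four-class accuracy,
Cohen's κ = (p_o − p_e)/(1 − p_e) with Landis–Koch qualitative bands,
and per-stage one-vs-rest accuracy. Metrics are computed per night
before aggregation.

**Sleep parameters** — TIB, TST, SE = 100·TST/TIB, SL, WASO, LPS
(latency to the first 10 continuous minutes of sleep), REML, and
stage minutes, with per-subject averaging (one point per subject).

**Subject level** — after two-sided 5% trimming on the
device−reference differences, the absolute-agreement average-measures
intraclass correlation from the two-way layout (subjects random,
raters fixed, k = 2),

    ICC(A,k) = (MS_R − MS_E) / (MS_R + (MS_C − MS_E)/n),

with an F-based 95% lower bound and Cicchetti rating; and
repeated-measures Bland–Altman for unequal replicate counts, where the
bias is the mean of per-subject mean differences and the SD of a single
difference pools the variance components through the harmonic mean m_h
of the replicate counts,

    sd² = s_b² + (1 − 1/m_h)·s_w²,   LoA = bias ± 1.96·sd,

with MOVER confidence intervals on the limits. Differences are
reference − device, so a positive bias means the device underestimates.

## Worked example

```python
from somnoval import cohort, run_validation

pairs, truth = cohort.simulate_cohort(seed=1)   # study-shaped cohort
report = run_validation(pairs)
row = report.ebe_table.set_index("group").loc["all"]
print(f"nights={report.metadata['n_nights']} "
      f"acc2={row['accuracy2_pct']:.1f}% kappa2={row['kappa2']:.2f}")
icc = report.icc_table.set_index(["group", "parameter"])
print("TST ICC(A,k) = %.2f" % icc.loc[("all", "tst_min"), "icc"])
```

prints

```
nights=443 acc2=88.0% kappa2=0.63
TST ICC(A,k) = 0.93
```

i.e. a 246-subject synthetic cohort whose device hypnograms were
corrupted with a published device-vs-PSG confusion matrix shows ~88%
wake/sleep accuracy with substantial chance-corrected agreement
(κ 0.63), and excellent subject-level reliability for total sleep time.

The same pipeline is available from a shell:

```
somnoval simulate --groups healthy,insomnia --n-subjects 5 --seed 1 --out sim/
somnoval validate --psg sim/psg.csv --device sim/device.csv --out report/
somnoval report --report-dir report/
```

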