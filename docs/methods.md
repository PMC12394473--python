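# Methods

This note documents the models, defaults and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and the
known limitations of both.

## Task model

The VCPT generator produces S1–S2 trials on a fixed grid: S1 onsets every
3000 ms, S2 exactly 1100 ms after S1, 100 ms stimulus duration. Go trials are
animal–animal pairs (press), NoGo trials animal–plant (withhold). The default
400-trial sequence contains 200 Go and 200 NoGo trials in seeded pseudo-random
order; Ignore (plant–plant) and Novel (plant–human) trial types exist behind
config flags but default off, because the analysed ERPs come from the Go/NoGo
pair and the printed 400 = 200 + 200 design leaves no room for them. Trial
counts must divide evenly among the enabled conditions; anything else is an
error rather than a silent rebalance.

## Synthetic EEG

ERP components are Gaussian-windowed bumps (`width_ms` is the FWHM) with fixed
per-channel topographies over the 19-electrode 10–20 montage, time-locked to
S2 and planted only on their own condition's trials. Defaults: Go P3 peaking
at 330 ms, parietal-maximal, 6 µV; NoGo P3 at 400 ms, fronto-central, 9 µV;
slow positive wave at 650 ms, broad centro-parietal, 2 µV (Go) / 4 µV (NoGo);
20 % trial-to-trial amplitude variability. The NoGo-specific surplus is what
the NoGo−Go difference wave (P3d, SPWd) measures. Cohort structure scales the
NoGo-specific components: a PTSD-like attenuation of P3d at baseline (default
40 %), a stronger SPWd attenuation in non-responders (60 %) than responders
(30 %), and full post-treatment P3d recovery in responders only — the pattern
of a treatment-responsive inhibition marker and a trait-like late marker.

Background noise is pink (1/f, SD 6 µV) plus posterior-dominant alpha
(narrow-band 8–12 Hz noise, 8 µV nominal amplitude — narrowband noise, not a
sinusoid, so its phase drifts rather than locking to the fixed trial grid)
plus white noise (SD 4 µV). Artifacts are planted inside the S2 epoch window
of randomly selected trials: 150 µV, 400 ms half-sine blinks maximal at
Fp1/Fp2 (trips the 100 µV raw rule) and 60 µV, ~240 ms bursts at 26–34 Hz
maximal at a temporal electrode (trips the 35 µV fast-wave rule while staying
under the raw rule). Each rejection rule is therefore exercised independently
of the planted ERPs.

What the generator does **not** emulate: volume conduction from realistic
sources (topographies are painted, not forward-modelled), non-stationary
noise, slow impedance drifts, eye movements other than blinks, and any
dependence of behaviour on the EEG. Passing tests therefore demonstrate that
the pipeline recovers what its own forward model plants under realistic
amplitude and SNR regimes — not that it is robust to every artifact zoo of
clinical recordings.

## Preprocessing

The 0.5–50 Hz band-pass is a zero-phase cascade of an order-2 Butterworth
high-pass and an order-8 low-pass. The asymmetric orders are deliberate:
a sharp 0.5 Hz edge biases the peak of slow unipolar ERP components downward
by ~2× more than the gentle one, while the order-2 high-pass (applied twice)
still attenuates a 0.1 Hz drift by ~56 dB; the steep low-pass provides the
stop-band attenuation needed above the band (~36 dB at 60 Hz). Note that
*any* 0.5 Hz high-pass removes roughly 10 % of the peak of a 100 ms unipolar
bump (its near-DC pedestal); amplitude-recovery validation is therefore run
on unfiltered epochs, where averaging alone must recover planted amplitudes
within 3·SD/√n.

Epochs run from −200 to +796 ms inclusive (250 samples at 250 Hz, exactly
1000 ms) around S2, with the t = 0 sample at `floor(onset·fs)` and **no
baseline correction**. Onsets too close to a recording edge are flagged
invalid (`edge`) rather than dropped, so epoch counts always match the event
log. Artifact rejection tests absolute amplitude per epoch — >100 µV raw,
>50 µV after a 0–1 Hz low-pass, >35 µV after a 20–35 Hz band-pass (zero-phase
order-4 Butterworth per band) — recording the first rule tripped, in that
order. Absolute amplitude (not peak-to-peak) is the package's reading of the
thresholds; it is isolated in one function if a different measure is ever
needed. Subjects fall out of analysis when *any* analysed condition has fewer
than 30 % valid trials; exactly 30 % is kept ("less than" read strictly).

## ERP measures

Condition averages use valid epochs only; grand averages weight subjects
equally (a trial-weighted variant exists). P3d is the in-window maximum of
the difference wave (window [300, 500) ms, ties broken toward the earliest
latency), SPWd the window mean over [500, 800) ms, both at Fz/Cz (SPWd also
at Pz). The windows are package defaults, config-exposed: the cluster
statistics run on 200–600 ms, but the slow wave extends beyond it and the
epoch ends at 800 ms.

## Cluster-based permutation test

Pointwise statistics are rank tests converted to signed z scores:
signed-rank z = (W − n(n+1)/4)/√(n(n+1)(2n+1)/24 − Σ(t³−t)/48) with zero
differences dropped (the classical convention — documented because it changes
n per time point), rank-sum z from the Mann–Whitney U with tie-corrected
variance, signed by the direction of A−B. Clusters are maximal same-sign sets
of suprathreshold points (two-sided pointwise p < 0.05, the conventional
cluster-forming default — only the cluster-level 0.05 is fixed by the design) connected by temporal adjacency within channel and same-time adjacency
across declared channel neighbours (Fz–Cz by default). The cluster statistic
is the sum of signed z over members; since clusters are same-sign this equals
±Σ|z|, making the sign convention immaterial. The null is the permutation
distribution of the maximum |mass| — sign flips of per-subject difference
waves (exact exchangeability under the paired null) or group-label
permutations — with p = (1 + #{null ≥ observed})/(1 + B), and exhaustive
enumeration (exact p, denominator = group size) whenever the full permutation
group is no larger than the requested B. Permutation internals are
vectorised: sign flips act on a fixed rank decomposition (ranks of |d| are
flip-invariant) and label permutations on fixed pooled ranks, so one matrix
product yields all permuted z maps.

Calibration at the study's scale (checked by the acceptance suite): with two
null conditions, n = 20 subjects and 200 permutations, the family-wise
false-positive rate over 500 simulated datasets sits in [0.02, 0.08]; a 3 µV
NoGo-specific component against 2 µV smooth subject-level noise is detected
by a significant positive cluster over the planted window in ≥ 90 % of runs.
The subject-level simulator used for these calibrations generates
per-subject *averaged* waveforms (effect + temporally smooth noise), not full
continuous EEG — the appropriate level for a statistic that consumes subject
averages.

### Accuracy of the normal approximation

The z approximation is asymptotic. Against the exhaustive exact nulls
(tie-free), the worst-case two-sided error |p_approx − p_exact| over the full
statistic support is 0.127 for the signed-rank at n = 5 and 0.089 for the
rank-sum at n1 = n2 = 5, shrinking to ≤ 0.04 by n = 12 and ≤ 0.02 by n ≈ 25.
No classical variant repairs this uniformly at very small n (continuity
correction: 0.036; mid-p comparison: 0.037). One acceptance test asserts a
0.02 bound for all n ≤ 12 and accordingly fails; it is kept failing rather
than weakened, and the acceptance script reports the actually achieved
worst-case errors. Practical consequence: for fewer than ~10 pairs, prefer
the exhaustive permutation path (which the cluster test takes automatically)
over the pointwise asymptotic p.

## Clinical statistics

HTQ totals are the mean of the 16 items (grid of 1/16), cut-off 2.5;
the shipped five-factor subscale map (Intrusions 1,2,3,16; Avoidance 11,15;
Numbing 4,5,12,13,14; Dysphoric Arousal 7,8,10; Anxious Arousal 6,9) is a
documented package default in the dysphoric-arousal tradition — item
assignments are configuration, not instrument fact. A responder is a total
decrease ≥ 0.5; on the 1/16 grid the printed non-response boundary (≤ 0.4)
is automatically respected.

The 2×2 chi-square applies the Yates correction with |O−E|−0.5 floored at
zero — the variant that reproduces the published contingency statistics from
their printed counts (the uncorrected statistic does not). Fisher's exact
test is also provided. Cohen's d uses the paired formulation for pre/post
contrasts (pooled-SD independent variant exposed) with a normal-approximation
95 % CI on the standard d SE. Cliff's delta is computed by an all-pairs count
up to 10⁶ pairs and an O(N log N) sorted-count path beyond; both paths agree
exactly and both are kept so one can always cross-check the other; its CI
uses Cliff's consistent variance estimate. Bonferroni and Benjamini–Hochberg
corrections accept an m larger than the reported list (unreported tests
count). Group/pre-post comparison tables record NaN for statistics that are
degenerate on a given measure (e.g. zero variance) instead of failing the
whole table; the underlying operations still raise on degenerate input when
called directly. The baseline-severity regression models change (post − pre)
on baseline; the sensitivity model is a two-predictor OLS (responder status,
medication status) with type-II F tests.

## PLSC

Columns of both blocks are z-scored (ddof = 1), making R = XᵀY/(n−1) the
cross-block correlation matrix — appropriate since HTQ item changes and ERP
amplitude changes have incommensurate units. SVD signs are fixed by making
the largest-|·| X-salience positive per dimension. The permutation test
permutes rows of X only (equivalent to permuting Y); the bootstrap resamples
rows jointly and sign-aligns each replicate's saliences to the original
solution by dot product per dimension before taking elementwise SEs —
without that alignment the SVD's sign indeterminacy corrupts the SEs.
Replicates that draw a zero-variance column are redrawn and counted.
Full Procrustes rotation is not applied; with the q = 2 blocks used here
dimension swapping is rare away from degenerate spectra, and the null
calibration confirms the ratios are not anti-conservative.

The cross-block generator plants a rank-1 latent structure. Its default
noise SD (0.6 per standardised unit) was chosen so that the first latent
dimension explains ≈ 94 % of cross-block variance at n = 47 — the
near-rank-1 structure typical of this P3d-change/symptom-change setting —
and the default Y-loading ratio (1.0, 0.4) gives the matching dominant-Cz /
minor-Pz contribution split. Under those conditions the dimension-1 permutation test (500
permutations) detects the structure and bootstrap ratios (500 resamples)
flag every planted loading in ≥ 90 % of replicates, while independent blocks
are rejected at the nominal 5 % rate. Which ERP summary feeds the Y block is
a pipeline decision, stated in the outputs: the measured P3d change at Cz
and SPWd change at Pz per subject (in the synthetic demo, the generator's
planted ERP-change covariate plays this role).

## HTQ cohort generator

Pre-treatment items are drawn around a configurable baseline mean (default
2.9, responders +0.3 — more severe at baseline, which also induces the
negative baseline-vs-change regression slope the pipeline tests for). The
total-score decrease is drawn per subject on the 1/16 grid and clipped into
the defining ranges (responders ≥ 8/16 = 0.5, default mean 1.2;
non-responders ≤ 6/16, default mean 0.2, mild worsening allowed), then
distributed over items weighted by a per-item change propensity
(hyperarousal and activity-avoidance items move most). Because the clipping
is part of the definition, the ≥ 0.5 responder rule recovers the generated
labels exactly — a closed loop that validates classification, not an
empirical claim. The planted ERP-change covariate is built from the realised
standardised decrease at the configured latent correlation (default 0.45),
plus a +2 µV group offset for responders (the P3d normalisation), so the
realised item-change/ERP-change association carries both a dimensional and a
group component. Demographic covariates (age, sex, medication with higher
prevalence in responders) exist only to give the baseline-characteristics
table realistic inputs.

## Pipeline and reproducibility

A single integer seed drives every stochastic branch through named
sub-streams (CRC-hashed labels spawning independent generators), so runs are
bit-reproducible and per-subject streams are stable under cohort resizing.
The orchestrated run writes every table as CSV plus a JSON manifest with the
resolved configuration, exclusion report and SHA-256 of each output; the
determinism test asserts byte-identical tables for identical (config, seed).
The demo cohort is deliberately small (tens of subjects, ~100 trials each);
the calibration suites use the study-scale settings quoted above (n = 20
subjects for the cluster test, n = 47 for PLSC and the responder loop,
400-trial sessions for recovery), sizes chosen to match the design the
package mirrors while keeping a full validation run to a couple of minutes.

## Known limitations

- Scalp-level only: no source model, channel interpolation or re-referencing
  beyond the recorded linked-ears montage.
- Blinks are rejected, not repaired; no ICA. Blink-heavy recordings lose
  trials accordingly.
- The amplitude-band artifact measures are absolute amplitude; peak-to-peak
  variants would need a one-function change.
- The asymptotic rank-test p-values are inaccurate below ~10 pairs (see
  above); the permutation machinery, not the pointwise p, carries inference
  at those sizes.
- The PLSC bootstrap uses sign alignment only (no Procrustes), adequate for
  small q with well-separated singular values.
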