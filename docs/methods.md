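# Methods

This note documents the models, parameter choices and numerical decisions
behind `filmsense`, in the spirit of a methods appendix: what is computed,
what is assumed, and what passing tests do and do not establish.

## 1. Analysis pipeline

### Filtering

Each modality is filtered with a linear-phase FIR filter designed by the
windowed-sinc (Hamming) method: EDA low-pass 1 Hz, respiration low-pass
3 Hz, ECG band-pass 1–30 Hz. Neither a filter order nor a design method is
canonical for this procedure, so the package fixes a rule: the number of
taps is `4·fs / lowest_cutoff`, rounded odd (Type I, so a band-pass has no
constrained gain at Nyquist) and capped at 8191. This puts roughly four
transition widths inside the lowest passband edge, giving ≥ 50 dB stopband
attenuation and < 0.1 dB passband ripple at every default setting; the
half-amplitude (−6 dB) point of a windowed-sinc design falls at each cutoff.

Filtering is **zero-phase** by default: one forward and one backward pass
over a signal padded at both ends with one filter length of reflected
samples. Zero-phase application is chosen so that segment boundaries and
energy landmarks are not displaced by group delay; a `single-pass` mode
exists for sensitivity analysis. Signals shorter than three filter lengths
are rejected rather than silently edge-dominated.

### Amplitude normalization

The default mode is **unit energy**: x ← x / √(Σ x²), after which the
sample mean is removed (in that order). A `literal` mode dividing by Σ x²
itself — a form the normalization is sometimes written in — is available
behind a flag; it is not the default because it is not scale-invariant
(doubling the input halves the output) and gives the result units of
1/amplitude. All downstream energies are therefore dimensionless shares of
each record's total energy.

**Consequence worth stating explicitly**: if the normalized span and the
analyzed span coincide, every record's windowed energies sum to ~1, so the
caffeine and placebo 10-point profiles are forced to (nearly) equal sums
and only *shape* differences survive — group separation by a threshold
becomes impossible no matter how strong the physiological effect. The
pipeline therefore normalizes over the **whole recording**, which includes
a pre-intake baseline phase (default 15 min, mirroring the acquisition
protocol in which a baseline task precedes film intake), and computes
profiles on the 50-min post-intake span. The condition-independent
baseline anchors each record's energy scale, so a caffeine-elevated
post-intake span keeps a genuine between-group offset after normalization.

### Energy features

Within each contiguous 5-min segment, power energy EN = Σ |x(n)|² is
computed over rectangular windows of 5 s. "Computed every 5 s" fixes the
window step at the window width — contiguous, non-overlapping — and the
step is configurable for sensitivity analysis. A trailing remainder
shorter than one window (or one segment) is dropped and logged. Window
energies are averaged per segment, segment means averaged over each
group's subjects (subjects are truncated to the common minimum segment
count if ragged), and the two groups' 10-point profiles are z-scored
**jointly**: pooled mean and pooled population (divide-by-n) standard
deviation. Joint rather than per-group standardization is essential —
per-group z-scoring would erase exactly the between-group gap that
classification measures.

### Classifier bank and LOOCV

Eleven classifiers are evaluated per modality, with fixed hyperparameters
(no search): fine and medium decision trees (both capped at 150 splits —
the caps coincide, so the two rows are identical by construction, and the
conventional fine/medium distinction exists only in name), SVMs with
polynomial kernels of degree 1/2/3 (box constraints 5/3/2, kernel
(x·y + 1)^d at unit scale), 3-nearest-neighbor classifiers with cosine and
cubic-Minkowski distances, linear and quadratic discriminant analysis with
full covariance, logistic regression (listed under discriminant analysis
in the reconstructed comparison; implemented as plain logistic
regression), and X-ROC.

**X-ROC** is reconstructed, not copied: the source comparison names it as
its best performer but never defines it. Here it is the ROC-optimal scalar
threshold: all midpoints of adjacent sorted training values are swept in
both polarities and the pair maximizing training accuracy (equivalently
Youden's J) is kept; ties are broken by the largest margin to the nearest
training point, then by the smaller threshold. A constant feature
degenerates to training-majority prediction. Its outputs should not be
claimed to replicate the original classifier.

Leave-one-out cross-validation trains on n−1 points and predicts the
held-out one; accuracy is the percentage of correct folds. Degenerate
folds never crash: a single-class training fold predicts its sole class,
and an estimator that cannot fit a fold (e.g. QDA with one sample left in
a class) falls back to the training majority, logged. With one-dimensional
inputs the cosine distance collapses to sign (dis)agreement, so cosine-KNN
accuracy is governed by scikit-learn's index-order tie-breaking among
equidistant neighbors; this degeneracy is inherent to the reconstructed
design and is left visible.

The classification sample is, by default, one z-scored **group-mean**
energy point (20 points, 10 per class, 1-D); a per-subject-point variant
(`sample_unit="subject_point"`) is available for sensitivity analysis.

## 2. Synthetic cohort generator

The generator emulates the study design: n subjects (default 13), each
recorded in two blinded conditions across three modalities at a
configurable rate (default 1000 Hz; analyses in the test suite run at
80–100 Hz, see §4), for a 15-min baseline plus 50 analyzed minutes.

### Pharmacokinetic effect model

No effect model is published for these films, so the generator adopts a
two-compartment Bateman profile: a **free** caffeine fraction and a
**microencapsulated** fraction, each absorbed at first order (ka_free,
ka_enc) and eliminated at a common ke, summed and delayed by an absorption
lag:

    e(t) = B(t − lag; D_free, ka_free, ke) + B(t − lag; D_enc, ka_enc, ke)
    B(t; D, ka, ke) = D·ka/(ka − ke)·(e^(−ke·t) − e^(−ka·t))

with the analytic limit D·ka·t·e^(−ka·t) when |ka − ke| < 1e−12. Defaults:
D_free = D_enc = 1 effect unit, **ka_free = 1.0/min**, ka_enc = 0.02/min,
ke = 0.01/min, lag = 1 min. The free-fraction rate reflects buccal
absorption, which acts within minutes — a slower free fraction would leave
the first analyzed segment with a deep energy deficit relative to placebo
and make ECG *less* discriminable than EDA, inverting the intended
ordering. The encapsulated fraction (peak ≈ 69 min) sustains the effect
through the session. All four PK values are invented placeholders for a
dose–response that the underlying studies do not quantify; they are dials,
not pharmacological claims. A placebo is the same profile with both doses
zero, generated through the identical code path.

### Modality models and effect coupling

Per-subject baselines are drawn from documented priors (heart rate
N(70, 7) bpm clipped to [50, 90]; RR jitter N(40, 12) ms; tonic skin
conductance N(5, 1.5) µS; SCR rate N(4, 1)/min; breathing rate
N(15, 2)/min; per-subject log-normal jitter of SD 0.15 on every gain).
The normalized effect e(t) (reference scale 1) couples in with gains
α_ecg = 0.15, β_eda = 0.08, γ_scr = 0.4, δ_resp = 0.05, additionally
scaled per modality (ECG 1.0, EDA 0.6, RF 0.3):

* **ECG** — beats are one fixed PQRST template (five Gaussian bumps)
  placed on an RR grid; instantaneous HR = baseline·(1 + α·e). Window
  energy is then proportional to the local beat count, so the energy
  profile traces e(t) directly. Beat centers are quantized to the sample
  grid (≤ half a sample period; irrelevant at 5-s windows). HRV is plain
  Gaussian RR jitter with a 250-ms refractory floor; respiratory sinus
  arrhythmia is omitted as invisible to these features.
* **EDA** — tonic level (1 + β·e)·baseline plus a slow random walk (total
  SD 0.3 µS), plus phasic SCRs: per-sample Bernoulli events at rate
  (1 + γ·e)·base (a shared uniform array makes the realized event set
  monotone in the rate), log-normal amplitudes (median 0.5 µS, σ = 0.4)
  scaled by (1 + β·e), convolved with a biexponential kernel (rise 0.7 s,
  decay 3 s). Conductance is clipped at zero. An optional electrode-removal
  artifact adds 3-µS white noise to the final 5 min.
* **Respiration** — quasi-sinusoid at (1 + δ·e)·rate/60 Hz with a weak
  amplitude coupling of half the frequency gain, slow amplitude-modulation
  noise (depth 0.25, ~30-s correlation) and strong additive noise
  (SD 0.35 vs. unit amplitude). Frequency changes barely move windowed
  energy, so respiration is by construction the least discriminable
  modality; the small amplitude coupling keeps its dose response strictly
  monotone rather than exactly flat.

Measurement noise: ECG 0.03 mV, EDA 0.01 µS white noise. The gains and
scalings are chosen once so the between-condition energy separation orders
ECG > EDA > RF, the qualitative finding this pipeline is built to detect;
none of them is a claim about caffeine physiology.

### What the generator does *not* emulate

Real morphology beyond what energy features see: no arrhythmias, motion
artifacts, electrode impedance drift, baseline wander, respiratory sinus
arrhythmia, or circadian structure; no pharmacodynamic fit to published
caffeine PK values. Passing tests therefore establishes that the pipeline
recovers a planted, pharmacokinetically shaped energy effect with the
intended modality ordering — not that real recordings would behave this
way.

### Reproducibility

One master seed. Every record draws from
`SeedSequence(master_seed, spawn_key=(subject_index, stream))` with PCG64,
where stream 0 is the subject-parameter draw and streams 1–6 enumerate
condition × modality. Identical config + seed reproduces a cohort
bit-for-bit across runs and platforms, and adding subjects never perturbs
existing ones.

## 3. I/O formats

CSV is the interchange dialect (`# key: value` metadata, `time_s,value`
rows, 17-significant-digit values, loss-free round trip; the loader
rejects missing metadata, NaNs, and time columns off by more than half a
sample period). EDF is the archival option: a minimal single-channel,
single-data-record EDF writer/reader with the standard 16-bit quantization
over the declared physical range (round-trip error ≤ one step); `mne` can
read the produced files. The proprietary acquisition format of commercial
biosignal systems is deliberately not parsed.

## 4. Problem sizes and numerical choices

* The replicate experiments in the test suite (discriminability ordering
  and null calibration, 100 seeds each) run 5-subject cohorts at 80 Hz —
  the smallest rate at which the 1–30 Hz ECG band-pass is designable —
  with the full 15 + 50 min session. Cohort size affects only the
  smoothness of group means, not the planted separation structure.
* Contiguous window energies are computed as exact block sums (no
  cumulative-sum cancellation); the overlapping-window path uses a
  cumulative sum.
* Zero-phase filtering squares the magnitude response; passband assertions
  account for it.
* z-scoring uses the population (divide-by-n) SD; a pooled SD of zero
  (identical points) is an error, not a silent pass-through.
* Degenerate classifier folds: see §1. All stochastic estimators are
  seeded from the classify settings, making every LOOCV result
  deterministic.
* The null-calibration expectation is *below* 50 % on average (~40 %):
  leave-one-out on exchangeable points is pessimistically biased, since
  removing a point shifts the training majority toward the opposite class.
  This bias is a property of LOOCV at n = 20, not a defect.

## 5. Known limitations

* The X-ROC reconstruction and the "logistic under discriminant analysis"
  reading are best-effort interpretations of an under-specified comparison.
* With 10 points per group, LOOCV accuracy is quantized to 5-point steps;
  small effect differences are invisible.
* The generator's effect sizes, PK constants and noise levels are
  placeholders; conclusions about real oral films require real recordings.
* Sessions shorter than the segment span are truncated to the common
  minimum segment count; the headline 10-point analysis requires a full
  50-min analyzed span.
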