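# Methods

This note documents the models, estimators and numerical choices behind
`pcspectra`, what the synthetic data do and do not emulate, and the known
limitations.  All quantities referred to here are computed by the test
suite or by `scripts/acceptance.py`; nothing below is an empirical claim
beyond what those runs produce.

## Spectral estimation

A recording is a uniformly sampled membrane-potential trace; the standard
analysis window is 60 s (configurable; the window length is a convention,
not a physical constant).  The signal mean is removed first so the PSD
has no zero-frequency component.  The estimator is a Welch average:

- segment length W = one third of the signal length (for 60 s at 1 kHz,
  W = 20 000 samples, i.e. 20 s);
- Hamming taper, 50 % overlap (five segments);
- each segment zero-padded to 2 W before the FFT, giving a grid step of
  fs / 2W (0.025 Hz at the default settings) — padding interpolates the
  spectrum, it does not add resolution;
- one-sided density normalisation, so for broadband signals the integral
  over [0, Nyquist] equals the signal variance (checked against a
  hand-rolled direct-DFT oracle; agreement within 1 %).  For narrowband
  signals the taper redistributes line power locally, as with any
  windowed estimator.

The smoother is a centred rectangular (boxcar) moving average, default
width 5 bins.  Edges use truncated-window renormalisation, so smoothing
is linear, preserves constants, and approximately preserves integrated
power.  Five bins is wide enough to suppress segment-averaging ripple yet
narrow relative to the separation between a fundamental and its first
harmonic at every frequency the study deals with (≥ 0.35 Hz ≈ 14 bins).
The taper shape and overlap fraction are exposed as arguments.

## Peak detection

Peaks are found with the Hilbert-transform zero-crossing method: the
discrete Hilbert transform of the (smoothed) power sequence crosses zero
from negative to positive at each spectral maximum, and those crossings
are used as guides.  Two practical refinements were needed to make the
method reliable on multi-peak spectra:

1. **Baseline detrending before the transform.**  The Hilbert transform
   of a sequence dominated by one large peak is offset near smaller
   peaks, which can erase their zero crossings.  A wide moving-average
   baseline (about one tenth of the spectrum length, much wider than any
   resolved peak) is subtracted first; each peak then produces a local
   zero-mean excursion with its own crossing.  Peak *locations* are still
   read from the untransformed power values.
2. **Windowed ascent and a prominence floor.**  Each crossing is walked
   to the nearest local maximum using a ±3-bin argmax step (so the walk
   is not trapped by sub-bin noise ripples), deduplicated, verified to be
   a local maximum within ±2 bins, and kept only if its topographic
   prominence is at least 5 % of the spectrum's maximum power.  The
   prominence floor is a design choice: without one, noise ripples
   produce spurious crossings.  Candidates below 0.2 Hz are dropped to
   exclude the residual DC shoulder left by mean subtraction.

Reported frequencies are refined to sub-bin precision by a parabolic fit
through the three power values around the maximum.  On random smooth
spectra (sums of 1–4 Gaussian bumps plus a noise floor) the detector
agrees with a brute-force local-maxima search (scipy `find_peaks` with the
same prominence floor) in ≥ 95 % of cases — the disagreements are bump
pairs merged below the smoother's resolution.

**Harmonic pruning** walks the detected peaks upward in frequency and
discards any peak within 5 % (relative) of an integer multiple of an
already-retained peak.  The rule is idempotent and never removes the
lowest peak.  The 5 % tolerance matches the bin resolution at the default
settings.  Among the retained fundamentals the *dominant* one (largest
power) is reported per cell — this combines the position-of-the-maximum
reading with the leftmost-of-a-series rule, and cells retaining more than
one fundamental are flagged.

**Band assignment** uses the firing-mode label when known (tonic →
sodium, burst → calcium), because the frequency-based fallback
(switching < 1 Hz, calcium 1–15 Hz, sodium ≥ 15 Hz, from the literature
band ranges) misclassifies slowed tonic cells: an ataxic tonic cell
firing at 6.5 Hz has a sodium-band fundamental inside the nominal calcium
range.  The fallback is therefore second-class and only used for
unlabelled traces.

**Band energies** are trapezoidal integrals of the smoothed PSD over the
ten 10 Hz bands of 0–100 Hz, each normalised by the integral over the
full [0, Nyquist] range.  Fractions are scale-invariant and sum to the
in-range fraction.

## Statistics

*Lilliefors test.*  The statistic is the Kolmogorov–Smirnov sup-distance
between the empirical CDF and a normal CDF with mean and SD estimated
from the sample.  Because the null distribution is parameter-free, the
p-value is Monte-Carlo: the fraction of simulated standard-normal samples
of the same size whose statistic is at least the observed one (default
10 000 draws, seeded, with the null table cached per sample size).  This
is exact-in-the-limit at any n rather than relying on the classical
lookup table, which matters for the small group sizes here (down to
n = 4).  Calibration: type-I error at α = 0.05 within [0.035, 0.065] over
1000 null replicates, and null p-values uniform to KS distance ≤ 0.06.

*Group comparison.*  Groups of unequal size cannot be paired, so the
default two-group comparison is the two-sided Mann–Whitney rank-sum test:
exact enumeration when the pooled size is ≤ 12 with no ties, otherwise
the normal approximation with tie correction.  A paired Wilcoxon
signed-rank variant is available behind a flag.  The significance
threshold defaults to α = 0.01, with any other level (e.g. 0.001)
available as a parameter.  No multiple-testing correction is applied.

## Synthetic Purkinje-cell traces

The generator reproduces the *spectral* structure the pipeline assumes,
not PC biophysics:

- **Tonic cells**: stereotyped biphasic spike waveforms (2 ms wide,
  80 mV, fast rise / exponential decay with a small
  afterhyperpolarisation lobe) at Gamma-renewal times with rate f_na and
  ISI coefficient of variation `cv_isi` (shape 1/cv²), plus white
  Gaussian noise (0.5 mV SD), 60 s at 1 kHz.
- **Burst cells**: burst onsets as a Gamma renewal process at f_ca;
  each burst is a half-sine depolarising envelope (20 mV) of the burst
  duration carrying 4 spikes at 40 Hz (40 mV).  With these defaults a
  burst cell keeps ~65–80 % of its energy below 10 Hz, matching the
  burst-mode energy profile the analysis is meant to resolve; a tonic
  cell keeps essentially none.
- **Cohorts**: per-cell fundamentals are drawn from each group's
  mean ± SD truncated to the group's observed frequency range (normal:
  7 tonic at 22.53 ± 5.49 Hz in [15.05, 31.2], 13 burst at
  4.22 ± 2.02 Hz in [1.04, 7.85]; 3-AP: 3 tonic at 6.46 ± 0.23 in
  [6.22, 6.68], 16 burst at 1.52 ± 1.19 in [0.35, 4.57]; riluzole +
  3-AP: 2 tonic at 31.34 ± 4.07, 2 burst at 3.88 ± 1.37, positivity
  only).  Truncating to the observed ranges, rather than merely at zero,
  keeps every generated cell inside the regime the analysis window can
  resolve (a 0.05 Hz burster would show three bursts in 60 s).
- **Regularity defaults** (`cv_isi` = 0.02 tonic, `cv_burst` = 0.05):
  chosen so a 60 s cell shows the single dominant fundamental plus a
  smaller harmonic that characterises real PC spectra.  At cv ≳ 0.05 the
  fundamental line of a 60 s window broadens and splits below the
  prominence floor, a property of short windows rather than of the
  detector.

Every generator is deterministic given its seed; cohort cells get child
seeds from the cohort seed.

*What passing tests show and do not show.*  Ground truth for per-cell
recovery is the **realized** rate (reciprocal mean inter-event interval)
rather than the nominal parameter: over 60 s the realized rate of a
stochastic train differs from its parameter by more than one frequency
bin, and the pipeline can only see the signal it is given.  Parameter-
level agreement is asserted at the cohort level (recovered group means
within 2 SD/√n of the generating means).  The surrogates are stationary
with white noise; real recordings have baseline drift, electrode noise
and mode switching, so real tonic cells carry a few percent of their
energy below 10 Hz where the surrogates carry almost none.  Pipeline
performance on the surrogates therefore bounds only the
signal-structure-dependent part of real-data behaviour.

## Reduced Purkinje-cell model

A single-compartment conductance-based model stands in for the
multi-compartment PC model used in the original in-silico experiment
(out of scope here).  Membrane equation (µA/cm², mV, ms, µM):

    C dV/dt = −I_NaF − I_Kdr − I_CaP − I_CaT − I_KC − I_K2 − I_L + I_noise
    d[Ca]/dt = −α_Ca (I_CaP + I_CaT) − ([Ca] − Ca_rest)/τ_Ca

with fast sodium (instantaneous m³, slow-recovery inactivation gate h:
half −60 mV, slope 3, recovery ≈ 40 ms when hyperpolarised),
delayed-rectifier potassium (n⁴), high-threshold P-type calcium
(instantaneous, half −38 mV — the spike calcium source), low-threshold
T-type calcium (instantaneous activation, slow inactivation u: half
−58 mV, τ up to ≈ 440 ms — the burst pacer), a BK-type calcium- and
voltage-activated potassium current KC, a purely calcium-gated K2, and a
leak with reversal −60 mV.  Defaults live in
`src/pcspectra/data/pcmodel_defaults.yaml` so the parameter set is
explicit and swappable.

Mechanism: at rest the T-type window current and the leak depolarise the
cell to sodium threshold, giving spontaneous tonic firing (~23 spikes/s
at the defaults, within the 10–100 spike/s range of spontaneous PC
firing; the initial potential is −68 mV).  Spike calcium entry activates
KC and K2; their afterhyperpolarisation spaces the spikes *and* is what
lets the slowly recovering NaF inactivation gate reset.  Setting
g_KC = g_K2 = 0 removes that AHP: sodium inactivation accumulates, fast
firing fails, and the cell settles into slow (~5 Hz) calcium oscillations
paced by T-type inactivation, with sodium spikelets riding each calcium
upstroke.  Spectrally, the 0–10 Hz energy fraction rises from ~0.05
(baseline) to ~0.49 (full blockade) and increases monotonically through
25 % blockade steps.  The kinetic *forms* are standard
(Hodgkin–Huxley-style, the spike gates from the fast-spiking interneuron
family); the parameters were tuned for this qualitative switch, not fit
to PC voltage data, so the model is a mechanism demonstration, not a
quantitative PC model — reproducing the full model's printed firing rate
or exact peak frequency is explicitly not attempted.

Numerics: fixed-step integration at dt = 0.00625 ms — exponential Euler
for V (exact for the locally linearised conductance equation, hence
stable through the stiff spike upstroke) and for all gates, forward Euler
for the calcium pool.  Halving dt changes the 5 s spike count by < 2 %
(the convergence check runs noise-free, since different step counts
consume a seeded noise stream differently).  Membrane current noise
(0.02 µA/cm² per √ms, seeded) prevents degenerate phase locking; at
higher noise the baseline develops spike doublets whose subharmonic can
confuse harmonic pruning, which is why the default is small.  A voltage
excursion beyond ±200 mV raises an instability error naming dt.

## Scaled-down study sizes

The acceptance checks run at desk scale: 100+ synthetic cells for
recovery, 100 replicate cohort draws for the group contrast, 200 random
spectra for the peak-detector comparison, 1000 null replicates for test
calibration, and 8 s model simulations (first second discarded as onset
transient).  These sizes give stable pass/fail behaviour under the fixed
seeds used by the tests while keeping the full suite in the minutes
range.

## Known limitations

- The frequency-based band fallback cannot distinguish a slowed sodium
  fundamental from a calcium fundamental; mode labels are authoritative.
- Harmonic pruning can demote a true fundamental if a genuine
  subharmonic (e.g. period-2 firing) sits below it; the per-cell flag
  for multiple retained fundamentals is the audit hook.
- Parseval-level normalisation holds for broadband signals; pure-tone
  line heights depend on the taper, as with any Welch estimator.
- The synthetic traces and the reduced model are structural surrogates:
  they validate the pipeline's inference machinery, not any biological
  claim about real PC recordings.
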