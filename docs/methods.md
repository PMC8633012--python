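# Methods

This note documents the statistical model behind `ispc`, the parameters that
matter, the numerical choices made where the design was genuinely open, and
the known limits of the test.

## The problem

Given a single-channel, uniformly sampled, non-stationary time series, we ask
which pairs of frequency bands have *covarying power*: when power rises in
one band, does it rise (or fall) in another?  The natural estimate — the
Pearson correlation between two rows of a wavelet power spectrum — is biased
by three mechanisms that have nothing to do with the signal:

1. **Frequency-domain oversampling.**  A continuous wavelet transform places
   scales closer together than their bandwidths, so adjacent scales partly
   measure the same spectral content and correlate positively for *any*
   input.
2. **Time-domain oversampling.**  Within one scale, adjacent coefficients
   share input samples, so every power row is autocorrelated; correlations
   between autocorrelated series have inflated sampling variance.
3. **Signal non-stationarity.**  The signal's own power modulation adds
   further intra-band autocorrelation beyond what the transform causes.

The test standardizes each observed inter-scale correlation against a null
built from two Monte Carlo elements that jointly account for all three, and
controls the false discovery rate over all scale pairs under dependency.

## Pipeline

### Decomposition

The analysing wavelet is the analytic generalized Morse wavelet, defined in
frequency by `Psi(w) ∝ w^beta exp(-w^gamma)` for `w > 0`, with `gamma = 3`
(the Airy wavelet) and `beta = 20` by default.  This is the parameterization
in which mainstream toolboxes quote the order as `B = 20` for `gamma = 3`
(time–bandwidth product `P^2 = beta * gamma = 60`).  The peak angular
frequency `w_p = (beta/gamma)^(1/gamma)` gives the unique scale-to-frequency
map `f_c(s) = w_p * fs / (2 pi s)`.

Scales are laid out logarithmically at 10 voices per octave.  The default
frequency limits follow energy-decay rules: the top scale is the one whose
response has decayed to 10% of peak at Nyquist; the bottom scale is the
widest whose envelope e-folding time still fits in half the record.  The
transform is evaluated in the frequency domain after zero-padding to the
next power of two; padding only affects coefficients outside the cone of
influence, which are discarded downstream.

The cone of influence (COI) uses the one-sided e-folding time of the wavelet
envelope, measured numerically once per `(gamma, beta)` by synthesizing the
wavelet at a reference scale and locating where its envelope falls below
`peak/e`; the e-folding time scales linearly with scale.  A coefficient is
edge-free iff its distance to the nearer record edge exceeds the e-folding
time of its scale.

### Power, COI filtering, correlation

Power is the elementwise squared magnitude of the coefficients.  Scales with
less than 90% of samples inside the COI are dropped; the surviving scales
are then restricted to the widest common time window in which every retained
cell is edge-free (because the COI is monotone in scale, this window is set
by the widest retained scale — per-pair windows would change the estimand
pair by pair and cost far more).  Correlations are computed on raw power
over that window with a standardize-and-multiply matrix product; a
log-power option exists but is off by default.  Zero-variance scales keep
their row (as NaN) and are reported as *untested*, never as non-significant.

### The two-element null

**White-noise element.**  `L` independent white-noise records of the same
length and rate as the (clipped) data are pushed through the identical
CWT/COI/correlation path, and the mean correlation matrix `rho_bar` over
draws is recorded.  With input whose band powers are uncorrelated, the mean
isolates the frequency-oversampling bias of the transform: near the
diagonal `rho_bar` approaches 1, and it decays to zero within a few voices
of separation.  Noise draws are not clipped — white noise has no
cyclic-discontinuity structure to remove, and a fixed length guarantees the
same retained scale grid in every draw and in the data.

The noise marginal matters more than one might expect: cross-scale power
covariances carry a fourth-cumulant term from samples shared by the two
wavelets, so uniform noise (excess kurtosis −1.2) and Gaussian noise differ
by up to ~0.1 in `rho_bar` at high frequencies where wavelets span few
samples.  The default is Gaussian; the validation suite matches the null's
noise kind to the signal's noise model (uniform for the uniform white-noise
signal).  When the data's noise floor is materially non-Gaussian, match the
kind via `RunConfig(noise_kind=...)`.

**Phase-randomization element.**  Each retained power row of the *data* is
independently phase-randomized `H` times; each surrogate set is correlated,
giving per-pair mean `phi_bar` (approximately 0, since independent
autocorrelated series are uncorrelated on average) and unbiased sample
variance `Var(phi)` — the spread expected from intra-band autocorrelation
alone.  The default surrogate is the Fourier-transform (FT) method, which
preserves each row's amplitude spectrum (hence autocovariance) exactly but
not its histogram; its nulls are close to normal, which the multiple-testing
step requires.  IAAFT (exact histogram, approximate spectrum) is available
but its nulls are often non-normal; `normality_diagnostics` screens either
choice (D'Agostino–Pearson per pair, Benjamini–Hochberg FDR).  A
coefficient-domain variant (randomize the complex coefficient row, then take
squared magnitude) is also provided; it keeps surrogate power nonnegative
and behaves nearly identically in calibration.

**Combination.**  The null for pair `(a, b)` is
`N(rho_bar + phi_bar, Var(phi))`; the observed correlation is standardized
to `T_ab = (r_ab − rho_bar − phi_bar) / sd(phi)`.  Adding `rho_bar` is
deliberately conservative near the diagonal: a pair whose null mean is close
to 1 can essentially never be rejected, whatever the data show.

### Multiple testing

The threshold on `|T|` is chosen by the data-driven procedure for
correlation-type statistics under dependency: the smallest
`t ∈ [0, d_u]`, `d_u = sqrt(4 log u − 2 log log u)` (natural logs), with
`(2 − 2 Phi(t)) * u(u−1)/2 / max(R(t), 1) ≤ alpha`, where `R(t)` counts
pairs with `|T| ≥ t`.  Because the criterion's numerator is continuous and
decreasing while `R` changes only at observed values, the infimum is found
exactly by scanning `{0} ∪ sorted |T| ∪ {d_u}` — no tolerance is involved.
If no threshold qualifies, the conservative fallback `2 sqrt(log u)` is
used.  Under a simulated global null (u = 50, i.i.d. standard-normal T,
alpha = 0.05) the mean false-discovery proportion stays within Monte Carlo
error of the target level.

### Preprocessing

Phase-randomizing a finite row implicitly treats it as one period of a
cycle, so the raw signal is first clipped so that its last kept sample is
within 1% of its first sample, then zero-meaned.  The scale for
"approximately equal" is the peak-to-peak range of the initial 5% of the
record (plus a 1e−9·median|x| numerical floor so exact-zero anchors such as
Hanning endpoints match at float precision).  A global-range reference would
never reject a strongly monotonous signal (its range dwarfs any local
variation), and `|x_1|` alone degenerates when the record starts at noise
level; the start-local reference handles both, and is what rejects an
exponential ramp as unsupported.  Clipping must retain at least half the
record, else `NoClipPointError` marks the signal class as unsupported.
Re-clipping a clipped signal is a no-op up to a tolerance-width tail in
range mode; in the default mode zero-meaning rescales the tolerance, so
idempotence is only approximate.

Long recordings can optionally be truncated to standard length buckets
(350/400/500 s) so one cached white-noise null serves many recordings; this
is off by default for synthetic runs.

## Monte Carlo sizes and seeds

Defaults are sized for the desk-scale validation suite: `L = 250`
white-noise draws and `H = 150` phase-randomization draws (50 s records at
1 kHz, about 92 retained scales spanning 0.7–390 Hz, analysis window about
45 s; a full run takes a couple of minutes on one CPU).  Production
analyses of long recordings typically raise these to `L ≈ 1000`,
`H ≈ 250`.  All randomness flows from one root seed through spawned,
order-independent substreams: white-noise draw `v` and surrogate iteration
`h` have their own deterministic child seeds, so results are bit-identical
across reruns and invariant to execution order.

## The synthetic suite: what it emulates and what it does not

The generators produce the qualitative regimes the test must separate:
stationary narrowband content (double sinusoid, 10 + 50 Hz under a
whole-record Hanning envelope), transient narrowband content (Hanning
pulses, 30 Hz at 10–10.5 s and 5 Hz at 25–26.5 s), transient FM content
(quadratic chirps, 20→50 Hz and 1→5 Hz in the same intervals), broadband
harmonically locked content (square wave via its odd-harmonic series,
fundamental 2 Hz by default so many harmonics fit in band), a strongly
monotonous trend (exponential ramp, rejected at clipping), and structureless
noise (uniform white noise).  Additive Gaussian noise defaults to standard
deviation 0.05 against unit carrier amplitude — small enough not to mask
the deterministic structure, large enough that every scale has a nonzero
floor; carrier amplitudes and the square-wave fundamental are package
choices where only the construction, not the constants, is prescribed.

These signals do not emulate real recordings: no 1/f background, no line
noise, no artifacts, no measurement-chain filtering.  Passing the suite
shows the machinery separates the regimes above; it does not show that a
particular significant pair in real data is neural rather than instrumental
— that remains a pre-processing question.

Expected suite outcomes at alpha = 0.001: white noise — empty mask; double
pulse and double chirp — one main cluster per carrier, centered on the
diagonal; square wave — broad significance among well-separated band pairs
with the near-diagonal low-frequency region dark; exponential — clip error.

## Counting "main groupings"

Significance maps are summarized by the number of large 8-connected
clusters in the symmetrized mask (diagonal excluded), keeping components
with at least 0.5% of the matrix area.  Because the test provably cannot
reject immediately adjacent pairs (their null mean is ~1), a physical
cluster centered on the diagonal appears as two mirror lobes flanking a
thin dark band; a qualifying component that comes within 5 cells (half an
octave at 10 voices) of the diagonal is therefore merged with its mirror
and counted once, while well-separated off-diagonal clusters count together
with their mirrors — matching how such maps are read.

## Known limitations

* **Full-record amplitude modulation is invisible.**  A power row dominated
  by a record-length envelope (e.g. a whole-signal Hanning window) has on
  the order of one effective degree of freedom; two such rows correlate
  near ±1 by chance, and the FT null faithfully reports that (sd of the
  null ≈ 0.7).  Measured on the enveloped double sinusoid: r(10 Hz, 50 Hz)
  = 1.00 yet max |T| = 2.3 across the matrix — nothing is significant, and
  nothing can be.  Modulation must repeat or be localized (pulses, chirps,
  harmonic beating) to be distinguishable from chance.  This also means the
  test gets *more* sensitive with longer records only insofar as the shared
  structure recurs.
* **Extreme conservativeness near the diagonal**, by construction; near-
  diagonal non-significance is uninformative.
* **Instantaneous, linear association only**: no lags, Pearson only.
* **The white-noise bias is not fully input-independent** (kurtosis
  sensitivity above); the null's noise model is a modelling choice.
* **Monotonous signals are out of scope** (clipping rejects them); windowing
  as an alternative would distort the correlation weighting toward the
  record center and is not implemented.
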