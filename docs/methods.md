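# Methods

## Model

A 1D absorptive spectrum on a ppm grid x is modelled as a sum of K
Lorentzian signals plus white Gaussian noise:

    F(x) = sum_k (M_k / pi) * (g_k/2) / ((x - w_k)^2 + (g_k/2)^2),
    g_k = 10^(b_k) / f0   (FWHM converted from Hz to ppm),

with theta_k = {M_k, w_k, b_k}: M_k the peak area in arbitrary units
(integrating the component over ppm gives M_k), w_k the chemical shift in
ppm, b_k = log10(FWHM/Hz), and f0 the spectrometer frequency in MHz.  The
area-normalised form is used because M is interpreted as the macroscopic
magnetisation, i.e. the integral of the line, not its height.

Priors are independent uniforms on a box: M in [0, 700] a.u., w in
[-62, -55] ppm, b in [1, 4] (FWHM 10 Hz to 10,000 Hz).  The noise sigma
is a plug-in constant estimated from the FID tail, not a sampled
parameter, so the log likelihood is

    log L(theta) = sum_n [ -0.5*log(2*pi*sigma^2) - (y_n - F(x_n))^2 / (2*sigma^2) ].

The likelihood is evaluated over the full spectrum (N = 8192 under the
default preprocessing); K = 0 is the pure-noise model with no parameters.

## Preprocessing

1. **Digital-filter removal.** The group delay's integer part is undone by
   a circular sample shift, the fractional part by an exact frequency-
   domain phase ramp.  Length is preserved.
2. **Noise sigma.** The per-quadrature time-domain SD sigma_t is measured
   on the FID tail after 30.6 ms (where the signal has decayed).  With an
   unnormalized forward DFT and noise confined to the first n_keep points,
   each spectral bin's real part has variance n_keep * sigma_t^2; the
   estimator returns sqrt(n_keep) * sigma_t.  This bridge is unit-tested
   against the empirical spectral SD (Monte-Carlo over 50 seeds).
3. **Truncate + zero-fill.** First 4096 complex points (30.6 ms at the
   237 ppm / 565 MHz geometry) kept, zero-filled to 8192.
4. **Transform.** Unnormalized FFT, no apodization, real part kept, ppm
   axis descending with the carrier (`reference_shift`) at the window
   centre; the TFA preset puts the carrier at -76.55 ppm.
5. **Baseline.** A 4th-order polynomial fitted by iterative masking:
   points more than 3 robust sigmas (1.4826*MAD) *above* the running fit
   are excluded and the fit repeated, <= 10 passes.  Peaks are positive in
   absorptive data, hence the one-sided mask.
6. **Display only.** A 200 Hz exponential line broadening may be applied
   to model and observed FIDs for overlays; never before fitting.
   Convolution of Lorentzians makes the displayed width = FWHM + 200 Hz.

No phase correction is applied anywhere; the contract covers purely
absorptive (zero-phase) data and the simulator emits exactly that.

**Known limitation (baseline vs broad lines).** The robust mask cannot
exclude the sub-threshold far tails of a Lorentzian, so part of the tail
is absorbed into the polynomial.  The effect scales with the ratio of
linewidth to spectral window: at the full 237 ppm sweep a 165 Hz line
loses < 1% of its area, while on an 8x reduced sweep the bias reaches
~5% of M.  Quantitative recovery checks therefore run at the full sweep;
model-order selection, which is insensitive to a few percent of area, may
use reduced sweeps.

## Model-order selection

F(K) = -log p(D|K) is computed by thermodynamic integration,
F(K) = -int_0^1 E_beta[log L] d(beta), over a geometric inverse-
temperature ladder beta_j = beta1^(1-(j-1)/(J-1)) with beta_0 = 0
prepended (published geometry: J = 45, beta1 = 0.01, consecutive ratio
0.9006, 46 values).  At each beta > 0, n_chains independent adaptive
random-walk Metropolis chains start from random in-box points; at
beta = 0 the tempered posterior is the prior, so exact i.i.d. prior draws
are used.  Per (K, beta), each chain's retained-sample mean log
likelihood is screened by a two-sided generalized ESD outlier test
(alpha = 0.05, at most `max_outliers` removals; published setting: at
most 9 of 19 chains) and the surviving means are pooled with equal
weights.  The trapezoidal rule over the ladder gives F(K); K = 0 is
closed-form.  P(K|D) is the overflow-safe softmax of -F(K) under a
uniform prior on K in {0..K_max}, K_max = 3 by default.

**Sampler.** Gaussian random-walk Metropolis, vectorised across all
(beta, chain) walkers.  During burn-in the proposal covariance is adapted
Haario-style (2.38^2/d times the running sample covariance, refreshed
every 100 steps) together with a per-walker log step-size tuned toward
25% acceptance; both are frozen at the end of burn-in.  Because the prior
is uniform, acceptance inside the box reduces to exp(beta * dlogL) and
proposals outside the box are rejected outright.  All randomness for one
(seed, K) run flows from a single PCG64 generator seeded by the pair, so
reruns are bit-identical.

**Scales.** Published ("paper" profile): 400,000 steps, 200,000 burn-in,
thinning 100 (2000 retained per chain), 19 chains, 46 temperatures;
posterior run 100,050,000 / 50,000 / 200 (500,000 retained).
Workstation ("desk" profile): J = 12 ladder, 5 chains of 20,000 / 10,000 /
10, posterior run 60,000 / 10,000 / 25 with one chain.  The desk profile
resolves the same free-energy differences on the synthetic test problems
(they are tens to thousands of nats) at a few seconds per (K, scan).

**Ladder density near beta = 0.** E_beta[log L] drops by orders of
magnitude as beta -> 0 under the diffuse prior (measured around -1.5e4 on
an N = 256 problem whose F is ~1.2e3), so the trapezoid segment
[0, beta1] dominates the quadrature error when beta1 = 0.01.  For
evidence-accuracy validation against brute-force grid quadrature the
ladder is extended toward zero (beta1 = 1e-5, J = 24), which brings the
TI-vs-quadrature gap to ~0.2 nats on that problem.  Model *comparison* is
insensitive to this: the [0, beta1] error is nearly K-independent and
largely cancels in F differences, which is why the published beta1 = 0.01
geometry ranks models correctly.

## Posterior summaries

At the selected K, a long beta = 1 run produces retained draws with their
unnormalized log posterior.  Label switching (the K!-fold symmetry of the
exchangeable mixture) is resolved by the anchor procedure: an anchor
theta_bar is initialised to a randomly chosen draw (seeded); each draw is
then permuted to minimise the standardized Euclidean distance to the
anchor, and the anchor is reset to the component-wise mean of the
relabeled draws; the two updates alternate until no permutation changes
or 20 iterations.  Per-dimension scales for the distance are the pooled
SDs of the unrelabeled draws, computed once and held fixed (determinism);
zero-variance dimensions fall back to scale 1 with a warning.  Relabeling
is a pure per-draw permutation — parameter multisets and log posteriors
are untouched.

The MAP estimate is the retained draw with the largest log posterior
(ties: earliest index).  Credible intervals are percentile-based
([2.5, 97.5] at the default 95% level) on the relabeled draws; FWHM
intervals are 10^(interval of b) endpoint-wise, since percentiles commute
with monotone maps.

## Synthetic data

The simulator writes s(t_n) = sum_k A_k exp(i*2*pi*dnu_k*t_n -
pi*FWHM_k*t_n + i*phase_k) + eps_n with eps_n complex white Gaussian
(per-quadrature SD sigma_t).  The amplitude convention
A_k = 2 * dwell * f0 * area_k makes the preprocessed spectrum's
numerically integrated area equal area_k: the one-sided signal
contributes half its t = 0 amplitude as a flat offset across bins (the
Euler-Maclaurin half-sample term), which the baseline step removes, and
the remaining absorptive part integrates to area_k.  The convention is
locked by a round-trip test (area recovered within 1%, width within one
axis point, for a 50 Hz line at the full sweep).

What it emulates: the acquisition geometry (565 MHz, 237 ppm sweep,
65,536-point records — 16,384 by default since only 30.6 ms is fitted),
linewidths from the in vitro (27-165 Hz) to the in-cell (200-1000+ Hz)
regimes, SNR from ~50 down to the noise floor, and digital-filter group
delays.  What it does not: chemical-exchange lineshapes, phase errors,
baseline roll from hardware, t1 noise, or field drift — passing tests
show the inference machinery is correct under its own assumptions, not
that those assumptions hold for any particular instrument.

Named scenarios (`paper_preset_scenarios()`) pin the published regimes:
a 27.5 Hz narrow line and a 164.8 Hz broad line (the GDP- and
GMPPNP-bound reporter linewidths), a resolvable two-signal case near
-58/-58.9 ppm (64.6 and 164.8 Hz, separation 508 Hz), an in-cell-like
700 Hz line at SNR 5, and pure noise.  Scenario SNR is defined as
spectral peak height over sigma and is chosen to straddle the detection
threshold where the true in-cell value is not quantified.

**Reduced-sweep test family.** Inference-heavy tests use acquisitions
with sweep 237/2^m ppm and n_keep 4096/2^m, which preserve both the
30.6 ms fitted duration and the 0.0289 ppm/point resolution exactly while
cutting the likelihood grid by 2^m.  Problem sizes used: N = 512 for
model-order selection (three scenarios, three seeds each), N = 256 for
the evidence-vs-quadrature check, and the full N = 8192 for coverage and
round-trip physics (20 and 2 runs respectively).

## Validation oracles

- **Evidence:** `nmrdecon.validation.grid_log_evidence_k1` integrates
  likelihood x prior over the K = 1 box on a dense 200^3 grid (the M
  dimension via the exact quadratic SSR expansion), sharing no code with
  the TI path.  TI agrees within ~0.2 nats on the N = 256 problem.
- **Coverage:** 20 seeded single-signal runs at SNR ~ 25; 95% CIs cover
  the true (M, w, b) in >= 85% of runs per parameter (observed: 100%),
  and the MAP shift lands within one spectral point in all runs.
- **Distributional:** at beta = 0, and at beta = 1 with a flat
  likelihood, retained draws pass per-dimension KS tests against the
  uniform prior.
- **Deterministic identities:** K = 0 free energy equals its closed form
  exactly; a constant TI integrand c gives F = -c; P(K|D) sums to 1 to
  1e-12; gESD never removes more than its cap; relabeling preserves
  per-draw multisets exactly.

## Numerical and degenerate-input choices

- Trapezoidal rule for the thermodynamic integral; beta = 0 handled by
  exact prior sampling rather than MCMC.
- Non-finite likelihood at initialisation triggers up to 5 seeded
  redraws, then an error.
- Cholesky failures during covariance adaptation keep the previous
  proposal factor; a tiny diagonal jitter (1e-12 of the box span squared)
  guards rank deficiency.
- gESD with a zero sample SD (identical chain means) removes nothing;
  fewer than 3 chains skips the test.
- MAP ties break to the earliest draw; percentile CIs require >= 40
  draws; zero-width intervals are legal.
- The FID container stores floats via `repr` round-tripping, so
  write -> read is bit-exact.
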