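# nmrdecon

Bayesian spectral deconvolution for low signal-to-noise 1D NMR spectra,
built for in-cell ¹⁹F protein NMR where signals are broad, few, and close
to the noise floor.

In-cell ¹⁹F spectra of labelled proteins often contain one to three
heavily broadened resonances buried in thermal noise; deciding *how many*
signals are present, and quantifying their parameters with honest
uncertainties, is exactly where by-eye peak picking fails. `nmrdecon`
treats the problem as Bayesian inference:

- each signal *k* is an absorptive Lorentzian with parameters
  θ_k = {M_k, ω_k, β_k} — peak area (a.u.), chemical shift (ppm), and
  log₁₀ of the FWHM in Hz — under independent uniform priors
  (M ∈ [0, 700] a.u., ω ∈ [−62, −55] ppm, β ∈ [1, 4], i.e. FWHM between
  10 Hz and 10,000 Hz);
- the spectrum model is F(x) = Σₖ f_k(x; θ_k) and, because no apodization
  is applied before fitting, the spectral noise is white Gaussian with a
  σ estimated from the FID tail, giving the usual Gaussian log likelihood
  over all N = 8192 points;
- the number of signals K is selected by the Bayes free energy
  F(K) = −log p(D|K), computed by thermodynamic integration
  F(K) = −∫₀¹ E_β[log L] dβ over a geometric ladder of inverse
  temperatures (β₁ = 0.01, ratio 0.9006, 46 steps at the published
  scale), with independent adaptive Metropolis chains per temperature and
  a generalized-ESD test that drops chains stuck in poor local modes;
- posterior summaries at the selected K come from a long β = 1 run: the
  K!-fold label-switching symmetry is resolved by an iterative anchor
  relabeling (standardized Euclidean distance, ≤ 20 iterations), then the
  MAP draw and percentile 95% credible intervals are reported per signal.

A forward simulator generates FIDs with the exact statistical structure
the analysis assumes (decaying complex exponentials + complex white
noise, optional digital-filter group delay), so the whole chain is
testable end-to-end without any measured data.

## Worked example

```python
from nmrdecon import (PriorBox, build_ladder, evidence_scan, preprocess,
                      simulate_fid, sample_posterior_full, relabel_samples,
                      credible_intervals)
from nmrdecon.sampler import DESK_TEMPERED, ChainConfig
from nmrdecon.synthetic import AcquisitionParams, SimComponent

acq = AcquisitionParams(sweep_width=237/8, n_points=2048,
                        reference_shift=-58.5, noise_sigma_t=0.45)
truth = [SimComponent(180.0, -58.00, 64.6), SimComponent(150.0, -58.90, 164.8)]
spec = preprocess(simulate_fid(truth, acq, seed=5), n_keep=512, n_total=1024)

samples = sample_posterior_full(spec, K=2,
    cfg=ChainConfig(60_000, 10_000, 25, n_chains=1), box=PriorBox(), seed=5)
summary = credible_intervals(relabel_samples(samples, seed=5))
```

prints (via `examples/03_posterior_summaries.py`):

```
signal  M (a.u.)              shift (ppm)              FWHM (Hz)
1       176.5 [173.5, 178.9]   -58.000 [ -58.001, -57.999]    62.9 [  61.5,  64.3]
2       145.6 [140.9, 149.6]   -58.898 [ -58.902, -58.893]   160.4 [ 153.5, 166.9]
```

Both simulated signals are recovered: MAP areas, shifts and linewidths sit
at (or within a few percent of) the ground truth, and the 95% intervals
quantify what the data actually constrain — shifts to ~0.002 ppm,
linewidths to a few Hz at this SNR. `examples/02_model_order_selection.py`
shows the matching model-order step, where F(K) picks K = 2 decisively and
K = 3 pays the Occam penalty.

The same chain is available from the shell:

```bash
nmrdecon simulate --scenario two_component --out runs/input --seed 3
nmrdecon deconvolve --fid runs/input/two_component.fid.csv --profile desk \
    --seed 3 --out runs/two
nmrdecon report runs/two
```

`--profile paper` switches every sampler setting to the published scale
(46 temperatures, 19 chains of 400k steps, a 10⁸-step posterior run);
`desk` is sized for a workstation CPU.

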