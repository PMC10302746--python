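"""Posterior run, relabeling, MAP estimates and credible intervals.

Runs the beta = 1 sampler on a two-signal spectrum at fixed K = 2, resolves
the 2!-fold label-switching symmetry with the anchor procedure, and prints
per-signal MAP estimates with 95% credible intervals.
"""

import numpy as np

from nmrdecon import (
    PriorBox,
    credible_intervals,
    preprocess,
    relabel_samples,
    sample_posterior_full,
    simulate_fid,
)
from nmrdecon.sampler import ChainConfig
from nmrdecon.synthetic import AcquisitionParams, SimComponent

acq = AcquisitionParams(
    sweep_width=237.0 / 8, n_points=2048, reference_shift=-58.5, noise_sigma_t=0.45
)
truth = [
    SimComponent(area=180.0, shift=-58.00, fwhm=64.6),
    SimComponent(area=150.0, shift=-58.90, fwhm=164.8),
]
spec = preprocess(simulate_fid(truth, acq, seed=5), n_keep=512, n_total=1024)

cfg = ChainConfig(total_steps=60_000, burn_in=10_000, thinning=25, n_chains=1)
samples = sample_posterior_full(spec, K=2, cfg=cfg, box=PriorBox(), seed=5)
samples = relabel_samples(samples, seed=5)
summary = credible_intervals(samples)

print(f"{samples.T} retained draws, K = {summary.K}\n")
print("signal  M (a.u.)              shift (ppm)              FWHM (Hz)")
for i, c in enumerate(summary.components, start=1):
    print(
        f"{i}       {c.map_M:5.1f} [{c.ci_M[0]:5.1f},{c.ci_M[1]:6.1f}]  "
        f"{c.map_omega:8.3f} [{c.ci_omega[0]:8.3f},{c.ci_omega[1]:8.3f}]  "
        f"{c.map_fwhm_hz:6.1f} [{c.ci_fwhm_hz[0]:6.1f},{c.ci_fwhm_hz[1]:6.1f}]"
    )
print("\ntruth:  (180.0, -58.000, 64.6) and (150.0, -58.900, 164.8)")
# After relabeling, signal 1 tracks one chemical species and signal 2 the
# other; without it the marginals would mix the two and the intervals
# would be meaningless.
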