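"""Tempered MCMC, chain-outlier exclusion, and Bayes-free-energy model selection.

The number of signals K is selected by computing, for each candidate K, the
Bayes free energy F(K) = -log p(D | K) via thermodynamic integration:

    F(K) = - \\int_0^1 E_beta[ log L(theta) ] d beta

where E_beta is the expectation under the tempered posterior
p_beta(theta | D) \\propto phi(theta) L(theta)^beta.  The integral is
approximated by the trapezoidal rule over a geometric ladder of inverse
temperatures (beta_0 = 0, beta_J = 1).  At each positive beta, several
independent adaptive random-walk Metropolis chains are run from random
in-box starting points; chains trapped in poor local modes are excluded by
a generalized extreme Studentized deviate (gESD) test on their retained-
sample mean log likelihood, and the surviving per-chain means are pooled
with equal weights.  At beta = 0 the tempered posterior is the prior, so
exact i.i.d. prior draws replace MCMC.  The pure-noise model K = 0 has no
parameters and its free energy is available in closed form.

P(K | D) then follows by normalising exp(-F(K)) under a uniform prior on K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
from scipy import special, stats

from .model import PriorBox, log_likelihood_batch
from .posterior import PosteriorSamples
from .spectra import Spectrum

__all__ = [
    "TemperatureLadder",
    "ChainConfig",
    "EvidenceResult",
    "TemperedRun",
    "build_ladder",
    "retained_samples",
    "sample_tempered",
    "exclude_outlier_chains",
    "free_energy_zero_model",
    "free_energy_from_means",
    "model_order_posterior",
    "evidence_scan",
    "sample_posterior_full",
    "PAPER_TEMPERED",
    "PAPER_POSTERIOR",
    "DESK_TEMPERED",
    "DESK_POSTERIOR",
    "PAPER_LADDER_J",
    "PAPER_LADDER_BETA1",
]

PAPER_LADDER_J = 45
PAPER_LADDER_BETA1 = 0.01


@dataclass(frozen=True)
class TemperatureLadder:
    """Ordered inverse temperatures [0 = beta_0 < beta_1 < ... < beta_J = 1]."""

    betas: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.betas, dtype=float)
        object.__setattr__(self, "betas", b)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("ladder needs at least [0, 1]")
        if b[0] != 0.0:
            raise ValueError("ladder must start at beta = 0")
        if abs(b[-1] - 1.0) > 1e-9:
            raise ValueError("ladder must end at beta = 1")
        if not np.all(np.diff(b) > 0):
            raise ValueError("ladder must be strictly increasing")
        if b.size >= 4:
            ratios = b[1:-1] / b[2:]
            if not np.allclose(ratios, ratios[0], rtol=1e-8):
                raise ValueError("ladder must be geometric for j >= 1")

    @property
    def J(self) -> int:
        """Index of the top temperature; the ladder has J + 1 entries."""
        return self.betas.size - 1

    def __len__(self) -> int:
        return self.betas.size


def build_ladder(J: int = PAPER_LADDER_J, beta1: float = PAPER_LADDER_BETA1) -> TemperatureLadder:
    """Geometric inverse-temperature ladder with beta_J = 1 exactly.

    beta_j = beta1 * r^{-(j-1)} with r = beta1^{1/(J-1)}, so consecutive
    ratios beta_{j-1}/beta_j are constant (0.9006 for the J=45, beta1=0.01
    defaults) and beta_0 = 0 is prepended: 46 entries by default.
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    if not 0.0 < beta1 <= 1.0:
        raise ValueError(f"beta1 must lie in (0, 1], got {beta1}")
    if J == 1:
        return TemperatureLadder(np.array([0.0, 1.0]))
    j = np.arange(1, J + 1)
    betas = beta1 ** (1.0 - (j - 1) / (J - 1))
    betas[-1] = 1.0
    return TemperatureLadder(np.concatenate(([0.0], betas)))


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run settings for one stage (tempered scan or posterior run)."""

    total_steps: int
    burn_in: int
    thinning: int
    n_chains: int = 1
    max_outliers: int = 0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.burn_in < self.total_steps:
            raise ValueError("burn_in must be < total_steps")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if not 0 <= self.max_outliers < self.n_chains:
            raise ValueError("max_outliers must be < n_chains")


def retained_samples(cfg: ChainConfig) -> int:
    """Number of retained MCMC samples per chain: floor((total-burn)/thinning)."""
    return (cfg.total_steps - cfg.burn_in) // cfg.thinning


#: Published analysis settings: 19 chains of 400k steps (200k burn-in,
#: thinning 100 -> 2000 retained samples each) per temperature, with up to
#: 9 chains excluded by the gESD test.
PAPER_TEMPERED = ChainConfig(400_000, 200_000, 100, n_chains=19, max_outliers=9)

#: Published beta = 1 posterior run: 100,050,000 steps, 50,000 burn-in,
#: thinning 200 -> 500,000 retained samples.
PAPER_POSTERIOR = ChainConfig(100_050_000, 50_000, 200, n_chains=1)

#: Scaled-down settings sized for a single workstation CPU.
DESK_TEMPERED = ChainConfig(20_000, 10_000, 10, n_chains=5, max_outliers=2)
DESK_POSTERIOR = ChainConfig(60_000, 10_000, 25, n_chains=1)


# ---------------------------------------------------------------------------
# adaptive random-walk Metropolis, vectorised over walkers
# ---------------------------------------------------------------------------

def _adaptive_metropolis(
    loglik_fn: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    betas: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    total_steps: int,
    burn_in: int,
    thinning: int,
    rng: np.random.Generator,
    target_accept: float = 0.25,
    adapt_interval: int = 100,
):
    """Run W independent random-walk Metropolis chains in lockstep.

    Each walker w targets phi(theta) * L(theta)^{betas[w]} with phi uniform
    on the box, so acceptance reduces to exp(beta * delta logL) inside the
    box and rejection outside.  The proposal is Gaussian; its covariance is
    adapted during burn-in (Haario-style scaling 2.38^2/d of the running
    sample covariance, plus per-walker step-size tuning toward the target
    acceptance rate) and frozen afterwards.

    Returns (samples (R, W, d), logliks (R, W), acceptance_rate (W,)).
    """
    x = np.array(x0, dtype=float)
    W, d = x.shape
    span = upper - lower

    ll = loglik_fn(x)
    for _ in range(5):
        bad = ~np.isfinite(ll)
        if not bad.any():
            break
        x[bad] = rng.uniform(lower, upper, size=(int(bad.sum()), d))
        ll = loglik_fn(x)
    else:
        raise RuntimeError("non-finite likelihood at initialization after retries")

    # per-walker proposal: chol factors (W, d, d) and log step scales
    chol = np.zeros((W, d, d))
    chol[:, np.arange(d), np.arange(d)] = 0.05 * span
    log_s = np.zeros(W)

    # running moments for covariance adaptation
    cnt = 0
    sum_x = np.zeros((W, d))
    sum_xx = np.zeros((W, d, d))
    acc_window = np.zeros(W)
    acc_total = np.zeros(W)
    n_after = 0

    n_retained = (total_steps - burn_in) // thinning
    samples = np.empty((n_retained, W, d))
    logliks = np.empty((n_retained, W))
    r = 0

    base_scale = 2.38**2 / d
    for step in range(total_steps):
        z = rng.standard_normal((W, d))
        prop = x + np.exp(log_s)[:, None] * np.einsum("wij,wj->wi", chol, z)
        inside = np.all((prop >= lower) & (prop <= upper), axis=1)
        ll_prop = np.full(W, -np.inf)
        if inside.any():
            ll_prop[inside] = loglik_fn(prop[inside])
        log_alpha = np.full(W, -np.inf)
        log_alpha[inside] = betas[inside] * (ll_prop[inside] - ll[inside])
        accept = np.log(rng.uniform(size=W)) < log_alpha
        x[accept] = prop[accept]
        ll[accept] = ll_prop[accept]
        acc_window += accept

        if step < burn_in:
            sum_x += x
            sum_xx += x[:, :, None] * x[:, None, :]
            cnt += 1
            if (step + 1) % adapt_interval == 0:
                rate = acc_window / adapt_interval
                log_s += rate - target_accept
                acc_window[:] = 0.0
                if cnt >= 20 * d:
                    mean = sum_x / cnt
                    cov = sum_xx / cnt - mean[:, :, None] * mean[:, None, :]
                    cov *= base_scale
                    cov[:, np.arange(d), np.arange(d)] += 1e-12 * span**2 + 1e-300
                    try:
                        chol = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        pass  # keep previous factor
        else:
            acc_total += accept
            k = step - burn_in
            n_after += 1
            if (k + 1) % thinning == 0 and r < n_retained:
                samples[r] = x
                logliks[r] = ll
                r += 1

    acc_rate = acc_total / max(n_after, 1)
    return samples[:r], logliks[:r], acc_rate


@dataclass(frozen=True)
class TemperedRun:
    """Raw output of a tempered scan for one K: per-(beta, chain) retained-
    sample mean log likelihoods and post-burn-in acceptance rates."""

    K: int
    betas: np.ndarray                # (J+1,)
    mean_loglik: np.ndarray          # (J+1, n_chains)
    acceptance: np.ndarray           # (J, n_chains); beta = 0 has no MCMC
    n_retained: int


def _chunked_loglik(spec: Spectrum, thetas: np.ndarray, chunk: int = 256) -> np.ndarray:
    out = np.empty(thetas.shape[0])
    for i in range(0, thetas.shape[0], chunk):
        out[i : i + chunk] = log_likelihood_batch(spec, thetas[i : i + chunk])
    return out


def sample_tempered(
    spec: Spectrum,
    K: int,
    ladder: TemperatureLadder,
    cfg: ChainConfig,
    box: PriorBox,
    seed: int = 0,
) -> TemperedRun:
    """Tempered scan for a fixed K: independent chains at every beta > 0,
    exact prior draws at beta = 0.

    All (beta, chain) walkers are advanced in lockstep from a single stream
    seeded by (seed, K), with independent random in-box initialisation per
    walker.  Records each walker's retained-sample mean log likelihood; the
    expectations feed the thermodynamic integral.
    """
    if K < 1:
        raise ValueError("K must be >= 1 here; K = 0 is handled in closed form")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), int(K))))
    betas_mcmc = ladder.betas[1:]
    J, C = betas_mcmc.size, cfg.n_chains
    W, d = J * C, 3 * K
    beta_vec = np.repeat(betas_mcmc, C)
    lower = np.tile(box.lower, K)
    upper = np.tile(box.upper, K)

    x0 = box.sample(rng, K, W).reshape(W, d)

    def loglik_fn(X: np.ndarray) -> np.ndarray:
        return log_likelihood_batch(spec, X.reshape(-1, K, 3))

    samples, lls, acc = _adaptive_metropolis(
        loglik_fn, x0, beta_vec, lower, upper,
        cfg.total_steps, cfg.burn_in, cfg.thinning, rng,
    )
    R = lls.shape[0]
    mean_ll = np.empty((J + 1, C))
    mean_ll[1:] = lls.mean(axis=0).reshape(J, C)

    # beta = 0: the tempered posterior is the prior; use exact iid draws
    for c in range(C):
        draws = box.sample(rng, K, R)
        mean_ll[0, c] = _chunked_loglik(spec, draws).mean()

    return TemperedRun(
        K=K,
        betas=ladder.betas.copy(),
        mean_loglik=mean_ll,
        acceptance=acc.reshape(J, C),
        n_retained=R,
    )


# ---------------------------------------------------------------------------
# outlier chains, free energy, P(K | D)
# ---------------------------------------------------------------------------

def exclude_outlier_chains(
    values: Sequence[float], max_outliers: int, alpha: float = 0.05
) -> np.ndarray:
    """Indices of chains surviving a two-sided generalized ESD outlier test.

    The test statistic at each step is the maximum Studentized deviation of
    the remaining values; at most ``max_outliers`` values are ever removed.
    Used on per-chain mean log likelihoods to drop chains stuck in poor
    local modes before pooling.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("gESD test needs at least 3 values")
    if max_outliers >= n:
        raise ValueError("max_outliers must be < number of chains")
    if max_outliers == 0:
        return np.arange(n)

    alive = list(range(n))
    candidates: List[tuple] = []
    for _ in range(max_outliers):
        cur = x[alive]
        m = cur.mean()
        s = cur.std(ddof=1)
        if s == 0:
            break
        dev = np.abs(cur - m)
        j = int(np.argmax(dev))
        r_stat = dev[j] / s
        ni = len(alive)
        p = 1.0 - alpha / (2.0 * ni)
        tcrit = stats.t.ppf(p, ni - 2)
        lam = (ni - 1) * tcrit / np.sqrt((ni - 2 + tcrit**2) * ni)
        candidates.append((alive[j], r_stat > lam))
        del alive[j]

    # number of outliers = largest i whose statistic exceeded its critical value
    n_out = 0
    for i, (_, significant) in enumerate(candidates, start=1):
        if significant:
            n_out = i
    removed = {candidates[i][0] for i in range(n_out)}
    return np.array([i for i in range(n) if i not in removed], dtype=int)


def free_energy_zero_model(spec: Spectrum) -> float:
    """F(0) = -log L(D | pure-noise model), exactly (no sampling)."""
    sigma = spec.noise_sigma
    if sigma <= 0:
        raise ValueError("spec.noise_sigma must be positive")
    n = spec.n_points
    ll0 = -0.5 * n * np.log(2.0 * np.pi * sigma**2) - np.sum(
        spec.intensity**2
    ) / (2.0 * sigma**2)
    return float(-ll0)


def free_energy_from_means(betas: np.ndarray, pooled_means: np.ndarray) -> float:
    """Trapezoidal thermodynamic integral: F = -int_0^1 E_beta[logL] dbeta."""
    betas = np.asarray(betas, dtype=float)
    pooled = np.asarray(pooled_means, dtype=float)
    if betas.shape != pooled.shape:
        missing = betas.size - pooled.size
        raise ValueError(f"expectations missing for {missing} temperatures")
    if not np.all(np.isfinite(pooled)):
        bad = betas[~np.isfinite(pooled)]
        raise ValueError(f"non-finite expectations at temperatures {bad}")
    return float(-np.trapezoid(pooled, betas))


def model_order_posterior(
    free_energy_by_K: Dict[int, float],
    log_prior_by_K: Optional[Dict[int, float]] = None,
) -> Dict[int, float]:
    """P(K | D) proportional to exp(-F(K)) * phi(K), overflow-safe.

    phi(K) defaults to uniform over the candidate set.
    """
    ks = sorted(free_energy_by_K)
    logw = np.array([-free_energy_by_K[k] for k in ks], dtype=float)
    if log_prior_by_K is not None:
        logw = logw + np.array([log_prior_by_K[k] for k in ks])
    if not np.any(np.isfinite(logw)):
        raise ValueError("all free energies are infinite")
    logw -= special.logsumexp(logw)
    return {k: float(np.exp(v)) for k, v in zip(ks, logw)}


@dataclass(frozen=True)
class EvidenceResult:
    """Free energies, P(K | D), and per-(K, beta) chain diagnostics."""

    free_energy_by_K: Dict[int, float]
    posterior_by_K: Dict[int, float]
    mean_loglik: Dict[int, np.ndarray]        # K -> (J+1, n_chains)
    excluded_chains: Dict[int, List[List[int]]]  # K -> per-beta excluded ids
    betas: np.ndarray

    @property
    def best_K(self) -> int:
        return max(self.posterior_by_K, key=self.posterior_by_K.get)


def evidence_scan(
    spec: Spectrum,
    ladder: TemperatureLadder,
    cfg: ChainConfig,
    box: PriorBox,
    K_max: int = 3,
    seed: int = 0,
) -> EvidenceResult:
    """F(K) and P(K | D) for K = 0..K_max.

    K = 0 is exact; each K >= 1 runs a tempered scan, applies the gESD test
    per temperature, pools surviving per-chain mean log likelihoods with
    equal weights, and integrates over the ladder.
    """
    fe: Dict[int, float] = {0: free_energy_zero_model(spec)}
    mean_ll: Dict[int, np.ndarray] = {}
    excluded: Dict[int, List[List[int]]] = {}
    for K in range(1, K_max + 1):
        run = sample_tempered(spec, K, ladder, cfg, box, seed=seed)
        pooled = np.empty(len(ladder))
        excl_K: List[List[int]] = []
        for j in range(len(ladder)):
            row = run.mean_loglik[j]
            if cfg.n_chains >= 3 and cfg.max_outliers > 0:
                kept = exclude_outlier_chains(row, cfg.max_outliers)
            else:
                kept = np.arange(cfg.n_chains)
            pooled[j] = row[kept].mean()
            excl_K.append(sorted(set(range(cfg.n_chains)) - set(kept.tolist())))
        fe[K] = free_energy_from_means(run.betas, pooled)
        mean_ll[K] = run.mean_loglik
        excluded[K] = excl_K
    post = model_order_posterior(fe)
    return EvidenceResult(
        free_energy_by_K=fe,
        posterior_by_K=post,
        mean_loglik=mean_ll,
        excluded_chains=excluded,
        betas=ladder.betas.copy(),
    )


def sample_posterior_full(
    spec: Spectrum,
    K: int,
    cfg: ChainConfig = DESK_POSTERIOR,
    box: PriorBox = PriorBox(),
    seed: int = 0,
) -> PosteriorSamples:
    """Long beta = 1 run producing the retained posterior draws for K.

    Draws from every chain are concatenated; each retained draw carries its
    unnormalized log posterior density (log prior + log likelihood), which
    downstream MAP estimation maximises.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), int(K), 1)))
    W, d = cfg.n_chains, 3 * K
    lower = np.tile(box.lower, K)
    upper = np.tile(box.upper, K)
    x0 = box.sample(rng, K, W).reshape(W, d)

    def loglik_fn(X: np.ndarray) -> np.ndarray:
        return log_likelihood_batch(spec, X.reshape(-1, K, 3))

    samples, lls, _ = _adaptive_metropolis(
        loglik_fn, x0, np.ones(W), lower, upper,
        cfg.total_steps, cfg.burn_in, cfg.thinning, rng,
    )
    R = samples.shape[0]
    draws = samples.transpose(1, 0, 2).reshape(W * R, K, 3)
    lp = lls.T.reshape(W * R) - K * box.log_volume
    return PosteriorSamples(draws=draws, log_posterior=lp, K=K)
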