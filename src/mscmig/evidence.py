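"""Marginal likelihoods by thermodynamic integration; Bayes factors.

The log marginal likelihood is the path integral

    ln p(X) = \\int_0^1 E_beta[ ln p(X|G) ] d beta,

where the expectation is taken under the power posterior
p(Theta) p(G|Theta) p(X|G)^beta.  The integral is evaluated by
Gauss-Legendre quadrature on (0, 1); each quadrature point runs its own
independently seeded MCMC chain.  Bayes factors are differences of log
marginals, with |log B| > 4.6 (B > 100 or B < 1/100) flagged as strong
evidence, the conventional threshold for these gene-flow tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mcmc import MCMCSettings, run_mcmc
from .model import Locus, MigrationSpec, PriorSpec
from .species import SpeciesTree

__all__ = [
    "PowerSchedule",
    "schedule",
    "log_marginal",
    "thermodynamic_integral",
    "bayes_factor",
    "BayesFactor",
]

LOG_B_SIGNIFICANT = math.log(100.0)  # |log B| > 4.6


@dataclass(frozen=True)
class PowerSchedule:
    """Gauss-Legendre quadrature points for the power-posterior path."""

    beta: np.ndarray  # strictly increasing, in (0, 1)
    weights: np.ndarray  # sum to 1

    def __post_init__(self):
        if not np.all(np.diff(self.beta) > 0):
            raise ValueError("beta must be strictly increasing")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")

    @property
    def K(self) -> int:
        return int(self.beta.size)


def schedule(K: int) -> PowerSchedule:
    """K-point Gauss-Legendre schedule mapped linearly from (-1,1) to (0,1)."""
    if K < 1:
        raise ValueError("need at least one quadrature point")
    x, w = np.polynomial.legendre.leggauss(K)
    return PowerSchedule(beta=(x + 1.0) / 2.0, weights=w / 2.0)


def thermodynamic_integral(mean_loglik, sched: PowerSchedule) -> float:
    """Quadrature sum  sum_k w_k * E_{beta_k}[ln p(X|G)].

    ``mean_loglik`` maps a power beta to the expected log likelihood under
    the corresponding power posterior; it may be analytic (closed-form
    checks) or a Monte-Carlo estimate.
    """
    return float(sum(w * mean_loglik(float(b))
                     for b, w in zip(sched.beta, sched.weights)))


def _batch_se(x: np.ndarray, n_batches: int = 20) -> float:
    """Autocorrelation-robust standard error of the mean via batch means."""
    n = x.size
    if n < 2 * n_batches:
        return float(x.std(ddof=1) / math.sqrt(max(n, 2)))
    m = n // n_batches
    means = x[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return float(means.std(ddof=1) / math.sqrt(n_batches))


def log_marginal(loci: list[Locus], stree: SpeciesTree, mig: MigrationSpec,
                 priors: PriorSpec, sched: PowerSchedule,
                 settings: MCMCSettings, seed: int
                 ) -> tuple[float, float]:
    """Estimate ln p(X) for one model; returns (estimate, MC standard error).

    One power-posterior chain per quadrature point, each burned in
    independently with its own seed stream.
    """
    total = 0.0
    var = 0.0
    for k in range(sched.K):
        beta_k = float(sched.beta[k])
        w_k = float(sched.weights[k])
        sett = MCMCSettings(
            n_iter=settings.n_iter, burnin=settings.burnin,
            thin=settings.thin, beta=beta_k,
            tau_kernel=settings.tau_kernel,
            ages_per_locus=settings.ages_per_locus,
            sprs_per_locus=settings.sprs_per_locus,
            migtimes_per_locus=settings.migtimes_per_locus,
            tune=settings.tune, tune_interval=settings.tune_interval,
            mix_theta=settings.mix_theta)
        sub_seed = int(np.random.SeedSequence(seed, spawn_key=(k,))
                       .generate_state(1)[0] % (2**31 - 1))
        trace = run_mcmc(loci, stree, mig, priors, sett, seed=sub_seed)
        lnl = trace["lnL"]
        total += w_k * float(lnl.mean())
        var += (w_k * _batch_se(lnl)) ** 2
    return total, math.sqrt(var)


@dataclass(frozen=True)
class BayesFactor:
    log_b: float
    significant: bool

    def __float__(self) -> float:
        return self.log_b


def bayes_factor(logml_a: float, logml_b: float) -> BayesFactor:
    """log Bayes factor of model a over model b, with the |log B| > 4.6 flag."""
    if not (math.isfinite(logml_a) and math.isfinite(logml_b)):
        raise ValueError("log marginal likelihoods must be finite")
    log_b = logml_a - logml_b
    return BayesFactor(log_b=log_b,
                       significant=abs(log_b) > LOG_B_SIGNIFICANT)
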