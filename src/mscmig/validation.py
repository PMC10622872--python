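"""Reusable validation harnesses for the sampler.

Two checks, both standard for coalescent MCMC software:

* **prior sampling** -- run the full kernel mixture with the likelihood
  fixed to 1; every parameter marginal must then reproduce its prior
  (gamma for theta, M and the root age; the ratio of a non-root age to
  the root age is uniform on (0,1)).  This exercises every proposal,
  including the gene-tree moves, because the gene-tree density p(G|Theta)
  stays in the target.

* **Bayesian simulation** -- draw Theta from the prior, simulate a dataset,
  re-analyse it under the same prior, and repeat; across replicates the
  95% HPD interval must cover the generating value ~95% of the time and
  the pooled posterior must match the prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .mcmc import MCMCSettings, hpd_interval, run_mcmc
from .model import MigrationSpec, PriorSpec
from .simulate import SampleConfig, bayesian_replicate
from .species import SpeciesTree

__all__ = ["CalibrationReport", "prior_sampling_check", "bayesian_simulation"]


@dataclass
class CalibrationReport:
    """Outcome of a validation harness run."""

    n_rep: int
    coverage: dict[str, float] = field(default_factory=dict)
    ks_pvalue: dict[str, float] = field(default_factory=dict)
    ks_distance: dict[str, float] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self):
        for v in self.coverage.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("coverage must lie in [0, 1]")

    def coverage_ok(self, prob: float = 0.95, conf: float = 0.99) -> bool:
        """Every parameter's coverage inside the binomial `conf` band."""
        if not self.coverage:
            return False
        lo, hi = _stats.binom.interval(conf, self.n_rep, prob)
        return all(lo <= v * self.n_rep <= hi for v in self.coverage.values())

    def to_dict(self) -> dict:
        return {
            "n_rep": self.n_rep,
            "coverage": self.coverage,
            "ks_pvalue": self.ks_pvalue,
            "ks_distance": self.ks_distance,
            "notes": self.notes,
        }


def _prior_cdfs(stree: SpeciesTree, mig: MigrationSpec, priors: PriorSpec):
    """Map each traced parameter to its (possibly transformed) prior CDF.

    Non-root divergence times are checked through the ratio tau/tau_root,
    whose marginal prior is uniform on (0, 1) for every non-root node
    under the order-statistics prior.
    """
    checks = {}
    g = _stats.gamma
    root_lab = stree.labels[stree.root]
    for i in stree.internal_nodes:
        lab = stree.labels[i]
        if i == stree.root:
            checks[f"tau_{lab}"] = (None, g(priors.tau_shape,
                                            scale=1.0 / priors.tau_rate).cdf)
        else:
            checks[f"tau_{lab}"] = (f"tau_{root_lab}",
                                    _stats.uniform().cdf)
    for lab in stree.labels:
        checks[f"theta_{lab}"] = (None, g(priors.theta_shape,
                                          scale=1.0 / priors.theta_rate).cdf)
    for s, j in mig.pairs:
        checks[f"M_{s}_{j}"] = (None, g(priors.mig_shape,
                                        scale=1.0 / priors.mig_rate).cdf)
    return checks


def prior_sampling_check(stree: SpeciesTree, mig: MigrationSpec,
                         priors: PriorSpec, config: SampleConfig,
                         settings: MCMCSettings, seed: int,
                         thin: int = 50) -> CalibrationReport:
    """Run a likelihood-free chain and compare each marginal to its prior.

    Samples are thinned before the KS test to reduce autocorrelation; the
    reported p-values are therefore conservative screening statistics, not
    exact tests.
    """
    trace = run_mcmc(None, stree, mig, priors, settings, seed=seed,
                     sample_config=config)
    checks = _prior_cdfs(stree, mig, priors)
    rep = CalibrationReport(n_rep=1, notes="prior-sampling check")
    for name, (ratio_of, cdf) in checks.items():
        x = trace[name][::thin]
        if ratio_of is not None:
            x = x / trace[ratio_of][::thin]
        ks = _stats.kstest(x, cdf)
        rep.ks_pvalue[name] = float(ks.pvalue)
        rep.ks_distance[name] = float(ks.statistic)
    return rep


def bayesian_simulation(stree: SpeciesTree, mig: MigrationSpec,
                        priors: PriorSpec, config: SampleConfig,
                        n_rep: int, settings: MCMCSettings,
                        seed: int, hpd_prob: float = 0.95
                        ) -> CalibrationReport:
    """Prior-draw / simulate / re-infer calibration over replicate datasets.

    Reports per-parameter HPD coverage of the generating values and the KS
    distance between the pooled posterior (one draw per replicate per
    parameter would be exact; here the pooled thinned samples are used as
    a screening statistic) and the prior.
    """
    if n_rep < 2:
        raise ValueError("need at least two replicates")
    rng = np.random.default_rng(seed)
    covered: dict[str, int] = {}
    pooled: dict[str, list[np.ndarray]] = {}
    for _ in range(n_rep):
        truth, data = bayesian_replicate(priors, stree, mig, config, rng)
        loci = [loc for _, loc in data]
        chain_seed = int(rng.integers(2**31 - 1))
        trace = run_mcmc(loci, stree, mig, priors, settings, seed=chain_seed)
        values = {}
        for i in stree.internal_nodes:
            values[f"tau_{stree.labels[i]}"] = float(truth.tau[i])
        for i, lab in enumerate(stree.labels):
            values[f"theta_{lab}"] = float(truth.theta[i])
        for k, (s, j) in enumerate(mig.pairs):
            values[f"M_{s}_{j}"] = float(truth.M[k])
        for name, tv in values.items():
            x = trace[name]
            lo, hi = hpd_interval(x, hpd_prob)
            covered[name] = covered.get(name, 0) + int(lo <= tv <= hi)
            pooled.setdefault(name, []).append(x[:: max(1, x.size // 50)])
    rep = CalibrationReport(n_rep=n_rep, notes="Bayesian simulation")
    checks = _prior_cdfs(stree, mig, priors)
    for name, cnt in covered.items():
        rep.coverage[name] = cnt / n_rep
    for name, (ratio_of, cdf) in checks.items():
        if ratio_of is not None:
            continue  # pooled ratios need per-replicate roots; skip
        x = np.concatenate(pooled[name])
        ks = _stats.kstest(x, cdf)
        rep.ks_pvalue[name] = float(ks.pvalue)
        rep.ks_distance[name] = float(ks.statistic)
    return rep
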