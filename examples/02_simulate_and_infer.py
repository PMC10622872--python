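"""Simulate a multilocus dataset with gene flow and re-estimate everything.

Uses the three-species benchmark with B<->C migration: simulates 6 loci
(4 sequences per species, 500 sites, JC69), runs the MCMC sampler, and
prints posterior means with 95% HPD intervals next to the generating
values.  The root age is the slowest-mixing parameter, so the chain is
deliberately long for a small dataset.  Runs in about two minutes.
"""

import time

from mscmig import MCMCSettings, SampleConfig, run_mcmc, simulate_dataset
from mscmig.designs import three_species_bc_migration
from mscmig.io import summarize
from mscmig.mcmc import Trace  # noqa: F401  (type of the result)

stree, mig, truth, priors = three_species_bc_migration()
cfg = SampleConfig(n_seq=4, n_loci=6, n_sites=500)
data = simulate_dataset(stree, mig, truth, cfg, seed=811)
loci = [loc for _, loc in data]
print(f"simulated {len(loci)} loci; "
      f"mean migration events per genealogy "
      f"{sum(g.n_migrations for g, _ in data) / len(data):.2f}")

t0 = time.time()
settings = MCMCSettings(n_iter=26000, burnin=4000, thin=3)
trace = run_mcmc(loci, stree, mig, priors, settings, seed=812)
print(f"MCMC finished in {time.time() - t0:.0f}s; "
      f"acceptance (tau moves) "
      f"{trace.acceptance.get('tau/4', float('nan')):.2f}")

table = summarize(trace)
truth_by_name = {}
for i in stree.internal_nodes:
    truth_by_name[f"tau_{stree.labels[i]}"] = truth.tau[i]
for i, lab in enumerate(stree.labels):
    truth_by_name[f"theta_{lab}"] = truth.theta[i]
for k, (s, j) in enumerate(mig.pairs):
    truth_by_name[f"M_{s}_{j}"] = truth.M[k]

print(f"\n{'param':<10}{'true':>8}{'mean':>9}{'95% HPD':>20}")
for name, row in table.iterrows():
    print(f"{name:<10}{truth_by_name[name]:>8.4f}{row['mean']:>9.4f}"
          f"    ({row['hpd_lo']:.4f}, {row['hpd_hi']:.4f})")
print("\n-> nearly every interval covers its generating value (at 95% "
      "coverage the odd near-miss among nine parameters is expected); "
      "migration rates carry the wide intervals a handful of loci "
      "implies, and production analyses should run far longer chains.")
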