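# Methods

`mscmig` implements full-likelihood Bayesian inference under the
multispecies coalescent with migration (MSC-M), the continuous-gene-flow
member of the isolation-with-migration model family. This note documents
the model, the sampler, the numerical choices, and what the synthetic
benchmarks do and do not establish.

## Model

A rooted binary species tree defines one population per node. Time runs
from 0 at the present into the past and is measured in expected mutations
per site; a population labelled `j` is extant on `[tau_j, tau_parent(j))`.
The parameters are `Theta = {tau, theta, M}`:

* `tau` — species divergence times;
* `theta` — mutation-scaled population sizes: a pair of lineages in
  population `j` coalesces at rate `2/theta_j`;
* `M_sj = N_j m_sj` — the expected number of migrants per generation from
  species `s` into species `j`, defined forward in time. Traced backward,
  a lineage in `j` jumps into `s` at rate `4 M_sj / theta_j`. The
  connection `(s, j)` is *active* exactly while both populations are
  extant; its activity can therefore flip when `tau` changes.

The latent variable at locus `i` is the full genealogy `G_i`: topology,
coalescent times, and the ordered migration history (which lineage
switched population, when, and between which pair). The joint target is

    p(Theta, G | X) ∝ p(Theta) p(G | Theta) p(X | G).

`p(G|Theta)` is a product over populations of variable-rate Poisson
factors: `log(2/(theta_j h_i))` per coalescence, `log(4 M_sj/(theta_j h_i))`
per migration event into `j`, minus the exposures
`n(n-1) t / (theta_j h_i)` and `4 n t M_sj / (theta_j h_i)` accumulated
over the constant-rate segments between events. `h_i` is the per-locus
heredity scalar (1 autosomal, 3/4 X, 1/4 Y/mtDNA); by default it rescales
theta identically in the coalescent and migration terms
(`scale_migration_by_h=True`, exposed because the conventions differ only
when `h != 1`). The process, and therefore the density, stops at each
locus' MRCA: the single remaining lineage's later wandering between
populations is marginalized out exactly and carries no terms. All density
work is done through per-locus sufficient statistics (coalescence and
migration counts plus the two exposures), which depend on `(G, tau)` but
not on `(theta, M)` — parameter updates are then O(loci) scalar work.

`p(X|G)` is the Felsenstein pruning likelihood under JC69 with uniform
root frequencies and compressed site patterns; gaps and ambiguity codes
are treated as missing. Migration events never enter the likelihood: the
mutation rate is population-independent, so only coalescent times set
branch lengths.

## Priors

Gamma distributions parameterized by (shape `a`, rate `b`), mean `a/b`:
one gamma shared by all `theta`, one for the root age, one shared by all
migration rates. Non-root divergence times are uniform order statistics
on `(0, tau_root)` subject to the tree's ancestor–descendant constraints;
the normalising constant comes from the hook-length formula for the
internal-node poset, keeping the prior proper (this matters for marginal
likelihoods). The literature this implements states only that gamma
priors were used for all three blocks; the uniform-order choice for
non-root ages is our reconstruction of standard practice and is flagged
as such. Rates of *inactive* migration connections keep their gamma
density in the target: this doubles as the pseudo-prior of the
composite-space construction below. A rate fixed at exactly 0 is treated
as a point mass (degenerate no-migration case) rather than through the
gamma density.

## Sampler

One iteration applies, in order: rubber-band divergence-time updates
(one per internal node), a configurable number of divergence-time
*slides*, sliding-window updates of every `theta` and every `M`, per-locus
genealogy moves (node ages, regrafts, migration-event times), and a
global mixing move. Step sizes are tuned toward ~30% acceptance during
burn-in only, then frozen, which preserves detailed balance for the
recorded samples.

* **theta / M sliding windows.** Reflection at zero; only the prior and
  the gene-tree density enter the ratio.
* **Migration-time slide.** The event moves within the interval bounded
  by its neighbours on the same edge and the activity window; the
  likelihood is untouched.
* **Node-age slide.** Bounds come from the entering lineages' last
  population switches, the species divergence below which the two
  entering lineages are in different populations, and the first event on
  the node's own edge. The node's population follows the move
  deterministically.
* **Rubber-band divergence-time update.** Gene-tree node ages in the two
  daughter populations within `(tau_l, tau)` map linearly onto
  `(tau_l, tau')`; ages in the updated population map onto
  `(tau', tau_u)` (for the root, the upper side is a rigid shift). The
  *extended* variant maps affected migration times the same way, with the
  product of scale factors as the Jacobian; the *rejection* variant
  leaves migration times untouched and abandons the move on any conflict.
  Both are available (`tau_kernel`); the extended variant is the default
  and mixes no worse, substantially better when events are plentiful.
  Because activity windows are recomputed, migration-rate parameters may
  appear or disappear during the move: with pseudo-prior = prior
  (metropolized Carlin–Chib), the rate's prior term cancels from the
  ratio and the only extra rule is that a flip which would orphan
  existing migration events rejects. Correctness of this composite-space
  behaviour is enforced by the prior-sampling test on a four-species
  model whose ancestral connection flips with the tau order (long-run
  P(tauS < tauT) = 1/2, the prior value).
* **Divergence-time slide with relabelling.** A cheap complement to the
  rubber band: `tau` slides without touching any gene-tree *time*;
  coalescences whose population's lifespan no longer contains their age
  are relabelled deterministically to the population on the other side of
  the boundary (an involution, so the proposal stays symmetric), and any
  configuration that cannot be relabelled consistently rejects. Branch
  lengths are unchanged, so the likelihood drops out and the move can be
  applied several times per iteration (`tau_slides`).
* **Regraft (SPR) with migration.** A non-root node is pruned and its
  lineage re-simulated backward under the current parameters: migration
  at the per-lineage rates, coalescence at rate `2/(theta h)` with each
  backbone lineage in the same population. The Hastings ratio is the
  density of the old path scored under the same law against the same
  backbone. Configurations that would leave migration events above the
  new MRCA are outside the state space and reject. On a two-sequence
  locus the move reduces to drawing the coalescent time from its exact
  conditional, which the tests verify distributionally.
* **Mixing move.** All divergence times, coalescent times and migration
  times rescale by `c = exp(step (u - 1/2))` with proposal ratio `c^d`,
  `d` the number of scaled variables; optionally theta rescales too
  (`mix_theta`, default off, since the main text of the source literature
  leaves this ambiguous).

With no data (likelihood ≡ 1) the chain samples `p(Theta) p(G|Theta)`;
with `beta` in (0,1) it targets the power posterior used for
thermodynamic integration.

Chains start from moment estimates: within-species JC distance for tip
`theta`; half the *largest* spanning between-clade divergence (gene flow
only lowers apparent divergence) minus the mean tip `theta`, floored at
the prior-implied ladder, for node ages. Gene trees are then simulated
from the starting parameters, which guarantees a valid joint state.

## Marginal likelihoods and Bayes factors

`ln p(X)` is the thermodynamic integral of the expected log likelihood
along the power-posterior path, evaluated by K-point Gauss–Legendre
quadrature mapped linearly to (0,1) (default K = 8; the conjugate-toy
test shows K = 8 is already exact to ~1e-6 on smooth paths). Each
quadrature point runs an independently seeded chain; standard errors use
batch means. Bayes factors are differences of log marginals with the
conventional |log B| > 4.6 threshold for strong evidence. Marginal
likelihoods are comparable between models on the same species tree (the
order-statistics constant cancels in every Bayes factor we form).

## Validation harnesses

* **Prior sampling** (`prior_sampling_check`): likelihood ≡ 1, KS
  comparison of every parameter marginal against its prior (non-root ages
  via the ratio to the root age, which is uniform). Samples are thinned
  before the KS test; the root age is the stickiest parameter
  (integrated autocorrelation ~70 iterations even in prior mode), so
  meaningful checks need thinning of that order.
* **Bayesian simulation** (`bayesian_simulation`): draw `Theta` from the
  prior, simulate, re-infer under the same prior, repeat; 95% HPD
  coverage of the generating values must sit inside the binomial band,
  and the pooled posterior approaches the prior.

Beyond these, the test suite cross-validates every pairing of components:
density vs a hand-transcribed worked example (|Δ| < 1e-10 over random
draws), density vs simulator by importance-sampling normalisation
(E[p_target/p_proposal] = 1, checked shallow and ~1000 coalescent units
deep), pruning vs a brute-force sum over internal states and vs the
sequence simulator's joint pattern frequencies (likelihood sums to 1 over
all site columns), and each genealogy kernel against the simulator's
distribution with `Theta` held fixed.

## Numerical choices

* All densities in log space; events of rate zero map to −inf.
* Half-open population lifespans `[start, end)`; an event at exactly a
  boundary belongs to the segment ending there; divergences sort before
  same-time genealogical events.
* Pruning uses per-node rescaling by the maximum partial likelihood.
* Exposure statistics rescale linearly under the mixing move, so that
  move needs no event resweep.
* Proposals that would produce exactly tied event times have probability
  zero and are not specially handled beyond the tie-break above.

## Benchmark designs and desk-scale sizes

`mscmig.designs` provides the standard benchmark configurations: the
three-species tree ((A,B)S,C)R with `tauR = 0.02`, `tauS = 0.01`,
`thetaA = thetaS = 0.015`, `thetaB = thetaC = thetaR = 0.025`, with either
B↔C migration (`M_BC = 0.2`, `M_CB = 0.1`) or all eight rates
(`M_AB = 0.12, M_BA = 0.21, M_AC = 0.13, M_CA = 0.31, M_BC = 0.23,
M_CB = 0.32, M_CS = 0.2, M_SC = 0.1`); and four-population stepping-stone
and island models with `theta = 0.002`, `M = 0.15` and divergence times
around 1000 coalescent units, under which all coalescence predates every
divergence and ancestral sizes are prior-only. Analysis priors put the
root-age prior mean at 0.024 and the migration prior mean at the centre
of the generating rates, mirroring the usual benchmark practice of
centring priors near truth.

Problem sizes are deliberately desk scale. The acceptance script
simulates one dataset per design — L = 100 loci (4 sequences per species,
500 sites) for the B↔C and stepping-stone designs, L = 150 for the
saturated design — and runs chains of 11500 / 2600 / 5000 iterations
(burn-in 3500 / 800 / 1500) with a lightened per-locus move schedule
(one node-age and one event-time update per locus per iteration): the
slow directions are the divergence times and migration rates, so for a
fixed CPU budget longer chains beat denser genealogy sweeps. The test
suite uses much smaller L (6–20) with 8k–26k iteration chains: in
data-rich migration models the root age and the migration rates relax
diffusively (integrated autocorrelation of thousands of iterations), and
at smaller L the posteriors are wider and the chains equilibrate
honestly within the suite's runtime. The Bayesian-simulation calibration
runs 14 replicates at (L = 8, S = 2, N = 200); the gene-flow
Bayes-factor check uses L = 28 loci and 3 quadrature points. Production
analyses should use chains an order of magnitude longer than any of
these.

## What the synthetic benchmarks do and do not show

The generator produces data exactly under the model: free recombination
between loci, none within, JC69 mutation, constant per-population rates.
Passing tests therefore demonstrate the internal correctness of the
density, simulator, likelihood and sampler — not robustness to
recombination within loci, rate variation across sites or lineages,
selection, or misspecified migration structure, none of which the model
represents. Migration-rate estimates remain diffuse at desk-scale locus
counts; that is a property of the inference problem, matching the
behaviour reported for these benchmarks at far larger L.

## Known limitations

* JC69 only; no rate heterogeneity or partitioned models.
* The species phylogeny and the set of migration connections are fixed;
  no cross-model moves over phylogenies or migration-edge sets.
* Migration histories are sampled explicitly, not integrated analytically
  (the continuous-time Markov chain alternative scales poorly in species
  and sequences but is exact per locus; it is the natural cross-check for
  very small problems).
* Mixing over the root age / migration-rate ridge is diffusive; honest
  credible intervals require long chains, and the per-move acceptance
  log plus split-half comparisons should always be inspected.
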