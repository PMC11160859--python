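# Methods

## Population models

A model is a time-homogeneous (optionally time-varying) Markov jump process
on a finite truncated integer lattice, specified by jump marks.  Each mark
bundles a rate `α_u(t, x)`, a deterministic state update, and a
*participants* descriptor saying how the event touches lineages: a single
parent deme and offspring demes for birth-type events, dying demes, a
(source, destination) pair for migrations, sampled demes for sampling events,
and compound combinations (birth/death as in the Moran model, sample/death
for removal-on-sampling).  The production vector — lineages emerging per deme,
with dying lineages excluded and a surviving parent included — is derived
from this descriptor and is constant per mark by construction.

Builtin models: `sirs`, `seirs` (demes E, I; five marks: transmission
birth, progression migration, recovery death, sampling, waning neutral),
`two_strain`, `progression`, `superspreading`, `moran`, and `lbd` (linear
birth–death with per-capita birth λ, death μ, sampling ψ and binomial
sampling ρ at the horizon).  Closed epidemics use the simplex
`S + E + I + R = N` as their state space; the linear birth–death model uses
`0 ≤ x ≤ xmax` with an explicit truncation bound.  Transitions whose target
leaves the truncated lattice contribute hazard but no gain; the filters
report the probability mass sitting on boundary states so users can verify
the truncation was generous enough (likelihoods are invariant to the bound
once the boundary mass is negligible, which the tests check).

## Genealogies

Genealogies are node tables (id, time, kind ∈ {root, internal, sample, tip},
deme, parent).  A node stores the deme of the edge *above* it; deme changes
therefore occur only at nodes.  All paths are càdlàg: values at an event time
are post-event, and an edge occupies the half-open interval
`[t(parent), t(child))`.  Roots anchor trees at time 0.

*Pruning* drops tips and recursively removes childless non-sample nodes.
Internal nodes left with one child (inline nodes) are retained: they mark
deme changes and births whose other descendants were pruned, and the colored
filter treats each of them as a genuine singular event.  *Obscuring* erases
demes and splices out inline internal nodes, leaving only branch points and
samples with their times.

Sample labels are assigned in collection order (simultaneous samples ordered
by deme, then draw order), and all likelihoods are for ordered samples; an
unordered convention differs by `k!` per simultaneous k-sample event.

## Likelihood machinery

The per-event weight is `φ_u = binomial_ratio(n(x), ℓ, r^u, s) · Q_u`, with
the binomial ratio computed in log space (exact `Fraction` arithmetic is
available and used to verify the Chu–Vandermonde normalization
`Σ_s ratio · Π_i C(ℓ_i, s_i) = 1`, reading the normalizing factor as the
per-deme product of binomials, which is the reading under which the identity
holds).  The compatibility indicator `Q` is an explicit rule table over
(event class, local node kinds, deme pattern): branch points accept only
birth-type marks with matching parent deme and saturation ≤ production;
color changes accept matching migrations or births; sample nodes accept
sampling marks of matching deme and multiplicity; and at non-node times every
mark is compatible except sampling marks, whose events always leave a node
(sample nodes are never pruned).

**Likelihood given a history** is the product of φ over the history's jumps,
zero unless the genealogy's event times are among the jump times.

**Colored filter.**  The weight vector over population states satisfies a
linear ODE between genealogical events — gains `α_u(x′→x) · φ_u(s=0)` for
non-sampling marks, losses at the full total hazard — and a sparse
multiplicative update at each event time.  The likelihood is the terminal
total mass.  The adjoint form integrates the transposed system backward from
a terminal condition of ones and returns `Σ_x F(0,x) p0(x)`; forward and
adjoint agree to integration accuracy and are both exposed.

**Obscured filter.**  The weight is indexed by (state, hidden coloring),
where a coloring assigns a deme to each extant lineage of the tree.  Its
regular part adds *hidden-inline* gains in which one observed lineage passes
invisibly through an event: for a birth-type mark with parent deme d, any
observed lineage currently in d may continue as any emergent deme; for a
migration, any observed lineage in the source deme may move.  Summing these
gains over the single-deme Moran model reproduces the classical net
coalescent decay `−μ C(ℓ,2)/C(n,2)` exactly (verified in rational
arithmetic), which pins down the construction.  Initial weights put the full
`p0(x)` mass on every coloring the occupancy can support; the reported
likelihood is the sum over terminal colorings.

**Integration.**  For time-homogeneous models each inter-event segment is a
constant sparse linear system and is propagated by the action of the matrix
exponential (`expm_multiply`), which is effectively exact and is what lets
the generic solver meet 1e-8 agreement with closed forms.  Time-varying
rates fall back to an adaptive LSODA integration at rtol 1e-8 / atol 1e-12
(both tolerances are exposed).  Weights are renormalized after every segment
with the log-scale accumulated, so likelihoods of order e-300 and below are
representable.  Structurally impossible data yield −∞, not an error.

**Scheduled events.**  Deterministic-time events enter as singular updates:
binomial sampling at the horizon multiplies by
`C(n_d, k) ρ^k (1−ρ)^{n_d−k}`, and fully conditioned terminal sampling by 1.

## Sampling-time conventions

Two conventions coexist, chosen per mark:

* **Hazard sampling** (`lbd`, `seirs`, …): sampling is a Poisson process; its
  hazard appears as a pure loss between events (the probability that no
  unobserved samples occurred is part of the likelihood), and each sample
  node contributes `α_u φ_u`.
* **Conditioned sampling** (`moran`): the sample *times* are conditioned on,
  as in the serially-sampled coalescent; the mark is flagged
  `observed_only`, contributes no hazard between events, and each sample
  contributes the Poisson density factor ψ times the uniform-choice pattern
  probability — terminal samples `ψ(1 − ℓ/n)`, inline samples `ψ/n`, with ℓ
  the post-event count.  This makes the Moran filter agree exactly with the
  classical serially-sampled coalescent likelihood.  The simulator still
  generates sampling times as a Poisson process when creating data.

Lineage-count conventions at events are always post-event (càdlàg); the
closed forms use the same convention, fixed by requiring exact agreement with
the filter.

## Simulation

Gillespie simulation, exact for time-homogeneous rates; time-varying rates
require a user-declared bound and use thinning.  All randomness flows through
one `numpy.random.Generator`; every public entry point takes a seed and is
bit-reproducible.  Genealogy actions choose participant lineages uniformly
within demes, and per-deme tip counts are asserted equal to the occupancy
along the path when checking is enabled.  The Moran compound event selects
the dying lineage uniformly among the n−1 non-parents, which yields pair
coalescence at rate `μ/C(n,2)`.

## Monte-Carlo estimators

`montecarlo_loglik` is an importance-sampling check of the colored filter:
histories are simulated with jumps *forced* at the genealogical event times
(uniform choice among compatible mark/state options, weight `m_t α_u φ_u`),
sampling hazards are removed from the proposal and restored as an exact
`exp(−∫ Σ α dt)` factor, and free jumps carry their `φ(s=0)` weight.  The
weight mean is unbiased for the filter likelihood.  Naively averaging the
history-conditional likelihood over unconditioned simulations would be
degenerate — a fixed genealogy's event times are hit with probability zero —
so the forced-jump construction is the meaningful form of that average.

`smc_loglik` extends this to obscured genealogies: particles carry (state,
hidden coloring); hidden updates at free jumps are proposed proportionally to
φ with the marginal Σφ absorbed into the weight, and forced node updates draw
from the columns of the same singular gain matrices the deterministic filter
uses.  Particles run in independent blocks (~200 particles each); systematic
resampling triggers within a block when the effective sample size falls below
half the block; the combined estimator is the mean of the per-block unbiased
estimators and the standard error is a delete-one-block jackknife, which
stays honest under resampling.  Proposals are uniform over locally compatible
options, as the change-of-measure theory explicitly permits; user-supplied
proposal kernels are a natural extension point but are not implemented.

## Study designs used in the tests

The test suite simulates its own data; sizes were chosen to be desk-scale
while keeping Monte-Carlo checks sharp:

* SEIRS case study: N = 16, β = 2.5, σ = 2, γ = 1, ψ = 0.3, ω = 0.5, two
  initial infectious hosts, horizon 2.5, genealogies with 3–4 samples;
  the history-averaging check uses 1e5 forced histories, SMC checks 1e4
  particles.
* Moran fixtures: n = 6–8, μ = 1–2, serial ψ ≈ 1, horizons 2–3.
* Linear birth–death: a grid of (λ, μ, ψ, ρ) with x0 ∈ {1,2,3}, horizon 2,
  truncation 120; parameter recovery uses λ = 1.5, μ = 1, ψ = 0.5, ρ = 1,
  x0 = 10, horizon 2, 50 simulated genealogies.

What passing these tests shows — and does not show.  The generator emulates
exchangeable compartmental dynamics exactly, so agreement between the
solvers and the closed forms is a check of correctness, not of model realism.
Real sequence data add phylogenetic reconstruction error, non-exchangeable
hosts, and sampling schemes correlated with the epidemic state, none of which
the synthetic data exhibit.

## Limitations

* Deterministic filters enumerate the truncated state space (and, for
  obscured trees, `|demes|^ℓ` hidden colorings); they are meant for desk-scale
  validation and small studies.  SMC is the path to larger models, with cost
  linear in samples and particles.
* One event type per instant: simultaneous multi-parent births and
  simultaneous multi-deme migration or sampling are not supported by the
  filters (multi-deme simultaneous sampling is accepted at the mark level for
  production arithmetic but flagged by `validate_model`).
* Time-varying rates are supported through the ODE path but no builtin
  exercises them; exact simulation then requires a declared rate envelope.
* No diffusion (continuous-state) components; no likelihood gradients; no
  inference machinery beyond likelihood evaluation and the scipy optimizers
  used in the tests.
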