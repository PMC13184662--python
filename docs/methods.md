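# Methods

## The game

`coordsig` simulates a population playing a generalized Bach-or-Stravinsky
(BoS) coordination game.  Each agent has a fixed *preference type* T with a
payoff vector pi_T over the available actions: when two agents resolve to the
same action a, each earns its own pi_T(a); miscoordination pays 0.  Unlike
the classic two-player BoS, any number of types and actions is allowed, so
one population can contain rivals (no mutually valued action except a
grudging third option), nested subgroups (a zealous sect valuing its parent
group's greeting second-best), or blends (a type happy with either of two
other groups' norms).

Agents may also broadcast discrete *identity signals* in D dimensions.
Dimension k offers a null symbol 0 plus one or more real signals.
Broadcasting and attending are coupled per dimension: an agent that
broadcasts 0 in dimension k also ignores dimension k in everyone else,
perceiving partners as silent there.  Attending to a dimension costs `c` per
interaction.  A *strategy profile* is a heritable string: the D broadcast
symbols followed by one contingent action for every receivable signal
combination (all combinations are enumerated mixed-radix, first dimension
most significant, 0 first; profiles serialize to fixed-length digit
strings).

A dyadic interaction resolves in two steps: each side masks the partner's
signal vector by its own attention, looks up its contingent action for the
perceived combination, and earns pi_T(a) if both resolved actions agree,
minus c times its own attended dimensions.

## Dynamics

The population holds a fixed count of agents per type (type identity never
changes).  Per time step, in order:

1. **Mutation.**  Each agent is selected with probability mu1; each element
   of a selected agent's profile string is resampled uniformly from its
   alphabet with probability mu2.
2. **Utilities.**  A strategy's utility for a type is its expected dyadic
   payoff against a partner drawn from the whole population (own type
   included), i.e. the population-share-weighted mean payoff.
3. **Selection.**  A discrete replicator update within each type:
   n_s <- n_s * U_s / U-bar, then renormalization so each type's total is
   exactly conserved.

Two representations of the population are available:

- **Agent-resampling mode (default).**  Masses are whole agents.  Mutation
  is drawn exactly (binomial selection, per-element resampling), and after
  the replicator reweighting the integer population is redrawn from the
  post-selection distribution (a Wright-Fisher style multinomial).  This
  mode is stochastic but fully reproducible given the seed.
- **Expected-flow mode.**  Masses are continuous; mutation is applied as the
  expected mass flow through the product kernel, and the whole run is a
  deterministic map of the initial population.

The stochastic mode is the default because several scenarios hinge on
symmetric ties that deterministic flow freezes rather than resolves: e.g.
when a blended minority has no distinct norm of its own, which parent norm
it adopts internally is decided by symmetry breaking, and the expected-flow
map simply preserves the initial near-50/50 split forever.  The
expected-flow mode remains useful for fast, noise-free analysis of
asymmetric scenarios.

Utilities can be negative when attention costs exceed coordination payoffs.
Since the replicator ratio update needs positive weights, whenever a type's
minimum utility over present strategies is <= 0, that type's utilities are
shifted by a common constant so the minimum is 1e-9.  The shift preserves
the ranking of strategies; it is applied only when needed so that the
dynamics are the textbook discrete replicator whenever payoffs are positive.

### Convergence

The full profile distribution never settles: actions contingent on signal
combinations a type cannot perceive are selectively neutral, so mutation
and drift keep reshuffling them on a 1/(mu1*mu2) timescale.  Convergence is
therefore monitored on the selection-relevant *margins* — each type's
distribution over broadcast signal vectors plus its per-combination action
marginals:

- deterministic runs stop when every type's per-step L1 margin change stays
  below `convergence_tol` (1e-6) for `convergence_window` (25) steps;
- stochastic runs fluctuate at the sampling noise floor, so they stop when
  the modal pattern (each type's modal signal and modal action on every
  combination perceivable under it) has been unchanged for 2,000 steps and
  the exponentially smoothed margins (alpha = 0.02) have drifted less than
  0.1 (L1, per type) across that window.  Both the pattern and the drift are
  restricted to components that are perceivable *and* payoff-relevant
  against the current modal profiles: a type can be genuinely indifferent
  over its response to some perceived combination (e.g. responses to
  partners who will never adopt any action it values), and such entries
  random-walk under mutation forever.

Runs that hit the step cap are returned with `converged=False` and are
still classified; analyses report the flag.

## Parameter defaults and what they mean

| parameter | default | meaning |
|---|---|---|
| N | 1000 | agents; sets initial-condition granularity and sampling noise |
| mu1 | 0.1 | per-agent mutation probability per step |
| mu2 | 0.1 | per-element resampling probability given selection |
| V | 2 (baseline) / 4 (multidimensional scenarios) | preferred-greeting payoff |
| c | 0 (baseline) / 0.02 (costly scenarios) | attention cost per dimension per interaction |
| steps | 6000 | step cap |
| dominance threshold | 0.90 | mass share for a type to "reliably" signal/act |

N, mu1, mu2 and the step cap are not identified by the scenario definitions
and were fixed once at values typical for replicator-with-mutation models of
this size: mutation strong enough to keep the strategy space explored from a
random start (expected per-element rewrite rate mu1*mu2 = 1%), weak enough
that modal profiles stay above the 0.90 dominance threshold at
mutation-selection equilibrium.  The dominance threshold exists because
mutation keeps a few percent of deviant profiles alive, so exact unanimity
never occurs; 0.90 cleanly separates resolved from genuinely mixed states
at these mutation rates.

## Scenarios

Six preset scenario families ship with the package (see
`src/coordsig/presets/*.yaml`, which record the payoff tables and population
shares verbatim; every numeric choice there is the package's own
transcription of the scenario narratives):

- **two-type-base** — Ummians (share d) vs Kishus; V for the preferred
  greeting, 1 for the other.  With the signal space switched off this is the
  bare generalized BoS with its three pure equilibria; with one signalling
  dimension it is the cross-cultural-competence scenario.
- **three-type-cost** — adds Akkadians (share a, default 1/3) who value only
  their own greeting, while Sumerian types get a tolerance payoff w = 0.5
  for the Akkadian greeting; one dimension, two real signals, c = 0.02.
  Larger costs (c around 0.1) suppress signal emergence entirely in this
  scenario: the population settles on signal-free norms before conditioning
  can co-evolve with broadcasting.
- **single-embedding** — Girshites nested in Lagashites, Akkadians outside;
  compare one dimension with two signals against two dimensions with one.
- **intersectional** — Ummians and Lagashites value only their own greeting
  (plus Akkadian tolerance 1); Kishus value both parent greetings at kp = 2
  and, in the intersectional variant, a distinct Kish greeting at VK = V;
  VK = 0 gives the mere-conjunction variant.  Kishus are a share r (default
  0.2), parents (0.6 - r)/2 each, Akkadians 0.40.  Two dimensions, one
  signal each, c = 0.02.
- **disjoint-double / hierarchical-double** — two subgroups nested in a
  Sumerian super-group side by side (dimensions (1,2)) or in a chain
  (three dimensions); Akkadians at 0.55.

The share and payoff values the narratives leave open were fixed as follows.
The intersectional scenario's shares are pinned by the published synergy
fractions (below).  The Kishu parent-greeting payoff kp = 2 keeps the
minority's conditioned coordination clearly better than opting out of
signalling, while the Akkadian tolerance stays at 1 — raising it to 2 makes
the all-Akkadian uniform norm the dominant attractor, which contradicts the
scenario's intent.

## Structure extraction, classification and optimality

A converged population is summarized per type by its modal signal vector
and, for every combination perceivable under that signal, its modal
contingent action (threshold 0.90; unperceivable combinations inherit the
action of their masked image, since the population has no selected opinion
about them).  Classification is rule-based on the matrix of resolved dyadic
actions between modal profiles: uniform norms, each-type-plays-its-own
miscoordination, behaviourally optimal outcomes (named by the norm the
conflicted dyad adopts), ignore-signal lock-ins (named by the ignoring
types party to a coordination failure), conjunctive signalling with either
a distinct internal norm (intersectional) or an inherited one
(conjunctive-merger), and the two double-embedding patterns.  Anything else
is `other`, keyed by a canonical signature (per-type attention pattern plus
the resolved-action matrix) so that outcome counting over a batch can treat
distinct unnamed structures as distinct categories.

A structure is *optimal* when (i) every dyad sharing a mutually positive
action coordinates on one, (ii) the coordinated action maximizes the dyad's
payoff sum (an alternative Pareto-style clause is available behind a flag),
and (iii) no structure satisfying (i)-(ii) has a strictly lower
population-weighted total attention cost.  Clause (iii) is verified by
exhaustive search over per-type signal assignments (with contingent actions
chosen by constraint propagation over the sum-maximal dyad actions); spaces
with more than 10,000 candidate assignments return an explicit
`undecided-iii` status instead of a guess.

## Information decomposition

For two-dimensional signal spaces the package decomposes the mutual
information the two signal dimensions carry about a target variable into
redundancy, unique, and synergy components.  The joint distribution
p(s1, s2, T) places each type's population share on its modal signal vector
(or its full signal mixture when unresolved).  The default target is the
type's *in-group coordination norm* — the action it plays upon perceiving
its own signal combination — rather than the latent preference type: two
types that look and behave identically inside their groups then share a
target value, which is exactly what makes the intersectional and
mere-conjunction structures distinguishable despite sharing a signalling
system.  The latent type is available as an alternative target.

Redundancy defaults to the bivariate minimum-mutual-information measure
R = min(I(S1;T), I(S2;T)), so synergy = I(S1,S2;T) - max(I1, I2); the
Williams-Beer I_min built from specific information is also implemented and
cross-checked against an independent reference implementation.  Both yield
non-negative components that sum to the total mutual information; with the
MMI measure the smaller unique component is zero by construction.  At the
intersectional scenario's default shares (0.2/0.2/0.2/0.4) the synergy
fraction is 49.5% at the intersectional equilibrium and 36.2% averaged over
the two mere-conjunction equilibria (the two are symmetric, so the average
equals either one).

## What the simulations do and do not show

All inputs are generated internally: initial populations are uniform random
profile draws (or a seeded named structure plus uniform noise), and payoff
tables are the shipped presets.  Reported basin sizes are therefore
estimates of the attractor structure of this model, at desk-scale replicate
counts (binomial error ~ 1/sqrt(n) per cell), and say nothing about real
populations beyond the model's assumptions: random mixing (no homophily,
space, or networks), fixed preferences, overt unambiguous signals, coupled
broadcast/attention, and payoff-monotone oblique transmission.  Several
scenarios possess multiple genuinely stable outcomes; which one a run
reaches depends on the random start, so headline frequencies shift with any
change to the transcribed payoff values within their plausible ranges.  The
outcome taxonomy's category count at the 0.5% rarity threshold additionally
depends on pooled replicate counts.

## Numerical notes

- Utilities for all S strategies are computed in O(V * S) per step (V =
  number of signal vectors) by pooling partners into a
  (signal, perceived-combination, response) table; the brute-force pairwise
  definition is kept as `dynamics.utility` and the two are tested against
  each other.
- Ties in modal extraction break toward the lexicographically smallest
  serialization; classification is invariant to consistent relabelling of
  signals and actions.
- Degenerate inputs: types with zero share are skipped everywhere; a
  zero-information joint reports synergy fraction 0 with a `degenerate`
  flag; empty populations raise a state error.
- Batch seeds derive deterministically from a base seed
  (seed_i = base + 1000003 * i mod 2^31), and every run is bit-reproducible
  given its config.
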