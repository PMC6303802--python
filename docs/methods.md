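# Methods

## Model overview

`dsdkin` treats a DNA strand-displacement system at three resolutions.

* **Domain level.** A domain is a named contiguous strand section with a
  length in nucleotides; `d*` denotes its Watson–Crick complement
  (`d**` normalizes to `d`). Strands are 5'→3' domain lists; a complex is an
  ordered strand list (identity up to circular permutation) with a
  non-pseudoknotted pairing in which every domain is fully unbound or fully
  bound to one complementary domain. Structures are written in
  dot-parens-plus: `.` unbound, matched `()` a bound pair, `+` a strand
  break. Only `.()+` are accepted; whitespace is ignored; pseudoknot
  brackets are not supported.
* **Sequence level.** Each nucleotide is unbound or paired with a
  Watson–Crick partner or G-T wobble. A domain bound to its partner implies
  antiparallel nucleotide pairing: base i pairs base L−1−i of the partner.
* **Strand level.** Secondary structure is erased; a complex is just its
  circular strand order. The "state of the simulation box" is a multiset of
  strand-level complexes.

## Reaction enumeration and condensation

Enumeration closes the declared complexes under four moves: bind (two
unbound complementary domains, intra- or inter-complex, if the result is
unpseudoknotted and connected), unbind (a pair opens; if the complex
disconnects it splits into the two circular arcs), 3-way branch migration
(an unbound domain held adjacent to a branch point displaces an identical
bound domain; if the displaced strand loses its last bond the products
separate in the same move), and 4-way branch migration (adjacent bound
domains with identical partners exchange partners; because the exchange can
change the planar strand interleaving, arbitrary strand orders are tried
when no rotation of the old order is unpseudoknotted).

Timescale separation is a policy object, not a physical model: unimolecular
moves are fast, bimolecular moves slow, and unbinding is fast only for
domains up to a toehold threshold (default 7 nt, configurable per move
type). Resting macrostates are the strongly connected components of the
fast-reaction digraph with no outgoing fast edge (networkx provides the SCC
condensation); all other conformations are transient. Condensation computes,
for each slow reaction between resting conformations, the set of reachable
resting-macrostate multisets ("fates") by a monotone fixpoint over the fast
digraph; one condensed reaction per (reactants, fate). Fate *sets* only are
computed — fate probabilities and rates come from stochastic simulation, so
the heavier probability-propagating condensation algorithms are not needed.
A self-loop fate marks the unproductive channel. Enumeration caps: max 6
strands per complex (binds beyond are skipped and the network flagged
incomplete) and max 1000 complexes (an explicit error by default).

## p-approximation

A sequence structure is a p-approximation of a domain conformation when
every domain's fraction of correctly configured nucleotides is ≥ p
(inclusive, real-valued comparison). Two match rules exist because the
definition can be read two ways: the default `defect` rule counts a
nucleotide correct only if its pairing state equals the implied one exactly
(this is what makes a structure match at most one conformation when
p > 0.5); the `literal` rule additionally counts any unbound nucleotide as
correct. Default p = p' = 0.51, which tolerates partially migrated branch
domains. Strand-order alignment uses the canonical (lexicographically
minimal) rotation of both structures' strand name lists.

## First-step model and stop states

For reactant multiset A (one or two resting macrostates) the model contains
one productive reaction per condensed fate, an unproductive reaction
(products = A) whenever |A| = 2, and exactly one spurious reaction.
Compatible stop states are the strand-level product multisets; spurious stop
states are derived by considering, for every reachable post-binding box
state, every contiguous bipartition of each complex's circular strand order
(a single dissociation of an unpseudoknotted complex always yields two
contiguous arcs) and keeping those whose outcome is not BFS-reachable in the
strand-level subnetwork. Dissociation back to reachable states — including
the original reactants — is unproductive, not spurious, and a trajectory
that leaves the subnetwork is spurious even if it would later rejoin an
expected pathway (this biases rate estimates conservatively). Spurious stop
states are always tested in ordered-complex mode. Classification halts on
first membership, so non-minimal stop-state supersets are harmless.

Three acceptance modes grade how closely final structures must resemble the
product macrostates: `ordered-complex` (strand-level identity only),
`count-by-complex` (whole-complex correct fraction ≥ p'), `count-by-domain`
(every domain ≥ p'). Acceptance is provably nested in that order and the
suite checks the nesting on randomized ensembles.

## Rate estimators

With N trajectories, N_i corresponding to reaction i, per-trajectory
collision rates k_coll (per molar per second) and completion times τ2
(seconds):

* Outcome probability: posterior mean (N_i+1)/(N+2) and sd
  sqrt(p̂(1−p̂)/(N+3)) under a uniform prior — the Beta(N_i+1, N−N_i+1)
  moments, never exactly 0 or 1, so adaptive precision control works before
  the first success.
* Bimolecular k1: k̂1 = Σ_{S_i=1} k_coll / (N+2). Its error bar is the
  exact posterior sd of p·k_coll under independence, with p the Beta
  posterior and the collision-rate scale carrying an inverse-gamma(N_i+2, S)
  posterior (1/k³ prior, exponential likelihood — the unique choice whose
  posterior mean reproduces the point estimate above):
  σ̂ = k̂1 sqrt((2(N+2)−N_i)/(N_i(N+3))). The test suite cross-validates
  this against Monte-Carlo sampling of that posterior. With zero successes
  the estimate is 0 and a Bayesian upper-bound companion
  mean(k_coll)/(N+2) is reported instead — such channels may be extreme
  overestimates and are omitted from assembled CRNs by default.
* Bimolecular k2: k̂2 = Σ k_coll / Σ k_coll τ2 over successes (exactly
  N_i/Στ2 for constant k_coll), with an effective sample size
  N_eff = (Σk)²/Σk² in the error bar; σ̂ undefined for N_eff ≤ 1.
* Unimolecular reactions: k̂2 = 1/mean(τ2); k̂1 = k_fast·P̂_A(i) with
  k_fast = k_scale·max_i k̂2 (k_scale default 100, minimum 10). Only the
  relative k1 values are meaningful; the Markov chain reproduces
  P_A(i) = k1_i/Σ k1_j exactly.
* Trajectories with no initial step count in N only; unresolved trajectories
  (step cap, default 10⁶ moves) are reported separately and excluded from
  tallies.

Adaptive estimation simulates in batches (default 100) until σ̂_k1/k̂1
reaches the requested precision or a trajectory cap, flagging the result if
the target was not met. Precision is targeted on k1 because it sets the
CRN's bimolecular timescale.

## Toy backends

The built-in backends replace a nearest-neighbour thermodynamic sampler and
an elementary-step kinetic simulator with exactly solvable counterparts.

* `ToyEnergyModel`: E = bp_energy·(paired nt) + loop_penalty·(unpaired nt),
  defaults −1.0 kcal/mol per pair and 0, at 298.15 K. Ensembles are
  enumerated exhaustively (minimum hairpin loop 3 nt, G-T wobble allowed,
  refusal above 10⁵ structures) and sampled exactly; conditioned initial
  states use rejection sampling with a 10⁵ cap.
* `ToyKineticModel`: intra-complex bind 10⁵ /s; unbind
  10⁵·exp(bp_energy·L/RT) /s with bp_energy −1.7 kcal/mol/nt at RT = 0.593
  kcal/mol, which gives toehold-length dependence and detailed balance
  against the energy model when bind and unbind prefactors match; branch
  migration 10⁶/L² /s (an unbiased L-step random walk); bimolecular
  nucleation 3×10⁶ /M/s per feasible first domain contact. k_coll is the
  nucleation rate times the number of feasible contacts of the sampled
  conformation pair, and the first trajectory event is one uniformly chosen
  contact. When the collision itself completes the reaction (no
  dissociation step follows), the unimolecular stage is recorded as a
  single zippering event at the helix-closing timescale rather than zero.
  These magnitudes are chosen to resemble experimental strand-displacement
  scales, but the backend is a stand-in at domain resolution, not a
  sequence-dependent kinetic model.
* `exact_first_step_solution` builds the same chain's generator matrix and
  solves for absorption probabilities and conditional mean times, providing
  the ground truth the simulated estimates are tested against.
* `generate_synthetic_records` draws trajectory records from declared
  outcome/k_coll/τ2 distributions (constant, exponential, lognormal) for
  estimator calibration tests.

What the toys do *not* emulate: sequence-dependent thermodynamics and
kinetics (nearest-neighbour stacks, mismatches, coaxial stacking),
base-pair-resolution trajectories, temperature dependence, and pseudoknots.
Passing tests therefore validate the framework's statistics, stop-state
logic and estimator calibration — not quantitative rate predictions for
real sequences, which require genuine sampling and simulation backends
behind the same interfaces.

## CRN assembly, simulation and scores

Each estimated reaction pair contributes A → A_i (k1) and A_i → P_i (k2);
spurious products go to an absorbing sink. ODE integration uses
scipy's LSODA with rtol 1e-8 / atol 1e-12 defaults (rate constants span
many orders of magnitude; a failed integration is retried once with BDF and
tightened tolerances). The Gillespie SSA converts bimolecular rate constants
with c = k/(N_A·V), halved propensity for identical reactants. Depletion
scores follow the closed forms α_AB = K_AB c_B/(1+Σ K_AA' c_A'),
α_A = Σ K c/(1+Σ K c), α = max_A α_A, β_A = Σ c_A' k1_s, β = max β_A; the
partner sum runs over all macrostates with an unproductive (resp. spurious)
channel with A, including self-interaction when enumerated, and the matrix
is not symmetric under unequal concentrations. The α bound assumes
unproductive reactions are faster than productive ones; this is asserted,
not enforced. Systems without maximum concentrations are not scored.

## Problem sizes and determinism

The test and acceptance workloads use desk-scale fixtures: a 3-strand
toehold-displacement toy (21 complexes enumerated), a 4-strand double
displacement (81 complexes), duplex ensembles of ≤ a few hundred structures,
10⁴ stochastic trajectories per estimate and 200–500 replicate ensembles of
10⁴ synthetic records for recovery coverage. All randomness flows from
caller-provided seeds through numpy Generators; pipeline reports are
byte-identical across runs with the same seed.

## Known limitations

* One resting macrostate per strand-level complex is assumed (systems with
  kinetically separated conformations of the same strand multiset get a
  warning and should be analysed with caution).
* The enumerator implements single-step, local moves only — no remote
  toeholds, cooperative binding, or polymerization guards; networks that
  grow past the caps are rejected rather than truncated silently.
* The domain-level trajectory generator supports ordered-complex stop mode;
  the stricter modes apply when sequence-level structures are supplied to
  the classifier.
* Spurious products are modelled as permanently lost; their internal
  kinetics are out of scope.
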