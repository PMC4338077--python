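# Methods

## The game

Each interaction round, Nature draws a state: α with probability λ, β
otherwise. Groups of N individuals are assembled uniformly at random
from a well-mixed population of Z. Every member emits the binary signal
its genotype prescribes for the realized state; signal 1 costs the
emitter c_S, signal 0 is free and stands for "no signal". All members
then act on the majority signal in the group — the simplest quorum-
sensing reaction — and an exact tie (possible only for even N) is
resolved by a fair coin. Acting means cooperating (contributing c to the
public good) or shirking, per the genotype's action bit for that
majority signal.

Under α, k cooperators produce a per-beneficiary benefit F·k·c/N once
k ≥ M; the threshold uses the Heaviside convention θ(0) = 1, so exactly
meeting the quorum pays. Under β the benefit factor is zero, so
cooperation is pure cost. The shirker role is a global switch:
*defectors* receive the benefit without contributing, *loners* receive
exactly 0 in both states; against loners a cooperator's benefit is
F·c·θ(k − M) (participation in a successful joint venture) rather than
the share F·k·c/N. The signaling cost is charged whenever the
individual's emitted signal in the realized state is 1, regardless of
the group's majority or the action taken.

A genotype is written (σ_α σ_β | A_0 A_1). The full space has all 16
genotypes; the reduced space (8 genotypes) constrains A_0 = 0, i.e.
cooperation only ever follows the costly signal. The canonical ordering
everywhere (matrices, CSV output) is lexicographic on
(σ_α, σ_β, A_0, A_1).

## Expected fitness

Fitness is the expected game payoff. In a bimorphic population with k
U-strategists, a focal U draws its N−1 co-players without replacement
from the remaining Z−1 individuals, so the number j of same-type
co-players is hypergeometric:

    Ω_U(k) = Σ_j C(k−1, j) C(Z−k, N−1−j) / C(Z−1, N−1) · π_U(j),

and analogously for V. Group payoffs π are evaluated analytically,
averaging exact signal ties over both readings (the expectation of the
coin flip), so Ω is deterministic. Out-of-range binomial coefficients
are zero, which handles edge compositions without special cases. The
majority is counted over all N members, focal included. Per ordered
strategy pair the full profile Ω(k), k = 1..Z−1, is computed vectorized
and cached.

## Fixation and the embedded chain

Updating is the pairwise-comparison (Fermi) birth–death rule with
selection intensity γ: T±(k) = (k/Z)·((Z−k)/(Z−1))·[1+e^(∓γΔΩ(k))]^(−1).
Only the ratio φ_k = T−/T+ = e^(−γΔΩ(k)) enters the fixation
probability, which is evaluated as cumulative sums of −γΔΩ followed by
log-sum-exp; this is exact in the neutral limit (ρ = 1/Z) and remains
finite and accurate for γ well beyond 10.

With mutation rate μ → 0 the population is monomorphic between invasion
attempts, and evolution reduces to an n_S-state Markov chain with
off-diagonal entries η·ρ_{V,U}, η = (n_S − 1)^(−1). The stationary
distribution is obtained by solving π(T − I) = 0 with Σπ = 1 appended as
a linear least-squares system, which is deterministic. Uniqueness is
checked *structurally*: the chain must have exactly one closed
communicating class of its nonzero-transition graph; several closed
classes raise an error naming them. We deliberately do not test
uniqueness through eigenvalue multiplicity: under strong selection the
chain is metastable and its second eigenvalue can sit within 1e−9 of
one while the chain is still irreducible (every ρ is positive, if
astronomically small), and the stationary distribution is perfectly
well-defined there.

Chains can be restricted to any strategy subset; the pairwise ρ values
are reused and η is renormalized to (|subset| − 1)^(−1).

## Robustness classifiers

A strategy A is evolutionarily robust (ERS) when ρ_{A,B} < 1/Z strictly
for every mutant B. Comparisons against 1/Z use a 1e−12 relative band so
that exactly neutral pairs — whose ρ equals 1/Z up to log-domain
rounding — classify as neutral rather than as marginal winners or
losers. Strictness matters: at γ = 0 nothing is robust, and strategy
pairs that never express their differing bits (for example the two
silent never-cooperators (00|00) and (00|01), which are payoff-identical
at *every* parameter point) can never certify each other's robustness.
A consequence worth knowing: the sink nodes of the invasion graph
(edges where ρ > 1/Z) always contain the ERS set, but can exceed it at
nodes whose best invader is exactly neutral.

Two alternative stability measures are provided: `ers_plus_fitness`
additionally requires a single mutant of any other strategy to have
lower fitness than the residents (evaluated at mutant count 1), and is
always a refinement of ERS; `counter_invasion` accepts strategies whose
every above-neutral invader is counter-invaded with a larger
probability.

## The stochastic simulator

The agent-based simulator implements the same process explicitly: per
step, a random focal individual imitates a second random individual with
the Fermi probability, and with probability μ the updated individual's
strategy is replaced by one of the n_S strategies uniformly at random.
The mutation draw is made per update step and overrides the imitation
outcome for that step — the process-level coupling of mutation to
reproduction is a modelling choice; for μ < 1/Z², the validated regime,
it is immaterial because mutations essentially never land inside an
ongoing invasion sweep.

Two accelerations are distributionally exact:

* while the population is monomorphic, imitation cannot change anything,
  so the dwell time to the next mutation event is drawn directly from
  its geometric law instead of being stepped through;
* fixation-probability trials follow the embedded jump chain over the
  mutant count (at interior k the next change is upward with probability
  T+/(T+ + T−) = [1+e^(−γΔΩ(k))]^(−1)); self-loop steps cannot alter
  which boundary absorbs the walk.

Fitness during a bimorphic sweep uses the exact hypergeometric
expectation (cached per strategy pair). When a second mutation creates a
third coexisting strategy — or when `sampled_groups` mode is selected —
fitness is the mean payoff over sampled groups (focal plus N−1 distinct
others), with majority ties resolved by actual coin flips. Runs are
bit-reproducible from the seed, and Z is conserved at every step.

What the simulator does *not* emulate: population structure, group-size
variation, or any signal noise; agreement between simulator and
embedded chain therefore validates the small-mutation reduction and the
fixation algebra, not the model's fit to any empirical system.

## Default parameters and problem sizes

The headline parameter point is Z = 100, N = 9, M = 5, c = 0.5,
c_S = 0.2, F = 10, λ = 0.5, γ = 5, defector shirkers; the limit cases
λ ∈ {0, 1} and the cycling regime (c = 0.3, c_S = 0.06, γ = 0.5,
λ = 0.8) use the same Z, N, M. F = 10 makes successful collective
action strongly beneficial (benefit ≈ F·c at full cooperation) while
keeping the coordination dilemma; c_S = 0.2 < c/2 places the default in
the regime where costly signaling can dominate.

The simulator cross-validation uses a smaller population, Z = 36, N = 5,
M = 3, λ = 0.8, γ = 0.5, μ = 1e−5 (so μ < 1/Z² ≈ 7.7e−4), run for 8×10⁹
update steps (~8×10⁴ mutation events after the monomorphic-dwell
acceleration); that length was chosen so the rare monomorphic states are
visited often enough for a stable rank comparison against the embedded
chain. Fixation estimates use 2×10⁴ trials, giving binomial standard
errors of a few 1e−3.

## Numerical policy and limitations

* log-sum-exp with max subtraction for ρ; tolerances of 1e−10 on
  row-stochasticity and stationarity residuals, 1e−12 for neutral-limit
  identities.
* ρ values can underflow to exactly 0 under very strong selection; the
  chain construction tolerates this, and the structural uniqueness check
  treats such transitions as absent.
* Sweeps evaluate each grid point independently from a fresh chain;
  invalid parameter combinations (e.g. M > N) yield error rows, not
  aborts.
* Beyond-small-mutation stationary behavior over the full polymorphic
  state space is out of scope analytically; the simulator is the only
  route there, and its sampled-group fitness mode is an estimator, not
  an exact expectation, once three or more strategies coexist.
* The reduced space keeps all eight (σ_α, σ_β, A_1) combinations with
  A_0 = 0; constraining additional bits is not implemented.
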