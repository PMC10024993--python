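# Methods

This note records the models, conventions and numerical choices behind
invaderkit, and what the test suite does and does not establish.

## Matrix games and ESS classification

Phenotypes are probabilities x ∈ [0, 1] of choosing one of two behaviours
(C or D); the pay-off of x against y is the bilinear extension of the 2×2
pure-strategy matrix. Because both stability margins are linear in the
alternative strategy y, evolutionary stability is decided at y ∈ {0, 1};
this is exact, not an approximation, and is the reason the package never
scans y for classification (brute-force scans appear only as independent
test oracles).

Conventions:

- *Strict* ESS means the first-order margin w(x\*, x\*) − w(y, x\*) is
  strictly positive for all y ≠ x\*. At an interior mixed ESS that margin
  vanishes identically, so interior ESSs are classified *weak* — they are
  uninvadable through the second-order condition w(x\*, y) > w(y, y).
- Equality is |Δ| ≤ tol with default tol = 1e−9, chosen for pay-off
  arithmetic in double precision at pay-off magnitudes O(1–10).
- Interior candidates within tol of a corner are merged with the corner; a
  degenerate interior denominator (w10 − w00 + w01 − w11 ≈ 0) is reported
  as a skipped candidate rather than silently dropped.

Singular points of scalar invasion-fitness functions are located by
bisection on sign changes of the selection gradient g(x) = ∂λ/∂y|_{y=x}
(64-point scan by default) and classified by central second differences
with step h = 1e−4; each derivative is recomputed at h/2 and must agree to
1e−3 relative (a Richardson consistency check), otherwise the point is
labelled `marginal` instead of being forced into a class. ESS requires
∂²λ/∂y² < −tol, convergence stability g′ < −tol; the four sign
combinations give CSS, evolutionary branching, Garden of Eden and
repellor.

## Single-locus dynamics

The haploid recursion p′ = p·w(1, p)/w̄ assumes mean-field random pairing:
an individual's partner plays the population mean phenotype. The diploid
recursion uses allele marginal fitnesses under Hardy–Weinberg proportions
each generation (random mating, non-overlapping generations), with
interactions at the adult, post-mating stage. The recursion itself is a
standard construction; the package's interest is the correspondence
between its stable equilibria and the game's ESSs.

Internal stability is measured as the spectral radius of a
central-difference Jacobian restricted to the simplex tangent space
(directions e_i − e_a), so the conserved total frequency never produces a
spurious unit eigenvalue.

What the correspondence does and does not say: an ESS produced by some
allele-frequency vector is stably maintained; the tests construct such
compositions explicitly and verify they are attractors. The converse is
false in general — a corner equilibrium can be internally stable at a
non-ESS phenotype when the heterozygote phenotype blocks the only mutational
path toward the ESS — so the suite asserts the ESS property only for stable
polymorphic equilibria whose mean phenotype is locally free to move in both
directions (|dx̄/dp| bounded away from 0).

## Two-locus external stability

The recursion follows the classical selection–recombination form on
chromosome (gamete) frequencies, with recombination (rate R ∈ (0, 0.5])
exchanging locus-B alleles in double heterozygotes and the census taken
after selection and recombination. Rare-mutant external stability
linearizes the map of mutant chromosome frequencies over locus-B
backgrounds: a mutant chromosome paired with a resident chromosome (k, l)
transmits its background with probability 1 − R and the partner's
background l with probability R, weighted by the pair's fitness over the
resident mean fitness. All terms quadratic in mutant frequency are
dropped.

The guard on this reconstruction is the identity test: with pay-offs
linear in phenotype, the leading eigenvalue of the linearized map must
equal w(x_μ, x̂)/w(x̂, x̂), with x_μ = Σ u_j p̂_kl x_μjkl averaging the
mutant phenotype over the stationary background distribution u. The suite
asserts this to 1e−9 on 200 random models, checks eigenvalue invariance to
the power-iteration start, and cross-checks the sign of λ − 1 against the
fate of a mutant seeded at frequency 1e−8 in the full nonlinear
recursion with the mutant embedded as a third allele.

Equilibria are found by forward iteration (default tolerance 1e−12, capped
iterations with an explicit non-convergence flag); a rejected start or a
non-equilibrium argument to the stability analysis raises rather than
returning a silently meaningless eigenvalue.

## Mutation-rate modifier in a cyclic environment

Haploid two-locus model: a major locus A1/A2 under viability selection
(mismatched allele has fitness 1 − s_e in environment e) and a neutral
modifier locus that sets the symmetric A1↔A2 mutation rate of its own
chromosome. The environment alternates deterministically, T generations of
environment 1 then T of environment 2, starting in environment 1;
stochastic environments are out of scope. Life-cycle order is selection →
mutation → recombination with the census after recombination; the mutation
rate applied is that of the modifier allele currently on the chromosome.
Two structural invariants guard this construction: a mutant modifier with
the resident's rate has monodromy eigenvalue exactly 1, and with selection
off the per-generation matrix is doubly stochastic.

The resident (modifier fixed) reduces to one dimension; whole cycles are
iterated from frequency 0.5 until the start-of-cycle state moves by less
than 1e−12 (default cap 1e5 cycles). Invasion is decided by the ordered
product of the 2T per-generation 2×2 mutant maps along the converged
cycle, accumulated with per-step max-norm scaling and a log-norm
accumulator so large T cannot underflow; the per-generation rate reported
for plotting is the 2T-th root.

The ES rate scanner evaluates the diagonal selection gradient
λ(μ + δ, μ) − 1 (δ = 1e−4) on a grid (default 41 points on [0, 0.05],
which is [0, 2.5/T] at the reference epoch length T = 50; for other epoch
lengths the natural range is the same rule rescaled, since the crossing is
expected near 1/T), refines each +→− sign change by bisection to
1e−5, and then verifies the candidate against the full mutant grid.

Two empirical notes, both computed by the suite:

- At T = 50, s1 = 0.01, s2 = 0.015, r = 0, the attracting crossing sits at
  μ\* ≈ 0.0279 ≈ 1.4/T, and μ\*(r) decreases to 0 by r = 0.2.
- The PIP at those parameters is *bistable*: the diagonal gradient is
  negative below μ ≈ 0.0075, so rates near zero are locally stable too,
  and mutants with near-zero rates invade the μ\* resident (max per-
  generation λ ≈ 1.001). A non-mutating lineage settles on the allele
  favoured in the harsher environment and pays only the milder cost s1 per
  cycle, which beats the resident's mean fitness when the costs are
  asymmetric. `es_rate` therefore reports the crossing together with an
  honest `uninvadable` flag rather than asserting global uninvadability.

## Group- and class-structured invasion fitness

Infinite island model: infinitely many groups with n_s residents in each
of c classes; a rare mutant lineage is tracked by the per-class mutant
counts k per group, giving a multitype branching process over the
Π(n_s + 1) − 1 non-empty states (hard cap 1e4 states). Because the mutant
is globally rare, immigrants are never mutants and each emigrant mutant
founds a new singleton-mutant group; the projection matrix combines an
exact per-class binomial transition for the focal group with the expected
number of emigrant-founded singletons. The offspring-accounting identity
Σ_{k′} k′_{s′} a_{k′k} = Σ_s k_s ω_{s′sk} holds by construction and is
asserted to 1e−10 for every kernel, as is the equality between the Perron
eigenvalue and the lineage-fitness average Σ ω q.

The built-in demographic kernel is a haploid Wright–Fisher island model
with fecundity selection: fecundity 1 + δ·(mean pay-off against the n − 1
groupmates), each adult slot filled by a philopatric juvenile with
probability 1 − m (sampled ∝ parental fecundity within the group) or by a
resident immigrant with probability m, and per-capita emigrant success
m·f/f̄. A generic linear kernel (arbitrary classes, coefficients linear in
phenotypes, explicit philopatric/emigrant split) backs the randomized
identity tests.

Derived summaries: q_{k,s} ∝ k_s u_k (stationary context distribution of a
lineage member), relatedness r_{σ|s} as the expected mutant fraction among
a mutant's class-σ groupmates under q (undefined, and reported as such,
when a class has no groupmates), and reproductive values v from the left
Perron eigenvector of the resident class-transition matrix normalized so
Σ v_s n_s/n = 1. At neutrality the lineage-based relatedness coincides
with identity-by-descent under the same life cycle, which a seeded
Monte-Carlo simulation confirms within 3 standard errors.

Cost–benefit partition conventions (the open design point): costs and
benefits are marginal derivatives of individual fitness at the all-resident
point times the phenotype deviation, computed from a full member-phenotype
profile so that competitive feedbacks (my expression changes my
competitor's fecundity) are included. Benefit coefficients are stored per
recipient; the actor-centred (inclusive-fitness) sum and the between-group
term use the total conferred by one actor, (n_σ − [σ = s])·β, while the
within-group term uses the per-recipient β. With a single symbol used in
both places the two partitions agree only for n = 2; with this convention
they are algebraically identical for the one-class case, and the suite
asserts exact agreement plus O(δ²) convergence of both to the eigenvalue.
Two scope notes: (i) the O(δ²) property requires an additive game
(w11 − w10 − w01 + w00 = 0, the canonical cost–benefit parametrization);
synergistic pay-offs leave an O(δ·Δx²) cross term that a two-term
partition cannot represent. (ii) For multiple classes the two partitions
weight cross-class benefits differently (actor-centred vs
neighbour-modulated) and are only asserted against each other for one
class.

The sex-ratio application is the two-class specialization in closed form:
a rare autosomal mutant heterozygote transmits through daughters
(∝ y/x̂) and sons (∝ (1 − y)/(1 − x̂)) with factor 1/2 on each route and
the class-abundance weights F/M = x̂/(1 − x̂). At x̂ = 1/2 the leading
eigenvalue is 1 for every mutant — the Fisherian ratio is selectively flat
in all directions, and it is the unique resident with λ ≤ 1 everywhere.

## Synthetic fixtures and what passing tests show

All random fixtures are seeded and deterministic: pay-off matrices with
prescribed ordering chains (minimum slot separation 1e−3·range so
classifications are unambiguous), symmetric genotype–phenotype maps and
tensors, and small linear group kernels with critical (column-sum-1)
baselines. They emulate the *structure* of the models — orderings,
symmetries, simplex constraints — not any empirical organism; passing
tests establish internal mathematical consistency (recursions, eigenvalue
identities, partitions, oracles) and the qualitative phenomena above, not
quantitative predictions for real populations.

Problem sizes used by the suite and acceptance script (chosen as desk-scale
model checks): two alleles per locus for the randomized identity batteries
(200 models), group sizes n ≤ 3 for the island analyses, 21–41-point rate
grids, and seeded stochastic oracles with 3e4–1e5 replicates compared at 3
standard errors.

## Known limitations

- Two behaviours only; games with three or more pure strategies (e.g.
  rock–paper–scissors) and role-asymmetric games are out of scope.
- Deterministic dynamics throughout: no genetic drift, no fixation
  probabilities, no stochastic environments.
- The diploid and two-locus models assume random mating and non-overlapping
  generations; the island model assumes infinitely many groups.
- `classify_singular` assumes a numerically twice-differentiable fitness
  function on the search interval; kinked or noisy functions will be
  reported as `marginal`.
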