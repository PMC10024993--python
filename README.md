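# invaderkit

Evolutionarily stable strategy (ESS) analysis through **invasion fitness**:
the geometric growth rate λ of a rare mutant lineage in a resident
population. A phenotype x* is uninvadable when λ(y, x*) < 1 for every
alternative y, which for matrix games reduces to the classical stability
conditions

> w(x\*, x\*) > w(y, x\*)   (strict ESS), or
> w(x\*, x\*) = w(y, x\*) and w(x\*, y) > w(y, y)   (weak ESS),

and in structured or genetically explicit populations becomes the Perron
eigenvalue of the linearized rare-mutant dynamics. The package is aimed at
evolutionary theorists who want to move between the phenotypic (game
theoretic) and population-genetic/demographic views of the same model and
check that they agree.

## What is implemented

- **`games`** — 2×2 matrix games with mixed strategies: bilinear pay-off
  w(x, y), ESS classification (checking the pure alternatives suffices by
  linearity), the interior mixed ESS
  x\* = (w10 − w00)/(w10 − w00 + w01 − w11), relative fitness
  ω(y, x) = w(y, x)/w(x, x), pairwise invasibility plots (PIPs), and
  singular-point classification for scalar invasion-fitness functions
  (CSS / evolutionary branching / Garden of Eden / repellor).
- **`dynamics`** — haploid two-genotype and diploid one-locus multiallele
  selection recursions under random mating and mean-field pairing, with
  fixed-point iteration and numerical internal-stability (spectral radius)
  analysis. Stable equilibria realise the game's ESSs whenever the
  genotype–phenotype map can produce them.
- **`twolocus`** — diploid two-locus selection–recombination recursion on
  chromosome frequencies, internal equilibria, and external stability of a
  new mutant allele: λ equals the pay-off ratio w(x_μ, x̂)/w(x̂, x̂) where
  x_μ averages the mutant's phenotype over its stationary chromosome
  backgrounds, so externally stable equilibria generate ESS phenotypes
  independently of the recombination rate.
- **`modifier`** — haploid mutation-rate modifier linked (recombination
  rate r) to a major locus under selection that alternates every T
  generations. Resident limit cycles, monodromy (full-period) invasion
  eigenvalues, PIPs, and the evolutionarily stable mutation rate: ≈ 1/T at
  tight linkage, decreasing with r, and 0 (the reduction principle) in a
  constant environment.
- **`structured`** — invasion fitness in Wright's infinite island model
  with demographic classes: exact multitype branching projection matrix
  over group states, lineage fitness, stationary context distribution,
  reproductive values, relatedness, and the equivalent inclusive-fitness
  (−c + Σ b·r) and group-selection (between- vs within-group) partitions
  of λ − 1; plus the two-class sex-ratio model whose unique uninvadable
  brood ratio is 1:1 daughters:sons.
- **`fixtures`/`config`/`gridio`/`cli`** — seeded random model generators,
  YAML/JSON run configs, TSV grid round-trips and the `invaderkit`
  command-line interface.

## Worked example

The Prisoner's Dilemma ordering w01 > w11 > w00 > w10 makes defection the
unique strict ESS:

```sh
$ invaderkit game --payoff 3,0,5,1
{
  "game_class": "prisoners_dilemma",
  "ess": [{"strategy": 0.0, "ess_class": "strict", "note": ""}]
}
```

The ES mutation rate under environmental alternation every T = 50
generations with mismatch costs s1 = 0.01, s2 = 0.015 and a perfectly
linked modifier (r = 0):

```sh
$ invaderkit modifier-es --t 50 --s1 0.01 --s2 0.015 --r 0
{
  "mu_star": 0.0279052734375,
  "bracket": [0.0275, 0.02875],
  "method": "diagonal_sign_change",
  "uninvadable": false,
  "max_lam_pergen": 1.0009782870967645
}
```

μ\* ≈ 0.028 ≈ 1/T: the population tunes its mutation rate to the pace of
environmental change. `uninvadable: false` reports a real feature of these
parameters: the PIP is bistable, and mutant rates near zero (lineages that
stop mutating and pay only the smaller mismatch cost) can still invade even
though μ\* is the attracting diagonal crossing (see `docs/methods.md`).

A sex-ratio mutant moving a son-biased population (residents produce 30%
daughters) toward parity invades:

```sh
$ invaderkit sexratio --resident 0.3 --mutant 0.5
{"lambda": 1.1209234292461647}
```

λ > 1 through the rarer sex, exactly as equal-investment arguments predict;
scanning residents shows 0.5 is the only ratio with λ ≤ 1 for every mutant.

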