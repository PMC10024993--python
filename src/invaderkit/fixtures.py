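"""Deterministic random fixtures: games, genotype-phenotype maps, kernels.

Every generator takes an integer seed (or a numpy Generator) and is fully
deterministic for a given seed.  Ordering-class game fixtures satisfy the
requested pay-off inequality chain by construction.
"""

from __future__ import annotations

import numpy as np

from .games import PayoffMatrix
from .structured import LinearKernel

__all__ = [
    "rng_from_seed",
    "random_game",
    "random_gp_map",
    "random_twolocus_map",
    "random_group_kernel",
]


def rng_from_seed(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(int(seed))


def random_game(ordering: str, seed, low: float = 0.0, high: float = 5.0) -> PayoffMatrix:
    """Random pay-off matrix with a prescribed ordering.

    ``ordering``: "prisoners_dilemma" (w01 > w11 > w00 > w10), "hawk_dove"
    (w01 > w11 > w10 > w00) or "any" (no constraint).  Four sorted uniform
    draws are assigned to the slots of the requested chain, with a minimum
    gap so classifications are numerically unambiguous.
    """
    rng = rng_from_seed(seed)
    vals = np.sort(rng.uniform(low, high, size=4))
    # enforce a minimal separation relative to the range
    gap = 1e-3 * (high - low)
    for i in range(1, 4):
        if vals[i] - vals[i - 1] < gap:
            vals[i:] += gap - (vals[i] - vals[i - 1])
    a, b, c, d = vals  # a < b < c < d
    if ordering == "prisoners_dilemma":
        return PayoffMatrix(w11=c, w10=a, w01=d, w00=b)
    if ordering == "hawk_dove":
        return PayoffMatrix(w11=c, w10=b, w01=d, w00=a)
    if ordering == "any":
        v = rng.permutation(vals)
        return PayoffMatrix(*v)
    raise ValueError(f"unknown ordering {ordering!r}")


def random_gp_map(a: int, seed, cover: tuple[float, float] | None = None) -> np.ndarray:
    """Random symmetric a x a diploid genotype-phenotype map in [0, 1].

    With ``cover=(lo, hi)``, the homozygote phenotypes are forced to
    straddle the interval (some genotype at or below lo, some at or above
    hi) so any trait value inside it is reachable by allele mixing.
    """
    rng = rng_from_seed(seed)
    x = rng.uniform(0.0, 1.0, size=(a, a))
    x = (x + x.T) / 2.0
    if cover is not None:
        lo, hi = cover
        x[0, 0] = rng.uniform(0.0, lo) if lo > 0 else 0.0
        x[1, 1] = rng.uniform(hi, 1.0) if hi < 1 else 1.0
    return x


def random_twolocus_map(a: int, b: int, seed, additive: bool = False) -> np.ndarray:
    """Random phenotype tensor x[i, j, k, l] with genotype symmetry.

    ``additive=True`` builds the map from per-allele effects summed over
    the four alleles and squashed into [0, 1] (no epistasis or dominance).
    """
    rng = rng_from_seed(seed)
    if additive:
        ea = rng.uniform(0.0, 0.25, size=a)
        eb = rng.uniform(0.0, 0.25, size=b)
        x = (
            ea[:, None, None, None]
            + eb[None, :, None, None]
            + ea[None, None, :, None]
            + eb[None, None, None, :]
        )
        return np.clip(x, 0.0, 1.0)
    x = rng.uniform(0.0, 1.0, size=(a, b, a, b))
    return (x + np.transpose(x, (2, 3, 0, 1))) / 2.0


def random_group_kernel(
    n_s,
    seed,
    coeff_scale: float = 0.01,
    y=None,
    xhat=None,
) -> LinearKernel:
    """Random linear multi-class group fitness kernel.

    Baseline per-capita offspring numbers have unit column sums so the
    resident population exactly replaces itself (the neutral kernel is
    critical, Perron eigenvalue 1); own-phenotype and per-groupmate
    coefficients are uniform draws of magnitude ``coeff_scale``, small
    enough that fitness stays positive and philopatric slot-filling
    probabilities stay inside [0, 1] for small groups.
    """
    rng = rng_from_seed(seed)
    n_s = tuple(int(v) for v in n_s)
    c = len(n_s)
    off = 0.05
    base = np.eye(c) * (1.0 - off * (c - 1)) + off * (1.0 - np.eye(c))
    own = rng.uniform(-coeff_scale, coeff_scale, size=(c, c))
    per = rng.uniform(-coeff_scale, coeff_scale, size=(c, c, c))
    if y is None:
        y = rng.uniform(0.0, 1.0, size=c)
    if xhat is None:
        xhat = rng.uniform(0.0, 1.0, size=c)
    philo_frac = float(rng.uniform(0.2, 0.8))
    return LinearKernel(n_s, base, own, per, philo_frac, y, xhat)
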