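"""Single-locus selection recursions linking ESSs to population genetics.

Two models with random pairwise interactions and discrete generations:

* a haploid asexual population with two genotypes, phenotypes x = 1
  (always C) and x = 0 (always D), tracked by the frequency ``p`` of the
  cooperator genotype;
* a randomly mating diploid population with ``a`` alleles at one locus,
  genotype A_i A_j choosing C with probability ``x[i, j]``, tracked by the
  allele-frequency vector.

Stable equilibria of these recursions realise the ESSs of the underlying
matrix game (the Eshel-Lessard correspondence): the mean phenotype at an
internally stable equilibrium classifies as an ESS of the pay-off matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .games import PayoffMatrix, payoff

__all__ = [
    "DiploidLocusModel",
    "mean_phenotype",
    "haploid_step",
    "diploid_step",
    "iterate_to_equilibrium",
    "internal_stability",
]

_CLIP_WARN = 1e-10


@dataclass(frozen=True)
class DiploidLocusModel:
    """One diploid locus with ``a`` alleles and a genotype-phenotype map.

    ``x[i, j]`` is the probability that genotype A_i A_j chooses C; the map
    must be symmetric (genotype order is irrelevant) with entries in [0, 1].
    """

    x: np.ndarray
    W: PayoffMatrix

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        if x.ndim != 2 or x.shape[0] != x.shape[1]:
            raise ValueError("phenotype map must be a square matrix")
        if not np.allclose(x, x.T):
            raise ValueError("phenotype map must be symmetric (x_ij = x_ji)")
        if np.any(x < 0) or np.any(x > 1):
            raise ValueError("phenotypes must lie in [0, 1]")

    @property
    def n_alleles(self) -> int:
        return self.x.shape[0]


def _check_simplex(p: np.ndarray, n: int) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (n,):
        raise ValueError(f"allele-frequency vector must have length {n}")
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-12:
        raise ValueError("frequencies must be non-negative and sum to 1")
    return p


def mean_phenotype(p: np.ndarray, model: DiploidLocusModel) -> float:
    """Random-mating mean phenotype x(p) = sum_ij p_i p_j x_ij."""
    p = _check_simplex(p, model.n_alleles)
    return float(p @ model.x @ p)


def haploid_step(p: float, W: PayoffMatrix) -> float:
    """One generation of haploid selection with random pairing.

    p' = p w(1, p) / wbar with wbar = p w(1, p) + (1-p) w(0, p); the partner
    phenotype argument is the population mean p itself (mean-field pairing).
    """
    p = float(p)
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    w1 = payoff(1.0, p, W)
    w0 = payoff(0.0, p, W)
    wbar = p * w1 + (1.0 - p) * w0
    if wbar <= 0:
        raise ValueError(f"mean fitness {wbar} must be positive")
    return min(1.0, max(0.0, p * w1 / wbar))


def diploid_step(p: np.ndarray, model: DiploidLocusModel) -> np.ndarray:
    """One generation of the diploid marginal-fitness recursion.

    Under random mating, genotypes are at Hardy-Weinberg proportions each
    generation, so the allele update is p'_i = p_i m_i / wbar with marginal
    fitness m_i = sum_j p_j w(x_ij, x(p)) and wbar = sum_ij p_i p_j
    w(x_ij, x(p)).  Interactions happen at the adult (post-mating) stage
    against the population mean phenotype.
    """
    p = _check_simplex(p, model.n_alleles)
    xbar = float(p @ model.x @ p)
    # w(x_ij, xbar) is linear in x_ij: w = w(0, xbar) + x_ij * (w(1,xbar)-w(0,xbar))
    w1 = payoff(1.0, xbar, model.W)
    w0 = payoff(0.0, xbar, model.W)
    wmat = w0 + model.x * (w1 - w0)
    marg = wmat @ p
    wbar = float(p @ marg)
    if wbar <= 0:
        raise ValueError(f"mean fitness {wbar} must be positive")
    q = p * marg / wbar
    if np.any(q < -_CLIP_WARN):
        warnings.warn("allele frequency clipped by more than 1e-10", RuntimeWarning)
    q = np.clip(q, 0.0, None)
    return q / q.sum()


def iterate_to_equilibrium(step, start, tol: float = 1e-12, max_iter: int = 1_000_000):
    """Fixed-point iteration of ``step`` until the sup-norm update < tol.

    Returns ``(state, converged)``; non-convergence after ``max_iter`` steps
    is reported through the flag, never silently truncated.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    state = np.asarray(start, dtype=float) if np.ndim(start) else float(start)
    for _ in range(int(max_iter)):
        nxt = step(state)
        delta = np.max(np.abs(np.asarray(nxt) - np.asarray(state)))
        state = nxt
        if delta < tol:
            return state, True
    return state, False


def internal_stability(step, equilibrium, h: float = 1e-7, fp_tol: float = 1e-8) -> float:
    """Spectral radius of the linearized map at a fixed point.

    For vector (simplex) states, the Jacobian is computed by central
    differences along simplex-tangent directions (e_i - e_n shifts) so the
    constraint sum p = 1 is respected; a radius < 1 means internal
    stability.  Raises if ``equilibrium`` is not a fixed point within
    ``fp_tol``.
    """
    eq = np.asarray(equilibrium, dtype=float) if np.ndim(equilibrium) else float(equilibrium)
    resid = np.max(np.abs(np.asarray(step(eq)) - np.asarray(eq)))
    if resid > fp_tol:
        raise ValueError(f"point is not a fixed point: residual {resid:g} > {fp_tol:g}")
    if np.ndim(eq) == 0:
        # scalar state: one-sided differences at the boundary of [0, 1]
        lo = max(0.0, eq - h)
        hi = min(1.0, eq + h)
        return abs((step(hi) - step(lo)) / (hi - lo))
    n = eq.shape[0]
    if n == 1:
        return 1.0  # single allele: trivially neutral
    # tangent basis: t_i = e_i - e_n, i = 0..n-2
    J = np.zeros((n - 1, n - 1))
    for i in range(n - 1):
        t = np.zeros(n)
        t[i], t[-1] = 1.0, -1.0
        hp = min(h, 0.5 * min(eq[i] if eq[i] > 0 else h, eq[-1] if eq[-1] > 0 else h))
        hp = max(hp, 1e-12)
        fwd = np.asarray(step(_project(eq + hp * t)))
        bwd = np.asarray(step(_project(eq - hp * t)))
        col = (fwd - bwd) / (2.0 * hp)
        J[:, i] = col[:-1]  # coordinates in the tangent basis: first n-1 comps
    return float(np.max(np.abs(np.linalg.eigvals(J)))) if J.size else 1.0


def _project(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 0.0, None)
    return p / p.sum()
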