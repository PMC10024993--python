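"""Mutation-rate modifier evolution in a cyclically changing environment.

A haploid population carries a major locus with alleles A1/A2 under
viability selection that flips every ``T`` generations (environment 1
favours A1, mismatch cost ``s1``; environment 2 favours A2, cost ``s2``)
and a modifier locus, recombining with the major locus at rate ``r``,
whose only effect is the symmetric mutation rate A1 <-> A2 it induces on
the chromosome that carries it.

The resident population (modifier fixed at rate ``mu_res``) settles on a
period-2T limit cycle of the major-allele frequency.  A rare mutant
modifier with rate ``mu_mut`` then grows or shrinks at the leading
eigenvalue of the monodromy matrix: the ordered product of 2T linearized
per-generation 2x2 maps of the mutant chromosome frequencies (M A1, M A2)
along the resident cycle.  Scanning resident and mutant rates gives
pairwise invasibility plots; the sign change of the diagonal selection
gradient locates the evolutionarily stable mutation rate, which at tight
linkage is approximately 1/T and collapses to the reduction-principle
value 0 in a constant environment.

Life-cycle order: selection, then mutation at the rate of the carried
modifier allele, then recombination; census after recombination.  Fitness
normalisation is by the resident mean fitness each generation.
"""

from __future__ import annotations
from dataclasses import dataclass

import numpy as np

from .games import PIPGrid

__all__ = [
    "ModifierModelSpec",
    "ResidentCycle",
    "MonodromyResult",
    "ESRateResult",
    "resident_step",
    "find_limit_cycle",
    "mutant_generation_matrix",
    "invasion_eigenvalue",
    "pip",
    "es_rate",
]


@dataclass(frozen=True)
class ModifierModelSpec:
    """Parameters of the cyclic two-environment modifier model.

    ``T``: generations per environmental epoch (full period 2T).
    ``s1``, ``s2``: fitness cost of carrying the mismatched major allele in
    environments 1 and 2 (mismatched fitness 1 - s).
    ``r``: recombination rate between major and modifier locus, in [0, 0.5].
    ``mu_res``, ``mu_mut``: resident and mutant modifier mutation rates,
    both in [0, 0.5].
    """

    T: int = 50
    s1: float = 0.01
    s2: float = 0.015
    r: float = 0.0
    mu_res: float = 0.02
    mu_mut: float = 0.02
    constant_environment: bool = False  # environment 1 all the time

    def __post_init__(self) -> None:
        if int(self.T) != self.T or self.T < 1:
            raise ValueError("T must be a positive integer")
        object.__setattr__(self, "T", int(self.T))
        for name in ("s1", "s2"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if not (0.0 <= self.r <= 0.5):
            raise ValueError("r must lie in [0, 0.5]")
        for name in ("mu_res", "mu_mut"):
            v = getattr(self, name)
            if not (0.0 <= v <= 0.5):
                raise ValueError(f"{name} must lie in [0, 0.5]")

    def env(self, t: int) -> int:
        """Environment (1 or 2) in generation ``t`` of the cycle."""
        if self.constant_environment:
            return 1
        return 1 if (t % (2 * self.T)) < self.T else 2

    def fitnesses(self, env: int) -> tuple[float, float]:
        """(w_A1, w_A2) in the given environment."""
        if env == 1:
            return 1.0, 1.0 - self.s1
        return 1.0 - self.s2, 1.0


@dataclass(frozen=True)
class ResidentCycle:
    """Converged periodic orbit of the resident major-allele frequency.

    ``states[t]`` is the frequency of A1 (on the resident modifier
    background) at the start of generation ``t``, for t = 0..2T-1;
    ``residual`` is the sup-norm distance between successive cycles at
    acceptance.
    """

    states: np.ndarray
    residual: float


@dataclass(frozen=True)
class MonodromyResult:
    lam_cycle: float  # leading-eigenvalue magnitude over one full period 2T
    lam_pergen: float  # lam_cycle ** (1 / (2 T))


@dataclass(frozen=True)
class ESRateResult:
    mu_star: float
    bracket: tuple[float, float]
    method: str  # "diagonal_sign_change" | "boundary"
    uninvadable: bool
    candidates: tuple = ()
    max_lam_pergen: float = float("nan")


def resident_step(freq: float, env: int, mu: float, spec: ModifierModelSpec):
    """One resident generation: selection in ``env`` then mutation at ``mu``.

    Works elementwise on arrays (used to converge many residents at once).
    """
    p = np.asarray(freq, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("frequency must lie in [0, 1]")
    w1, w2 = spec.fitnesses(env)
    wbar = p * w1 + (1.0 - p) * w2
    psel = p * w1 / wbar
    out = psel * (1.0 - mu) + (1.0 - psel) * mu
    return out if out.ndim else float(out)


def _cycle_batch(mus: np.ndarray, spec: ModifierModelSpec, tol: float, max_cycles: int):
    """Start-of-generation resident states for a batch of mutation rates.

    Returns (states, residuals): states has shape (2T, n) with states[t, i]
    the A1 frequency at the start of generation t for resident rate mus[i].
    """
    mus = np.atleast_1d(np.asarray(mus, dtype=float))
    n = mus.size
    period = 2 * spec.T
    p = np.full(n, 0.5)
    resid = np.full(n, np.inf)
    for _ in range(int(max_cycles)):
        p0 = p.copy()
        for t in range(period):
            p = resident_step(p, spec.env(t), mus, spec)
        resid = np.abs(p - p0)
        if np.max(resid) < tol:
            break
    states = np.empty((period, n))
    for t in range(period):
        states[t] = p
        p = resident_step(p, spec.env(t), mus, spec)
    return states, resid


def find_limit_cycle(
    spec: ModifierModelSpec, tol: float = 1e-12, max_cycles: int = 100_000
) -> ResidentCycle:
    """Converge the resident limit cycle from frequency 0.5.

    Whole 2T-generation cycles are iterated until the start-of-cycle state
    moves by less than ``tol``; non-convergence raises.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    states, resid = _cycle_batch(np.array([spec.mu_res]), spec, tol, max_cycles)
    if resid[0] >= tol:
        raise RuntimeError(
            f"resident cycle did not converge: residual {resid[0]:g} after {max_cycles} cycles"
        )
    return ResidentCycle(states=states[:, 0], residual=float(resid[0]))


def mutant_generation_matrix(
    resident_state: float, env: int, spec: ModifierModelSpec, mu_mut: float | None = None
) -> np.ndarray:
    """Linearized one-generation map of rare mutant-modifier chromosomes.

    State order (M A1, M A2).  Selection at the environment's fitnesses
    divided by the resident mean fitness, mutation at the mutant's rate
    (the rate follows the modifier allele carried), then recombination at
    rate ``r`` with a resident chromosome whose major-allele frequency is
    the resident's post-selection post-mutation frequency this generation.
    """
    if mu_mut is None:
        mu_mut = spec.mu_mut
    p = float(resident_state)
    w1, w2 = spec.fitnesses(env)
    wbar = p * w1 + (1.0 - p) * w2
    S = np.array([[w1, 0.0], [0.0, w2]]) / wbar
    U = np.array([[1.0 - mu_mut, mu_mut], [mu_mut, 1.0 - mu_mut]])
    q = resident_step(p, env, spec.mu_res, spec)  # resident A1 freq after sel+mut
    R = (1.0 - spec.r) * np.eye(2) + spec.r * np.array([[q, q], [1.0 - q, 1.0 - q]])
    return R @ U @ S


def _monodromy_pairwise(
    states: np.ndarray, mu_res: np.ndarray, mu_muts: np.ndarray, spec: ModifierModelSpec
) -> np.ndarray:
    """lam_cycle for paired (resident orbit, mutant rate) columns.

    ``states`` has shape (2T, n); column i is the start-of-generation
    resident orbit for resident rate ``mu_res[i]``, and ``mu_muts[i]`` is
    the mutant rate tested against it.  The 2T 2x2 maps are multiplied in
    order with per-step scaling and a log-norm accumulator so large T
    cannot underflow.
    """
    mu_res = np.atleast_1d(np.asarray(mu_res, dtype=float))
    mu_muts = np.atleast_1d(np.asarray(mu_muts, dtype=float))
    n = mu_muts.size
    P = np.broadcast_to(np.eye(2), (n, 2, 2)).copy()
    logscale = np.zeros(n)
    period = 2 * spec.T
    eye = np.eye(2)
    for t in range(period):
        env = spec.env(t)
        p = np.asarray(states[t], dtype=float)
        w1, w2 = spec.fitnesses(env)
        wbar = p * w1 + (1.0 - p) * w2
        psel = p * w1 / wbar
        q = psel * (1.0 - mu_res) + (1.0 - psel) * mu_res
        # L = R @ U @ S / wbar; U varies with the mutant rate, R with q
        U = np.empty((n, 2, 2))
        U[:, 0, 0] = U[:, 1, 1] = 1.0 - mu_muts
        U[:, 0, 1] = U[:, 1, 0] = mu_muts
        L = U * (np.array([w1, w2]) / wbar[:, None])[:, None, :]
        R = (1.0 - spec.r) * eye[None, :, :] + spec.r * np.stack(
            [np.stack([q, q], axis=-1), np.stack([1.0 - q, 1.0 - q], axis=-1)], axis=1
        )
        P = R @ L @ P
        nrm = np.abs(P).max(axis=(1, 2))
        P /= nrm[:, None, None]
        logscale += np.log(nrm)
    # spectral radius of each scaled 2x2 product
    tr = P[:, 0, 0] + P[:, 1, 1]
    det = P[:, 0, 0] * P[:, 1, 1] - P[:, 0, 1] * P[:, 1, 0]
    disc = tr * tr - 4.0 * det
    sq = np.sqrt(np.maximum(disc, 0.0))
    rad = np.where(
        disc >= 0,
        np.maximum(np.abs(tr + sq), np.abs(tr - sq)) / 2.0,
        np.sqrt(np.maximum(det, 0.0)),  # complex pair: |lam| = sqrt(det)
    )
    return np.exp(logscale + np.log(rad))


def invasion_eigenvalue(spec: ModifierModelSpec, cycle: ResidentCycle | None = None) -> MonodromyResult:
    """Invasion eigenvalue of the mutant modifier over one full period.

    ``lam_cycle`` > 1 means the mutant rate invades the resident rate.
    """
    if cycle is None:
        cycle = find_limit_cycle(spec)
    states = cycle.states[:, None]
    lam_cycle = float(
        _monodromy_pairwise(states, np.array([spec.mu_res]), np.array([spec.mu_mut]), spec)[0]
    )
    return MonodromyResult(lam_cycle=lam_cycle, lam_pergen=lam_cycle ** (1.0 / (2 * spec.T)))


def pip(
    spec: ModifierModelSpec,
    resident_grid,
    mutant_grid,
    tol: float = 1e-12,
    max_cycles: int = 100_000,
) -> PIPGrid:
    """Pairwise invasibility plot of mutant vs resident mutation rates.

    Entries are per-generation invasion eigenvalues lam_cycle^(1/2T); the
    diagonal is 1 up to numerical tolerance (a modifier identical to the
    resident is neutral).
    """
    res = np.asarray(resident_grid, dtype=float)
    mut = np.asarray(mutant_grid, dtype=float)
    if np.any(res < 0) or np.any(res > 0.5) or np.any(mut < 0) or np.any(mut > 0.5):
        raise ValueError("mutation-rate grids must lie in [0, 0.5]")
    states, resid = _cycle_batch(res, spec, tol, max_cycles)
    # pairwise flattening: column (i, j) pairs mutant i with resident j
    nm, nr = mut.size, res.size
    states_pair = np.repeat(states, nm, axis=1)  # resident j repeated for each mutant
    mu_res_pair = np.repeat(res, nm)
    mu_mut_pair = np.tile(mut, nr)
    lam_cycle = _monodromy_pairwise(states_pair, mu_res_pair, mu_mut_pair, spec)
    lam = lam_cycle.reshape(nr, nm).T ** (1.0 / (2 * spec.T))
    return PIPGrid(res, mut, lam)


def _diagonal_gradient(spec: ModifierModelSpec, mu_hat: float, delta: float,
                       tol: float, max_cycles: int) -> float:
    """lam_cycle(mu_hat + delta, mu_hat) - 1: sign of selection on the rate."""
    states, _ = _cycle_batch(np.array([mu_hat]), spec, tol, max_cycles)
    up = min(mu_hat + delta, 0.5)
    lam = float(_monodromy_pairwise(states, np.array([mu_hat]), np.array([up]), spec)[0])
    return lam - 1.0


def es_rate(
    spec: ModifierModelSpec,
    grid=None,
    tol: float = 1e-5,
    cycle_tol: float = 1e-12,
    max_cycles: int = 100_000,
    gradient_delta: float = 1e-4,
) -> ESRateResult:
    """Evolutionarily stable mutation rate on a resident grid.

    Scans the diagonal selection gradient lam(mu + delta, mu) - 1 over the
    grid (default 41 points on [0, 0.05]); a +/- sign change brackets a
    candidate ES rate which is refined by bisection to ``tol``.  A gradient
    negative everywhere returns the boundary rate 0 (reduction-principle
    case).  Every candidate is then verified against the full grid of
    mutant rates; ``uninvadable`` reports the verdict for ``mu_star``.
    Multiple sign changes are all reported in ``candidates``.
    """
    if grid is None:
        grid = np.linspace(0.0, 0.05, 41)
    grid = np.asarray(grid, dtype=float)
    states, _ = _cycle_batch(grid, spec, cycle_tol, max_cycles)
    grads = (
        _monodromy_pairwise(states, grid, np.minimum(grid + gradient_delta, 0.5), spec) - 1.0
    )
    candidates: list[tuple[float, tuple[float, float]]] = []
    for i in range(len(grid) - 1):
        if grads[i] > 0.0 and grads[i + 1] <= 0.0:
            a, b = float(grid[i]), float(grid[i + 1])
            ga = grads[i]
            while b - a > tol:
                m = 0.5 * (a + b)
                gm = _diagonal_gradient(spec, m, gradient_delta, cycle_tol, max_cycles)
                if ga * gm <= 0:
                    b = m
                else:
                    a, ga = m, gm
            candidates.append((0.5 * (a + b), (float(grid[i]), float(grid[i + 1]))))
    if not candidates:
        if np.all(grads <= 0.0):
            mu_star, bracket, method = float(grid[0]), (float(grid[0]), float(grid[0])), "boundary"
        elif np.all(grads >= 0.0):
            mu_star, bracket, method = float(grid[-1]), (float(grid[-1]), float(grid[-1])), "boundary"
        else:
            # gradient flips - to + only: interior repellor, boundaries are ES
            mu_star, bracket, method = float(grid[0]), (float(grid[0]), float(grid[0])), "boundary"
    else:
        mu_star, bracket = candidates[0]
        method = "diagonal_sign_change"
    # verify uninvadability of mu_star against the whole mutant grid
    states, _ = _cycle_batch(np.array([mu_star]), spec, cycle_tol, max_cycles)
    states_pair = np.repeat(states, grid.size, axis=1)
    lams = _monodromy_pairwise(
        states_pair, np.full(grid.size, mu_star), grid, spec
    ) ** (1.0 / (2 * spec.T))
    max_lam = float(np.max(lams))
    uninvadable = bool(max_lam <= 1.0 + max(tol, 1e-7))
    return ESRateResult(
        mu_star=mu_star,
        bracket=bracket,
        method=method,
        uninvadable=uninvadable,
        candidates=tuple(candidates),
        max_lam_pergen=max_lam,
    )
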