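"""Invasion fitness in group- and class-structured populations.

The population is an infinite island model: infinitely many groups, each
holding ``n_s`` residents in each of ``c`` demographic classes, connected
by uniform migration.  A rare mutant lineage is tracked by the number of
mutants per class in each group, k = (k_1, ..., k_c); because the mutant
is globally rare, immigrants into any focal group are never mutants and
emigrant mutants found new single-mutant groups.  The lineage therefore
grows as a multitype branching process whose mean matrix A (the projection
matrix over group states) has a Perron eigenvalue lambda: the invasion
fitness of the mutant phenotype.

From the same eigen-solution the module derives the stationary mutant
context distribution q_{k,s}, its class marginals q_s, class reproductive
values v_s, and within-group relatedness r_{sigma|s}; these feed two
algebraically equivalent partitions of lambda - 1: an inclusive-fitness
(actor-centred) form in costs, benefits and relatedness, and a
group-selection (between-group vs within-group) form.

A convention the partitions rely on: benefit coefficients are stored
per recipient.  The actor-centred form and the between-group term use the
total benefit conferred by one actor (per-recipient coefficient times the
number of recipients in the class), while the within-group term uses the
per-recipient coefficient (the benefit a focal receives from one mutant
groupmate).  With both terms written in the same symbol the two partitions
only agree for groups of two; with this convention they agree exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GroupModelSpec",
    "IslandKernel",
    "LinearKernel",
    "ProjectionMatrix",
    "InvasionResult",
    "FitnessPartition",
    "enumerate_group_states",
    "build_projection",
    "leading_eigenpair",
    "lineage_fitness",
    "demographic_summaries",
    "decompose_costs_benefits",
    "inclusive_fitness",
    "group_partition",
    "invasion_analysis",
    "sex_ratio_invasion",
]

STATE_CAP = 10_000


# ---------------------------------------------------------------------------
# fitness kernels


class IslandKernel:
    """Haploid Wright-Fisher island model with fecundity selection.

    One demographic class; groups of ``n`` adults.  Each adult's fecundity
    is 1 + delta * (mean pay-off against its n-1 groupmates) under the 2x2
    game ``W`` (pay-off of phenotype a against phenotype b is the bilinear
    w(a, b)).  Each of the n adult slots of the next generation is filled
    by a philopatric juvenile with probability 1 - m (chosen proportionally
    to parental fecundity within the group) and by an immigrant, never a
    mutant, with probability m.  Emigrant juveniles compete in the global
    pool: an adult's expected number of offspring established in other
    groups is m * (own fecundity) / (resident mean fecundity).

    The kernel exposes the philopatric and emigrant parts of the individual
    relative fitness separately; their sum is the total expected number of
    adult offspring of a mutant, counted after all life-cycle events.
    """

    def __init__(self, n: int, m: float, W, delta: float):
        if n < 1:
            raise ValueError("group size n must be >= 1")
        if not (0.0 < m <= 1.0):
            raise ValueError("migration probability m must lie in (0, 1]")
        if delta < 0:
            raise ValueError("selection intensity delta must be >= 0")
        self.n = int(n)
        self.m = float(m)
        self.W = W
        self.delta = float(delta)

    def n_s(self) -> tuple[int, ...]:
        return (self.n,)

    def _payoff(self, a: float, b: float) -> float:
        W = self.W
        return (
            a * b * W.w11
            + a * (1 - b) * W.w10
            + (1 - a) * b * W.w01
            + (1 - a) * (1 - b) * W.w00
        )

    def _fecundities(self, k: int, y: float, xhat: float) -> tuple[float, float, float]:
        """(mutant, in-group resident, population resident) fecundities."""
        n = self.n
        if n == 1:
            pi_mut = self._payoff(y, xhat)  # partners drawn from other groups
            pi_res = self._payoff(xhat, xhat)
        else:
            pi_mut = ((k - 1) * self._payoff(y, y) + (n - k) * self._payoff(y, xhat)) / (n - 1)
            pi_res = (k * self._payoff(xhat, y) + (n - k - 1) * self._payoff(xhat, xhat)) / (
                n - 1
            )
        pi_pop = self._payoff(xhat, xhat)
        return (
            1.0 + self.delta * pi_mut,
            1.0 + self.delta * pi_res,
            1.0 + self.delta * pi_pop,
        )

    def fitness_parts(self, k_vec, y_vec, xhat_vec, s: int = 0, s_prime: int = 0):
        """(philopatric, emigrant) expected offspring of one class-s mutant."""
        k = int(k_vec[0])
        y, xhat = float(y_vec[0]), float(xhat_vec[0])
        f_mut, f_res, f_pop = self._fecundities(k, y, xhat)
        total = k * f_mut + (self.n - k) * f_res
        philo = self.n * (1.0 - self.m) * f_mut / total
        emig = self.m * f_mut / f_pop
        return philo, emig

    def fitness_parts_profile(self, phenos: np.ndarray, focal: int, xhat: float):
        """Fitness parts of ``focal`` given the full vector of group phenotypes.

        Used for marginal (cost/benefit) derivatives: ``phenos`` has length
        n and entry i is group member i's phenotype; the rest of the
        population is monomorphic at ``xhat``.
        """
        n = self.n
        if n == 1:
            f = 1.0 + self.delta * self._payoff(phenos[0], xhat)
            f_pop = 1.0 + self.delta * self._payoff(xhat, xhat)
            return n * (1.0 - self.m) * f / f, self.m * f / f_pop
        fec = np.empty(n)
        for i in range(n):
            others = [phenos[j] for j in range(n) if j != i]
            pi = sum(self._payoff(phenos[i], o) for o in others) / (n - 1)
            fec[i] = 1.0 + self.delta * pi
        f_pop = 1.0 + self.delta * self._payoff(xhat, xhat)
        philo = n * (1.0 - self.m) * fec[focal] / fec.sum()
        emig = self.m * fec[focal] / f_pop
        return philo, emig


class LinearKernel:
    """Generic multi-class kernel with fitness linear in phenotypes.

    Individual relative fitness of a class-s mutant in a group with mutant
    count vector k, split into philopatric and emigrant parts:

        omega_{s's k} = base[s', s]
                        + own[s', s] * (y_s - xhat_s)
                        + sum_sigma per[s', sigma, s] * (k_sigma - [sigma == s]) * (y_sigma - xhat_sigma)

    where ``per[s', sigma, s]`` is the per-groupmate effect of one mutant
    class-sigma groupmate on a class-s individual's class-s' offspring
    production.  ``philo_frac`` in [0, 1] splits every term into the
    philopatric part (competing for the n_{s'} local slots) and the
    emigrant part (founding new groups).  Coefficients must keep the
    philopatric slot-filling probabilities within [0, 1] on the tested
    phenotype ranges; build_projection validates this.
    """

    def __init__(self, n_s, base, own, per, philo_frac: float, y, xhat):
        self._n_s = tuple(int(v) for v in n_s)
        c = len(self._n_s)
        self.base = np.asarray(base, dtype=float).reshape(c, c)
        self.own = np.asarray(own, dtype=float).reshape(c, c)
        self.per = np.asarray(per, dtype=float).reshape(c, c, c)
        if not (0.0 <= philo_frac <= 1.0):
            raise ValueError("philo_frac must lie in [0, 1]")
        self.philo_frac = float(philo_frac)
        self.y = np.asarray(y, dtype=float)
        self.xhat = np.asarray(xhat, dtype=float)

    def n_s(self) -> tuple[int, ...]:
        return self._n_s

    def omega(self, k_vec, s: int, s_prime: int) -> float:
        dy = self.y - self.xhat
        val = self.base[s_prime, s] + self.own[s_prime, s] * dy[s]
        for sigma in range(len(self._n_s)):
            mates = k_vec[sigma] - (1 if sigma == s else 0)
            val += self.per[s_prime, sigma, s] * mates * dy[sigma]
        return val

    def fitness_parts(self, k_vec, y_vec, xhat_vec, s: int = 0, s_prime: int = 0):
        w = self.omega(k_vec, s, s_prime)
        return self.philo_frac * w, (1.0 - self.philo_frac) * w


# ---------------------------------------------------------------------------
# state space and projection matrix


def enumerate_group_states(n_s) -> list[tuple[int, ...]]:
    """All mutant-count vectors k with 0 <= k_s <= n_s, excluding zero.

    Lexicographic order; count is prod(n_s + 1) - 1.  Raises if the state
    space exceeds the cap of 10^4 states.
    """
    n_s = tuple(int(v) for v in n_s)
    if any(v < 1 for v in n_s):
        raise ValueError("all class sizes must be positive")
    count = math.prod(v + 1 for v in n_s) - 1
    if count > STATE_CAP:
        raise ValueError(
            f"state space has {count} states (> {STATE_CAP}); coarsen classes or shrink n"
        )
    states = [
        k for k in itertools.product(*(range(v + 1) for v in n_s)) if any(k)
    ]
    return states


@dataclass(frozen=True)
class GroupModelSpec:
    """A kernel together with mutant and resident phenotypes.

    ``kernel`` must expose ``n_s()`` and ``fitness_parts(k, y, xhat, s, s')``
    returning the (philopatric, emigrant) parts of the expected number of
    class-s' offspring of a class-s mutant in a group in state k.
    """

    kernel: object
    y: np.ndarray
    xhat: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "y", np.atleast_1d(np.asarray(self.y, dtype=float)))
        object.__setattr__(self, "xhat", np.atleast_1d(np.asarray(self.xhat, dtype=float)))
        c = len(self.kernel.n_s())
        if self.y.shape != (c,) or self.xhat.shape != (c,):
            raise ValueError(f"phenotype vectors must have length {c}")

    @property
    def n_s(self) -> tuple[int, ...]:
        return self.kernel.n_s()


@dataclass(frozen=True)
class ProjectionMatrix:
    states: tuple
    A: np.ndarray


@dataclass(frozen=True)
class InvasionResult:
    lam: float
    u: np.ndarray
    q_ks: np.ndarray  # rows: states, cols: classes
    q_s: np.ndarray
    v_s: np.ndarray
    r_sigma_s: np.ndarray  # r[sigma, s]; nan where undefined (no groupmates)
    states: tuple


@dataclass(frozen=True)
class FitnessPartition:
    cost: np.ndarray  # c[s', s]
    benefit_total: np.ndarray  # B[s', sigma, s]: total conferred by one class-s actor
    benefit_per: np.ndarray  # beta[s', sigma, s]: per class-sigma recipient
    if_value: float = float("nan")
    group_terms: np.ndarray | None = None
    within_terms: np.ndarray | None = None
    gs_value: float = float("nan")


def _omega_matrix(spec: GroupModelSpec, k_vec) -> np.ndarray:
    """omega[s', s]: expected class-s' offspring of a class-s mutant in k."""
    c = len(spec.n_s)
    out = np.empty((c, c))
    for s in range(c):
        for sp in range(c):
            philo, emig = spec.kernel.fitness_parts(k_vec, spec.y, spec.xhat, s, sp)
            out[sp, s] = philo + emig
    return out


def _philo_emig(spec: GroupModelSpec, k_vec) -> tuple[np.ndarray, np.ndarray]:
    c = len(spec.n_s)
    philo = np.empty((c, c))
    emig = np.empty((c, c))
    for s in range(c):
        for sp in range(c):
            ph, em = spec.kernel.fitness_parts(k_vec, spec.y, spec.xhat, s, sp)
            philo[sp, s] = ph
            emig[sp, s] = em
    return philo, emig


def build_projection(spec: GroupModelSpec) -> ProjectionMatrix:
    """Expected-group-count projection matrix over mutant group states.

    From a group in state k: each of the n_{s'} class-s' slots of the same
    group next generation is mutant independently with probability
    phi_{s'}(k) = sum_s k_s * philo_{s's}(k) / n_{s'} (binomial within each
    class, independent across classes), and emigrant mutant offspring found
    new groups with a single class-s' mutant at expected rate
    e_{s'}(k) = sum_s k_s * emig_{s's}(k).  Entry a_{k'k} is the expected
    number of next-generation mutant groups in state k' descending from one
    state-k group.
    """
    states = enumerate_group_states(spec.n_s)
    index = {k: i for i, k in enumerate(states)}
    n_s = spec.n_s
    c = len(n_s)
    N = len(states)
    A = np.zeros((N, N))
    for j, k in enumerate(states):
        philo, emig = _philo_emig(spec, k)
        if np.any(philo < -1e-12) or np.any(emig < -1e-12):
            raise ValueError(f"kernel returned negative fitness at state {k}")
        kv = np.asarray(k, dtype=float)
        phi = np.clip((philo @ kv) / np.asarray(n_s, dtype=float), 0.0, 1.0)
        e = emig @ kv
        # binomial distribution over k' for the focal group's next state
        pmfs = [_binom_pmf(n_s[s], phi[s]) for s in range(c)]
        for kp in itertools.product(*(range(v + 1) for v in n_s)):
            if not any(kp):
                continue
            prob = 1.0
            for s in range(c):
                prob *= pmfs[s][kp[s]]
            if prob > 0.0:
                A[index[kp], j] += prob
        # emigrant-founded singleton groups
        for s in range(c):
            if e[s] > 0.0:
                single = tuple(1 if t == s else 0 for t in range(c))
                A[index[single], j] += e[s]
    return ProjectionMatrix(tuple(states), A)


def _binom_pmf(n: int, p: float) -> np.ndarray:
    out = np.empty(n + 1)
    q = 1.0 - p
    for k in range(n + 1):
        out[k] = math.comb(n, k) * p**k * q ** (n - k)
    return out


def leading_eigenpair(A: np.ndarray, tol: float = 1e-13) -> tuple[float, np.ndarray]:
    """Perron eigenvalue and non-negative right eigenvector, sum(u) = 1.

    Dense eigensolve with a power-iteration fallback when the dominant
    eigenvector is not sign-consistent (reducible or defective matrices);
    ties on magnitude are broken toward the eigenvector with non-negative
    entries.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < -1e-12):
        raise ValueError("projection matrix must be non-negative")
    vals, vecs = np.linalg.eig(A)
    order = np.argsort(-np.abs(vals))
    for k in order:
        if abs(np.abs(vals[k]) - np.abs(vals[order[0]])) > 1e-12 * max(1.0, np.abs(vals[order[0]])):
            break
        v = np.real(vecs[:, k])
        if abs(np.imag(vals[k])) > 1e-12:
            continue
        if np.all(v <= 1e-10) :
            v = -v
        if np.all(v >= -1e-10):
            v = np.clip(v, 0.0, None)
            s = v.sum()
            if s > 0:
                return float(np.abs(vals[k])), v / s
    # fallback: power iteration
    n = A.shape[0]
    v = np.full(n, 1.0 / n)
    lam = 1.0
    for _ in range(100_000):
        w = A @ v
        s = w.sum()
        if s <= 0:
            return 0.0, v
        w /= s
        if np.max(np.abs(w - v)) < tol:
            return float(s), w
        v, lam = w, s
    return float(lam), v


def lineage_fitness(spec: GroupModelSpec, u: np.ndarray, states=None) -> float:
    """Average fitness of a mutant allele over its stationary contexts.

    lambda = sum_{k,s',s} omega_{s's k} q_{k,s} with q_{k,s} proportional
    to k_s u_k; equals the Perron eigenvalue of the projection matrix.
    """
    if states is None:
        states = enumerate_group_states(spec.n_s)
    u = np.asarray(u, dtype=float)
    K = np.asarray(states, dtype=float)  # (N, c)
    weights = K * u[:, None]  # k_s u_k
    total = weights.sum()
    if total <= 0:
        raise ValueError("degenerate stationary distribution")
    lam = 0.0
    for i, k in enumerate(states):
        omega = _omega_matrix(spec, k)  # [s', s]
        lam += float(omega.sum(axis=0) @ weights[i]) / total
    return lam


def demographic_summaries(spec: GroupModelSpec, A: ProjectionMatrix, u: np.ndarray):
    """Stationary context distribution, class marginals, reproductive
    values and relatedness.

    q_{k,s} = k_s u_k / sum k_s u_k; q_s sums over k; r_{sigma|s} is the
    expected mutant fraction among a mutant's class-sigma groupmates under
    q (self excluded when sigma == s), nan when a class has no groupmates;
    v_s is the left Perron eigenvector of the resident class-aggregated
    offspring matrix, normalised so sum_s v_s n_s / n = 1.
    """
    states = A.states
    n_s = spec.n_s
    c = len(n_s)
    u = np.asarray(u, dtype=float)
    K = np.asarray(states, dtype=float)
    w = K * u[:, None]
    q_ks = w / w.sum()
    q_s = q_ks.sum(axis=0)
    # relatedness
    r = np.full((c, c), np.nan)
    for s in range(c):
        if q_s[s] <= 0:
            continue
        cond = q_ks[:, s] / q_s[s]
        for sigma in range(c):
            denom = n_s[sigma] - (1 if sigma == s else 0)
            if denom == 0:
                continue
            frac = (K[:, sigma] - (1.0 if sigma == s else 0.0)) / denom
            r[sigma, s] = float(cond @ frac)
    # reproductive values from the resident class transition matrix
    res_spec = GroupModelSpec(kernel=spec.kernel, y=spec.xhat, xhat=spec.xhat)
    # a resident's expected class-s' offspring: evaluate the kernel for a
    # "mutant" with resident phenotype in a group with a single mutant
    omega_res = np.empty((c, c))
    for s in range(c):
        k = tuple(1 if t == s else 0 for t in range(c))
        omega_res[:, s] = _omega_matrix(res_spec, k)[:, s]
    vals, vecs = np.linalg.eig(omega_res.T)
    k = int(np.argmax(np.real(vals)))
    v = np.real(vecs[:, k])
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    shares = np.asarray(n_s, dtype=float) / sum(n_s)
    v = v / (v @ shares)
    return q_ks, q_s, v, r


def decompose_costs_benefits(spec: GroupModelSpec, h: float = 1e-6):
    """Marginal cost and benefit coefficients of mutant expression.

    cost[s', s] = - d omega_{s's} / d (own phenotype) * (y_s - xhat_s):
    the marginal decrease in class-s' offspring of a class-s individual
    from its own expression.  benefit_per[s', sigma, s] is the marginal
    increase in class-s' offspring of a class-sigma individual caused by
    one expressing groupmate of class s; benefit_total multiplies by the
    number of such recipients (n_sigma - [sigma == s]).  Derivatives are
    evaluated at the all-resident point by central differences (exact for
    kernels linear in phenotypes).
    """
    n_s = spec.n_s
    c = len(n_s)
    dy = spec.y - spec.xhat
    cost = np.zeros((c, c))
    beta = np.zeros((c, c, c))  # [s', recipient sigma, actor s]
    if hasattr(spec.kernel, "fitness_parts_profile"):
        # single-class kernels with an explicit member-phenotype profile
        n = n_s[0]
        xh = float(spec.xhat[0])
        base = np.full(n, xh)

        def total(phenos, focal):
            ph, em = spec.kernel.fitness_parts_profile(phenos, focal, xh)
            return ph + em

        up = base.copy()
        up[0] = xh + h
        dn = base.copy()
        dn[0] = xh - h
        d_own = (total(up, 0) - total(dn, 0)) / (2 * h)
        cost[0, 0] = -d_own * dy[0]
        if n >= 2:
            up = base.copy()
            up[1] = xh + h
            dn = base.copy()
            dn[1] = xh - h
            d_mate = (total(up, 0) - total(dn, 0)) / (2 * h)
            beta[0, 0, 0] = d_mate * dy[0]
        if not np.all(np.isfinite(cost)) or not np.all(np.isfinite(beta)):
            raise ValueError("non-finite marginal fitness derivative")
    elif isinstance(spec.kernel, LinearKernel):
        for s in range(c):
            for sp in range(c):
                cost[sp, s] = -spec.kernel.own[sp, s] * dy[s]
            for sigma in range(c):
                for sp in range(c):
                    # effect on a class-sigma recipient of one class-s actor
                    beta[sp, sigma, s] = spec.kernel.per[sp, s, sigma] * dy[s]
    else:
        raise TypeError("kernel does not expose marginal fitness effects")
    n_arr = np.asarray(n_s, dtype=float)
    recipients = n_arr[None, :, None] - (np.arange(c)[:, None] == np.arange(c)[None, :])[None, :, :]
    benefit_total = beta * recipients
    return FitnessPartition(cost=cost, benefit_total=benefit_total, benefit_per=beta)


def inclusive_fitness(spec: GroupModelSpec, summaries, partition: FitnessPartition) -> float:
    """Actor-centred (inclusive-fitness) reconstruction of lambda.

    lambda_if = 1 + sum_{s',s} q_s v_{s'} ( -c_{s's}
                  + sum_sigma B_{s' sigma <- s} r_{sigma|s} )

    with B the total benefit conferred by one class-s actor on class-sigma
    recipients.  Raises when a benefit coefficient multiplies an undefined
    relatedness (a class without groupmates).
    """
    _, q_s, v_s, r = summaries
    c = len(q_s)
    val = 1.0
    for s in range(c):
        for sp in range(c):
            contrib = -partition.cost[sp, s]
            for sigma in range(c):
                B = partition.benefit_total[sp, sigma, s]
                if B != 0.0:
                    if not np.isfinite(r[sigma, s]):
                        raise ValueError(
                            f"relatedness r[{sigma}|{s}] undefined but benefit non-zero"
                        )
                    contrib += B * r[sigma, s]
            val += q_s[s] * v_s[sp] * contrib
    return val


def group_partition(spec: GroupModelSpec, summaries, partition: FitnessPartition):
    """Between-group vs within-group (neighbour-modulated) partition.

    omega_G[s', s]  = (B_{s's<-s} - c_{s's}) (1/n_s + (n_s - 1)/n_s r_{s|s})
                      + sum_{sigma != s} B_{s's<-sigma} r_{sigma|s}
    omega_dG[s', s] = -(beta_{s's<-s} + c_{s's}) (n_s - 1)/n_s (1 - r_{s|s})

    using the total benefit B in the between-group term and the
    per-recipient benefit beta in the within-group term (see module
    docstring).  Returns (group_terms, within_terms, lambda_gs) with
    lambda_gs = 1 + sum q_s v_{s'} (omega_G + omega_dG), equal to the
    inclusive-fitness value.
    """
    _, q_s, v_s, r = summaries
    n_s = spec.n_s
    c = len(q_s)
    omega_G = np.zeros((c, c))
    omega_dG = np.zeros((c, c))
    for s in range(c):
        ns = n_s[s]
        r_ss = r[s, s] if np.isfinite(r[s, s]) else 0.0
        for sp in range(c):
            # benefit *received by* class s actors-as-recipients from class-s actors
            B_ss = partition.benefit_total[sp, s, s]
            beta_ss = partition.benefit_per[sp, s, s]
            g = (B_ss - partition.cost[sp, s]) * (1.0 / ns + (ns - 1.0) / ns * r_ss)
            for sigma in range(c):
                if sigma == s:
                    continue
                B = partition.benefit_total[sp, s, sigma]
                if B != 0.0:
                    if not np.isfinite(r[sigma, s]):
                        raise ValueError(
                            f"relatedness r[{sigma}|{s}] undefined but benefit non-zero"
                        )
                    g += B * r[sigma, s]
            omega_G[sp, s] = g
            omega_dG[sp, s] = -(beta_ss + partition.cost[sp, s]) * (ns - 1.0) / ns * (
                1.0 - r_ss
            )
    lam_gs = 1.0 + float(np.einsum("s,p,ps->", q_s, v_s, omega_G + omega_dG))
    return omega_G, omega_dG, lam_gs


def invasion_analysis(spec: GroupModelSpec) -> InvasionResult:
    """Full eigen-analysis: lambda, u, q, v, r for one spec."""
    proj = build_projection(spec)
    lam, u = leading_eigenpair(proj.A)
    q_ks, q_s, v_s, r = demographic_summaries(spec, proj, u)
    return InvasionResult(lam=lam, u=u, q_ks=q_ks, q_s=q_s, v_s=v_s, r_sigma_s=r, states=proj.states)


# ---------------------------------------------------------------------------
# sex ratio


def sex_ratio_invasion(y: float, xhat: float) -> float:
    """Invasion fitness of a rare sex-ratio mutant under autosomal control.

    Two classes: the mutant allele sits in a female or in a male.  With the
    resident brood sex ratio xhat (proportion daughters) and mutant mothers
    producing proportion y, a rare heterozygous carrier transmits the
    allele to half of its offspring.  A mutant mother's expected numbers of
    breeding daughters and sons are (y / xhat) and ((1 - y) / (1 - xhat))
    times the resident's (one daughter and M/F sons); a mutant father mates
    with resident mothers, so his brood has the resident ratio.  The 2x2
    projection matrix then is

        A = 1/2 [[ y/xhat,                      F/M ],
                 [ ((1-y)/(1-xhat)) (M/F),      1   ]],  F/M = xhat/(1-xhat),

    whose leading eigenvalue is returned.  At xhat = 1/2 the eigenvalue is
    1 for every y (the Fisherian equal-investment ratio is selectively
    neutral in all directions, hence uninvadable).
    """
    y = float(y)
    xhat = float(xhat)
    if not (0.0 < y < 1.0) or not (0.0 < xhat < 1.0):
        raise ValueError("sex ratios must lie strictly inside (0, 1)")
    FM = xhat / (1.0 - xhat)  # females per male
    A = 0.5 * np.array(
        [
            [y / xhat, FM],
            [((1.0 - y) / (1.0 - xhat)) / FM, 1.0],
        ]
    )
    return float(np.max(np.abs(np.linalg.eigvals(A))))
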