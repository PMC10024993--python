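"""Two-strategy matrix games, ESS classification and invasion-fitness tools.

The core objects are a 2x2 pay-off matrix ``W`` for pure strategies C and D
and mixed strategies ``x`` in [0, 1] giving the probability of choosing C.
Because the pay-off of a mixed strategist is the bilinear extension of the
pure-strategy pay-offs, evolutionary stability of a candidate ``x*`` only
needs to be checked against the pure alternatives y = 0 and y = 1: the
stability margin w(x*, x*) - w(y, x*) is linear in y, so its sign on [0, 1]
is decided at the endpoints.

Also provided: pairwise invasibility plots (PIPs) for arbitrary scalar
invasion-fitness functions and classification of singular points of the
adaptive dynamics (CSS, branching point, Garden of Eden, repellor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PayoffMatrix",
    "ESSReport",
    "GameClass",
    "PIPGrid",
    "SingularPointReport",
    "payoff",
    "classify_strategy",
    "find_ess",
    "relative_fitness",
    "game_class",
    "pip",
    "classify_singular",
]

DEFAULT_TOL = 1e-9


@dataclass(frozen=True)
class PayoffMatrix:
    """Pay-offs w(I, J) of pure strategy I played against pure strategy J.

    ``w11`` is C against C, ``w10`` C against D, ``w01`` D against C and
    ``w00`` D against D.
    """

    w11: float
    w10: float
    w01: float
    w00: float

    def __post_init__(self) -> None:
        for name in ("w11", "w10", "w01", "w00"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"pay-off {name} must be finite, got {v!r}")

    def as_array(self) -> np.ndarray:
        """2x2 array ordered [[w11, w10], [w01, w00]]."""
        return np.array([[self.w11, self.w10], [self.w01, self.w00]], dtype=float)


@dataclass(frozen=True)
class ESSReport:
    """Outcome of testing one strategy for evolutionary stability.

    ``witnesses`` maps each checked alternative y to the pair
    (w(x*,x*) - w(y,x*), w(x*,y) - w(y,y)): the margin of the first-order
    stability condition and, when that margin is zero, the second-order one.
    """

    strategy: float
    ess_class: str  # "strict" | "weak" | "none"
    witnesses: dict = field(default_factory=dict)
    note: str = ""


@dataclass(frozen=True)
class GameClass:
    label: str  # "prisoners_dilemma" | "hawk_dove" | "other"


@dataclass(frozen=True)
class PIPGrid:
    """Invasion fitness lambda(mutant, resident) tabulated over a grid.

    Rows index mutant values, columns resident values.  ``invadable`` is the
    boolean mask lambda > 1.
    """

    resident_values: np.ndarray
    mutant_values: np.ndarray
    lam: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.lam, dtype=float)
        if lam.shape != (len(self.mutant_values), len(self.resident_values)):
            raise ValueError("lam shape must be (n_mutant, n_resident)")
        if not np.all(np.isfinite(lam)):
            bad = np.argwhere(~np.isfinite(lam))[0]
            raise ValueError(
                "non-finite invasion fitness at mutant="
                f"{self.mutant_values[bad[0]]}, resident={self.resident_values[bad[1]]}"
            )

    @property
    def invadable(self) -> np.ndarray:
        return np.asarray(self.lam) > 1.0


@dataclass(frozen=True)
class SingularPointReport:
    location: float
    is_ess: bool
    is_convergence_stable: bool
    label: str  # "css" | "branching" | "garden_of_eden" | "repellor" | "marginal"
    d2lam_dy2: float = float("nan")
    dgradient_dx: float = float("nan")


def _check_prob(name: str, v: float) -> float:
    v = float(v)
    if not (0.0 <= v <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
    return v


def payoff(x: float, y: float, W: PayoffMatrix) -> float:
    """Expected pay-off of a mixed strategist x against a mixed strategist y.

    Bilinear extension: w(x, y) = x y w11 + x(1-y) w10 + (1-x) y w01
    + (1-x)(1-y) w00; linear in each argument.
    """
    x = _check_prob("x", x)
    y = _check_prob("y", y)
    return (
        x * y * W.w11
        + x * (1.0 - y) * W.w10
        + (1.0 - x) * y * W.w01
        + (1.0 - x) * (1.0 - y) * W.w00
    )


def game_class(W: PayoffMatrix) -> GameClass:
    """Classify the pay-off ordering: Prisoner's Dilemma, Hawk-Dove or other.

    PD: w01 > w11 > w00 > w10 (defection dominant, mutual cooperation better
    than mutual defection).  Hawk-Dove/Snowdrift: w01 > w11 > w10 > w00.
    """
    if W.w01 > W.w11 > W.w00 > W.w10:
        return GameClass("prisoners_dilemma")
    if W.w01 > W.w11 > W.w10 > W.w00:
        return GameClass("hawk_dove")
    return GameClass("other")


def classify_strategy(x: float, W: PayoffMatrix, tol: float = DEFAULT_TOL) -> ESSReport:
    """Test whether ``x`` is a strict ESS, a weak ESS, or neither.

    A resident x* is stable against a rare alternative y when either
    w(x*, x*) > w(y, x*), or those are equal and w(x*, y) > w(y, y).
    Differences with absolute value <= tol count as equality.  By linearity
    of the stability margins in y, checking y in {0, 1} decides all y.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    x = _check_prob("x", x)
    wxx = payoff(x, x, W)
    witnesses: dict[float, tuple[float, float]] = {}
    classes = []
    for y in (0.0, 1.0):
        first = wxx - payoff(y, x, W)  # w(x*,x*) - w(y,x*)
        second = payoff(x, y, W) - payoff(y, y, W)  # w(x*,y) - w(y,y)
        witnesses[y] = (first, second)
        if abs(y - x) <= tol:
            classes.append("self")  # x* itself; neutral by definition
        elif first > tol:
            classes.append("strict")
        elif abs(first) <= tol and second > tol:
            classes.append("weak")
        else:
            classes.append("none")
    # Interior x*: both margins are linear in y and vanish at y = x*, so if
    # the first margin is strictly positive at both endpoints that already
    # contradicts linearity unless x* is an endpoint.  For an interior x*
    # the first margin is zero for all y (it is linear with two roots), so
    # stability rests on the second-order condition.
    real = [c for c in classes if c != "self"]
    if not real:
        # degenerate: x within tol of both 0 and 1 impossible; treat as none
        return ESSReport(x, "none", witnesses, note="no alternative to check")
    if all(c == "strict" for c in real):
        cls = "strict"
    elif all(c in ("strict", "weak") for c in real):
        cls = "weak"
    else:
        cls = "none"
    # Interior candidates: the first margin is linear in y with roots at
    # y = x* (self) and hence vanishes identically; stability then rests on
    # the second-order condition holding strictly at both endpoints, which
    # is the weak-ESS case by definition.
    if tol < x < 1.0 - tol:
        firsts = [witnesses[y][0] for y in (0.0, 1.0)]
        seconds = [witnesses[y][1] for y in (0.0, 1.0)]
        if all(abs(f) <= tol for f in firsts):
            cls = "weak" if all(s > tol for s in seconds) else "none"
    return ESSReport(x, cls, witnesses)


def find_ess(W: PayoffMatrix, tol: float = DEFAULT_TOL) -> list[ESSReport]:
    """All ESSs among the corners {0, 1} and the interior candidate.

    The interior candidate x* = (w10 - w00) / (w10 - w00 + w01 - w11) is the
    mixed equilibrium where both behaviours earn equal pay-off; it is only
    examined when the denominator is non-degenerate and x* falls inside
    (0, 1).  Corner-merging: an interior candidate within tol of 0 or 1 is
    dropped in favour of the corner.
    """
    candidates: list[tuple[float, str]] = [(0.0, ""), (1.0, "")]
    denom = (W.w10 - W.w00) + (W.w01 - W.w11)
    if abs(denom) <= tol * max(1.0, abs(W.w10 - W.w00)):
        candidates.append((math.nan, "interior candidate skipped: degenerate denominator"))
    else:
        xstar = (W.w10 - W.w00) / denom
        if tol < xstar < 1.0 - tol:
            candidates.append((xstar, ""))
    out: list[ESSReport] = []
    for cand, note in candidates:
        if math.isnan(cand):
            out.append(ESSReport(cand, "skipped", note=note))
            continue
        rep = classify_strategy(cand, W, tol=tol)
        if rep.ess_class in ("strict", "weak"):
            out.append(rep)
    return out


def relative_fitness(y: float, x: float, W: PayoffMatrix) -> float:
    """Relative fitness omega(y, x) = w(y, x) / w(x, x) of a rare mutant y.

    The resident mean pay-off w(x, x) must be positive for the ratio to be
    interpretable as a geometric growth rate.  A strict ESS at x is
    equivalent to omega(y, x) < 1 for all y != x.
    """
    wxx = payoff(x, x, W)
    if wxx <= 0:
        raise ValueError(f"resident mean pay-off w(x,x)={wxx} must be positive")
    return payoff(y, x, W) / wxx


def pip(fitness_fn, resident_values, mutant_values) -> PIPGrid:
    """Tabulate invasion fitness over the (mutant, resident) grid product.

    ``fitness_fn(mutant, resident)`` must return a finite positive growth
    rate; non-finite values raise an error naming the offending grid point.
    """
    res = np.asarray(resident_values, dtype=float)
    mut = np.asarray(mutant_values, dtype=float)
    if res.size == 0 or mut.size == 0:
        raise ValueError("grids must be non-empty")
    lam = np.empty((mut.size, res.size))
    for i, yv in enumerate(mut):
        for j, xv in enumerate(res):
            lam[i, j] = fitness_fn(yv, xv)
    return PIPGrid(res, mut, lam)


def _selection_gradient(fitness_fn, x: float, h: float) -> float:
    """Central-difference d lambda / d y at y = x."""
    return (fitness_fn(x + h, x) - fitness_fn(x - h, x)) / (2.0 * h)


def classify_singular(
    fitness_fn,
    search_interval: tuple[float, float],
    h: float = 1e-4,
    tol: float = 1e-6,
    n_scan: int = 64,
) -> list[SingularPointReport]:
    """Locate and classify singular points of a scalar invasion-fitness map.

    The selection gradient g(x) = d lambda(y, x)/d y at y = x is scanned on
    ``n_scan`` points of the interval; sign changes are refined by bisection.
    At each root x*:

    * evolutionary stability (ESS): d2 lambda/d y2 at (x*, x*) < -tol;
    * convergence stability: g'(x*) < -tol;

    both by central differences with step ``h`` and a Richardson check (the
    h/2 estimate must agree to 1e-3 relative, else the point is labelled
    ``marginal``).  Labels: css (both), branching (convergent, not ESS),
    garden_of_eden (ESS, not convergent), repellor (neither).
    """
    if h <= 0 or tol <= 0:
        raise ValueError("h and tol must be positive")
    lo, hi = float(search_interval[0]), float(search_interval[1])
    xs = np.linspace(lo + h, hi - h, n_scan)
    gs = np.array([_selection_gradient(fitness_fn, float(x), h) for x in xs])
    reports: list[SingularPointReport] = []
    for i in range(len(xs) - 1):
        g0, g1 = gs[i], gs[i + 1]
        if abs(g0) <= tol and abs(g1) <= tol:
            continue  # flat gradient region, not a genuine crossing
        if g0 == 0.0 or g0 * g1 < 0.0:
            a, b = float(xs[i]), float(xs[i + 1])
            ga = g0
            for _ in range(200):
                m = 0.5 * (a + b)
                gm = _selection_gradient(fitness_fn, m, h)
                if ga * gm <= 0:
                    b = m
                else:
                    a, ga = m, gm
                if b - a < 1e-12:
                    break
            xstar = 0.5 * (a + b)
            reports.append(_classify_point(fitness_fn, xstar, h, tol))
    return reports


def _classify_point(fitness_fn, xstar: float, h: float, tol: float) -> SingularPointReport:
    def d2_mut(step: float) -> float:
        return (
            fitness_fn(xstar + step, xstar)
            - 2.0 * fitness_fn(xstar, xstar)
            + fitness_fn(xstar - step, xstar)
        ) / step**2

    def dgrad(step: float) -> float:
        return (
            _selection_gradient(fitness_fn, xstar + step, step)
            - _selection_gradient(fitness_fn, xstar - step, step)
        ) / (2.0 * step)

    d2 = d2_mut(h)
    d2_half = d2_mut(h / 2.0)
    gp = dgrad(h)
    gp_half = dgrad(h / 2.0)

    def agrees(a: float, b: float) -> bool:
        scale = max(abs(a), abs(b), tol)
        return abs(a - b) <= 1e-3 * scale

    if not (agrees(d2, d2_half) and agrees(gp, gp_half)):
        return SingularPointReport(xstar, False, False, "marginal", d2_half, gp_half)
    d2, gp = d2_half, gp_half
    if abs(d2) <= tol or abs(gp) <= tol:
        return SingularPointReport(xstar, False, False, "marginal", d2, gp)
    is_ess = d2 < -tol
    is_cs = gp < -tol
    if is_ess and is_cs:
        label = "css"
    elif is_cs:
        label = "branching"
    elif is_ess:
        label = "garden_of_eden"
    else:
        label = "repellor"
    return SingularPointReport(xstar, is_ess, is_cs, label, d2, gp)
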