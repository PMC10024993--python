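import numpy as np
import pytest

from invaderkit import games


@pytest.fixture
def pd_matrix() -> games.PayoffMatrix:
    """Prisoner's Dilemma: defection dominant, cooperation mutually better."""
    return games.PayoffMatrix(w11=3, w10=0, w01=5, w00=1)


@pytest.fixture
def hd_matrix() -> games.PayoffMatrix:
    """Hawk-Dove / Snowdrift: interior mixed ESS at x* = 0.5."""
    return games.PayoffMatrix(w11=1, w10=3, w01=4, w00=0)


@pytest.fixture
def additive_pd_matrix() -> games.PayoffMatrix:
    """Additive (cost-benefit) PD: benefit 3, cost 1, no synergy term."""
    return games.PayoffMatrix(w11=2, w10=-1, w01=3, w00=0)


def brute_force_ess_class(x: float, W: games.PayoffMatrix, grid=None, tol=1e-9) -> str:
    """Independent oracle: evaluate the stability conditions on a dense y grid.

    Each alternative y is scored by the sign of the first-order margin
    w(x,x) - w(y,x) (with a +/- tol neutral band) and, inside the band, of
    the second-order margin w(x,y) - w(y,y).  Alternatives neutral in both
    margins (e.g. y approaching x, where the margins vanish linearly and
    quadratically) carry no evidence either way.  The strategy is strict if
    every alternative loses at first order, invadable if any alternative
    wins at either order, and weak when the only non-neutral evidence is
    second-order wins.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 201)
    wxx = games.payoff(x, x, W)
    strict = True
    invadable = False
    weak_evidence = False
    for y in grid:
        if abs(y - x) <= 1e-12:
            continue
        first = wxx - games.payoff(y, x, W)
        if first > tol:
            continue
        strict = False
        if first < -tol:
            invadable = True
            continue
        second = games.payoff(x, y, W) - games.payoff(y, y, W)
        if second > tol:
            weak_evidence = True
        elif second < -tol:
            invadable = True
    if invadable:
        return "none"
    if strict:
        return "strict"
    return "weak" if weak_evidence else "none"
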