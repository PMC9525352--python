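"""Concentration-response curve primitives.

All responses are expressed as percent of solvent control, so an unaffected
well sits at 100.  Two model families are used throughout the battery:

* a four-parameter logistic ("variable slope" sigmoid) on log10 concentration,
  with the orientation carried by the sign of the Hill coefficient, and
* a biphasic bell built from two logistic transitions — the response leaves
  the control level, rises (or dips) to a peak plateau and then moves to a
  second plateau at higher concentrations.

The benchmark concentration (BMC) at a benchmark response (BMR) of ``b`` is
the lowest concentration at which the curve deviates from the control level
by at least ``b`` percentage points in the adverse direction.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
from scipy.optimize import brentq

CONTROL_LEVEL = 100.0

#: adverse directions understood by the BMC solvers
DIRECTIONS = ("decrease", "increase", "both")


def _log10(c: np.ndarray | float) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        return np.log10(c)


def sigmoid(conc, bottom: float, top: float, log10_ec50: float, hill: float):
    """Variable-slope logistic.

    ``hill > 0`` rises from ``bottom`` (c -> 0) to ``top`` (c -> inf);
    ``hill < 0`` falls from ``top`` to ``bottom``.  ``conc = 0`` evaluates to
    the appropriate zero-concentration plateau.
    """
    x = _log10(conc)
    with np.errstate(over="ignore"):
        frac = 1.0 / (1.0 + 10.0 ** ((log10_ec50 - x) * hill))
    return bottom + (top - bottom) * frac


def bell(
    conc,
    bottom: float,
    top: float,
    log10_ec50: float,
    hill: float,
    log10_ec50_secondary: float,
    hill_secondary: float,
    anchor: float = CONTROL_LEVEL,
):
    """Rise-then-fall biphasic curve anchored at the control level.

    Sum of two logistic transitions: ``anchor -> top`` centred at
    ``log10_ec50`` and ``top -> bottom`` centred at ``log10_ec50_secondary``
    (both Hill coefficients positive).  For c -> 0 the curve evaluates to
    ``anchor`` (100, percent of control); when the two half-maximal points are
    well separated it plateaus near ``top`` in between and approaches
    ``bottom`` at high concentrations, which lets the same form describe
    responses that rise above and later fall below the control level.
    """
    x = _log10(conc)
    with np.errstate(over="ignore"):
        up1 = 1.0 / (1.0 + 10.0 ** ((log10_ec50 - x) * hill))
        up2 = 1.0 / (1.0 + 10.0 ** ((log10_ec50_secondary - x) * hill_secondary))
    return anchor + (top - anchor) * up1 + (bottom - top) * up2


def _threshold(bmr: float, direction: str) -> float:
    if direction == "decrease":
        return CONTROL_LEVEL - bmr
    if direction == "increase":
        return CONTROL_LEVEL + bmr
    raise ValueError(f"direction must be 'decrease' or 'increase', got {direction!r}")


def _expand_directions(direction: str) -> Iterable[str]:
    if direction == "both":
        return ("decrease", "increase")
    if direction in ("decrease", "increase"):
        return (direction,)
    raise ValueError(f"unknown direction {direction!r}")


def sigmoid_bmc(
    bottom: float,
    top: float,
    log10_ec50: float,
    hill: float,
    bmr: float,
    direction: str,
    c_max: float,
) -> float | None:
    """Closed-form BMC of a fitted sigmoid, or ``None`` when censored.

    Solves ``sigmoid(c) = 100 -/+ bmr`` and keeps the crossing only if the
    adverse deviation persists toward high concentrations and the crossing
    lies at or below the highest tested concentration ``c_max``.
    """
    if not 0 < bmr < 100:
        raise ValueError("bmr must lie in (0, 100)")
    cands = []
    hi_plateau = top if hill > 0 else bottom  # limit for c -> inf
    for d in _expand_directions(direction):
        t = _threshold(bmr, d)
        lo, hi = min(bottom, top), max(bottom, top)
        if not lo < t < hi:
            continue
        adverse_at_high = hi_plateau <= t if d == "decrease" else hi_plateau >= t
        if not adverse_at_high:
            continue
        x = log10_ec50 - np.log10((top - t) / (t - bottom)) / hill
        c = 10.0 ** x
        if c <= c_max:
            cands.append(c)
    return min(cands) if cands else None


def bmc_numeric(
    f: Callable[[np.ndarray], np.ndarray],
    bmr: float,
    direction: str,
    c_max: float,
    c_min: float | None = None,
    n_grid: int = 4000,
) -> float | None:
    """Lowest concentration in ``(0, c_max]`` where ``f`` deviates adversely.

    Brackets the first crossing of the BMR threshold on a log-spaced grid and
    refines it with Brent's method; used for bell fits (one search per limb
    falls out naturally from scanning in increasing concentration) and as a
    brute-force oracle for the closed-form sigmoid solution.
    """
    if not 0 < bmr < 100:
        raise ValueError("bmr must lie in (0, 100)")
    if c_min is None:
        c_min = c_max * 1e-8
    grid = np.logspace(np.log10(c_min), np.log10(c_max), n_grid)
    y = np.asarray(f(grid), dtype=float)
    best: float | None = None
    for d in _expand_directions(direction):
        t = _threshold(bmr, d)
        g = (y <= t) if d == "decrease" else (y >= t)
        if not g.any():
            continue
        i = int(np.argmax(g))
        if i == 0:
            # already adverse at the bottom of the search range
            cand = float(grid[0])
        else:
            def h(logc, _t=t, _sign=(1.0 if d == "decrease" else -1.0)):
                return _sign * (float(f(10.0 ** logc)) - _t)

            a, b = np.log10(grid[i - 1]), np.log10(grid[i])
            cand = float(10.0 ** brentq(h, a, b, xtol=1e-13, rtol=8.9e-16))
        if best is None or cand < best:
            best = cand
    return best
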