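"""Distributed-delay logistic models reduced by the linear chain trick.

Two fractional logistic variants carry a weak exponential memory kernel
``exp(-a(t-s))`` on the crowding term:

* variant I  — ``D^{a1} x = rho x - rho (int_0^t e^{-a(t-s)} x(s) ds)^2``
* variant II — ``D^{a1} x = rho x - rho  int_0^t e^{-a(t-s)} x^2(s) ds``

Introducing the auxiliary chain variable ``y(t)`` for the integral turns each
into a two-component incommensurate Caputo system with orders ``(alpha1, 1)``
and ``y(0) = 0``:

* variant I:  D^{a1} x = rho x - rho y^2,   D y = x   - a y,  equilibria (0,0), (a^2, a)
* variant II: D^{a1} x = rho x - rho y,     D y = x^2 - a y,  equilibria (0,0), (a, a)

At the positive equilibrium both variants share the characteristic
polynomial ``lambda^{M(a1+1)} + a lambda^{M a1} - rho lambda^M + a rho``,
so their stability maps coincide; at the trivial equilibrium the constant
term flips to ``-a rho < 0``, which forces a positive real root and hence
instability for every parameter choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .orders import (
    DEFAULT_TOL,
    IncommensurateLinearization,
    RationalOrder,
    SparsePolynomial,
    StabilityReport,
    characteristic_polynomial,
    rationalize,
    stability_report,
)

__all__ = [
    "ChainModel",
    "RegionGrid",
    "equilibria",
    "jacobian",
    "char_poly_at",
    "region_scan",
]

Variant = Literal["I", "II"]
Which = Literal["trivial", "positive"]


@dataclass(frozen=True)
class ChainModel:
    """Parameter bundle for one distributed-delay variant.

    rho is the logistic growth coefficient, a the kernel decay rate (1/time),
    alpha1 the Caputo order of the population equation; the chain variable
    always carries order 1.
    """

    variant: Variant
    rho: float
    a: float
    alpha1: RationalOrder

    def __post_init__(self) -> None:
        if self.variant not in ("I", "II"):
            raise ValueError(f"variant must be 'I' or 'II', got {self.variant!r}")
        if self.rho <= 0 or self.a <= 0:
            raise ValueError("rho and a must be positive")
        if not 0 < self.alpha1.alpha < 1:
            raise ValueError("alpha1 must lie strictly in (0, 1)")

    @classmethod
    def create(
        cls,
        variant: Variant,
        rho: float,
        a: float,
        alpha1: float,
        convention: str = "fixed_denominator",
        denominator: int = 100,
    ) -> "ChainModel":
        return cls(variant, rho, a, rationalize(alpha1, convention, denominator))

    @property
    def orders(self) -> tuple[RationalOrder, RationalOrder]:
        return (self.alpha1, rationalize(1.0, "reduced"))

    def rhs(self) -> Callable[[float, np.ndarray], np.ndarray]:
        """Vector field of the reduced two-component system."""
        rho, a = self.rho, self.a
        if self.variant == "I":
            def f(t: float, s: np.ndarray) -> np.ndarray:
                x, y = s
                return np.array([rho * x - rho * y * y, x - a * y])
        else:
            def f(t: float, s: np.ndarray) -> np.ndarray:
                x, y = s
                return np.array([rho * x - rho * y, x * x - a * y])
        return f


def equilibria(model: ChainModel) -> list[tuple[float, float]]:
    """The trivial and positive equilibria, in that order."""
    if model.variant == "I":
        return [(0.0, 0.0), (model.a**2, model.a)]
    return [(0.0, 0.0), (model.a, model.a)]


def jacobian(model: ChainModel, point: tuple[float, float]) -> np.ndarray:
    """Jacobian of the reduced system at an equilibrium point."""
    x, y = point
    res = model.rhs()(0.0, np.asarray(point, float))
    if np.max(np.abs(res)) > 1e-9:
        raise ValueError(f"{point} is not an equilibrium (residual {res})")
    rho, a = model.rho, model.a
    if model.variant == "I":
        return np.array([[rho, -2.0 * rho * y], [1.0, -a]])
    return np.array([[rho, -rho], [2.0 * x, -a]])


def char_poly_at(model: ChainModel, which: Which, M: int | None = None) -> SparsePolynomial:
    """Characteristic polynomial at the trivial or positive equilibrium.

    With denominator-100 orders the positive equilibrium of either variant
    gives ``{M(a1+1): 1, M a1: a, M: -rho, 0: +a rho}``; the trivial one has
    constant term ``-a rho``.
    """
    eq = equilibria(model)[0 if which == "trivial" else 1]
    lin = IncommensurateLinearization(
        jacobian(model, eq),
        model.orders,
        M if M is not None else _default_M(model),
    )
    return characteristic_polynomial(lin)


def _default_M(model: ChainModel) -> int:
    from .orders import common_multiple

    return common_multiple(model.orders)


def positive_equilibrium_report(
    model: ChainModel, tol: float = DEFAULT_TOL, M: int | None = None
) -> StabilityReport:
    """Full min-|arg| stability report at the positive equilibrium."""
    M = M if M is not None else _default_M(model)
    return stability_report(char_poly_at(model, "positive", M), M, tol=tol)


@dataclass(frozen=True)
class RegionGrid:
    """Verdict map of a parameter-plane scan.

    ``imfos[i, j]`` and ``verdict[i, j]`` belong to the node
    ``(axis1_values[i], axis2_values[j])``.
    """

    axis1: str
    axis2: str
    axis1_values: np.ndarray
    axis2_values: np.ndarray
    min_arg: np.ndarray
    imfos: np.ndarray
    verdict: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.axis1_values), len(self.axis2_values))
        for name in ("min_arg", "imfos", "verdict"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} matrix shape does not match axes")

    def stable_fraction(self) -> float:
        return float(np.mean(self.verdict == "stable"))


_PLANES = {("alpha1", "a"), ("rho", "a"), ("alpha1", "rho")}


def region_scan(
    variant: Variant,
    plane: tuple[str, str],
    axis1_values: np.ndarray,
    axis2_values: np.ndarray,
    fixed: dict[str, float],
    tol: float = DEFAULT_TOL,
    convention: str = "fixed_denominator",
    denominator: int = 100,
    refine_boundary: bool = False,
) -> RegionGrid:
    """Evaluate the positive-equilibrium verdict on a parameter-plane grid.

    ``plane`` names the two scanned parameters (e.g. ``("alpha1", "a")``);
    ``fixed`` supplies the remaining one.  With ``refine_boundary`` the
    stable/unstable crossing along each axis2 row is bisected to 1e-4
    relative width and stored on the grid attribute ``boundary``.
    """
    if tuple(plane) not in _PLANES:
        raise ValueError(f"plane must be one of {sorted(_PLANES)}, got {plane}")
    axis1_values = np.asarray(axis1_values, float)
    axis2_values = np.asarray(axis2_values, float)
    _check_axis(plane[0], axis1_values)
    _check_axis(plane[1], axis2_values)

    n1, n2 = len(axis1_values), len(axis2_values)
    marg = np.empty((n1, n2))
    imfos = np.empty((n1, n2))
    verdict = np.empty((n1, n2), dtype=object)

    def evaluate(v1: float, v2: float) -> StabilityReport:
        params = dict(fixed)
        params[plane[0]] = v1
        params[plane[1]] = v2
        model = ChainModel.create(
            variant, params["rho"], params["a"], params["alpha1"],
            convention, denominator,
        )
        return positive_equilibrium_report(model, tol=tol)

    for i, v1 in enumerate(axis1_values):
        for j, v2 in enumerate(axis2_values):
            rep = evaluate(v1, v2)
            marg[i, j] = rep.min_arg
            imfos[i, j] = rep.imfos
            verdict[i, j] = rep.verdict

    grid = RegionGrid(plane[0], plane[1], axis1_values, axis2_values,
                      marg, imfos, verdict.astype(str))
    if refine_boundary:
        object.__setattr__(grid, "boundary", _bisect_boundary(evaluate, grid))
    return grid


def _check_axis(name: str, values: np.ndarray) -> None:
    if np.any(values <= 0):
        raise ValueError(f"axis {name} must be strictly positive")
    if name == "alpha1" and np.any(values >= 1):
        raise ValueError("alpha1 axis must stay inside (0, 1)")


def _bisect_boundary(evaluate, grid: RegionGrid) -> np.ndarray:
    """Per-row bisection of the stable/unstable transition along axis2."""
    out = np.full(len(grid.axis1_values), np.nan)
    for i, v1 in enumerate(grid.axis1_values):
        row = grid.verdict[i]
        flips = np.nonzero(row[:-1] != row[1:])[0]
        if flips.size == 0:
            continue
        j = int(flips[0])
        lo, hi = grid.axis2_values[j], grid.axis2_values[j + 1]
        lo_stable = row[j] == "stable"
        while (hi - lo) > 1e-4 * max(abs(hi), 1.0):
            mid = 0.5 * (lo + hi)
            if (evaluate(v1, mid).verdict == "stable") == lo_stable:
                lo = mid
            else:
                hi = mid
        out[i] = 0.5 * (lo + hi)
    return out


def bisect_boundary_in_a(
    variant: Variant,
    alpha1: float,
    rho: float,
    a_lo: float,
    a_hi: float,
    tol: float = DEFAULT_TOL,
    rel_width: float = 1e-4,
) -> float:
    """Bisect the critical kernel rate ``a`` between an unstable and a stable value."""
    rep = lambda a: positive_equilibrium_report(
        ChainModel.create(variant, rho, a, alpha1), tol=tol
    )
    lo_stable = rep(a_lo).verdict == "stable"
    hi_stable = rep(a_hi).verdict == "stable"
    if lo_stable == hi_stable:
        raise ValueError("bracket does not straddle the stability boundary")
    while (a_hi - a_lo) > rel_width * max(abs(a_hi), 1.0):
        mid = 0.5 * (a_lo + a_hi)
        if (rep(mid).verdict == "stable") == lo_stable:
            a_lo = mid
        else:
            a_hi = mid
    return 0.5 * (a_lo + a_hi)
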