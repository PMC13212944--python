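"""Incommensurate fractional-order linear stability analysis.

For a Caputo system ``D^{alpha_i} x_i = f_i(x)`` with rational orders
``alpha_i = v_i / u_i`` the linearization at an equilibrium is stable iff
every root of the generalized characteristic determinant

    det( diag(lambda^{M alpha_i}) - J ) = 0,    M = lcm(u_1, ..., u_n),

lies outside the wedge ``|arg(lambda)| <= pi / (2M)``.  The *instability
measure* ``pi/(2M) - min|arg(lambda)|`` is negative exactly on the stable
side; this module builds the determinant as an exact sparse polynomial in
``lambda``, finds all of its roots, and classifies the equilibrium.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import permutations
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "DegenerateRootError",
    "RationalOrder",
    "IncommensurateLinearization",
    "SparsePolynomial",
    "StabilityReport",
    "rationalize",
    "common_multiple",
    "characteristic_polynomial",
    "all_roots",
    "min_arg",
    "stability_report",
]

#: default marginality tolerance, radians.  Printed near-threshold cases sit
#: within ~3e-6 rad of pi/(2M) while decisive cases are >= 3e-5 away, so 1e-5
#: separates the two regimes with an order of magnitude to spare either side.
DEFAULT_TOL = 1e-5

_MAX_RATIONALIZE_DENOM = 10**6


class DegenerateRootError(ValueError):
    """Raised when the characteristic polynomial has a root at the origin.

    The min-|arg| criterion presumes a nonsingular constant term; a zero root
    means the linearization itself is degenerate and no verdict is issued.
    """


@dataclass(frozen=True)
class RationalOrder:
    """A fractional order held as an exact rational ``v/u``.

    ``reduced`` records which rationalization convention produced the pair:
    under the reduced convention ``gcd(v, u) == 1``; under a fixed-denominator
    convention the pair is kept unreduced so that the common multiple M (and
    hence the stability wedge ``pi/(2M)``) matches the convention's
    denominator even when the fraction would simplify.
    """

    alpha: float
    numerator: int
    denominator: int
    reduced: bool

    def __post_init__(self) -> None:
        v, u = self.numerator, self.denominator
        if u <= 0 or v <= 0 or v > u:
            raise ValueError(f"order must satisfy 0 < v <= u, got {v}/{u}")
        if abs(v / u - self.alpha) > 1e-12:
            raise ValueError(f"{v}/{u} does not represent alpha={self.alpha!r}")
        if self.reduced and math.gcd(v, u) != 1:
            raise ValueError(f"{v}/{u} marked reduced but gcd != 1")

    def as_fraction(self) -> Fraction:
        return Fraction(self.numerator, self.denominator)


def rationalize(
    alpha: float,
    convention: Literal["reduced", "fixed_denominator"] = "fixed_denominator",
    denominator: int = 100,
) -> RationalOrder:
    """Express ``alpha`` in (0, 1] as an exact rational order.

    ``fixed_denominator`` (default, d=100) writes alpha as ``v/d`` without
    reducing, so two-decimal orders all share denominator 100 and the wedge
    threshold is pi/200 regardless of whether the fraction simplifies.
    ``reduced`` returns the coprime pair instead.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"order must lie in (0, 1], got {alpha!r}")
    if convention == "fixed_denominator":
        scaled = alpha * denominator
        v = round(scaled)
        if abs(scaled - v) > 1e-9:
            raise ValueError(
                f"alpha={alpha!r} is not representable as v/{denominator}"
            )
        return RationalOrder(alpha, v, denominator, reduced=False)
    if convention == "reduced":
        frac = Fraction(alpha).limit_denominator(_MAX_RATIONALIZE_DENOM)
        if abs(float(frac) - alpha) > 1e-12:
            raise ValueError(f"cannot rationalize alpha={alpha!r} exactly")
        return RationalOrder(alpha, frac.numerator, frac.denominator, reduced=True)
    raise ValueError(f"unknown rationalization convention {convention!r}")


def common_multiple(orders: Sequence[RationalOrder]) -> int:
    """Least common multiple M of the orders' denominators."""
    if not orders:
        raise ValueError("need at least one order")
    return math.lcm(*(o.denominator for o in orders))


@dataclass(frozen=True)
class IncommensurateLinearization:
    """Jacobian of a fractional system at an equilibrium, with its orders."""

    jacobian: np.ndarray
    orders: tuple[RationalOrder, ...]
    M: int

    def __post_init__(self) -> None:
        jac = np.asarray(self.jacobian, dtype=float)
        object.__setattr__(self, "jacobian", jac)
        object.__setattr__(self, "orders", tuple(self.orders))
        if jac.ndim != 2 or jac.shape[0] != jac.shape[1]:
            raise ValueError(f"jacobian must be square, got shape {jac.shape}")
        if jac.shape[0] != len(self.orders):
            raise ValueError("jacobian size does not match number of orders")
        for o in self.orders:
            if self.M % o.denominator:
                raise ValueError(
                    f"M={self.M} is not divisible by denominator {o.denominator}"
                )

    @classmethod
    def from_jacobian(
        cls, jacobian: np.ndarray, orders: Sequence[RationalOrder]
    ) -> "IncommensurateLinearization":
        return cls(np.asarray(jacobian, float), tuple(orders), common_multiple(orders))


@dataclass(frozen=True)
class SparsePolynomial:
    """Real polynomial stored as (integer exponent, coefficient) pairs.

    Terms are kept with strictly descending exponents and nonzero
    coefficients; the zero polynomial is the empty term list.
    """

    terms: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        cleaned = tuple(
            (int(e), float(c)) for e, c in sorted(self.terms, reverse=True) if c != 0.0
        )
        exps = [e for e, _ in cleaned]
        if len(set(exps)) != len(exps):
            raise ValueError("duplicate exponents")
        if any(e < 0 for e in exps):
            raise ValueError("negative exponent")
        object.__setattr__(self, "terms", cleaned)

    @classmethod
    def from_dict(cls, d: dict[int, float]) -> "SparsePolynomial":
        return cls(tuple(d.items()))

    @property
    def degree(self) -> int:
        if not self.terms:
            raise ValueError("zero polynomial has no degree")
        return self.terms[0][0]

    @property
    def constant_term(self) -> float:
        for e, c in self.terms:
            if e == 0:
                return c
        return 0.0

    def __call__(self, x: complex) -> complex:
        return sum(c * x**e for e, c in self.terms)

    def derivative(self) -> "SparsePolynomial":
        return SparsePolynomial(tuple((e - 1, e * c) for e, c in self.terms if e > 0))

    def dense_coefficients(self) -> np.ndarray:
        """Coefficient vector in descending powers (numpy convention)."""
        out = np.zeros(self.degree + 1)
        for e, c in self.terms:
            out[self.degree - e] = c
        return out

    # polynomial-ring arithmetic, used by the determinant expansion
    def __add__(self, other: "SparsePolynomial") -> "SparsePolynomial":
        acc = dict(self.terms)
        for e, c in other.terms:
            acc[e] = acc.get(e, 0.0) + c
        return SparsePolynomial.from_dict(acc)

    def __neg__(self) -> "SparsePolynomial":
        return SparsePolynomial(tuple((e, -c) for e, c in self.terms))

    def __mul__(self, other: "SparsePolynomial") -> "SparsePolynomial":
        acc: dict[int, float] = {}
        for e1, c1 in self.terms:
            for e2, c2 in other.terms:
                e = e1 + e2
                acc[e] = acc.get(e, 0.0) + c1 * c2
        return SparsePolynomial.from_dict(acc)


def characteristic_polynomial(lin: IncommensurateLinearization) -> SparsePolynomial:
    """Expand ``det(diag(lambda^{M alpha_i}) - J)`` into a sparse polynomial.

    Because ``M alpha_i`` is an integer for every order, each diagonal entry
    ``lambda^{M alpha_i} - a_ii`` is an honest polynomial in lambda and the
    determinant expands exactly (Leibniz over the polynomial ring; the n! cost
    is irrelevant at the system sizes handled here).
    """
    jac, orders, M = lin.jacobian, lin.orders, lin.M
    n = jac.shape[0]
    entries: list[list[SparsePolynomial]] = []
    for i in range(n):
        row = []
        for j in range(n):
            if i == j:
                exp = M * orders[i].as_fraction()
                assert exp.denominator == 1
                row.append(
                    SparsePolynomial(((int(exp), 1.0), (0, -jac[i, i])))
                )
            else:
                row.append(SparsePolynomial(((0, -jac[i, j]),)))
        entries.append(row)

    acc: dict[int, float] = {}
    for perm in permutations(range(n)):
        sign = _parity(perm)
        prod = SparsePolynomial(((0, float(sign)),))
        for i in range(n):
            prod = prod * entries[i][perm[i]]
        for e, c in prod.terms:
            acc[e] = acc.get(e, 0.0) + c
    return SparsePolynomial.from_dict(acc)


def _parity(perm: Sequence[int]) -> int:
    seen = [False] * len(perm)
    sign = 1
    for i in range(len(perm)):
        if seen[i]:
            continue
        j, length = i, 0
        while not seen[j]:
            seen[j] = True
            j = perm[j]
            length += 1
        if length % 2 == 0:
            sign = -sign
    return sign


def all_roots(p: SparsePolynomial, refine: bool = True) -> np.ndarray:
    """All deg(p) roots of ``p``, with multiplicity.

    Roots come from the eigenvalues of the balanced companion matrix of the
    dense expansion; with ``refine`` each root is then polished by Newton
    iteration on the sparse form until the correction stalls below
    ``1e-13 * (1 + |lambda|)``.
    """
    if not p.terms or p.degree < 1:
        raise ValueError("stability queries need degree >= 1")
    roots = np.roots(p.dense_coefficients())
    if refine:
        dp = p.derivative()
        roots = np.array([_newton_polish(p, dp, r) for r in roots])
    return roots


def _newton_polish(
    p: SparsePolynomial, dp: SparsePolynomial, x: complex, max_iter: int = 30
) -> complex:
    for _ in range(max_iter):
        d = dp(x)
        if d == 0:
            return x
        step = p(x) / d
        x_new = x - step
        if abs(step) < 1e-13 * (1.0 + abs(x_new)):
            return x_new
        x = x_new
    return x


def residuals(p: SparsePolynomial, roots: Iterable[complex]) -> np.ndarray:
    return np.array([abs(p(r)) for r in roots])


def min_arg(roots: Sequence[complex], zero_tol: float = 1e-12) -> float:
    """Minimum of |Arg(lambda)| over the root set, Arg in (-pi, pi].

    A root at the origin has no argument; it signals a degenerate
    linearization and raises rather than being dropped.
    """
    roots = np.asarray(roots, complex)
    if roots.size == 0:
        raise ValueError("empty root set")
    if np.any(np.abs(roots) < zero_tol):
        raise DegenerateRootError("degenerate: zero root")
    return float(np.min(np.abs(np.angle(roots))))


@dataclass(frozen=True)
class StabilityReport:
    """Outcome of the min-|arg| stability test for one equilibrium."""

    min_arg: float
    threshold: float          # pi / (2M)
    imfos: float              # threshold - min_arg; negative <=> stable
    verdict: Literal["stable", "unstable", "marginal"]
    n_roots: int
    worst_root: complex
    M: int
    tol: float

    def to_dict(self) -> dict:
        return {
            "min_arg": self.min_arg,
            "threshold": self.threshold,
            "imfos": self.imfos,
            "verdict": self.verdict,
            "n_roots": self.n_roots,
            "worst_root": [self.worst_root.real, self.worst_root.imag],
            "M": self.M,
            "tol": self.tol,
        }


def stability_report(
    p: SparsePolynomial,
    M: int,
    tol: float = DEFAULT_TOL,
    mp_fallback: bool = True,
) -> StabilityReport:
    """Classify an equilibrium from its characteristic polynomial.

    Verdict is ``stable`` when min|arg| clears the wedge threshold pi/(2M) by
    more than ``tol``, ``unstable`` when it falls short by more than ``tol``,
    and ``marginal`` in between (the Hopf/periodic band).  When the margin is
    within ``10 * tol`` of the threshold the minimizing roots are re-polished
    at 50-digit precision before the verdict is issued.
    """
    if M < 1:
        raise ValueError("M must be a positive integer")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if p.degree >= 1 and p.constant_term == 0.0:
        raise DegenerateRootError("degenerate: zero root (zero constant term)")
    roots = all_roots(p, refine=True)
    m = min_arg(roots)
    threshold = math.pi / (2 * M)
    if mp_fallback and abs(threshold - m) < 10 * tol:
        roots = _polish_extremal_roots(p, roots)
        m = min_arg(roots)
    worst = roots[int(np.argmin(np.abs(np.angle(roots))))]
    imfos = threshold - m
    if imfos < -tol:
        verdict = "stable"
    elif imfos > tol:
        verdict = "unstable"
    else:
        verdict = "marginal"
    return StabilityReport(
        min_arg=m,
        threshold=threshold,
        imfos=imfos,
        verdict=verdict,
        n_roots=len(roots),
        worst_root=complex(worst),
        M=M,
        tol=tol,
    )


def _polish_extremal_roots(
    p: SparsePolynomial, roots: np.ndarray, k: int = 6, dps: int = 50
) -> np.ndarray:
    """Re-run Newton at ``dps`` digits on the k roots of smallest |arg|."""
    import mpmath

    order = np.argsort(np.abs(np.angle(roots)))
    polished = roots.copy()
    with mpmath.workdps(dps):
        terms = [(e, mpmath.mpf(c)) for e, c in p.terms]
        dterms = [(e - 1, e * c) for e, c in terms if e > 0]

        def ev(ts, x):
            return sum(c * x**e for e, c in ts)

        for idx in order[:k]:
            x = mpmath.mpc(roots[idx])
            for _ in range(60):
                d = ev(dterms, x)
                if d == 0:
                    break
                step = ev(terms, x) / d
                x -= step
                if abs(step) < mpmath.mpf(10) ** (-dps + 5) * (1 + abs(x)):
                    break
            polished[idx] = complex(x)
    return polished
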