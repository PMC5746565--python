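"""Univariate polynomial machinery for resonant-mode counting.

The number of resonant modes of a stochastic interaction network is the
number of local minima of ``R(x) = det(x I + J^2)`` on the positive real
axis, where ``x`` stands for the squared angular frequency omega^2.  This
module provides the polynomial ``R``, its Sturm chain, exact counting of
distinct positive real roots of ``R'``, Sturm-guided root isolation, and
the minimum/maximum classification that turns root counts into mode counts.

Coefficients are stored in descending powers.  When every coefficient is a
:class:`fractions.Fraction` (or integer) the whole pipeline runs in exact
rational arithmetic; float coefficients use a relative zero tolerance of
``1e-12``, since sign decisions on tiny Sturm coefficients are the only
numerically fragile step of the method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "Poly",
    "SturmChain",
    "CriticalPoint",
    "ModeCountResult",
    "derivative",
    "r_polynomial",
    "sturm_chain",
    "sign_changes_at",
    "count_positive_roots",
    "descartes_bound",
    "count_resonant_modes",
    "count_modes_of_poly",
    "n3_resonance_condition",
]

#: relative magnitude below which a float coefficient is treated as zero
COEFF_ZERO_RTOL = 1e-12

_EXACT_TYPES = (int, Fraction, np.integer)


def _is_exact_scalar(c) -> bool:
    return isinstance(c, _EXACT_TYPES)


class Poly:
    """Real univariate polynomial, coefficients in descending powers.

    Supports exact (``int``/``Fraction``) and float coefficients; all
    arithmetic stays within the coefficient field of the input.
    """

    __slots__ = ("coeffs", "exact")

    def __init__(self, coeffs: Sequence):
        coeffs = list(coeffs)
        if not coeffs:
            coeffs = [0]
        exact = all(_is_exact_scalar(c) for c in coeffs)
        if exact:
            # normalize away numpy integer internals so comparisons stay pure
            coeffs = [
                Fraction(int(c)) if isinstance(c, (int, np.integer))
                else Fraction(int(c.numerator), int(c.denominator))
                for c in coeffs
            ]
            while len(coeffs) > 1 and coeffs[0] == 0:
                coeffs.pop(0)
        else:
            coeffs = [float(c) for c in coeffs]
            scale = max(abs(c) for c in coeffs)
            tol = COEFF_ZERO_RTOL * scale
            coeffs = [0.0 if abs(c) <= tol else c for c in coeffs]
            while len(coeffs) > 1 and coeffs[0] == 0.0:
                coeffs.pop(0)
        self.coeffs = tuple(coeffs)
        self.exact = exact

    # -- basic protocol ----------------------------------------------------
    @property
    def degree(self) -> int:
        return len(self.coeffs) - 1

    def is_zero(self) -> bool:
        return len(self.coeffs) == 1 and self.coeffs[0] == 0

    def __call__(self, x):
        acc = self.coeffs[0]
        for c in self.coeffs[1:]:
            acc = acc * x + c
        return acc

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Poly({list(self.coeffs)!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, Poly) and self.coeffs == other.coeffs

    def __hash__(self) -> int:
        return hash(self.coeffs)

    # -- calculus / algebra ------------------------------------------------
    def deriv(self) -> "Poly":
        return derivative(self)

    def monic(self) -> "Poly":
        lead = self.coeffs[0]
        if lead == 0:
            return self
        return Poly([c / lead for c in self.coeffs])

    def scale_tol(self) -> float:
        """Magnitude scale for zero decisions on evaluations (floats only)."""
        return COEFF_ZERO_RTOL * max(abs(float(c)) for c in self.coeffs)

    def sign_at(self, x) -> int:
        """Sign of p(x), with a relative zero tolerance in float mode."""
        v = self(x)
        if self.exact:
            if v > 0:
                return 1
            return -1 if v < 0 else 0
        # conservative magnitude bound sum|c_i| * max(1,|x|)^deg
        m = max(1.0, abs(float(x))) ** self.degree
        tol = COEFF_ZERO_RTOL * sum(abs(c) for c in self.coeffs) * m
        if abs(v) <= tol:
            return 0
        return 1 if v > 0 else -1

    def cauchy_bound(self):
        """Upper bound on the absolute value of all real roots."""
        lead = abs(self.coeffs[0])
        rest = [abs(c) for c in self.coeffs[1:]]
        if not rest:
            return Fraction(1) if self.exact else 1.0
        b = 1 + max(rest) / lead
        return b


def derivative(p: Poly) -> Poly:
    """Formal derivative; a constant input yields the zero polynomial."""
    n = p.degree
    if n == 0:
        return Poly([0 if p.exact else 0.0])
    return Poly([c * (n - k) for k, c in enumerate(p.coeffs[:-1])])


def _polyrem(num: Poly, den: Poly) -> Poly:
    """Remainder of polynomial long division num / den."""
    if den.is_zero():
        raise ZeroDivisionError("polynomial division by zero")
    r = list(num.coeffs)
    d = list(den.coeffs)
    dd = len(d) - 1
    lead = d[0]
    while len(r) - 1 >= dd and any(c != 0 for c in r):
        if r[0] == 0:
            r.pop(0)
            continue
        q = r[0] / lead
        for i in range(len(d)):
            r[i] = r[i] - q * d[i]
        r.pop(0)
    if not r:
        r = [0]
    return Poly(r)


@dataclass(frozen=True)
class SturmChain:
    """Canonical Sturm chain p0, p1 = p0', p_{i+1} = -rem(p_{i-1}, p_i).

    The chain terminates when the remainder vanishes; for inputs with
    repeated roots the last member is (a multiple of) the gcd, and the
    sign-change count then yields *distinct* real roots.
    """

    polys: tuple

    def __len__(self) -> int:
        return len(self.polys)


def sturm_chain(p: Poly) -> SturmChain:
    if p.is_zero():
        raise ValueError("Sturm chain of the zero polynomial is undefined")
    chain = [p]
    if p.degree >= 1:
        chain.append(derivative(p))
        while chain[-1].degree >= 1:
            rem = _polyrem(chain[-2], chain[-1])
            if rem.is_zero():
                break
            chain.append(Poly([-c for c in rem.coeffs]))
            if chain[-1].degree == 0:
                break
    return SturmChain(tuple(chain))


def _sign_changes(signs: Sequence[int]) -> int:
    """Sign changes in a sequence, skipping zeros (standard convention)."""
    nz = [s for s in signs if s != 0]
    return sum(1 for a, b in zip(nz, nz[1:]) if a * b < 0)


def sign_changes_at(chain: SturmChain, point) -> int:
    """sigma(point) for point in {'zero', 'infinity'} or a real number.

    At infinity only the leading coefficients matter; at zero the constant
    terms.  Zero entries are skipped in the sign-change count.
    """
    if point == "infinity":
        signs = [(1 if p.coeffs[0] > 0 else -1) for p in chain.polys]
    elif point == "zero":
        signs = [p.sign_at(0) for p in chain.polys]
    else:
        signs = [p.sign_at(point) for p in chain.polys]
    return _sign_changes(signs)


def _strip_zero_roots(p: Poly) -> Poly:
    """Divide out x^m so that p(0) != 0 (roots at the origin are excluded)."""
    coeffs = list(p.coeffs)
    while len(coeffs) > 1 and coeffs[-1] == 0:
        coeffs.pop()
    return Poly(coeffs)


def count_roots_in(chain: SturmChain, a, b) -> int:
    """Number of distinct real roots in (a, b] by Sturm's theorem."""
    return sign_changes_at(chain, a) - sign_changes_at(chain, b)


def count_positive_roots(p: Poly) -> int:
    """Exact number of distinct real roots of p in (0, infinity).

    A root at the origin is divided out first and not counted.
    """
    if p.is_zero():
        raise ValueError("cannot count roots of the zero polynomial")
    p = _strip_zero_roots(p)
    if p.degree == 0:
        return 0
    chain = sturm_chain(p)
    return sign_changes_at(chain, "zero") - sign_changes_at(chain, "infinity")


def descartes_bound(p: Poly) -> int:
    """Descartes' upper bound on positive real roots (sign changes of
    consecutive nonzero coefficients, descending powers)."""
    if p.is_zero():
        raise ValueError("Descartes bound of the zero polynomial is undefined")
    return _sign_changes([(1 if c > 0 else -1) for c in p.coeffs if c != 0])


# ---------------------------------------------------------------------------
# R(omega^2) and mode counting
# ---------------------------------------------------------------------------

def _is_exact_matrix(J) -> bool:
    arr = np.asarray(J)
    if arr.dtype == object:
        return all(_is_exact_scalar(v) for v in arr.ravel())
    return np.issubdtype(arr.dtype, np.integer)


def _charpoly_exact(A) -> list:
    """det(xI - A) by Faddeev-LeVerrier over Fractions (exact)."""
    n = A.shape[0]
    A = np.array([[Fraction(v) for v in row] for row in A], dtype=object)
    M = np.array([[Fraction(int(i == j)) for j in range(n)] for i in range(n)],
                 dtype=object)
    coeffs = [Fraction(1)]
    for k in range(1, n + 1):
        AM = A @ M
        c = -sum(AM[i, i] for i in range(n)) / k
        coeffs.append(c)
        M = AM + c * np.array(
            [[Fraction(int(i == j)) for j in range(n)] for i in range(n)],
            dtype=object)
    return coeffs


def r_polynomial(J) -> Poly:
    """The spectral denominator R(x) = det(x I + J^2), x = omega^2.

    Equals the characteristic polynomial of J^2 under omega^2 = -lambda;
    monic, with constant term det(J)^2 >= 0.  Integer or Fraction input
    runs exactly; float input goes through numpy's characteristic
    polynomial (eigenvalue based).
    """
    J = np.asarray(J)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError(f"Jacobian must be square, got shape {J.shape}")
    if _is_exact_matrix(J):
        J2 = np.array([[Fraction(v) for v in row] for row in J], dtype=object)
        J2 = J2 @ J2
        return Poly(_charpoly_exact(-J2))
    J = J.astype(float)
    return Poly(np.poly(-(J @ J)))


def isolate_positive_roots(p: Poly, refine_to: float = 1e-10) -> list:
    """Disjoint intervals (a, b], each containing exactly one distinct
    positive root of p, refined by Sturm-count bisection.

    Works for floats and Fractions alike; the count inside each interval is
    maintained exactly by the Sturm chain, so repeated roots and roots
    where p does not change sign (even multiplicity) are still isolated.
    """
    p = _strip_zero_roots(p)
    if p.degree == 0:
        return []
    chain = sturm_chain(p)
    hi = p.cauchy_bound()
    lo = hi * 0  # typed zero (Fraction(0) or 0.0)
    total = count_roots_in(chain, lo, hi)
    if total == 0:
        return []

    intervals = []
    stack = [(lo, hi, total)]
    while stack:
        a, b, k = stack.pop()
        if k <= 0:
            continue
        if k == 1:
            intervals.append((a, b))
            continue
        if not float(b - a) > 0:  # cannot split further (coincident roots)
            intervals.append((a, b))
            continue
        mid = (a + b) / 2
        kl = count_roots_in(chain, a, mid)
        stack.append((a, mid, kl))
        stack.append((mid, b, k - kl))
    # refine each isolating interval by bisection on the Sturm count
    refined = []
    for a, b in intervals:
        width_goal = refine_to * max(1.0, float(b))
        it = 0
        while float(b - a) > width_goal and it < 200:
            mid = (a + b) / 2
            if count_roots_in(chain, a, mid) == 1:
                b = mid
            else:
                a = mid
            it += 1
        refined.append((a, b))
    refined.sort(key=lambda ab: float(ab[0]))
    return refined


@dataclass(frozen=True)
class CriticalPoint:
    x: float
    kind: str  # 'minimum' | 'maximum' | 'inflection'

    @property
    def omega(self) -> float:
        return float(np.sqrt(self.x))


@dataclass
class ModeCountResult:
    """Resonant-mode count of a network, with classified critical points."""

    n_species: int
    n_modes: int
    critical_points: list = field(default_factory=list)
    r_coefficients: list = field(default_factory=list)
    method: str = "sturm"

    @property
    def resonant_frequencies(self) -> list:
        return [cp.omega for cp in self.critical_points if cp.kind == "minimum"]

    def to_dict(self) -> dict:
        return {
            "n_species": self.n_species,
            "n_modes": self.n_modes,
            "critical_points": [
                {"x": cp.x, "omega": cp.omega, "kind": cp.kind}
                for cp in self.critical_points
            ],
            "coefficients": [float(c) for c in self.r_coefficients],
            "method": self.method,
        }


def count_modes_of_poly(R: Poly, n_species: int | None = None) -> ModeCountResult:
    """Classify the positive critical points of R and count its minima.

    R(0) = det(J)^2 >= 0 and R -> +inf, so minima and maxima alternate on
    (0, inf) and the largest critical point, when any exists, is a minimum.
    A critical point where R' does not change sign (an even-multiplicity
    root of R') is a saddle/inflection of R and excluded, with a warning.
    """
    if n_species is None:
        n_species = R.degree
    dR = derivative(R)
    intervals = isolate_positive_roots(dR)

    def raw_sign(x) -> int:
        v = float(dR(x))
        return (v > 0) - (v < 0)

    crit = []
    for idx, (a, b) in enumerate(intervals):
        # sample R' strictly between consecutive roots, where its sign is
        # constant; right of the largest root the sign is that of the
        # (positive) leading coefficient
        left_pt = (float(intervals[idx - 1][1]) + float(a)) / 2 if idx else \
            float(a) / 2
        sa = raw_sign(left_pt)
        if idx + 1 < len(intervals):
            sb = raw_sign((float(b) + float(intervals[idx + 1][0])) / 2)
        else:
            sb = 1 if dR.coeffs[0] > 0 else -1
        xloc = 0.5 * (float(a) + float(b))
        if sa < 0 < sb:
            kind = "minimum"
        elif sa > 0 > sb:
            kind = "maximum"
        else:
            kind = "inflection"
            warnings.warn(
                f"degenerate critical point of R at x={xloc:.6g}: "
                "R' does not change sign; excluded from mode count",
                stacklevel=2,
            )
        crit.append(CriticalPoint(x=xloc, kind=kind))
    n_modes = sum(1 for cp in crit if cp.kind == "minimum")
    if crit and all(cp.kind != "inflection" for cp in crit):
        assert crit[-1].kind == "minimum", "largest critical point must be a minimum"
    assert n_modes <= n_species // 2, "mode count exceeds floor(n/2)"
    return ModeCountResult(
        n_species=n_species,
        n_modes=n_modes,
        critical_points=crit,
        r_coefficients=list(R.coeffs),
    )


def count_resonant_modes(J) -> ModeCountResult:
    """Count the resonant modes of a network from its Jacobian.

    Builds R(x) = det(xI + J^2), counts the distinct positive roots of R'
    exactly by Sturm's theorem, isolates each by Sturm-guided bisection and
    classifies it by the sign change of R'; the modes are the minima and
    their resonant frequencies are omega_R = sqrt(x).
    """
    J = np.asarray(J)
    R = r_polynomial(J)
    return count_modes_of_poly(R, n_species=J.shape[0])


def n3_resonance_condition(a1, a2) -> str:
    """Resonance test for a three-species network from (a1, a2) alone.

    For n = 3, R(x) = x^3 + a1 x^2 + a2 x + a3 and resonance is decided by
    R' = 3x^2 + 2 a1 x + a2: the steady state supports stochastic
    oscillation iff the Sturm chain of R' evaluated at 0 and infinity
    shows a sign-change difference of one or two (one positive critical
    point means the larger, minimum branch exists; two means a maximum /
    minimum pair).  Returns ``'resonance'`` or ``'no_resonance'``.
    """
    dR = Poly([3, 2 * a1, a2]) if all(
        _is_exact_scalar(v) for v in (a1, a2)) else Poly([3.0, 2.0 * a1, a2])
    diff = count_positive_roots(dR)
    return "resonance" if diff in (1, 2) else "no_resonance"
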