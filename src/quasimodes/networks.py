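"""Cyclic autocatalytic network family and generic user-supplied systems.

The worked family is the uniform-rate cyclic autocatalytic network on n
species (rock-paper-scissors for n = 3): species X_i catalyses its own
replication at the expense of X_{i-1},

    X_{i-1} + X_i -> 2 X_i        (rate r),
    0 -> X_i                      (inflow alpha),
    X_i -> 0                      (outflow beta),

with cyclic index identification X_{n+1} = X_1.  The mean-field
concentration equations are

    dx_i/dt = r x_i (x_{i-1} - x_{i+1}) + alpha - beta x_i,

with a single uniform steady state x* = alpha/beta.  The Jacobian there is
the circulant  J = -beta I + r x* (C - C^T)  (C the cyclic shift), whose
eigenvalues -beta + 2 i r x* sin(2 pi k / n) have negative real part for
every positive parameter choice: the deterministic system never oscillates
persistently, which is exactly what makes it the canonical testbed for
noise-driven quasi-cycles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Real

import numpy as np

__all__ = [
    "NetworkSpec",
    "GenericSystem",
    "SteadyState",
    "ode_rhs",
    "steady_state",
    "jacobian",
    "squared_jacobian",
    "random_stable_system",
    "load_jacobian",
    "component_submatrices",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of the uniform cyclic autocatalytic network.

    Parameters
    ----------
    n : int
        Number of species (>= 2).
    r : float
        Autocatalytic replication rate (per concentration per time).
    alpha : float
        Constant inflow rate of each species.
    beta : float
        First-order outflow (dilution/degradation) rate.
    """

    n: int
    r: float = 1.0
    alpha: float = 0.1
    beta: float = 0.1

    def __post_init__(self):
        if int(self.n) != self.n or self.n < 2:
            raise ValueError(f"species count n must be an integer >= 2, got {self.n}")
        for name in ("r", "alpha", "beta"):
            v = getattr(self, name)
            if not (isinstance(v, Real) and v > 0):
                raise ValueError(f"rate parameter {name} must be positive, got {v!r}")
        object.__setattr__(self, "n", int(self.n))


@dataclass
class GenericSystem:
    """An arbitrary square Jacobian of a (presumed) stable steady state."""

    jacobian: np.ndarray
    label: str = ""

    def __post_init__(self):
        J = np.asarray(self.jacobian, dtype=float)
        if J.ndim != 2 or J.shape[0] != J.shape[1]:
            raise ValueError(f"Jacobian must be a square matrix, got shape {J.shape}")
        self.jacobian = J
        abscissa = float(np.max(np.linalg.eigvals(J).real))
        if abscissa >= 0:
            warnings.warn(
                f"Jacobian '{self.label or 'user matrix'}' has spectral abscissa "
                f"{abscissa:.3g} >= 0: the steady state is not stable, and the "
                "quasi-cycle analysis assumes a stable fixed point",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return self.jacobian.shape[0]


@dataclass(frozen=True)
class SteadyState:
    """Steady-state concentrations and the system size Omega."""

    concentrations: np.ndarray
    omega: float = 1.0


def _as_state(spec: NetworkSpec, state) -> np.ndarray:
    x = np.asarray(state, dtype=float)
    if x.shape != (spec.n,):
        raise ValueError(
            f"state has shape {x.shape}, expected ({spec.n},) for an "
            f"{spec.n}-species network"
        )
    return x


def ode_rhs(spec: NetworkSpec, state) -> np.ndarray:
    """Mean-field time derivative dx_i/dt = r x_i (x_{i-1} - x_{i+1}) + alpha - beta x_i."""
    x = _as_state(spec, state)
    xm = np.roll(x, 1)   # x_{i-1}
    xp = np.roll(x, -1)  # x_{i+1}
    return spec.r * x * (xm - xp) + spec.alpha - spec.beta * x


def steady_state(spec: NetworkSpec, omega: float = 1.0) -> SteadyState:
    """The unique uniform steady state x_i* = alpha/beta for all i."""
    xstar = spec.alpha / spec.beta
    return SteadyState(np.full(spec.n, xstar, dtype=float), omega=omega)


def jacobian(spec: NetworkSpec, exact: bool = False) -> np.ndarray:
    """Closed-form Jacobian at the steady state.

    J = -beta I + c (C - C^T) with c = r alpha / beta and C the cyclic
    shift; circulant, with always-negative diagonal.  For n = 2 the two
    neighbour contributions cancel and J = -beta I.  With ``exact=True``
    the entries are ``fractions.Fraction`` (decimal-literal parameters such
    as 0.1 are read at their printed decimal value).
    """
    n = spec.n
    if exact:
        r, a, b = (Fraction(str(v)) for v in (spec.r, spec.alpha, spec.beta))
        c = r * a / b
        J = np.full((n, n), Fraction(0), dtype=object)
        for i in range(n):
            J[i, i] = -b
            J[i, (i - 1) % n] += c
            J[i, (i + 1) % n] -= c
        return J
    c = spec.r * spec.alpha / spec.beta
    J = -spec.beta * np.eye(n)
    for i in range(n):
        J[i, (i - 1) % n] += c
        J[i, (i + 1) % n] -= c
    return J


def squared_jacobian(system) -> np.ndarray:
    """J @ J for a NetworkSpec, GenericSystem or raw square matrix.

    Resonant modes depend on the network only through this matrix.
    """
    if isinstance(system, NetworkSpec):
        J = jacobian(system)
    elif isinstance(system, GenericSystem):
        J = system.jacobian
    else:
        J = np.asarray(system)
        if J.ndim != 2 or J.shape[0] != J.shape[1]:
            raise ValueError(f"matrix must be square, got shape {J.shape}")
    return J @ J


def random_stable_system(n: int, seed: int) -> GenericSystem:
    """Reproducible random system with all eigenvalues in the left half-plane.

    A Ginibre matrix shifted left past its spectral abscissa by a margin
    drawn from the same stream; used as a property-test fixture generator.
    """
    if n < 2:
        raise ValueError("need at least two species")
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((n, n))
    abscissa = float(np.max(np.linalg.eigvals(G).real))
    margin = 0.1 + rng.exponential(1.0)
    J = G - (abscissa + margin) * np.eye(n)
    return GenericSystem(J, label=f"random(n={n}, seed={seed})")


def load_jacobian(path) -> np.ndarray:
    """Read a square numeric matrix from a whitespace- or comma-separated file."""
    with open(path) as fh:
        text = fh.read()
    delimiter = "," if "," in text else None
    try:
        M = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"could not parse matrix file {path}: {exc}") from exc
    if M.shape[0] != M.shape[1]:
        raise ValueError(f"matrix in {path} is not square: shape {M.shape}")
    return M


def component_submatrices(J, zero_tol: float | None = None) -> list:
    """Weakly-connected components of the graph of J, as principal submatrices.

    The analysis assumes no disjoint subnetworks; when the graph of J is
    disconnected each component is analysed separately.  Returns a list of
    (vertex_indices, submatrix) pairs in vertex order.
    """
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    J = np.asarray(J, dtype=float)
    if zero_tol is None:
        zero_tol = 1e-12 * max(1.0, float(np.max(np.abs(J))))
    adj = (np.abs(J) > zero_tol).astype(int)
    ncomp, labels = connected_components(sp.csr_matrix(adj), directed=True,
                                         connection="weak")
    out = []
    for c in range(ncomp):
        idx = np.where(labels == c)[0]
        out.append((idx, J[np.ix_(idx, idx)]))
    return out
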