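"""Parameter sweeps, phase diagrams, and the eigenvalue-pair comparator.

A phase diagram maps each point of a parameter grid to its integer number
of resonant modes (exact Sturm count).  On the alpha = beta slice of the
autocatalytic family, the diagram splits into a small number of connected
regions: flat spectrum, one mode, two modes, ...  The older eigenvalue
approximation predicts one resonance per complex-conjugate eigenvalue pair
of J with Im(lambda)^2 > Re(lambda)^2; it is fast but can over-count,
because it looks at one quadratic factor of the characteristic polynomial
of J^2 at a time while the remaining factors can flatten the minimum.
``compare_methods`` tabulates both counts cell by cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .networks import NetworkSpec, jacobian
from .polyroots import count_resonant_modes

__all__ = [
    "ParameterGrid",
    "PhaseDiagram",
    "RegionSummary",
    "scan_phase_diagram",
    "connected_regions",
    "eigenvalue_mode_prediction",
    "compare_methods",
]


@dataclass(frozen=True)
class ParameterGrid:
    """Grid over the alpha = beta slice: axes are alpha (= beta) and r."""

    alpha: np.ndarray
    r: np.ndarray
    scale: str = "log"

    @classmethod
    def from_ranges(cls, alpha_range=(1e-3, 1.0), r_range=(0.1, 10.0),
                    steps: int = 200, scale: str = "log") -> "ParameterGrid":
        if steps < 2:
            raise ValueError("grid needs at least 2 steps per axis")
        for lo, hi in (alpha_range, r_range):
            if not (0 < lo < hi):
                raise ValueError("rate-parameter ranges must be positive and increasing")
        if scale == "log":
            alpha = np.geomspace(*alpha_range, steps)
            r = np.geomspace(*r_range, steps)
        elif scale == "linear":
            alpha = np.linspace(*alpha_range, steps)
            r = np.linspace(*r_range, steps)
        else:
            raise ValueError(f"unknown scale {scale!r}")
        return cls(alpha=alpha, r=r, scale=scale)

    @property
    def shape(self) -> tuple:
        return (len(self.r), len(self.alpha))


@dataclass
class PhaseDiagram:
    """Integer mode counts on a grid; counts[i, j] is at (r[i], alpha[j])."""

    counts: np.ndarray
    grid: ParameterGrid
    n: int
    method: str = "sturm"
    unstable: np.ndarray | None = None

    def __post_init__(self):
        assert self.counts.min() >= 0
        assert self.counts.max() <= self.n // 2

    def to_frame(self) -> pd.DataFrame:
        A, R = np.meshgrid(self.grid.alpha, self.grid.r)
        return pd.DataFrame({
            "alpha": A.ravel(),
            "beta": A.ravel(),
            "r": R.ravel(),
            "n_modes": self.counts.ravel(),
        })


@dataclass
class RegionSummary:
    """Connected regions of constant mode count (4-neighbour connectivity)."""

    n_regions: int
    labels: np.ndarray
    regions: list = field(default_factory=list)  # dicts: value, size, bbox


def scan_phase_diagram(family, grid: ParameterGrid) -> PhaseDiagram:
    """Sturm mode count at every grid point of the alpha = beta slice.

    ``family`` is a NetworkSpec template (its n is used; alpha, beta, r are
    swept) or an integer species count.  Deterministic given the grid.
    """
    n = family.n if isinstance(family, NetworkSpec) else int(family)
    counts = np.zeros(grid.shape, dtype=int)
    unstable = np.zeros(grid.shape, dtype=bool)
    for i, r in enumerate(grid.r):
        for j, a in enumerate(grid.alpha):
            spec = NetworkSpec(n=n, r=float(r), alpha=float(a), beta=float(a))
            J = jacobian(spec)
            if np.max(np.linalg.eigvals(J).real) >= 0:  # never for this family
                unstable[i, j] = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                counts[i, j] = count_resonant_modes(J).n_modes
    return PhaseDiagram(counts=counts, grid=grid, n=n,
                        unstable=unstable if unstable.any() else None)


def connected_regions(pd_: PhaseDiagram) -> RegionSummary:
    """Label 4-connected regions of equal mode count by flood fill."""
    counts = pd_.counts
    if counts.size == 0:
        raise ValueError("empty phase diagram")
    mask_excl = pd_.unstable if pd_.unstable is not None else np.zeros_like(
        counts, dtype=bool)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels = np.zeros_like(counts)
    regions = []
    offset = 0
    for value in np.unique(counts[~mask_excl]):
        lab, nlab = ndimage.label((counts == value) & ~mask_excl,
                                  structure=structure)
        labels[lab > 0] = lab[lab > 0] + offset
        for sl_idx, sl in enumerate(ndimage.find_objects(lab), start=1):
            regions.append({
                "region_id": offset + sl_idx,
                "n_modes": int(value),
                "size": int(np.sum(lab == sl_idx)),
                "bbox": [int(sl[0].start), int(sl[0].stop),
                         int(sl[1].start), int(sl[1].stop)],
            })
        offset += nlab
    return RegionSummary(n_regions=offset, labels=labels, regions=regions)


def eigenvalue_mode_prediction(J) -> int:
    """Resonance count by the eigenvalue-pair approximation.

    One predicted resonance per complex-conjugate pair of eigenvalues of J
    with Im(lambda)^2 - Re(lambda)^2 > 0.  Prone to false positives
    relative to the exact Sturm count.
    """
    J = np.asarray(J, dtype=float)
    lam = np.linalg.eigvals(J)
    scale = max(1.0, float(np.max(np.abs(lam))))
    upper = lam[lam.imag > 1e-9 * scale]  # one representative per pair
    return int(np.sum(upper.imag**2 - upper.real**2 > 0))


def compare_methods(family, grid: ParameterGrid) -> tuple:
    """Per-cell Sturm vs eigenvalue mode counts on the alpha = beta slice.

    Returns (DataFrame with columns alpha, beta, r, sturm_modes,
    eigen_modes, agree; summary dict).  The expected asymmetry is that the
    eigenvalue criterion fires at least wherever Sturm finds a mode and
    additionally on false-positive cells; any cell violating the inclusion
    is counted in the summary.
    """
    n = family.n if isinstance(family, NetworkSpec) else int(family)
    pd_diag = scan_phase_diagram(n, grid)
    eigen = np.zeros(grid.shape, dtype=int)
    for i, r in enumerate(grid.r):
        for j, a in enumerate(grid.alpha):
            spec = NetworkSpec(n=n, r=float(r), alpha=float(a), beta=float(a))
            eigen[i, j] = eigenvalue_mode_prediction(jacobian(spec))
    A, R = np.meshgrid(grid.alpha, grid.r)
    df = pd.DataFrame({
        "alpha": A.ravel(), "beta": A.ravel(), "r": R.ravel(),
        "sturm_modes": pd_diag.counts.ravel(),
        "eigen_modes": eigen.ravel(),
    })
    df["agree"] = df.sturm_modes == df.eigen_modes
    summary = {
        "n_cells": int(len(df)),
        "n_agree": int(df.agree.sum()),
        "eigen_false_positive_cells": int(
            ((df.eigen_modes > df.sturm_modes)).sum()),
        "sturm_exceeds_eigen_cells": int(
            ((df.sturm_modes > df.eigen_modes)).sum()),
        "inclusion_violations": int(
            ((df.sturm_modes >= 1) & (df.eigen_modes == 0)).sum()),
    }
    return df, summary
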