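"""Langevin simulation and power spectra for validating mode predictions.

Fluctuations x about a stable steady state follow the linear (chemical)
Langevin equation  dx/dt = J x + eta  with white Gaussian noise
<eta_i(t) eta_j(t')> = B_ij delta(t - t').  The per-species spectrum is

    P_k(omega) = Q_k(omega^2) / R(omega^2),
    R(omega^2) = |det(-i omega I - J)|^2 = det(J^2 + omega^2 I),

so every species shares the denominator R and, generically, the spectral
peaks sit at the minima of R: the resonant modes.  Peak *locations* are
therefore independent of B; only the peak shapes and relative intensities
are not.  The default noise model B = (1/Omega) I reflects demographic
noise shrinking with system size Omega without requiring the
master-equation expansion that fixes the exact covariances.

Simulation is Euler-Maruyama; spectra are averaged periodograms of the
post-transient segment, normalized to unit area for comparison with the
analytic curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "NoiseModel",
    "SimConfig",
    "TrajectoryEnsemble",
    "SpectrumEstimate",
    "euler_maruyama",
    "averaged_spectrum",
    "analytic_spectrum",
    "detect_peaks",
]


@dataclass(frozen=True)
class NoiseModel:
    """Noise covariance B (symmetric positive semidefinite)."""

    B: np.ndarray
    provenance: str = "user_supplied"

    def __post_init__(self):
        B = np.asarray(self.B, dtype=float)
        if B.ndim != 2 or B.shape[0] != B.shape[1]:
            raise ValueError("noise covariance must be a square matrix")
        if not np.allclose(B, B.T, atol=1e-12 * max(1.0, np.abs(B).max())):
            raise ValueError("noise covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(B)) < -1e-12 * max(1.0, np.abs(B).max()):
            raise ValueError("noise covariance must be positive semidefinite")
        object.__setattr__(self, "B", B)

    @classmethod
    def identity_scaled(cls, n: int, omega_system: float) -> "NoiseModel":
        """Default demographic-noise model B = (1/Omega) I."""
        return cls(np.eye(n) / omega_system, provenance="identity_scaled")

    def factor(self) -> np.ndarray:
        """L with L L^T = B (eigenvalue square root, PSD-safe)."""
        w, V = np.linalg.eigh(self.B)
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


@dataclass(frozen=True)
class SimConfig:
    """Euler-Maruyama run configuration.

    ``sample_every`` thins the recorded trajectory (the integrator still
    steps at ``dt``); ``transient_fraction`` of each recorded trajectory is
    discarded before spectral estimation.
    """

    dt: float = 0.01
    t_end: float = 200.0
    omega_system: float = 5000.0
    n_reps: int = 200
    seed: int = 0
    transient_fraction: float = 0.1
    sample_every: int = 1

    def __post_init__(self):
        if self.dt <= 0 or self.t_end <= 10 * self.dt:
            raise ValueError("need dt > 0 and t_end >> dt")
        if self.n_reps < 1:
            raise ValueError("need n_reps >= 1")
        if not 0 <= self.transient_fraction < 1:
            raise ValueError("transient_fraction must be in [0, 1)")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")


@dataclass(frozen=True)
class TrajectoryEnsemble:
    times: np.ndarray          # (n_samples,)
    values: np.ndarray         # (n_reps, n_samples, n_species)
    config: SimConfig


@dataclass(frozen=True)
class SpectrumEstimate:
    omega: np.ndarray          # angular frequency grid, omega > 0
    power: np.ndarray          # (n_omega, n_species)
    n_reps: int = 1
    normalized: bool = True

    def species_mean(self) -> np.ndarray:
        return self.power.mean(axis=1)


def _check_em_stability(J: np.ndarray, dt: float) -> None:
    lam = np.linalg.eigvals(J)
    growth = np.max(np.abs(1.0 + dt * lam))
    if growth >= 1.0:
        warnings.warn(
            f"Euler-Maruyama amplification factor max|1 + dt*lambda| = "
            f"{growth:.6f} >= 1 at dt={dt}: the integration is numerically "
            "unstable; reduce dt below 2|Re(lambda)|/Im(lambda)^2",
            stacklevel=3,
        )


def euler_maruyama(J, noise: NoiseModel, config: SimConfig,
                   x0=None) -> TrajectoryEnsemble:
    """Integrate dx = J x dt + L sqrt(dt) xi, L L^T = B, xi ~ N(0, I).

    All repetitions run vectorized from one seeded generator; identical
    seeds give identical ensembles.  A warning is emitted when J is not
    stable or when dt violates the explicit-scheme stability bound.
    """
    J = np.asarray(J, dtype=float)
    n = J.shape[0]
    if np.max(np.linalg.eigvals(J).real) >= 0:
        warnings.warn("Jacobian is not stable; fluctuations will not be "
                      "stationary", stacklevel=2)
    _check_em_stability(J, config.dt)
    L = noise.factor()
    if L.shape[0] != n:
        raise ValueError("noise covariance dimension does not match Jacobian")
    rng = np.random.default_rng(config.seed)
    n_steps = int(round(config.t_end / config.dt))
    stride = config.sample_every
    n_samples = n_steps // stride + 1
    x = np.zeros((config.n_reps, n)) if x0 is None else np.tile(
        np.asarray(x0, dtype=float), (config.n_reps, 1))
    out = np.empty((config.n_reps, n_samples, n))
    out[:, 0, :] = x
    sqdt = np.sqrt(config.dt)
    JT = J.T
    LT = L.T
    k = 1
    for step in range(1, n_steps + 1):
        xi = rng.standard_normal((config.n_reps, n))
        x = x + config.dt * (x @ JT) + sqdt * (xi @ LT)
        if step % stride == 0:
            out[:, k, :] = x
            k += 1
    times = np.arange(n_samples) * (config.dt * stride)
    return TrajectoryEnsemble(times=times, values=out[:, :k, :], config=config)


def averaged_spectrum(traj: TrajectoryEnsemble,
                      config: SimConfig | None = None,
                      normalize: bool = True) -> SpectrumEstimate:
    """Per-species periodogram of the post-transient segment, averaged over
    repetitions and normalized to unit area over the angular-frequency grid."""
    config = config or traj.config
    values = traj.values
    n_samples = values.shape[1]
    if n_samples < 2:
        raise ValueError("need at least 2 samples for a spectrum")
    start = int(np.floor(config.transient_fraction * n_samples))
    seg = values[:, start:, :]
    dt_s = float(traj.times[1] - traj.times[0])
    freqs, pxx = sp_signal.periodogram(seg, fs=1.0 / dt_s, axis=1,
                                       detrend="constant")
    power = pxx.mean(axis=0)           # (n_freq, n_species)
    omega = 2.0 * np.pi * freqs
    keep = omega > 0
    omega, power = omega[keep], power[keep]
    if normalize:
        area = np.trapezoid(power, omega, axis=0)
        power = power / area
    return SpectrumEstimate(omega=omega, power=power,
                            n_reps=values.shape[0], normalized=normalize)


def analytic_spectrum(J, B, omegas, normalize: bool = True) -> SpectrumEstimate:
    """Exact linear-Langevin spectrum P_k(w) = [(iwI - J)^-1 B (iwI - J)^-H]_kk.

    Computed by complex linear solves per frequency (no symbolic
    adjugates); the common denominator is R(omega^2) = det(J^2 + omega^2 I).
    """
    J = np.asarray(J, dtype=float)
    B = np.asarray(B, dtype=float)
    n = J.shape[0]
    omegas = np.asarray(omegas, dtype=float)
    if np.max(np.linalg.eigvals(J).real) >= 0:
        raise ValueError("analytic spectrum requires a stable Jacobian")
    I = np.eye(n)
    power = np.empty((len(omegas), n))
    for k, w in enumerate(omegas):
        Phi = np.linalg.solve(1j * w * I - J, I)
        S = Phi @ B @ Phi.conj().T
        power[k] = S.diagonal().real
    if normalize:
        area = np.trapezoid(power, omegas, axis=0)
        power = power / area
    return SpectrumEstimate(omega=omegas, power=power, n_reps=0,
                            normalized=normalize)


def detect_peaks(spectrum: SpectrumEstimate, species: int | None = None,
                 prominence_frac: float = 0.05, smooth_window: int = 5,
                 height_factor: float = 2.0) -> np.ndarray:
    """Interior spectral peaks (omega > 0), as angular frequencies.

    The spectrum (species mean unless ``species`` is given) is smoothed by a
    ``smooth_window``-bin moving average (reflect-padded); peaks are local
    maxima with prominence at least ``prominence_frac`` of the smoothed
    spectrum's range and height at least ``height_factor`` times its median
    (the latter rejects wiggles of a flat noise spectrum).  Each detection
    is refined to the raw-spectrum argmax within the smoothing window.
    """
    if spectrum.power.size == 0:
        raise ValueError("empty spectrum")
    p = (spectrum.species_mean() if species is None
         else spectrum.power[:, species])
    w = max(1, int(smooth_window))
    if w > 1 and len(p) > 2 * w:
        pad = np.pad(p, w, mode="reflect")
        q = np.convolve(pad, np.ones(w) / w, mode="same")[w:-w]
    else:
        q = p
    rng = float(q.max() - q.min())
    med = float(np.median(q))
    idx, _ = sp_signal.find_peaks(q, prominence=prominence_frac * rng,
                                  height=height_factor * med)
    half = w // 2 + 1
    refined = []
    for i in idx:
        lo, hi = max(0, i - half), min(len(p), i + half + 1)
        refined.append(lo + int(np.argmax(p[lo:hi])))
    return spectrum.omega[sorted(set(refined))]
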