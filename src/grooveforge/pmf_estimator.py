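"""Potential of mean force from constant-velocity pulling work traces.

A harmonic guide ("dummy atom" plus virtual spring, stiffness k) is dragged
at constant velocity v along the reaction coordinate xi, its center
following lambda(t) = lambda0 + v*t.  The external work accumulated by one
trajectory is

    W(t) = v * integral_0^t k * (lambda(t') - xi(t')) dt'

evaluated here by trapezoidal quadrature on the recorded sample times.
Jarzynski's equality turns an ensemble of such non-equilibrium work values
into an equilibrium free-energy difference,

    exp(-beta * dA(lambda)) = < exp(-beta * W(lambda)) >,

which holds regardless of pulling speed; the average runs over trajectories
whose starting states are drawn from equilibrium.  When the spring is stiff
enough that xi tracks lambda closely, the free-energy profile in lambda is,
to leading order, the PMF itself: Phi(xi = lambda) = dA(lambda) - dA(lambda0)
(the stiff-spring approximation; a second-order correction in 1/k is
available behind a flag).

Units: energies kcal/mol, distances Angstrom, time ns, k kcal/(mol*A^2).
Scores supplied in kJ/mol can be converted with :func:`kj_to_kcal`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from .errors import InputError, TraceFormatError

__all__ = [
    "KB_KCAL_PER_MOL_K",
    "kj_to_kcal",
    "ThermoParams",
    "PullingProtocol",
    "PullingTrajectory",
    "compute_work",
    "WorkEnsemble",
    "jarzynski_delta_A",
    "cumulant2_delta_A",
    "delta_A_profile",
    "PMFProfile",
    "stiff_spring_pmf",
    "bootstrap_uncertainty",
    "average_force_profile",
    "estimate_pmf",
]

#: Boltzmann constant in kcal/(mol*K).
KB_KCAL_PER_MOL_K = 0.0019872041

_KJ_TO_KCAL = 0.239006


def kj_to_kcal(value):
    """Convert kJ/mol quantities to kcal/mol."""
    return np.asarray(value, dtype=float) * _KJ_TO_KCAL


@dataclass(frozen=True)
class ThermoParams:
    """Temperature and derived inverse temperature beta = 1/(kB*T)."""

    temperature: float = 310.0
    kB: float = KB_KCAL_PER_MOL_K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise InputError("temperature must be positive")

    @property
    def beta(self) -> float:
        return 1.0 / (self.kB * self.temperature)


@dataclass(frozen=True)
class PullingProtocol:
    """Constant-velocity guide schedule lambda(t) = lambda0 + v*t."""

    k: float  # spring constant, kcal/(mol*A^2)
    v: float  # pulling velocity, A/ns
    lambda0: float = 0.0
    temperature: float = 310.0

    def __post_init__(self) -> None:
        if self.k <= 0 or self.v <= 0:
            raise InputError("spring constant and velocity must be positive")

    def lambda_at(self, t) -> np.ndarray:
        return self.lambda0 + self.v * np.asarray(t, dtype=float)


@dataclass
class PullingTrajectory:
    """One pulling run: time, guide position, reaction coordinate, force.

    The force column is optional; when absent it is reconstructed as
    k*(lambda - xi).  Construction validates monotone time, the guide
    schedule, and (when present) force consistency.
    """

    time: np.ndarray  # ns
    lam: np.ndarray  # guide position, A
    xi: np.ndarray  # reaction coordinate, A
    protocol: PullingProtocol
    force: Optional[np.ndarray] = None  # kcal/(mol*A)
    source: Optional[str] = None
    schedule_atol: float = 1e-4

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.xi = np.asarray(self.xi, dtype=float)
        n = self.time.size
        if n < 2:
            raise TraceFormatError("trajectory needs at least two samples")
        if self.lam.size != n or self.xi.size != n:
            raise TraceFormatError("column lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise TraceFormatError("time must be strictly increasing")
        expected = self.protocol.lambda_at(self.time)
        if np.max(np.abs(self.lam - expected)) > self.schedule_atol:
            raise TraceFormatError(
                "guide positions deviate from the constant-velocity schedule"
            )
        if self.force is not None:
            self.force = np.asarray(self.force, dtype=float)
            if self.force.size != n:
                raise TraceFormatError("force column length differs")
            spring = self.protocol.k * (self.lam - self.xi)
            scale = max(1.0, float(np.max(np.abs(spring))))
            if np.max(np.abs(self.force - spring)) > 1e-3 * scale:
                raise TraceFormatError(
                    "force column inconsistent with k*(lambda - xi)"
                )

    def effective_force(self) -> np.ndarray:
        if self.force is not None:
            return self.force
        return self.protocol.k * (self.lam - self.xi)


def compute_work(trajectory: PullingTrajectory) -> np.ndarray:
    """Accumulated external work W(t), trapezoidal in t; W(0) = 0."""
    f = trajectory.effective_force()
    dt = np.diff(trajectory.time)
    increments = 0.5 * (f[1:] + f[:-1]) * dt * trajectory.protocol.v
    return np.concatenate([[0.0], np.cumsum(increments)])


@dataclass
class WorkEnsemble:
    """Per-trajectory work resampled onto a common guide-position grid."""

    lam_grid: np.ndarray  # (G,)
    works: np.ndarray  # (M, G); works[:, 0] == 0 when grid starts at lambda0
    protocol: PullingProtocol

    @property
    def n_trajectories(self) -> int:
        return self.works.shape[0]

    @classmethod
    def from_trajectories(
        cls,
        trajectories: Sequence[PullingTrajectory],
        lam_grid: np.ndarray,
    ) -> "WorkEnsemble":
        trajectories = list(trajectories)
        if not trajectories:
            raise InputError("empty trajectory ensemble")
        lam_grid = np.asarray(lam_grid, dtype=float)
        if lam_grid.size < 2 or np.any(np.diff(lam_grid) <= 0):
            raise InputError("lambda grid must be increasing with >= 2 points")
        protocol = trajectories[0].protocol
        rows = []
        for traj in trajectories:
            lam = traj.lam
            if lam_grid[0] < lam[0] - 1e-9 or lam_grid[-1] > lam[-1] + 1e-9:
                raise InputError(
                    "lambda grid extends beyond the recorded pulling range"
                )
            w = compute_work(traj)
            on_grid = np.interp(lam_grid, lam, w)
            rows.append(on_grid - on_grid[0])  # anchor at grid start
        return cls(lam_grid=lam_grid, works=np.vstack(rows), protocol=protocol)


def _as_work_array(works_at_lambda: Iterable[float]) -> np.ndarray:
    w = np.asarray(list(works_at_lambda), dtype=float)
    if w.size == 0:
        raise InputError("empty work ensemble")
    return w


def jarzynski_delta_A(
    works_at_lambda: Iterable[float], thermo: ThermoParams = ThermoParams()
) -> float:
    """dA = -(1/beta) * log < exp(-beta W) >, via a shifted log-sum-exp."""
    w = _as_work_array(works_at_lambda)
    beta = thermo.beta
    return float(-(logsumexp(-beta * w) - np.log(w.size)) / beta)


def cumulant2_delta_A(
    works_at_lambda: Iterable[float], thermo: ThermoParams = ThermoParams()
) -> float:
    """Second-order cumulant estimator: mean(W) - beta*var(W)/2 (unbiased var).

    Exact for Gaussian work distributions and far less sample-hungry than
    the exponential average; a companion, not a replacement.
    """
    w = _as_work_array(works_at_lambda)
    if w.size < 2:
        raise InputError("cumulant estimator needs at least two work values")
    return float(np.mean(w) - thermo.beta * np.var(w, ddof=1) / 2.0)


def _profile(works: np.ndarray, thermo: ThermoParams, estimator: str) -> np.ndarray:
    beta = thermo.beta
    if estimator == "jarzynski":
        return -(logsumexp(-beta * works, axis=0) - np.log(works.shape[0])) / beta
    if estimator == "cumulant2":
        if works.shape[0] < 2:
            raise InputError("cumulant estimator needs at least two trajectories")
        return np.mean(works, axis=0) - beta * np.var(works, axis=0, ddof=1) / 2.0
    raise InputError(f"unknown estimator {estimator!r}")


def delta_A_profile(
    ensemble: WorkEnsemble,
    thermo: ThermoParams = ThermoParams(),
    estimator: str = "jarzynski",
) -> np.ndarray:
    """Free-energy profile dA(lambda) on the ensemble's grid."""
    return _profile(ensemble.works, thermo, estimator)


@dataclass
class PMFProfile:
    """Free-energy estimate Phi(xi), anchored to zero at the grid start."""

    xi: np.ndarray
    phi: np.ndarray  # kcal/mol
    lam: np.ndarray
    delta_A: np.ndarray
    spring_constant: float
    estimator: str
    ci_lo: Optional[np.ndarray] = None
    ci_hi: Optional[np.ndarray] = None

    @property
    def uncertainty(self) -> Optional[np.ndarray]:
        if self.ci_lo is None or self.ci_hi is None:
            return None
        return self.ci_hi - self.ci_lo


def stiff_spring_pmf(
    lam_grid: np.ndarray,
    delta_A: np.ndarray,
    protocol: PullingProtocol,
    second_order: bool = False,
    estimator: str = "jarzynski",
) -> PMFProfile:
    """Map dA(lambda) to Phi(xi) under the stiff-spring approximation.

    Leading order (default): Phi(xi = lambda) = dA(lambda) - dA(lambda0).
    With ``second_order`` the 1/k correction is applied:
    xi = lambda - dA'/k, Phi = dA - (dA')^2 / (2k), then re-anchored.
    The spring constant is recorded so users can judge stiffness validity.
    """
    lam_grid = np.asarray(lam_grid, dtype=float)
    delta_A = np.asarray(delta_A, dtype=float)
    if np.any(np.diff(lam_grid) <= 0):
        raise InputError("lambda grid must be strictly increasing")
    if second_order:
        slope = np.gradient(delta_A, lam_grid)
        xi = lam_grid - slope / protocol.k
        phi = delta_A - slope**2 / (2.0 * protocol.k)
    else:
        xi = lam_grid.copy()
        phi = delta_A.copy()
    phi = phi - phi[0]
    return PMFProfile(
        xi=xi,
        phi=phi,
        lam=lam_grid,
        delta_A=delta_A - delta_A[0],
        spring_constant=protocol.k,
        estimator=estimator,
    )


def bootstrap_uncertainty(
    ensemble: WorkEnsemble,
    thermo: ThermoParams = ThermoParams(),
    replicates: int = 200,
    seed: int = 0,
    estimator: str = "jarzynski",
    ci: float = 0.95,
) -> Tuple[np.ndarray, np.ndarray]:
    """Percentile interval of dA(lambda) from trajectory-level resampling."""
    if ensemble.n_trajectories < 2:
        raise InputError("bootstrap needs at least two trajectories")
    if replicates < 1:
        raise InputError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    m = ensemble.n_trajectories
    profiles = np.empty((replicates, ensemble.lam_grid.size))
    for r in range(replicates):
        idx = rng.integers(0, m, size=m)
        profiles[r] = _profile(ensemble.works[idx], thermo, estimator)
    tail = 100.0 * (1.0 - ci) / 2.0
    lo, hi = np.percentile(profiles, [tail, 100.0 - tail], axis=0)
    return lo, hi


def average_force_profile(
    trajectories: Sequence[PullingTrajectory], lam_grid: np.ndarray
) -> np.ndarray:
    """Pointwise mean of the spring force k*(lambda - xi) on a common grid."""
    trajectories = list(trajectories)
    if not trajectories:
        raise InputError("empty trajectory ensemble")
    lam_grid = np.asarray(lam_grid, dtype=float)
    rows = [
        np.interp(lam_grid, traj.lam, traj.effective_force())
        for traj in trajectories
    ]
    return np.mean(np.vstack(rows), axis=0)


def estimate_pmf(
    trajectories: Sequence[PullingTrajectory],
    lam_grid: np.ndarray,
    thermo: ThermoParams = ThermoParams(),
    estimator: str = "jarzynski",
    bootstrap_replicates: int = 0,
    seed: int = 0,
    second_order: bool = False,
) -> PMFProfile:
    """Traces -> work ensemble -> dA(lambda) -> stiff-spring PMF, one call."""
    ensemble = WorkEnsemble.from_trajectories(trajectories, lam_grid)
    delta_A = delta_A_profile(ensemble, thermo, estimator)
    profile = stiff_spring_pmf(
        ensemble.lam_grid,
        delta_A,
        ensemble.protocol,
        second_order=second_order,
        estimator=estimator,
    )
    if bootstrap_replicates > 0:
        lo, hi = bootstrap_uncertainty(
            ensemble, thermo, bootstrap_replicates, seed, estimator
        )
        profile.ci_lo = lo - delta_A[0]
        profile.ci_hi = hi - delta_A[0]
    return profile
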