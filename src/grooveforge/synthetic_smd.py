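"""Ground-truth pulling ensembles from an overdamped Langevin particle.

A single coordinate xi moves in a known 1-D potential U while a harmonic
guide of stiffness k is dragged past it at constant velocity:

    dxi = [ -U'(xi) - k*(xi - lambda(t)) ] / gamma * dt
          + sqrt(2*dt / (beta*gamma)) * eta,     eta ~ N(0, 1)

(Euler-Maruyama).  Because U is known exactly, the PMF estimator can be
validated end-to-end: simulate, estimate, compare against U - U(start).
Overdamped dynamics suffice for estimator validation and avoid mass and
thermostat choices entirely.

The default validation scenario uses a harmonic potential of stiffness
1 kcal/(mol*A^2) centered mid-range, guide stiffness k = 50 kcal/(mol*A^2),
v = 1 A/ns, friction gamma = 1 kcal*ns/(mol*A^2), T = 310 K, and 50
trajectories pulled over 1 A.  The pulled distance is set by a dissipation
budget: the mean dissipated work of this overdamped model is about
gamma*v*L, and the exponential average over ~50 trajectories converges only
while the work spread obeys beta*sigma_W <~ 2; at L = 1 A the scenario sits
inside that envelope, so the quasi-static and stiff-spring assumptions hold
measurably rather than nominally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, InputError
from .pmf_estimator import PullingProtocol, PullingTrajectory, ThermoParams

__all__ = [
    "PotentialSpec",
    "LangevinParams",
    "GroundTruth",
    "simulate_pulling",
    "ground_truth_pmf",
    "ValidationScenario",
    "default_validation_scenario",
]


@dataclass(frozen=True)
class PotentialSpec:
    """A 1-D potential and its derivative, evaluable on the pulling range.

    Forms: ``flat``; ``harmonic`` (stiffness a, center c):
    U = a/2 (x-c)^2; ``double-well`` (barrier h, center c, half-spacing w):
    quartic with minima at c +/- w and barrier h at c; ``piecewise-linear``
    (knots xs, values us).
    """

    form: str
    params: Tuple[float, ...] = ()
    knots: Optional[Tuple[Tuple[float, ...], Tuple[float, ...]]] = None

    @classmethod
    def flat(cls) -> "PotentialSpec":
        return cls("flat")

    @classmethod
    def harmonic(cls, stiffness: float, center: float) -> "PotentialSpec":
        return cls("harmonic", (stiffness, center))

    @classmethod
    def double_well(
        cls, barrier: float, center: float, half_spacing: float
    ) -> "PotentialSpec":
        return cls("double-well", (barrier, center, half_spacing))

    @classmethod
    def piecewise_linear(
        cls, xs: Sequence[float], us: Sequence[float]
    ) -> "PotentialSpec":
        xs = tuple(float(x) for x in xs)
        us = tuple(float(u) for u in us)
        if len(xs) != len(us) or len(xs) < 2:
            raise InputError("piecewise-linear needs matching knots (>= 2)")
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise InputError("piecewise-linear knots must be increasing")
        return cls("piecewise-linear", knots=(xs, us))

    def energy(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form == "flat":
            return np.zeros_like(x)
        if self.form == "harmonic":
            a, c = self.params
            return 0.5 * a * (x - c) ** 2
        if self.form == "double-well":
            h, c, w = self.params
            return h * ((x - c) ** 2 - w**2) ** 2 / w**4
        if self.form == "piecewise-linear":
            xs, us = self.knots
            return np.interp(x, xs, us)
        raise ConfigurationError(f"unknown potential form {self.form!r}")

    def gradient(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form == "flat":
            return np.zeros_like(x)
        if self.form == "harmonic":
            a, c = self.params
            return a * (x - c)
        if self.form == "double-well":
            h, c, w = self.params
            return 4.0 * h * (x - c) * ((x - c) ** 2 - w**2) / w**4
        if self.form == "piecewise-linear":
            xs, us = self.knots
            slopes = np.diff(us) / np.diff(xs)
            idx = np.clip(np.searchsorted(xs, x, side="right") - 1, 0, len(slopes) - 1)
            return slopes[idx]
        raise ConfigurationError(f"unknown potential form {self.form!r}")

    def max_curvature(self, lo: float, hi: float) -> float:
        """Upper bound on |U''| over [lo, hi], for the time-step guard."""
        if self.form == "flat" or self.form == "piecewise-linear":
            return 0.0
        if self.form == "harmonic":
            return abs(self.params[0])
        x = np.linspace(lo, hi, 1001)
        grad = self.gradient(x)
        return float(np.max(np.abs(np.gradient(grad, x))))


@dataclass(frozen=True)
class LangevinParams:
    """Integrator settings for the overdamped pulling simulation."""

    gamma: float = 1.0  # friction, kcal*ns/(mol*A^2)
    dt: float = 5e-4  # ns
    temperature: float = 310.0  # K
    seed: int = 0
    n_trajectories: int = 50
    init: str = "equilibrium-in-guide"  # or "fixed"
    stride: int = 10  # record every `stride` steps

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.dt <= 0:
            raise ConfigurationError("gamma and dt must be positive")
        if self.n_trajectories < 1:
            raise ConfigurationError("need at least one trajectory")
        if self.init not in ("equilibrium-in-guide", "fixed"):
            raise ConfigurationError(f"unknown init mode {self.init!r}")
        if self.stride < 1:
            raise ConfigurationError("stride must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic PMF on the pulled range, anchored at the start."""

    xi: np.ndarray
    phi: np.ndarray


def _trajectory_seeds(seed: int, n: int) -> List[np.random.SeedSequence]:
    # fixed splitting rule: master SeedSequence spawns one child per run
    return np.random.SeedSequence(seed).spawn(n)


def simulate_pulling(
    potential: PotentialSpec,
    protocol: PullingProtocol,
    params: LangevinParams,
    pull_distance: float,
) -> List[PullingTrajectory]:
    """Euler-Maruyama ensemble of guided pulls over ``pull_distance``.

    Stability guard: dt * (k + max|U''|) / gamma must stay below 0.1, else a
    configuration error advises a smaller time step.  Trajectories are
    seeded independently via a spawned SeedSequence per run, so the ensemble
    is bit-reproducible for a given master seed.
    """
    if pull_distance <= 0:
        raise InputError("pull_distance must be positive")
    lo = protocol.lambda0 - 1.0
    hi = protocol.lambda0 + pull_distance + 1.0
    curvature = potential.max_curvature(lo, hi)
    stiffness_ratio = params.dt * (protocol.k + curvature) / params.gamma
    if stiffness_ratio >= 0.1:
        raise ConfigurationError(
            f"unstable integration: dt*(k + max U'')/gamma = "
            f"{stiffness_ratio:.3f} >= 0.1; reduce dt below "
            f"{0.1 * params.gamma / (protocol.k + curvature):.2e} ns"
        )
    beta = ThermoParams(params.temperature).beta
    n_steps = int(round(pull_distance / (protocol.v * params.dt)))
    if n_steps < params.stride:
        raise ConfigurationError("pull too short for the recording stride")
    m = params.n_trajectories
    seeds = _trajectory_seeds(params.seed, m)
    rngs = [np.random.default_rng(s) for s in seeds]

    if params.init == "equilibrium-in-guide":
        width = np.sqrt(1.0 / (beta * protocol.k))
        xi = np.array(
            [protocol.lambda0 + r.normal(0.0, width) for r in rngs]
        )
    else:
        xi = np.full(m, protocol.lambda0, dtype=float)

    # pre-draw each run's noise stream from its own generator
    noise = np.vstack([r.normal(size=n_steps) for r in rngs])
    noise_scale = np.sqrt(2.0 * params.dt / (beta * params.gamma))

    n_records = n_steps // params.stride + 1
    rec_t = np.empty(n_records)
    rec_xi = np.empty((n_records, m))
    rec_t[0] = 0.0
    rec_xi[0] = xi
    r = 1
    for i in range(n_steps):
        t = i * params.dt
        lam = protocol.lambda0 + protocol.v * t
        drift = (-potential.gradient(xi) - protocol.k * (xi - lam)) / params.gamma
        xi = xi + drift * params.dt + noise_scale * noise[:, i]
        if (i + 1) % params.stride == 0:
            rec_t[r] = (i + 1) * params.dt
            rec_xi[r] = xi
            r += 1
    rec_t = rec_t[:r]
    rec_xi = rec_xi[:r]
    rec_lam = protocol.lambda_at(rec_t)
    return [
        PullingTrajectory(
            time=rec_t.copy(),
            lam=rec_lam.copy(),
            xi=rec_xi[:, j].copy(),
            protocol=protocol,
            source=f"synthetic:{params.seed}/{j}",
        )
        for j in range(m)
    ]


def ground_truth_pmf(
    potential: PotentialSpec, grid: np.ndarray
) -> GroundTruth:
    """U(xi) - U(grid start) on ``grid``."""
    grid = np.asarray(grid, dtype=float)
    u = potential.energy(grid)
    return GroundTruth(xi=grid, phi=u - u[0])


@dataclass(frozen=True)
class ValidationScenario:
    """Everything needed for an end-to-end estimator check."""

    potential: PotentialSpec
    protocol: PullingProtocol
    params: LangevinParams
    pull_distance: float
    lam_grid: np.ndarray = field(repr=False)

    @property
    def thermo(self) -> ThermoParams:
        return ThermoParams(self.params.temperature)

    def ground_truth(self) -> GroundTruth:
        return ground_truth_pmf(self.potential, self.lam_grid)

    def simulate(self) -> List[PullingTrajectory]:
        return simulate_pulling(
            self.potential, self.protocol, self.params, self.pull_distance
        )


def default_validation_scenario(
    seed: int = 0,
    v: float = 1.0,
    n_trajectories: int = 50,
) -> ValidationScenario:
    """Harmonic potential, stiff guide, short dissipation-budgeted pull.

    See the module docstring for why the pulled distance is 1 A.
    """
    pull_distance = 1.0
    protocol = PullingProtocol(k=50.0, v=v, lambda0=0.0, temperature=310.0)
    potential = PotentialSpec.harmonic(stiffness=1.0, center=pull_distance / 2)
    params = LangevinParams(
        gamma=1.0,
        dt=5e-4,
        temperature=310.0,
        seed=seed,
        n_trajectories=n_trajectories,
        stride=10,
    )
    lam_grid = np.linspace(0.0, pull_distance, 41)
    return ValidationScenario(
        potential=potential,
        protocol=protocol,
        params=params,
        pull_distance=pull_distance,
        lam_grid=lam_grid,
    )
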