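"""Classical collision trajectories of a drift-gas probe in the ion's
potential, and the scattering angle chi they produce.

The ion is held rigid; the collision is the equivalent one-body problem of
a probe with the ion-gas reduced mass mu moving in the interaction
potential.  For a multi-site gas the molecular axis is frozen during each
trajectory (orientation enters as an extra averaged variable).  The probe
starts far enough out that the potential is a negligible fraction of its
kinetic energy, and the trajectory ends once it is outside that radius
again and receding; chi is the angle between the asymptotic incoming and
outgoing velocities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from . import _kernels
from .constants import COULOMB_MEV_A, MEV_TO_DA_A2_PS2
from .potential import LJParameters, DriftGasModel, R_MIN_GUARD
from .structures import MolecularIon

__all__ = [
    "CollisionParams",
    "IntegratorSettings",
    "TrajectoryResult",
    "TrappedOrbitError",
    "EnergyConservationError",
    "scatter",
    "deflection_integral_oracle",
]


class TrappedOrbitError(RuntimeError):
    """The probe exceeded the step cap without leaving the interaction region."""


class EnergyConservationError(ArithmeticError):
    """Relative energy drift exceeded tolerance after all step refinements."""


@dataclass(frozen=True)
class CollisionParams:
    """Impact parameter b (A), relative speed g (A/ps) and the Euler angles
    (z-y-z convention) orienting the ion for this collision."""

    b: float
    g: float
    theta: float = 0.0
    phi: float = 0.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError("impact parameter b must be >= 0")
        if self.g <= 0:
            raise ValueError("relative speed g must be > 0")

    @property
    def rotation(self) -> np.ndarray:
        return Rotation.from_euler(
            "zyz", [self.theta, self.phi, self.gamma]
        ).as_matrix()


@dataclass(frozen=True)
class IntegratorSettings:
    """Adaptive RK45 controls.

    ``energy_tolerance`` is the accepted relative drift of total energy over
    a trajectory; on violation the run is retried with ``rtol`` tightened by
    ``retry_factor`` up to ``max_retries`` times.  ``start_energy_fraction``
    sets the start/stop radius: |V| there must be below this fraction of the
    probe's kinetic energy.
    """

    rtol: float = 1e-7
    energy_tolerance: float = 1e-3
    max_steps: int = 200_000
    start_energy_fraction: float = 1e-3
    rmin_guard: float = R_MIN_GUARD
    max_retries: int = 3
    retry_factor: float = 0.01


@dataclass(frozen=True)
class TrajectoryResult:
    """Scattering angle (rad, in [0, pi]), relative energy drift and the
    integrator step count of one accepted trajectory."""

    chi: float
    energy_drift: float
    steps: int


class _System:
    """Packed arrays for one (ion, gas, LJ table) combination."""

    def __init__(
        self,
        ion: MolecularIon,
        gas: DriftGasModel,
        lj: LJParameters | None = None,
    ) -> None:
        lj = lj or LJParameters.default()
        self.ion = ion
        self.gas = gas
        self.lj = lj
        com = np.average(ion.positions, axis=0, weights=ion.masses)
        self.apos = ion.positions - com
        self.aq = ion.partial_charges
        self.eps, self.sig = lj.for_ion(ion)
        self.site_off, self.site_lj, self.site_q = gas.site_arrays
        self.alpha = gas.polarizability
        self.mu = ion.mass * gas.mass / (ion.mass + gas.mass)
        self.extent = float(np.max(np.linalg.norm(self.apos, axis=1)))

    def potential(self, pos: np.ndarray, axis: np.ndarray, positions=None) -> float:
        apos = self.apos if positions is None else positions
        V, _, _, ok = _kernels.eval_potential_force(
            pos, axis, apos, self.aq, self.eps, self.sig,
            self.site_off, self.site_lj, self.site_q,
            self.alpha, COULOMB_MEV_A, R_MIN_GUARD,
        )
        return float(V)

    def start_radius(self, e_kin_mev: float, fraction: float) -> float:
        """Smallest probe distance where |V| is below fraction * kinetic energy,
        probed along the coordinate axes."""
        directions = np.vstack([np.eye(3), -np.eye(3)])
        axis = np.array([0.0, 0.0, 1.0])
        r = self.extent + 6.0
        target = fraction * e_kin_mev
        while r < 400.0:
            vmax = max(
                abs(self.potential(r * d, axis)) for d in directions
            )
            if vmax < target:
                return 1.1 * r
            r *= 1.15
        return r

    def run(
        self,
        positions: np.ndarray,
        axis: np.ndarray,
        b: float,
        g: float,
        r_start: float,
        integ: IntegratorSettings,
    ) -> TrajectoryResult:
        """One trajectory on pre-rotated ion coordinates."""
        x0 = np.sqrt(max(r_start * r_start - b * b, 25.0))
        y0 = np.array([-x0, b, 0.0, g, 0.0, 0.0])
        r_exit = 1.02 * np.hypot(x0, b)
        e_kin = 0.5 * self.mu * g * g / MEV_TO_DA_A2_PS2  # meV
        v_start = self.potential(y0[:3], axis, positions)
        rtol = integ.rtol
        for attempt in range(integ.max_retries + 1):
            y, status, steps = _kernels.propagate(
                y0, self.mu, axis, positions, self.aq, self.eps, self.sig,
                self.site_off, self.site_lj, self.site_q,
                self.alpha, COULOMB_MEV_A, integ.rmin_guard,
                rtol, r_exit * r_exit, integ.max_steps,
            )
            if status == _kernels.STATUS_TRAPPED:
                raise TrappedOrbitError(
                    f"no exit after {integ.max_steps} steps (b={b:.2f} A, "
                    f"g={g:.2f} A/ps)"
                )
            if status == _kernels.STATUS_GUARD:
                raise ArithmeticError(
                    "probe entered the near-singular core region"
                )
            v_end = self.potential(y[:3], axis, positions)
            e0 = e_kin + v_start
            e1 = (
                0.5 * self.mu * (y[3] ** 2 + y[4] ** 2 + y[5] ** 2)
                / MEV_TO_DA_A2_PS2
                + v_end
            )
            drift = abs(e1 - e0) / e_kin
            if drift <= integ.energy_tolerance:
                v_out = y[3:6]
                chi = float(
                    np.arccos(np.clip(v_out[0] / np.linalg.norm(v_out), -1, 1))
                )
                return TrajectoryResult(
                    chi=chi, energy_drift=float(drift), steps=int(steps)
                )
            rtol *= integ.retry_factor
        raise EnergyConservationError(
            f"energy drift {drift:.2e} above {integ.energy_tolerance:.0e} "
            f"after {integ.max_retries} refinements"
        )


def scatter(
    ion: MolecularIon,
    gas: DriftGasModel,
    params: CollisionParams,
    integ: IntegratorSettings | None = None,
    lj: LJParameters | None = None,
    gas_axis=None,
) -> TrajectoryResult:
    """Integrate one collision trajectory and return its scattering angle.

    The incoming probe travels along +x with perpendicular offset ``params.b``;
    the ion is rotated by the Euler angles of *params* about its center of
    mass.  ``gas_axis`` (unit vector) freezes the gas orientation for
    multi-site models; it defaults to +z.
    """
    integ = integ or IntegratorSettings()
    sys = _System(ion, gas, lj)
    rot = params.rotation
    positions = sys.apos @ rot.T
    axis = (
        np.array([0.0, 0.0, 1.0]) if gas_axis is None else np.asarray(gas_axis, float)
    )
    e_kin = 0.5 * sys.mu * params.g ** 2 / MEV_TO_DA_A2_PS2
    r_start = sys.start_radius(e_kin, integ.start_energy_fraction)
    return sys.run(positions, axis, params.b, params.g, r_start, integ)


# -- independent oracle ------------------------------------------------------


def deflection_integral_oracle(
    potential,
    b: float,
    g: float,
    mu: float,
    r_max: float = 200.0,
) -> float:
    """Classical deflection angle for a spherically symmetric potential.

    Evaluates ``chi = pi - 2 b * integral_{r0}^inf dr / (r^2 sqrt(F(r)))``
    with ``F(r) = 1 - (b/r)^2 - V(r)/E`` and the outermost turning point r0
    found by root bracketing; the square-root singularity is removed by the
    substitution ``r = r0 / (1 - t^2)``.  *potential* maps r (A) to V (meV);
    *mu* is the reduced mass (Da), *g* the relative speed (A/ps).

    This quadrature route is entirely independent of the trajectory
    integrator and serves as its test oracle.  The returned angle is signed
    (negative for net attraction) and may exceed -pi for orbiting-like
    collisions.
    """
    if g <= 0 or mu <= 0:
        raise ValueError("g and mu must be positive")
    e_mev = 0.5 * mu * g * g / MEV_TO_DA_A2_PS2
    if e_mev <= 0:
        raise ValueError("kinetic energy must be positive")

    def f_eff(r: float) -> float:
        return 1.0 - (b / r) ** 2 - potential(r) / e_mev

    # outermost turning point: scan inward for the first sign change
    grid = np.geomspace(r_max, 1e-2, 4000)
    vals = np.array([f_eff(r) for r in grid])
    if vals[0] <= 0:
        raise ValueError("no turning point found: F < 0 at r_max")
    idx = np.argmax(vals <= 0)
    if vals[idx] > 0:
        raise ValueError("no turning point found below r_max")
    r0 = brentq(f_eff, grid[idx], grid[idx - 1], xtol=1e-13, rtol=1e-14)

    if b == 0.0:
        return np.pi

    def integrand(t: float) -> float:
        u = 1.0 - t * t
        val = f_eff(r0 / u)
        if val <= 0.0:
            # round-off just outside the turning point
            return 0.0
        return 2.0 * t / np.sqrt(val)

    integral, _ = quad(integrand, 0.0, 1.0, limit=200, epsabs=1e-11, epsrel=1e-10)
    return float(np.pi - 2.0 * (b / r0) * integral)
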