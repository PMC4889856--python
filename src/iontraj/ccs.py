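"""Trajectory-method collision cross section.

The momentum-transfer cross section is the average of the transport
integrand 1 - cos(chi) over

* ion orientation, uniform on SO(3) (Euler angles with uniform theta, gamma
  and cos-uniform phi, i.e. the sin(phi) measure),
* relative speed g, with the Maxwell-Boltzmann transport weight
  proportional to g^5 exp(-mu g^2 / 2 kB T), handled by a deterministic
  generalized Gauss-Laguerre quadrature whose weights sum to exactly 1,
* impact parameter, uniform in b^2 up to a cutoff b_max (stratified, with
  optional jitter), so that

      Omega = pi b_max^2 * < 1 - cos chi >.

The normalization is anchored analytically: plugging in the hard-sphere
deflection law chi = 2 arccos(b/d) returns Omega = pi d^2 independent of
temperature and masses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.special import roots_genlaguerre

from .constants import KB_MEV, MEV_TO_DA_A2_PS2
from .potential import LJParameters, DriftGasModel
from .structures import MolecularIon
from .trajectory import (
    IntegratorSettings,
    TrappedOrbitError,
    _System,
)

__all__ = [
    "SamplingPlan",
    "CCSResult",
    "DEFAULT_PLAN",
    "fast_plan",
    "velocity_quadrature",
    "choose_bmax",
    "compute_ccs",
]


@dataclass(frozen=True)
class SamplingPlan:
    """How many orientations, velocity nodes and impact parameters to use.

    ``b_max=None`` means the cutoff is determined per ion by
    :func:`choose_bmax`.  ``stratified_jitter`` randomizes the position of
    each impact-parameter sample within its b^2 stratum; with it off the
    b average is a deterministic midpoint rule.
    """

    n_orientations: int = 250
    n_velocity_points: int = 16
    n_impact_samples: int = 40
    seed: int = 0
    b_max: float | None = None
    n_batches: int = 10
    stratified_jitter: bool = True

    def __post_init__(self) -> None:
        if min(self.n_orientations, self.n_velocity_points, self.n_impact_samples) < 1:
            raise ValueError("all sampling counts must be >= 1")
        if self.b_max is not None and self.b_max <= 0:
            raise ValueError("b_max must be positive")
        if self.n_batches < 2:
            raise ValueError("need at least 2 batches for a stderr estimate")


DEFAULT_PLAN = SamplingPlan()


def fast_plan(seed: int = 0, **overrides) -> SamplingPlan:
    """Reduced desk-scale plan (~37k trajectories per ion).

    Impact-parameter strata outnumber orientations: the cutoff b_max is
    dominated by the long charge-induced-dipole tail, so fine b^2
    stratification is what keeps the collision core well resolved.
    """
    kw = dict(n_orientations=48, n_velocity_points=8, n_impact_samples=96, seed=seed)
    kw.update(overrides)
    return SamplingPlan(**kw)


@dataclass(frozen=True)
class CCSResult:
    """Trajectory-method cross section with its Monte-Carlo uncertainty."""

    omega: float  # A^2
    stderr: float  # A^2
    temperature: float  # K
    trapped_fraction: float
    plan: SamplingPlan
    b_max: float
    gas: str
    lj_provenance: str = "packaged N2-lineage defaults"
    warnings: tuple[str, ...] = ()
    n_trajectories: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["plan"] = asdict(self.plan)
        return json.dumps(d, indent=2)


def velocity_quadrature(
    T: float, mu: float, n_points: int
) -> tuple[np.ndarray, np.ndarray]:
    """Nodes (A/ps) and weights for the g^5 exp(-mu g^2/2 kB T) average.

    Substituting u = mu g^2 / (2 kB T) turns the weight into u^2 e^-u, a
    generalized Gauss-Laguerre problem (alpha=2, norm Gamma(3)=2).  The
    returned weights sum to exactly 1, so a constant cross section is
    reproduced unchanged; nodes scale as sqrt(T).
    """
    if T <= 0 or mu <= 0:
        raise ValueError("T and mu must be positive")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    u, w = roots_genlaguerre(n_points, 2.0)
    kt = KB_MEV * T * MEV_TO_DA_A2_PS2  # kB T in Da A^2/ps^2
    a = mu / (2.0 * kt)
    g = np.sqrt(u / a)
    weights = w / 2.0
    weights = weights / weights.sum()  # remove residual round-off
    return g, weights


_BMAX_ROTATIONS = [
    Rotation.identity().as_matrix(),
    Rotation.from_euler("x", 90, degrees=True).as_matrix(),
    Rotation.from_euler("y", 90, degrees=True).as_matrix(),
    Rotation.from_euler("z", 45, degrees=True).as_matrix(),
    Rotation.from_euler("zyz", [40, 65, 20], degrees=True).as_matrix(),
    Rotation.from_euler("zyz", [200, 120, 300], degrees=True).as_matrix(),
]

_BMAX_CHI_THRESHOLD = 1e-3  # rad
_BMAX_SAFETY = 1.2


def choose_bmax(
    ion: MolecularIon,
    gas: DriftGasModel,
    T: float,
    lj: LJParameters | None = None,
    integ: IntegratorSettings | None = None,
) -> float:
    """Impact-parameter cutoff: smallest b with deflection below 1e-3 rad
    over a fixed orientation set, times a 1.2 safety factor.

    The scan runs at the lowest node of an 8-point velocity quadrature
    (slow collisions deflect most) and marches outward in 1 A steps.
    """
    integ = integ or IntegratorSettings()
    sys = _System(ion, gas, lj)
    g_nodes, _ = velocity_quadrature(T, sys.mu, 8)
    g = float(g_nodes[0])
    e_kin = 0.5 * sys.mu * g * g / MEV_TO_DA_A2_PS2
    r_start = sys.start_radius(e_kin, integ.start_energy_fraction)
    axis = np.array([0.0, 0.0, 1.0])
    tight = replace(integ, rtol=min(integ.rtol, 1e-8))
    b = np.floor(sys.extent) + 3.0
    while b <= 100.0:
        rs = max(r_start, b + 5.0)
        chi_max = max(
            sys.run(sys.apos @ rot.T, axis, b, g, rs, tight).chi
            for rot in _BMAX_ROTATIONS
        )
        if chi_max < _BMAX_CHI_THRESHOLD:
            return float(_BMAX_SAFETY * b)
        b += 1.0
    raise RuntimeError("b_max search did not converge within 100 A")


def compute_ccs(
    ion: MolecularIon,
    gas: DriftGasModel,
    T: float,
    plan: SamplingPlan = DEFAULT_PLAN,
    lj: LJParameters | None = None,
    integ: IntegratorSettings | None = None,
    deflection_fn=None,
) -> CCSResult:
    """Trajectory-method collision cross section at temperature *T* (K).

    ``deflection_fn(b, g) -> chi`` replaces the trajectory integration when
    given (analytic deflection laws, test oracles); otherwise every sample
    runs a classical trajectory.  Identical inputs (including the plan seed)
    give bit-identical results.  Raises :class:`TrappedOrbitError` if more
    than 1% of trajectories fail to leave the interaction region.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    integ = integ or IntegratorSettings()
    sys = _System(ion, gas, lj)
    g_nodes, g_weights = velocity_quadrature(T, sys.mu, plan.n_velocity_points)

    b_max = plan.b_max if plan.b_max is not None else choose_bmax(ion, gas, T, lj, integ)

    rng = np.random.default_rng(plan.seed)
    e_kin_min = 0.5 * sys.mu * float(g_nodes[0]) ** 2 / MEV_TO_DA_A2_PS2
    r_start = (
        sys.start_radius(e_kin_min, integ.start_energy_fraction)
        if deflection_fn is None
        else 0.0
    )

    n_b = plan.n_impact_samples
    orient_values = np.empty(plan.n_orientations)
    trapped = 0
    total = 0
    edge_chi = 0.0
    for io in range(plan.n_orientations):
        theta, gamma = rng.uniform(0.0, 2.0 * np.pi, size=2)
        phi = np.arccos(rng.uniform(-1.0, 1.0))
        rot = Rotation.from_euler("zyz", [theta, phi, gamma]).as_matrix()
        positions = sys.apos @ rot.T
        val = 0.0
        for g, w in zip(g_nodes, g_weights):
            acc = 0.0
            for jb in range(n_b):
                frac = rng.random() if plan.stratified_jitter else 0.5
                b = b_max * np.sqrt((jb + frac) / n_b)
                if sys.gas.multi_site:
                    axis = rng.normal(size=3)
                    axis /= np.linalg.norm(axis)
                else:
                    axis = np.array([0.0, 0.0, 1.0])
                total += 1
                if deflection_fn is not None:
                    one_minus_cos = 1.0 - np.cos(deflection_fn(b, g))
                else:
                    try:
                        rs = max(r_start, b + 5.0)
                        res = sys.run(positions, axis, b, float(g), rs, integ)
                        one_minus_cos = 1.0 - np.cos(res.chi)
                        if jb == n_b - 1 and res.chi > edge_chi:
                            edge_chi = res.chi
                    except TrappedOrbitError:
                        trapped += 1
                        one_minus_cos = 1.0  # isotropic mean of 1 - cos
                acc += one_minus_cos
            val += w * acc / n_b
        orient_values[io] = val

    trapped_fraction = trapped / max(total, 1)
    if trapped_fraction > 0.01:
        raise TrappedOrbitError(
            f"{100 * trapped_fraction:.1f}% of trajectories were trapped; "
            "tighten the integrator settings or revisit the potential"
        )

    omega = np.pi * b_max**2 * float(np.mean(orient_values))
    n_batches = min(plan.n_batches, len(orient_values))
    if n_batches >= 2:
        batch_means = [
            np.mean(chunk)
            for chunk in np.array_split(orient_values, n_batches)
        ]
        stderr = (
            np.pi
            * b_max**2
            * float(np.std(batch_means, ddof=1) / np.sqrt(n_batches))
        )
    else:
        stderr = 0.0  # a single orientation carries no spread estimate

    warnings: list[str] = []
    if deflection_fn is None and edge_chi > 10 * _BMAX_CHI_THRESHOLD:
        warnings.append(
            f"deflection {edge_chi:.1e} rad near b_max={b_max:.1f} A; "
            "cutoff may be too small"
        )
    return CCSResult(
        omega=float(omega),
        stderr=stderr,
        temperature=float(T),
        trapped_fraction=trapped_fraction,
        plan=plan,
        b_max=float(b_max),
        gas=gas.name,
        warnings=tuple(warnings),
        n_trajectories=total,
    )
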