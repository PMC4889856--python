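# Methods

This note documents the physical model behind `iontraj`, the numerical
choices, and what the packaged template structures can and cannot show.

## Model

### Interaction potential

The ion is rigid; the drift-gas molecule is a probe with three interaction
terms (units: Å, Da, meV, e, ps throughout; conversions centralized in
`iontraj.constants`):

1. **Lennard-Jones.** Each ion atom i interacts with each gas LJ site
   through 4ε_i[(σ_i/r)¹² − (σ_i/r)⁶].  Parameters are stored per
   ion-element/gas pair (no combining rule), the way trajectory-method
   tables are published.  The packaged defaults for H, C, N, O versus N₂
   (ε = 0.82/4.65/4.55/4.39 meV, σ = 2.38/3.50/3.38/3.04 Å) are an
   informed choice in the nitrogen-extended trajectory-method lineage; they
   are echoed in result metadata and overridable from YAML.  Elements
   without tabulated parameters raise rather than defaulting silently.
2. **Charge–induced dipole.** −(α/2)|E|² evaluated at the gas center of
   mass, with E the field of the ion's partial charges and α = 1.710 Å³
   for N₂.  For a net-charged ion this gives the attractive r⁻⁴ tail that
   dominates the long-range physics.
3. **Ion–quadrupole (optional).** The full `N2` model carries two LJ sites
   1.10 Å apart and three point charges (−0.4825, +0.965, −0.4825 e)
   reproducing the molecular quadrupole.  The cheaper `N2-iso` model (one
   LJ site, no charges) is the desk-scale default; the gas axis of the
   multi-site model is frozen per trajectory and sampled isotropically, so
   orientation enters as an extra averaged variable rather than a
   propagated degree of freedom.

Forces are analytic (including the field-gradient term of the induced
dipole) and are validated against central finite differences to 1e-5
relative in the tests.

### Trajectories and the cross section

Collisions are elastic: the equivalent one-body problem integrates the
6-dimensional probe state with an adaptive Cash–Karp RK45 (relative
tolerance 1e-7 by default).  The probe starts where |V| ≤ 1e-3 of its
kinetic energy ½μg² and the trajectory ends on the same sphere moving
outward; the final step is bisected onto that sphere so the scattering
angle does not depend on step-size overshoot.  Accepted trajectories must
conserve total energy to 1e-3 relative (default), else the integration is
retried at tighter tolerance; trajectories that exceed the step cap
(possible orbiting in the r⁻⁴ tail) are counted, contribute the isotropic
mean 1 − cos χ = 1, and abort the run if they exceed 1% of samples.

The cross section averages 1 − cos χ over:

- **orientation**: Haar-uniform rotations from uniform θ, γ and
  cos-uniform φ (the sin φ measure);
- **relative speed**: the transport weight a³g⁵e^{−ag²} (a = μ/2k_BT),
  mapped by u = ag² onto a generalized Gauss–Laguerre rule (weight u²e^{−u},
  norm Γ(3) = 2).  Weights sum to exactly 1, so a constant cross section
  passes through unchanged and nodes scale as √T;
- **impact parameter**: stratified-uniform in b² up to a cutoff b_max, with
  per-stratum jitter.  With jitter off the b average is a midpoint rule,
  which makes the hard-sphere plug-in test exact at machine precision —
  this anchors the overall normalization Ω_HS = πd² analytically instead
  of relying on any printed prefactor.

**Cutoff.** `choose_bmax` marches b outward (1 Å steps, six fixed
orientations, the slowest velocity node) until the deflection falls below
1e-3 rad, then applies a 1.2 safety factor.  For singly charged small ions
this lands near 40 Å: the cutoff is set by the monopole-induced-dipole
tail, not molecular size.  A consequence is that the collision core
occupies a small fraction of the b² range, so the reduced sampling plan
deliberately uses more impact strata (96) than orientations (48); the
dominant remaining variance is genuine orientation anisotropy.

**Uncertainty.** Orientations are split into 10 batches; the standard
error comes from the spread of batch means.  Identical inputs (including
the plan seed) give bit-identical results.

### Mobility layer

Mason–Schamp with μ = mM/(m+M); K₀ reduces to 273.15 K / 101325 Pa number
density.  Note that for a fixed Ω the reduction K₀ = K·N/N₀ removes the
density dependence exactly but not the physical 1/√T factor of K — the
package treats table values as directly comparable numbers, as is common
practice when the reporting convention is not stated.  Drift-time
conversion is K = L²/(t_D U) with L in cm, U in V, t_D in ms.

The N₂→O₂ transfer uses the Langevin polarization limit, where
K ∝ 1/√(αμ) and α ∝ (D − 1): the ratio needs only the two dielectric
constants and masses.  Packaged values (N₂ 1.000547, O₂ 1.000494 at
20 °C/1 atm) are consistent with the gas polarizabilities 1.740/1.569 Å³.
Air is 0.79 N₂ / 0.21 O₂ by Blanc's law (argon folded into N₂).  The
resulting air-vs-N₂ shift is ≤ 0.5% over 19–142 Da — comfortably inside
the few-percent bound that justifies comparing N₂ calculations with
dry-air measurements.

## Template structures

The fixture builders stand in for quantum-chemically optimized geometries
using textbook values: hydronium O–H 0.98 Å with 111.7° angles and waters
hydrogen-bonded at O–O 2.70 Å (second shell 2.85 Å); aromatic C–C 1.39 Å,
C–H 1.09 Å with an axial water 3 Å above the ring centroid; all-anti
alkane backbones (C–C 1.54 Å, tetrahedral angles) with one water 3 Å above
the midpoint carbon.  Partial charges are fixed per-family templates that
sum exactly to the +1 e total charge (e.g. hydronium O −0.40/H +0.467,
neutral polar waters O −0.66/H +0.33, alkanes H +0.06 with carbons sharing
the remainder).  The attachment geometry of the water to the aromatics and
alkanes is one plausible choice among several; nothing in the pipeline
depends on it beyond the resulting shape.

Because geometry and charges are idealized, computed mobilities for these
templates are *plausible* values that reproduce trends — e.g. the strict
decrease of K from hexane to decane that matches the experimental ordering
— but not the per-species numbers obtained from DFT-optimized structures
with quantum-chemical charge schemes.  Those per-species comparisons enter
the package as packaged reference tables instead, and their mean-unsigned-
error statistics (11.29/10.45/11.68% for the water clusters under
Mulliken/MK/Hirshfeld charges; 10.9/2.6/3.0% for the alkanes) are
recomputed exactly from the table values.  For the alkane MK column the
recomputed MUE rounds to 2.6; one printed rendering of the same table
shows 2.5, and the comparison report notes both.

## Problem sizes and defaults

| knob | default | why |
| --- | --- | --- |
| sampling plan (full) | 250 orientations × 16 velocity nodes × 40 impact samples | classic desk-scale trajectory-method workload, minutes/ion |
| sampling plan (reduced, `fast_plan`) | 48 × 8 × 96 | ~37k trajectories, ~15–30 s/ion; b-strata outnumber orientations (see cutoff note) |
| integrator rtol | 1e-7 | keeps energy drift ≲1e-5 while staying fast |
| energy tolerance | 1e-3 relative | elastic-collision contract; violations retried then raised |
| start/stop radius | \|V\| ≤ 1e-3 ½μg² | bounds truncation without a fixed box |
| b_max rule | deflection < 1e-3 rad × 1.2 | explicit, reproducible cutoff |
| charge-sum tolerance | 0.01 e | catches truncated charge tables, accepts rounded QM output |
| air composition | 0.79/0.21 N₂/O₂ | two-gas weighting, argon folded into N₂ |
| resolving power | 40 | standard for compact commercial drift tubes |

The end-to-end alkane ordering check uses a paired design — the same plan
and seed for all five ions — so between-ion differences are strongly
correlated and the ordering is resolved without needing sub-percent
per-ion standard errors.

## Verification strategy

- The deflection-angle quadrature oracle (turning-point root bracketing +
  singularity-removed quadrature, built on scipy) is fully independent of
  the numba trajectory integrator; they agree to 1e-3 rad on spherical
  LJ systems, and the orientation/velocity/impact averaging agrees with a
  dense (g, b) product quadrature within statistical uncertainty.
- Hard-sphere and zero-potential limits are exact anchors.
- Rotation invariance of Ω, time reversal of trajectories, energy
  conservation, and force/finite-difference agreement are tested directly.

## Limitations

- No ion flexibility, vibration, or conformer averaging; no inelastic or
  charge-transfer channels; no quantum scattering corrections.
- Low-field (linear) mobilities only.
- LJ parameters and the N₂ charge model are literature-informed defaults,
  not fitted to any dataset shipped here.
- Template charges are static family-level choices; users supply their own
  xyzq files for scheme-specific (Mulliken/MK/Hirshfeld) charges.
- Negative-mode ions and dimers are out of scope.
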