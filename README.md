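# iontraj

Trajectory-method collision cross sections and ion mobilities of small
molecular ions in nitrogen and air.

## What this is for

Drift-tube ion mobility spectrometry (IMS) separates gas-phase ions by how
fast they drift through a buffer gas under a weak electric field.  The link
between a molecular structure and its measured mobility is the
momentum-transfer collision cross section Ω: given a candidate geometry with
per-atom partial charges, one can compute Ω, convert it to a mobility, and
compare against the measurement — the standard workflow for structure
assignment of unknowns.  `iontraj` implements this pipeline for small ions
(roughly 19–160 Da: the protonated water clusters of the reactant-ion peak,
benzene and toluene radical cations, and n-alkane/water clusters) drifting
in N₂ or ambient air.

The core is the **trajectory method**: classical scattering trajectories of
an N₂ probe in the ion's interaction potential (pairwise 12-6
Lennard-Jones + ion charge/induced-dipole, optionally the N₂ quadrupole),
whose deflection angles χ are averaged over ion orientation, impact
parameter b, and the Maxwell–Boltzmann distribution of relative speeds g:

    Ω = ⟨ ∫ 2πb (1 − cos χ(θ,φ,γ; g; b)) db ⟩_{orientation, g}

with the g-average taken under the transport weight ∝ g⁵ exp(−μg²/2k_BT)
(μ = ion–gas reduced mass).  The normalization is anchored analytically:
plugging in the hard-sphere deflection law returns Ω = πd² exactly.
Mobility follows from the Mason–Schamp equation

    K = (3/16) (q/N) √(2π / μk_BT) / Ω,

drift times convert through K = L²/(t_D·U), and N₂ mobilities transfer to
air via the Langevin polarization-limit ratio
K_O₂/K_N₂ = √[(D_N₂−1)M_N₂(m+M_O₂) / ((D_O₂−1)M_O₂(m+M_N₂))]
mixed by Blanc's law (1/K_air = 0.79/K_N₂ + 0.21/K_O₂).

The package also ships two reference tables (water-cluster and n-alkane
mobilities with trajectory-method values for Mulliken, Merz–Kollman–Singh
and Hirshfeld charge schemes) and reproduces their mean-unsigned-error
statistics, plus a Gaussian drift-time spectrum renderer (resolving power
t_D/Δt_FWHM, default 40).

## Worked example

```python
import iontraj as it
from iontraj.ccs import compute_ccs, fast_plan
from iontraj.mobility import mason_schamp, air_from_n2

ion = it.build_water_cluster(4)          # (H3O+)(H2O)4, nominal mass 91 Da
gas = it.drift_gas("N2-iso")             # single-site isotropic N2 model
res = compute_ccs(ion, gas, 298.15, fast_plan(seed=0))
K = mason_schamp(res.omega, ion.mass, gas.mass, ion.total_charge, 298.15)
K_air = air_from_n2(K, ion.mass)
print(f"omega = {res.omega:.1f} +- {res.stderr:.1f} A^2")
print(f"K_N2  = {K.K:.3f} cm^2/Vs   K_air = {K_air.K:.3f}")
```

prints (about 20 s on one CPU; bit-reproducible for a fixed plan/seed):

```
omega = 101.3 +- 4.5 A^2
K_N2  = 2.496 cm^2/Vs   K_air = 2.496
```

That is: the template hydronium/4-water cluster has a cross section of
~101 Å² against N₂ at 298 K, giving a mobility of ~2.5 cm²V⁻¹s⁻¹; the
transfer to air moves it by only +0.02% — the air correction is far below
the few-percent level for all masses in scope, which is why calculations
in pure N₂ are directly comparable with measurements in dry air.  Note the
template geometry/charges are idealized, so the absolute K is a plausible
value, not a reproduction of any particular quantum-chemically optimized
structure (reference calculations for this cluster lie near 2.1–2.3).

The same pipeline is scriptable from the shell:

```sh
iontraj compare tables            # MUE statistics of the packaged tables
iontraj mobility from-drift --voltage 1925 --drift-time 6.0
iontraj ccs my_ion.xyzq --gas N2-iso --seed 1
```

Structures are read from an XYZ dialect with a fifth per-atom partial-charge
column (in e) and `charge=<int>` in the comment line.

## Layout

- `iontraj.structures` — atoms, molecular ions, xyzq file I/O, rigid motions
- `iontraj.fixtures` — template geometries for the benchmark ion families
- `iontraj.potential` — LJ + electrostatics ion/N₂ interaction, gas models
- `iontraj.trajectory` — adaptive RK45 scattering, deflection-integral oracle
- `iontraj.ccs` — orientation/velocity/impact averaging, cutoff choice
- `iontraj.mobility` — Mason–Schamp, drift times, O₂/air transfer
- `iontraj.compare` — MUE statistics, spectrum rendering
- `docs/methods.md` — model assumptions, parameter choices, limitations
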