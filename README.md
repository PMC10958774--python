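# eden3d

Simulation and morphometrics of genetic demixing on expanding **spherical**
bacterial frontiers.

When a well-mixed population of two neutral, fluorescently labelled strains
grows outward into fresh territory, random birth fluctuations at the
frontier segregate the genotypes into monoclonal **sectors**.  In 2D colony
range expansions this coarsening settles into a fixed number of sectors; on
the closed 2D surface of a 3D (spherical) colony the dynamics differ
qualitatively: sectors first **merge** while the micro-colonies of the
founders fuse, and thereafter they steadily **split**, because a sector
boundary on the expanding surface is a fluctuating line from which new
domains pinch off.  `eden3d` provides the lattice model and the complete
metrics suite needed to quantify this, for simulated colonies and for
externally segmented confocal (CLSM) masks alike.

## The model

A 3D Eden growth model on a cubic lattice (`L = 200` by default).  Founders
are placed in a central sphere of radius `R_s = 19` sites: each site inside
the sphere is occupied independently with probability `N/V`,
`V = (4/3)πR_s³`, so the founder count is binomial with mean `N`
(`N ∈ {16, 144, 1150}` emulate the bead seeding concentrations `m/10`, `m`,
`m×10`).  Founders carry color 1 or 2 with equal probability
(*two-species* mode) or a unique lineage label each (*multi-species* mode).
Growth repeats, for `5×10⁵` events:

1. pick a surface site (occupied, ≥ 1 empty face neighbour) uniformly from
   the surface list `S`;
2. pick one of its empty face neighbours uniformly;
3. fill it with the parent's label;
4. update `S` incrementally.

Each division advances time by `1/|S|`, so one time unit is a generation.

## The metrics

All metrics act on a single-voxel-thick colored surface mask and work
identically for model lattices and segmented microscopy volumes:

- **Radius** (from z-projections): `⟨R(t)⟩ = (1/N√π) Σₙ √A⁽ⁿ⁾_prj(t)` —
  the mean of per-colony radii.
- **Compactness**: `ρ_prj = 4πA_prj/P²`, normalized by the same quotient of
  an equal-area pixel-resolved circle so the square-pixel perimeter bias
  cancels (`ρ = 1` for a rasterized circle).
- **Occupancy**: `⟨𝒪(t)⟩ = (1/N) Σₙ A⁽ⁿ⁾_focal/A⁽ⁿ⁾` — surface fraction of
  one genotype.
- **Sectors**: connected same-colored surface regions (26-connectivity by
  default, minimum area 1 site for model colonies / 10 voxels for
  experimental masks); area-weighted survival curves
  `P(A_sec > a) = Σ_{Aᵢ>a} Aᵢ / Σᵢ Aᵢ`; and the **splitting rate** — the
  OLS slope of the ensemble-mean sector count `⟨σ(t)⟩` on its late linear
  branch.

A small pipeline ingests two-channel binary segmentation volumes
(double-labeled voxels resolved to red, enclosed cavities filled, the
shadowed far hemisphere cut off) and bead-dosimetry helpers convert culture
OD to expected founders per inoculation bead.

## Worked example

```python
import eden3d as e
from eden3d.morphometrics import sector_count_series, fit_splitting_rate

params = e.SimParams(mean_seed_count=144, species_mode="two_species",
                     n_steps=500_000)
ensemble = e.run_ensemble(params, n_replicates=15, base_seed=7)
series = sector_count_series(ensemble)
print(series.head(4).round(2).to_string(index=False))
print(fit_splitting_rate(series).summary())
```

prints (about 15 s on one core):

```
  t  sigma_mean  sigma_sem
0.0      140.73       2.61
1.0      134.40       2.70
2.0      121.13       2.34
3.0       94.67       2.58
splitting rate: 1.635 +/- 0.065 gen^-1  (window t in [14.0, 31.0], n=18, R^2=0.9757)
```

The ~141 sectors at `t = 0` are the founder micro-colonies; the falling
counts are the merging phase, and after the minimum (≈ 11 sectors near
`t = 12`) sector splitting takes over at a steady ≈ 1.6 sectors per
generation — the splitting rate for the intermediate seeding
concentration.  The same objects expose `R(t)`, `ρ(t)`, `𝒪(t)`, surface
areas and full sector tables per replicate.

A CLI mirrors the library for shell use:

```sh
eden3d simulate --mean-seed-count 144 --n-replicates 15 --base-seed 7 --out run/
eden3d analyze run/ --fit-rate --out analysis/
eden3d fixtures --kind wedge_shell --radius 10 --out wedges.npz
eden3d inoculum
```

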