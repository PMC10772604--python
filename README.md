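# aerotraits

Diagnose the hypoxia-tolerance traits of marine ectotherms from where
they live.

Oxygen and temperature jointly limit where marine animals can sustain
an active population: warming raises metabolic O2 demand while the
physiology of O2 supply has its own temperature dependence.  For most
of marine biodiversity these traits have never been measured in a
laboratory — but they leave a fingerprint in biogeography, as the
lowest O2 level a species inhabits at each temperature.  `aerotraits`
extracts that fingerprint from occurrence records paired with gridded
ocean climatologies of temperature and O2 partial pressure, and is
aimed at ecophysiologists and macroecologists who want active hypoxia
traits for many species at once, plus the downstream comparative
analyses.

## The model

The Metabolic Index is the ratio of organismal O2 supply to the demand
of an ecologically active population,

```
Phi(pO2, T) = A_eco · pO2 / f(E_eco(T), T)
f(E, T)     = exp(−E/k_B · [1/T_K − 1/T_ref,K])
E_eco(T)    = E_eco_ref + dEdT · (T − T_ref)
```

with `A_eco` (atm⁻¹) the active hypoxia tolerance, `E_eco` (eV) its
temperature sensitivity at `T_ref = 15 °C`, and `dEdT` (eV/°C) the
linear drift of that sensitivity across the inhabited range.  Water
with `Phi ≥ 1` — equivalently `pO2 ≥ pO2_act(T) = f/A_eco` — is
metabolically viable.  The three traits are diagnosed per species by
exhaustive grid search maximizing the F1-score of the `Phi ≥ 1`
classifier over the species' presence/background samples in T–pO2
state space.  Trait algebra links the result to laboratory quantities:
`A_eco = A_o/Φ_crit = 1/(V_h·Φ_crit)` and
`E_eco = E_d − E_s + E_Φcrit`.

The package ships a fully synthetic test bed (structured ocean +
species with known traits), the trait fitter (also exposed as a
scikit-learn-style `MetabolicIndexClassifier`), aerobic habitat-volume
grids, range-edge sensitivities, `E_Φcrit` estimators, latitudinal
summaries and Kolmogorov–Smirnov comparisons, and phylogenetic-signal
analysis (Grafen branch lengths, maximum-likelihood Pagel's λ with a
likelihood-ratio test).  See `docs/methods.md` for the full account.

## Worked example

```python
import aerotraits as at

env = at.make_ocean(resolution_deg=2.0, seed=1)
truth = at.TraitSet("demo", A_eco=8.0, E_eco_ref=0.3, dEdT=0.02)
species = at.SyntheticSpeciesTruth("demo", truth, phi_max=1.4,
                                   n_presence=500, noise_rate=0.05, seed=3)
records = at.simulate_species(env, species)

dataset = at.build_occupancy(records, env)
fit = at.fit_traits(dataset)
edges = at.edge_sensitivities(fit)
vol = at.habitat_volume(env, fit.traits.A_eco, fit.traits.E_eco_ref,
                        fit.traits.dEdT, phi_max=1.4, depth_band=(0, 100))
```

Formatted, the fitted quantities read:

```
A_eco       8.21  (truth 8.00) 1/atm
E_eco_ref   0.30  (truth 0.30) eV
dEdT       0.022  (truth 0.020) eV/degC
F1 0.81   T_C 2.5 C   T_W 20.5 C   Phi_max 1.76
E_eco at warm/cold edges: +0.42 / +0.03 eV (delta 0.40)
aerobic habitat volume, 0-100 m: 6.40e+15 m^3
E_eco decomposition 0.7 - 0.4 + (-0.1) = 0.2 eV
```

Reading the output: the fitter recovered the species' tolerance within
3% and its temperature sensitivity exactly, from 500 noisy occurrence
records.  `T_C`/`T_W` are the 5th/95th percentiles of inhabited
temperature; `Phi_max` is the 95th percentile of the Metabolic Index
over occupied water — the species' O2 supply headroom above sustained
needs.  The edge sensitivities evaluate `E_eco(T)` at the warm and cold
range edges; their difference equals `dEdT·(T_W − T_C)` exactly.  The
habitat volume is the water volume with `1 ≤ Phi ≤ 1.4` in the upper
100 m.  The final line composes the net temperature dependence of
active hypoxia tolerance from demand (0.7 eV), supply (0.4 eV) and
activity-ratio (−0.1 eV) components.

## Command line

```
aerotraits simulate      --out demo --seed 1          # ocean + species + tree
aerotraits fit-traits    --occurrences demo/occurrences.csv \
                         --environment demo/ocean.nc --out fit
aerotraits diagnose      --traits fit/traits.csv \
                         --occurrences demo/occurrences.csv --out diag
aerotraits habitat-volume --environment demo/ocean.nc --out hv
aerotraits phylo-signal  --tree demo/tree.nwk --traits fit/traits.csv --out phy
```

Every stage logs read/dropped/matched counts to stderr and writes a
JSON run manifest (configuration, hash, seeds, row counts); rerunning
an identical manifest reproduces identical output bytes.

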