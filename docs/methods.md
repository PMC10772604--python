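# Methods

## The model

The package diagnoses temperature-dependent hypoxia tolerance for
marine ectotherms from where they occur in the ocean.  The organismal
O2 balance is summarized by the Metabolic Index

    Phi(pO2, T) = A_eco * pO2 / f(E_eco(T), T),
    f(E, T)     = exp(-E/k_B * (1/T_K - 1/Tref_K)),

the ratio of O2 supply to the demand of an ecologically active
population.  `Phi >= 1` marks metabolically viable water; the viability
boundary is the temperature-dependent minimum partial pressure
`pO2_act(T) = f(E_eco(T), T) / A_eco`.

Phi is normalized to the *active* threshold: what biogeography can
constrain is the product of resting tolerance and the sustained:resting
metabolic-rate ratio (`A_eco = A_o / Phi_crit = 1/(V_h * Phi_crit)`),
never the two factors separately.  Phi as used here therefore equals
the resting-state index divided by Phi_crit, and the diagnosed upper
occupancy percentile `Phi_max` is the species' supply headroom
*relative to Phi_crit*.

The effective activation energy varies linearly with temperature,
`E_eco(T) = E_eco_ref + dEdT * (T - T_ref)`, a one-parameter summary of
the multi-step nature of physiological O2 supply (diffusion-limited in
warm water, ventilation/circulation-limited in cold).  Trait algebra
connects the field estimates to laboratory quantities:
`E_eco = E_d - E_s + E_phicrit` and `E_phicrit = E_eco - E_o`, where
`E_d` and `E_s` are demand and supply activation energies and
`E_phicrit` is the temperature sensitivity of the sustained:resting
ratio (negative when activity costs rise more slowly with warming than
maintenance).  Temperatures are degrees Celsius throughout the API and
converted to Kelvin only inside the Arrhenius factor;
`k_B = 8.617333262e-5 eV/K`.

## Trait fitting

Occurrence records are snapped to grid cells (half-open cell intervals,
nearest depth level; records without depth default to the surface
level, a flag-controlled choice).  Cells are then projected onto binned
T-pO2 state space: 1 degC temperature bins and 5-to-12% multiplicative
pO2 bins (default 10%; multiplicative because thresholds span decades
and the recovery tolerance is relative).  Presence samples are the
occupied bins; background samples are the bins realized by ocean cells
in the background domain but never occupied.

Two aspects of the background universe matter and are deliberate:

* **Domain.**  All ocean cells within the species' occupied depth range
  extended by one level, and within its occupied latitude range padded
  by 5 degrees.  The F1-score is insensitive to far-field true
  negatives, but false positives need a stated universe, and columns
  the species never visits carry no information about its threshold.
* **Upper-envelope clamp.**  Within each temperature column, background
  bins above the species' occupied upper pO2 envelope (95th percentile
  of occupied bins, plus one bin of pad) are excluded.  The classifier
  being fitted is one-sided (`Phi >= 1`), and the quantity being
  estimated is the *lower* threshold above which occurrences are common
  and below which they are rare; water richer in O2 than the species
  ever occupies says nothing about that threshold, and counting it as
  false positive biases the fit toward explaining it away with extreme
  temperature sensitivities.  Both behaviours are measured and the
  clamp is configurable (`OccupancyOptions.clamp_to_envelope`).

Traits are the argmax of the (optionally weighted) F1-score
`2TP/(2TP + FP + FN)` of the `Phi >= 1` prediction over an exhaustive
grid: A_eco log-spaced 0.5-100 atm^-1 (40 points), E_eco_ref -1..2 eV
in 0.05 steps, dEdT 0..0.12 eV/degC in 0.01 steps — deliberately wider
than the trait distribution itself — followed by one local refinement
pass spanning +-2 coarse steps at 5x density.  Near-maximal F1 values
form plateaus (the binned data cannot distinguish curves that differ by
less than one reclassified sample), so the selection treats every grid
point within `0.5/total-presence-weight` of the maximum as tied and
picks the plateau's median point (log A, E, dEdT in grid-step units);
any residual tie falls back to a fixed ordering (lowest A, |E| nearest
zero, lowest dEdT).  A corner pick here is measurably biased (low A,
E pulled toward zero).  The search is vectorized — for each (E, dEdT)
pair the per-sample habitability threshold in A is `g = f/pO2`, so one
`searchsorted`/`bincount` pass yields the confusion counts for the
whole A axis — and is checked against a naive triple-loop oracle in the
tests.

Fit quality is reported as the F1 itself, confusion counts, the
5th/95th percentiles of inhabited temperature (T_C, T_W), and Phi_max
(95th percentile of Phi over presence samples at the fitted traits).
All percentiles use linear interpolation between closest ranks.
Species with fewer than 10 unique occupied cells are skipped with an
explicit reason.

## Synthetic data

The generators exist so that every downstream stage can be exercised
end to end, with known ground truth, without any data download.  They
are pure functions of their parameters and a seed; reruns are
bit-identical.

**Ocean.**  A cell-centered grid (default 2 degrees, 8 layers over
0-1000 m — the depth range holding the habitat analysed here) with:

* surface temperature falling from 29 degC at the equator to -1.8 degC
  at the poles (cos^2 profile), decaying with depth toward 2 degC over
  a 300 m thermocline scale;
* surface pO2 near 0.21 atm with mild cold-water supersaturation
  (up to +0.015 atm);
* an oxygen minimum zone (core pO2 0.02 atm in the tropics) whose core
  depth varies by longitude between 150 and 500 m, so that — as in the
  real ocean's eastern-boundary OMZs — low pO2 coexists with warm
  thermocline temperatures;
* O2-depleted "aged" deep water (up to 55% depletion centred at
  1400 m, hemisphere-modulated), the analogue of the deep North
  Pacific, so cold temperature classes also span a broad pO2 range;
* smooth seeded low-order zonal structure in both fields and an
  idealized two-continent land mask.

The last three items are what make hypoxia traits diagnosable at all:
the fitted threshold curve is only constrained at temperatures where
the ocean actually offers water below it.

**Species.**  A species truth is (TraitSet, Phi_max, n_presence,
noise_rate, seed).  Occurrence records are drawn with replacement,
probability proportional to cell volume, from the habitat
`1 <= Phi <= Phi_max`; each record is flipped to a uniformly random
non-habitat ocean cell with probability `noise_rate` (the simplest
misdetection model).  Defaults are the study conditions used by the
recovery tests: 500 records, 5% noise, truth `Phi_max = 1.4` — the
median supply headroom observed across real species; occupancy bands
much wider than that produce synthetic species whose habitable volume
vastly exceeds what 500 records can attest, and bands are what the
diagnosed Phi_max distribution actually shows.  Random truths are drawn
from the *reported* trait distribution (A_eco log-uniform 2-50 atm^-1,
E_eco_ref uniform -0.5..1.0 eV, dEdT normal with mean 0.05 and s.d.
0.03 eV/degC clipped to [0, 0.12]); the search grid remains much wider.
Draws whose habitat holds fewer than 30 cells are redrawn — such
species could never pass the occupancy gate.

What the generator deliberately does **not** emulate: observation
effort bias (real occurrence data are strongly coastal- and
surface-biased; sampling here is unbiased volume-weighted sampling),
ocean circulation, mesoscale variability, and seasonality (a
sinusoidal monthly cycle is available via `make_ocean(monthly=True)`
but the recovery studies use annual fields).  Passing tests therefore
show that the estimator recovers known traits under clean, unbiased
sampling of a structured ocean — not that it is robust to the effort
biases of real archives.

**Clades.**  Tip traits are simulated as multivariate normal draws with
covariance `sigma2 * C_lambda` on a random join-topology tree with
Grafen branch lengths, for testing the phylogenetic-signal machinery.

## Phylogenetic signal

Trees are read and written as Newick (dendropy).  For taxonomy trees
without divergence times, Grafen branch lengths set each node's height
to its number of descendant tips minus one, normalized by (total tips
minus one) and raised to the power rho (default 0.4); tips sit at
height zero, branch length is parent height minus child height, and
polytomies are handled natively.

Pagel's lambda multiplies the off-diagonal entries of the
shared-path-length matrix C.  The fit profiles the likelihood: for each
lambda the root mean and rate sigma^2 have closed-form GLS estimates;
lambda is maximized over [0, 1] by a 0.01-step grid scan followed by
bounded scalar refinement (the grid scan guards against local optima).
The likelihood uses the dense covariance matrix and Cholesky
factorization — at the problem sizes this package targets (up to a few
thousand matched tips) the dense solve is fast, simple and is itself
validated against a 1e-4-step dense lambda grid in the tests.
Covariance matrices failing Cholesky, or whose smallest squared
Cholesky pivot falls below 1e-12 of the largest, raise a singularity
error naming the likely cause (zero-length branches between distinct
tips).  The likelihood-ratio test against lambda = 0 reports both the
plain chi-square(1) p-value and the boundary-corrected (halved)
version, since lambda = 0 lies on the parameter boundary.

## Downstream diagnostics

* Aerobic habitat volume: the summed cell volume with
  `1 <= Phi <= Phi_max` in a depth band (defaults: Phi_max 1.4;
  bands 0-100 m and 100-1000 m; dEdT 0.025 eV/degC, the
  laboratory-derived central value).  Monthly grids average the monthly
  habitable volumes (an intersection/union variant was considered and
  rejected as harder to interpret; the flag can be added without
  breaking the schema).
* Range-edge sensitivities: `E_eco(T_edge) = E_eco_ref +
  dEdT*(T_edge - T_ref)` at T_W and T_C; the identity
  `delta = dEdT*(T_W - T_C)` holds to machine precision.
* `E_phicrit` from paired field/laboratory sensitivities
  (`E_eco - E_o`) or from factorial aerobic scope measured at several
  temperatures (least-squares Arrhenius slope of ln FAS).
* Latitudinal band summaries (species placed at their median occurrence
  latitude) and two-sample Kolmogorov-Smirnov comparisons (exact D;
  asymptotic p with the n*m/(n+m) effective sample size).

## Numerical and interface choices

* All generators and fits are deterministic given seeds; CLI stages
  write a JSON manifest (config, config hash, seeds, row counts) and
  identical manifests reproduce identical outputs byte for byte.
* Environment grids travel as NetCDF-3 classic files; temperature
  declared in K is converted, undeclared unit mismatches are schema
  errors, and grids lacking cell volumes get spherical-shell volumes
  from their coordinates.
* Longitudes normalize to [-180, 180); latitude outside [-90, 90] drops
  the record (counted); cell intervals are half-open.
* F1 is defined as 0 when TP = 0 with errors present, and undefined
  (an error) when all counts vanish.

## Known limitations

* The recovery of `E_eco_ref` (and hence `A_eco` at the reference
  temperature) is intrinsically limited for species whose inhabited
  temperature range does not straddle T_ref = 15 degC: the fit
  constrains the effective activation energy along the inhabited arc,
  and referencing it to T_ref extrapolates with the fitted dEdT, whose
  error is amplified by the distance between the range centre and
  T_ref.  Real diagnoses share this property — tolerances referenced
  outside a species' native range can even cross atmospheric pressure.
  The recovery acceptance test documents the achieved rates; the A_eco
  recovery rate is substantially higher than the E_eco_ref rate.
* The F1 objective has plateau degeneracies by construction; reported
  traits are plateau centres, and downstream users should treat the F1
  value and the `edge:`/`low_skill` flags as first-class outputs.
* Binned state-space occupancy quantizes the envelope at the bin width;
  tolerance below ~5% in A_eco is not meaningful at the default bins.
* No spatial thinning or effort-bias correction is implemented
  (out of scope), and the Kolmogorov-Smirnov p-values are asymptotic.
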