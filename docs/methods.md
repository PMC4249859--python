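# Methods

## Model

Two cell populations (Eph-receptor-expressing and ephrin-expressing) are
represented by their centres on a 2-D rectangular field. The model collapses
the many molecular pathways of Eph/ephrin signalling into three terms:

1. **Random motility.** On time scales much longer than a cell's persistence
   time, single-cell MSD is linear in time, so free motion is a 2-D Brownian
   motion with diffusion coefficient `D`. Substrate drag is assumed large,
   so velocity is not a state variable (overdamped limit).
2. **Pairwise interaction.** All cell-cell mechanics are bundled into a
   radial force `F(d) = −u′(d)` from the potential
   `u(d) = R·e^(−d/r) − A·e^(−d/a)` with `r < a`: a short-ranged repulsive
   core (surface tension, volume exclusion) and a longer-ranged adhesive
   well (the sum of all adhesion systems, cadherins included). Two like
   cells rest where `u′ = 0`:
   `d* = ln(R·a/(A·r))/(1/r − 1/a)`; the effective cell radius is
   `r_eff = d*/2`. Heterotypic contact signalling attenuates *only* the
   adhesive term by `(1−C)`, `C ∈ [0, 1]` — repulsion is never attenuated,
   so at `C = 1` a net outward force remains at every distance.
3. **Proliferation.** A pure-birth (Yule) process: divisions are memoryless
   with rate β per cell, implemented per macro step as an independent
   Bernoulli with `p = 1 − e^(−β·dt)` (equal in law to exponential
   inter-division times, cross-checked in the tests against an event-driven
   simulation). Daughters inherit the type and spawn 1 µm away in a uniform
   random direction; the repulsive core separates the pair within a few
   steps. Cell death is neglected: segregation completes within ~2 days,
   over which death is negligible in the experimental system this models.

Positions advance by first-order Euler–Maruyama
(`X ← X + F_total·dt + Normal(0, 2·D·dt)` per axis), then the boundary
condition, then births.

## Parameters

| parameter | meaning | default | unit |
|---|---|---|---|
| R, A | repulsion / attraction magnitude | 250, 100 | dimensionless |
| r, a | repulsion / attraction length scale | 5.8, 7.5 | µm |
| C | heterotypic adhesion attenuation | scenario-dependent (0–1) | – |
| D | diffusion coefficient | 5 | µm²/min |
| β | birth rate | ln2/24 ≈ 0.0289 | 1/h |
| dt | integration step | 4 | s |
| cutoff | interaction truncation radius | 60 | µm |
| domain | field size | 640 × 640 | µm |
| N₀ | initial cells (desk scale) | 256 | – |

With the default force parameters `d* ≈ 30.0 µm`, i.e. `r_eff ≈ 15 µm`,
matching HEK293-scale cells. The magnitudes are unitless potential
amplitudes; only `R/A` (through `d*`) and the derivative scales `R/r`, `A/a`
(µm/min drift) are physically meaningful. β defaults to a 24-h doubling
time. D = 5 µm²/min is of the order measured for motile epithelial-like
cells on fibronectin.

When the two populations carry unequal parameters (e.g. `R_eph = 220` vs
`R_ephrin = 250`), a mixed pair uses the component-wise arithmetic mean of
(R, A, r, a). Any single shared parameter set per pair keeps `F_ij = −F_ji`
exactly (momentum conservation, and the drift sums to zero); the arithmetic
mean is the simplest such rule.

### Scale

The experimental well (≈50,000 cells on 0.8 cm²) is represented at the same
seeding density, 6.25×10⁻⁴ cells/µm², on a 640×640 µm field — 256 initial
cells ("desk scale"). Density, not count, controls the interaction physics,
so patterns form at the same rate; full scale is reachable by enlarging the
domain in the config. Ensemble analyses in the tests and the acceptance
script use 12-simulated-hour runs for the mixing statistic and 24-hour runs
for the density comparison (cluster formation and the equilibrium-spacing
difference are fully established by then), with 10–20 independent seeds.

## Numerical choices

* **Time step and stability.** The stiffest mode of the dynamics is the
  longitudinal relaxation of a close pair, with linearized rate
  `λ = 2·|u''(0)|` (the factor 2 from relative motion). `step` enforces
  `dt ≤ 1/λ_max` over the three pair classes — the non-oscillatory
  (monotone) relaxation limit, which also underwrites the energy-descent
  property of the noiseless dynamics. For the default `C = 1` parameters
  `λ_max = 2·R/r² per class ⇒ dt_max ≈ 4.04 s`; the default `dt = 4 s` sits
  just inside. Violations raise an error naming the admissible maximum.
* **Interaction cutoff.** Forces are truncated at 60 µm (≈8·a), where the
  largest neglected term (`A/a·e^(−60/7.5) ≈ 3×10⁻³ µm/min` per pair) is
  two orders below typical drift and four below the per-step Brownian
  displacement. Neighbour search uses a k-d tree rebuilt each step; the
  oracle-equivalence check compares indexed against all-pairs drift at a
  120 µm cutoff, where the truncation tail (<2×10⁻⁶ per pair) is below the
  10⁻⁴ comparison tolerance, and verifies exact pair-set recovery at 60 µm.
* **Boundaries.** Default REFLECTING (a field within a dish); PERIODIC is
  available for bulk behaviour free of wall artifacts.
* **Coincident centres.** `u′(0)` is finite for the exponential form; the
  force direction for a zero-distance pair is a uniform random unit vector
  from the run's RNG stream. A deterministic tie-break would bias
  daughter-cell separation after division.
* **Determinism.** One RNG stream per run, seeded from the config; draws
  occur in a fixed traversal order (cells in ascending id, which is array
  order). Snapshot times are computed from the integer step counter, not by
  accumulating floats. Positions are serialised at 4 decimals; identical
  (config, seed) gives byte-identical CSV output.
* **Update order.** Motion step, then births, per macro step.
* **Force/potential checks** compare the analytic force against a centred
  difference of the potential at `rtol = 10⁻⁶` with an `atol = 10⁻⁹` floor
  (pure relative error is ill-posed where the force crosses zero at d\*).

## Cluster quantification

Simulated snapshots are rasterized exactly: a pixel (1 µm/px default, must
be ≤ r_eff/3) is foreground iff its centre lies within r_eff of a cell
centre of the population. Connected components use 8-connectivity by
default, so discs meeting diagonally merge, mirroring physical contact.
Areas are pixel counts × pixel area. Size bins are half-open and
lower-inclusive — [100, 1500), [1500, 15000), [15000, ∞) µm², components
under 100 µm² discarded; the experimental convention for edge inclusivity
is not recorded, so this one is documented rather than inferred. Cells are
counted per cluster by the component under each cell centre (exact for
simulation, where no intensity surrogate is needed; a cell's own disc
guarantees its centre is on foreground). Density is 1000·cells/area. The
intensity thresholding required for microscopy is out of scope: simulated
images have exactly three colours.

The heterotypic contact fraction complements the raster pipeline: among
pairs within 1.1·2·r_eff, the fraction with differing types. A well-mixed
seeding with Eph fraction p starts near 2pq/(p² + q² + 2pq) and segregation
drives the value down; type-blind dynamics (C = 0) leave it within the
baseline's sampling band.

## Synthetic data

`fixtures.mixed_seeding` emulates seeding a counted cell suspension:
uniform random positions with a 2 µm minimum separation (rejection
sampling), types assigned by random permutation so the ratio is exact.
`fixtures.synthetic_constellation` plants hexagonally packed clusters
(densest 2-D packing, making density comparisons crisp) with ground truth
computed by two oracles sharing no code with the production pipeline: plain
union-find over the disc touching graph, and a brute-force
pixel-centre-in-union-of-discs area scan. The generators do not emulate
microscopy noise, illumination gradients, intensity statistics, or
cell-to-cell variability in expression level — so passing tests demonstrate
the model's and pipeline's internal correctness, not agreement with any
particular experimental image set.

## Design decisions taken where the design was open

* **Potential form.** The exponential pair potential above is the package's
  canonical form; it is isolated in one module (`core_model`) so an
  alternative (e.g. power-law) can be swapped without touching the
  simulator.
* **Intermediate attenuation.** The low-ephrin scenario uses `C = 0.5` as a
  documented placeholder for "partial signalling"; any value strictly
  between 0 and 1 produces the intermediate phenotype.
* **Mixing rule, tie-break, bin edges, connectivity** — as above; each is a
  choice among behaviourally close alternatives, fixed and documented.

## Limitations

* Cells are isotropic points with pairwise forces: no shape, polarity,
  three-body mechanics, or force dependence on local density.
* No contact inhibition of proliferation; growth is exponential throughout,
  so very long runs overcrowd the field.
* No cell death, chemotaxis, or 3-D effects.
* The attenuation constant C is phenomenological; it is not fitted to
  experimental images here (no experimental data ships with the package).
* Population-level variability (e.g. "slow cells" with low expression) is
  not modelled; every cell of a population shares one parameter set.
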