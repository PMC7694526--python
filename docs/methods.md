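# Methods

## Model

The package implements a standard dissipative particle dynamics (DPD)
model of poly(lactic acid) (PLA) nanoparticle formation in water, with
three solute chemistries: the amphiphilic lipopeptides Pam1CSK4 and
Pam3CSK4 and the hydrophobe vitamin E (alpha-tocopherol).

Nine coarse-grained bead species are used.  One W bead represents three
water molecules (54 Da, radius 3.23 Å).  PLA is a linear chain of 70
lactic-acid beads (LA).  The lipopeptides are trees built from modified
cysteine (C), serine (S), lysine (K), modified glycerol (G) and C3H6
fatty-acid units (F, five per palmitoyl tail): Pam1CSK4 carries one tail
(12 beads), Pam3CSK4 three tails (22 beads by default).  Vitamin E is a
chromanol bead (CHR) plus three five-carbon tail beads (C5).  Bead masses
are heterogeneous (42 Da for F up to 219 Da for CHR); masses other than
W, F and CHR are fragment masses of the mapped chemical groups and can be
overridden.

All beads interact through the soft linear DPD repulsion
`F_C = a_ij (1 - r/r_c) e_ij` inside the single cutoff r_c, plus the
pairwise dissipative/random thermostat

    F_D = -gamma (1 - r/r_c)^2 (e.v) e,
    F_R = sigma (1 - r/r_c) theta dt^(-1/2) e,   sigma^2 = 2 gamma kT,

and harmonic springs `k (r - r0)` between bonded beads.  The repulsion
amplitudes come from Flory-Huggins theory:
`chi_ij = (v/RT)(delta_i - delta_j)^2` with Hildebrand solubility
parameters delta in (J/cm^3)^1/2 and the pair's mean molar volume v in
cm^3/mol, mapped as `a_ij = 25 + 3.50 chi_ij`.  The package ships the two
interaction tables used for all production runs (one for water/PLA/Pam
systems, one for water/PLA/vitamin E); their diagonals are the
Groot-Rabone like-pair value 78, appropriate for a three-water bead at
reduced density rho = 3, and the shipped tables are authoritative for
simulations.  The formula pathway (`build_matrix_from_solubilities`)
exists for parameterizing new molecules: it applies the affine map to
off-diagonals and takes the diagonal from configuration (default 78),
because the affine map with chi_ii = 0 would yield 25 on the diagonal and
contradict the shipped tables.

## Units

r_c is the W-bead diameter, 2 x 3.23 = 6.46 Å.  With water at 1 g/cm^3
and 54 Da per bead this puts rho = 3.0 beads in every r_c^3 — the
standard DPD liquid density — so every builder fills space at rho = 3.
Energies are in kT = 1; masses in units of one W bead (54 Da).  Run
lengths quoted in nanoseconds use a bookkeeping convention of 3 ps of
represented time per DPD step (10 ns = 3,334 steps).  This mapping is a
reporting convention, not a dynamical calibration: DPD dynamics are not
transposable to wall-clock solvent dynamics.

## Integrator and thermostat

Modified velocity-Verlet (Groot-Warren): half-kick, drift with periodic
wrapping, force evaluation at the predicted velocity `v + lambda dt f`,
corrector half-kick.  Defaults: dt = 0.04, gamma = 4.5 (hence
sigma = 3.0), kT = 1, k_bond = 4, r0_bond = 0, lambda = 0.65.  lambda =
0.65 rather than 1/2 is deliberate: it is the value Groot and Warren
recommend for gamma = 4.5, and in our pure-water benchmark at dt = 0.04
it holds the measured kinetic temperature within 3% of target
(lambda = 1/2 overshoots to ~1.035).  All constants are config-exposed.

Pair random numbers come from a counter-based splitmix64 hash keyed on
(seed, step, i, j), giving every pair one symmetric unit-variance uniform
draw per step.  Consequences: random forces are exactly antisymmetric
(momentum is conserved to floating-point accumulation, < 1e-6 N over 1e4
steps), results are independent of pair iteration order, and a seed fully
determines a trajectory bit-for-bit on one platform.  Forces are
evaluated with a cell list (cell edge >= r_c, rebuilt every step — soft
potentials and a small dt make skin optimizations unnecessary); boxes
smaller than 3 r_c per axis fall back to an all-pairs loop.  Coincident
beads (r = 0) contribute no force; the soft core makes this benign.

## Initial states (synthetic-data builders)

The three builders generate the study geometries at the study
compositions; solute amounts are molecule-number ratios against water
beads, the convention used throughout:

* `random_mixed_box` — concentrated solutions: water plus 3/10/30%
  lipopeptide in a cubic box (280 Å at full scale).
* `droplet_setup` — nanoprecipitation: a central sphere (130 Å radius at
  full scale, in a 280 Å box) holding water:PLA:Pam = 201:67:1 or
  water:PLA:vitamin E = 750:125:117 per integer scale unit (the vitamin E
  recipe is 8.0% w/w vitamin E vs PLA), bulk water outside; the scale
  unit is chosen so the droplet interior sits at rho = 3.
* `slab_setup` — saturation: a 100 Å PLA layer at one end of a
  500x100x100 Å box, lipopeptide at 1/5/10% dispersed in the water phase.

### Composition basis

The solution and slab compositions are stated as "N% (number of solute
molecules vs water molecules)".  Taken literally, that reading places the
nominally concentrated systems deep in a solvent-poor regime: a Pam1CSK4
molecule carries 12 beads, so a 30% molecule ratio means 3.6 solute beads
per water bead — 78% solute by volume (87% for the 22-bead Pam3CSK4, and
>50% already at a 5-10% ratio in the slab systems).  At such volume
fractions the hydrophobic phase percolates into a single box-spanning
network (we verified this directly: at a 30% molecule ratio every
lipopeptide joins one connected aggregate within a few thousand steps and
stays there), which contradicts the behavior the model is supposed to
show — discrete micelles surrounded by water, molecules diffusing to and
saturating a PLA layer.  No water-continuous morphology is possible above
~50% solute volume regardless of force field, so the literal reading is
internally inconsistent with the described outcomes.

The builders therefore support two percentage bases.  `pct_basis=
"molecules"` (the default) implements the literal reading.  `pct_basis=
"beads"` counts solute beads against water beads (30% -> 23% solute
volume), which keeps every stated concentration in the water-continuous
regime.  The shipped scenarios and headline measurements apply a
per-condition rule: the literal basis wherever it remains
water-continuous (the 3% solution runs, at 26% solute volume, form
micelles exactly as described), and the bead basis where the literal one
is inconsistent with the described behavior (the 10% and 30% solutions;
the whole 1/5/10% slab series, kept on one basis for comparability).
Under the bead basis the 30% runs reproduce the expected phenomenology:
~5 nm spherical Pam1CSK4 micelles, and a wormlike Pam3CSK4 network
coexisting with small spherical micelles.

Chains grow as random walks with bond length r_c/2; overlaps are allowed
(soft cores) and relaxed by a 100-step warm-up at dt/10 before
production.  Velocities are Maxwell-Boltzmann at kT = 1 with net momentum
removed.  Note that these nominal compositions are far more concentrated
than the laboratory process they mimic (the solute occupies tens of
percent by volume); this is a property of the study conditions
themselves, discussed under Limitations.

## Estimators

The study reports sizes and localization that were originally read off
renderings; here each observable is an explicit, configurable estimator:

* **Clusters**: connected components of molecules whose filtered beads
  (default: hydrophobic species) lie within a cutoff (default 1.0 r_c,
  the interaction range) under the minimum image.
* **Centers under PBC**: circular-mean (angle-average) centers, followed
  by minimum-image unwrapping — all metrics are invariant to periodic
  shifts.
* **Micelle diameter**: sphere-equivalent gyration diameter
  `2 sqrt(5/3) R_g` (exact for a uniform ball), reported in nm.
* **Shape**: gyration-tensor eigenvalues l1 >= l2 >= l3; wormlike when
  sqrt(l1/l3) > 3, else sphere; degenerate tensors count as wormlike.
* **Bilayer thickness**: `2 sqrt(3 l3)` — the slab-equivalent full width;
  the constant is fixed by the uniform-slab second moment
  (l3 = (t/2)^2/3 for full width t) and verified against that closed
  form in the tests.  A box-spanning wormlike network has no meaningful
  global gyration, so its thickness is measured locally: the same
  slab-equivalent form applied to the smallest second-moment eigenvalue
  of the aggregate beads inside probe balls (median over probes, probe
  radius adapted to ~1.3x the estimate in a second pass), verified
  against a synthetic percolating slab.
* **Nanoparticle diameter**: twice the radius where the radial density
  profile of LA beads about the particle center first falls below half
  its core plateau (bin width 0.5 r_c); clusters under 100 beads fall
  back to the gyration diameter, flagged as such.
* **Encapsulated fraction**: a solute molecule is *inside* if any bead is
  within the cutoff of a host LA bead, *micelle* if it sits in a
  solute-only cluster of >= 3 molecules, else *free*.
* **Water exclusion**: W density inside half the particle radius over the
  box-average W density (~1 for mixed, ~0 for a dry core).
* Aggregates whose unwrapped extent reaches the shortest box edge
  (percolating clusters) have no meaningful gyration diameter and are
  excluded from size statistics — at high solute fractions the
  hydrophobic phase can span the box, and pretending such a network has
  a "diameter" would corrupt the averages.

Headline observables are averaged over the final 20% of snapshots with a
standard deviation.

## Problem sizes

Full-size geometries (280^3 Å, ~2.4e5 beads; 300 ns slab runs) are
supported but are multi-hour jobs on one core.  The shipped drivers,
tests and the acceptance script use desk-scale versions chosen once:
concentrated-solution runs in a ~130 Å box (~20 r_c, ~24.5k beads) for
3,334 steps (10 ns of represented time); dilute runs in a 100 Å box for
2,000 steps; droplet runs with a 55 Å droplet in a 130 Å box for 1,500
steps; slab runs with a 40 Å layer in a 250x60x60 Å box for 5,000 steps.
These keep every observable's physics (micellization, collapse,
adsorption, layer saturation) while fitting interactive time budgets.

## Limitations

* The nominal compositions, taken verbatim from the study design, are
  extremely concentrated once expressed in bead-volume terms (e.g. at a
  30% molecule ratio the lipopeptide occupies ~3/4 of the bead volume;
  the droplet interior is ~95% PLA by bead count).  In this regime the
  hydrophobic phase can form a single percolating network rather than
  discrete micelles, and size estimators then report only the
  non-percolating aggregates.  The laboratory systems they mimic are far
  more dilute; conclusions transfer qualitatively, not quantitatively.
* DPD time is not physical time; only ordering/ensemble observables are
  compared, never kinetics.
* No electrostatics: the lysine charge is implicit in the repulsion
  table.
* The generator emulates compositions and densities, not the
  acetone/ethanol co-solvent of the laboratory nanoprecipitation (the
  model's droplet is aqueous), nor polymer polydispersity (all chains are
  exactly 70-mers).
* Wormlike-aggregate thickness is underestimated: the model's flexible
  chains (no angular stiffness) coil, so the Pam3CSK4 wormlike phase
  forms thin cylinders (~3 nm local width, round cross-sections) rather
  than the ~5.3 nm flattened bilayers seen by small-angle X-ray
  scattering, which presume extended, aligned lipopeptides.  Micelle
  diameters, which depend on aggregate packing rather than single-chain
  extension, come out quantitatively right.
* Drug release and long-time ripening are out of scope: the soft-core
  model over-accelerates demixing, which is why encapsulation happens
  within nanoseconds of represented time.
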