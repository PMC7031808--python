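# Methods

`sdpfit` implements a joint small-angle x-ray and neutron scattering
(SAXS/SANS) analysis of peptide-doped lipid bilayers in the
scattering-density-profile (SDP) framework, together with the synthetic-data
machinery needed to validate every stage by round-trip recovery, and a small
geometric utility for classifying peptide dimers in coarse-grained
trajectories.  This note records the model, its assumptions, the default
numbers, and the design choices that were genuinely open.

## The SDP unit cell

The bilayer is described per *unit cell*: a column of cross-section `A_U`
(the area per averaged lipid) containing one lipid per leaflet, a peptide
share of `P:L` peptides per lipid, and water.  The membrane normal is `z`,
with `z = 0` at the midplane; leaflets are strictly symmetric (peptides are
assumed to partition fully and distribute equally between leaflets).

Each quasimolecular group `i` (volume `V_i`, multiplicity `m_i` per lipid)
is a mirrored pair of Gaussian volume-probability functions

    P_i(z) = V_i m_i / (A_U s_i sqrt(2 pi)) [ exp(-(z-z_i)^2 / 2 s_i^2)
                                            + exp(-(z+z_i)^2 / 2 s_i^2) ]

so that its full-bilayer integral is exactly `2 V_i m_i / A_U`.  The
hydrocarbon core is an error-function envelope of half-width
`D_C = V_HC / A_U` (volume closure: `V_HC` is the summed chain volume per
lipid) and interfacial width `sigma_HC`; the methylene probability is the
envelope minus the CH and CH3 Gaussians, so the core is filled exactly and
the CH2 term never needs its own normalisation.  Water is the complement,
`P_W = 1 - sum_i P_i`.

The POPE/POPG (3:1 mol/mol) membrane is parsed as one *hybrid* lipid:
chains (CH2 x 28, CH3 x 2, one CH group at the oleoyl double bond), carbonyl
glycerol (CG) and phosphate (PO4) are shared at common positions, while the
two headgroup identities keep independent groups — ethanolamine (ENX) with
multiplicity 0.75 and headgroup glycerol (PG2) with multiplicity 0.25.
Adsorbed peptides are one Gaussian at `z_p` with width `sigma_p` and volume
`V_P (P:L)` per leaflet; an equimolar two-peptide mixture is merged into a
single Gaussian with mole-fraction-averaged composition and the summed P:L.

### Scattering contrast

X-ray work uses electron densities `n_e / V` (e/A^3) with an arbitrary
per-dataset intensity scale; neutron work uses coherent scattering-length
densities from a standard table (b_H = -3.7406 fm, b_D = 6.671 fm, etc.).
Labile hydrogens are assumed to exchange completely with the solvent, so a
group with `n_exch` labile H at D2O mole fraction `x_D` has
`b(x_D) = b_H + n_exch x_D (b_D - b_H)`; the solvent itself is water of
volume `V_W = 30.0 A^3` (35 degC; linear in T with slope 0.0093 A^3/K).
Peptide *volumes are inputs* (defaults `V_L18W-PGLa = 4927.8 A^3`,
`V_MG2a = 5748.0 A^3`, the experimentally determined totals); residue-volume
table sums are deliberately not attempted because such tables are not
consistent with measured whole-peptide volumes.

### Form factor and intensity

For dilute vesicles analysed at `q > 0.05 1/A` (above the vesicle-scale
regime) the intensity is `I(q) = scale |F(q)|^2 / q^2 + background` with the
flat-bilayer amplitude evaluated in closed form: each mirrored Gaussian
contributes `2 (V m / A_U) drho cos(q z) exp(-q^2 s^2 / 2)`, the envelope
contributes `2 drho_CH2 sin(q D_C)/q exp(-q^2 sigma_HC^2/2)`, and CH/CH3
carry their contrast relative to CH2 to reproduce the subtraction
construction exactly.  The test suite pins the analytic amplitude to a
numerical cosine transform of the real-space contrast profile at 1e-6 of
the amplitude maximum.  SANS resolution smearing (Gaussian in q) is
available but off by default; the fitted window and the smooth synthetic
curves make it a second-order effect.

## Joint ensemble fitting

One structure is fitted simultaneously to four contrasts (SAXS; SANS at
100/75/50% D2O).  The cost is the weighted joint chi-square over the fitted
q-windows.  Per-dataset `scale` and flat `background` are profiled
analytically (weighted linear least squares, scale constrained positive),
so they never enter the search space.  Two soft penalties keep the model
physical: quadratic penalties on total volume probability exceeding
1 + 0.02 and on methylene probability dropping below -0.02 (weight 1e4).
The 2% tolerances reflect that an adsorbed peptide Gaussian legitimately
overlaps the lipid envelope by a percent or two in this parameterisation;
violations beyond that are penalised, never silently clipped.

Default free parameters: `A_U`; `z`/`sigma` of ENX, PG2, PO4, CG;
`sigma_HC`; and `z_p`, `sigma_p` when peptide is present.  Group volumes,
the CH/CH3 widths and the CH position fraction (`z_CH = 0.45 D_C`) are
fixed by configuration — standard SDP practice that keeps the problem
determined with four contrasts.

The global optimiser is a genetic algorithm (population 64, tournament
selection of 3, uniform crossover p = 0.7, per-gene Gaussian mutation
p = 0.1 with step 0.1 of the parameter range annealed by 0.985 per
generation, elitism 2, up to 300 generations with early stopping).
Robustness and uncertainties come from an *ensemble* of independent runs
with random starting populations (400 is the customary production size for
experimental data; the shipped tests and the acceptance script use 40,
which this package's calibration experiments show is sufficient for the
second-moment uncertainties to cover the generating values).  Reported estimates are the
center of mass of each parameter's distribution over runs; uncertainties
are square roots of second central moments.  Derived quantities (below) are
computed run-by-run and aggregated the same way.  Run seeds are spawned
once from the base seed, so serial and parallel execution give bit-for-bit
identical ensembles.

Two local refinements are available and *off* by default: a scalar polish
inside the GA (`GAConfig(polish=True)`, L-BFGS-B from the run's best) and
`JointSDPModel.polish`, a trust-region least-squares refinement
(scipy `least_squares`/TRF on the weighted residual vector) that descends
the narrow chi-square valleys far more effectively than any scalar method.
They stay off for ensembles because polishing collapses the runs into the
few deepest minima and destroys the ensemble-spread uncertainty measure;
GA-multistart + TRF polish is the protocol for convergence checks such as
the noise-free round trip.

## Derived structural parameters

* Luzzati thickness `D_B = 2 V_LP / A_U`, with `V_LP = V_L + (P:L) V_P`;
  identical (to quadrature accuracy) to the water-deficit integral
  `int (1 - P_W) dz`.
* Hydrocarbon half-thickness `D_C = V_HC / A_U` (outer edge of the
  methylene region).  `2 dD_C` vs. the peptide-free reference is the
  peptide-volume-free measure of membrane thinning.
* Headgroup distance `D_HD = z_PO4 - z_CG`, a projected headgroup-tilt
  proxy.
* Peptide position `z_p`.

Delta tables against a reference system round to 1 decimal (the convention
used when quoting changes); report tables print 2 decimals.

Thermal-expansion analysis fits `A_U(T)` by ordinary least squares and
reports the slope with its standard error; temperature series are expected
to come from reduced SAXS-only fits (limited structural resolution), with
lipid and water volumes moved along configurable linear temperature
coefficients.

## Synthetic studies

The generator emulates the four-contrast experiment: SAXS over
q = 0.0098-0.9 1/A (400 log-spaced points) and SANS at 100/75/50% D2O over
q = 0.005-0.42 1/A (150 points each), with multiplicative Gaussian noise of
1% relative sd (the data-quality regime of a modern synchrotron/reactor
experiment) and a sigma floor of 1e-6 of the curve maximum.  Ground-truth
parameter sets are shipped for the four studied systems, encoding the
reported `A_U`, `D_HD` and `z_p` of each (pure: A_U = 60.56 A^2,
D_HD = 4.19 A; +L18W-PGLa: 61.26, 4.07, z_p = 15.75 A; +MG2a: 62.00, 3.80,
16.29; mixture: 63.29, 4.45, 15.98; P:L = 1:200).  Gaussian widths and the
ENX/PG2 positions are not printed per system, so the shipped values are
package defaults chosen once from the POPE/POPG SDP literature; default
chain volumes (V_CH2 = 27.5, V_CH3 = 55.0, V_CH = 50.0 A^3 per group) give
V_HC = 930 A^3 and hence D_C within ~0.05 A of the reported values at the
reported areas.

What the generator does *not* emulate: instrument resolution smearing,
counting-statistics (Poisson) noise shapes, vesicle polydispersity and
multilamellarity (irrelevant above q = 0.05 1/A), and incoherent-background
structure.  Passing round trips therefore demonstrate correctness of the
model/fit machinery under the stated noise model, not robustness to every
instrumental artefact of real data.

## Identifiability, tolerances, numerical choices

On noise-free four-contrast data the model is fully identifiable: GA
multistart followed by the trust-region least-squares polish drives the
joint cost to numerical zero and recovers *every* free parameter to well
under 0.5% (peptide position to ~1e-3 A).  At realistic noise the
identifiability is hierarchical: `A_U`, `z_PO4`, `z_CG`, the core widths
and `z_p` stay sharply determined, while the minority outer-headgroup
groups ENX (0.75/cell) and PG2 (0.25/cell) overlap at similar contrast and
develop broad, strongly correlated ensemble distributions — their large
second-moment uncertainties are the honest statement of that.  With 1%
noise the 40-run ensembles recover the generating `A_U`, `D_HD` and `z_p`
within about one ensemble SD in all four systems.

Other numerical conventions: Gaussian widths are floored at 1 A (narrower
features are below the resolution of the fitted q-range); q = 0 is excluded
(the amplitude's q -> 0 limit exists but the 1/q^2 Lorentz factor does
not); the packing penalty is evaluated on a 0.5 A grid to z = 45 A; the
dimer classifier breaks an exact 90-degree axis angle toward antiparallel,
uses the five marker pairs {COM-COM, N-N, C-C, N-C, C-N} in its
">= 2 within 1 nm" criterion (the distance set is configurable because the
original rule does not enumerate the cross terms), and pairs peptides
greedily and exclusively by ascending COM distance so trimeric contacts are
not double-counted.

## Problem sizes used by the shipped tests

The test suite and `scripts/acceptance.py` run 40-run ensembles with the
GA capped at 200 generations (annealing 0.98) — roughly two minutes per
system on one core — and quadrature oracles on 0.01-0.02 A grids.  These
sizes are the package's validation defaults; production analyses should use
the full 400-run ensemble (`n_runs=400`) and, if desired, more generations.

## Known limitations

* Symmetric leaflets only; no asymmetric peptide partitioning.
* Single-Gaussian peptide envelope; no peptide form factor or orientation.
* No interbilayer structure factor (valid for dilute, non-aggregating
  vesicles only) and no vesicle-scale low-q model.
* Moment-based ensemble uncertainties, not Bayesian posteriors; they
  quantify optimiser-ensemble spread on one dataset, which the calibration
  experiments show behaves conservatively here, but they are not confidence
  intervals in the frequentist sense.
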