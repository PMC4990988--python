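# Methods

This note documents the models, conventions, parameter choices and known
limitations of `lirquant`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## Equilibrium models

All concentrations are µM throughout the package; unit conversion is the
caller's job at I/O boundaries.

**Single site.** R + L ⇌ RL with K_d = [R][L]/[RL]. The solver returns the
smaller root of the binding quadratic in the numerically stable form
2R₀L₀/(b + √(b²−4R₀L₀)), b = R₀+L₀+K_d, which is exact in the degenerate
limits (no ligand, infinitely tight binding).

**Two-ligand competition.** One receptor, two mutually exclusive ligands.
Writing the free-ligand concentrations as A_f = A₀/(1+R/K_A) (and likewise
B_f), the receptor mass balance R(1 + A_f/K_A + B_f/K_B) − R₀ is strictly
increasing in R on [0, R₀] and brackets a sign change, so Brent's method
converges unconditionally; tolerance 1e-12 µM. No initial guess is needed —
this is why a bracketed scalar solve was chosen over a multidimensional
root-find on all five species.

The bound-species ratio RA/RB returns an infinite sentinel (not an
exception) when RB = 0 so titration sweeps through degenerate corners do
not abort. At the competition-assay conditions (5 µM receptor, 5 µM of each
peptide, K_d 3.2 and 10.9 µM) the predicted ratio is 2.44. This is
deliberately *not* asserted to equal the observed 3:1 bound-species
abundance: the equilibrium prediction under ligand depletion, the unknown
relative gas-phase response factors of the two complexes, and the
uncertainty on both constants (±1.1 µM maps to a ratio interval of roughly
1.8–3.5) all make "consistent with 3:1, point estimate > 2" the defensible
statement. Response-factor scaling is exposed in the spectrum synthesizer
so both the raw and scaled ratios can be produced.

## ITC

**Heat model.** Perfusion (constant-volume overflow) convention of
cell-feedback calorimeters: each injection dV into cell volume V₀ scales
pre-existing total concentrations by (1 − dV/V₀); freshly delivered
injectant carries the (1 − dV/2V₀) first-order mid-injection correction.
Observed heat of injection i:

    ΔQ_i = Q_i − Q_{i−1} + (dV_i/V₀)(Q_i + Q_{i−1})/2 + q_mix,
    Q_i  = [RL]_i · ΔH · V₀,   [RL]_i from the quadratic with site
                               concentration n·[receptor]_i.

q_mix is a single constant per titration (a buffer-mismatch heat), fitted
as a nuisance parameter, not proportional to injection volume. The
simulator and the fitter share this convention exactly; noise-free
round-trip recovery to 1e-4 relative is a regression test, and the model is
checked against an independently coded closed-form (Wiseman-style) isotherm
evaluation to 1e-9.

**Default design.** 1400 µL cell, 30 µM receptor, 25 × 10 µL injections of
350 µM peptide. A 15 µM starting concentration is also in circulation for
this system; 30 µM is the default here and any value is selectable through
`TitrationSchedule`. Default synthetic noise is Gaussian with σ = 2% of the
largest |heat| — a "high-quality isotherm" level; no instrument noise
figure is available to calibrate against.

**Ground-truth enthalpies.** No numeric ΔH values are published for this
peptide pair, only that the mutant's enthalpy of interaction is
substantially reduced. The simulation presets use −9000 cal/mol (WT) and
−5500 cal/mol (L341V), typical of low-µM peptide–protein exotherms. Because
the noise level scales with the largest heat and all heats are proportional
to ΔH (with q_mix = 0), the K_d-recovery statistics are exactly invariant
to this choice — it sets the scale of the plot, not the difficulty of the
fit.

**Fitter.** Levenberg–Marquardt least squares over (log K_d, ΔH, n, q_mix);
the log parameterization enforces K_d > 0 without constraints. Standard
errors come from the Gauss–Newton curvature at the optimum scaled by the
residual variance, with the K_d error mapped back by the delta method.
First-injection discard is available but off by default. The Wiseman
parameter c = n[R]₀/K_d is reported and a warning is raised outside
[1, 1000].

**Known statistical limitation.** At the mutant condition c ≈ 2.8 and the
titration reaches only ~2.3 molar equivalents, so the isotherm constrains
K_d weakly: large-K_d fits can be compensated by inflated |ΔH|, n and
q_mix. Profile-RSS scans confirm such outlier fits are genuine global
optima, not optimizer failures. The consequence is a right-skewed K_d
sampling distribution with a mean bias of roughly +5% at 2% noise; a
30-replicate mean can land just outside ±10% of truth. The package reports
the estimator honestly rather than constraining n or trimming outliers;
median-based summaries are markedly more robust (median bias < 1%).

## Native MS

Peptide masses are residue-table sums plus one water (monoisotopic and
average tables embedded from the standard proteomics values); m/z follows
the positive-ion convention (M + z·1.007276)/z. Spectra are rendered as
Gaussians on a regular m/z grid (default 500–4000, step 0.02) with area ∝
concentration × response factor; no isotope envelopes, adducts or
charge-state distributions. The abundance-ratio extractor integrates
baseline-subtracted trapezoids in symmetric windows around the two complex
peaks.

The receptor construct's exact mass is not published; the generators use a
synthetic stand-in of 14.6 kDa (configurable), which places the 9+ complex
peaks 1.56 m/z apart. The generator therefore defaults to σ = 0.2 m/z peaks
(the synthesizer's own default is 0.5) so that ±0.6 m/z windows are
non-overlapping; round-trip closure (synthesize → extract vs equilibrium
ratio) holds to 1%.

## NMR CSP

Weighted CSP: √(Δδ_H² + (Δδ_N/5)²); the 1/5 nitrogen scaling is exposed as
a parameter. Classification thresholds are strict inequalities, > 0.5 ppm
(moderate) and > 1.0 ppm (strong). The differential map is the signed WT −
mutant difference per shared residue; the selection threshold for
"substantially different" is a package decision (default |ΔΔδ| > 0.1 ppm,
configurable and recorded in output) — no published numeric criterion
exists. Residues missing from either list are excluded, never zero-filled.

Peak tracking pairs by residue label by default; an unlabeled mode assigns
by greedy nearest-neighbour in the (1, 1/5)-weighted metric under a
one-to-one constraint and is verified against exhaustive optimal assignment
on lists of ≤ 8 peaks. Greedy matching can differ from the global optimum
on adversarial geometries; for titration-sized displacements they coincide.

The count-structured presets (`preset_csp_maps`) embed, by construction, 19
residues above 0.5 ppm of which 9 exceed 1.0 ppm, and a mutant map
differing at exactly 8 residues. They validate the counting and
classification machinery; the per-residue magnitudes are synthetic, since
only graphical per-residue data exist for this system.

Structure annotation writes class codes 0/1/2 into the B-factor column of a
PDB copy (gemmi), matching residues by author sequence number across all
chains.

## Colocalization

Costes thresholds: orthogonal (total-least-squares) regression ch2 =
a·ch1 + b over the masked voxels, then a scan of T1 descending through the
*sorted unique* intensities of channel 1 with T2 = a·T1 + b, returning the
largest pair for which voxels below both thresholds have Pearson r ≤ 0.
Exact unique-value descent (no binning) keeps the procedure deterministic
and equal to an exhaustive-scan oracle, which is asserted on ≤ 4096-voxel
fixtures. If no candidate achieves r ≤ 0 the channel minima are returned
with a warning flag.

Per cell, the primary PCC is computed over in-mask voxels above both
thresholds (minimum 20 voxels, else an undefined-result marker); the
whole-mask global PCC is always co-reported, since which variant commercial
software reports is ambiguous. Correlation treats voxels isotropically —
it is dimensionless — and the voxel size is carried only for generator
realism.

Group statistics: one-way fixed-effects ANOVA from between/within sums of
squares (cross-checked against an independent implementation in tests), all
pairwise pooled-variance t contrasts with Šidák adjustment
p_adj = 1 − (1−p)^m. Identical groups yield F = 0, p = 1; zero within-group
variance with distinct means yields an infinite-F sentinel. The null
calibration of the F test (type-I error at α = 0.05 within [0.03, 0.07]
over 1000 simulated null datasets) is part of the acceptance suite. A
balanced two-factor ANOVA (`two_way_anova`) serves replicate blot designs,
with many-to-one Dunnett-style contrasts approximated by Šidák adjustment.

**Imaging generator.** Cells are elliptical masks (default stack 8×64×64,
voxels 0.2×0.1×0.1 µm) containing 40 point puncta blurred by a Gaussian PSF
(σ = 0.7, 1.3, 1.3 voxels) over a diffuse cytoplasmic background; a
fraction `f_acidic` of puncta is red-only (acidified vesicles — EGFP
quenched), the remainder emit in both channels with tightly correlated
amplitudes (green gain 0.8, 3% proportional jitter). Shot noise is
approximated as Gaussian with variance equal to the mean, rounded to
integer counts — adequate above ~20 counts and convenient because integer
intensities keep the Costes unique-value scan small. Condition presets
encode the reporter biology by `f_acidic` alone: WT 0.60 > L341V 0.35 >
BafA1-treated arms (0.08/0.05), with rapamycin-treated mutant at 0.55
(restored toward WT). What the synthetic images do *not* contain: real PSF
anisotropy/restoration artefacts, vesicle size distributions, cytoplasmic
autofluorescence structure, cell-to-cell expression variability beyond
punctum-amplitude jitter. Passing the direction-of-effect tests therefore
shows the thresholding/correlation/statistics machinery responds correctly
to acidic-fraction differences, not that real cells would produce these
PCC values.

## Blot normalization

Per construct: subtract the control-bead density from each specific-bead
density, divide target signals by the construct's own background-corrected
glutathione (input) signal, then divide by the WT values so WT ≡ (1, 1).
Lanes whose control reaches the glutathione signal are rejected with a
diagnostic. The generator inverts this chain exactly (zero-noise round trip
is exact) and applies mean-one lognormal multiplicative noise per band.
Lane tracing of gel images is out of scope; band areas are the input
currency.

## Reproducibility

Every generator is a deterministic function of (parameters, seed); master
seeds fan out through numpy `SeedSequence.spawn`, and each dataset carries a
`GroundTruth` record sufficient to regenerate it bit-identically. Problem
sizes used by the validation suite — 30 ITC replicates per arm, 50 cells ×
4 conditions, 1000 null ANOVA datasets — were chosen as the smallest
designs that pin down the respective statistics; the whole suite runs in
well under a minute except the imaging study (~10 s).
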