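# Methods

## Scope and data model

The package implements the standard lattice-field 3D-QSAR chain for a
pre-aligned congeneric series: structures with per-atom physicochemical
properties → field descriptors on a cubic lattice → PLS with leave-one-out
(LOO) cross-validation → external validation → robustness and domain
checks → contour maps. Inputs are SDF (V2000) or TRIPOS MOL2 structures
(coordinates in Å, assumed minimized and aligned; conformer generation and
geometry optimization are out of scope) plus an activity table (EC₅₀ in µM
or pEC₅₀; pEC₅₀ = 6 − log₁₀ EC₅₀[µM]).

Per-atom properties: partial charges are Gasteiger–Marsili by default
(charges present in the input file can be kept instead); hydrophobicity is
the Ghose–Crippen atomic logP contribution; van der Waals radii are the
Bondi set; H-bond flags follow simple rules — donor: any H on N/O/S (flag
carried on the heavy atom and its hydrogens), acceptor: N or O with an
available lone pair, excluding quaternary and nitro nitrogens.

An optional rigid Kabsch superposition (SVD, ≥3 non-collinear mapped atom
pairs) is provided for series that are not yet in a common frame.

## Fields

The lattice spans the union bounding box of the series plus 4 Å padding on
every face, spacing 2 Å, with the origin snapped down to integer multiples
of the spacing so that translated replicas of a dataset produce identical
columns.

* CoMFA steric: LJ 6-12, E = ε[(rₘ/r)¹² − 2(rₘ/r)⁶] with rₘ = R_atom +
  R_probe, ε = √(ε_atom·ε_probe), probe ε = 0.107 kcal/mol (sp³ C), atom
  well depths from a Tripos-style table. Truncated to ±30 kcal/mol.
* CoMFA electrostatic: 332.0636·qᵢ·q_probe/(ε(r)·r) with ε(r) = r, i.e.
  ∝ 1/r²; r is floored at 10⁻⁶ Å. Same truncation. At lattice points where
  the steric energy hits the cutoff (inside the van der Waals envelope)
  the electrostatic value is masked and imputed with the column mean over
  the unmasked molecules; the mask is retained on the block.
* CoMSIA: A_k(q) = −Σᵢ w_probe,k·w_ik·exp(−0.3·r²) for steric (w = r³_vdW),
  electrostatic (partial charge), hydrophobic (logP contribution), donor
  and acceptor (binary flags); probe radius 1 Å, all probe weights +1.
  No truncation. H-bond fields use atom-centred flags, not extended
  pseudo-atom placements.

The dielectric model, padding and LJ parameter table are documented
package choices — commercial implementations do not publish theirs, so
absolute CoMFA energies are not comparable across programs; all numeric
guarantees here rest on closed-form kernel tests and on statistics
downstream of the descriptors.

## Preprocessing and PLS

Columns whose training-set standard deviation (sample sd, in the column's
native units) falls below the filter threshold are dropped; the default
threshold 2.0 is an energy-scale (kcal/mol) setting appropriate for CoMFA
fields. The CoMSIA similarity indices of the small synthetic
pseudo-molecules live on a unitless scale well below 2, so the synthetic
CoMSIA analyses disable the filter (threshold 0); the filter contract
itself is unit-agnostic and fully configurable. After filtering, each
field block is scaled by the inverse of its overall sd (CoMFA-STD) so no
block dominates by magnitude; "none" is available.

The regression is NIPALS PLS (scikit-learn backend, no per-column
autoscaling) with coefficients reported in the native column space.
LOO cross-validation refits the column filter and scaling inside every
fold. q² = 1 − PRESS/Σ(yᵢ−ȳ)² with ȳ the full training-set mean; SEP =
√(PRESS/(n−N−1)); SEE = √(RSS/(n−N−1)); F = (r²/N)/((1−r²)/(n−N−1)).
The optimal component count maximizes q², ties broken towards fewer
components, capped at ⌊n/3⌋. Sample-distance shortcuts (SAMPLS) are not
implemented; the LOO loop is the definition and is tested against a
literal from-scratch refit loop at 10⁻¹⁰.

Per-field contributions are Σ|coef_j|·sd_j over the block's retained
columns, normalized across blocks (invariant to block rescaling).

Model selection enumerates non-empty field subsets (3 for CoMFA, 31 for
CoMSIA; the ten named combinations of the source study ship as a preset),
gates on q² > 0.5 and ranks by test-set r², ties by q².

## External validation

On test-set experimental x and predicted y: r² is the squared Pearson
correlation (this convention — not 1 − PRESS/SD — reproduces the published
values; the PRESS-based predictive r² is reported separately as
`r2_press`). Through-origin regressions give k = Σxy/Σx², r0² = 1 −
Σ(y−kx)²/Σ(y−ȳ)², and the primed pair with roles swapped. Conditions:
q² > 0.5, r² > 0.6, (r²−r0²)/r² < 0.1 (either orientation), 0.85 ≤ k ≤
1.15 (either), |r0²−r0′²| < 0.3. rm² is reported in both circulating
variants — abs: r²(1−|r²−r0²|), sqrt: r²(1−√(r²−r0²)) — with sqrt as the
default: it reproduces the published CoMSIA value (0.843) from unrounded
intermediates, which the abs form does not. Residuals are experimental −
predicted; |residual| > 0.4 log units flags an outlier (0.4 is the
smallest round threshold that reproduces exactly the published outlier
sets {18, 23} and {40, 41}), and metrics are computed both with and
without flagged compounds — the outlier-excluded variant is the one that
matches the published summary table.

## Y-randomization

Activities are permuted uniformly (per-iteration seeds spawned from one
master seed), the whole pipeline including LOO is refit, and q²/r²_ncv are
recorded per iteration (default 10). The original component count is
reused by default (`reselect_n` switches to re-optimizing per iteration).
The strict verdict requires q² < 0.5 and r²_ncv < 0.6 in every iteration;
note that with N at the ⌊n/3⌋ cap the randomized *training* r²_ncv can
exceed 0.6 on small sets even when q² separation is total, so the
scientifically load-bearing check is that every randomized q² falls below
0.5 and below the true model's q².

## Applicability domain (standardization approach)

S_ik = |x_ik − mean_i|/sd_i with training statistics (sample sd;
zero-variance columns dropped with a warning). Decision: s_max ≤ 3 →
inside; s_min ≥ 3 → outside; otherwise S_new = S̄_k + 1.28·σ(S_k), inside
iff S_new ≤ 3. The published description of the S_new branch is garbled;
the implemented rule follows the cited standardization-approach method,
whose reported outcome presupposes exactly this decision. σ uses the
sample convention, switchable to population.

## Contour maps

Per retained column, the display value is PLS coefficient × training sd;
filtered columns carry 0. Σ|voxel| per field equals the unnormalized field
contribution, tying the maps to the contribution computation. Contour
levels default to the 80th/20th percentiles of the nonzero voxel values
(linear interpolation between order statistics). Export: OpenDX (via
gridDataFormats) and Gaussian cube (hand-written; lengths converted to
bohr, values in C order with z fastest).

## Synthetic generator

The generator emulates the statistical structure the method assumes: a
rigid 6-carbon scaffold (lattice-commensurate coordinates, so substituent
sites sit on grid points and map hotspots are directly interpretable),
three fixed substituent sites, and an 8-template substituent library
(H, C, N, O, F, S, Cl, Br with Bondi radii, small charges, logP
contributions and H-bond flags; all radii distinct). Activity = 1.5 +
2.0·R_vdW(site 0) − 3.0·q(site 1) + 1.5·logP(site 2) + N(0, noise²),
defaults: 41 molecules, noise sd 0.1, activity span ≈ 3.5–4 log units,
29/12 stratified train/test split — the shape of the study this generator
stands in for. Effects are planted on atomic properties rather than on
descriptor columns, so end-to-end recovery exercises the field engines,
not just the regression.

What the generator does **not** emulate: real valence chemistry,
conformational flexibility, correlated substituent effects, alignment
error, or activity cliffs. Passing recovery tests therefore demonstrates
that the pipeline is numerically correct and can find planted localized
signal; it does not certify performance on real series.

## Problem sizes and numerical choices

The default synthetic study produces a 9×8×6 = 432-point grid, ~200–450
retained CoMFA columns and 2160 CoMSIA columns; a full pipeline run
(fields, LOO over 9 component counts, validation, domain, contours) takes
seconds on one CPU, and the whole test suite runs in well under a minute.
Degenerate guards: grids have ≥2 points per axis; Coulomb distances are
floored at 10⁻⁶ Å; all-dropped column filters raise with advice to lower
the threshold; through-origin statistics require Σx² > 0 and non-constant
y. Ties in component selection go to the smaller N. The LOO q² reference
mean is the full training mean (computed once), the convention matching
the published q² definition.

## Known limitations

* Absolute CoMFA field values are not comparable to Sybyl's (undocumented
  vendor parameters); only the published per-compound activity tables,
  which ship as fixtures, are reproduced numerically.
* PLS predictions are not invariant to duplicating a *subset* of columns
  (that changes the covariance structure); only whole-matrix duplication
  (≡ global rescaling) is.
* The 2 Å lattice bounds how precisely map hotspots can localize planted
  sites: first-shell neighbours sit at exactly one spacing, diagonal
  second-shell voxels at √2 spacings, so halo-shaped fields necessarily
  spread their top decile beyond one spacing.
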