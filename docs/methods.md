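# Methods

This note records the scientific and numerical choices behind `ciflint`:
what each check computes, the defaults and why, what the synthetic-data
generator does and does not emulate, and known limitations.

## Conventions

Fractional coordinates throughout; operator translations reduced to
[0, 1); the Cartesian frame has **a** along *x* and **b** in the
*xy*-plane. Intensities are F² on a common scale with σ(F²) > 0; negative
F² are preserved as read and clamped only where a formula requires it
(|Fo| in R1, the P term of the weighting scheme). s = sin θ/λ (Å⁻¹),
d = 1/(2s).

## Symmetry engine

Hall symbols are decoded (lattice letter, optional leading `-` for a
centre at the origin, rotation fields with the implied-axis rules, screw
and glide suffixes, origin shifts in twelfths) and the generators are
closed under composition in an exact integer representation (translations
in 24ths mod 24; closure capped at order 192). The closure is the
authority for everything downstream: centrosymmetry, crystal system
(classified from the proper-rotation content of the point group), the Laue
group used for merging, and extinction conditions (h extinct iff some
operator has hR = h with h·t not integral). The package's own expansion is
cross-checked in the test suite against gemmi's independent tables over
all tabulated settings, and expanding the 230 standard settings yields 230
distinct canonical operator sets.

The Hermann–Mauguin ↔ Hall correspondence table is materialised at import
time from gemmi's space-group tables rather than stored as a data file.
For Hall symbols that are not tabulated settings the HM↔Hall comparison
is skipped and said so in the report (the boundary of "uncommon
non-standard settings" is drawn at table membership).

Cell-metric consistency uses the constraint set of the crystal system
determined **from the operators** (never inferred from metric
pseudo-symmetry), with tolerance max(3·su, 0.002 Å / 0.02°). The
monoclinic unique axis is read off the two-fold direction.

Site symmetry order (sso) is counted by enumerating operators that fix the
site within a Cartesian tolerance (default 0.01 Å) modulo lattice
translations; ssm = nsym/sso and SOF = occupancy/sso. `s_uvw` symmetry
codes encode translation + 5 per digit, hence only −5…4 are
representable; multi-digit extensions are rejected.

## Model checks

* Molecular weight sums bundled standard atomic weights over the
  non-bracketed formula only; density is ρ = Z·Mr·1.66054/V (g cm⁻³),
  compared at 0.01 g cm⁻³.
* The Hirshfeld rigid-bond test projects the CIF U tensor on the bond:
  z(U) = mᵀUm with m = N·Oᵀ·û (N = diag(a*, b*, c*)). Isotropic atoms
  project to Uiso itself. The su of Δ = |z_A − z_B| is propagated to first
  order from the U su's. Defaults: flag at 5σ, serious at 10σ,
  metal–ligand bonds relaxed to 12σ; all configurable and echoed with the
  finding. Hydrogens and disordered atoms are excluded from the scan.
* Connectivity: d < r_cov(A) + r_cov(B) + 0.4 Å (nearest image). Contacts:
  intermolecular d < r_vdW(A) + r_vdW(B) − 0.2 Å, classified H⋯H /
  O⋯O,O⋯N (missing-H signature) / halogen⋯halogen (informational) /
  other; symmetry-generated approaches short enough to be bonds are
  treated as polymeric links, not contacts. Radii come from gemmi's
  element tables (Bondi-style vdW, standard covalent).
* Centre of gravity: the unweighted centroid of each connected species
  must lie in [0,1)³; species with ≤ 3 non-H atoms (waters, counter-ions)
  downgrade to a note, and the suggested corrective translation is
  reported.
* Absorption: the linear coefficient is computed from the optical theorem,
  σ_atom = 2·r_e·λ·f″(λ), with f″ from the Cromer–Liberman computation in
  gemmi. This is photoabsorption only: it underestimates μ for the very
  lightest elements where incoherent scattering matters, which is
  acceptable for the factor-2 plausibility test on 1 − T (expected
  T = exp(−μt) over the crystal-dimension range). Anything the anomalous
  tables cannot cover degrades to "unverified", never a guess.
* Data-to-parameter ratio thresholds: below 10/8/6 give C/B/A for
  non-centrosymmetric structures, 12/10/8 centrosymmetric.
* Reported f′/f″ are compared at max(0.1, 10 %) against values computed at
  the reported wavelength (valid 1–100 keV).

## Reflection statistics

Merging groups reflections under the point-group rotations, adding the
Friedel relation only for centrosymmetric structures so that anomalous
(Bijvoet) signal survives merging in non-centrosymmetric ones. Group means
are inverse-variance weighted; R(int) = Σ|F² − ⟨F²⟩| / ΣF² over multiply
measured groups. Whether a file is merged is decided by Laue-orbit
redundancy, not by duplicate index triples.

Completeness counts symmetry-unique, non-extinct lattice points to the
resolution limit (ten equal-width shells); the headline number is taken at
s = 0.6 Å⁻¹ when the data reach it. A noise cutoff is suggested at the
first shell whose observed fraction (I > 2σ) drops below 30 %.

R1 is computed on F over the observed subset (default I > 2σ(I); the
criterion is configurable because upstream conventions differ, and the
report always states which was used); wR2 and S on F² over all data with
w = 1/[σ² + (aP)² + bP], P = (max(Fo²,0) + 2Fc²)/3. The analysis of
variance uses ten equal-population resolution bins and fixed Fc/Fc(max)
edges 0–0.1–0.2–0.4–0.6–0.8–1.0; K = ⟨Fo²⟩/⟨Fc²⟩ outside [0.8, 1.2] or
bin GooF > 2 are findings, but bins with fewer than 10 reflections are
never flagged (the statistic is χ²-noisy there). The normal-probability
plot fits the central 80 % of ordered weighted residuals against normal
order statistics (Blom plotting positions).

The absolute-structure estimate is a Parsons-style quotient fit:
q_o = (I⁺−I⁻)/(I⁺+I⁻) regressed on the calculated quotients of the x = 0
model via q_o = (1−2x)q_c, weighted by first-order-propagated variances;
pairs with |q_c| < 10⁻⁴ are dropped. x > 0.5 advises inversion;
|x − 0.5| < 2·su is indeterminate. The Bayesian (Hooft-style) treatment is
deliberately not implemented and the report labels the estimate
accordingly.

The fabrication screen fits σ² = c₀ + c₁I + c₂I² over positive
intensities; R² > 0.9999 together with an rms relative residual below 1 %
is "suspicious" — flagged as an indication, never proof. The 1 % limit
leaves room for the fixed-point rounding of reflection formats while
staying an order of magnitude below genuine counting-statistics scatter.
Plot data (1/σ vs log₁₀ I) are returned for illustration.

## Density maps

The difference synthesis ρ(x) = (1/V)·Σ(|Fo|−|Fc|)·e^{iφc}·e^{−2πih·x} is
evaluated by FFT after Friedel completion, with F(000) excluded, so the
map mean is exactly zero; the FFT equals direct summation to 10⁻⁸ on small
coefficient sets. The grid must be finer than d_min/3 (default step
0.2 Å). Excursions beyond the ±0.5 e Å⁻³ featureless bound grade C/B/A at
0.5/1.0/1.5 e Å⁻³; extrema within 1 Å of an atom with Z ≥ 20 are reported
separately as probable absorption artefacts. On-atom |ρ| > 0.5 e Å⁻³
(the featureless bound again) flags a possible atom-type error —
in the generator's wrong-atom-type fixture a C-for-N error produces
≈ +0.9 e Å⁻³ on the site against a ±0.1 noise floor. Residual density on
bonds is reported as a quality measure only under a spherical-atom
refinement. H-site support: as-is maps flag H below −0.2 e Å⁻³; omit-mode
maps require +0.2 e Å⁻³.

Voids: a voxel is blocked within r_vdW + probe (default 1.2 Å) of any
symmetry-expanded atom; free voxels are clustered under periodic
6-connectivity; regions under 20 ų are suppressed but counted. Void
volume plus blocked volume partitions V exactly on the grid. Electron
counts integrate the difference map over the void voxels and are reported
as-is (negative totals carry a caveat); full solvent-contribution
iteration is out of scope. Integration recovers an omitted 10-electron
water to within the series truncation at s_max = 0.65 Å⁻¹ in a
centrosymmetric host; in non-centrosymmetric structures |Fo|−|Fc|
syntheses show omitted density at reduced weight, a known property of the
Fc-phased approximation, so counts there are lower bounds.

## Missed symmetry and twinning

ADDSYM-style search: hydrogens and disordered atoms excluded, element
identity ignored by default. Candidates come from the coordinates:
frequent pair-difference vectors (extra translations and centerings), pair
midpoints (inversion centres; the translation 2c is snapped to the 1/24
grid, bounding the rounding error at ~1/48 cell), and two-folds/mirrors
about cell axes and face diagonals with translations fitted from the
coordinates. A candidate passes when ≥ 85 % of eligible atoms map onto an
eligible atom within 0.45 Å (both defaults configurable and echoed in the
report). Note that a single displaced atom breaks two matches (its own and
its partner's), so the conforming fraction is (n−2)/n in that case. The
implied group is identified by closing the operator set and looking it up;
when unmerged data are available the implied extinctions are
cross-checked against them and the violation count is reported alongside.
Full Niggli-reduction lattice-symmetry hunting is intentionally not done;
the scope is centering translations plus the seven-system metric checks.

Twin laws: two-fold rotations about direct [uvw] and reciprocal (hkl) rows
with coprime indices ≤ 2, kept only when the index action lies within 0.05
of half-integers (a twin law must map the lattice approximately onto
itself — for an exactly cubic metric every surviving candidate is a
lattice symmetry and the list is empty), deduplicated and filtered against
the Laue group. An outlier (Fo² > 2Fc² and Fo² > 10σ; at least 20
required) is explained by law M when hM rounds to a lattice point within
0.1 whose Fc² exceeds the outlier's and whose θ matches within 0.1°. Laws
explaining ≥ 60 % of outliers are scored: α̂ minimises R1 of the model
(1−α)Fc²(h) + αFc²(hM) over [0, 0.5] (bounded golden-section, tolerance
10⁻³), and the R1 drop is reported as an estimate of the refinement gain,
not a reproduction of any upstream convention. The HKLF5 export writes
overlap pairs with the negative-batch-first convention and echoes the
empirical overlap criterion; pre-filtered data (outliers removed) defeat
detection and the report says so.

## Embedded payloads and checksums

Semicolon text fields are preserved byte-exact so payload checksums are
meaningful. The checksum algorithm itself is a documented reference
implementation (a linear-congruential digest over printable non-blank
characters, constants 1366/150889/714025, result 1…714024) behind a
pluggable interface; the fixture generator uses the same algorithm, so
edit-detection is exercised end-to-end. It has not been validated against
external tools, so a mismatch is reported at B level, never A, and a
missing checksum degrades to an "unverified" note.

## The synthetic-data generator

`fixtures` builds a random connected molecule (heavy-atom chain plus
hydrogens, bond lengths 1.5/1.0 Å) in the asymmetric unit, rejecting
self-clashes and symmetry-image approaches closer than the van der Waals
sum minus 0.1 Å, so a correct ("golden") structure carries no short
contacts and no voids. Structure factors are the exact spherical-atom sum
with four-Gaussian form factors, isotropic Debye–Waller factors and
optional anomalous terms; extinct reflections vanish below 10⁻⁸ by
construction. Observed data follow σ²(I) = σ₀² + k·I (defaults σ₀ = 0.5,
k = 0.02) with Gaussian noise, sampled over the full sphere to
s_max = 0.65 Å⁻¹ so merging statistics see real redundancy. The standard
fixtures are a P2₁/c structure (6 heavy atoms + 4 H in an
8 × 9 × 10 Å cell, β = 101°) and a P2₁ structure with β = 90.2°
(pseudo-merohedral-twin prone; a sulfur variant supplies resonant signal);
sizes chosen so a dataset builds in well under a second and the full
validation of one archive takes ~0.3 s.

The generator writes everything the validator consumes — CIF with
operator loop, atom loop, formula/Z/density, refinement summary computed
from its own data, f′/f″ loop, crystal size and transmission range, plus
embedded RES/HKL payloads with checksums, an FCF and an HKLF4 file — so
the golden path is internally consistent by construction and triggers zero
A/B/C alerts.

What the generator does **not** emulate: anisotropic displacement in the
structure-factor sum (anisotropic tensors are exercised directly in the
Hirshfeld tests), absorption, extinction, thermal diffuse scattering,
realistic disorder, special-position occupancies, and profile-level
artefacts. Passing tests therefore demonstrate the correctness of the
*computations* on data obeying the stated models, not robustness to every
pathology of real detectors.

## Limitations

* CIF 1.1 only; CIF2/DDLm is rejected with a clear error, and no
  dictionary-level (DDL) vocabulary validation is attempted.
* No refinement: R values are evaluated, never minimised (except the
  one-parameter twin-fraction scan).
* No magnetic or (3+d)-dimensional superspace groups; no origin-choice
  interconversion beyond what the tabulated Hall symbols encode.
* Moiety-formula parsing is best-effort; mismatches never exceed a note.
* The Flack-parameter machinery requires unmerged (or at least
  Friedel-separate) data with calculated intensities for both mates.
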