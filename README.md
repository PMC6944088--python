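# ciflint

`ciflint` is a validation toolkit for small-molecule crystal-structure
archives. It reads a CIF 1.1 file (crystal data, model parameters,
symmetry, refinement summary, optionally embedded SHELX-style `.res`/`.hkl`
payloads with checksums) together with reflection data (a CIF-style FCF
loop or SHELX HKLF4 records), re-derives everything that can be re-derived,
and reports discrepancies as a levelled **ALERT** list — A (serious),
B, C (check), G (informative) — in the spirit of automated checkCIF-style
structure validation. ALERTs are not necessarily errors; they are items a
careful author or referee should look at.

It is aimed at people who produce or review crystal-structure data:
crystallographers checking a refinement before deposition, referees, and
software developers who need the individual checks as a library.

## What it checks

* **Symmetry** — Hall symbols are expanded to the full operator group by an
  in-package parser and closure engine (verified against the 230
  space-group types); the Hermann–Mauguin symbol, Hall symbol, listed
  operator loop and cell metric are cross-checked; site occupancies obey
  `sso = nsym/ssm` and `SOF = occupancy/sso`; ORTEP-style `s_uvw` symmetry
  codes are encoded/decoded (translations −5…4 only); systematic-absence
  conditions are derived from the operators, and extinct reflections
  observed above noise are listed.
* **Model** — sum-formula/Z/density arithmetic (a bracketed `[+solvent]`
  part contributes nothing to Mr or density); the Hirshfeld rigid-bond
  test on anisotropic displacement parameters; covalent connectivity,
  short intermolecular contacts classified H⋯H / O⋯O,O⋯N (missing H) /
  halogen⋯halogen (informational); centre-of-gravity placement of each
  species; transmission-range plausibility from μ and the crystal size;
  data-to-parameter ratio; resonant scattering factors f′/f″ against
  computed values.
* **Reflection statistics** — merging and R(int); shell-wise completeness
  against the symmetry-unique reflection count (the copper-sphere
  resolution sin θ/λ = 1/1.5418 = 0.65 Å⁻¹ is the reference, with the
  completeness requirement at 0.6 Å⁻¹); R1/wR2/S recomputed three ways
  (CIF weights, σ-only weights, reported) with the two-parameter weighting
  `w = 1/[σ² + (aP)² + bP]`, `P = (max(Fo²,0) + 2Fc²)/3`; analysis of
  variance in resolution and Fc/Fc(max) bins (scaling K, bin GooF);
  normal-probability plot; a Parsons-style Bijvoet-quotient estimate of
  the absolute-structure (Flack) parameter with inversion advised above
  0.5; a fabricated-data screen on σ(I) vs I.
* **Density maps** — the Fc-phased |Fo|−|Fc| difference map by FFT
  (zero-mean, F(000) excluded), graded excursions beyond the ±0.5 e Å⁻³
  featureless bound, on-atom density (atom-type errors), H-site support,
  residual density on bonds, solvent-accessible voids with integrated
  electron counts.
* **Missed symmetry and twinning** — an ADDSYM-style coordinate search
  (H and disordered atoms excluded, element identity ignored by default, a
  configurable percentage of atoms allowed not to conform) proposing extra
  translations, inversion centres and two-folds/mirrors with the implied
  group; a TwinRotMat-style reflection search that explains Iobs ≫ Icalc
  outliers by two-fold rotations of the lattice, estimates the twin
  fraction α by minimising R1 of the mixed model, and can export an
  HKLF5-style file.

Every check is exercised by a synthetic-data generator
(`ciflint.fixtures`) that builds random, internally consistent structures,
computes exact spherical-atom structure factors, and injects deliberate
corruptions (stripped inversion, wrong atom type, misplaced H, twinning,
inverted structure, fabricated σ, edited embedded payloads, inflated
low-order data) that each trigger exactly the intended ALERT.

## Worked example

```python
import ciflint
from ciflint import fixtures

dataset = fixtures.make_dataset(fixtures.golden_spec())   # P2_1/c, seed 7
report = ciflint.run_validation(ciflint.parse_cif(dataset.cif))
print(ciflint.render_report(report))
```

prints

```
========================================================================
ciflint validation report (ciflint 0.1.0)
========================================================================
data_I
------------------------------------------------------------------------
  R1       wR2      S        set
  0.0089   0.0098   1.0055   recalculated (CIF weights)
  0.0089   0.0098   1.0055   reweighted (sigma weights)
  0.0089   0.0098   1.0056   reported
  rint                 0.0105
  completeness         1.0000
  residual_density     -0.0480 0.0491
  void_volume          0
  reflection_source    embedded _shelx_hkl_file + recalculated Fc
  observed_criterion   I > 2sigma(I)
  fabrication          unremarkable
  ALERT counts  A: 0, B: 0, C: 0, G: 2
  ALERT 0978 [G] mean difference density on bonds: -0.002 e/A^3 over 15 bonds ...
  ALERT 9081 [G] check not assessed: twin search: only 0 intensity outliers ...
```

The three R-value rows agree because the archive is self-consistent: the
toolkit re-created the reflection data from the embedded HKL payload,
recomputed Fc from the model in the CIF, merged (R(int) = 0.0105 over a
fourfold-redundant sphere), and reproduced the reported R1 = 0.0089,
wR2 = 0.0098 and S ≈ 1.01. The residual map is featureless (±0.05 e Å⁻³),
there are no voids, and only informative G-level notes remain. Corrupt the
same archive — e.g.
`fixtures.make_dataset(fixtures.golden_spec(corruption=("strip_inversion",)))`
— and the report gains an A-level ADDSYM alert proposing the missing
inversion centre with the implied group P2₁/c.

From a shell:

```bash
ciflint check structure.cif --fcf structure.fcf --format chk
```

Exit status 0 means no A-level alerts, 1 means A-level alerts are present,
2 means the file could not be validated.

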