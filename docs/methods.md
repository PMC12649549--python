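# Methods

## Cyclic permutation

A parent peptide of length L placed on a circle is read clockwise from
each start position. Rotation k (k = 1..L−1) is `seq[k:] + seq[:k]`;
rotation 0 is the parent itself and is never a library member. For the
W5K family the rotations carry their published names (W5K01 at offset 1
through W5K12 at offset 12); otherwise members are named
`<parent>_rot<k>`. Terminal chemistry (N-acetyl, C-amide) is metadata
inherited unchanged by every rotation — the family is synthesised with
both caps, which removes the two terminal charges. Periodic parents
(e.g. `AAAA`) produce repeated rotations; these are retained and flagged
`duplicate` rather than dropped, so the member count is always L−1.

## Descriptors

**Hydrophobicity scales.** ⟨H⟩ and ⟨μH⟩ use the Fauchère–Pliska (1983)
octanol/water side-chain scale, the convention of helical-wheel
amphipathicity calculators; GRAVY uses Kyte–Doolittle (1982). Both are
bundled as literal 20-value tables.

**Hydrophobic moment.** Residue i (0-based; residue 0 at angle 0) sits at
wheel angle i·δ with δ = 100° (3.6 residues/turn ideal α-helix). The
moment is the resultant of the per-residue hydrophobicity vectors divided
by N (1/N normalisation, not 1/ΣH). With δ = 100° and L = 13 the wheel
angles are pairwise distinct, so the 13-mer's wheel has no overlapping
spokes.

**Instability index.** II = (10/L)·Σᵢ DIWV(resᵢ, resᵢ₊₁) over the L−1
adjacent dipeptides, computed on the bare sequence (terminal caps
ignored), with the Guruprasad (1990) dipeptide weights as shipped by
Biopython (`Bio.SeqUtils.ProtParamData.DIWV`). A useful identity: each
rotation's linear dipeptide set is the full cyclic set minus one
wrap-around pair, so II(rotation k) = (10/L)(S_cyc − DIWV(omitted pair)).
Rotations that omit pairs with equal weights therefore share an II value,
which is why ten of the thirteen W5K family members print 21.68.

**Net charge.** The default formal model counts +1 per Lys/Arg, −1 per
Asp/Glu, +1 per His only below pH 6, and ±1 for free termini; for the
capped W5K family this gives +7. A Henderson–Hasselbalch titration model
(standard sidechain/terminus pKa values) is available for real-valued
charges at arbitrary pH; the formal model is the reporting default.

**Molecular weight.** Average (not monoisotopic) masses via Biopython,
plus +42.037 Da for N-acetylation and −0.985 Da for C-amidation, giving
1840.3 Da for the capped parent. (A published figure of "18.4 kDa" for
this 13-mer is off by a factor of ten and is treated as a decimal typo.)

**Presentation rounding.** All descriptors are computed at full precision;
table writers round half-up to 2 d.p. (⟨H⟩, ⟨μH⟩, AI, II, MW) and
3 d.p. (GRAVY).

## Censored MICs and selectivity

MICs live on the assay's two-fold series 50, 25, 12.5, 6.25, 3.13, 1.56,
0.78 µg/mL and are right-censored at 50 (cells "`>50`"). Panel readers
accept wide (strains × peptides, with `strain` and `gram` columns) and
long CSV; censoring is preserved end-to-end and re-emitted as `>bound` in
exports. The geometric mean substitutes exactly 100 µg/mL for censored
cells (configurable, pinned by tests at 100); GM is reported per Gram
class and combined. When a panel carries multiple media, selectivity is
scored on the baseline MH broth only — condition-stratified panels (NaCl,
MgCl2, pH variants) are scored per condition but do not enter TI.

**HC10.** The dose–response interpolation convention is: find the first
upward crossing of the 10% threshold and interpolate linearly in
log10(concentration) between the bracketing measured points; a measured
point exactly at 10% is returned as-is; a curve that never reaches 10%
returns the 108.7 µg/mL cap with a censored flag; non-monotone curves are
flagged and resolved at the first crossing. Measured HC10 values for the
W5K family are experimental inputs (their raw curves are not bundled);
the estimator is exercised on synthetic logistic curves where the exact
answer HC50·9^(−1/hill) is known.

**TI.** TI = HC10/GM, computed on unrounded GMs and rounded half-up to
1 d.p. only for presentation. Reconstructing the family's published
selectivity table from the bundled MIC panel and HC10 column reproduces
every GM cell at 1 d.p. and every TI cell to the printed digit except one
(parent TI vs Gram-negatives: 30.0/2.061 = 14.56, printed 14.5 — the
source table's own rounding is inconsistent there, cf. 19.98 printed as
20.0), so TI tests allow a one-tick (±0.1) margin.

**Units.** The MIC pipeline is µg/mL throughout. µM↔µg/mL conversion is
never implicit: it requires an explicit molecular weight, because the
family's published 200 µM ≡ 108.7 µg/mL equivalence implies an MW
inconsistent with any 13-mer; the 108.7 cap is honoured as printed.

**Parent comparison.** Because "n-fold difference" is ambiguous between
ratios and dilution steps, the comparison table reports both
(`ratio = MIC/MIC_parent` and `dilution_steps = log2 ratio`) plus an
`at_or_below_parent` flag; censored member cells never qualify, and
bounds are labelled `lower`/`upper`/`unknown` when either cell is
censored.

## Synthetic assays

The generators emulate the study's assay structure, not its biology:

- **MIC panels.** True log2-MICs are perturbed by Gaussian replicate
  noise in log2-dilution space (default SD 0.5 steps — typical ±1-step
  reproducibility of broth microdilution), then snapped *up* to the
  dilution grid (a well is scored at the lowest tested inhibiting
  concentration); latent values above 50 µg/mL become ">50". This
  reproduces the quantisation and right-censoring of real panels but not
  strain-level correlations, inoculum effects or medium dependence.
- **Dose–response curves.** response(c) = 100/(1 + (HC50/c)^hill) with
  additive Gaussian noise (default 3%), truncated to [0, 100], on a
  two-fold grid descending from 108.7 µg/mL; default Hill slope 2.0
  (typical for AMP hemolysis). The leakage generator emits raw
  fluorescence plus baseline/full-lysis controls so the normalisation
  formula must be applied first. Real curves can saturate below 100% or
  be non-monotone; the generator covers those regimes only via noise.
- **Seeding.** One global seed fans out to named substreams (CRC32 spawn
  keys), so identical seeds give bit-identical tables and adding a
  generator never perturbs the others.

The default recovery study (4 peptides × 6 strains × 10 seeds,
`analysis/04_synthetic_recovery.py`) recovers GM within one dilution step
in 39/40 peptide-seed cases (the one exception sits exactly at the
boundary, driven by censoring flips in the partially resistant peptide)
and HC10 within one grid step in all cases. Passing these tests shows the
pipeline's bookkeeping (censoring, substitution, stratification,
interpolation) is correct under the stated noise model; it does not
validate the noise model against wet-lab variability.

## Scope and limitations

- Structure prediction, CD/NMR interpretation, image segmentation and
  significance testing are out of scope; wound areas, hemolysis
  absorbances and leakage fluorescence enter as numbers, not pixels or
  spectra.
- The bundled W5K dataset covers the baseline MH-broth panel and the
  measured HC10 column; salt/pH-stratified panels are supported as input
  formats and exercised synthetically but not bundled.
- Problem sizes everywhere (13-mer library, 10-strain panel, ≤10-seed
  recovery studies) are the natural desk scale of this analysis; the full
  suite runs in seconds.
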