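# permamp

Cyclic sequence-permutation design and selectivity scoring for
antimicrobial peptides (AMPs).

Short cationic AMPs kill bacteria by disrupting membranes; their potency
and host-cell toxicity depend not only on residue composition but on how
charged (Lys/Arg) and hydrophobic (Trp/Leu) residues are arranged along
the helix. Cyclic permutation is a design strategy that probes exactly
this: reading a parent sequence from every start position around a circle
yields L−1 rotations with identical composition — hence identical charge,
GRAVY, aliphatic index and mass — but different amphipathic geometry.
`permamp` implements the full design-and-evaluation loop for such
libraries, built around the Lys/Trp-rich 13-mer W5K/A9W
(Ac-KKWRKWLKWLAKK-NH2) and its twelve permutants W5K01–W5K12.

The core quantities:

- **Hydrophobic moment** ⟨μH⟩ = (1/N)·|Σᵢ Hᵢ(cos iδ, sin iδ)| with
  δ = 100°/residue (ideal α-helix) and the Fauchère–Pliska scale —
  the amphipathicity of the helical wheel, sensitive to residue order.
- **Instability index** II = (10/L)·Σ DIWV(resᵢ, resᵢ₊₁) over adjacent
  dipeptides (Guruprasad weights); II < 40 predicts a stable peptide.
  Rotations of one parent differ only in which cyclic dipeptide the linear
  sequence omits, which is why most rotations share one II value.
- **Censored MIC geometric mean** GM = exp(mean ln MIC) over a strain
  panel, substituting 100 µg/mL for right-censored ">50" cells, stratified
  by Gram class.
- **Therapeutic index** TI = HC10/GM, where HC10 is the lowest
  concentration causing 10% hemolysis (capped at 108.7 µg/mL when no
  hemolysis is detected at the top tested dose). Larger TI = more
  selective for bacteria over host cells.

A seeded synthetic-assay module emulates two-fold-dilution MIC panels with
replicate noise and censoring, and logistic hemolysis/calcein-leakage
curves, so the whole pipeline is testable against known ground truth.

## Worked example

```python
from permamp import datasets, descriptors, assays

lib = datasets.w5k_library()          # parent + 12 rotations
df = descriptors.describe_library(lib)
print(df.loc[0, "gravy"], df.loc[0, "charge"])   # -1.6308, 7.0 (all rows equal)
print(df.set_index("name").loc["W5K06", "muH"])  # 0.2763 -> prints as 0.28

panel = datasets.w5k_mic_panel()      # MH-broth MICs, ">50" preserved
hc10 = datasets.w5k_hc10()            # measured HC10 inputs
report = assays.ti_report(panel, dict(zip(hc10["peptide"], hc10["hc10_ug_ml"])))
print(report.set_index("peptide").loc["W5K10"].round(1))
# GM_neg 3.1, GM_pos 9.5, GM_all 5.4, HC10 108.7, TI_all 20.0
```

The analysis is also packaged as narrative drivers:

```bash
python analysis/01_build_library.py        # library FASTA + helical-wheel CSV
python analysis/02_descriptor_table.py     # descriptor table; order-invariance check
python analysis/03_selectivity_scoring.py  # GM / HC10 / TI report, parent comparison
python analysis/04_synthetic_recovery.py   # ground-truth recovery on synthetic assays
```

`02` prints the shared composition descriptors (GRAVY −1.631, ⟨H⟩ 0.27,
AI 67.69, z +7, MW 1840.3 Da) and the per-rotation ⟨μH⟩ (0.28–0.75) and II
columns; `03` prints the full selectivity table, e.g. W5K11: GM_all
3.3 µg/mL, HC10 71.0 µg/mL, TI 21.2 — the most selective family member.
Outputs land in `results/`.

A `permamp` console command exposes the same steps
(`permamp permute|describe|ti|simulate|recover`, each with `--help`).

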