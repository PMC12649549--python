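"""Bundled reference dataset: the W5K/A9W cyclic-permutation peptide family.

W5K/A9W (Ac-KKWRKWLKWLAKK-NH2) is a lysine/tryptophan-rich antimicrobial
peptide; its 12 cyclic permutants W5K01..W5K12 share its composition but
reorder the residues.  The package bundles the family's characterised
baseline assay inputs as small CSVs:

* ``w5k_mic_mh.csv`` — MICs (ug/mL, two-fold series, right-censored at
  50) against 5 Gram-negative and 5 Gram-positive strains in MH broth;
* ``w5k_hc10.csv`` — measured HC10 per peptide (ug/mL), capped at 108.7
  (the top tested dose) for peptides with no detectable hemolysis.

HC10 values are experimental inputs; the package estimates HC10 from
dose-response curves only when raw curves are supplied.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .assays import MICPanel
from .peptide import Peptide, PermutationLibrary, cyclic_permutations

PARENT_NAME = "W5K/A9W"
PARENT_SEQUENCE = "KKWRKWLKWLAKK"

#: Rotation start offset -> published derivative name.
W5K_NAMES = {k: f"W5K{k:02d}" for k in range(1, 13)}


def w5k_parent() -> Peptide:
    """The parent peptide, N-acetylated and C-amidated."""
    return Peptide(PARENT_NAME, PARENT_SEQUENCE,
                   n_terminus="acetyl", c_terminus="amide")


def w5k_library() -> PermutationLibrary:
    """The parent plus its 12 cyclic permutants, under their published names."""
    return cyclic_permutations(w5k_parent(), names=W5K_NAMES)


def _data_path(name: str):
    return resources.files("permamp").joinpath("data", name)


def w5k_mic_panel() -> MICPanel:
    """Baseline (MH broth) MIC panel for the family, censoring preserved."""
    with resources.as_file(_data_path("w5k_mic_mh.csv")) as path:
        return MICPanel.from_wide_csv(path)


def w5k_hc10() -> pd.DataFrame:
    """Measured HC10 inputs: columns peptide, hc10_ug_ml, censored."""
    with resources.as_file(_data_path("w5k_hc10.csv")) as path:
        return pd.read_csv(path)
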