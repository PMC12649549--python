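"""Physicochemical descriptors for amphipathic peptides.

Two groups of descriptors are computed:

* composition-only (GRAVY, mean hydrophobicity <H>, aliphatic index,
  formal net charge, molecular weight) — invariant under any reordering
  of the sequence, in particular under cyclic permutation;
* sequence-order-aware (hydrophobic moment <muH>, Guruprasad instability
  index) — these change between rotations and are what a permutation
  scan is designed to probe.

The hydrophobic moment follows the Eisenberg construction: each residue's
hydrophobicity is placed as a vector at helical-wheel angle i*delta
(delta = 100 deg for an ideal alpha helix) and the resultant magnitude is
normalised by length,

    muH = (1/N) * |sum_i H_i (cos(i*delta), sin(i*delta))|.

The instability index is the Guruprasad dipeptide-weight sum,
II = (10/L) * sum over adjacent pairs of DIWV(res_i, res_{i+1}); peptides
with II < 40 are conventionally called stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Union

import pandas as pd
from Bio.SeqUtils import molecular_weight as _bio_mw
from Bio.SeqUtils.ProtParamData import DIWV  # Guruprasad 1990 dipeptide weights

from .peptide import CANONICAL_AA, Peptide, PermutationLibrary, helical_wheel

PeptideLike = Union[Peptide, str]


def _seq(p: PeptideLike) -> str:
    return p.sequence if isinstance(p, Peptide) else p


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, as assay tables are printed."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class HydrophobicityScale:
    """A named per-residue hydrophobicity table covering all 20 residues."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(CANONICAL_AA) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")


#: Fauchere & Pliska (1983) octanol/water side-chain transfer free energies;
#: the scale used by helical-wheel amphipathicity calculators for <H>/<muH>.
FAUCHERE_PLISKA = HydrophobicityScale(
    "fauchere-pliska",
    {
        "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
        "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
        "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
        "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
    },
)

#: Kyte & Doolittle (1982) hydropathy; the scale behind GRAVY.
KYTE_DOOLITTLE = HydrophobicityScale(
    "kyte-doolittle",
    {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
        "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
        "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
        "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    },
)

SCALES = {s.name: s for s in (FAUCHERE_PLISKA, KYTE_DOOLITTLE)}

#: Average residue masses are taken from Biopython; terminal-group deltas:
WATER_AVG = 18.0153
ACETYL_DELTA = 42.0367   # +C2H2O on the N-terminus
AMIDE_DELTA = -0.9847    # C-terminal OH -> NH2

#: Sidechain/terminus pKa values for the optional titration charge model.
PKA = {
    "K": 10.54, "R": 12.48, "H": 6.04, "D": 3.90, "E": 4.07,
    "C": 8.37, "Y": 10.46, "nterm": 9.0, "cterm": 2.35,
}


def gravy(p: PeptideLike) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value."""
    seq = _seq(p)
    return sum(KYTE_DOOLITTLE.values[a] for a in seq) / len(seq)


def mean_hydrophobicity(p: PeptideLike,
                        scale: HydrophobicityScale = FAUCHERE_PLISKA) -> float:
    """Mean per-residue hydrophobicity <H> on the given scale."""
    seq = _seq(p)
    return sum(scale.values[a] for a in seq) / len(seq)


def hydrophobic_moment(p: PeptideLike,
                       scale: HydrophobicityScale = FAUCHERE_PLISKA,
                       delta_deg: float = 100.0) -> float:
    """Length-normalised helical hydrophobic moment <muH>."""
    seq = _seq(p)
    if not seq:
        raise ValueError("hydrophobic moment of an empty sequence is undefined")
    pep = p if isinstance(p, Peptide) else None
    if pep is not None:
        vectors = helical_wheel(pep, delta_deg).unit_vectors()
    else:
        vectors = [
            (math.cos(math.radians(i * delta_deg)), math.sin(math.radians(i * delta_deg)))
            for i in range(len(seq))
        ]
    cx = sum(scale.values[a] * v[0] for a, v in zip(seq, vectors))
    sy = sum(scale.values[a] * v[1] for a, v in zip(seq, vectors))
    return math.hypot(cx, sy) / len(seq)


def aliphatic_index(p: PeptideLike) -> float:
    """Ikai aliphatic index: 100*X_A + 290*X_V + 390*(X_I + X_L)."""
    seq = _seq(p)
    n = len(seq)
    return (100.0 * seq.count("A") + 290.0 * seq.count("V")
            + 390.0 * (seq.count("I") + seq.count("L"))) / n


def instability_index(p: PeptideLike) -> float:
    """Guruprasad instability index, (10/L) * sum of adjacent DIWV weights.

    Computed on the bare sequence; terminal modifications are ignored,
    matching the protein-parameter web calculators.
    """
    seq = _seq(p)
    if len(seq) < 2:
        raise ValueError("instability index requires length >= 2")
    total = sum(DIWV[a][b] for a, b in zip(seq, seq[1:]))
    return 10.0 / len(seq) * total


def is_stable(p: PeptideLike) -> bool:
    """Conventional stability call: II < 40."""
    return instability_index(p) < 40.0


def net_charge(p: Peptide, model: str = "formal", pH: float = 7.4) -> float:
    """Net charge at the given pH.

    ``formal`` counts unit charges: +1 per K/R (and H below pH 6), -1 per
    D/E, plus free-terminus charges; returns an integer-valued float.
    ``titration`` returns the Henderson-Hasselbalch expected charge.
    """
    seq = p.sequence
    if model == "formal":
        z = seq.count("K") + seq.count("R") - seq.count("D") - seq.count("E")
        if pH < 6.0:
            z += seq.count("H")
        if p.n_terminus == "free":
            z += 1
        if p.c_terminus == "free":
            z -= 1
        return float(z)
    if model == "titration":
        def pos(pka: float) -> float:
            return 1.0 / (1.0 + 10.0 ** (pH - pka))

        def neg(pka: float) -> float:
            return -1.0 / (1.0 + 10.0 ** (pka - pH))

        z = 0.0
        for aa in seq:
            if aa in ("K", "R", "H"):
                z += pos(PKA[aa])
            elif aa in ("D", "E", "C", "Y"):
                z += neg(PKA[aa])
        if p.n_terminus == "free":
            z += pos(PKA["nterm"])
        if p.c_terminus == "free":
            z += neg(PKA["cterm"])
        return z
    raise ValueError(f"unknown charge model {model!r}")


def peptide_mw(p: Peptide) -> float:
    """Average molecular weight in Da, including terminal modifications."""
    mw = _bio_mw(p.sequence, seq_type="protein")  # average masses + water
    if p.n_terminus == "acetyl":
        mw += ACETYL_DELTA
    if p.c_terminus == "amide":
        mw += AMIDE_DELTA
    return mw


@dataclass(frozen=True)
class DescriptorSet:
    """Full descriptor record for one peptide."""

    name: str
    sequence: str
    mean_hydrophobicity: float
    hydrophobic_moment: float
    gravy: float
    aliphatic_index: float
    instability_index: float
    stable: bool
    net_charge: float
    molecular_weight: float


def describe(p: Peptide) -> DescriptorSet:
    return DescriptorSet(
        name=p.name,
        sequence=p.sequence,
        mean_hydrophobicity=mean_hydrophobicity(p),
        hydrophobic_moment=hydrophobic_moment(p),
        gravy=gravy(p),
        aliphatic_index=aliphatic_index(p),
        instability_index=instability_index(p),
        stable=is_stable(p),
        net_charge=net_charge(p),
        molecular_weight=peptide_mw(p),
    )


def describe_library(lib: PermutationLibrary) -> pd.DataFrame:
    """One descriptor row per peptide (parent first, then each rotation)."""
    rows = []
    for p in lib.peptides():
        d = describe(p)
        rows.append({
            "name": d.name,
            "sequence": d.sequence,
            "label": p.modified_label(),
            "nterm": p.n_terminus,
            "cterm": p.c_terminus,
            "H_mean": d.mean_hydrophobicity,
            "muH": d.hydrophobic_moment,
            "gravy": d.gravy,
            "AI": d.aliphatic_index,
            "II": d.instability_index,
            "stable": d.stable,
            "charge": d.net_charge,
            "MW": d.molecular_weight,
        })
    return pd.DataFrame(rows)


def write_descriptor_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write the descriptor table with assay-table presentation rounding."""
    out = df.copy()
    for col, nd in (("H_mean", 2), ("muH", 2), ("gravy", 3),
                    ("AI", 2), ("II", 2), ("MW", 2)):
        out[col] = out[col].map(lambda x, nd=nd: round_half_up(x, nd))
    out.to_csv(path, index=False)
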