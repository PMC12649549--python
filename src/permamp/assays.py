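"""Censored MIC handling, dose-response summaries, and selectivity scoring.

Broth-microdilution MICs live on a two-fold dilution grid and are right-
censored at the highest tested concentration (cells printed ">50").  The
panel geometric mean (GM) substitutes a fixed value (default 100 ug/mL,
i.e. one dilution step above the 50 ug/mL ceiling) for censored cells.
Selectivity is scored as the therapeutic index TI = HC10 / GM, where HC10
is the lowest concentration producing 10% hemolysis, capped at the top
tested dose when no hemolysis is detected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .descriptors import round_half_up

#: The assay's two-fold dilution series, highest first (ug/mL).
DILUTION_GRID = (50.0, 25.0, 12.5, 6.25, 3.13, 1.56, 0.78)

#: Substitute used for ">50" cells in geometric means (ug/mL).
CENSOR_SUBSTITUTE = 100.0

#: Top hemolysis dose tested; HC10 cap for non-hemolytic peptides (ug/mL).
HC10_CAP = 108.7


class AssayError(ValueError):
    """Raised for malformed assay tables or invalid assay parameters."""


@dataclass(frozen=True)
class MICValue:
    """A possibly right-censored MIC. ``censor`` is 'exact' or 'above'."""

    concentration: float
    censor: str = "exact"

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise AssayError(f"MIC concentration must be positive, got {self.concentration}")
        if self.censor not in ("exact", "above"):
            raise AssayError(f"censor must be 'exact' or 'above', got {self.censor!r}")

    def __str__(self) -> str:
        prefix = ">" if self.censor == "above" else ""
        return f"{prefix}{self.concentration:g}"


@dataclass(frozen=True)
class Strain:
    id: str
    gram: str  # "negative" | "positive"

    def __post_init__(self) -> None:
        if self.gram not in ("negative", "positive"):
            raise AssayError(f"gram must be 'negative' or 'positive', got {self.gram!r}")


@dataclass(frozen=True)
class Condition:
    """Growth condition metadata for salt/pH-stratified panels."""

    medium: str = "MH"
    NaCl_mM: float = 0.0
    MgCl2_mM: float = 0.0
    pH: float = 7.4

    def __post_init__(self) -> None:
        if self.NaCl_mM < 0 or self.MgCl2_mM < 0:
            raise AssayError("salt concentrations must be non-negative")
        if not (0.0 < self.pH < 14.0):
            raise AssayError(f"pH must lie in (0, 14), got {self.pH}")


def parse_mic_cell(text: str, context: str = "") -> MICValue:
    """Parse a MIC table cell such as ``"3.13"`` or ``">50"``."""
    cell = str(text).strip().replace("**", "")
    where = f" ({context})" if context else ""
    censor = "exact"
    if cell.startswith(">"):
        censor = "above"
        cell = cell[1:].strip()
    try:
        conc = float(cell)
    except ValueError:
        raise AssayError(f"malformed MIC cell {text!r}{where}") from None
    if conc <= 0:
        raise AssayError(f"MIC bound must be positive in cell {text!r}{where}")
    return MICValue(conc, censor)


PANEL_COLUMNS = ["peptide", "strain", "gram", "medium",
                 "NaCl_mM", "MgCl2_mM", "pH", "mic", "censor"]


class MICPanel:
    """A peptides x strains x conditions matrix of censored MICs.

    Backed by a long-format :class:`pandas.DataFrame` with columns
    ``peptide, strain, gram, medium, NaCl_mM, MgCl2_mM, pH, mic, censor``.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in PANEL_COLUMNS if c not in data.columns]
        if missing:
            raise AssayError(f"MIC panel missing columns {missing}")
        dup_keys = ["peptide", "strain", "medium", "NaCl_mM", "MgCl2_mM", "pH"]
        if data.duplicated(subset=dup_keys).any():
            dups = data[data.duplicated(subset=dup_keys, keep=False)]
            raise AssayError(
                f"duplicate (peptide, strain, condition) entries:\n{dups[dup_keys]}"
            )
        bad_gram = set(data["gram"]) - {"negative", "positive"}
        if bad_gram:
            raise AssayError(f"unknown gram labels {sorted(bad_gram)}")
        self.data = data.reset_index(drop=True)

    # -- constructors -------------------------------------------------
    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, Strain, MICValue]],
        condition: Condition = Condition(),
    ) -> "MICPanel":
        rows = [
            {"peptide": pep, "strain": st.id, "gram": st.gram,
             "medium": condition.medium, "NaCl_mM": condition.NaCl_mM,
             "MgCl2_mM": condition.MgCl2_mM, "pH": condition.pH,
             "mic": mic.concentration, "censor": mic.censor}
            for pep, st, mic in records
        ]
        return cls(pd.DataFrame(rows, columns=PANEL_COLUMNS))

    @classmethod
    def from_long_csv(cls, path: str | Path) -> "MICPanel":
        df = pd.read_csv(path)
        if "censor" not in df.columns:
            parsed = [parse_mic_cell(v, context=f"row {i}") for i, v in enumerate(df["mic"])]
            df["censor"] = [m.censor for m in parsed]
            df["mic"] = [m.concentration for m in parsed]
        return cls(df)

    @classmethod
    def from_wide_csv(cls, path: str | Path,
                      condition: Condition = Condition()) -> "MICPanel":
        """Read a strains x peptides table; needs ``strain`` and ``gram`` columns."""
        df = pd.read_csv(path)
        for col in ("strain", "gram"):
            if col not in df.columns:
                raise AssayError(f"wide MIC table needs a {col!r} column")
        peptide_cols = [c for c in df.columns if c not in ("strain", "gram")]
        records = []
        for _, row in df.iterrows():
            strain = Strain(row["strain"], row["gram"])
            for pep in peptide_cols:
                mic = parse_mic_cell(row[pep], context=f"strain {strain.id}, peptide {pep}")
                records.append((pep, strain, mic))
        return cls.from_records(records, condition)

    # -- accessors ----------------------------------------------------
    def peptides(self) -> list[str]:
        return list(dict.fromkeys(self.data["peptide"]))

    def strains(self) -> list[str]:
        return list(dict.fromkeys(self.data["strain"]))

    def subset(self, **conditions) -> "MICPanel":
        """Filter by equality on any panel column, e.g. ``medium="MH"``."""
        df = self.data
        for col, val in conditions.items():
            df = df[df[col] == val]
        return MICPanel(df)

    def mic_values(self, peptide: str, gram: str | None = None) -> list[MICValue]:
        df = self.data[self.data["peptide"] == peptide]
        if gram is not None:
            df = df[df["gram"] == gram]
        return [MICValue(c, cen) for c, cen in zip(df["mic"], df["censor"])]

    def to_long_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def geometric_mean_mic(values: Sequence[MICValue],
                       censor_substitute: float = CENSOR_SUBSTITUTE) -> float:
    """Geometric mean of a MIC set with fixed substitution for censored cells."""
    if not values:
        raise AssayError("geometric mean of an empty MIC set is undefined")
    subs = [censor_substitute if v.censor == "above" else v.concentration
            for v in values]
    return float(gmean(subs))


def hemolysis_percent(A_sample: float, A_PBS: float, A_triton: float) -> float:
    """Percent hemolysis from raw absorbances: 100*(A_s - A_blank)/(A_full - A_blank).

    Negative values (sample below blank) are preserved; clamp only at
    presentation if needed.
    """
    denom = A_triton - A_PBS
    if denom == 0:
        raise AssayError("full-lysis and blank absorbances are equal; cannot normalise")
    return (A_sample - A_PBS) / denom * 100.0


def leakage_percent(F: float, F0: float, Fr: float) -> float:
    """Percent calcein leakage: 100*(F - F0)/(Fr - F0)."""
    denom = Fr - F0
    if denom == 0:
        raise AssayError("full-leakage and baseline fluorescence are equal")
    return (F - F0) / denom * 100.0


def repair_rate(area_0h: float, area_24h: float) -> float:
    """Wound closure fraction (Area_0h - Area_24h)/Area_0h; negative if the gap grew."""
    if area_0h <= 0:
        raise AssayError(f"initial wound area must be positive, got {area_0h}")
    return (area_0h - area_24h) / area_0h


@dataclass(frozen=True)
class DoseResponse:
    """A (concentration, response %) curve; concentrations strictly increasing."""

    concentrations: tuple[float, ...]
    responses: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.responses):
            raise AssayError("concentration and response lengths differ")
        if len(self.concentrations) == 0:
            raise AssayError("dose-response curve is empty")
        c = np.asarray(self.concentrations, dtype=float)
        if np.any(c <= 0):
            raise AssayError("concentrations must be positive")
        if np.any(np.diff(c) <= 0):
            raise AssayError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.responses)):
            raise AssayError("responses must be finite")


@dataclass(frozen=True)
class HC10Estimate:
    value: float
    censored: bool = False      # no response reached the threshold; value is the cap
    nonmonotone: bool = False   # curve dipped before the first upward crossing


def estimate_hc10(curve: DoseResponse, threshold: float = 10.0,
                  cap: float = HC10_CAP) -> HC10Estimate:
    """Lowest concentration whose response reaches ``threshold`` percent.

    The crossing is located at the first upward crossing, interpolating
    linearly in log10(concentration) between the bracketing measured
    points; a measured point exactly at the threshold is returned as-is.
    If the whole curve stays below the threshold, the cap is returned with
    ``censored=True``.
    """
    c = np.asarray(curve.concentrations, dtype=float)
    r = np.asarray(curve.responses, dtype=float)
    above = r >= threshold
    if not above.any():
        return HC10Estimate(cap, censored=True)
    i = int(np.argmax(above))  # first index at/above threshold
    nonmono = bool(np.any(np.diff(r[: i + 1]) < 0))
    if r[i] == threshold or i == 0:
        return HC10Estimate(float(c[i]), nonmonotone=nonmono)
    lo, hi = i - 1, i
    frac = (threshold - r[lo]) / (r[hi] - r[lo])
    logc = math.log10(c[lo]) + frac * (math.log10(c[hi]) - math.log10(c[lo]))
    return HC10Estimate(10.0 ** logc, nonmonotone=nonmono)


def therapeutic_index(hc10: float, gm: float) -> float:
    """Selectivity ratio HC10/GM; larger favours bacteria over host cells."""
    if gm <= 0:
        raise AssayError(f"GM must be positive, got {gm}")
    return hc10 / gm


def ti_report(panel: MICPanel, hc10_by_peptide: Mapping[str, float],
              censored_hc10: Iterable[str] = (),
              censor_substitute: float = CENSOR_SUBSTITUTE,
              medium: str | None = "MH") -> pd.DataFrame:
    """Per-peptide GM (Gram-negative / -positive / combined), HC10 and TI.

    ``hc10_by_peptide`` is an input (measured or estimated upstream); TI is
    computed on unrounded GMs.  If the panel carries multiple media, only
    ``medium`` (baseline broth) is scored; pass ``medium=None`` to disable.
    """
    if medium is not None and (panel.data["medium"] == medium).any():
        panel = panel.subset(medium=medium)
    censored = set(censored_hc10)
    rows = []
    for pep in panel.peptides():
        if pep not in hc10_by_peptide:
            raise AssayError(f"no HC10 provided for peptide {pep!r}")
        gm_neg = geometric_mean_mic(panel.mic_values(pep, "negative"), censor_substitute)
        gm_pos = geometric_mean_mic(panel.mic_values(pep, "positive"), censor_substitute)
        gm_all = geometric_mean_mic(panel.mic_values(pep), censor_substitute)
        hc10 = float(hc10_by_peptide[pep])
        rows.append({
            "peptide": pep,
            "GM_neg": gm_neg, "GM_pos": gm_pos, "GM_all": gm_all,
            "HC10": hc10, "HC10_censored": pep in censored,
            "TI_neg": therapeutic_index(hc10, gm_neg),
            "TI_pos": therapeutic_index(hc10, gm_pos),
            "TI_all": therapeutic_index(hc10, gm_all),
        })
    return pd.DataFrame(rows)


def write_ti_report(report: pd.DataFrame, path: str | Path) -> None:
    """Write the TI report with 1 d.p. presentation rounding."""
    out = report.copy()
    for col in ("GM_neg", "GM_pos", "GM_all", "HC10", "TI_neg", "TI_pos", "TI_all"):
        out[col] = out[col].map(lambda x: round_half_up(x, 1))
    out.to_csv(path, index=False)


def compare_to_parent(panel: MICPanel, parent: str) -> pd.DataFrame:
    """Per-cell comparison of each peptide's MIC against the parent's.

    Returns ratio = MIC/MIC_parent, dilution_steps = log2(ratio), a bound
    qualifier for censored cells, and ``at_or_below_parent`` (censored
    member cells never qualify).
    """
    df = panel.data
    cond_keys = ["strain", "medium", "NaCl_mM", "MgCl2_mM", "pH"]
    parent_df = df[df["peptide"] == parent]
    if parent_df.empty:
        raise AssayError(f"parent peptide {parent!r} not in panel")
    parent_map = parent_df.set_index(cond_keys)[["mic", "censor"]]
    rows = []
    for _, row in df[df["peptide"] != parent].iterrows():
        key = tuple(row[k] for k in cond_keys)
        try:
            pm = parent_map.loc[key]
        except KeyError:
            raise AssayError(f"parent MIC missing for condition {key}") from None
        ratio = row["mic"] / pm["mic"]
        member_cens = row["censor"] == "above"
        parent_cens = pm["censor"] == "above"
        if member_cens and parent_cens:
            bound = "unknown"
        elif member_cens:
            bound = "lower"   # true ratio exceeds the reported one
        elif parent_cens:
            bound = "upper"
        else:
            bound = "exact"
        at_or_below = (not member_cens) and row["mic"] <= pm["mic"]
        rows.append({
            "peptide": row["peptide"], "strain": row["strain"],
            "medium": row["medium"], "NaCl_mM": row["NaCl_mM"],
            "MgCl2_mM": row["MgCl2_mM"], "pH": row["pH"],
            "ratio": ratio, "ratio_bound": bound,
            "dilution_steps": math.log2(ratio),
            "at_or_below_parent": at_or_below,
        })
    return pd.DataFrame(rows)


def export_heatmap_matrix(panel: MICPanel, path: str | Path) -> None:
    """Wide strains x peptides TSV with censored cells rendered as ``>bound``."""
    df = panel.data.copy()
    df["cell"] = [str(MICValue(c, cen)) for c, cen in zip(df["mic"], df["censor"])]
    wide = df.pivot(index="strain", columns="peptide", values="cell")
    wide = wide.reindex(index=panel.strains(), columns=panel.peptides())
    wide.to_csv(path, sep="\t")
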