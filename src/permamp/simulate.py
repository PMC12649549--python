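"""Seeded synthetic assay generators with ground-truth bookkeeping.

The generators emulate the structure of the study's wet-lab readouts so
the whole scoring pipeline (parse -> GM -> HC10 -> TI) can be exercised
and checked against known truth:

* MIC panels: the true log2 MIC per (peptide, strain) is perturbed by
  Gaussian replicate noise in log2-dilution space and snapped *up* to the
  two-fold dilution grid (a microdilution well is scored at the lowest
  tested concentration that inhibits); values above the top grid point
  are right-censored (">50").
* Hemolysis / calcein-leakage curves: saturating logistic dose-response
  response(c) = 100 / (1 + (HC50/c)^hill) with additive Gaussian noise,
  truncated to [0, 100].  The closed-form threshold concentration
  HC10 = HC50 * 9^(-1/hill) makes estimator error measurable exactly.

One global seed fans out to independent substreams per assay so adding a
generator never perturbs the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assays import (
    CENSOR_SUBSTITUTE,
    HC10_CAP,
    Condition,
    DoseResponse,
    MICPanel,
    MICValue,
    Strain,
    estimate_hc10,
    geometric_mean_mic,
    therapeutic_index,
)

#: Default two-fold series (ug/mL), highest first — the tested assay grid.
DEFAULT_GRID = (50.0, 25.0, 12.5, 6.25, 3.13, 1.56, 0.78)


@dataclass(frozen=True)
class MICGroundTruth:
    """True MICs (log2 ug/mL) per (peptide, strain) plus the assay grid.

    ``replicate_sd`` is the replicate noise in dilution steps; 0.5 is a
    typical plus/minus-one-step reproducibility for broth microdilution.
    """

    table: pd.DataFrame  # columns: peptide, strain, gram, true_log2_mic
    dilution_grid: tuple[float, ...] = DEFAULT_GRID
    replicate_sd: float = 0.5

    def __post_init__(self) -> None:
        grid = np.asarray(self.dilution_grid)
        ratios = grid[:-1] / grid[1:]
        if not np.allclose(ratios, 2.0, rtol=0.01):
            raise ValueError("dilution grid must be a descending two-fold series")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be >= 0")

    def true_mic(self, peptide: str, strain: str) -> float:
        t = self.table
        row = t[(t["peptide"] == peptide) & (t["strain"] == strain)]
        return float(2.0 ** row["true_log2_mic"].iloc[0])


@dataclass(frozen=True)
class CurveGroundTruth:
    """Logistic dose-response truth: midpoint HC50, Hill slope, noise."""

    hc50: float
    hill: float = 2.0
    noise_sd: float = 3.0  # percent, additive
    grid: tuple[float, ...] = tuple(HC10_CAP / 2.0 ** k for k in range(7, -1, -1))

    def __post_init__(self) -> None:
        if self.hc50 <= 0 or self.hill <= 0:
            raise ValueError("hc50 and hill must be positive")

    @property
    def analytic_hc10(self) -> float:
        """Closed-form 10%-response concentration, HC50 * 9^(-1/hill)."""
        return self.hc50 * 9.0 ** (-1.0 / self.hill)

    def response(self, c: np.ndarray | float) -> np.ndarray | float:
        return 100.0 / (1.0 + (self.hc50 / np.asarray(c, dtype=float)) ** self.hill)


def _spawn(seed: int, key: str) -> np.random.Generator:
    """Derive an independent, named substream from the global seed."""
    child = np.random.SeedSequence(
        entropy=seed, spawn_key=(zlib.crc32(key.encode()) % (2 ** 31),)
    )
    return np.random.default_rng(child)


def gen_mic_panel(truth: MICGroundTruth, seed: int,
                  condition: Condition = Condition()) -> MICPanel:
    """Simulate one observed MIC panel from ground truth (deterministic per seed)."""
    rng = _spawn(seed, "mic_panel")
    grid_desc = np.asarray(truth.dilution_grid, dtype=float)  # highest first
    grid_asc = np.sort(grid_desc)
    records = []
    for _, row in truth.table.iterrows():
        eps = rng.normal(0.0, truth.replicate_sd) if truth.replicate_sd > 0 else 0.0
        latent = 2.0 ** (row["true_log2_mic"] + eps)
        at_or_above = grid_asc[grid_asc >= latent * (1 - 1e-12)]
        if at_or_above.size == 0:
            mic = MICValue(float(grid_asc[-1]), "above")
        else:
            mic = MICValue(float(at_or_above[0]), "exact")
        records.append((row["peptide"], Strain(row["strain"], row["gram"]), mic))
    return MICPanel.from_records(records, condition)


def gen_hemolysis_curve(truth: CurveGroundTruth, seed: int) -> DoseResponse:
    """Simulate a hemolysis dose-response curve (already in percent)."""
    rng = _spawn(seed, "hemolysis")
    c = np.asarray(truth.grid, dtype=float)
    r = np.asarray(truth.response(c), dtype=float)
    if truth.noise_sd > 0:
        r = r + rng.normal(0.0, truth.noise_sd, size=r.shape)
    r = np.clip(r, 0.0, 100.0)
    return DoseResponse(tuple(c), tuple(r))


@dataclass(frozen=True)
class LeakageExperiment:
    """Raw calcein-leakage readout: fluorescence plus baseline/full-lysis controls."""

    concentrations: tuple[float, ...]
    F: tuple[float, ...]
    F0: float
    Fr: float


def gen_leakage_curve(truth: CurveGroundTruth, seed: int,
                      F0: float = 50.0, Fr: float = 950.0) -> LeakageExperiment:
    """Simulate raw fluorescence so ``leakage_percent`` must be applied first."""
    rng = _spawn(seed, "leakage")
    c = np.asarray(truth.grid, dtype=float)
    frac = np.asarray(truth.response(c), dtype=float) / 100.0
    F = F0 + frac * (Fr - F0)
    if truth.noise_sd > 0:
        F = F + rng.normal(0.0, truth.noise_sd / 100.0 * (Fr - F0), size=F.shape)
    return LeakageExperiment(tuple(c), tuple(F), F0, Fr)


def default_ground_truth() -> tuple[MICGroundTruth, dict[str, CurveGroundTruth]]:
    """A small study-shaped truth set: 4 peptides x 6 strains (3 G-, 3 G+).

    True MICs span the tested grid including one fully resistant pairing
    (off-grid high, always censored); hemolysis midpoints span selective
    (HC50 above the tested range) to lytic.
    """
    strains = [("EC1", "negative"), ("PA1", "negative"), ("AB1", "negative"),
               ("SA1", "positive"), ("SA2", "positive"), ("SA3", "positive")]
    true_mics = {
        "pepA": [3.13, 3.13, 1.56, 6.25, 12.5, 12.5],
        "pepB": [6.25, 12.5, 6.25, 25.0, 25.0, 50.0],
        "pepC": [25.0, 50.0, 25.0, 80.0, 80.0, 80.0],   # partially resistant
        "pepD": [1.56, 1.56, 0.78, 3.13, 3.13, 6.25],
    }
    rows = []
    for pep, mics in true_mics.items():
        for (sid, gram), mic in zip(strains, mics):
            rows.append({"peptide": pep, "strain": sid, "gram": gram,
                         "true_log2_mic": np.log2(mic)})
    mic_truth = MICGroundTruth(pd.DataFrame(rows))
    curve_truth = {
        "pepA": CurveGroundTruth(hc50=60.0),
        "pepB": CurveGroundTruth(hc50=90.0),
        "pepC": CurveGroundTruth(hc50=400.0),  # non-hemolytic in tested range
        "pepD": CurveGroundTruth(hc50=30.0),
    }
    return mic_truth, curve_truth


def recovery_suite(seeds: Sequence[int],
                   mic_truth: MICGroundTruth | None = None,
                   curve_truth: dict[str, CurveGroundTruth] | None = None) -> pd.DataFrame:
    """End-to-end parameter recovery: generate -> score -> compare to truth.

    For each seed, a MIC panel and hemolysis curves are simulated, GM /
    HC10 / TI are computed by the analysis pipeline, and errors against
    the analytic truth are reported: GM error in dilution steps, HC10
    error in log2 grid steps, and the propagated TI ratio error.
    """
    if mic_truth is None or curve_truth is None:
        d_mic, d_curve = default_ground_truth()
        mic_truth = mic_truth or d_mic
        curve_truth = curve_truth or d_curve
    grid = np.asarray(mic_truth.dilution_grid, dtype=float)
    top = grid.max()
    rows = []
    for seed in seeds:
        panel = gen_mic_panel(mic_truth, seed)
        for pep in panel.peptides():
            # truth GM: substitute the censor value for true MICs beyond the grid
            t = mic_truth.table
            true_vals = [
                MICValue(top, "above") if 2.0 ** r > top * (1 + 1e-9)
                else MICValue(2.0 ** r, "exact")
                for r in t[t["peptide"] == pep]["true_log2_mic"]
            ]
            gm_true = geometric_mean_mic(true_vals)
            gm_obs = geometric_mean_mic(panel.mic_values(pep))
            gm_err_steps = abs(np.log2(gm_obs / gm_true))

            ct = curve_truth[pep]
            curve = gen_hemolysis_curve(ct, seed)
            est = estimate_hc10(curve)
            hc10_true = min(ct.analytic_hc10, HC10_CAP)
            hc10_err_steps = abs(np.log2(est.value / hc10_true))

            ti_obs = therapeutic_index(est.value, gm_obs)
            ti_true = therapeutic_index(hc10_true, gm_true)
            rows.append({
                "seed": seed, "peptide": pep,
                "gm_true": gm_true, "gm_obs": gm_obs,
                "gm_err_steps": gm_err_steps,
                "hc10_true": hc10_true, "hc10_obs": est.value,
                "hc10_censored": est.censored,
                "hc10_err_steps": hc10_err_steps,
                "ti_true": ti_true, "ti_obs": ti_obs,
                "gm_within_1_step": gm_err_steps <= 1.0 + 1e-9,
                "hc10_within_1_step": hc10_err_steps <= 1.0 + 1e-9,
            })
    return pd.DataFrame(rows)


def write_truth_json(mic_truth: MICGroundTruth,
                     curve_truth: dict[str, CurveGroundTruth],
                     path: str | Path) -> None:
    """Persist ground truth next to generated data for recovery tests."""
    payload = {
        "mic": {
            "replicate_sd": mic_truth.replicate_sd,
            "dilution_grid": list(mic_truth.dilution_grid),
            "table": mic_truth.table.to_dict(orient="records"),
        },
        "curves": {
            pep: {"hc50": ct.hc50, "hill": ct.hill, "noise_sd": ct.noise_sd,
                  "analytic_hc10": ct.analytic_hc10, "grid": list(ct.grid)}
            for pep, ct in curve_truth.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))
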