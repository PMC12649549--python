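"""Selectivity scoring of the W5K family from its baseline MIC panel.

Computes Gram-stratified geometric-mean MICs (censored ">50" cells
substituted with 100 ug/mL), joins the measured HC10 inputs, and scores
the therapeutic index TI = HC10/GM.  Also exports the parent-relative
comparison (the "at or below parent" bold mask) and a heatmap-ready MIC
matrix.
"""

from pathlib import Path

from permamp import assays, datasets

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    panel = datasets.w5k_mic_panel()
    hc10_df = datasets.w5k_hc10()
    hc10 = dict(zip(hc10_df["peptide"], hc10_df["hc10_ug_ml"]))
    censored = set(hc10_df.loc[hc10_df["censored"], "peptide"])

    report = assays.ti_report(panel, hc10, censored_hc10=censored)
    assays.write_ti_report(report, OUT / "w5k_ti_report.csv")

    cmp = assays.compare_to_parent(panel, datasets.PARENT_NAME)
    cmp.to_csv(OUT / "w5k_vs_parent.csv", index=False)
    assays.export_heatmap_matrix(panel, OUT / "w5k_mic_heatmap.tsv")

    printable = report.copy()
    for col in ("GM_neg", "GM_pos", "GM_all", "TI_neg", "TI_pos", "TI_all"):
        printable[col] = printable[col].round(1)
    print(printable.to_string(index=False))

    best = report.loc[report["TI_all"].idxmax()]
    print(f"\nmost selective: {best['peptide']} "
          f"(TI = {best['TI_all']:.1f}; HC10 {'censored at' if best['HC10_censored'] else 'measured'} "
          f"{best['HC10']:.1f} ug/mL, GM {best['GM_all']:.1f} ug/mL)")
    n_bold = int(cmp["at_or_below_parent"].sum())
    print(f"cells at or below the parent MIC: {n_bold} of {len(cmp)}")
    print(f"wrote TI report, parent comparison and heatmap matrix to {OUT}")


if __name__ == "__main__":
    main()
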