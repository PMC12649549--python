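"""Build the W5K cyclic-permutation library and export its geometry.

Generates the 12 rotations of W5K/A9W (Ac-KKWRKWLKWLAKK-NH2) under their
published names, writes the library FASTA (terminal chemistry in the
description line) and the helical-wheel coordinates used for amphipathicity
plots, and prints the rotation table.
"""

from pathlib import Path

from permamp import datasets, peptide

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    lib = datasets.w5k_library()
    peptide.write_fasta(lib, OUT / "w5k_library.fasta")
    peptide.wheel_to_csv(lib.peptides(), OUT / "w5k_wheel.csv")

    print(f"parent: {lib.parent.name}  {lib.parent.modified_label()}")
    print(f"rotations: {len(lib)} (start offsets 1..{len(lib)})")
    for m in lib.members:
        dup = "  [duplicate]" if m.duplicate else ""
        print(f"  {m.peptide.name}: {m.peptide.modified_label()}{dup}")
    print(f"\nwrote {OUT/'w5k_library.fasta'} and {OUT/'w5k_wheel.csv'}")


if __name__ == "__main__":
    main()
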