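"""Characterised reference values for the W5K peptide family.

Sequences, sequence-order descriptors, and the baseline selectivity table
as published for W5K/A9W and its 12 cyclic permutants.  Used by the test
suite to pin full-table reproduction.
"""

# name -> (sequence, muH at 2 d.p., instability index at 2 d.p.)
W5K_TABLE = {
    "W5K/A9W": ("KKWRKWLKWLAKK", 0.72, 21.68),
    "W5K01": ("KWRKWLKWLAKKK", 0.59, 21.68),
    "W5K02": ("WRKWLKWLAKKKK", 0.67, 21.68),
    "W5K03": ("RKWLKWLAKKKKW", 0.54, 21.68),
    "W5K04": ("KWLKWLAKKKKWR", 0.39, 21.68),
    "W5K05": ("WLKWLAKKKKWRK", 0.44, 21.68),
    "W5K06": ("LKWLAKKKKWRKW", 0.28, 12.19),
    "W5K07": ("KWLAKKKKWRKWL", 0.52, 28.22),
    "W5K08": ("WLAKKKKWRKWLK", 0.57, 21.68),
    "W5K09": ("LAKKKKWRKWLKW", 0.37, 12.19),
    "W5K10": ("AKKKKWRKWLKWL", 0.61, 21.68),
    "W5K11": ("KKKKWRKWLKWLA", 0.61, 21.68),
    "W5K12": ("KKKWRKWLKWLAK", 0.75, 21.68),
}

# Parent composition descriptors.
PARENT_GRAVY = -1.631
PARENT_AI = 67.69
PARENT_H_MEAN = 0.27
PARENT_CHARGE = 7

# name -> (GM_neg, GM_pos, GM_all, HC10, TI_neg, TI_pos, TI_all) at 1 d.p.
SELECTIVITY_TABLE = {
    "W5K/A9W": (2.1, 8.2, 4.1, 30.0, 14.5, 3.6, 7.3),
    "W5K01": (8.2, 28.7, 15.4, 70.9, 8.6, 2.5, 4.6),
    "W5K02": (7.2, 21.8, 12.5, 16.7, 2.3, 0.8, 1.3),
    "W5K03": (16.5, 66.0, 33.0, 108.7, 6.6, 1.6, 3.3),
    "W5K04": (18.9, 66.0, 35.4, 108.7, 5.7, 1.6, 3.1),
    "W5K05": (12.5, 33.0, 20.3, 108.7, 8.7, 3.3, 5.4),
    "W5K06": (43.5, 75.8, 57.4, 108.7, 2.5, 1.4, 1.9),
    "W5K07": (21.8, 87.1, 43.5, 108.7, 5.0, 1.2, 2.5),
    "W5K08": (50.0, 75.8, 61.6, 108.7, 2.2, 1.4, 1.8),
    "W5K09": (33.0, 75.8, 50.0, 108.7, 3.3, 1.4, 2.2),
    "W5K10": (3.1, 9.5, 5.4, 108.7, 34.8, 11.5, 20.0),
    "W5K11": (2.1, 5.4, 3.3, 71.0, 34.5, 13.0, 21.2),
    "W5K12": (2.4, 4.7, 3.4, 41.7, 17.6, 8.8, 12.4),
}

#: Independent average residue masses (Da) for the molecular-weight oracle.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
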