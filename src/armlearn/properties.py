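"""Curated per-amino-acid physicochemical property table.

25 descriptors per residue spanning hydrophobicity, size, polarity, charge,
hydrogen bonding, secondary-structure propensity and flexibility, drawn from
classic literature scales (Kyte-Doolittle and Eisenberg hydropathies,
Hopp-Woods hydrophilicity, Zamyatnin volumes, Grantham and Zimmerman
polarity, Chou-Fasman propensities, Tien maximal solvent accessibility,
Zimmerman bulkiness) plus simple composition-derived counts (heavy side-chain
atoms, rotatable bonds, hydrogen-bond donors/acceptors, class indicators).

This is a self-contained default table: any user-supplied table with the
same layout (20 amino-acid rows x property columns) can be used instead.
Columns are z-scored across the 20 amino acids before use so that kernel
lengthscales on different properties are comparable.
"""

from __future__ import annotations

import pandas as pd

# fmt: off
# Row order: A C D E F G H I K L M N P Q R S T V W Y (alphabetical 1-letter)
_AA_ORDER = list("ACDEFGHIKLMNPQRSTVWY")

_RAW: dict[str, list[float]] = {
    #                     A      C      D      E      F      G      H      I      K      L      M      N      P      Q      R      S      T      V      W      Y
    "hydropathy_kd":   [ 1.8,   2.5,  -3.5,  -3.5,   2.8,  -0.4,  -3.2,   4.5,  -3.9,   3.8,   1.9,  -3.5,  -1.6,  -3.5,  -4.5,  -0.8,  -0.7,   4.2,  -0.9,  -1.3],
    "hydrophob_eisen": [ 0.62,  0.29, -0.90, -0.74,  1.19,  0.48, -0.40,  1.38, -1.50,  1.06,  0.64, -0.78,  0.12, -0.85, -2.53, -0.18, -0.05,  1.08,  0.81,  0.26],
    "hydrophil_hw":    [-0.5,  -1.0,   3.0,   3.0,  -2.5,   0.0,  -0.5,  -1.8,   3.0,  -1.8,  -1.3,   0.2,   0.0,   0.2,   3.0,   0.3,  -0.4,  -1.5,  -3.4,  -2.3],
    "volume":          [88.6, 108.5, 111.1, 138.4, 189.9,  60.1, 153.2, 166.7, 168.6, 166.7, 162.9, 114.1, 112.7, 143.8, 173.4,  89.0, 116.1, 140.0, 227.8, 193.6],
    "residue_mass":    [71.08,103.14,115.09,129.12,147.18, 57.05,137.14,113.16,128.17,113.16,131.19,114.10, 97.12,128.13,156.19, 87.08,101.10, 99.13,186.21,163.18],
    "bulkiness":       [11.50, 13.46, 11.68, 13.57, 19.80,  3.40, 13.69, 21.40, 15.71, 21.40, 16.25, 12.82, 17.43, 14.45, 14.28,  9.47, 15.77, 21.57, 21.67, 18.03],
    "refractivity":    [ 4.34, 35.77, 13.28, 17.56, 29.40,  0.00, 21.81, 19.06, 21.29, 18.78, 21.64, 13.28, 10.93, 17.56, 26.02,  6.35, 11.01, 13.92, 42.53, 31.53],
    "max_sasa":        [129.0, 167.0, 193.0, 223.0, 240.0, 104.0, 224.0, 197.0, 236.0, 201.0, 224.0, 195.0, 159.0, 225.0, 274.0, 155.0, 172.0, 174.0, 285.0, 263.0],
    "polarity_grantham":[ 8.1,   5.5,  13.0,  12.3,   5.2,   9.0,  10.4,   5.2,  11.3,   4.9,   5.7,  11.6,   8.0,  10.5,  10.5,   9.2,   8.6,   5.9,   5.4,   6.2],
    "polarity_zimmerman":[0.00,  1.48, 49.70, 49.90,  0.35,  0.00, 51.60,  0.13, 49.50,  0.13,  1.43,  3.38,  1.58,  3.53, 52.00,  1.67,  1.66,  0.13,  2.10,  1.61],
    "isoelectric_point":[6.00,  5.07,  2.77,  3.22,  5.48,  5.97,  7.59,  6.02,  9.74,  5.98,  5.74,  5.41,  6.30,  5.65, 10.76,  5.68,  5.60,  5.96,  5.89,  5.66],
    "net_charge_ph7":  [ 0.0,   0.0,  -1.0,  -1.0,   0.0,   0.0,   0.1,   0.0,   1.0,   0.0,   0.0,   0.0,   0.0,   0.0,   1.0,   0.0,   0.0,   0.0,   0.0,   0.0],
    "flexibility":     [ 0.36,  0.35,  0.51,  0.50,  0.31,  0.54,  0.32,  0.46,  0.47,  0.37,  0.30,  0.46,  0.51,  0.49,  0.53,  0.51,  0.44,  0.39,  0.31,  0.42],
    "helix_propensity":[ 1.42,  0.70,  1.01,  1.51,  1.13,  0.57,  1.00,  1.08,  1.16,  1.21,  1.45,  0.67,  0.57,  1.11,  0.98,  0.77,  0.83,  1.06,  1.08,  0.69],
    "sheet_propensity":[ 0.83,  1.19,  0.54,  0.37,  1.38,  0.75,  0.87,  1.60,  0.74,  1.30,  1.05,  0.89,  0.55,  1.10,  0.93,  0.75,  1.19,  1.70,  1.37,  1.47],
    "turn_propensity": [ 0.66,  1.19,  1.46,  0.74,  0.60,  1.56,  0.95,  0.47,  1.01,  0.59,  0.60,  1.56,  1.52,  0.98,  0.95,  1.43,  0.96,  0.50,  0.96,  1.14],
    "hbond_donors":    [ 0,     1,     0,     0,     0,     0,     1,     0,     1,     0,     0,     1,     0,     1,     3,     1,     1,     0,     1,     1  ],
    "hbond_acceptors": [ 0,     1,     4,     4,     0,     0,     1,     0,     0,     0,     1,     2,     0,     2,     0,     2,     2,     0,     0,     2  ],
    "side_chain_atoms":[ 1,     2,     4,     5,     7,     0,     6,     4,     5,     4,     4,     4,     3,     5,     7,     2,     3,     3,    10,     8  ],
    "rotatable_bonds": [ 0,     1,     2,     3,     2,     0,     2,     2,     4,     2,     3,     2,     0,     3,     4,     1,     1,     1,     2,     2  ],
    "aromatic":        [ 0,     0,     0,     0,     1,     0,     1,     0,     0,     0,     0,     0,     0,     0,     0,     0,     0,     0,     1,     1  ],
    "aliphatic":       [ 1,     0,     0,     0,     0,     0,     0,     1,     0,     1,     0,     0,     0,     0,     0,     0,     0,     1,     0,     0  ],
    "branched":        [ 0,     0,     0,     0,     0,     0,     0,     1,     0,     1,     0,     0,     0,     0,     0,     0,     1,     1,     0,     0  ],
    "sulfur":          [ 0,     1,     0,     0,     0,     0,     0,     0,     0,     0,     1,     0,     0,     0,     0,     0,     0,     0,     0,     0  ],
    "nucleophilic_ox": [ 0,     1,     0,     0,     0,     0,     0,     0,     0,     0,     0,     0,     0,     0,     0,     1,     1,     0,     0,     1  ],
}
# fmt: on


def raw_property_frame() -> pd.DataFrame:
    """The unscaled 20x25 property table (amino-acid rows, property columns)."""
    df = pd.DataFrame(_RAW, index=_AA_ORDER, dtype=float)
    df.index.name = "amino_acid"
    return df
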