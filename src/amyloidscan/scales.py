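"""Physicochemical amino-acid scales used as regression features.

Four classic scales cover the properties known to drive amyloid fibril
stability: side-chain hydrophobicity (Kyte & Doolittle), polarity and
side-chain bulkiness (Zimmerman), and beta-sheet propensity
(Chou & Fasman P(b)).
"""

from __future__ import annotations

KYTE_DOOLITTLE_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

ZIMMERMAN_POLARITY = {
    "A": 0.00, "G": 0.00, "I": 0.13, "L": 0.13, "V": 0.13,
    "F": 0.35, "M": 1.43, "C": 1.48, "P": 1.58, "Y": 1.61,
    "T": 1.66, "S": 1.67, "W": 2.10, "N": 3.38, "Q": 3.53,
    "K": 49.50, "D": 49.70, "E": 49.90, "H": 51.60, "R": 52.00,
}

ZIMMERMAN_BULKINESS = {
    "A": 11.50, "R": 14.28, "N": 12.82, "D": 11.68, "C": 13.46,
    "Q": 14.45, "E": 13.57, "G": 3.40, "H": 13.69, "I": 21.40,
    "L": 21.40, "K": 15.71, "M": 16.25, "F": 19.80, "P": 17.43,
    "S": 9.47, "T": 15.77, "W": 21.67, "Y": 18.03, "V": 21.57,
}

CHOU_FASMAN_BETA_SHEET = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19,
    "Q": 1.10, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60,
    "L": 1.30, "K": 0.74, "M": 1.05, "F": 1.38, "P": 0.55,
    "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.70,
}

#: Feature-name -> scale table, in the order features are emitted.
SCALES = {
    "hydrophobicity": KYTE_DOOLITTLE_HYDROPATHY,
    "polarity": ZIMMERMAN_POLARITY,
    "beta_sheet_propensity": CHOU_FASMAN_BETA_SHEET,
    "bulkiness": ZIMMERMAN_BULKINESS,
}
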