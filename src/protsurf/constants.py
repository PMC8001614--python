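"""Reference tables: van der Waals radii, maximal accessible areas, the
Kyte–Doolittle hydropathy scale and residue polarity partitions.

All residue types are 3-letter upper-case codes. Areas are in Å².
"""

from __future__ import annotations

# Element -> van der Waals radius, Å. Hydrogens are dropped at load time by
# default (cryo-EM depositions lack them) but a radius is kept for completeness.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "D": 1.20,
    "P": 1.80,
    "SE": 1.90,
}

STANDARD_AA: frozenset[str] = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

# Common modified residues mapped to their parent standard code; anything not
# listed here and not standard is kept in the model but excluded from
# composition / hydropathy statistics.
NONSTANDARD_PARENT: dict[str, str] = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",
    "HYP": "PRO",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "CSO": "CYS",
    "CSS": "CYS",
    "MLY": "LYS",
    "M3L": "LYS",
    "KCX": "LYS",
    "PCA": "GLU",
    "FME": "MET",
}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

# Maximal accessible surface areas used to normalize SASA to RSA.
# Rost & Sander (1994) is the default normalization; Tien et al. (2013)
# theoretical values are selectable by config.
MAX_ASA_TABLES: dict[str, dict[str, float]] = {
    "RostSander1994": {
        "ALA": 106.0, "ARG": 248.0, "ASN": 157.0, "ASP": 163.0,
        "CYS": 135.0, "GLN": 198.0, "GLU": 194.0, "GLY": 84.0,
        "HIS": 184.0, "ILE": 169.0, "LEU": 164.0, "LYS": 205.0,
        "MET": 188.0, "PHE": 197.0, "PRO": 136.0, "SER": 130.0,
        "THR": 142.0, "TRP": 227.0, "TYR": 222.0, "VAL": 142.0,
    },
    "Tien2013": {
        "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0,
        "CYS": 167.0, "GLN": 225.0, "GLU": 223.0, "GLY": 104.0,
        "HIS": 224.0, "ILE": 197.0, "LEU": 201.0, "LYS": 236.0,
        "MET": 224.0, "PHE": 240.0, "PRO": 159.0, "SER": 155.0,
        "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
    },
}

# Kyte & Doolittle (1982) hydropathy index: +4.5 (Ile, most hydrophobic)
# to -4.5 (Arg, most hydrophilic).
KD_SCALE: dict[str, float] = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

# Polarity partitions of the 20 standard types. "default" is the textbook
# partition with histidine counted as charged; "his_neutral" moves HIS to the
# polar-uncharged class.
POLARITY_SCHEMES: dict[str, dict[str, frozenset[str]]] = {
    "default": {
        "charged": frozenset({"ASP", "GLU", "LYS", "ARG", "HIS"}),
        "polar_uncharged": frozenset({"SER", "THR", "ASN", "GLN", "TYR", "CYS"}),
        "nonpolar": frozenset(
            {"GLY", "ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"}
        ),
    },
    "his_neutral": {
        "charged": frozenset({"ASP", "GLU", "LYS", "ARG"}),
        "polar_uncharged": frozenset(
            {"SER", "THR", "ASN", "GLN", "TYR", "CYS", "HIS"}
        ),
        "nonpolar": frozenset(
            {"GLY", "ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"}
        ),
    },
}


def standardize_res_type(res_type: str) -> tuple[str, bool]:
    """Map a residue name to its standard 3-letter code.

    Returns ``(code, is_standard)``; non-mappable names come back unchanged
    with ``is_standard=False``.
    """
    name = res_type.strip().upper()
    if name in STANDARD_AA:
        return name, True
    if name in NONSTANDARD_PARENT:
        return NONSTANDARD_PARENT[name], True
    return name, False
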