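"""Built-in per-element parameters.

Masses in amu; van der Waals radii are the Bondi compilation (Å). The radius
table is a default only — analyses that are radius-sensitive (SASA, nonpolar
solvation) accept per-atom overrides.
"""

ELEMENT_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "MG": 24.305, "NA": 22.990, "CL": 35.45, "K": 39.098,
    "CA": 40.078, "ZN": 65.38, "FE": 55.845, "MN": 54.938, "SE": 78.971,
}

# Bondi (1964) van der Waals radii, Å.
ELEMENT_VDW = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "MG": 1.73, "NA": 2.27, "CL": 1.75, "K": 2.75,
    "CA": 2.31, "ZN": 1.39, "FE": 2.00, "MN": 2.00, "SE": 1.90,
}

# Names that denote two-letter elements when they appear as full atom names
# (ions / metals in HETATM records). Protein atom names like "CA" (alpha
# carbon) are NOT in this set's scope: it is consulted only for HETATM
# records lacking an element column.
TWO_LETTER_ION_NAMES = {"MG", "NA", "CL", "ZN", "FE", "MN", "SE"}


def infer_element(atom_name: str, record: str = "ATOM") -> str:
    """Infer the element symbol from a PDB atom name.

    Standard-residue atom names start with the element's single letter
    (possibly preceded by a digit, e.g. ``1HB``). For HETATM records a
    full two-letter ion name (``MG``, ``CL`` ...) is taken as the element.
    """
    name = atom_name.strip().upper()
    if record == "HETATM" and name in TWO_LETTER_ION_NAMES:
        return name
    for ch in name:
        if ch.isalpha():
            return ch
    return ""
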