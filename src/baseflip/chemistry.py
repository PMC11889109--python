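"""Chemical naming tables and standard base geometry.

The per-base heavy-atom coordinates are the standard nucleic-acid reference
frame of Olson et al. (the convention shared by 3DNA and Curves-class tools):
the frame origin sits at the idealized base-pair centre, +x points into the
major groove, +y toward the reference-strand backbone and +z along the
reference strand 5'->3'.  All base atoms are planar at z = 0.  C1' is placed
at the frame position shared by purines and pyrimidines.
"""

from __future__ import annotations

import gemmi
import numpy as np

# ---------------------------------------------------------------------------
# residue naming dialects
# ---------------------------------------------------------------------------

#: map of accepted residue-name spellings to a one-letter canonical code
NUCLEOTIDE_ALIASES: dict[str, str] = {}
for _code, _names in {
    "A": ("DA", "A", "ADE"),
    "C": ("DC", "C", "CYT"),
    "G": ("DG", "G", "GUA"),
    "T": ("DT", "T", "THY"),
    "U": ("DU", "U", "URA", "URI"),
}.items():
    for _n in _names:
        NUCLEOTIDE_ALIASES[_n] = _code

#: canonical PDB residue name emitted by the builder, per one-letter code
PDB_RESNAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT", "U": "DU"}

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CTU")
COMPLEMENT = {"A": "T", "T": "A", "U": "A", "G": "C", "C": "G"}
# the strand-II partner the builder places opposite each strand-I base;
# uracil pairs adenine exactly as thymine does
WC_PARTNER = {"A": "T", "T": "A", "C": "G", "G": "C", "U": "A"}

#: residue names treated as uracil analogs when hunting for a flipped base in
#: an experimental recognition complex (2'-deoxypseudouridine and friends)
URACIL_ANALOG_NAMES = ("PSU", "PDU", "UPS", "UMS", "5IU", "BRU", "UFT")

AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL MSE SEC PYL HSD HSE HSP".split()
)


def canonical_na(resname: str) -> str | None:
    """One-letter nucleotide code for a residue name, or None if not nucleic."""
    return NUCLEOTIDE_ALIASES.get(resname.strip().upper())


def is_nucleotide(resname: str) -> bool:
    return canonical_na(resname) is not None


def is_amino_acid(resname: str) -> bool:
    return resname.strip().upper() in AMINO_ACIDS


# ---------------------------------------------------------------------------
# moiety atom-name tables
# ---------------------------------------------------------------------------

def _prime_variants(names: tuple[str, ...]) -> frozenset[str]:
    out = set()
    for n in names:
        out.add(n)
        out.add(n.replace("'", "*"))
    return frozenset(out)


#: sugar moiety; O3' is grouped with the sugar it belongs to, never with the
#: downstream phosphate
SUGAR_ATOMS = _prime_variants(
    ("C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O2'", "O3'",
     "H1'", "H2'", "H2''", "H3'", "H4'", "H5'", "H5''")
)

#: 5'-phosphate moiety of a nucleotide
PHOSPHATE_ATOMS = _prime_variants(
    ("P", "OP1", "O1P", "OP2", "O2P", "OP3", "O3P", "O5'", "HO5'")
)

#: everything of a nucleotide that is neither sugar nor phosphate: ring plus
#: exocyclic substituents and base protons
BASE_ATOMS = frozenset(
    "N1 C2 N3 C4 C5 C6 N7 C8 N9 O2 O4 O6 N2 N4 N6 C7 C5M C5A "
    "H1 H2 H3 H5 H6 H8 H21 H22 H41 H42 H61 H62 H71 H72 H73 "
    "1H2 2H2 1H4 2H4 1H6 2H6 1H5M 2H5M 3H5M".split()
)

#: atoms stripped when demethylating thymine to uracil
THYMINE_METHYL = frozenset("C7 C5M C5A H71 H72 H73 1H5M 2H5M 3H5M".split())


def atom_mass(element: str) -> float:
    """Standard atomic weight (amu) for an element symbol."""
    el = gemmi.Element(element.capitalize() if element else "X")
    w = el.weight
    if not np.isfinite(w) or w <= 0:
        return 12.011  # unknown elements behave like carbon
    return float(w)


def element_from_name(name: str, resname: str = "") -> str:
    """Infer the element from a PDB atom name when the element column is blank."""
    s = name.strip().upper().lstrip("0123456789")
    if not s:
        return "C"
    if s[0] == "H" or (len(name) >= 2 and name[0] in "123456789" and s[0] == "H"):
        return "H"
    for two in ("CL", "BR", "NA", "MG", "ZN", "FE", "MN", "SE"):
        if s.startswith(two) and len(s) >= 2 and not is_nucleotide(resname):
            # two-letter symbols are rare in nucleic/protein context; only
            # accept them when the name is exactly the symbol
            if s == two:
                return two.capitalize()
    return s[0]


# ---------------------------------------------------------------------------
# standard reference-frame base coordinates (x, y); z = 0 for all atoms
# ---------------------------------------------------------------------------

STANDARD_BASE_XY: dict[str, dict[str, tuple[float, float]]] = {
    "A": {
        "N9": (-1.291, 4.498), "C8": (0.024, 4.897), "N7": (0.877, 3.902),
        "C5": (0.071, 2.771), "C6": (0.369, 1.398), "N6": (1.611, 0.909),
        "N1": (-0.668, 0.532), "C2": (-1.912, 1.023), "N3": (-2.320, 2.290),
        "C4": (-1.267, 3.124),
    },
    "G": {
        "N9": (-1.289, 4.551), "C8": (0.023, 4.962), "N7": (0.870, 3.969),
        "C5": (0.071, 2.833), "C6": (0.424, 1.460), "O6": (1.554, 0.955),
        "N1": (-0.700, 0.641), "C2": (-1.999, 1.087), "N2": (-2.949, 0.139),
        "N3": (-2.342, 2.364), "C4": (-1.265, 3.177),
    },
    "C": {
        "N1": (-1.285, 4.542), "C2": (-1.472, 3.158), "O2": (-2.628, 2.709),
        "N3": (-0.391, 2.344), "C4": (0.837, 2.868), "N4": (1.875, 2.027),
        "C5": (1.056, 4.275), "C6": (-0.023, 5.068),
    },
    "T": {
        "N1": (-1.284, 4.500), "C2": (-1.462, 3.135), "O2": (-2.562, 2.608),
        "N3": (-0.298, 2.407), "C4": (0.994, 2.897), "O4": (1.944, 2.119),
        "C5": (1.106, 4.338), "C7": (2.466, 4.961), "C6": (-0.024, 5.057),
    },
    "U": {
        "N1": (-1.284, 4.500), "C2": (-1.462, 3.131), "O2": (-2.563, 2.608),
        "N3": (-0.302, 2.397), "C4": (0.989, 2.884), "O4": (1.935, 2.094),
        "C5": (1.089, 4.311), "C6": (-0.024, 5.053),
    },
}

#: C1' position in the standard base frame (identical for purines/pyrimidines)
C1_PRIME_STD = np.array([-2.477, 5.399, 0.0])

#: ring atoms used to least-squares fit a base onto its standard frame
FRAME_FIT_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "T": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

#: glycosidic nitrogen per base
GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "T": "N1", "U": "N1"}
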