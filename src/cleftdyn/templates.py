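"""Residue chemistry templates for hydrogen-bond analysis.

For each residue name we record which N/O heavy atoms are expected to carry
hydrogens (donors, with the expected hydrogen count and a geometry class
used when placing missing protons) and which are lone-pair acceptors.
Backbone entries (N donor, O/OXT acceptors) are merged in for every amino
acid.  The NADP(H) entries follow the PDB chemical-component atom naming
for NAP (oxidized, 2'-phosphate) and NDP (reduced); the moiety map assigns
each cofactor heavy atom to the adenine, nicotinamide or
dinucleotide/phosphate group.
"""

from __future__ import annotations

from .structio import AMINO_ACIDS, WATER_RESNAMES

# geometry classes for hydrogen placement
SP2 = "sp2"      # fixed in the plane of the heavy-atom frame (amides, guanidinium)
SP3 = "sp3"      # rotatable hydroxyl: torsion chosen toward the nearest acceptor
WATER = "water"

# donors: heavy atom -> (number of hydrogens, geometry class)
# acceptors: heavy atoms with lone-pair capacity
_SIDECHAINS: dict[str, dict] = {
    "SER": {"donors": {"OG": (1, SP3)}, "acceptors": {"OG"}},
    "THR": {"donors": {"OG1": (1, SP3)}, "acceptors": {"OG1"}},
    "TYR": {"donors": {"OH": (1, SP3)}, "acceptors": {"OH"}},
    "ASN": {"donors": {"ND2": (2, SP2)}, "acceptors": {"OD1"}},
    "GLN": {"donors": {"NE2": (2, SP2)}, "acceptors": {"OE1"}},
    "ASP": {"donors": {}, "acceptors": {"OD1", "OD2"}},
    "GLU": {"donors": {}, "acceptors": {"OE1", "OE2"}},
    "LYS": {"donors": {"NZ": (3, SP3)}, "acceptors": set()},
    "ARG": {
        "donors": {"NE": (1, SP2), "NH1": (2, SP2), "NH2": (2, SP2)},
        "acceptors": set(),
    },
    # neutral His, proton on ND1 (HSD tautomer); the ring N without a
    # hydrogen is treated as acceptor at assignment time either way
    "HIS": {"donors": {"ND1": (1, SP2)}, "acceptors": {"NE2"}},
    "HSD": {"donors": {"ND1": (1, SP2)}, "acceptors": {"NE2"}},
    "HSE": {"donors": {"NE2": (1, SP2)}, "acceptors": {"ND1"}},
    "HSP": {"donors": {"ND1": (1, SP2), "NE2": (1, SP2)}, "acceptors": set()},
    "TRP": {"donors": {"NE1": (1, SP2)}, "acceptors": set()},
    "CYS": {"donors": {}, "acceptors": set()},  # thiol excluded (N/O only)
    "MET": {"donors": {}, "acceptors": set()},
}

_COFACTOR = {
    "donors": {
        "N6A": (2, SP2),   # adenine exocyclic amine
        "N7N": (2, SP2),   # nicotinamide amide NH2
        "O2D": (1, SP3), "O3D": (1, SP3), "O3B": (1, SP3),  # ribose hydroxyls
    },
    "acceptors": {
        # adenine ring nitrogens
        "N1A", "N3A", "N7A",
        # nicotinamide carbonyl and ring N
        "O7N", "N1N",
        # ribose ring / hydroxyl oxygens
        "O4B", "O4D", "O2D", "O3D", "O3B",
        # pyrophosphate and 2'-phosphate oxygens
        "O1A", "O2A", "O1N", "O2N", "O3", "O5B", "O5D",
        "O1X", "O2X", "O3X", "O2B",
    },
}

ADENINE = "adenine"
NICOTINAMIDE = "nicotinamide"
DINUCLEOTIDE = "dinucleotide/phosphate"

#: cofactor heavy-atom name -> moiety, PDB component naming for NAP/NDP
NADP_MOIETY_MAP: dict[str, str] = {}
for _name in ("N1A", "C2A", "N3A", "C4A", "C5A", "C6A", "N6A", "N7A", "C8A", "N9A"):
    NADP_MOIETY_MAP[_name] = ADENINE
for _name in ("N1N", "C2N", "C3N", "C4N", "C5N", "C6N", "C7N", "O7N", "N7N"):
    NADP_MOIETY_MAP[_name] = NICOTINAMIDE
for _name in (
    "C1B", "C2B", "O2B", "C3B", "O3B", "C4B", "O4B", "C5B", "O5B",
    "C1D", "C2D", "O2D", "C3D", "O3D", "C4D", "O4D", "C5D", "O5D",
    "PA", "O1A", "O2A", "O3", "PN", "O1N", "O2N",
    "P2B", "O1X", "O2X", "O3X",
):
    NADP_MOIETY_MAP[_name] = DINUCLEOTIDE


def residue_template(resname: str) -> dict | None:
    """Donor/acceptor template for a residue name, or None if unknown."""
    resname = resname.upper()
    if resname in WATER_RESNAMES:
        return {"donors": {"O": (2, WATER), "OW": (2, WATER), "OH2": (2, WATER)},
                "acceptors": {"O", "OW", "OH2"}}
    if resname in ("NAP", "NDP"):
        return _COFACTOR
    if resname in AMINO_ACIDS:
        side = _SIDECHAINS.get(resname, {"donors": {}, "acceptors": set()})
        donors = {"N": (0 if resname == "PRO" else 1, SP2)}
        donors.update(side["donors"])
        acceptors = {"O", "OXT"} | set(side["acceptors"])
        return {"donors": donors, "acceptors": acceptors}
    if resname in ("ZN", "NA", "CL", "MG", "K", "CA"):
        return {"donors": {}, "acceptors": set()}
    return None
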