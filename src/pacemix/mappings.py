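"""Residue -> coarse-grained bead mapping (MARTINI 2.2-style, one backbone
bead BB on the C-alpha position plus 0-4 side-chain beads at the centre of
mass of their member heavy atoms).

The member-atom splits follow the standard four-heavy-atoms-per-bead
MARTINI convention; bead types refer to the bundled CG parameter table.
Treat this as editable input data: pass your own table to
:func:`pacemix.topology_builder.map_to_cg` for other mappings.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BeadDef:
    name: str           # BB, SC1 ...
    members: tuple      # heavy-atom names contributing to the bead position
    type_key: str       # CG parameter-table type
    mass: float = 72.0  # amu (45 for small ring beads)


BACKBONE_MEMBERS = ("N", "CA", "C", "O")


def _bb(type_key: str = "P5") -> BeadDef:
    return BeadDef("BB", BACKBONE_MEMBERS, type_key)


CG_MAPPING: dict[str, tuple[BeadDef, ...]] = {
    "GLY": (_bb(),),
    "ALA": (_bb("P4"),),
    "CYS": (_bb(), BeadDef("SC1", ("CB", "SG"), "C5")),
    "VAL": (_bb(), BeadDef("SC1", ("CB", "CG1", "CG2"), "C2")),
    "LEU": (_bb(), BeadDef("SC1", ("CB", "CG", "CD1", "CD2"), "C1")),
    "ILE": (_bb(), BeadDef("SC1", ("CB", "CG1", "CG2", "CD1"), "C1")),
    "MET": (_bb(), BeadDef("SC1", ("CB", "CG", "SD", "CE"), "C5")),
    "PRO": (_bb(), BeadDef("SC1", ("CB", "CG", "CD"), "C3")),
    "SER": (_bb(), BeadDef("SC1", ("CB", "OG"), "P1")),
    "THR": (_bb(), BeadDef("SC1", ("CB", "OG1", "CG2"), "P1")),
    "ASN": (_bb(), BeadDef("SC1", ("CB", "CG", "OD1", "ND2"), "P5")),
    "GLN": (_bb(), BeadDef("SC1", ("CB", "CG", "CD", "OE1", "NE2"), "P4")),
    "ASP": (_bb(), BeadDef("SC1", ("CB", "CG", "OD1", "OD2"), "Qa")),
    "GLU": (_bb(), BeadDef("SC1", ("CB", "CG", "CD", "OE1", "OE2"), "Qa")),
    "LYS": (_bb(), BeadDef("SC1", ("CB", "CG", "CD"), "C3"),
            BeadDef("SC2", ("CE", "NZ"), "Qd")),
    "ARG": (_bb(), BeadDef("SC1", ("CB", "CG", "CD"), "N0"),
            BeadDef("SC2", ("NE", "CZ", "NH1", "NH2"), "Qd")),
    "HIS": (_bb(), BeadDef("SC1", ("CB", "CG"), "SC4", 45.0),
            BeadDef("SC2", ("CD2", "NE2"), "SP1", 45.0),
            BeadDef("SC3", ("ND1", "CE1"), "SP1", 45.0)),
    "PHE": (_bb(), BeadDef("SC1", ("CB", "CG", "CD1"), "SC5", 45.0),
            BeadDef("SC2", ("CD2", "CE2"), "SC5", 45.0),
            BeadDef("SC3", ("CE1", "CZ"), "SC5", 45.0)),
    "TYR": (_bb(), BeadDef("SC1", ("CB", "CG", "CD1"), "SC4", 45.0),
            BeadDef("SC2", ("CD2", "CE2"), "SC4", 45.0),
            BeadDef("SC3", ("CE1", "CZ", "OH"), "SP1", 45.0)),
    "TRP": (_bb(), BeadDef("SC1", ("CB", "CG", "CD2"), "SC4", 45.0),
            BeadDef("SC2", ("CD1", "NE1", "CE2"), "SP1", 45.0),
            BeadDef("SC3", ("CE3", "CZ3"), "SC5", 45.0),
            BeadDef("SC4", ("CZ2", "CH2"), "SC5", 45.0)),
}
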