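"""Structure data model, PDB I/O and secondary-structure assignment.

Internal length unit is nanometres throughout the package; PDB files are
read and written in angstroms and converted at the boundary.  Every residue
carries a secondary-structure label (``H``/``E``/``C``), an environment tag
(``solution``/``membrane``) and a resolution tag per site (``UA`` for
united-atom sites, ``CG`` for coarse-grained beads).  Coarse-grained beads
are recognised by their names (``BB``, ``SC1`` ... ``SC4``), the ELNEDYN
convention in which the backbone bead sits on the C-alpha position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import gemmi
import numpy as np

UA = "UA"
CG = "CG"

#: bead names that mark a site as coarse-grained
CG_BEAD_NAMES = frozenset({"BB", "SC1", "SC2", "SC3", "SC4"})

ANGSTROM_PER_NM = 10.0

_ELEMENT_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "X": 72.0,
}


class StructureError(ValueError):
    """Raised for malformed structures or unparsable structure files."""


@dataclass
class Site:
    """One interaction site: a united-atom atom or a coarse-grained bead."""

    id: int
    chain_id: str
    residue_index: int
    name: str
    position: np.ndarray          # nm
    resolution: str = UA          # UA | CG
    charge: float = 0.0           # e
    mass: float = 0.0             # amu
    type_key: str = ""            # force-field type
    element: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"site {self.name}: position must be a finite 3-vector")
        if self.mass < 0:
            raise StructureError(f"site {self.name}: negative mass")
        if self.resolution not in (UA, CG):
            raise StructureError(f"site {self.name}: bad resolution {self.resolution!r}")


@dataclass
class Residue:
    index: int                    # author numbering
    name: str                     # 3-letter code
    sites: list[Site] = field(default_factory=list)
    ss_label: str = "C"           # H | E | C
    environment: str = "solution"  # solution | membrane

    def site(self, name: str) -> Optional[Site]:
        for s in self.sites:
            if s.name == name:
                return s
        return None

    @property
    def backbone_site(self) -> Optional[Site]:
        """The C-alpha atom (UA) or BB bead (CG) of the residue."""
        return self.site("CA") or self.site("BB")


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Structure:
    """Chains of residues plus optional extra coordinate frames (models)."""

    chains: list[Chain] = field(default_factory=list)
    box: Optional[np.ndarray] = None               # nm
    extra_frames: list[np.ndarray] = field(default_factory=list)

    @property
    def model_count(self) -> int:
        return 1 + len(self.extra_frames)

    def residues(self) -> Iterator[Residue]:
        for ch in self.chains:
            yield from ch.residues

    def sites(self) -> Iterator[Site]:
        for r in self.residues():
            yield from r.sites

    @property
    def n_residues(self) -> int:
        return sum(len(ch.residues) for ch in self.chains)

    @property
    def n_sites(self) -> int:
        return sum(1 for _ in self.sites())

    def coords(self) -> np.ndarray:
        """(n_sites, 3) coordinate array in nm, site order."""
        if self.n_sites == 0:
            return np.zeros((0, 3))
        return np.array([s.position for s in self.sites()])

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        sites = list(self.sites())
        if xyz.shape != (len(sites), 3):
            raise StructureError(f"coordinate array shape {xyz.shape} != ({len(sites)}, 3)")
        for s, p in zip(sites, xyz):
            s.position = p.copy()

    def frame_coords(self, i: int) -> np.ndarray:
        """Coordinates of model ``i`` (0-based); frame 0 is the live coordinates."""
        if i == 0:
            return self.coords()
        return self.extra_frames[i - 1]

    def residue(self, chain_id: str, index: int) -> Residue:
        for ch in self.chains:
            if ch.id == chain_id:
                for r in ch.residues:
                    if r.index == index:
                        return r
        raise KeyError(f"no residue {index} in chain {chain_id!r}")

    def copy(self) -> "Structure":
        import copy as _copy
        return _copy.deepcopy(self)

    def validate(self) -> None:
        ids = [s.id for s in self.sites()]
        if len(ids) != len(set(ids)):
            raise StructureError("site ids are not unique")
        for ch in self.chains:
            idx = [r.index for r in ch.residues]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise StructureError(f"chain {ch.id}: residue indices not strictly increasing")
            for r in ch.residues:
                n_bb = sum(1 for s in r.sites if s.name in ("CA", "BB"))
                if n_bb > 1:
                    raise StructureError(f"residue {ch.id}:{r.index} has {n_bb} backbone sites")


def _mass_of(element: str) -> float:
    return _ELEMENT_MASS.get(element.upper(), 0.0)


def guess_element(atom_name: str) -> str:
    """Element from a PDB atom name; CG bead names map to the pseudo-element X."""
    if atom_name in CG_BEAD_NAMES:
        return "X"
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] == "H" or (len(atom_name) > len(stripped) and stripped[0] == "H"):
        return "H"
    if stripped[:2].capitalize() in ("Cl", "Br", "Fe", "Zn", "Mg", "Na"):
        return stripped[:2].capitalize()
    return stripped[0]


def read_structure(path, format: str = "pdb") -> Structure:
    """Read a (possibly multi-model) PDB file into a :class:`Structure`.

    Coordinates are converted from angstrom to nm.  For alternate locations
    the highest-occupancy conformer is kept (alphabetical altloc on ties).
    Extra MODELs become trajectory frames (``extra_frames``).
    """
    if format != "pdb":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0 or sum(ch.count_atom_sites() for ch in st[0]) == 0:
        raise StructureError(f"{path}: no ATOM records")

    out = Structure()
    site_id = 0
    for gch in st[0]:
        chain = Chain(id=gch.name)
        for gres in gch:
            res = Residue(index=gres.seqid.num, name=gres.name)
            # altloc resolution: best occupancy per atom name, ties alphabetical
            best: dict[str, gemmi.Atom] = {}
            for atom in gres:
                prev = best.get(atom.name)
                if prev is None:
                    best[atom.name] = atom
                elif atom.altloc == prev.altloc == "\0" or (not atom.altloc and not prev.altloc):
                    raise StructureError(
                        f"{path}: duplicate atom {atom.name!r} in residue "
                        f"{gch.name}:{gres.seqid.num} ({gres.name})"
                    )
                elif (atom.occ, -ord(atom.altloc or "~")) > (prev.occ, -ord(prev.altloc or "~")):
                    best[atom.name] = atom
            # preserve file order of the retained conformers
            seen = set()
            for atom in gres:
                if atom.name in seen or best[atom.name] is not atom:
                    continue
                seen.add(atom.name)
                elem = atom.element.name if atom.element and atom.element.name != "X" else ""
                elem = elem or guess_element(atom.name)
                res.sites.append(Site(
                    id=site_id,
                    chain_id=gch.name,
                    residue_index=gres.seqid.num,
                    name=atom.name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]) / ANGSTROM_PER_NM,
                    resolution=CG if atom.name in CG_BEAD_NAMES else UA,
                    mass=_mass_of(elem) if elem else 0.0,
                    element=elem,
                ))
                site_id += 1
            chain.residues.append(res)
        out.chains.append(chain)

    if st.cell and st.cell.a > 1.0:
        out.box = np.array([st.cell.a, st.cell.b, st.cell.c]) / ANGSTROM_PER_NM

    n_sites = out.n_sites
    for model in list(st)[1:]:
        xyz = []
        for gch in model:
            for gres in gch:
                for atom in gres:
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        arr = np.asarray(xyz) / ANGSTROM_PER_NM
        if arr.shape != (n_sites, 3):
            raise StructureError(f"{path}: MODEL with {len(xyz)} atoms, expected {n_sites}")
        out.extra_frames.append(arr)
    out.validate()
    return out


def write_structure(s: Structure, path) -> None:
    """Write a Structure (and any extra frames) as a PDB file, in angstrom."""
    if s.n_sites == 0:
        raise StructureError("refusing to write an empty structure")
    s.validate()
    st = gemmi.Structure()
    st.name = "pacemix"
    frames = [s.coords()] + list(s.extra_frames)
    for imodel, xyz in enumerate(frames, start=1):
        model = gemmi.Model(imodel)
        k = 0
        for ch in s.chains:
            gch = gemmi.Chain(ch.id)
            for r in ch.residues:
                gres = gemmi.Residue()
                gres.name = r.name
                gres.seqid = gemmi.SeqId(r.index, " ")
                for site in r.sites:
                    atom = gemmi.Atom()
                    atom.name = site.name
                    p = xyz[k] * ANGSTROM_PER_NM
                    atom.pos = gemmi.Position(*p)
                    atom.occ = 1.0
                    elem = site.element or guess_element(site.name)
                    try:
                        atom.element = gemmi.Element(elem if elem != "X" else "C")
                    except Exception:
                        atom.element = gemmi.Element("C")
                    gres.add_atom(atom)
                    k += 1
                gch.add_residue(gres)
            model.add_chain(gch)
        st.add_model(model)
    if s.box is not None:
        a, b, c = np.asarray(s.box) * ANGSTROM_PER_NM
        st.cell = gemmi.UnitCell(a, b, c, 90, 90, 90)
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


# ---------------------------------------------------------------------------
# secondary structure

def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    b2 = p3 - p2
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    return math.degrees(math.atan2(y, x))


# dihedral windows for the heuristic assignment (degrees)
_HELIX_PHI = (-100.0, -30.0)
_HELIX_PSI = (-80.0, -5.0)
_SHEET_PHI = (-180.0, -90.0)
_SHEET_PSI = (90.0, 180.0)
_MIN_HELIX_RUN = 4
_MIN_SHEET_RUN = 3


def backbone_dihedrals(chain: Chain) -> list[tuple[Optional[float], Optional[float]]]:
    """(phi, psi) per residue; None where the flanking residue is missing."""
    out: list[tuple[Optional[float], Optional[float]]] = []
    rs = chain.residues
    for i, r in enumerate(rs):
        n, ca, c = r.site("N"), r.site("CA"), r.site("C")
        if n is None or ca is None or c is None:
            raise StructureError(
                f"residue {chain.id}:{r.index} lacks backbone N/CA/C for dihedral assignment")
        phi = psi = None
        if i > 0 and rs[i - 1].index == r.index - 1:
            cprev = rs[i - 1].site("C")
            if cprev is not None:
                phi = dihedral(cprev.position, n.position, ca.position, c.position)
        if i + 1 < len(rs) and rs[i + 1].index == r.index + 1:
            nnext = rs[i + 1].site("N")
            if nnext is not None:
                psi = dihedral(n.position, ca.position, c.position, nnext.position)
        out.append((phi, psi))
    return out


def _in_window(x: Optional[float], lo: float, hi: float) -> bool:
    return x is not None and lo < x < hi


def assign_secondary_structure(
    s: Structure, mode: str = "dihedral", annotation: Optional[str] = None
) -> Structure:
    """Set ``ss_label`` on every residue (in place; the structure is returned).

    ``dihedral`` mode labels H for >= 4 consecutive residues with helical
    (phi, psi), E for >= 3 consecutive residues with extended (phi, psi),
    otherwise C; chain termini lacking a dihedral are C.  ``provided`` mode
    copies a one-character-per-residue H/E/C string verbatim.
    """
    if mode == "provided":
        if annotation is None or len(annotation) != s.n_residues:
            raise ValueError(
                f"annotation length {len(annotation or '')} != residue count {s.n_residues}")
        if set(annotation) - set("HEC"):
            raise ValueError("annotation may only contain H, E, C")
        for r, lab in zip(s.residues(), annotation):
            r.ss_label = lab
        return s
    if mode != "dihedral":
        raise ValueError(f"unknown mode {mode!r}")

    for ch in s.chains:
        phipsi = backbone_dihedrals(ch)
        helical = [_in_window(phi, *_HELIX_PHI) and _in_window(psi, *_HELIX_PSI)
                   for phi, psi in phipsi]
        extended = [_in_window(phi, *_SHEET_PHI) and _in_window(psi, *_SHEET_PSI)
                    for phi, psi in phipsi]
        labels = ["C"] * len(ch.residues)
        for flags, lab, min_run in ((helical, "H", _MIN_HELIX_RUN),
                                    (extended, "E", _MIN_SHEET_RUN)):
            i = 0
            while i < len(flags):
                if flags[i]:
                    j = i
                    while j < len(flags) and flags[j]:
                        j += 1
                    if j - i >= min_run:
                        for k in range(i, j):
                            labels[k] = lab
                    i = j
                else:
                    i += 1
        for r, lab in zip(ch.residues, labels):
            r.ss_label = lab
    return s


def set_environment(s: Structure, environment: str = "solution",
                    residues: Optional[Sequence[tuple[str, int]]] = None) -> Structure:
    """Tag residues as ``solution`` or ``membrane`` (all residues by default)."""
    if environment not in ("solution", "membrane"):
        raise ValueError(f"bad environment {environment!r}")
    keys = set(residues) if residues is not None else None
    for ch in s.chains:
        for r in ch.residues:
            if keys is None or (ch.id, r.index) in keys:
                r.environment = environment
    return s
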