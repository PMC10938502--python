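"""Deterministic synthetic structures for testing and demonstration.

All generators are pure functions of their arguments (plus an explicit seed
where randomness is involved): the same call always produces byte-identical
structures.  Backbone geometry is built with the standard internal-coordinate
chain construction (NeRF) from ideal peptide bond lengths and angles, so the
dihedral-based secondary-structure labeller sees exactly the phi/psi values
the generator was given.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .model_core import (
    CG, UA, Chain, Residue, Site, Structure, assign_secondary_structure,
)

# ideal backbone internal coordinates, nm / degrees
BOND_N_CA = 0.1458
BOND_CA_C = 0.1525
BOND_C_N = 0.1329
BOND_C_O = 0.1231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA = 180.0

ALPHA_PHI, ALPHA_PSI = -57.0, -47.0
EXTENDED_PHI, EXTENDED_PSI = -120.0, 120.0
# polyproline-II-like coil: helical phi window but non-helical psi
COIL_PHI, COIL_PSI = -75.0, 145.0

_BB_MASS = {"N": 14.007, "CA": 12.011, "C": 12.011, "O": 15.999, "CB": 12.011}
_BB_ELEM = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d from a-b-c with |cd| = bond, angle(b,c,d), torsion(a,b,c,d)."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_backbone(phis: Sequence[float], psis: Sequence[float],
                  chain_id: str = "A", first_index: int = 1,
                  residue_names: Optional[Sequence[str]] = None,
                  start_site_id: int = 0) -> Chain:
    """Backbone chain (N, CA, C, O per residue) from per-residue dihedrals.

    ``phis[0]`` and ``psis[-1]`` are still used geometrically (to seed the
    chain and to place the last carbonyl O) but have no defined dihedral in
    the finished chain.
    """
    n = len(phis)
    if n < 1 or len(psis) != n:
        raise ValueError("need equal-length, non-empty phi/psi lists")
    names = list(residue_names) if residue_names is not None else ["ALA"] * n
    N = [None] * n
    CA = [None] * n
    C = [None] * n
    # seed residue 0 with ideal internal geometry in the xy plane
    N[0] = np.zeros(3)
    CA[0] = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    C[0] = CA[0] + np.array([-BOND_CA_C * math.cos(ang), BOND_CA_C * math.sin(ang), 0.0])
    for i in range(1, n):
        N[i] = _place(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psis[i - 1])
        CA[i] = _place(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        C[i] = _place(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, phis[i])
    chain = Chain(id=chain_id)
    sid = start_site_id
    for i in range(n):
        O = _place(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psis[i] + 180.0)
        res = Residue(index=first_index + i, name=names[i])
        for name, pos in (("N", N[i]), ("CA", CA[i]), ("C", C[i]), ("O", O)):
            res.sites.append(Site(
                id=sid, chain_id=chain_id, residue_index=res.index, name=name,
                position=pos, resolution=UA, mass=_BB_MASS[name], element=_BB_ELEM[name],
            ))
            sid += 1
        chain.residues.append(res)
    return chain


def make_ideal_helix(n: int, phi: float = ALPHA_PHI, psi: float = ALPHA_PSI,
                     chain_id: str = "A", first_index: int = 1) -> Structure:
    """Ideal alpha-helix of ``n`` residues (backbone N, CA, C, O).

    The default dihedrals give the canonical helix geometry: ~0.15 nm rise
    and ~100 degree twist per residue, C-alpha radius ~0.23 nm, consecutive
    C-alpha distance 3.8 A.  Interior residues are labelled H.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    s = Structure(chains=[make_backbone([phi] * n, [psi] * n, chain_id, first_index)])
    if n >= 3:
        assign_secondary_structure(s, mode="dihedral")
    return s


def make_extended_strand(n: int, phi: float = EXTENDED_PHI, psi: float = EXTENDED_PSI,
                         chain_id: str = "A", first_index: int = 1) -> Structure:
    """Extended (beta-strand-like) chain of ``n`` residues."""
    if n < 1:
        raise ValueError("n must be >= 1")
    s = Structure(chains=[make_backbone([phi] * n, [psi] * n, chain_id, first_index)])
    if n >= 3:
        assign_secondary_structure(s, mode="dihedral")
    return s


def make_two_domain_fixture(seed: int = 0, helix_len: int = 12, linker_len: int = 8):
    """Two helical domains joined by a coil linker, plus its partition pair.

    Returns ``(structure, (spec, swapped_spec))`` where both partition specs
    pass validation: the cut sits at the linker midpoint, more than two
    residues away from either helix.
    """
    from .partitioner import auto_partition_monomer, swap_resolutions

    n = 2 * helix_len + linker_len
    phis = [ALPHA_PHI] * helix_len + [COIL_PHI] * linker_len + [ALPHA_PHI] * helix_len
    psis = [ALPHA_PSI] * helix_len + [COIL_PSI] * linker_len + [ALPHA_PSI] * helix_len
    rng = np.random.default_rng(seed)
    # tiny deterministic dihedral jitter so distinct seeds give distinct files
    jitter = rng.uniform(-1.0, 1.0, size=(2, n))
    phis = [p + j for p, j in zip(phis, jitter[0])]
    psis = [p + j for p, j in zip(psis, jitter[1])]
    s = Structure(chains=[make_backbone(phis, psis)])
    assign_secondary_structure(s, mode="dihedral")
    spec = auto_partition_monomer(s, strategy="midpoint")
    return s, (spec, swap_resolutions(spec))


def make_sheet_fixture(sheet_strands: Sequence[Sequence[int]] = ((6, 6, 6), (6, 6, 6)),
                       spacing: float = 0.48) -> Structure:
    """Single chain whose strands form beta-sheets, for partition tests.

    ``sheet_strands`` gives the strand lengths of each sheet.  Strands of a
    sheet are extended segments laid side by side ``spacing`` nm apart
    (< 0.55 nm, so neighbours pair); consecutive sheets are separated by a
    large offset so they do not pair with each other.  Strands are joined by
    long coil linkers carrying C labels (secondary structure is attached as a
    provided annotation since the linkers are geometrically artificial).
    """
    chain = Chain(id="A")
    sid = 0
    resi = 1
    ss = []
    strand_groups = [list(g) for g in sheet_strands]
    y_offset = 0.0
    linker_len = 8
    for group in strand_groups:
        for k, slen in enumerate(group):
            sub = make_backbone([EXTENDED_PHI] * slen, [EXTENDED_PSI] * slen,
                                chain_id="A", first_index=resi, start_site_id=sid)
            shift = np.array([0.0, y_offset + k * spacing, 0.0])
            for r in sub.residues:
                for site in r.sites:
                    site.position = site.position + shift
            chain.residues.extend(sub.residues)
            ss.extend("E" * slen)
            sid += 4 * slen
            resi += slen
            # coil linker, placed far away in z so it pairs with nothing
            link = make_backbone([COIL_PHI] * linker_len, [COIL_PSI] * linker_len,
                                 chain_id="A", first_index=resi, start_site_id=sid)
            for r in link.residues:
                for site in r.sites:
                    site.position = site.position + shift + np.array([0.0, 0.0, 3.0 + resi * 0.1])
            chain.residues.extend(link.residues)
            ss.extend("C" * linker_len)
            sid += 4 * linker_len
            resi += linker_len
        y_offset += 10.0
    s = Structure(chains=[chain])
    assign_secondary_structure(s, mode="provided", annotation="".join(ss))
    return s


def make_chain_from_ss(ss: str, names: Optional[Sequence[str]] = None,
                       chain_id: str = "A") -> Structure:
    """Straight CA-trace-free backbone with a provided H/E/C annotation.

    Residues are built as an extended chain (so strands never pair into
    multi-strand sheets); the annotation is attached verbatim.  Used by the
    partition-rule property tests, where only labels and residue names matter.
    """
    n = len(ss)
    if n < 1:
        raise ValueError("empty annotation")
    s = Structure(chains=[make_backbone([EXTENDED_PHI] * n, [EXTENDED_PSI] * n,
                                        chain_id=chain_id, residue_names=names)])
    assign_secondary_structure(s, mode="provided", annotation=ss)
    return s


def _rotz(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_trimer_toy(tilt: float = 63.0, radius: float = 1.0,
                    arm_length: float = 6.0, r37: float = 1.8, r38: float = 0.8):
    """C3-symmetric toy mimicking a trimeric mechanosensitive channel.

    Per chain: an 11-residue "arm helix" (residues 850-860, CA sites on a
    short segment) whose centre of mass sits ``arm_length`` nm from the pore
    centre at angle ``tilt`` degrees from the internal (z) axis; two vertical
    pore helices ("TM37" at radius ``r37`` nm, "TM38" at ``r38`` nm, 5 CA
    sites each); one gating-valine CB marker at radius ``radius`` nm; plus
    shared cap (top) and CTD (bottom) marker sites.  Exact C3 symmetry about
    z by construction.

    Returns ``(structure, selections)`` where ``selections`` maps named
    groups to per-chain lists of site ids.
    """
    if not 0.0 < tilt < 180.0:
        raise ValueError("tilt must be in (0, 180)")
    sel: dict[str, list] = {
        "arm_helix": [], "ile859": [], "tm37": [], "tm38": [],
        "valine_cb": [], "cap": [], "ctd": [], "pore_region": [],
    }
    chains = []
    sid = 0
    t = math.radians(tilt)
    arm_dir0 = np.array([math.sin(t), 0.0, math.cos(t)])
    for c in range(3):
        R = _rotz(120.0 * c)
        ch = Chain(id="ABC"[c])
        arm_ids, tm37_ids, tm38_ids = [], [], []

        def add(resi, resname, name, pos, element="C", mass=12.011):
            nonlocal sid
            r = Residue(index=resi, name=resname)
            r.sites.append(Site(id=sid, chain_id=ch.id, residue_index=resi, name=name,
                                position=R @ np.asarray(pos, float), resolution=UA,
                                mass=mass, element=element))
            ch.residues.append(r)
            sid += 1
            return sid - 1

        # arm helix: 11 CA sites along a short segment, COM at arm_length*dir
        com = arm_length * arm_dir0
        seg = np.array([0.0, 0.0, 1.0])  # local direction of the helix segment
        perp = np.cross(arm_dir0, seg)
        axis = perp / np.linalg.norm(perp)
        for k, resi in enumerate(range(850, 861)):
            pos = com + (k - 5) * 0.15 * axis
            i = add(resi, "ILE" if resi == 859 else "ALA", "CA", pos)
            arm_ids.append(i)
            if resi == 859:
                sel["ile859"].append(i)
        sel["arm_helix"].append(arm_ids)
        # vertical pore helices, centred on z = 0
        for k in range(5):
            z = (k - 2) * 0.15
            tm37_ids.append(add(2150 + k, "ALA", "CA", [r37, 0.0, z]))
            tm38_ids.append(add(2460 + k, "ALA", "CA", [r38, 0.0, z]))
        sel["tm37"].append(tm37_ids)
        sel["tm38"].append(tm38_ids)
        sel["pore_region"].append(tm37_ids + tm38_ids)
        # gating valine CB marker
        sel["valine_cb"].append(add(2476, "VAL", "CB", [radius, 0.0, 0.0]))
        # cap (top) / CTD (bottom) markers on a small ring
        sel["cap"].append(add(2300, "ALA", "CA", [0.3, 0.0, 2.0]))
        sel["ctd"].append(add(2530, "ALA", "CA", [0.3, 0.0, -2.0]))
        chains.append(ch)
    s = Structure(chains=chains)
    return s, sel


def perturb_coordinates(s: Structure, amplitude: float, seed: int = 0) -> Structure:
    """Gaussian-displaced copy: per-axis std = amplitude/sqrt(3) (amplitude in A).

    For large site counts the RMSD to the original converges to ``amplitude``.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    out = s.copy()
    if amplitude == 0:
        return out
    rng = np.random.default_rng(seed)
    sigma_nm = amplitude / math.sqrt(3.0) / 10.0
    xyz = out.coords() + rng.normal(0.0, sigma_nm, size=(out.n_sites, 3))
    out.set_coords(xyz)
    return out
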