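"""Validation statistics for mixed-resolution models.

Backbone-site RMSD (C-alpha for UA residues, BB bead for CG residues) and
its decomposition into UA, CG and interface components; cross-resolution
backbone contacts; helical backbone hydrogen-bond counts; and the
dome/pore geometry observables used for trimeric mechanosensitive
channels (projection area from the circumradius of the three arm markers,
arm tilt angle, pore-helix and gating-residue centroid distances).

RMSD values are reported in angstrom (the resolution of the comparisons
they support); structure coordinates are nm internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .model_core import CG, UA, Structure
from .partitioner import PartitionSpec

NM_TO_ANGSTROM = 10.0


class AnalysisError(ValueError):
    pass


@dataclass
class RMSDReport:
    rmsd_all: float          # A
    rmsd_ua: Optional[float]
    rmsd_cg: Optional[float]
    rmsd_itf: Optional[float]
    n_ua: int
    n_cg: int

    @property
    def n(self) -> int:
        return self.n_ua + self.n_cg


@dataclass
class GeometryReport:
    a: float = float("nan")                # nm, marker triangle sides
    b: float = float("nan")
    c: float = float("nan")
    circumradius: float = float("nan")     # nm
    projection_area: float = float("nan")  # nm^2
    tilt_angle: float = float("nan")       # degrees
    d37: float = float("nan")              # A
    d38: float = float("nan")              # A
    dV: float = float("nan")               # A


# ---------------------------------------------------------------------------
# superposition

def superpose_rmsd(ref: np.ndarray, mob: np.ndarray) -> tuple:
    """Least-squares rigid superposition (Kabsch, proper rotation only).

    Returns ``(R, t, rmsd)`` with the fitted mobile coordinates given by
    ``mob @ R.T + t``; the RMSD is in the units of the input coordinates.
    """
    ref = np.asarray(ref, dtype=float)
    mob = np.asarray(mob, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise AnalysisError(f"selection shapes differ: {ref.shape} vs {mob.shape}")
    if len(ref) < 2:
        raise AnalysisError("need at least 2 points to superpose")
    cr = ref.mean(axis=0)
    cm = mob.mean(axis=0)
    P = mob - cm
    Q = ref - cr
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    fitted = P @ R.T + cr
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    t = cr - cm @ R.T
    return R, t, rmsd


def backbone_selection(s: Structure, p: Optional[PartitionSpec] = None):
    """(coords nm, resolutions) of one backbone site per residue: the
    C-alpha of UA residues and the BB bead of CG residues.  When a
    partition is given the resolution comes from it, otherwise from the
    site tags."""
    xyz, res = [], []
    for ch in s.chains:
        for r in ch.residues:
            site = r.backbone_site
            if site is None:
                continue
            xyz.append(site.position)
            if p is not None:
                res.append(p.resolution_of(ch.id, r.index))
            else:
                res.append(site.resolution)
    return np.array(xyz), res


def rmsd_decomposition(ref: Structure, model: Structure,
                       p: Optional[PartitionSpec] = None) -> RMSDReport:
    """Backbone RMSD (A) and its decomposition into UA/CG/interface parts.

    ``rmsd_all`` comes from one global fit over all backbone sites;
    ``rmsd_ua``/``rmsd_cg`` from separate fits over the UA or CG sites
    alone (internal deformation of each part); the interface component is
    the residual misplacement of the parts relative to each other::

        rmsd_itf = sqrt(max(0, (n rmsd_all^2 - n_ua rmsd_ua^2
                                 - n_cg rmsd_cg^2) / n))

    With an empty UA or CG set the undefined components are ``None``.
    """
    xr, res_r = backbone_selection(ref, p)
    xm, res_m = backbone_selection(model, p)
    if xr.shape != xm.shape or res_r != res_m:
        raise AnalysisError("reference and model backbone selections do not match")
    _, _, r_all = superpose_rmsd(xr, xm)
    ua_mask = np.array([x == UA for x in res_r])
    n_ua = int(ua_mask.sum())
    n_cg = len(res_r) - n_ua
    r_ua = r_cg = r_itf = None
    if n_ua >= 2:
        _, _, r_ua = superpose_rmsd(xr[ua_mask], xm[ua_mask])
    if n_cg >= 2:
        _, _, r_cg = superpose_rmsd(xr[~ua_mask], xm[~ua_mask])
    if r_ua is not None and r_cg is not None:
        n = n_ua + n_cg
        r_itf = math.sqrt(max(0.0, (n * r_all ** 2 - n_ua * r_ua ** 2
                                    - n_cg * r_cg ** 2) / n))
    to_A = NM_TO_ANGSTROM
    return RMSDReport(
        rmsd_all=r_all * to_A,
        rmsd_ua=None if r_ua is None else r_ua * to_A,
        rmsd_cg=None if r_cg is None else r_cg * to_A,
        rmsd_itf=None if r_itf is None else r_itf * to_A,
        n_ua=n_ua, n_cg=n_cg,
    )


# ---------------------------------------------------------------------------
# contacts and hydrogen bonds

def count_interface_contacts(s: Structure, p: Optional[PartitionSpec] = None,
                             cutoff: float = 6.0) -> int:
    """Number of (C-alpha, BB) pairs closer than ``cutoff`` angstrom between
    the UA and CG parts."""
    xyz, res = backbone_selection(s, p)
    ua = np.array([x == UA for x in res])
    if ua.all() or not ua.any():
        return 0
    d = cdist(xyz[ua], xyz[~ua]) * NM_TO_ANGSTROM
    return int((d < cutoff).sum())


def count_backbone_hbonds(s: Structure, cutoff: float = 3.5,
                          pair_offsets: Sequence[int] = (3, 4)) -> int:
    """Helical backbone hydrogen bonds: O(i)..N(i+3) / O(i)..N(i+4) pairs
    with both residues helical and O-N distance <= ``cutoff`` angstrom."""
    count = 0
    for ch in s.chains:
        by_index = {r.index: r for r in ch.residues}
        for r in ch.residues:
            if r.ss_label != "H":
                continue
            o = r.site("O")
            if o is None:
                continue
            for off in pair_offsets:
                partner = by_index.get(r.index + off)
                if partner is None or partner.ss_label != "H":
                    continue
                n = partner.site("N")
                if n is None:
                    continue
                if np.linalg.norm(o.position - n.position) * NM_TO_ANGSTROM <= cutoff:
                    count += 1
    return count


# ---------------------------------------------------------------------------
# dome / pore geometry

def projection_area(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> GeometryReport:
    """Projected dome area pi r^2 from the circumradius r of the triangle
    formed by the three arm marker sites (coordinates in nm)."""
    p1, p2, p3 = (np.asarray(x, dtype=float) for x in (p1, p2, p3))
    a = float(np.linalg.norm(p2 - p3))
    b = float(np.linalg.norm(p1 - p3))
    c = float(np.linalg.norm(p1 - p2))
    s2 = (a + b + c) * (-a + b + c) * (a - b + c) * (a + b - c)
    if s2 <= 0 or min(a, b, c) == 0:
        raise AnalysisError("collinear or coincident marker points")
    r = a * b * c / math.sqrt(s2)
    return GeometryReport(a=a, b=b, c=c, circumradius=r,
                          projection_area=math.pi * r * r)


def tilt_angle(arm_coords: np.ndarray, pore_coords: np.ndarray,
               axis_top_coords: np.ndarray, axis_bottom_coords: np.ndarray) -> float:
    """Angle (degrees) between the arm axis — centre of the pore selection
    to centre of the arm-helix selection — and the internal axis — centre of
    the bottom selection to centre of the top selection."""
    def com(x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if len(x) == 0:
            raise AnalysisError("empty selection")
        return x.mean(axis=0)
    v1 = com(arm_coords) - com(pore_coords)
    v2 = com(axis_top_coords) - com(axis_bottom_coords)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise AnalysisError("zero-length axis vector")
    cosx = float(v1 @ v2 / (n1 * n2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosx))))


def pore_metrics(tm37_sels: Sequence[np.ndarray], tm38_sels: Sequence[np.ndarray],
                 valine_cbetas: Sequence[np.ndarray]) -> tuple:
    """(d37, d38, dV) in angstrom from nm coordinate selections.

    The pore centre is the centroid of all TM37 and TM38 coordinates; d37 and
    d38 are the mean distances of the three per-chain helix centroids to it;
    dV is the mean distance of the three gating-residue C-beta atoms to their
    own centroid.
    """
    if len(tm37_sels) != 3 or len(tm38_sels) != 3 or len(valine_cbetas) != 3:
        raise AnalysisError("expected three selections per helix class and three C-betas")
    t37 = [np.atleast_2d(np.asarray(x, float)) for x in tm37_sels]
    t38 = [np.atleast_2d(np.asarray(x, float)) for x in tm38_sels]
    center = np.vstack(t37 + t38).mean(axis=0)
    d37 = float(np.mean([np.linalg.norm(x.mean(axis=0) - center) for x in t37]))
    d38 = float(np.mean([np.linalg.norm(x.mean(axis=0) - center) for x in t38]))
    cb = np.array([np.asarray(x, float).reshape(3) for x in valine_cbetas])
    cb_center = cb.mean(axis=0)
    dV = float(np.mean(np.linalg.norm(cb - cb_center, axis=1)))
    return d37 * NM_TO_ANGSTROM, d38 * NM_TO_ANGSTROM, dV * NM_TO_ANGSTROM


def trimer_geometry(s: Structure, sel: dict) -> GeometryReport:
    """Full geometry report for a trimer given named site-id selections (the
    dict produced by :func:`pacemix.fixtures.make_trimer_toy`)."""
    pos = {site.id: site.position for site in s.sites()}

    def coords(ids):
        return np.array([pos[i] for i in np.atleast_1d(ids)])
    rep = projection_area(*(pos[i] for i in sel["ile859"]))
    pore = np.vstack([coords(ids) for ids in sel["pore_region"]])
    top_c = coords(sel["cap"])
    bot_c = coords(sel["ctd"])
    tilts = [tilt_angle(coords(arm), pore, top_c, bot_c) for arm in sel["arm_helix"]]
    rep.tilt_angle = float(np.mean(tilts))
    rep.d37, rep.d38, rep.dV = pore_metrics(
        [coords(ids) for ids in sel["tm37"]],
        [coords(ids) for ids in sel["tm38"]],
        [pos[i] for i in sel["valine_cb"]])
    return rep


# ---------------------------------------------------------------------------
# trajectory statistics

def trajectory_metrics(ref: Structure, traj: Structure,
                       p: Optional[PartitionSpec] = None,
                       frames: Optional[Sequence[int]] = None,
                       contact_cutoff: float = 6.0) -> pd.DataFrame:
    """Per-frame RMSD decomposition, contacts and hydrogen-bond counts.

    ``frames`` selects 0-based model indices of ``traj`` (all by default),
    e.g. the last half of a run.  Returns one row per frame.
    """
    rows = []
    frame_ids = list(frames) if frames is not None else list(range(traj.model_count))
    work = traj.copy()
    for fi in frame_ids:
        work.set_coords(traj.frame_coords(fi))
        rep = rmsd_decomposition(ref, work, p)
        rows.append({
            "frame": fi,
            "rmsd_all": rep.rmsd_all,
            "rmsd_ua": rep.rmsd_ua,
            "rmsd_cg": rep.rmsd_cg,
            "rmsd_itf": rep.rmsd_itf,
            "contacts": count_interface_contacts(work, p, contact_cutoff),
            "hbonds": count_backbone_hbonds(work),
        })
    return pd.DataFrame(rows)
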