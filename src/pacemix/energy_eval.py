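"""Single-point evaluation of the cross-resolution energy terms.

The cross-resolution potential is a sum of

* Lennard-Jones + Coulomb interactions over all UA x CG site pairs more
  than two covalent bonds apart (mixed pair table; effective dielectric
  eps_r = 15; 1.2 nm cutoff for both terms, Coulomb optionally
  reaction-field corrected with eps_RF -> infinity);
* the stiff interface bond/angle terms and elastic springs (harmonic,
  zero at the reference structure by construction);
* the LJ-like helical backbone hydrogen-bond term O(i)..N(i+3), O(i)..N(i+4)
  for helical residues, with the well depth zeta-scaled in membranes.

Desk-scale evaluator: no periodic boundaries (a structure box is ignored
with a warning), no forces.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .model_core import CG, UA, Structure
from .param_mixer import HelicalHBParams, LJParams, ScalingFactors
from .topology_builder import MixedTopology

log = logging.getLogger(__name__)

#: electric conversion factor, kJ mol^-1 nm e^-2
COULOMB_CONSTANT = 138.935458


class EnergyEvalError(ValueError):
    pass


@dataclass(frozen=True)
class NonbondedSettings:
    cutoff: float = 1.2            # nm, LJ and Coulomb
    epsilon_r: float = 15.0        # effective dielectric
    coulomb_mode: str = "reaction_field"   # or "truncated"
    lj_shift: bool = False         # shift LJ to zero at the cutoff

    def __post_init__(self):
        if self.cutoff <= 0 or self.epsilon_r <= 0:
            raise EnergyEvalError("cutoff and epsilon_r must be positive")
        if self.coulomb_mode not in ("truncated", "reaction_field"):
            raise EnergyEvalError(f"bad coulomb_mode {self.coulomb_mode!r}")


@dataclass
class EnergyReport:
    lj: float = 0.0
    coulomb: float = 0.0
    interface_bonded: float = 0.0
    elastic: float = 0.0
    helical_hb: float = 0.0
    pair_breakdown: Optional[list] = field(default=None, repr=False)

    @property
    def total(self) -> float:
        return self.lj + self.coulomb + self.interface_bonded + self.elastic + self.helical_hb


def lj_energy(eps: float, sigma: float, r: float, cutoff: float, shift: bool) -> float:
    if r >= cutoff:
        return 0.0
    sr6 = (sigma / r) ** 6
    u = 4.0 * eps * (sr6 * sr6 - sr6)
    if shift:
        sc6 = (sigma / cutoff) ** 6
        u -= 4.0 * eps * (sc6 * sc6 - sc6)
    return u


def coulomb_energy(qi: float, qj: float, r: float, settings: NonbondedSettings) -> float:
    if r >= settings.cutoff:
        return 0.0
    pref = COULOMB_CONSTANT * qi * qj / settings.epsilon_r
    if settings.coulomb_mode == "truncated":
        return pref / r
    # reaction field with eps_RF -> infinity; zero at the cutoff
    rc = settings.cutoff
    return pref * (1.0 / r + r * r / (2.0 * rc ** 3) - 3.0 / (2.0 * rc))


def pair_cross_energy(p: LJParams, qi: float, qj: float, r: float,
                      settings: NonbondedSettings = NonbondedSettings()) -> tuple:
    """(LJ, Coulomb) energy of one UA-CG pair at separation ``r`` nm."""
    if r <= 0:
        raise EnergyEvalError("pair distance must be positive")
    return (lj_energy(p.epsilon, p.sigma, r, settings.cutoff, settings.lj_shift),
            coulomb_energy(qi, qj, r, settings))


def total_cross_nonbonded(top: MixedTopology,
                          settings: NonbondedSettings = NonbondedSettings(),
                          coords: Optional[np.ndarray] = None,
                          breakdown: bool = False) -> EnergyReport:
    """Sum of LJ + Coulomb over all non-excluded UA x CG pairs within the
    cutoff (vectorised; equal to the brute-force double loop)."""
    if coords is None:
        coords = top.coords()
    sites = top.sites
    ua_idx = [i for i, s in enumerate(sites) if s.resolution == UA]
    cg_idx = [i for i, s in enumerate(sites) if s.resolution == CG]
    report = EnergyReport(pair_breakdown=[] if breakdown else None)
    if not ua_idx or not cg_idx:
        return report
    xu = coords[ua_idx]
    xc = coords[cg_idx]
    d = cdist(xu, xc)
    qu = np.array([sites[i].charge for i in ua_idx])
    qc = np.array([sites[i].charge for i in cg_idx])
    eps = np.empty((len(ua_idx), len(cg_idx)))
    sig = np.empty_like(eps)
    for a, iu in enumerate(ua_idx):
        for b, ic in enumerate(cg_idx):
            key = (sites[iu].type_key, sites[ic].type_key)
            if key not in top.pair_table:
                raise EnergyEvalError(f"no pair parameters for type pair {key}")
            lj = top.pair_table[key]
            eps[a, b] = lj.epsilon
            sig[a, b] = lj.sigma
    mask = d < settings.cutoff
    for a, iu in enumerate(ua_idx):
        for b, ic in enumerate(cg_idx):
            pair = (min(sites[iu].id, sites[ic].id), max(sites[iu].id, sites[ic].id))
            if pair in top.exclusions:
                mask[a, b] = False
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = np.where(mask, (sig / np.where(mask, d, 1.0)) ** 6, 0.0)
        ulj = 4.0 * eps * (sr6 * sr6 - sr6)
        if settings.lj_shift:
            sc6 = (sig / settings.cutoff) ** 6
            ulj -= np.where(mask, 4.0 * eps * (sc6 * sc6 - sc6), 0.0)
        qq = COULOMB_CONSTANT * np.outer(qu, qc) / settings.epsilon_r
        if settings.coulomb_mode == "truncated":
            ucoul = np.where(mask, qq / np.where(mask, d, 1.0), 0.0)
        else:
            rc = settings.cutoff
            ucoul = np.where(
                mask, qq * (1.0 / np.where(mask, d, 1.0) + d * d / (2 * rc ** 3) - 3 / (2 * rc)),
                0.0)
    ulj = np.where(mask, ulj, 0.0)
    report.lj = float(ulj.sum())
    report.coulomb = float(ucoul.sum())
    if breakdown:
        for a, iu in enumerate(ua_idx):
            for b, ic in enumerate(cg_idx):
                if mask[a, b]:
                    report.pair_breakdown.append(
                        (sites[iu].id, sites[ic].id, float(d[a, b]),
                         float(ulj[a, b]), float(ucoul[a, b])))
    return report


def bonded_elastic_energy(top: MixedTopology,
                          coords: Optional[np.ndarray] = None) -> tuple:
    """(interface bonded, elastic) energies: sum of 1/2 k (d-d0)^2 over
    bonds/springs and 1/2 k (theta-theta0)^2 over interface angles (radians).

    CG backbone bonds count toward the interface-bonded channel only insofar
    as they are part of the bond list; they are zero at the reference too.
    """
    if coords is None:
        coords = top.coords()
    pos = {s.id: coords[i] for i, s in enumerate(top.sites)}
    e_bonded = 0.0
    for b in top.bonds:
        d = float(np.linalg.norm(pos[b.site_a] - pos[b.site_b]))
        e_bonded += 0.5 * b.k * (d - b.d0) ** 2
    for a in top.angles:
        v1 = pos[a.site_i] - pos[a.site_j]
        v2 = pos[a.site_k] - pos[a.site_j]
        cosx = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        theta = math.acos(max(-1.0, min(1.0, cosx)))
        e_bonded += 0.5 * a.k * (theta - math.radians(a.theta0)) ** 2
    e_elastic = 0.0
    for b in top.elastic_bonds:
        d = float(np.linalg.norm(pos[b.site_a] - pos[b.site_b]))
        e_elastic += 0.5 * b.k * (d - b.d0) ** 2
    return e_bonded, e_elastic


def helical_hb_energy(s: Structure, hb: HelicalHBParams = HelicalHBParams(),
                      f: ScalingFactors = ScalingFactors(),
                      pair_offsets: tuple = (3, 4)) -> float:
    """Helical hydrogen-bond energy: LJ-like O(i)..N(i+3) and O(i)..N(i+4)
    attractions summed over helical residues; membrane helices use
    zeta * epsilon_hel.

    Both partner residues must be helical (the term stabilises a turn, and
    all residues of a turn belong to the helix).
    """
    total = 0.0
    for ch in s.chains:
        by_index = {r.index: r for r in ch.residues}
        for r in ch.residues:
            if r.ss_label != "H":
                continue
            o = r.site("O")
            if o is None:
                raise EnergyEvalError(
                    f"helical residue {ch.id}:{r.index} lacks a backbone O atom")
            eps = f.zeta * hb.epsilon_hel if r.environment == "membrane" else hb.epsilon_hel
            for off in pair_offsets:
                partner = by_index.get(r.index + off)
                if partner is None or partner.ss_label != "H":
                    continue
                n = partner.site("N")
                if n is None:
                    raise EnergyEvalError(
                        f"helical residue {ch.id}:{partner.index} lacks a backbone N atom")
                rdist = float(np.linalg.norm(o.position - n.position))
                sr6 = (hb.sigma_hel / rdist) ** 6
                total += 4.0 * eps * (sr6 * sr6 - sr6)
    return total


def evaluate(s: Structure, top: MixedTopology,
             settings: NonbondedSettings = NonbondedSettings(),
             hb: HelicalHBParams = HelicalHBParams(),
             factors: Optional[ScalingFactors] = None,
             breakdown: bool = False) -> EnergyReport:
    """Full cross-resolution energy report for one structure/topology pair."""
    if s.box is not None:
        log.warning("periodic box present but ignored by the single-point evaluator")
    factors = factors or top.scaling
    report = total_cross_nonbonded(top, settings, breakdown=breakdown)
    report.interface_bonded, report.elastic = bonded_elastic_energy(top)
    report.helical_hb = helical_hb_energy(s, hb, factors)
    return report
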