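# Methods

## Model

`pacemix` implements the coupling layer of a mixed-resolution protein
model: a united-atom (UA) region (all heavy atoms plus polar hydrogens)
and a coarse-grained (CG) region (MARTINI-style beads, the backbone bead
BB on the Cα position, elastic-network restrained) coexist in one
molecule. The total potential is the sum of the two parent potentials
plus a cross-resolution term; only the cross term is in scope here, and
it consists of

1. **Nonbonded interactions** between every UA site i and CG site j more
   than two covalent bonds apart:
   U = 4εᵢⱼ[(σᵢⱼ/r)¹² − (σᵢⱼ/r)⁶] + f·qᵢqⱼ/(ε_r·r), with ε_r = 15 and
   f = 138.935458 kJ·mol⁻¹·nm·e⁻². Both terms are cut off at 1.2 nm;
   the Coulomb term may be reaction-field corrected
   (U ∝ 1/r + r²/(2r_c³) − 3/(2r_c), the ε_RF → ∞ limit, which vanishes
   at the cutoff) and the LJ term may be shifted to zero at the cutoff.
   Unlike-pair parameters come from Lorentz–Berthelot mixing of the
   parent tables, with the well depth uniformly rescaled: γ = 0.7 for
   UA-protein × CG-protein pairs, η = 0.95 for UA-protein × CG-lipid
   pairs. σ is never rescaled by any factor — the factors tune interaction
   strength, not contact distance.

2. **Interface bonded terms.** An interface severs either the N–Cα bond
   of the first UA residue (CG part N-terminal) or the Cα–C bond of the
   last UA residue (CG part C-terminal). Around each cut, with BB beads
   i, j on the CG side and Cα atoms k, l on the UA side (j and k adjacent
   to the cut): a harmonic bond j–k with K_b = 150000 kJ·nm⁻²·mol⁻¹ and
   harmonic angles i–j–k and j–k–l with K_a = 40.0 kJ·mol⁻¹·rad⁻²; all
   equilibrium values are measured on the reference structure, so every
   term is exactly zero there. In addition, cross-resolution elastic
   springs (K_E = 500 kJ·nm⁻²·mol⁻¹) connect {i, j} to every UA Cα and
   every BB bead to {k, l} wherever the reference distance lies in the
   native-contact window 0.5 nm < d < 0.9 nm.

3. **Elastic network** within the CG region: the same K_E springs between
   all BB pairs with reference distance in (0.5, 0.9) nm and sequence
   separation ≥ 2 (directly bonded beads are excluded because backbone
   bonds already restrain them).

4. **Helical hydrogen-bond term**: an LJ-like attraction
   4ε_hel[(σ_hel/r)¹² − (σ_hel/r)⁶] between the backbone carbonyl O of a
   helical residue i and the backbone N of residues i+3 and i+4. Membrane
   helices are stabilised more strongly than solution helices: their well
   depth is ζ·ε_hel with ζ = 1.5. The exact published exponents of this
   term are not available in machine-readable form, so the functional
   form is a pluggable component with the 12-6 form as the default.

## Partitioning rules

Interfaces are placed under four rules (ids used by the validator):
r1 — never inside a helix, and a multi-strand β-sheet is never split
across resolutions; r2 — at least two residues between the severed
residue and any helix/sheet residue (|r − h| ≥ 3 in sequence); r3 — never
across a proline; r4 — the severed bond must be consistent with which
side is CG. Sheets are detected as connected components of strand
pairing: strands are maximal E runs, and two strands pair when at least
two Cα–Cα distances between them fall below 0.55 nm (the source model
forbids cutting sheets but gives no detection rule; this one is simple
and reproducible).

The cut convention deserves a note. A cut is stored by the *boundary*
residue (last residue of the N-terminal segment); the severed bond is
Cα–C of that residue when the CG part is C-terminal and N–Cα of the next
residue when it is N-terminal. This is the unique convention under which
resolution swapping is an involution that preserves cut indices while
keeping the bond/side pairing consistent — the UA side always retains
the atoms adjacent to the cut.

Automatic partitioning: *midpoint* scans boundaries outward from the
sequence midpoint and returns the first admissible cut (N-terminal
tie-break, for determinism); *largest_sheet* keeps the sheet with the
most strand residues (growing the interval until no other sheet is
split) at one resolution and the remainder at the other. Secondary
structure is taken as given (`provided` mode is authoritative); the
bundled dihedral heuristic — H for ≥ 4 consecutive residues with
φ ∈ (−100°, −30°), ψ ∈ (−80°, −5°); E for ≥ 3 consecutive residues with
φ ∈ (−180°, −90°), ψ ∈ (90°, 180°); else C, termini C — exists so that
synthetic fixtures are self-labelling and tests deterministic. It is
deliberately not a DSSP replacement.

## Validation statistics

RMSD uses one backbone site per residue (Cα or BB, which coincide by the
mapping convention) and uniform-weight Kabsch superposition with a proper
rotation. The decomposition fits all sites globally (RMSD), the UA sites
alone (RMSD_UA) and the CG sites alone (RMSD_CG), and assigns the
remainder to the interface:

RMSD_itf = √(max(0, (N·RMSD² − N_UA·RMSD_UA² − N_CG·RMSD_CG²)/N)).

Separate local fits can only reduce the residual, so the radicand is
non-negative up to round-off (clamped at 0); an internally rigid but
hinge-displaced construct gives RMSD_UA = RMSD_CG = 0 and
RMSD_itf = RMSD. This residual form is one reading of the published
decomposition (printed only as an image); it reproduces the qualitative
behaviour — interface detachment raises RMSD_itf while the internal
RMSDs stay low — and is isolated in one function for easy replacement.

Contacts: Cα(UA)–BB(CG) pairs closer than 6 Å. Backbone hydrogen bonds:
O(i)···N(i+3/i+4) pairs within helical segments at ≤ 3.5 Å (no angular
term; the reference counting rule is unstated, so the simplest distance
criterion is used, and the cutoff is an argument). Trimer geometry:
projection area π·r² with r the circumradius of the triangle of the
three arm-marker backbone sites (circumradius from the side lengths,
r = abc/√((a+b+c)(−a+b+c)(a−b+c)(a+b−c))); arm tilt as the angle between
the pore-centre→arm-helix-centre vector and the bottom→top internal
axis; d37/d38 as the mean 3D distance of the three per-chain pore-helix
centroids to the centroid of all six helices; d_V as the mean distance
of the three gating-residue Cβ atoms to their own centroid. All reported
in Å.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| γ | 0.7 | – | UA-protein × CG-protein LJ depth factor |
| η | 0.95 | – | UA-protein × CG-lipid LJ depth factor |
| ζ | 1.5 | – | membrane helical H-bond depth factor |
| ε_r | 15 | – | effective dielectric for cross Coulomb |
| cutoff | 1.2 | nm | LJ and Coulomb truncation |
| K_b | 150000 | kJ·nm⁻²·mol⁻¹ | interface bond |
| K_a | 40.0 | kJ·mol⁻¹·rad⁻² | interface angles |
| K_E | 500 | kJ·nm⁻²·mol⁻¹ | elastic springs |
| window | (0.5, 0.9) | nm | native-contact elastic window |
| HMR | 4 | – | hydrogen mass multiplier |
| ε_hel, σ_hel | 5.0, 0.28 | kJ/mol, nm | helical H-bond well (illustrative) |

The γ/η/ζ defaults are the optimised values of the coupling scheme; they
are data, not things this toolkit refits (the simulation scans that
selected them are out of scope). The bundled UA/CG/lipid parameter
tables and the residue→bead mapping are small illustrative subsets with
realistic magnitudes: the full published tables are inputs the user
loads (`load_param_table`, MARTINI-itp or plain-column dialects;
C6/C12 files are converted via σ = (C12/C6)^{1/6}, ε = C6²/(4·C12)).
ε_hel/σ_hel likewise stand in for the parent UA model's helical term.

## Numerical choices

- Internal unit is nm (all force constants are quoted per nm²); PDB I/O
  converts to/from Å. Energies in kJ/mol, angles stored in degrees and
  evaluated in radians.
- The elastic window is an open interval; boundary distances get no
  spring.
- Altloc handling keeps the highest-occupancy conformer (alphabetical
  tie-break). Author residue numbering is preserved; ranges are
  inclusive.
- Covalent connectivity for exclusions is inferred by distance
  (heavy–heavy < 1.8 Å, X–H < 1.25 Å) plus peptide C–N links, CG bead
  chains and the interface bonds; exclusions are all pairs within two
  bonds (BFS).
- HMR borrows mass from the nearest heavy atom in the same residue;
  conservation is exact by construction.
- The midpoint tie-break is N-terminal; degenerate geometry (collinear
  triangle markers, zero-length axes, < 2 superposition points) raises
  instead of returning NaN.
- The single-point evaluator ignores periodic boxes (logged warning):
  it is a desk-scale verification tool, not an MD engine.

## What the synthetic fixtures do and do not show

The generators produce ideal backbone geometry (NeRF chains from ideal
bond lengths/angles and prescribed φ/ψ; the default helix emerges with
3.8 Å Cα spacing, ~1.5 Å rise and ~100° twist), exact C3 symmetry, and
seed-deterministic Gaussian perturbations. They emulate the *geometric*
features the operations consume — helices, linkers, sheets, trimeric
arms — not the physics of real proteins: no side-chain packing, no
solvent, no thermal ensembles. Passing tests therefore demonstrate that
the coupling terms, rules and metrics are implemented exactly as
specified (against brute-force oracles and closed forms), not that the
mixed model keeps real proteins stable; that judgement requires the
microsecond-scale simulations that are explicitly out of scope here.
Problem sizes used by the test and acceptance runs (≤ 200-site nonbonded
fixtures, 50–200 randomized cases per property, a 10⁴-site perturbation
check) were chosen as the smallest ensembles that exercise every branch
with comfortable statistics.

## Known limitations

- The UA parent's full internal potential (dihedrals, impropers, its own
  nonbonded matrix) and the CG parent's internal potential beyond the
  elastic network and backbone bonds are not evaluated — by design.
- Sheet detection is geometric and heuristic; unusual topologies
  (bifurcated sheets, β-bulges) may group differently than a
  hydrogen-bond-based assignment would.
- "Long loop" avoidance is not quantified in the source rules and is not
  enforced.
- The topology writer emits harmonic bonds, not constraints; an MD
  engine wanting constraints must convert.
- mmCIF, hydrogen placement and protonation assignment are out of scope.
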