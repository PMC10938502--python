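"""Bundled illustrative nonbonded parameter tables.

The mixed-resolution scheme inherits its base Lennard-Jones parameters from
the parent united-atom and MARTINI force fields; those published tables are
inputs to this toolkit, not part of it.  The dictionaries below are a small
internally consistent subset — realistic magnitudes (epsilon in kJ/mol,
sigma in nm, charges in e) sufficient to build and test complete topologies.
Load full published tables with :func:`pacemix.param_mixer.load_param_table`.
"""

# united-atom protein site types: type -> (epsilon, sigma, charge)
UA_TYPES = {
    "N":  (0.7113, 0.325, -0.40),
    "H":  (0.0657, 0.250,  0.25),
    "CA": (0.4577, 0.340,  0.10),
    "C":  (0.3598, 0.375,  0.55),
    "O":  (0.8786, 0.296, -0.50),
    "CB": (0.4577, 0.340,  0.00),
    "CT": (0.4577, 0.340,  0.00),   # generic aliphatic carbon
    "OT": (0.8786, 0.296, -0.40),   # generic polar oxygen
    "NT": (0.7113, 0.325, -0.30),   # generic polar nitrogen
    "S":  (1.0460, 0.355,  0.00),
}

# MARTINI-style CG protein bead types (sigma 0.47 nm, ring beads 0.43 nm)
CG_TYPES = {
    "P5":  (5.6, 0.47,  0.0),
    "P4":  (5.0, 0.47,  0.0),
    "P1":  (4.5, 0.47,  0.0),
    "Nda": (4.0, 0.47,  0.0),
    "N0":  (3.5, 0.47,  0.0),
    "C5":  (3.5, 0.47,  0.0),
    "C3":  (3.5, 0.47,  0.0),
    "C2":  (3.5, 0.47,  0.0),
    "C1":  (3.5, 0.47,  0.0),
    "Qd":  (5.6, 0.47,  1.0),
    "Qa":  (5.6, 0.47, -1.0),
    "SC4": (2.6, 0.43,  0.0),
    "SC5": (2.6, 0.43,  0.0),
    "SP1": (3.4, 0.43,  0.0),
}

# CG lipid bead types (phosphatidylcholine-like)
LIPID_TYPES = {
    "Q0":  (3.5, 0.47,  1.0),   # choline
    "Qa":  (5.6, 0.47, -1.0),   # phosphate
    "Na":  (4.0, 0.47,  0.0),   # glycerol ester
    "C1":  (3.5, 0.47,  0.0),   # acyl tail
}
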