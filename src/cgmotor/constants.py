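"""Physical constants and unit conventions.

Unit conventions used throughout the package: lengths in nm, energies in
kJ mol^-1, time in ps, temperature in K.  Angles are degrees at all I/O
boundaries (topology files, distribution tables, reports) and radians
internally wherever trigonometry happens.
"""

#: Boltzmann constant (gas constant per mole), kJ mol^-1 K^-1.
KB = 0.0083145

#: Default solvent probe radius for SASA, nm (water probe).
DEFAULT_PROBE_RADIUS = 0.14

#: Default bead radii by Martini size class, nm.
BEAD_CLASS_RADII = {
    "regular": 0.264,
    "small": 0.230,
    "tiny": 0.191,
}

#: van der Waals radii for common elements, nm (Rowland & Taylor values,
#: used to size atoms in atomistic structures for SASA comparisons).
ATOMIC_RADII = {
    "H": 0.110,
    "C": 0.177,
    "N": 0.164,
    "O": 0.158,
    "F": 0.146,
    "S": 0.181,
    "CL": 0.176,
    "BR": 0.187,
    "I": 0.203,
}
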