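"""Standard atomic masses (IUPAC 2021 abridged values, 4 significant digits).

A fixed embedded table keeps molar-mass computations bit-stable across
environments. Conventional values are used for elements whose standard
atomic weight is an interval; for elements without a standard atomic
weight the mass number of the most stable isotope is used.
"""

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.003,
    "Li": 6.940, "Be": 9.012, "B": 10.81, "C": 12.01, "N": 14.01,
    "O": 16.00, "F": 19.00, "Ne": 20.18,
    "Na": 22.99, "Mg": 24.31, "Al": 26.98, "Si": 28.09, "P": 30.97,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95,
    "K": 39.10, "Ca": 40.08, "Sc": 44.96, "Ti": 47.87, "V": 50.94,
    "Cr": 52.00, "Mn": 54.94, "Fe": 55.85, "Co": 58.93, "Ni": 58.69,
    "Cu": 63.55, "Zn": 65.38, "Ga": 69.72, "Ge": 72.63, "As": 74.92,
    "Se": 78.97, "Br": 79.90, "Kr": 83.80,
    "Rb": 85.47, "Sr": 87.62, "Y": 88.91, "Zr": 91.22, "Nb": 92.91,
    "Mo": 95.95, "Tc": 97.00, "Ru": 101.1, "Rh": 102.9, "Pd": 106.4,
    "Ag": 107.9, "Cd": 112.4, "In": 114.8, "Sn": 118.7, "Sb": 121.8,
    "Te": 127.6, "I": 126.9, "Xe": 131.3,
    "Cs": 132.9, "Ba": 137.3, "La": 138.9, "W": 183.8, "Pt": 195.1,
    "Au": 197.0, "Hg": 200.6, "Pb": 207.2,
    # Generic/placeholder atoms occasionally used in biomass formulas
    "R": 0.0, "X": 0.0,
}
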