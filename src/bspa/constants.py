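"""Physical constants and the internal isotope-mass table.

Masses are kept as a versioned table inside the package rather than taken
from a cheminformatics toolkit, so that the mass bookkeeping of enumerated
products is fully reproducible and independently checkable.  Monoisotopic
masses are the most-abundant-isotope masses (CODATA/AME2020-derived, in Da);
average masses are IUPAC standard atomic weights.
"""

from __future__ import annotations

#: Mass of a proton in Da, used for adduct m/z arithmetic.
PROTON_MASS = 1.007276466

#: Probability that a single carbon atom is 13C (natural abundance).
C13_ABUNDANCE = 0.0107

#: Mass difference between 13C and 12C in Da (isotopologue spacing).
C13_MASS_SHIFT = 1.00336

#: element -> (monoisotopic mass, average mass) in Da.
ISOTOPE_MASSES: dict[str, tuple[float, float]] = {
    "H": (1.00782503207, 1.008),
    "C": (12.0, 12.011),
    "N": (14.0030740048, 14.007),
    "O": (15.9949146196, 15.999),
    "F": (18.99840322, 18.998403163),
    "Na": (22.9897692809, 22.98976928),
    "P": (30.97376163, 30.973761998),
    "S": (31.97207100, 32.06),
    "Cl": (34.96885268, 35.45),
    "K": (38.96370668, 39.0983),
    "Br": (78.9183371, 79.904),
    "I": (126.904473, 126.90447),
}
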