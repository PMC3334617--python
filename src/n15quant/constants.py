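"""Physical constants shared by every stage.

The two per-unit isotope shifts are the heart of the method: a peptide that
carries one extra neutron because of an additional ``13C`` is heavier by
1.00335483781 Da, while one that carries it because of an additional ``15N``
is heavier by only 0.99703489341 Da.  The difference ``D_SHIFT`` between the
two spacings is what lets a high-resolution instrument tell an incompletely
labeled satellite peak apart from an ordinary carbon isotope peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyteomics import mass as _pmass

#: Mass added per 14N -> 15N substitution (Da).
DELTA_15N: float = 0.99703489341
#: Mass added per 12C -> 13C substitution (Da).
DELTA_13C: float = 1.00335483781
#: Spacing difference between a one-unit 13C shift and a one-unit 15N shift (Da).
D_SHIFT: float = DELTA_13C - DELTA_15N

PROTON_MASS: float = 1.00727646688
WATER_MASS: float = 18.0105646863

#: Natural abundance of 13C.
C13_ABUNDANCE: float = 0.0107

#: Carbamidomethylation of cysteine (iodoacetamide alkylation), the usual
#: fixed modification after FASP-style sample preparation.
CARBAMIDOMETHYL_MASS: float = 57.02146
#: Elemental composition of the carbamidomethyl group (C2H3NO).  The nitrogen
#: it adds is reagent-derived, i.e. *not* metabolically 15N-labeled, so it
#: contributes to mass but never to the labeling shift.
CARBAMIDOMETHYL_CARBONS: int = 2

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Monoisotopic residue (not free amino acid) masses, Da.
RESIDUE_MASS: dict[str, float] = {aa: _pmass.std_aa_mass[aa] for aa in AMINO_ACIDS}

#: Nitrogen atoms per residue (backbone amide + side chain).
RESIDUE_NITROGENS: dict[str, int] = {
    aa: int(_pmass.std_aa_comp[aa]["N"]) for aa in AMINO_ACIDS
}

#: Carbon atoms per residue; needed to synthesise natural 13C envelopes.
RESIDUE_CARBONS: dict[str, int] = {
    aa: int(_pmass.std_aa_comp[aa]["C"]) for aa in AMINO_ACIDS
}


@dataclass(frozen=True)
class IsotopeConstants:
    """Bundle of the isotope-spacing constants used throughout the pipeline."""

    delta_15N: float = DELTA_15N
    delta_13C: float = DELTA_13C
    proton_mass: float = PROTON_MASS
    water_mass: float = WATER_MASS
    d: float = field(default=D_SHIFT)

    def __post_init__(self) -> None:
        if abs(self.d - (self.delta_13C - self.delta_15N)) > 1e-12:
            raise ValueError("d must equal delta_13C - delta_15N")


CONSTANTS = IsotopeConstants()
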