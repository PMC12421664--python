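"""Physical constants and unit conversions.

Energies are carried in Hartree (Eh) internally — the unit quantum-chemistry
engines print — and converted to kcal/mol only at the matrix/reporting layer.
Distances are in Ångström throughout.
"""

#: CODATA-consistent conversion factor, kcal/mol per Hartree.
HARTREE_TO_KCAL = 627.5094740631


def hartree_to_kcal(e_hartree: float) -> float:
    return e_hartree * HARTREE_TO_KCAL


def kcal_to_hartree(e_kcal: float) -> float:
    return e_kcal / HARTREE_TO_KCAL
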