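"""Physicochemical protein properties: length, molecular weight, pI.

Average (not monoisotopic) residue masses and the EMBOSS pKa set, matching
the "theoretical MW/pI" convention of ExPASy-style reports. The isoelectric
point is found by bisection on the Henderson-Hasselbalch net charge, which
is strictly decreasing in pH.
"""

from __future__ import annotations

from dataclasses import dataclass

# Average residue masses (Da); residue = amino acid minus water.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153
# An unknown residue contributes the average of the standard twenty.
_X_MASS = sum(AVERAGE_RESIDUE_MASS.values()) / len(AVERAGE_RESIDUE_MASS)

# EMBOSS pKa values.
PKA_POSITIVE = {"nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


@dataclass(frozen=True)
class ProteinProperties:
    length: int
    molecular_weight: float  # Da
    isoelectric_point: float


def molecular_weight(protein: str) -> float:
    protein = protein.upper().replace("*", "")
    if not protein:
        raise ValueError("empty protein sequence")
    mass = WATER_MASS
    for aa in protein:
        mass += AVERAGE_RESIDUE_MASS.get(aa, _X_MASS)
    return mass

def net_charge(protein: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH (X carries no charge)."""
    protein = protein.upper().replace("*", "")
    counts = {aa: protein.count(aa) for aa in "KRHDECY"}
    charge = 1.0 / (1.0 + 10.0 ** (ph - PKA_POSITIVE["nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE["cterm"] - ph))
    for aa in "KRH":
        charge += counts[aa] / (1.0 + 10.0 ** (ph - PKA_POSITIVE[aa]))
    for aa in "DECY":
        charge -= counts[aa] / (1.0 + 10.0 ** (PKA_NEGATIVE[aa] - ph))
    return charge


def isoelectric_point(protein: str, tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14]."""
    if not protein.replace("*", ""):
        raise ValueError("empty protein sequence")
    lo, hi = 0.0, 14.0
    for _ in range(60):  # interval shrinks to ~1e-17 pH units
        mid = (lo + hi) / 2.0
        if net_charge(protein, mid) > 0:
            lo = mid
        else:
            hi = mid
    pi = (lo + hi) / 2.0
    if abs(net_charge(protein, pi)) > tol:
        # charge never crosses zero inside [0, 14] (it always does for
        # peptides with both termini, so this is a guard, not a path)
        raise ValueError("net charge does not vanish in pH range [0, 14]")
    return pi


def protein_properties(protein: str) -> ProteinProperties:
    protein = protein.upper().replace("*", "")
    if not protein:
        raise ValueError("empty protein sequence")
    return ProteinProperties(
        length=len(protein),
        molecular_weight=molecular_weight(protein),
        isoelectric_point=isoelectric_point(protein),
    )
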