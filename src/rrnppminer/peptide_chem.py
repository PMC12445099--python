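"""Peptide physicochemistry for mass-spectrometric peptide detection.

Implements the grand average of hydropathy (GRAVY, the mean Kyte-Doolittle
value over a peptide's residues), monoisotopic peptide masses built up
from atomic masses, mass deltas of post-translational modifications given
as signed elemental formulas (e.g. the H2 loss of a single C-C/C-S
crosslink or the N2H2 loss of an arginine-to-N-methyl-ornithine
conversion combined with a crosslink), monocharged and multicharged m/z,
and ppm-tolerance matching of observed peaks to candidate ions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "KYTE_DOOLITTLE",
    "ATOMIC_MONOISOTOPIC",
    "PROTON_MASS",
    "WATER_MASS",
    "RESIDUE_FORMULAS",
    "ModificationSpec",
    "PeptideIon",
    "CARBAMIDOMETHYL",
    "gravy",
    "monoisotopic_mass",
    "formula_mass",
    "modification_delta",
    "mz",
    "match_peaks",
]

#: Kyte & Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Monoisotopic atomic masses (Da).
ATOMIC_MONOISOTOPIC = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}
PROTON_MASS = 1.00727646688

#: Elemental composition of amino-acid residues (peptide-bonded, water removed).
RESIDUE_FORMULAS = {
    "G": "C2H3NO",
    "A": "C3H5NO",
    "S": "C3H5NO2",
    "P": "C5H7NO",
    "V": "C5H9NO",
    "T": "C4H7NO2",
    "C": "C3H5NOS",
    "L": "C6H11NO",
    "I": "C6H11NO",
    "N": "C4H6N2O2",
    "D": "C4H5NO3",
    "Q": "C5H8N2O2",
    "K": "C6H12N2O",
    "E": "C5H7NO3",
    "M": "C5H9NOS",
    "H": "C6H7N3O",
    "F": "C9H9NO",
    "R": "C6H12N4O",
    "Y": "C9H9NO2",
    "W": "C11H10N2O",
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _parse_formula(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos or not m.group(0):
            break
        pos = m.end()
        el, num = m.group(1), m.group(2)
        if el not in ATOMIC_MONOISOTOPIC:
            raise ValueError(f"unsupported element {el!r} in formula {formula!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of an elemental formula over H, C, N, O, S."""
    return sum(
        n * ATOMIC_MONOISOTOPIC[el] for el, n in _parse_formula(formula).items()
    )


WATER_MASS = formula_mass("H2O")


def gravy(peptide: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    if not peptide:
        raise ValueError("empty peptide")
    total = 0.0
    for i, ch in enumerate(peptide):
        if ch not in KYTE_DOOLITTLE:
            raise ValueError(f"non-standard residue {ch!r} at position {i + 1}")
        total += KYTE_DOOLITTLE[ch]
    return total / len(peptide)


def monoisotopic_mass(peptide: str) -> float:
    """Neutral monoisotopic peptide mass: residue masses plus one water."""
    if not peptide:
        raise ValueError("empty peptide")
    total = WATER_MASS
    for i, ch in enumerate(peptide):
        if ch not in RESIDUE_FORMULAS:
            raise ValueError(f"non-standard residue {ch!r} at position {i + 1}")
        total += formula_mass(RESIDUE_FORMULAS[ch])
    return total


@dataclass(frozen=True)
class ModificationSpec:
    """A named modification given by a signed elemental change.

    ``gained`` and ``lost`` are elemental formulas; the mass delta is the
    signed sum of the corresponding monoisotopic atomic masses.
    """

    name: str
    lost: str = ""
    gained: str = ""

    @property
    def mass_delta(self) -> float:
        delta = 0.0
        if self.gained:
            delta += formula_mass(self.gained)
        if self.lost:
            delta -= formula_mass(self.lost)
        return delta


def modification_delta(elemental_loss: str) -> float:
    """Mass delta (Da) for a pure elemental loss, e.g. "H2" -> -2.01565."""
    return -formula_mass(elemental_loss)


#: Iodoacetamide alkylation of cysteine (off by default in any workflow).
CARBAMIDOMETHYL = ModificationSpec("carbamidomethyl", gained="C2H3NO")


@dataclass
class PeptideIon:
    sequence: str
    modification: ModificationSpec | None = None
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")

    @property
    def neutral_mass(self) -> float:
        m = monoisotopic_mass(self.sequence)
        if self.modification is not None:
            m += self.modification.mass_delta
        return m

    @property
    def mz(self) -> float:
        return (self.neutral_mass + self.charge * PROTON_MASS) / self.charge


def mz(
    peptide: str, modification: ModificationSpec | None = None, charge: int = 1
) -> float:
    """m/z of a peptide ion: ((M + delta) + z * proton) / z."""
    return PeptideIon(peptide, modification, charge).mz


def match_peaks(
    observed_mz: Iterable[float],
    candidates: list[PeptideIon],
    tol_ppm: float = 10.0,
) -> list[dict]:
    """Match observed m/z values to candidate ions within a ppm tolerance.

    Returns one record per observed value with the matching candidates
    (possibly none) and an ambiguity flag when several candidates fall
    inside the window.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    out = []
    for obs in observed_mz:
        matches = []
        for cand in candidates:
            theo = cand.mz
            if abs(obs - theo) / theo <= tol_ppm * 1e-6:
                matches.append((cand, theo))
        out.append(
            {
                "observed_mz": obs,
                "matches": matches,
                "ambiguous": len(matches) > 1,
            }
        )
    return out
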