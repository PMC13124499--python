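"""Monoisotopic peptide and fragment-ion mass arithmetic.

Neutral peptide mass M = sum of residue masses + water (+ modifications).
b_i neutral = sum(residues 1..i) + mods therein; y_j neutral = sum(residues
n-j+1..n) + water + mods therein; m/z = (neutral + z * PROTON) / z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

PROTON = 1.007276
WATER = 18.0105646863

CARBAMIDOMETHYL = 57.02146  # static on C
OXIDATION = 15.99491        # dynamic on M

# 13C-12C and 15N-14N monoisotopic mass differences
DELTA_13C = 1.0033548
DELTA_15N = 0.9970349

#: Monoisotopic residue (amino-acid minus water) masses.
RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

# heavy-atom capacity (carbons, nitrogens) of the labelable C-terminal residues
_RESIDUE_ATOMS = {"K": (6, 2), "R": (6, 4)}


class SequenceError(ValueError):
    """Non-canonical residue or malformed sequence."""


@dataclass(frozen=True)
class IsotopeLabel:
    """Heavy-isotope composition of a C-terminal K/R standard-peptide label."""

    residue: str
    n13c: int
    n15n: int

    def __post_init__(self) -> None:
        if self.residue not in _RESIDUE_ATOMS:
            raise SequenceError(f"label residue must be K or R, got {self.residue!r}")
        max_c, max_n = _RESIDUE_ATOMS[self.residue]
        if not (0 <= self.n13c <= max_c):
            raise ValueError(f"{self.residue} has {max_c} carbons; n13c={self.n13c}")
        if not (0 <= self.n15n <= max_n):
            raise ValueError(f"{self.residue} has {max_n} nitrogens; n15n={self.n15n}")


def heavy_mass_shift(label: IsotopeLabel) -> float:
    """Mass delta of a heavy-labeled residue relative to its light form."""
    return label.n13c * DELTA_13C + label.n15n * DELTA_15N


def _check_sequence(sequence: str) -> None:
    bad = set(sequence) - RESIDUE_MASS.keys()
    if bad or not sequence:
        raise SequenceError(f"non-canonical residues {sorted(bad)} in {sequence!r}")


def _mod_deltas(sequence: str, variable_mods: tuple[tuple[int, float], ...]) -> list[float]:
    """Per-position mass deltas: static carbamidomethyl-C plus variable mods."""
    deltas = [CARBAMIDOMETHYL if aa == "C" else 0.0 for aa in sequence]
    for pos, delta in variable_mods:
        if not 1 <= pos <= len(sequence):
            raise ValueError(f"modification position {pos} outside 1..{len(sequence)}")
        deltas[pos - 1] += delta
    return deltas


def peptide_mass(
    sequence: str,
    variable_mods: tuple[tuple[int, float], ...] = (),
    cterm_shift: float = 0.0,
) -> float:
    """Neutral monoisotopic mass, carbamidomethyl-C applied statically."""
    _check_sequence(sequence)
    deltas = _mod_deltas(sequence, variable_mods)
    return (
        sum(RESIDUE_MASS[aa] for aa in sequence) + sum(deltas) + WATER + cterm_shift
    )


def precursor_mz(neutral_mass: float, charge: int) -> float:
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + charge * PROTON) / charge


def fragment_mz(
    sequence: str,
    series: str,
    index: int,
    charge: int = 1,
    variable_mods: tuple[tuple[int, float], ...] = (),
    cterm_shift: float = 0.0,
) -> float:
    """m/z of the b- or y-ion at ``index`` (1..n-1) and ``charge``.

    ``cterm_shift`` models a C-terminal heavy label: it moves every y-ion
    (and the precursor) but no b-ion.
    """
    _check_sequence(sequence)
    n = len(sequence)
    if not 1 <= index <= n - 1:
        raise ValueError(f"fragment index {index} outside 1..{n - 1}")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    deltas = _mod_deltas(sequence, variable_mods)
    if series == "b":
        neutral = sum(RESIDUE_MASS[aa] for aa in sequence[:index]) + sum(deltas[:index])
    elif series == "y":
        neutral = (
            sum(RESIDUE_MASS[aa] for aa in sequence[n - index:])
            + sum(deltas[n - index:])
            + WATER
            + cterm_shift
        )
    else:
        raise ValueError(f"series must be 'b' or 'y', got {series!r}")
    return (neutral + charge * PROTON) / charge


@dataclass(frozen=True)
class TheoreticalFragment:
    series: str
    index: int
    charge: int
    mz: float


def theoretical_fragments(
    sequence: str,
    charges: tuple[int, ...] = (1,),
    variable_mods: tuple[tuple[int, float], ...] = (),
    cterm_shift: float = 0.0,
) -> list[TheoreticalFragment]:
    """All b/y fragments of ``sequence`` at the requested fragment charges."""
    out = []
    for z in charges:
        for series in ("b", "y"):
            for i in range(1, len(sequence)):
                out.append(
                    TheoreticalFragment(
                        series,
                        i,
                        z,
                        fragment_mz(sequence, series, i, z, variable_mods, cterm_shift),
                    )
                )
    return out
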