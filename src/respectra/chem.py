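"""Amino-acid mass chemistry and sequence-identity utilities.

Monoisotopic residue masses, peptide and b/y fragment m/z computation, and the
sequence comparisons used when deciding whether two peptide hypotheses are
distinguishable by mass spectrometry at all (Levenshtein distance, I/L
equivalence, isobaric residue substitutions such as GVA<->NL).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib

# Standard monoisotopic residue masses (Da), 5-decimal precision.  I and L are
# isomers and share a mass; 25 ppm fragment matching needs <=1e-3 Da accuracy.
RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER = 18.010565
PROTON = 1.0072765

#: modification token -> (target residue letter, mass delta in Da)
MODIFICATIONS: dict[str, tuple[str, float]] = {
    "ox": ("M", 15.99491),    # methionine oxidation
    "cam": ("C", 57.02146),   # carbamidomethylated cysteine
}

BASIC_RESIDUES = frozenset("KRH")

MIN_LENGTH = 7
MAX_LENGTH = 30
MAX_PRECURSOR_CHARGE = 6

_MODSEQ_TOKEN = re.compile(r"([A-Z])(?:\((\w+)\))?")


class InvalidPeptideError(ValueError):
    """Raised when a peptide fails the domain constraints."""


def _check_sequence(sequence: str) -> None:
    for ch in sequence:
        if ch not in RESIDUE_MASS:
            raise InvalidPeptideError(f"unknown residue letter {ch!r} in {sequence!r}")


@dataclass(frozen=True)
class Peptide:
    """A modified peptide sequence with its precursor charge.

    ``modifications`` holds 1-based residue positions with a modification
    token from :data:`MODIFICATIONS` (``"ox"`` on M, ``"cam"`` on C).
    The identification domain is length 7-30 and precursor charge 1-6.
    """

    sequence: str
    modifications: tuple[tuple[int, str], ...] = field(default_factory=tuple)
    precursor_charge: int = 2

    def __post_init__(self) -> None:
        _check_sequence(self.sequence)
        n = len(self.sequence)
        if not MIN_LENGTH <= n <= MAX_LENGTH:
            raise InvalidPeptideError(
                f"peptide length {n} outside the supported range "
                f"{MIN_LENGTH}-{MAX_LENGTH}: {self.sequence!r}"
            )
        if not 1 <= self.precursor_charge <= MAX_PRECURSOR_CHARGE:
            raise InvalidPeptideError(
                f"precursor charge {self.precursor_charge} outside 1-{MAX_PRECURSOR_CHARGE}"
            )
        for pos, mod in self.modifications:
            if mod not in MODIFICATIONS:
                raise InvalidPeptideError(f"unknown modification token {mod!r}")
            target, _ = MODIFICATIONS[mod]
            if not 1 <= pos <= n:
                raise InvalidPeptideError(f"modification position {pos} outside 1..{n}")
            if self.sequence[pos - 1] != target:
                raise InvalidPeptideError(
                    f"modification {mod!r} at position {pos} targets "
                    f"{self.sequence[pos - 1]!r}, expected {target!r}"
                )

    @classmethod
    def from_modified_sequence(cls, text: str, precursor_charge: int = 2) -> "Peptide":
        """Parse the inline dialect ``"AC(cam)M(ox)K..."`` (underscores tolerated)."""
        text = text.strip().strip("_")
        seq_chars: list[str] = []
        mods: list[tuple[int, str]] = []
        pos = 0
        for match in _MODSEQ_TOKEN.finditer(text):
            if match.start() != pos:
                raise InvalidPeptideError(f"cannot parse modified sequence {text!r}")
            pos = match.end()
            seq_chars.append(match.group(1))
            if match.group(2) is not None:
                mods.append((len(seq_chars), match.group(2)))
        if pos != len(text):
            raise InvalidPeptideError(f"cannot parse modified sequence {text!r}")
        return cls("".join(seq_chars), tuple(mods), precursor_charge)

    @property
    def modified_sequence(self) -> str:
        by_pos = dict((p, m) for p, m in self.modifications)
        out = []
        for i, ch in enumerate(self.sequence, start=1):
            out.append(ch if i not in by_pos else f"{ch}({by_pos[i]})")
        return "".join(out)

    def __len__(self) -> int:
        return len(self.sequence)


def residue_masses(sequence: str, modifications: tuple[tuple[int, str], ...] = ()) -> list[float]:
    """Per-residue masses with modification deltas applied."""
    _check_sequence(sequence)
    masses = [RESIDUE_MASS[ch] for ch in sequence]
    for pos, mod in modifications:
        masses[pos - 1] += MODIFICATIONS[mod][1]
    return masses


def sequence_mass(sequence: str, modifications: tuple[tuple[int, str], ...] = ()) -> float:
    """Neutral monoisotopic mass of an arbitrary residue string (sum + water)."""
    return sum(residue_masses(sequence, modifications)) + WATER


def peptide_mass(peptide: Peptide) -> float:
    """Neutral monoisotopic mass (Da) of a :class:`Peptide`."""
    return sequence_mass(peptide.sequence, peptide.modifications)


def fragment_mz(peptide: Peptide, ion: str, index: int, charge: int) -> float:
    """m/z of the b- or y-ion with ``index`` residues at the given fragment charge.

    b_i = (sum of the first i residue masses + charge * proton) / charge;
    y_i = (sum of the last i residue masses + water + charge * proton) / charge.
    """
    if ion not in ("b", "y"):
        raise ValueError(f"ion must be 'b' or 'y', got {ion!r}")
    if charge < 1:
        raise ValueError(f"fragment charge must be >= 1, got {charge}")
    if not 1 <= index < len(peptide.sequence):
        raise ValueError(
            f"fragment index {index} outside 1..{len(peptide.sequence) - 1} "
            f"for {peptide.sequence!r}"
        )
    masses = residue_masses(peptide.sequence, peptide.modifications)
    if ion == "b":
        neutral = sum(masses[:index])
    else:
        neutral = sum(masses[-index:]) + WATER
    return (neutral + charge * PROTON) / charge


def fragment_neutral_mass(peptide: Peptide, ion: str, index: int) -> float:
    """Neutral mass of the fragment (b: residue sum, y: residue sum + water)."""
    return fragment_mz(peptide, ion, index, 1) - PROTON


def levenshtein(a: str, b: str) -> int:
    """Minimal edit distance (insertions/deletions/substitutions)."""
    if not a or not b:
        raise ValueError("levenshtein requires non-empty sequences")
    if a == b:
        return 0
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def il_equivalent(a: str, b: str) -> bool:
    """True iff the sequences are identical after collapsing I to L in both."""
    return a.replace("I", "L") == b.replace("I", "L")


def isobaric_pair(a: str, b: str, tol_ppm: float = 25.0,
                  mods_a: tuple[tuple[int, str], ...] = (),
                  mods_b: tuple[tuple[int, str], ...] = ()) -> bool:
    """True iff the neutral masses agree within ``tol_ppm`` of the mean mass."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    ma = sequence_mass(a, mods_a)
    mb = sequence_mass(b, mods_b)
    mean = 0.5 * (ma + mb)
    return abs(ma - mb) <= tol_ppm * 1e-6 * mean


#: residue combinations of (near-)equal mass that confound spliced/canonical calls
ISOBARIC_SUBSTITUTIONS: tuple[tuple[str, str], ...] = (
    ("GVA", "NL"),
    ("GG", "N"),
    ("GA", "Q"),
    ("I", "L"),
)
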