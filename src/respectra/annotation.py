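"""b/y fragment annotation against observed peaks and the masked intensity tensor.

The substrate of both prediction and similarity scoring is a fixed-shape
tensor: 29 fragment positions x {b, y} x fragment charge 1..3 (174 entries),
base-peak normalized, with the sentinel -1 marking entries that cannot exist
for a given peptide (position >= length, or fragment charge above the
precursor charge).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import MAX_LENGTH, MIN_LENGTH, Peptide, fragment_mz
from .io import RawSpectrum

MASKED = -1.0
N_POSITIONS = 29
IONS = ("b", "y")
N_CHARGES = 3
FLAT_DIM = N_POSITIONS * len(IONS) * N_CHARGES  # 174

#: matching tolerances by analyzer; the ion-trap value is conventional
DEFAULT_TOLERANCE = {"FTMS": ("ppm", 25.0), "ITMS": ("da", 0.4)}


def mask_array(length: int, precursor_charge: int) -> np.ndarray:
    """Boolean validity mask (29, 2, 3): True where an entry can exist."""
    if not MIN_LENGTH <= length <= MAX_LENGTH:
        raise ValueError(f"peptide length {length} outside {MIN_LENGTH}-{MAX_LENGTH}")
    pos_ok = np.arange(1, N_POSITIONS + 1) < length
    charge_ok = np.arange(1, N_CHARGES + 1) <= precursor_charge
    return pos_ok[:, None, None] & np.ones(2, bool)[None, :, None] & charge_ok[None, None, :]


def valid_dimension_count(length: int, precursor_charge: int) -> int:
    """min(length-1, 29) * 2 ion types * min(3, precursor_charge)."""
    return int(mask_array(length, precursor_charge).sum())


@dataclass
class FragmentMatrix:
    """Masked (29, 2, 3) relative-intensity tensor for one peptide/charge.

    The flat 174-vector layout (``.flat``) is position-major, b before y,
    fragment charge ascending — this ordering is part of the file contract
    for prediction vectors.
    """

    values: np.ndarray
    length: int
    precursor_charge: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_POSITIONS, len(IONS), N_CHARGES):
            raise ValueError(f"values must have shape (29, 2, 3), got {self.values.shape}")

    @classmethod
    def zeros(cls, length: int, precursor_charge: int) -> "FragmentMatrix":
        values = np.where(mask_array(length, precursor_charge), 0.0, MASKED)
        return cls(values, length, precursor_charge)

    @classmethod
    def from_flat(cls, flat: np.ndarray, length: int, precursor_charge: int) -> "FragmentMatrix":
        return cls(np.asarray(flat, float).reshape(N_POSITIONS, len(IONS), N_CHARGES),
                   length, precursor_charge)

    @property
    def mask(self) -> np.ndarray:
        return mask_array(self.length, self.precursor_charge)

    @property
    def flat(self) -> np.ndarray:
        return self.values.reshape(FLAT_DIM)

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def same_mask(self, other: "FragmentMatrix") -> bool:
        return (self.length == other.length
                and min(self.precursor_charge, N_CHARGES) == min(other.precursor_charge, N_CHARGES))


def base_peak_normalize(matrix: FragmentMatrix) -> FragmentMatrix:
    """Divide valid entries by the maximum valid entry; all-zero is unchanged.

    Idempotent; masked entries stay -1.
    """
    valid = matrix.mask
    peak = matrix.values[valid].max(initial=0.0)
    values = matrix.values.copy()
    if peak > 0:
        values[valid] = values[valid] / peak
    return FragmentMatrix(values, matrix.length, matrix.precursor_charge)


@dataclass
class AnnotationStats:
    n_theoretical: int
    n_matched: int
    n_matched_b: int
    n_matched_y: int
    frac_intensity_annotated: float


def theoretical_ions(peptide: Peptide) -> list[tuple[int, int, int, float]]:
    """All valid (position index 1.., ion index, charge, m/z) for the peptide."""
    mask = mask_array(len(peptide), peptide.precursor_charge)
    out = []
    for pos in range(1, N_POSITIONS + 1):
        for ion_idx, ion in enumerate(IONS):
            for charge in range(1, N_CHARGES + 1):
                if mask[pos - 1, ion_idx, charge - 1]:
                    out.append((pos, ion_idx, charge,
                                fragment_mz(peptide, ion, pos, charge)))
    return out


def _match_peak(spectrum: RawSpectrum, mz: float, tol_kind: str, tol: float) -> int | None:
    """Index of the best peak within tolerance: most intense, ties by ppm error."""
    width = mz * tol * 1e-6 if tol_kind == "ppm" else tol
    lo = np.searchsorted(spectrum.mz, mz - width, side="left")
    hi = np.searchsorted(spectrum.mz, mz + width, side="right")
    if lo == hi:
        return None
    window = slice(lo, hi)
    intens = spectrum.intensity[window]
    best = np.flatnonzero(intens == intens.max())
    if len(best) > 1:
        errors = np.abs(spectrum.mz[window][best] - mz)
        best = best[[int(np.argmin(errors))]]
    return int(lo + best[0])


def annotate(spectrum: RawSpectrum, peptide: Peptide,
             tol: tuple[str, float] | None = None) -> tuple[FragmentMatrix, AnnotationStats]:
    """Match theoretical b/y ions to observed peaks and build the intensity tensor.

    Each valid (position, ion, charge) entry receives the intensity of its
    matched peak (the most intense peak inside the tolerance window, ties
    broken by smallest m/z error) or 0.  A single observed peak may serve
    several theoretical ions.  The result is base-peak normalized.
    """
    if tol is None:
        tol = DEFAULT_TOLERANCE.get(spectrum.analyzer, DEFAULT_TOLERANCE["FTMS"])
    tol_kind, tol_value = tol
    matrix = FragmentMatrix.zeros(len(peptide), peptide.precursor_charge)
    matched_intensity = 0.0
    matched_peaks: set[int] = set()
    n_matched = n_b = n_y = 0
    for pos, ion_idx, charge, mz in theoretical_ions(peptide):
        idx = _match_peak(spectrum, mz, tol_kind, tol_value)
        if idx is None:
            continue
        matrix.values[pos - 1, ion_idx, charge - 1] = spectrum.intensity[idx]
        matched_peaks.add(idx)
        n_matched += 1
        if ion_idx == 0:
            n_b += 1
        else:
            n_y += 1
    for idx in matched_peaks:
        matched_intensity += spectrum.intensity[idx]
    total = float(spectrum.intensity.sum())
    stats = AnnotationStats(
        n_theoretical=valid_dimension_count(len(peptide), peptide.precursor_charge),
        n_matched=n_matched, n_matched_b=n_b, n_matched_y=n_y,
        frac_intensity_annotated=matched_intensity / total if total > 0 else 0.0,
    )
    return base_peak_normalize(matrix), stats


def annotation_to_table(matrix: FragmentMatrix, peptide: Peptide):
    """One row per valid dimension: pos, ion, charge, m/z, intensity (TSV dump)."""
    import pandas as pd

    rows = []
    for pos, ion_idx, charge, mz in theoretical_ions(peptide):
        rows.append({"position": pos, "ion": IONS[ion_idx], "charge": charge,
                     "mz": mz, "intensity": matrix.values[pos - 1, ion_idx, charge - 1]})
    return pd.DataFrame(rows)
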