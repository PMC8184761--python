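"""Position-weight-matrix motifs, emission-probability scoring, and
Jensen-Shannon divergence between motifs.

The emission probability of a peptide under an allele's motif is the sum of
its residue frequencies at the most position-restricted (anchor-like)
columns: positions are ranked by their maximum observed frequency and only
the top k (default 5) contribute, so 8-11-mer scores are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_INDEX = {ch: i for i, ch in enumerate(ALPHABET)}


@dataclass
class PWM:
    """A 20 x L column-stochastic frequency matrix."""

    matrix: np.ndarray
    n_peptides: int
    pseudocount: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != len(ALPHABET):
            raise ValueError("PWM matrix must have 20 rows")
        sums = self.matrix.sum(axis=0)
        if np.any(self.matrix < 0) or not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must be non-negative and sum to 1")

    @property
    def alphabet(self) -> str:
        return ALPHABET

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def frequency(self, residue: str, position: int) -> float:
        """Frequency of ``residue`` at 0-based ``position``."""
        return float(self.matrix[_INDEX[residue], position])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(ALPHABET),
                            columns=[f"pos{j + 1}" for j in range(self.length)])


def build_pwm(peptides: list[str], pseudocount: float = 0.0) -> PWM:
    """Column-wise residue frequencies with an optional additive pseudocount."""
    if not peptides:
        raise ValueError("build_pwm needs at least one peptide")
    length = len(peptides[0])
    if any(len(p) != length for p in peptides):
        raise ValueError("build_pwm requires equal-length peptides")
    counts = np.zeros((len(ALPHABET), length))
    for peptide in peptides:
        for j, ch in enumerate(peptide):
            counts[_INDEX[ch], j] += 1
    matrix = (counts + pseudocount) / (len(peptides) + len(ALPHABET) * pseudocount)
    return PWM(matrix, n_peptides=len(peptides), pseudocount=pseudocount)


def ranked_positions(pwm: PWM) -> np.ndarray:
    """Positions ordered by column maximum frequency, descending (stable)."""
    col_max = pwm.matrix.max(axis=0)
    return np.argsort(-col_max, kind="stable")


def emission_probability(peptide: str, pwms_by_length: dict[int, PWM],
                         top_k: int = 5) -> float | None:
    """Sum of the peptide's residue frequencies at the top-k ranked positions.

    Returns None when no PWM exists for the peptide's length (callers count
    skips).  The score is the raw top-k sum, bounded by [0, k].
    """
    pwm = pwms_by_length.get(len(peptide))
    if pwm is None:
        return None
    positions = ranked_positions(pwm)[:top_k]
    return float(sum(pwm.frequency(peptide[j], j) for j in positions))


def average_emission(peptides: list[str], pwms_by_length: dict[int, PWM],
                     top_k: int = 5) -> tuple[float, int]:
    """(mean emission across scoreable peptides, number skipped)."""
    scores = [emission_probability(p, pwms_by_length, top_k) for p in peptides]
    kept = [s for s in scores if s is not None]
    skipped = len(scores) - len(kept)
    return (float(np.mean(kept)) if kept else float("nan")), skipped


def js_divergence(pwm_a: PWM, pwm_b: PWM) -> float:
    """Mean base-2 Jensen-Shannon divergence across positions, in [0, 1]."""
    if pwm_a.length != pwm_b.length:
        raise ValueError("js_divergence requires PWMs of equal length")
    per_position = [
        jensenshannon(pwm_a.matrix[:, j], pwm_b.matrix[:, j], base=2) ** 2
        for j in range(pwm_a.length)
    ]
    return float(np.nan_to_num(np.mean(per_position)))
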