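"""Additive retention-time prediction, per-run calibration, and the
delta-iRT95 agreement metric.

The predictor is a linear model on residue composition and length — a
deliberately simple stand-in for a learned hydrophobicity model that still
produces an |observed - predicted| retention-time feature for rescoring the
way any learned predictor would.  Alignment of predicted to observed times
uses the repeated-median (Siegel) robust line.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def composition_features(sequences: list[str]) -> np.ndarray:
    """Residue counts (20) plus length for each sequence."""
    out = np.zeros((len(sequences), len(_ALPHABET) + 1))
    for i, seq in enumerate(sequences):
        for ch in seq:
            out[i, _ALPHABET.index(ch)] += 1
        out[i, -1] = len(seq)
    return out


class CompositionRTModel(BaseEstimator, RegressorMixin):
    """Least-squares retention-time model on residue composition.

    The residue-count columns sum to the length column, so the design is
    rank-deficient by construction; the minimum-norm solution is used and
    only predictions (not individual coefficients) are identifiable.
    Fitted attributes: ``coef_`` (20 residues), ``length_coef_``,
    ``intercept_``, ``residual_summary_``.
    """

    min_peptides = 30

    def fit(self, X: list[str], y: np.ndarray) -> "CompositionRTModel":
        if len(X) < self.min_peptides:
            raise ValueError(f"need >= {self.min_peptides} peptides to fit, got {len(X)}")
        design = np.hstack([composition_features(list(X)), np.ones((len(X), 1))])
        y = np.asarray(y, dtype=float)
        solution, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < design.shape[1]:
            # expected: counts + length are collinear; minimum-norm fit applies
            logger.info("rank-deficient RT design (rank %d of %d); minimum-norm fit",
                        rank, design.shape[1])
        self.coef_ = solution[:-2]
        self.length_coef_ = float(solution[-2])
        self.intercept_ = float(solution[-1])
        residuals = y - design @ solution
        self.residual_summary_ = {
            "median_abs": float(np.median(np.abs(residuals))),
            "rmse": float(np.sqrt(np.mean(residuals ** 2))),
            "n": len(X),
        }
        return self

    def predict(self, X: list[str]) -> np.ndarray:
        design = composition_features(list(X))
        return design[:, :-1] @ self.coef_ + design[:, -1] * self.length_coef_ + self.intercept_


def fit_rt(sequences: list[str], observed_rt: np.ndarray) -> CompositionRTModel:
    return CompositionRTModel().fit(sequences, observed_rt)


def align_rt(predicted: np.ndarray, observed: np.ndarray,
             confident_mask: np.ndarray | None = None
             ) -> tuple[np.ndarray, tuple[float, float]]:
    """Robust linear map from predicted to observed retention times.

    Fits a repeated-median (Siegel) line on the confident pairs and returns
    (residuals over all pairs, (slope, intercept)); residuals are
    observed - mapped.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if confident_mask is None:
        confident_mask = np.ones(len(predicted), dtype=bool)
    fit_x, fit_y = predicted[confident_mask], observed[confident_mask]
    if len(fit_x) < 10:
        raise ValueError("need >= 10 confident pairs for alignment")
    if np.ptp(fit_x) == 0:
        raise ValueError("degenerate alignment: all predicted values equal")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        slope, intercept = _stats.siegelslopes(fit_y, fit_x)
    residuals = observed - (slope * predicted + intercept)
    return residuals, (float(slope), float(intercept))


def delta_irt95(residuals: np.ndarray) -> float:
    """95th percentile of |residuals| (linear-interpolation percentile)."""
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size == 0:
        raise ValueError("delta_irt95 requires non-empty residuals")
    return float(np.percentile(np.abs(residuals), 95, method="linear"))
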