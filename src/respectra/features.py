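"""Spectral similarity scores and the rescoring feature vector.

The central score is the normalized spectral contrast angle
SA = 1 - 2*arccos(<p_hat, o_hat>)/pi between the L2-normalized predicted and
observed fragment-intensity vectors, computed over the dimensions valid in
both tensors.  The feature vector deliberately contains nothing derived from
any search engine's own score: target/decoy separation during rescoring must
come from prediction agreement alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .annotation import AnnotationStats, FragmentMatrix
from .chem import MAX_PRECURSOR_CHARGE, PROTON, peptide_mass
from .io import PSMRecord, RawSpectrum

FEATURE_NAMES = (
    "spectral_angle", "pearson", "pearson_defined", "spearman",
    "frac_pred_matched", "frac_intensity_annotated",
    "n_matched_b", "n_matched_y", "abs_delta_rt", "rt_missing",
    "abs_precursor_ppm", "length",
    "charge_1", "charge_2", "charge_3", "charge_4", "charge_5", "charge_6",
)


def _shared_valid(pred: FragmentMatrix, obs: FragmentMatrix) -> np.ndarray:
    if not pred.same_mask(obs):
        raise ValueError(
            "mismatched mask metadata: "
            f"({pred.length}, {pred.precursor_charge}) vs ({obs.length}, {obs.precursor_charge})"
        )
    return pred.mask & obs.mask


def spectral_angle(pred: FragmentMatrix, obs: FragmentMatrix) -> float:
    """Normalized spectral contrast angle in [0, 1] over shared valid dims.

    Negative predicted values are clipped to 0; if either vector is all-zero
    the angle is defined as 0 (an unmatchable PSM earns no credit).
    """
    shared = _shared_valid(pred, obs)
    p = np.clip(pred.values[shared], 0.0, None)
    o = obs.values[shared]
    return spectral_angle_vectors(p, o)


def spectral_angle_vectors(p: np.ndarray, o: np.ndarray) -> float:
    """SA between two non-negative intensity vectors (already mask-reduced)."""
    norm_p = np.linalg.norm(p)
    norm_o = np.linalg.norm(o)
    if norm_p == 0.0 or norm_o == 0.0:
        return 0.0
    cosine = float(np.dot(p, o) / (norm_p * norm_o))
    cosine = min(1.0, max(-1.0, cosine))
    return 1.0 - 2.0 * np.arccos(cosine) / np.pi


def sa_distributions(sa_values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Per-group SA summaries: median, fraction < 0.5, fraction >= 0.9, count.

    Empty groups are simply absent from the output (never reported as zero).
    """
    frame = pd.DataFrame({"sa": sa_values, "group": groups})
    out = frame.groupby("group", sort=True)["sa"].agg(
        median_sa="median",
        frac_below_05=lambda s: float((s < 0.5).mean()),
        frac_above_09=lambda s: float((s >= 0.9).mean()),
        n="count",
    )
    return out.reset_index()


def _safe_corr(func, p: np.ndarray, o: np.ndarray) -> tuple[float, float]:
    """(coefficient, defined-indicator); degenerate inputs map to (0, 0)."""
    if len(p) < 2 or np.std(p) == 0 or np.std(o) == 0:
        return 0.0, 0.0
    r = func(p, o)
    value = float(r[0] if isinstance(r, tuple) else r.statistic)
    if not np.isfinite(value):
        return 0.0, 0.0
    return value, 1.0


def build_features(psm: PSMRecord, pred: FragmentMatrix, obs: FragmentMatrix,
                   stats: AnnotationStats, spectrum: RawSpectrum | None = None,
                   rt_pred: float | None = None) -> dict[str, float]:
    """Assemble the rescoring feature vector for one PSM.

    ``engine_score`` is never part of the vector.  A missing retention-time
    prediction yields abs_delta_rt = 0 together with the ``rt_missing``
    indicator.
    """
    shared = _shared_valid(pred, obs)
    p = np.clip(pred.values[shared], 0.0, None)
    o = obs.values[shared]

    pearson, pearson_defined = _safe_corr(_stats.pearsonr, p, o)
    spearman, _ = _safe_corr(_stats.spearmanr, p, o)

    predicted_ions = p > 0
    frac_pred_matched = (float((o[predicted_ions] > 0).mean())
                         if predicted_ions.any() else 0.0)

    if rt_pred is None:
        abs_delta_rt, rt_missing = 0.0, 1.0
    else:
        abs_delta_rt, rt_missing = abs(psm.retention_time - rt_pred), 0.0

    abs_ppm = 0.0
    if spectrum is not None and spectrum.precursor_mz > 0:
        z = psm.peptide.precursor_charge
        theo = (peptide_mass(psm.peptide) + z * PROTON) / z
        abs_ppm = abs(spectrum.precursor_mz - theo) / theo * 1e6

    features = {
        "spectral_angle": spectral_angle(pred, obs),
        "pearson": pearson,
        "pearson_defined": pearson_defined,
        "spearman": spearman,
        "frac_pred_matched": frac_pred_matched,
        "frac_intensity_annotated": stats.frac_intensity_annotated,
        "n_matched_b": float(stats.n_matched_b),
        "n_matched_y": float(stats.n_matched_y),
        "abs_delta_rt": abs_delta_rt,
        "rt_missing": rt_missing,
        "abs_precursor_ppm": abs_ppm,
        "length": float(len(psm.peptide)),
    }
    for z in range(1, MAX_PRECURSOR_CHARGE + 1):
        features[f"charge_{z}"] = float(psm.peptide.precursor_charge == z)
    for name, value in features.items():
        if not np.isfinite(value):
            raise ValueError(f"non-finite feature {name!r} for PSM {psm.key()}")
    return features
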