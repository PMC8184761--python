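"""Semi-supervised target-decoy rescoring on spectral features only.

A Percolator-style scheme: per cross-validation fold, start from the single
best-separating feature, then iterate { label positives = targets at
q <= 0.01, negatives = all decoys; fit an L2 linear discriminant; rescore }.
Each PSM receives its score from the fold that never trained on it, fold
scores are standardized against their decoy population before pooling, and
q-values come from target-decoy competition with the conservative +1
numerator.  Engine scores are never part of the feature matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)

FORBIDDEN_FEATURES = ("engine_score",)


def tdc_qvalues(scores: np.ndarray, is_decoy: np.ndarray) -> np.ndarray:
    """Target-decoy q-values.

    FDR(s) = (#decoys >= s + 1) / max(1, #targets >= s); the q-value is the
    running minimum of FDR from the lowest score upward, capped at 1.  Ties
    are handled decoy-worst: FDR is evaluated per score threshold, so tied
    decoys count against tied targets.  Spectrum-level competition, when
    wanted, happens upstream.
    """
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    if not (~is_decoy).any() or not is_decoy.any():
        raise ValueError("tdc_qvalues needs at least one target and one decoy")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    n_decoys = np.cumsum(is_decoy[order])
    n_targets = np.cumsum(~is_decoy[order])
    # evaluate FDR at the last row of each tied group (full threshold counts)
    last_of_group = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    last_index = np.flatnonzero(last_of_group)
    group_of_row = last_index[np.searchsorted(last_index, np.arange(len(scores)))]
    fdr = ((n_decoys + 1) / np.maximum(1, n_targets))[group_of_row]
    qvals = np.minimum(1.0, np.minimum.accumulate(fdr[::-1])[::-1])
    out = np.empty(len(scores))
    out[order] = qvals
    return out


def _validate_features(features: pd.DataFrame) -> np.ndarray:
    for name in FORBIDDEN_FEATURES:
        if name in features.columns:
            raise ValueError(f"search-engine score {name!r} must not be a rescoring feature")
    values = np.asarray(features, dtype=float)
    if not np.isfinite(values).all():
        bad = features.columns[np.argwhere(~np.isfinite(values))[0, 1]]
        raise ValueError(f"non-finite values in feature {bad!r}")
    return values


def _accepted(scores: np.ndarray, is_decoy: np.ndarray, q: float) -> int:
    qv = tdc_qvalues(scores, is_decoy)
    return int(((qv <= q) & ~is_decoy).sum())


def _best_single_feature(X: np.ndarray, is_decoy: np.ndarray, q: float
                         ) -> tuple[int, float, int]:
    """(feature index, sign, accepted targets) of the best raw direction."""
    best = (0, 1.0, -1)
    for j in range(X.shape[1]):
        for sign in (1.0, -1.0):
            accepted = _accepted(sign * X[:, j], is_decoy, q)
            if accepted > best[2]:
                best = (j, sign, accepted)
    return best


@dataclass
class RescoreResult:
    """Cross-validated rescoring output plus the transferable model."""

    feature_names: list[str]
    scores: np.ndarray                      # per-PSM, decoy-standardized
    qvalues: np.ndarray                     # PSM-level
    fold_assignment: np.ndarray
    fold_weights: list[np.ndarray]
    n_accepted: int                          # targets at q <= threshold
    q_threshold: float
    transfer_scores: np.ndarray = field(default=None, repr=False)


class TargetDecoyRescorer(BaseEstimator):
    """sklearn-style estimator for feature-only semi-supervised rescoring.

    ``fit(X, y)`` takes the feature frame and the decoy indicator; fitted
    attributes include cross-validated ``scores_`` and ``qvalues_``.
    ``decision_function(X)`` applies the final model (trained on all folds)
    on the standardized shared score scale, so PSM lists from different
    search engines scored through one fitted rescorer are directly
    comparable.
    """

    def __init__(self, n_folds: int = 3, n_iterations: int = 10,
                 q_train: float = 0.01, C: float = 1.0, random_state: int = 0):
        self.n_folds = n_folds
        self.n_iterations = n_iterations
        self.q_train = q_train
        self.C = C
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _fit_direction(self, X: np.ndarray, is_decoy: np.ndarray
                       ) -> tuple[list[tuple[np.ndarray, float]], np.ndarray]:
        """Percolator iteration on one training split.

        Returns the best linear scorer (weights, bias) found — judged by
        accepted targets at ``q_train`` on the split — and its scores.
        """
        j, sign, accepted = _best_single_feature(X, is_decoy, self.q_train)
        weights = np.zeros(X.shape[1])
        weights[j] = sign
        best = (weights, 0.0, accepted)
        scores = X @ best[0]
        if accepted == 0:
            logger.warning("no positives at initialization; falling back to "
                           "best raw feature ranking")
            return (best[0], best[1]), scores
        for _ in range(self.n_iterations):
            qv = tdc_qvalues(scores, is_decoy)
            positives = (~is_decoy) & (qv <= self.q_train)
            if positives.sum() < 2:
                break
            rows = positives | is_decoy
            clf = LogisticRegression(C=self.C, max_iter=200)
            clf.fit(X[rows], positives[rows].astype(int))
            scores = X @ clf.coef_[0] + clf.intercept_[0]
            accepted = _accepted(scores, is_decoy, self.q_train)
            if accepted >= best[2]:
                best = (clf.coef_[0].copy(), float(clf.intercept_[0]), accepted)
        final_scores = X @ best[0] + best[1]
        return (best[0], best[1]), final_scores

    @staticmethod
    def _standardize(scores: np.ndarray, is_decoy: np.ndarray
                     ) -> tuple[np.ndarray, float, float]:
        mu = float(scores[is_decoy].mean())
        sd = float(scores[is_decoy].std())
        sd = sd if sd > 0 else 1.0
        return (scores - mu) / sd, mu, sd

    # -- estimator API -----------------------------------------------------
    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "TargetDecoyRescorer":
        values = _validate_features(X)
        is_decoy = np.asarray(y, dtype=bool)
        rng = np.random.default_rng(self.random_state)
        n = len(values)
        self.feature_names_ = list(X.columns)
        self.feature_mean_ = values.mean(axis=0)
        std = values.std(axis=0)
        # a (numerically) constant feature carries no signal; leave it unscaled
        # rather than amplifying float noise on transfer to other PSM lists
        floor = 1e-9 * np.maximum(1.0, np.abs(self.feature_mean_))
        self.feature_std_ = np.where(std > floor, std, 1.0)
        Z = (values - self.feature_mean_) / self.feature_std_

        folds = rng.permutation(n) % self.n_folds
        scores = np.empty(n)
        self.fold_weights_ = []
        for fold in range(self.n_folds):
            train = folds != fold
            (w, b), _ = self._fit_direction(Z[train], is_decoy[train])
            self.fold_weights_.append(np.concatenate([w, [b]]))
            held = Z[~train] @ w + b
            held_std, _, _ = self._standardize(held, is_decoy[~train])
            scores[~train] = held_std
        self.fold_assignment_ = folds
        self.scores_ = scores
        self.qvalues_ = tdc_qvalues(scores, is_decoy)
        self.n_accepted_ = int(((self.qvalues_ <= self.q_train) & ~is_decoy).sum())

        # final transferable model, trained on all PSMs
        (w, b), all_scores = self._fit_direction(Z, is_decoy)
        _, mu, sd = self._standardize(all_scores, is_decoy)
        self.transfer_weights_, self.transfer_bias_ = w, b
        self.transfer_mu_, self.transfer_sd_ = mu, sd
        self.transfer_scores_ = (all_scores - mu) / sd
        self.is_decoy_ = is_decoy
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        """Scores on the shared (decoy-standardized) scale of the fitted model."""
        if list(X.columns) != self.feature_names_:
            raise ValueError(
                "feature mismatch: expected "
                f"{self.feature_names_}, got {list(X.columns)}")
        values = _validate_features(X)
        Z = (values - self.feature_mean_) / self.feature_std_
        raw = Z @ self.transfer_weights_ + self.transfer_bias_
        return (raw - self.transfer_mu_) / self.transfer_sd_

    def result(self) -> RescoreResult:
        return RescoreResult(
            feature_names=self.feature_names_, scores=self.scores_,
            qvalues=self.qvalues_, fold_assignment=self.fold_assignment_,
            fold_weights=self.fold_weights_, n_accepted=self.n_accepted_,
            q_threshold=self.q_train, transfer_scores=self.transfer_scores_,
        )


def semi_supervised_rescore(features: pd.DataFrame, is_decoy: np.ndarray,
                            folds: int = 3, iterations: int = 10,
                            q_train: float = 0.01, random_state: int = 0
                            ) -> RescoreResult:
    rescorer = TargetDecoyRescorer(n_folds=folds, n_iterations=iterations,
                                   q_train=q_train, random_state=random_state)
    rescorer.fit(features, is_decoy)
    return rescorer.result()


def apply_pretrained(rescorer: TargetDecoyRescorer, features: pd.DataFrame,
                     is_decoy: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray | None]:
    """Score another engine's PSMs with a pre-trained model.

    Scores land on the shared standardized scale; q-values are recomputed on
    the new list when its decoy labels are supplied.
    """
    scores = rescorer.decision_function(features)
    qvalues = tdc_qvalues(scores, is_decoy) if is_decoy is not None else None
    return scores, qvalues


def peptide_qvalues(scores: np.ndarray, is_decoy: np.ndarray,
                    peptides: list[str]) -> pd.DataFrame:
    """Peptide-level q-values: best PSM per modified sequence, then TDC.

    Peptide identity includes modifications and excludes charge.
    """
    frame = pd.DataFrame({"peptide": peptides, "score": np.asarray(scores, float),
                          "is_decoy": np.asarray(is_decoy, bool)})
    best = (frame.sort_values("score", ascending=False, kind="stable")
            .groupby("peptide", sort=True).head(1).reset_index(drop=True))
    best["q_value"] = tdc_qvalues(best["score"].to_numpy(), best["is_decoy"].to_numpy())
    return best


def compare_sets(reference: set[str] | list[str], new: set[str] | list[str]
                 ) -> dict[str, object]:
    """Lost/shared/gained comparison of two peptide sets (Vennbar numbers)."""
    ref, new = set(reference), set(new)
    lost, shared, gained = ref - new, ref & new, new - ref
    return {
        "lost": len(lost), "shared": len(shared), "gained": len(gained),
        "lost_peptides": sorted(lost), "shared_peptides": sorted(shared),
        "gained_peptides": sorted(gained),
    }
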