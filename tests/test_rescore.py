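"""Target-decoy q-values, semi-supervised rescoring, model transfer,
peptide-level summaries and set comparison."""

import numpy as np
import pandas as pd
import pytest

from respectra.rescore import (TargetDecoyRescorer, apply_pretrained,
                               compare_sets, peptide_qvalues,
                               semi_supervised_rescore, tdc_qvalues)
from respectra.simulate import generate_psm_benchmark


def brute_force_qvalues(scores, is_decoy):
    """Enumerate every threshold; q = min FDR over thresholds at/below score."""
    scores = np.asarray(scores, float)
    is_decoy = np.asarray(is_decoy, bool)
    fdrs = {}
    for s in scores:
        decoys = ((scores > s) & is_decoy).sum() + ((scores == s) & is_decoy).sum()
        targets = ((scores > s) & ~is_decoy).sum() + ((scores == s) & ~is_decoy).sum()
        fdrs[s] = (decoys + 1) / max(1, targets)
    out = np.empty(len(scores))
    for i, s in enumerate(scores):
        out[i] = min(1.0, min(fdr for t, fdr in fdrs.items() if t <= s))
    return out


class TestTdcQvalues:
    def test_worked_example(self):
        scores = np.array([10.0, 9.0, 8.0, 8.5])
        is_decoy = np.array([False, False, False, True])
        q = tdc_qvalues(scores, is_decoy)
        # at score 9: one decoy above + 1 over two targets -> 0.5... running
        # minimum from below keeps it
        assert q[1] == pytest.approx(0.5)
        assert q[0] == pytest.approx(0.5)  # (0+1)/1 = 1 monotonized down to 0.5

    def test_no_decoy_above_top_target(self):
        q = tdc_qvalues(np.array([5.0, 1.0]), np.array([False, True]))
        assert q[0] == pytest.approx(1.0)  # (0+1)/1

    def test_matches_brute_force_on_random_inputs(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 40))
            scores = np.round(rng.normal(size=n), 1)  # ties likely
            is_decoy = rng.random(n) < 0.5
            if is_decoy.all() or not is_decoy.any():
                continue
            np.testing.assert_allclose(tdc_qvalues(scores, is_decoy),
                                       brute_force_qvalues(scores, is_decoy))

    def test_monotone_in_score(self, rng):
        scores = rng.normal(size=200)
        is_decoy = rng.random(200) < 0.5
        q = tdc_qvalues(scores, is_decoy)
        order = np.argsort(scores)
        assert np.all(np.diff(q[order]) <= 1e-12)

    def test_all_decoy_rejected(self):
        with pytest.raises(ValueError):
            tdc_qvalues(np.array([1.0, 2.0]), np.array([True, True]))


class TestSemiSupervisedRescore:
    def test_perfectly_separating_feature_accepts_all_targets(self):
        rng = np.random.default_rng(0)
        n = 150
        features = pd.DataFrame({
            "sa": np.concatenate([rng.uniform(0.8, 1.0, n),
                                  rng.uniform(0.0, 0.2, n)]),
            "noise": rng.normal(size=2 * n),
        })
        is_decoy = np.array([False] * n + [True] * n)
        result = semi_supervised_rescore(features, is_decoy, random_state=1)
        assert result.n_accepted == n

    def test_pure_noise_accepts_almost_nothing(self):
        accepted = []
        for seed in range(5):
            features, is_decoy, _ = generate_psm_benchmark(0, 300, 300, 0.0,
                                                           seed=seed)
            result = semi_supervised_rescore(features, is_decoy,
                                             random_state=seed)
            accepted.append(result.n_accepted)
        # q <= 0.01 on a 300-decoy null: expect about 1% of decoy count
        assert np.mean(accepted) <= 0.01 * 300 + 3

    def test_no_harm_over_initial_feature_ranking(self):
        from respectra.rescore import _best_single_feature, _accepted
        for seed in range(10):
            features, is_decoy, _ = generate_psm_benchmark(150, 150, 300, 2.0,
                                                           seed=seed)
            X = (features - features.mean()) / features.std()
            j, sign, initial = _best_single_feature(X.to_numpy(), is_decoy, 0.01)
            result = semi_supervised_rescore(features, is_decoy,
                                             random_state=seed)
            assert result.n_accepted >= initial - 5  # CV noise allowance

    def test_fdr_calibration_within_binomial_interval(self):
        """Pooled false-discovery proportion at q <= 0.05 across 10 seeds."""
        false_hits = total_hits = 0
        for seed in range(10):
            features, is_decoy, is_true = generate_psm_benchmark(
                400, 400, 400, 3.0, seed=100 + seed)
            result = semi_supervised_rescore(features, is_decoy,
                                             random_state=seed)
            accepted = (result.qvalues <= 0.05) & ~is_decoy
            total_hits += int(accepted.sum())
            false_hits += int((accepted & ~is_true).sum())
        fdp = false_hits / total_hits
        half_width = 1.96 * np.sqrt(0.05 * 0.95 / total_hits)
        assert 0.05 - half_width <= fdp <= 0.05 + half_width

    def test_cross_validation_no_self_scoring(self):
        features, is_decoy, _ = generate_psm_benchmark(100, 100, 200, 2.0, seed=3)
        rescorer = TargetDecoyRescorer(random_state=0).fit(features, is_decoy)
        assert len(np.unique(rescorer.fold_assignment_)) == 3


class TestApplyPretrained:
    @pytest.fixture
    def fitted(self):
        features, is_decoy, _ = generate_psm_benchmark(200, 100, 300, 2.5, seed=7)
        return TargetDecoyRescorer(random_state=0).fit(features, is_decoy), features, is_decoy

    def test_identity_on_own_training_features(self, fitted):
        rescorer, features, _ = fitted
        scores, _ = apply_pretrained(rescorer, features)
        np.testing.assert_allclose(scores, rescorer.transfer_scores_)

    def test_constant_feature_shift_shifts_scores_by_constant(self, fitted):
        rescorer, features, _ = fitted
        shifted = features.copy()
        shifted["spectral_angle"] += 2.0
        a, _ = apply_pretrained(rescorer, features)
        b, _ = apply_pretrained(rescorer, shifted)
        deltas = b - a
        np.testing.assert_allclose(deltas, deltas[0], atol=1e-9)

    def test_feature_mismatch_is_hard_error(self, fitted):
        rescorer, features, _ = fitted
        wrong = features.rename(columns={"spectral_angle": "sa"})
        with pytest.raises(ValueError, match="feature"):
            apply_pretrained(rescorer, wrong)

    def test_cross_engine_competition_single_best_psm(self, fitted):
        rescorer, features, is_decoy = fitted
        scores, qvalues = apply_pretrained(rescorer, features, is_decoy)
        assert qvalues is not None and len(scores) == len(features)
        frame = pd.DataFrame({"scan": np.repeat(np.arange(len(scores) // 2), 2),
                              "score": scores[:2 * (len(scores) // 2)]})
        best = frame.groupby("scan")["score"].max()
        assert len(best) == len(scores) // 2

    def test_engine_score_forbidden_as_feature(self):
        features = pd.DataFrame({"engine_score": [1.0, 2.0],
                                 "sa": [0.1, 0.9]})
        with pytest.raises(ValueError, match="engine_score"):
            TargetDecoyRescorer().fit(features, np.array([True, False]))


class TestPeptideLevel:
    def test_best_psm_per_peptide(self):
        scores = np.array([3.0, 5.0, 4.0, 1.0])
        is_decoy = np.array([False, False, False, True])
        peptides = ["PEPA", "PEPA", "PEPA", "REVA"]
        table = peptide_qvalues(scores, is_decoy, peptides)
        assert len(table) == 2
        assert table.loc[table["peptide"] == "PEPA", "score"].item() == 5.0

    def test_cardinality_not_exceeding_psms(self, rng):
        n = 50
        peptides = [f"PEP{i % 17}" for i in range(n)]
        table = peptide_qvalues(rng.normal(size=n), rng.random(n) < 0.4, peptides)
        assert len(table) <= n


class TestCompareSets:
    def test_lost_shared_gained(self):
        out = compare_sets({"A", "B"}, {"B", "C"})
        assert (out["lost"], out["shared"], out["gained"]) == (1, 1, 1)
        assert out["gained_peptides"] == ["C"]

    def test_conservation(self, rng):
        ref = {f"P{i}" for i in rng.integers(0, 40, size=25)}
        new = {f"P{i}" for i in rng.integers(0, 40, size=25)}
        out = compare_sets(ref, new)
        assert out["lost"] + out["shared"] == len(ref)
        assert out["shared"] + out["gained"] == len(new)

    def test_identical_sets(self):
        out = compare_sets({"A", "B"}, {"A", "B"})
        assert (out["lost"], out["shared"], out["gained"]) == (0, 2, 0)
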