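"""Predictor data hygiene, loss/schedule, training smoke, CE calibration."""

import numpy as np
import pandas as pd
import pytest

from respectra.intensity import (GRUIntensityPredictor, TrainConfig,
                                 calibrate_ce, clr_schedule, encode_frame,
                                 sa_loss, select_training_psms,
                                 split_by_sequence, unmodified)
from respectra.simulate import (RuleBasedIntensityPredictor, SimConfig,
                                sample_peptides, simulate_fragmentation,
                                training_frame)


def _frame(sequences, charge=2, nce=30.0, **extra):
    base = {"modified_sequence": sequences,
            "precursor_charge": charge, "nce": nce}
    base.update(extra)
    return pd.DataFrame(base)


class TestSplitBySequence:
    def test_rounding_7_2_1(self):
        frame = _frame([f"PEPTIDE{ch}" for ch in "ACDEFGHIKL"])
        train, test, holdout = split_by_sequence(frame, seed=0)
        assert (len(train), len(test), len(holdout)) == (7, 2, 1)

    def test_deterministic_and_disjoint(self):
        frame = _frame([f"PEPTIDE{a}{b}" for a in "ACDEF" for b in "GHIKL"])
        parts_a = split_by_sequence(frame, seed=5)
        parts_b = split_by_sequence(frame, seed=5)
        sets = []
        for pa, pb in zip(parts_a, parts_b):
            pd.testing.assert_frame_equal(pa, pb)
            sets.append(set(pa["modified_sequence"].map(unmodified)))
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])

    def test_modified_variants_travel_together(self):
        frame = _frame(["PEPTM(ox)IDEK", "PEPTMIDEK", "ALSPVIKQ", "GNDFPRAT",
                        "WVCTTLIY"])
        for part in split_by_sequence(frame, seed=1):
            seqs = set(part["modified_sequence"].map(unmodified))
            assert not ({"PEPTMIDEK"} < seqs) or "PEPTM(ox)IDEK" in set(
                part["modified_sequence"])
        # both PSMs of PEPTMIDEK end up in exactly one part
        counts = [int((part["modified_sequence"].map(unmodified) == "PEPTMIDEK").sum())
                  for part in split_by_sequence(frame, seed=1)]
        assert sorted(counts) == [0, 0, 2]

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            split_by_sequence(_frame(["PEPTIDEK", "ALSPVIKQ"]), seed=0)


class TestSelectTrainingPsms:
    def test_top3_per_group(self):
        frame = _frame(["PEPTIDEK"] * 5, rawfile="r",
                       scan=[1, 2, 3, 4, 5],
                       engine_score=[5.0, 9.0, 7.0, 8.0, 6.0])
        kept = select_training_psms(frame, k=3)
        assert sorted(kept["engine_score"]) == [7.0, 8.0, 9.0]

    def test_small_group_fully_retained(self):
        frame = _frame(["PEPTIDEK"] * 2, scan=[1, 2], engine_score=[1.0, 2.0],
                       rawfile="r")
        assert len(select_training_psms(frame, k=3)) == 2

    def test_groups_differing_only_in_nce_are_independent(self):
        frame = pd.concat([
            _frame(["PEPTIDEK"] * 4, nce=25.0, rawfile="r", scan=range(4),
                   engine_score=[1.0, 2.0, 3.0, 4.0]),
            _frame(["PEPTIDEK"] * 4, nce=30.0, rawfile="r", scan=range(4, 8),
                   engine_score=[1.0, 2.0, 3.0, 4.0]),
        ], ignore_index=True)
        kept = select_training_psms(frame, k=3)
        assert len(kept) == 6
        assert sorted(kept.groupby("nce").size()) == [3, 3]


class TestLossAndSchedule:
    def test_sa_loss_zero_iff_proportional(self):
        true = np.array([0.2, 0.8, 0.0, 0.0])
        mask = np.array([1.0, 1.0, 1.0, 0.0])
        assert sa_loss(true * 3.0, true, mask) == pytest.approx(0.0, abs=1e-3)
        orthogonal = np.array([0.0, 0.0, 1.0, 0.0])
        assert sa_loss(orthogonal, true, mask) == pytest.approx(1.0, abs=1e-3)

    def test_clr_limits_and_decay(self):
        cfg = TrainConfig()
        assert clr_schedule(0, 0, cfg) == pytest.approx(1e-7)
        assert clr_schedule(0, 4, cfg) == pytest.approx(1e-3)       # first peak
        assert clr_schedule(0, 20, cfg) == pytest.approx(1e-3 * 0.95 ** 2)
        # triangular: halfway up the first ramp
        assert clr_schedule(0, 2, cfg) == pytest.approx(
            1e-7 + 0.5 * (1e-3 - 1e-7))

    def test_low_always_below_high(self):
        cfg = TrainConfig()
        rates = [clr_schedule(s, e, cfg) for e in range(40) for s in (0,)]
        assert min(rates) >= cfg.clr_low
        assert max(rates) <= cfg.clr_high0


@pytest.fixture(scope="module")
def overfit_model():
    """A small network overfit on 50 noiseless spectra (capacity check)."""
    cfg = SimConfig(seed=2)
    peptides = sample_peptides(50, cfg)
    frame, y = training_frame(peptides, nce=30.0)
    tcfg = TrainConfig(max_epochs=30, batch_size=16, patience=30, seed=0)
    model = GRUIntensityPredictor(units=32, dec_units=16, dropout=0.0,
                                  train_config=tcfg, random_state=0)
    model.fit(frame, y)
    return model, frame, y


class TestTraining:
    def test_overfit_smoke_loss_decreases(self, overfit_model):
        model, _, _ = overfit_model
        losses = [h["train_loss"] for h in model.history_]
        assert losses[-1] < 0.5 * losses[0]
        # broadly monotone: each loss below the running best of 5 epochs before
        for i in range(5, len(losses)):
            assert losses[i] < min(losses[:i - 4]) + 0.05

    def test_predictions_masked_and_normalized(self, overfit_model):
        model, frame, _ = overfit_model
        pred = model.predict(frame.head(10))
        _, _, masks = encode_frame(frame.head(10))
        assert np.all(pred[~masks] == -1.0)
        valid_max = np.where(masks, pred, 0.0).max(axis=1)
        assert np.allclose(valid_max, 1.0)
        assert np.all(pred[masks] >= 0.0)

    def test_learns_proline_y_dominance(self, overfit_model):
        """The generator's proline rule surfaces in the trained predictions."""
        model, frame, y = overfit_model
        proline = frame[frame["modified_sequence"].str.contains("P")]
        if len(proline) == 0:
            pytest.skip("no proline peptide sampled")
        pred = model.predict(proline)
        _, _, masks = encode_frame(proline)
        b = np.where(masks, pred, 0.0)[:, 0::6] + np.where(masks, pred, 0.0)[:, 1::6] \
            + np.where(masks, pred, 0.0)[:, 2::6]
        yv = np.where(masks, pred, 0.0)[:, 3::6] + np.where(masks, pred, 0.0)[:, 4::6] \
            + np.where(masks, pred, 0.0)[:, 5::6]
        assert yv.sum() > b.sum()

    def test_save_load_round_trip(self, overfit_model, tmp_path):
        model, frame, _ = overfit_model
        path = tmp_path / "model.npz"
        model.save(str(path))
        back = GRUIntensityPredictor.load(str(path))
        np.testing.assert_allclose(back.predict(frame.head(5)),
                                   model.predict(frame.head(5)))


class TestCalibrateCe:
    def test_recovers_generating_nce(self):
        cfg = SimConfig(seed=13, ppm_jitter=3.0, noise_per_100th=0.5,
                        intensity_sigma=0.2, nce=30.0)
        rng = cfg.rng()
        peptides = sample_peptides(120, cfg, rng)
        frame, _ = training_frame(peptides, nce=cfg.nce)
        observed = np.stack([simulate_fragmentation(p, cfg.nce).flat
                             for p in peptides])
        best, curve = calibrate_ce(RuleBasedIntensityPredictor(), frame, observed)
        assert abs(best - 30.0) <= 1.0
        assert len(curve) == 21
        assert curve["median_sa"].max() == pytest.approx(1.0, abs=1e-6)

    def test_single_value_grid(self):
        cfg = SimConfig(seed=13)
        peptides = sample_peptides(5, cfg)
        frame, y = training_frame(peptides, nce=30.0)
        best, curve = calibrate_ce(RuleBasedIntensityPredictor(), frame, y,
                                   grid=[27])
        assert best == 27.0 and len(curve) == 1

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            calibrate_ce(RuleBasedIntensityPredictor(),
                         pd.DataFrame(columns=["modified_sequence",
                                               "precursor_charge", "nce"]),
                         np.empty((0, 174)))
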