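"""End-to-end wiring of the building blocks on synthetic data.

The central piece is the spliced-peptide audit: spectra rendered from
canonical ground truth are annotated under both the canonical and the
proposed spliced hypothesis, scored against intensity predictions, put on a
shared confidence scale by a rescoring model trained on the canonical
search (targets plus reversed-sequence decoys), and finally passed through
the consecutive splice filters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import annotate
from .features import build_features
from .io import PSMRecord
from .rescore import TargetDecoyRescorer, apply_pretrained
from .simulate import (ConfusionPair, RuleBasedIntensityPredictor, SimConfig,
                       generate_dataset, generate_decoy)
from .splice import DEFAULT_MARGIN, AccountingReport, SpliceCandidate, assess_spliced


def _features_for(peptide, spectrum, predictor, nce):
    psm = PSMRecord(spectrum.rawfile, spectrum.scan, peptide)
    pred = predictor.predict_matrix(peptide, nce)
    obs, stats = annotate(spectrum, peptide)
    return build_features(psm, pred, obs, stats, spectrum)


def rescorer_from_canonical_search(n_psms: int = 400, cfg: SimConfig | None = None,
                                   predictor=None, random_state: int = 0
                                   ) -> TargetDecoyRescorer:
    """Train a rescoring model on a canonical search (targets + decoys).

    Emulates fitting the semi-supervised model on an engine's full
    canonical-database results before transferring it to candidate lists; a
    1% FDR cut needs a few hundred targets to be meaningful at all.
    """
    if cfg is None:
        cfg = SimConfig(seed=random_state)
    if predictor is None:
        predictor = RuleBasedIntensityPredictor()
    dataset = generate_dataset(n_psms, cfg, n_decoys=n_psms)
    rows = [_features_for(item.psm.peptide, item.spectrum, predictor,
                          item.spectrum.nce) for item in dataset]
    features = pd.DataFrame(rows)
    is_decoy = np.array([item.psm.is_decoy for item in dataset])
    return TargetDecoyRescorer(random_state=random_state).fit(features, is_decoy)


def audit_confusion_pairs(pairs: list[ConfusionPair],
                          rescorer: TargetDecoyRescorer | None = None,
                          predictor=None,
                          q_threshold: float = 0.01,
                          margin: float = DEFAULT_MARGIN,
                          random_state: int = 0
                          ) -> tuple[AccountingReport, pd.DataFrame]:
    """Run the full splice re-assessment on generated confusion pairs.

    Candidate and competitor PSMs are scored by a model pre-trained on a
    canonical search (supplied or freshly trained), so all hypotheses live
    in one confidence space; candidate q-values come from target-decoy
    competition against reversed-sequence decoys of the canonical peptides.
    """
    if predictor is None:
        predictor = RuleBasedIntensityPredictor()
    if rescorer is None:
        rescorer = rescorer_from_canonical_search(predictor=predictor,
                                                  random_state=random_state)
    canonical_rows, spliced_rows, decoy_rows = [], [], []
    for pair in pairs:
        nce = pair.spectrum.nce
        canonical_rows.append(_features_for(pair.canonical, pair.spectrum,
                                            predictor, nce))
        spliced_rows.append(_features_for(pair.spliced, pair.spectrum,
                                          predictor, nce))
        decoy_rows.append(_features_for(generate_decoy(pair.canonical),
                                        pair.spectrum, predictor, nce))
    canonical = pd.DataFrame(canonical_rows)
    spliced = pd.DataFrame(spliced_rows)
    decoys = pd.DataFrame(decoy_rows)

    canonical_scores, _ = apply_pretrained(rescorer, canonical)
    spliced_scores, spliced_q = apply_pretrained(
        rescorer, pd.concat([spliced, decoys], ignore_index=True),
        np.r_[np.zeros(len(spliced), bool), np.ones(len(decoys), bool)])
    spliced_scores = spliced_scores[:len(spliced)]
    spliced_q = spliced_q[:len(spliced)]

    candidates = []
    for i, pair in enumerate(pairs):
        candidates.append(SpliceCandidate(
            sequence=pair.spliced_sequence,
            rawfile=pair.spectrum.rawfile, scan=pair.spectrum.scan,
            score=float(spliced_scores[i]), q_value=float(spliced_q[i]),
            competitors=[("canonical_search", pair.canonical.sequence,
                          float(canonical_scores[i]))],
        ))
    universe = {pair.canonical.sequence for pair in pairs}
    return assess_spliced(candidates, q_threshold=q_threshold, margin=margin,
                          canonical_universe=universe)


def model_recovery_experiment(n_spectra: int = 2000, nce: float = 30.0,
                              max_epochs: int = 50, seed: int = 11) -> dict:
    """Train the predictor on noiseless synthetic spectra and measure
    held-out agreement.

    Uses the 70/20/10 sequence-disjoint split; the held-out median spectral
    angle quantifies how well the network recovered the generative
    fragmentation rules on unseen sequences.
    """
    from .intensity import GRUIntensityPredictor, TrainConfig, split_by_sequence
    from .simulate import sample_peptides, training_frame

    cfg = SimConfig(seed=seed)
    peptides = sample_peptides(n_spectra, cfg)
    frame, y = training_frame(peptides, nce=nce)
    train, test, holdout = split_by_sequence(frame, seed=seed + 1)
    tcfg = TrainConfig(max_epochs=max_epochs, batch_size=16, patience=max_epochs,
                       restart_epoch=int(0.72 * max_epochs), restart_high=1e-4,
                       seed=seed)
    model = GRUIntensityPredictor(units=64, dec_units=32, dropout=0.0,
                                  train_config=tcfg, random_state=seed)
    model.fit(train, y[train.index.to_numpy()],
              validation=(test, y[test.index.to_numpy()]))
    median_sa = model.median_holdout_sa(holdout, y[holdout.index.to_numpy()])
    return {"model": model, "median_holdout_sa": median_sa,
            "n_epochs": model.n_epochs_,
            "split_sizes": (len(train), len(test), len(holdout))}


def ce_calibration_experiment(n_psms: int = 500, true_nce: float = 30.0,
                              seed: int = 13) -> dict:
    """Recover the acquisition NCE from rendered spectra via grid search."""
    from .intensity import calibrate_ce
    from .simulate import render_spectrum, sample_peptides, simulate_fragmentation

    cfg = SimConfig(seed=seed, nce=true_nce)
    rng = cfg.rng()
    peptides = sample_peptides(n_psms, cfg, rng)
    rows, observed = [], []
    for scan, peptide in enumerate(peptides, start=1):
        truth = simulate_fragmentation(peptide, true_nce)
        spectrum = render_spectrum(truth, peptide, cfg, rng, scan=scan)
        matrix, _ = annotate(spectrum, peptide)
        rows.append({"modified_sequence": peptide.modified_sequence,
                     "precursor_charge": peptide.precursor_charge,
                     "nce": true_nce})
        observed.append(matrix.flat)
    best, curve = calibrate_ce(RuleBasedIntensityPredictor(),
                               pd.DataFrame(rows), np.stack(observed))
    return {"calibrated_nce": best, "curve": curve}


def fdr_calibration_experiment(n_seeds: int = 10, n_true: int = 400,
                               n_false: int = 400, n_decoy: int = 400,
                               effect_size: float = 3.0, q: float = 0.05,
                               base_seed: int = 100) -> dict:
    """Pooled false-discovery proportion of the rescorer at a q cut.

    False targets and decoys are exchangeable, so the FDP among accepted
    targets is known exactly; pooling across seeds gives the binomial
    sample size for the calibration check.
    """
    from .rescore import semi_supervised_rescore
    from .simulate import generate_psm_benchmark

    false_hits = total_hits = 0
    for i in range(n_seeds):
        features, is_decoy, is_true = generate_psm_benchmark(
            n_true, n_false, n_decoy, effect_size, seed=base_seed + i)
        result = semi_supervised_rescore(features, is_decoy, random_state=i)
        accepted = (result.qvalues <= q) & ~is_decoy
        total_hits += int(accepted.sum())
        false_hits += int((accepted & ~is_true).sum())
    return {"fdp": false_hits / max(1, total_hits), "n_accepted": total_hits,
            "n_false_accepted": false_hits, "q": q}
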