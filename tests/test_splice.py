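"""Consecutive-filter re-assessment of proposed spliced peptides."""

import numpy as np
import pandas as pd
import pytest

from respectra.splice import (AccountingReport, SpliceCandidate,
                              assess_canonical, assess_spliced,
                              rank_best_psm_per_spectrum)


def make_candidate(sequence="ALSPVIKQ", score=5.0, q=0.001, competitors=(),
                   **kw):
    return SpliceCandidate(sequence=sequence, score=score, q_value=q,
                           competitors=list(competitors), **kw)


def build_stage_cohort(n_i, n_ii, n_iii, n_iv, n_clean):
    """Construct candidates engineered to fall at each consecutive stage."""
    out = []
    for i in range(n_i):   # not confident after rescoring
        out.append(make_candidate(sequence=f"AAAGNDFPR|A{'T' * (i % 3)}T",
                                  q=0.5, score=1.0))
    for i in range(n_ii):  # I/L isomer of a canonical peptide
        out.append(make_candidate(sequence="AIKGNDFPR",
                                  competitors=[("mq", "ALKGNDFPR", 0.0)]))
    for i in range(n_iii):  # outcompeted by a canonical PSM
        out.append(make_candidate(sequence="AVKGNDFPR", score=2.0,
                                  competitors=[("mq", "PEPTIDEKA", 3.0)]))
    for i in range(n_iv):  # wins, but not substantially (margin)
        out.append(make_candidate(sequence="AWKGNDFPR", score=2.9,
                                  competitors=[("mq", "PEPTIDEKC", 2.5)]))
    for i in range(n_clean):
        out.append(make_candidate(sequence="AYKGNDFPR", score=9.0,
                                  competitors=[("mq", "PEPTIDEKD", 2.0)]))
    return out


class TestAssessSpliced:
    def test_constructed_cohort_accounting(self):
        candidates = build_stage_cohort(2, 1, 3, 1, 3)
        report, verdicts = assess_spliced(candidates, margin=1.0)
        assert report.total == 10
        assert report.rejected == {"rescoring": 2, "il_isomer": 1,
                                   "better_competitor": 3, "score_margin": 1}
        assert report.retained == 3
        report.check()
        assert list(verdicts["verdict"]).count("retained") == 3

    def test_published_scale_accounting(self):
        """The four stages reject 596/90/315/66 of 1,230; 87% rejected."""
        candidates = build_stage_cohort(596, 90, 315, 66, 163)
        report, _ = assess_spliced(candidates, margin=1.0)
        assert report.total == 1230
        assert report.n_rejected == 1067
        assert round(report.rejected_percent) == 87
        assert report.retained == 163

    def test_margin_example_gap_04_rejected(self):
        candidate = make_candidate(score=2.9,
                                   competitors=[("mq", "PEPTIDEKA", 2.5)])
        report, verdicts = assess_spliced([candidate], margin=1.0)
        assert verdicts["verdict"].item() == "rejected_score_margin"
        # with a margin below the gap the candidate survives
        report, _ = assess_spliced([candidate], margin=0.3)
        assert report.retained == 1

    def test_zero_margin_rejects_nothing_at_stage_iv(self):
        candidates = build_stage_cohort(0, 0, 0, 5, 5)
        report, _ = assess_spliced(candidates, margin=0.0)
        assert report.rejected["score_margin"] == 0
        assert report.retained == 10

    def test_rejected_count_monotone_in_margin(self):
        rng = np.random.default_rng(8)
        candidates = [make_candidate(score=float(rng.uniform(0, 5)),
                                     competitors=[("mq", "PEPTIDEKA",
                                                   float(rng.uniform(0, 5)))])
                      for _ in range(100)]
        rejected = [assess_spliced(candidates, margin=m)[0].n_rejected
                    for m in (0.0, 0.5, 1.0, 2.0, 5.0)]
        assert rejected == sorted(rejected)

    def test_stage_order_is_consecutive(self):
        # fails both rescoring and margin: charged to the first stage only
        candidate = make_candidate(q=0.9, score=2.9,
                                   competitors=[("mq", "PEPTIDEKA", 2.5)])
        _, verdicts = assess_spliced([candidate])
        assert verdicts["verdict"].item() == "rejected_rescoring"

    def test_candidate_without_rescore_is_non_assessable(self):
        candidate = SpliceCandidate(sequence="ALSPVIKQ")
        report, verdicts = assess_spliced([candidate])
        assert report.non_assessable == 1
        assert verdicts["verdict"].item() == "non_assessable"
        report.check()

    def test_il_check_against_canonical_universe(self):
        candidate = make_candidate(sequence="AIKGNDFPR")
        report, _ = assess_spliced([candidate],
                                   canonical_universe={"ALKGNDFPR"})
        assert report.rejected["il_isomer"] == 1

    def test_splice_marker_ignored_for_sequence_logic(self):
        candidate = make_candidate(sequence="AIKGND|FPR",
                                   competitors=[("mq", "ALKGNDFPR", 0.0)])
        report, _ = assess_spliced([candidate])
        assert report.rejected["il_isomer"] == 1


class TestAssessCanonical:
    def test_published_scale_control(self):
        """179 of 3,994 rejected at rescoring (4%), 296 by better competitor."""
        candidates = ([make_candidate(q=0.5) for _ in range(179)]
                      + [make_candidate(score=1.0,
                                        competitors=[("mq", "PEPTIDEKA", 2.0)])
                         for _ in range(296)]
                      + [make_candidate(score=5.0) for _ in range(3519)])
        report, _ = assess_canonical(candidates)
        assert report.total == 3994
        assert report.rejected["rescoring"] == 179
        assert round(100 * report.rejected["rescoring"] / report.total) == 4
        assert report.rejected["better_competitor"] == 296
        assert report.retained == 3519
        assert "score_margin" not in [s for s, n in report.rejected.items() if n]

    def test_empty_input_zero_report(self):
        report, verdicts = assess_canonical([])
        assert report.total == 0 and report.retained == 0
        assert len(verdicts) == 0

    def test_no_competitors_means_no_stage_iii_rejections(self):
        candidates = [make_candidate() for _ in range(5)]
        report, _ = assess_canonical(candidates)
        assert report.rejected["better_competitor"] == 0
        assert report.retained == 5


class TestRankBestPsm:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["rawfile", "scan", "sequence",
                                           "engine", "score", "is_spliced"])

    def test_spliced_with_higher_score_ranks_first(self):
        frame = self._frame([("r", 1, "FAGDLVRNL", "mq", 2.5, False),
                             ("r", 1, "FAGDLVRGVA", "mascot", 2.9, True)])
        best = rank_best_psm_per_spectrum(frame)
        assert best["sequence"].item() == "FAGDLVRGVA"

    def test_single_engine_spectrum(self):
        frame = self._frame([("r", 2, "PEPTIDEKA", "mq", 1.0, False)])
        assert rank_best_psm_per_spectrum(frame)["sequence"].item() == "PEPTIDEKA"

    def test_tie_prefers_canonical(self):
        frame = self._frame([("r", 1, "FAGDLVRGVA", "mascot", 2.5, True),
                             ("r", 1, "FAGDLVRNL", "mq", 2.5, False)])
        best = rank_best_psm_per_spectrum(frame)
        assert best["sequence"].item() == "FAGDLVRNL"
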