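"""Re-assessment of proposed proteasomally spliced peptides.

A proposed spliced peptide survives only if it (i) stays confident under
feature-only rescoring, (ii) is not an I/L isomer of any canonical peptide,
(iii) beats every canonical competitor PSM for its spectrum on the shared
score scale, and (iv) beats the best competitor by more than a configurable
margin.  The filters are consecutive: a candidate is charged to the first
stage that rejects it, and the accounting always conserves
total = sum(rejections) + retained + non-assessable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .chem import il_equivalent

STAGES = ("rescoring", "il_isomer", "better_competitor", "score_margin")

#: the margin below which a spliced score is not "substantially better" than
#: the canonical alternative; the showcase ambiguity has a gap of 0.4, so the
#: default must exceed that — 1.0, exposed as a tunable
DEFAULT_MARGIN = 1.0


@dataclass
class SpliceCandidate:
    """A proposed spliced peptide with its rescoring outcome and competitors.

    ``sequence`` may carry the splice-position marker ``|``; all mass and
    sequence computation uses the concatenated sequence.  ``competitors``
    are (engine, sequence, shared-scale score) canonical alternatives for
    the same spectrum.
    """

    sequence: str
    rawfile: str = ""
    scan: int = 0
    score: float | None = None
    q_value: float | None = None
    competitors: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def plain_sequence(self) -> str:
        return self.sequence.replace("|", "")


@dataclass
class AccountingReport:
    total: int = 0
    rejected: dict[str, int] = field(default_factory=lambda: {s: 0 for s in STAGES})
    retained: int = 0
    non_assessable: int = 0

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected.values())

    @property
    def rejected_percent(self) -> float:
        return 100.0 * self.n_rejected / self.total if self.total else 0.0

    def check(self) -> None:
        assert self.total == self.n_rejected + self.retained + self.non_assessable

    def as_dict(self) -> dict:
        return {"total": self.total, **{f"rejected_{s}": self.rejected[s] for s in STAGES},
                "rejected": self.n_rejected, "rejected_percent": self.rejected_percent,
                "retained": self.retained, "non_assessable": self.non_assessable}


def _first_rejecting_stage(candidate: SpliceCandidate, q_threshold: float,
                           margin: float, canonical_universe: set[str],
                           stages: tuple[str, ...]) -> str | None:
    best_competitor = max((score for _, _, score in candidate.competitors),
                          default=None)
    for stage in stages:
        if stage == "rescoring":
            if candidate.q_value > q_threshold:
                return stage
        elif stage == "il_isomer":
            plain = candidate.plain_sequence
            pool = {seq for _, seq, _ in candidate.competitors} | canonical_universe
            if any(il_equivalent(plain, other) for other in pool if other != plain):
                return stage
        elif stage == "better_competitor":
            if best_competitor is not None and best_competitor >= candidate.score:
                return stage
        elif stage == "score_margin":
            if best_competitor is not None and 0.0 < candidate.score - best_competitor <= margin:
                return stage
    return None


def assess_spliced(candidates: list[SpliceCandidate], q_threshold: float = 0.01,
                   margin: float = DEFAULT_MARGIN,
                   canonical_universe: set[str] | None = None,
                   stages: tuple[str, ...] = STAGES
                   ) -> tuple[AccountingReport, pd.DataFrame]:
    """Run the consecutive filters and return accounting plus verdicts.

    A candidate without a rescoring result is counted as non-assessable —
    never silently retained.  Stage ii checks I/L equivalence against both
    the candidate's own competitors and the supplied canonical universe.
    """
    universe = canonical_universe or set()
    report = AccountingReport(total=len(candidates))
    rows = []
    for candidate in candidates:
        if candidate.score is None or candidate.q_value is None:
            report.non_assessable += 1
            verdict = "non_assessable"
        else:
            stage = _first_rejecting_stage(candidate, q_threshold, margin,
                                           universe, stages)
            if stage is None:
                report.retained += 1
                verdict = "retained"
            else:
                report.rejected[stage] += 1
                verdict = f"rejected_{stage}"
        rows.append({"sequence": candidate.sequence, "rawfile": candidate.rawfile,
                     "scan": candidate.scan, "score": candidate.score,
                     "q_value": candidate.q_value, "verdict": verdict})
    report.check()
    return report, pd.DataFrame(rows)


def assess_canonical(candidates: list[SpliceCandidate], q_threshold: float = 0.01,
                     canonical_universe: set[str] | None = None
                     ) -> tuple[AccountingReport, pd.DataFrame]:
    """The two-stage control: rescoring confidence and better competitor only."""
    return assess_spliced(candidates, q_threshold=q_threshold, margin=0.0,
                          canonical_universe=canonical_universe,
                          stages=("rescoring", "better_competitor"))


def rank_best_psm_per_spectrum(psms: pd.DataFrame) -> pd.DataFrame:
    """Best assignment per (rawfile, scan) across engines on the shared scale.

    Requires columns rawfile, scan, sequence, engine, score, is_spliced.
    Ties prefer the canonical over the spliced hypothesis, then the
    lexicographically smaller sequence.
    """
    ordered = psms.sort_values(
        ["rawfile", "scan", "score", "is_spliced", "sequence"],
        ascending=[True, True, False, True, True], kind="stable")
    return ordered.groupby(["rawfile", "scan"], sort=True).head(1).reset_index(drop=True)
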