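"""Scoring of identity claims against ground truth and cohort statistics."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .classifier import (
    ANIMAL,
    BOVINE,
    CHICKEN,
    Claim,
    HUMAN,
    INCONCLUSIVE,
    NA,
    NO,
    NONE_DETECTED,
    PORCINE,
    SEMEN,
    YES,
)
from .synthetic_data import BLOOD_TRUTHS

__all__ = [
    "FULL_CORRECT",
    "PARTIAL",
    "INCORRECT",
    "ScoredSample",
    "CohortSummary",
    "score_claim",
    "summarize",
    "report",
]

FULL_CORRECT = "full_correct"
PARTIAL = "partial"
INCORRECT = "incorrect"

_SPECIES_OF = {
    "bovine_blood": BOVINE,
    "porcine_blood": PORCINE,
    "chicken_blood": CHICKEN,
}


@dataclass(frozen=True)
class ScoredSample:
    sample_id: str
    truth: str
    claim: Claim
    verdict: str
    blood_false_negative: bool = False
    blood_false_positive: bool = False
    human_false_positive: bool = False


def score_claim(truth: str, claim: Claim, sample_id: str = "") -> ScoredSample:
    """Verdict over the applicable identification levels.

    A claim is fully correct iff every applicable level matches the truth
    (species level applies only to animal blood; semen truth requires a
    semen claim). An 'inconclusive' at the first diverging level yields a
    partial verdict; a definite wrong value yields an incorrect one.
    """
    blood_fn = truth in BLOOD_TRUTHS and claim.level_i_blood == NO
    blood_fp = truth not in BLOOD_TRUTHS and claim.level_i_blood == YES
    human_fp = truth != "human_blood" and claim.level_ii_provenance == HUMAN

    def scored(verdict: str) -> ScoredSample:
        return ScoredSample(
            sample_id=sample_id,
            truth=truth,
            claim=claim,
            verdict=verdict,
            blood_false_negative=blood_fn,
            blood_false_positive=blood_fp,
            human_false_positive=human_fp,
        )

    if truth in BLOOD_TRUTHS:
        expected = [(claim.level_i_blood, YES)]
        if truth == "human_blood":
            expected.append((claim.level_ii_provenance, HUMAN))
        else:
            expected.append((claim.level_ii_provenance, ANIMAL))
            expected.append((claim.level_iii_species, _SPECIES_OF[truth]))
        for got, want in expected:
            if got == want:
                continue
            return scored(PARTIAL if got == INCONCLUSIVE else INCORRECT)
        return scored(FULL_CORRECT)

    if truth == "semen":
        if claim.level_i_blood == YES:
            return scored(INCORRECT)
        if claim.level_iv_other_biofluid == SEMEN:
            return scored(FULL_CORRECT)
        if claim.level_i_blood == INCONCLUSIVE:
            return scored(PARTIAL)
        return scored(INCORRECT)

    # Non-biofluid-marker truths: correct means "not blood, nothing detected".
    if claim.level_i_blood == YES or claim.level_iv_other_biofluid == SEMEN:
        return scored(INCORRECT)
    if claim.level_i_blood == INCONCLUSIVE:
        return scored(PARTIAL)
    return scored(FULL_CORRECT)


def _rate(count: int, denom: int) -> float:
    return 100.0 * count / denom if denom else 0.0


@dataclass(frozen=True)
class CohortSummary:
    n: int
    full_correct: int
    partial: int
    incorrect: int
    blood_fn_count: int
    blood_fn_denominator: int
    blood_fp_count: int
    blood_fp_denominator: int
    human_fp_count: int
    per_truth: Mapping[str, Mapping[str, int]] = field(default_factory=dict)

    @property
    def full_correct_rate(self) -> float:
        return _rate(self.full_correct, self.n)

    @property
    def blood_fn_rate(self) -> float:
        return _rate(self.blood_fn_count, self.blood_fn_denominator)

    @property
    def blood_fp_rate(self) -> float:
        return _rate(self.blood_fp_count, self.blood_fp_denominator)


def summarize(
    scored: Sequence[ScoredSample],
    category_filter: Callable[[ScoredSample], bool] | Iterable[str] | None = None,
) -> CohortSummary:
    """Cohort statistics over the (optionally filtered) scored samples.

    ``category_filter`` may be a predicate over scored samples or a
    collection of truth-class names.
    """
    if not scored:
        raise ValueError("cannot summarize an empty cohort")
    if category_filter is None:
        selected = list(scored)
        label = "all"
    elif callable(category_filter):
        selected = [s for s in scored if category_filter(s)]
        label = getattr(category_filter, "__name__", "predicate")
    else:
        truths = set(category_filter)
        selected = [s for s in scored if s.truth in truths]
        label = ",".join(sorted(truths))
    if not selected:
        raise ValueError(f"category filter {label!r} selected no samples")
    counts = {FULL_CORRECT: 0, PARTIAL: 0, INCORRECT: 0}
    per_truth: dict[str, dict[str, int]] = {}
    for s in selected:
        counts[s.verdict] += 1
        per_truth.setdefault(s.truth, {FULL_CORRECT: 0, PARTIAL: 0, INCORRECT: 0})
        per_truth[s.truth][s.verdict] += 1
    blood = [s for s in selected if s.truth in BLOOD_TRUTHS]
    non_blood = [s for s in selected if s.truth not in BLOOD_TRUTHS]
    return CohortSummary(
        n=len(selected),
        full_correct=counts[FULL_CORRECT],
        partial=counts[PARTIAL],
        incorrect=counts[INCORRECT],
        blood_fn_count=sum(s.blood_false_negative for s in blood),
        blood_fn_denominator=len(blood),
        blood_fp_count=sum(s.blood_false_positive for s in non_blood),
        blood_fp_denominator=len(non_blood),
        human_fp_count=sum(s.human_false_positive for s in selected),
        per_truth=per_truth,
    )


def report(
    summary: CohortSummary,
    path: str | Path,
    scored: Sequence[ScoredSample] | None = None,
) -> None:
    """Write a TSV table (one row per sample when ``scored`` is given) plus a
    caption line with the headline rates."""
    if not str(path):
        raise ValueError("report path must be non-empty")
    path = Path(path)
    lines = []
    caption = (
        f"# n={summary.n} full_correct={summary.full_correct} "
        f"({summary.full_correct_rate:.1f}%) partial={summary.partial} "
        f"incorrect={summary.incorrect} "
        f"blood_FN={summary.blood_fn_count}/{summary.blood_fn_denominator} "
        f"({summary.blood_fn_rate:.1f}%) "
        f"blood_FP={summary.blood_fp_count}/{summary.blood_fp_denominator} "
        f"({summary.blood_fp_rate:.1f}%)"
    )
    lines.append(caption)
    header = [
        "sample_id", "truth", "level_i", "level_ii", "level_iii", "level_iv", "verdict",
    ]
    lines.append("\t".join(header))
    for s in scored or ():
        lines.append(
            "\t".join(
                [
                    s.sample_id,
                    s.truth,
                    s.claim.level_i_blood,
                    s.claim.level_ii_provenance,
                    s.claim.level_iii_species,
                    s.claim.level_iv_other_biofluid,
                    s.verdict,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
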