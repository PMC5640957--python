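"""Rank-threshold evaluation of normalization predictions.

For a rank threshold k, every candidate at rank <= k is a positive
prediction: a candidate is correct iff its concept ID (after alias
resolution) belongs to the mention's gold set. Each correct positive is
a TP, each incorrect positive an FP, and a mention with no correct
positive contributes one FN. A mention resolved by the exact-match
shortcut is assigned a single concept ID and counts as exactly one TP at
every threshold (no FPs). Precision, recall and F are

    p = TP / (TP + FP),  r = TP / (TP + FN),  f = 2pr / (p + r)

with the 0/0 cases defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, Sequence, TextIO

from .normalize import Candidate


class PredictionLike(Protocol):
    """What the evaluator needs from a per-mention prediction."""

    @property
    def candidates(self) -> Sequence[Candidate]: ...

    @property
    def exact_match(self) -> bool: ...

    @property
    def gold_concept_ids(self) -> set[str]: ...


@dataclass(frozen=True)
class EvalResult:
    rank_threshold: int
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f_score(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def judge_candidate(
    candidate: Candidate,
    gold_concept_ids: set[str],
    aliases: Mapping[str, str] | None = None,
) -> bool:
    """True iff the candidate's concept (after alias resolution) is one
    of the gold concepts; an empty gold set judges everything
    incorrect."""
    if not gold_concept_ids:
        return False
    cid = aliases.get(candidate.concept_id, candidate.concept_id) if aliases else candidate.concept_id
    gold = (
        {aliases.get(g, g) for g in gold_concept_ids} if aliases else gold_concept_ids
    )
    return cid in gold


def evaluate_at_rank(
    predictions: Iterable[PredictionLike],
    threshold: int,
    aliases: Mapping[str, str] | None = None,
    *,
    first_hit: bool = False,
) -> EvalResult:
    """Count TP/FP/FN at a rank threshold.

    ``first_hit=True`` switches to an alternative accounting in which
    candidates below the first correct one are ignored; the default
    counts every incorrect candidate above the threshold as an FP.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    tp = fp = fn = 0
    for pred in predictions:
        if pred.exact_match:
            correct = any(
                judge_candidate(c, pred.gold_concept_ids, aliases)
                for c in pred.candidates
            )
            if correct:
                tp += 1  # a single assigned ID; one TP at every threshold
            else:
                fn += 1
            continue
        hit = False
        for cand in pred.candidates:
            if cand.rank > threshold:
                break
            if judge_candidate(cand, pred.gold_concept_ids, aliases):
                tp += 1
                hit = True
                if first_hit:
                    break
            else:
                fp += 1
        if not hit:
            fn += 1
    return EvalResult(rank_threshold=threshold, tp=tp, fp=fp, fn=fn)


def evaluation_curve(
    predictions: Sequence[PredictionLike],
    max_threshold: int,
    aliases: Mapping[str, str] | None = None,
    *,
    first_hit: bool = False,
) -> list[EvalResult]:
    """Evaluate at every threshold 1..max_threshold. Recall is
    non-decreasing in the threshold."""
    if max_threshold < 1:
        raise ValueError("max_threshold must be >= 1")
    return [
        evaluate_at_rank(predictions, t, aliases, first_hit=first_hit)
        for t in range(1, max_threshold + 1)
    ]


def write_curve_tsv(curve: Iterable[EvalResult], handle: TextIO) -> None:
    handle.write("threshold\ttp\tfp\tfn\tprecision\trecall\tf_score\n")
    for res in curve:
        handle.write(
            f"{res.rank_threshold}\t{res.tp}\t{res.fp}\t{res.fn}"
            f"\t{res.precision:.4f}\t{res.recall:.4f}\t{res.f_score:.4f}\n"
        )
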