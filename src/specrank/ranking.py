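"""Within-set normalisation, combined scoring, quotient statistic, and ranking.

All normalisation happens within one candidate set (the compounds retrieved
for one precursor query): MS/MS raw scores and data-source counts are each
divided by the set maximum so both lie in [0, 1], and the combined score is
their unweighted sum in [0, 2].  Division by the set maximum (rather than
min–max scaling) keeps the normalised MS/MS score identical to the quotient
statistic, which is explicitly defined as the raw score relative to the
maximum raw score returned per precursor query.

The quotient serves as a confidence screen: a candidate whose raw score is
at least 13% of the best raw score in its set (cutoff 0.13, chosen at a 0.90
true-positive rate on a ROC curve) passes.  :func:`select_quotient_cutoff`
re-derives such a cutoff from labelled data.

Three ranking schemes are supported: ``msms_only`` (raw match score),
``ds_only`` (data-source count), and ``combined``.  Ties receive the worst
rank of their tie group (pessimistic competition ranking), which avoids
inflating top-k counts; ranks therefore depend only on the score values and
are invariant to candidate input order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import DomainError, SpecRankError
from .library import CompoundRecord
from .scoring import MatchResult

SCHEMES = ("msms_only", "ds_only", "combined")

#: Default quotient confidence cutoff (raw score / set-max raw score).
DEFAULT_QUOTIENT_CUTOFF = 0.13

_RANK_FIELD = {
    "msms_only": "rank_msms",
    "ds_only": "rank_ds",
    "combined": "rank_combined",
}


@dataclass
class CandidateScore:
    """All per-candidate scores, the quotient, and ranks under each scheme."""

    compound_id: str
    raw_msms: float
    ds_count: int
    no_predicted_data: bool = False
    norm_msms: float = 0.0
    norm_ds: float = 0.0
    combined: float = 0.0
    quotient: float = 0.0
    rank_msms: int | None = None
    rank_ds: int | None = None
    rank_combined: int | None = None


@dataclass
class RankedSet:
    """One query's fully scored and ranked candidate set.

    ``known_id`` carries the ground-truth compound identifier when
    evaluating; it may be absent for real unknowns.  ``candidates`` may be
    empty when no library record fell inside the precursor window.
    """

    query_id: str
    candidates: list[CandidateScore] = field(default_factory=list)
    known_id: str | None = None


def max_normalize(values: Sequence[float], method: str = "max") -> list[float]:
    """Normalise non-negative values to [0, 1] within a candidate set.

    ``method="max"`` (default) divides by the set maximum; an all-zero input
    maps to all zeros.  ``method="minmax"`` applies min–max scaling instead
    (a constant set maps to all zeros).
    """
    vals = [float(v) for v in values]
    if any(v < 0 for v in vals):
        raise DomainError("max_normalize requires non-negative values")
    if not vals:
        return []
    if method == "max":
        top = max(vals)
        if top == 0:
            return [0.0] * len(vals)
        return [v / top for v in vals]
    if method == "minmax":
        lo, hi = min(vals), max(vals)
        if hi == lo:
            return [0.0] * len(vals)
        return [(v - lo) / (hi - lo) for v in vals]
    raise SpecRankError(f"unknown normalisation method {method!r}")


def score_candidates(
    match_results: Sequence[MatchResult],
    records: Sequence[CompoundRecord],
    w_msms: float = 1.0,
    w_ds: float = 1.0,
    norm_method: str = "max",
) -> list[CandidateScore]:
    """Link metadata to match results and normalise within the candidate set.

    Requires exactly one :class:`MatchResult` per record (same compound ids).
    Fills ``norm_msms``, ``norm_ds``, ``combined = w_msms*norm_msms +
    w_ds*norm_ds`` and ``quotient = raw / max raw`` (0 when the set maximum
    is 0).  Output follows the order of ``records``.
    """
    by_id = {m.compound_id: m for m in match_results}
    rec_ids = [r.compound_id for r in records]
    if len(by_id) != len(match_results) or set(by_id) != set(rec_ids) or len(
        set(rec_ids)
    ) != len(rec_ids):
        raise SpecRankError(
            "match results and records must carry the same unique compound ids"
        )
    raws = [by_id[r.compound_id].raw_score for r in records]
    norm_msms = max_normalize(raws, method=norm_method)
    norm_ds = max_normalize([r.ds_count for r in records], method=norm_method)
    max_raw = max(raws) if raws else 0.0
    out = []
    for rec, raw, nm, nd in zip(records, raws, norm_msms, norm_ds):
        out.append(
            CandidateScore(
                compound_id=rec.compound_id,
                raw_msms=raw,
                ds_count=rec.ds_count,
                no_predicted_data=by_id[rec.compound_id].no_predicted_data,
                norm_msms=nm,
                norm_ds=nd,
                combined=w_msms * nm + w_ds * nd,
                quotient=raw / max_raw if max_raw > 0 else 0.0,
            )
        )
    return out


def _scheme_key(score: CandidateScore, scheme: str) -> float:
    if scheme == "msms_only":
        return score.raw_msms
    if scheme == "ds_only":
        return float(score.ds_count)
    if scheme == "combined":
        return score.combined
    raise SpecRankError(f"unknown ranking scheme {scheme!r}; expected one of {SCHEMES}")


def rank_candidates(
    scores: Sequence[CandidateScore], scheme: str
) -> list[CandidateScore]:
    """Rank one candidate set under a scheme (1 = best).

    Sorts descending on the scheme's key; tied candidates all receive the
    worst rank of their tie group, i.e. ``rank(c) = #{c': key(c') >= key(c)}``.
    The rank field for the scheme is filled in place on the given objects and
    the list is returned sorted (descending key, compound_id tiebreak).
    """
    fld = _RANK_FIELD.get(scheme)
    if fld is None:
        raise SpecRankError(
            f"unknown ranking scheme {scheme!r}; expected one of {SCHEMES}"
        )
    keys = [_scheme_key(s, scheme) for s in scores]
    for s, k in zip(scores, keys):
        setattr(s, fld, sum(1 for k2 in keys if k2 >= k))
    return sorted(scores, key=lambda s: (-_scheme_key(s, scheme), s.compound_id))


def rank_all_schemes(scores: Sequence[CandidateScore]) -> list[CandidateScore]:
    """Fill ranks for all three schemes; returns the list ordered by combined rank."""
    for scheme in ("msms_only", "ds_only"):
        rank_candidates(scores, scheme)
    return rank_candidates(scores, "combined")


def quotient_pass(
    score: CandidateScore | float, cutoff: float = DEFAULT_QUOTIENT_CUTOFF
) -> bool:
    """Confidence screen: True iff the quotient is >= the cutoff (inclusive)."""
    q = getattr(score, "quotient", score)
    return float(q) >= cutoff


def select_quotient_cutoff(
    labeled: Iterable[tuple[float, bool]], target_tpr: float = 0.90
) -> float:
    """Largest quotient cutoff retaining at least ``target_tpr`` of true positives.

    Given (quotient, is_true_positive) pairs, returns the largest threshold
    ``t`` such that the fraction of true positives with quotient >= t is at
    least ``target_tpr`` — the operating point of the quotient screen on an
    empirical ROC curve.  With n true positives this is the
    ``ceil(target_tpr * n)``-th largest true-positive quotient; a target of 0
    degenerates to the maximum observed quotient.

    Raises
    ------
    DomainError
        If no true positive is present or the target is outside [0, 1].
    """
    labeled = list(labeled)
    if not 0.0 <= target_tpr <= 1.0:
        raise DomainError("target_tpr must lie in [0, 1]")
    tps = sorted((float(q) for q, is_tp in labeled if is_tp), reverse=True)
    if not tps:
        raise DomainError("select_quotient_cutoff requires at least one true positive")
    # round() guards against e.g. 0.9 * 10 = 9.000000000000002 -> ceil 10
    k = math.ceil(round(target_tpr * len(tps), 9))
    if k <= 0:
        return max(float(q) for q, _ in labeled)
    return tps[k - 1]
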