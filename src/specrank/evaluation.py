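"""Aggregate ranked candidate sets into performance tables and score statistics.

Mirrors how spectral-identification contests report results: for each
ranking scheme, the number (and percentage) of known compounds ranked in the
top 1/5/10/20 of their candidate set, plus distribution statistics (median,
mean, quartiles) of the knowns' raw match scores and quotient values and the
fraction of knowns passing the quotient confidence cutoff.

Knowns absent from the candidate set — the compound was not in the searched
library — are reported in a dedicated unranked column rather than as a
worst rank, which makes database-presence ("database boosting") effects
directly measurable.  Knowns present but lacking predicted spectra are
likewise unranked under the spectral and combined schemes, since they could
not be spectrally scored.  Percentages are reported against both
denominators: all queries, and only the ranked (in-database, scoreable)
knowns.

Quartiles use linear interpolation (NumPy default, type 7); box-plot edges
drawn from these tables depend on that convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .ranking import DEFAULT_QUOTIENT_CUTOFF, SCHEMES, CandidateScore, RankedSet

DEFAULT_KS = (1, 5, 10, 20)

_RANK_FIELD = {
    "msms_only": "rank_msms",
    "ds_only": "rank_ds",
    "combined": "rank_combined",
}


@dataclass
class SchemeSummary:
    """Top-k counts and percentages for one ranking scheme."""

    topk: dict[int, int] = field(default_factory=dict)
    pct: dict[int, float] = field(default_factory=dict)
    pct_ranked: dict[int, float] = field(default_factory=dict)
    n_unranked: int = 0


@dataclass
class EvaluationSummary:
    """Dataset-level evaluation: per-scheme top-k tables plus score statistics."""

    dataset_id: str
    n_queries: int
    per_scheme: dict[str, SchemeSummary] = field(default_factory=dict)
    raw_stats: dict[str, float] = field(default_factory=dict)
    quotient_stats: dict[str, float] = field(default_factory=dict)
    frac_quotient_ge_cutoff: float = float("nan")
    quotient_cutoff: float = DEFAULT_QUOTIENT_CUTOFF


def _find_known(ranked: RankedSet) -> CandidateScore | None:
    if ranked.known_id is None:
        return None
    for cand in ranked.candidates:
        if cand.compound_id == ranked.known_id:
            return cand
    return None


def rank_of_known(ranked: RankedSet, scheme: str) -> int | None:
    """The known compound's rank under a scheme, or None if absent from the set."""
    fld = _RANK_FIELD[scheme]
    cand = _find_known(ranked)
    if cand is None:
        return None
    return getattr(cand, fld)


def _is_unranked(cand: CandidateScore | None, scheme: str) -> bool:
    if cand is None:
        return True
    # No predicted spectra: cannot be spectrally scored and ranked.
    return scheme in ("msms_only", "combined") and cand.no_predicted_data


def topk_table(
    ranked_sets: Sequence[RankedSet],
    ks: Sequence[int] = DEFAULT_KS,
    dataset_id: str = "dataset",
    cutoff: float = DEFAULT_QUOTIENT_CUTOFF,
) -> EvaluationSummary:
    """Count knowns ranked within each top-k threshold, per scheme.

    Unranked knowns (absent from the set, or unscoreable under the scheme)
    are never counted toward any k.  Raises :class:`DomainError` on empty
    input or when no set carries a known id.
    """
    if not ranked_sets:
        raise DomainError("topk_table requires at least one ranked set")
    if all(rs.known_id is None for rs in ranked_sets):
        raise DomainError("topk_table requires ground-truth known ids")
    n = len(ranked_sets)
    ks = sorted(ks)
    summary = EvaluationSummary(dataset_id=dataset_id, n_queries=n, quotient_cutoff=cutoff)
    for scheme in SCHEMES:
        ss = SchemeSummary(topk={k: 0 for k in ks})
        for rs in ranked_sets:
            cand = _find_known(rs)
            if _is_unranked(cand, scheme):
                ss.n_unranked += 1
                continue
            rank = getattr(cand, _RANK_FIELD[scheme])
            for k in ks:
                if rank is not None and rank <= k:
                    ss.topk[k] += 1
        n_ranked = n - ss.n_unranked
        for k in ks:
            ss.pct[k] = ss.topk[k] / n * 100.0
            ss.pct_ranked[k] = (ss.topk[k] / n_ranked * 100.0) if n_ranked else float("nan")
        summary.per_scheme[scheme] = ss
    try:
        raw_stats, quotient_stats, frac = score_distributions(ranked_sets, cutoff=cutoff)
    except DomainError:
        # No scoreable known at all: the top-k table is still well defined.
        raw_stats, quotient_stats, frac = {}, {}, float("nan")
    summary.raw_stats = raw_stats
    summary.quotient_stats = quotient_stats
    summary.frac_quotient_ge_cutoff = frac
    return summary


def _stats(values: np.ndarray) -> dict[str, float]:
    return {
        "median": float(np.median(values)),
        "mean": float(np.mean(values)),
        "q25": float(np.percentile(values, 25)),
        "q75": float(np.percentile(values, 75)),
    }


def score_distributions(
    ranked_sets: Sequence[RankedSet], cutoff: float = DEFAULT_QUOTIENT_CUTOFF
) -> tuple[dict[str, float], dict[str, float], float]:
    """Distribution statistics of the knowns' raw scores and quotients.

    Considers knowns that are present in their candidate set and spectrally
    scoreable.  Returns (raw_stats, quotient_stats, fraction of knowns with
    quotient >= cutoff); raises :class:`DomainError` when no known is
    scoreable.
    """
    raws, quotients = [], []
    for rs in ranked_sets:
        cand = _find_known(rs)
        if cand is None or cand.no_predicted_data:
            continue
        raws.append(cand.raw_msms)
        quotients.append(cand.quotient)
    if not raws:
        raise DomainError("no scoreable known compounds in the ranked sets")
    raws_arr = np.asarray(raws)
    q_arr = np.asarray(quotients)
    frac = float(np.mean(q_arr >= cutoff))
    return _stats(raws_arr), _stats(q_arr), frac


def summary_frame(summary: EvaluationSummary) -> pd.DataFrame:
    """The evaluation summary as a tidy one-row-per-scheme table."""
    rows = []
    for scheme, ss in summary.per_scheme.items():
        row: dict = {
            "dataset_id": summary.dataset_id,
            "scheme": scheme,
            "n_queries": summary.n_queries,
            "n_unranked": ss.n_unranked,
        }
        for k in sorted(ss.topk):
            row[f"top{k}"] = ss.topk[k]
            row[f"pct_top{k}"] = ss.pct[k]
            row[f"pct_ranked_top{k}"] = ss.pct_ranked[k]
        for name, val in summary.raw_stats.items():
            row[f"raw_{name}"] = val
        for name, val in summary.quotient_stats.items():
            row[f"quotient_{name}"] = val
        row["frac_quotient_ge_cutoff"] = summary.frac_quotient_ge_cutoff
        row["quotient_cutoff"] = summary.quotient_cutoff
        rows.append(row)
    return pd.DataFrame(rows)


def render_report(
    summary: EvaluationSummary,
    path,
    ranked_sets: Sequence[RankedSet] | None = None,
    long_path=None,
) -> None:
    """Write the summary CSV and, optionally, a box-plot-ready long-format CSV.

    The long format holds one row per scoreable known (dataset, query,
    compound, raw score, quotient) for downstream score-distribution plots.
    """
    summary_frame(summary).to_csv(path, index=False)
    if ranked_sets is not None:
        if long_path is None:
            p = Path(path)
            long_path = p.with_name(p.stem + "_known_scores" + p.suffix)
        write_known_scores(ranked_sets, summary.dataset_id, long_path)


def write_known_scores(
    ranked_sets: Sequence[RankedSet], dataset_id: str, path
) -> None:
    rows = []
    for rs in ranked_sets:
        cand = _find_known(rs)
        if cand is None or cand.no_predicted_data:
            continue
        rows.append(
            {
                "dataset_id": dataset_id,
                "query_id": rs.query_id,
                "compound_id": cand.compound_id,
                "raw_msms": cand.raw_msms,
                "quotient": cand.quotient,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_report(path) -> pd.DataFrame:
    """Read back a summary CSV written by :func:`render_report`."""
    return pd.read_csv(path)
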