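"""End-to-end orchestration: search -> score -> rank -> evaluate."""

from __future__ import annotations

from typing import Mapping, Sequence

from .evaluation import EvaluationSummary, topk_table
from .library import SpectralLibrary, search_by_precursor
from .ranking import (
    DEFAULT_QUOTIENT_CUTOFF,
    RankedSet,
    rank_all_schemes,
    score_candidates,
)
from .scoring import DEFAULT_TOL_DA, QueryInput, multi_energy_score
from .spectra import Spectrum
from .synthetic_data import Benchmark


def rank_query(
    library: SpectralLibrary,
    query: QueryInput,
    query_id: str | None = None,
    known_id: str | None = None,
    precursor_mz: float | None = None,
    polarity: str | None = None,
    tol_ppm: float = 10.0,
    tol_da: float = DEFAULT_TOL_DA,
) -> RankedSet:
    """Retrieve, score and rank the candidate set for one query.

    ``query`` is either a merged :class:`Spectrum` or a mapping of collision
    energy to per-energy spectra (paired scoring mode); in the latter case
    ``precursor_mz`` and ``polarity`` must be supplied or are taken from any
    member spectrum.
    """
    if isinstance(query, Spectrum):
        precursor_mz = precursor_mz if precursor_mz is not None else query.precursor_mz
        polarity = polarity if polarity is not None else query.polarity
        query_id = query_id if query_id is not None else query.spectrum_id
    else:
        member = next(iter(query.values()))
        precursor_mz = precursor_mz if precursor_mz is not None else member.precursor_mz
        polarity = polarity if polarity is not None else member.polarity
        query_id = query_id if query_id is not None else member.spectrum_id
    candidates = search_by_precursor(library, precursor_mz, polarity, tol_ppm=tol_ppm)
    if not candidates:
        return RankedSet(query_id=query_id, candidates=[], known_id=known_id)
    results = [
        multi_energy_score(query, library.predicted.get(rec.compound_id), tol_da=tol_da)
        for rec in candidates
    ]
    # Candidates without predicted spectra come back with an empty id; bind them.
    for res, rec in zip(results, candidates):
        if not res.compound_id:
            res.compound_id = rec.compound_id
    scores = score_candidates(results, candidates)
    rank_all_schemes(scores)
    return RankedSet(query_id=query_id, candidates=scores, known_id=known_id)


def run_benchmark(
    benchmark: Benchmark,
    tol_ppm: float = 10.0,
    tol_da: float = DEFAULT_TOL_DA,
    paired: bool = False,
) -> list[RankedSet]:
    """Rank every benchmark query against the benchmark library."""
    out = []
    for q in benchmark.queries:
        query: QueryInput = q.per_energy if paired else q.merged
        out.append(
            rank_query(
                benchmark.library,
                query,
                query_id=q.query_id,
                known_id=q.true_compound_id,
                precursor_mz=q.merged.precursor_mz,
                polarity=q.merged.polarity,
                tol_ppm=tol_ppm,
                tol_da=tol_da,
            )
        )
    return out


def evaluate_ranked_sets(
    ranked_sets: Sequence[RankedSet],
    dataset_id: str = "benchmark",
    cutoff: float = DEFAULT_QUOTIENT_CUTOFF,
) -> EvaluationSummary:
    """Summarise ranked sets into the top-k / score-distribution report."""
    return topk_table(ranked_sets, dataset_id=dataset_id, cutoff=cutoff)


def attach_truth(
    ranked_sets: Sequence[RankedSet], truth: Mapping[str, str]
) -> list[RankedSet]:
    """Fill ``known_id`` on ranked sets from a query_id -> compound_id map."""
    for rs in ranked_sets:
        if rs.query_id in truth:
            rs.known_id = truth[rs.query_id]
    return list(ranked_sets)
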