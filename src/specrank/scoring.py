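"""Peak matching and multi-energy cosine scoring.

The similarity between a query MS/MS spectrum and a predicted library
spectrum is the cosine dot product over matched peak pairs::

    score = sum_{(i,j) matched} w_q[i] * w_r[j] / (||w_q|| * ||w_r||)

with per-peak weights ``w = mz**mz_power * intensity**intensity_power`` and
the norms taken over ALL (non-zero-intensity) peaks of each spectrum, so
unmatched peaks on either side penalise the score.  The default weighting is
the plain cosine (``mz_power=0``, ``intensity_power=1``); the classic
Stein–Scott weighting (``mz_power=1``, ``intensity_power=0.5``) is available
through the exponent arguments.

Peak pairs are formed one-to-one within a fixed Da tolerance (default
0.02 Da) by a greedy pass over all in-tolerance pairs in ascending
|Δm/z| order.  Whenever the peaks of both spectra fall into tolerance
clusters of at most two members the greedy matching coincides with the
minimum-total-|Δm/z| assignment; in denser clusters it remains a maximal
matching (hence at least half the maximum possible number of pairs) and is
deterministic under any permutation of the input peak order.

Per-candidate scores at the three collision energies (10/20/40 eV) are
summed into a raw match score in [0, 3]; energies with no predicted
spectrum contribute zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

from .errors import DomainError, UndefinedScoreError
from .spectra import ENERGY_LEVELS, PredictedSpectrumSet, Spectrum

#: Default peak match tolerance in Da.
DEFAULT_TOL_DA = 0.02


@dataclass(frozen=True)
class PeakMatch:
    """One matched peak pair: indices into the sorted peak lists and their Δm/z."""

    query_index: int
    ref_index: int
    delta_mz: float


@dataclass
class MatchResult:
    """Scores of one candidate compound against a query.

    ``raw_score`` is the sum of the per-energy cosine scores and lies in
    [0, 3]; absent energies contribute 0.  ``no_predicted_data`` marks
    candidates that could not be spectrally scored (no predicted spectra);
    they keep a raw score of 0 but remain in the candidate set so that
    within-set normalisation sees the full set composition.
    """

    compound_id: str
    per_energy_score: dict[int, float] = field(default_factory=dict)
    raw_score: float = 0.0
    n_matched: dict[int, int] = field(default_factory=dict)
    no_predicted_data: bool = False


def _greedy_pairs(
    mz_q: np.ndarray, mz_r: np.ndarray, tol_da: float
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one pairing of two ascending m/z arrays within tol_da.

    All in-tolerance (i, j) pairs are ranked by (|Δ|, i, j) and accepted
    greedily, skipping peaks already used.  Deterministic given the inputs.
    """
    pairs: list[tuple[float, int, int]] = []
    j0 = 0
    nr = len(mz_r)
    for i, m in enumerate(mz_q):
        while j0 < nr and mz_r[j0] < m - tol_da:
            j0 += 1
        j = j0
        while j < nr and mz_r[j] <= m + tol_da:
            pairs.append((abs(mz_r[j] - m), i, j))
            j += 1
    pairs.sort()
    used_q: set[int] = set()
    used_r: set[int] = set()
    out: list[tuple[int, int, float]] = []
    for delta, i, j in pairs:
        if i in used_q or j in used_r:
            continue
        used_q.add(i)
        used_r.add(j)
        out.append((i, j, mz_r[j] - mz_q[i]))
    out.sort()
    return out


def match_peaks(
    query: Spectrum, reference: Spectrum, tol_da: float = DEFAULT_TOL_DA
) -> list[PeakMatch]:
    """One-to-one peak matching between two spectra at a Da tolerance.

    Returns matches as indices into the (ascending-m/z) peak lists, sorted by
    query index.  Each peak on either side appears in at most one pair and
    every pair satisfies ``|delta_mz| <= tol_da``.
    """
    if not tol_da > 0:
        raise DomainError("tol_da must be positive")
    return [
        PeakMatch(i, j, d)
        for i, j, d in _greedy_pairs(query.mz, reference.mz, tol_da)
    ]


def _weights(
    mz: np.ndarray, intensity: np.ndarray, mz_power: float, intensity_power: float
) -> np.ndarray:
    w = intensity**intensity_power
    if mz_power != 0:
        w = w * mz**mz_power
    return w


def cosine_score(
    query: Spectrum,
    reference: Spectrum,
    tol_da: float = DEFAULT_TOL_DA,
    mz_power: float = 0.0,
    intensity_power: float = 1.0,
) -> float:
    """Cosine dot-product similarity of two spectra in [0, 1].

    Zero-intensity peaks are removed before weighting and matching (they are
    retained by the parsers for losslessness but carry no signal).  The norms
    run over all remaining peaks of each spectrum, so the score reaches 1
    only when every peak of both spectra is matched with proportional
    weights.

    Raises
    ------
    UndefinedScoreError
        If either spectrum has no peak with positive intensity.
    """
    if not tol_da > 0:
        raise DomainError("tol_da must be positive")
    out = []
    for s in (query, reference):
        mz, inten = s.mz, s.intensity
        keep = inten > 0
        if not keep.any():
            raise UndefinedScoreError(
                f"spectrum {s.spectrum_id!r}: all intensities are zero; "
                "cosine score undefined"
            )
        out.append((mz[keep], inten[keep]))
    (mz_q, int_q), (mz_r, int_r) = out
    w_q = _weights(mz_q, int_q, mz_power, intensity_power)
    w_r = _weights(mz_r, int_r, mz_power, intensity_power)
    pairs = _greedy_pairs(mz_q, mz_r, tol_da)
    if pairs:
        iq = np.array([p[0] for p in pairs], dtype=int)
        jr = np.array([p[1] for p in pairs], dtype=int)
        dot = float(np.dot(np.ascontiguousarray(w_q[iq]), np.ascontiguousarray(w_r[jr])))
    else:
        dot = 0.0
    denom = math.sqrt(float(np.dot(w_q, w_q)) * float(np.dot(w_r, w_r)))
    score = dot / denom
    return min(1.0, max(0.0, score))


QueryInput = Union[Spectrum, Mapping[int, Spectrum]]


def multi_energy_score(
    query: QueryInput,
    predicted: PredictedSpectrumSet | None,
    tol_da: float = DEFAULT_TOL_DA,
    mz_power: float = 0.0,
    intensity_power: float = 1.0,
) -> MatchResult:
    """Raw match score of one candidate: cosine scores summed over energies.

    Two query modes are supported:

    * merged (default in the pipeline): ``query`` is a single
      :class:`Spectrum` (one challenge-style file per acquisition) and is
      scored against each available predicted energy;
    * paired: ``query`` is a mapping energy -> Spectrum and each query
      energy is scored only against the matching predicted energy.

    Energies absent on either side contribute 0, so the raw score lies in
    [0, 3].  A candidate with no predicted spectra returns raw 0 with
    ``no_predicted_data`` set.
    """
    if predicted is None or len(predicted) == 0:
        cid = predicted.compound_id if predicted is not None else ""
        return MatchResult(cid, {}, 0.0, {}, no_predicted_data=True)
    per_energy: dict[int, float] = {}
    n_matched: dict[int, int] = {}
    merged = isinstance(query, Spectrum)
    for energy in ENERGY_LEVELS:
        ref = predicted.spectra.get(energy)
        if ref is None:
            continue
        q = query if merged else query.get(energy)
        if q is None:
            continue
        per_energy[energy] = cosine_score(
            q, ref, tol_da=tol_da, mz_power=mz_power, intensity_power=intensity_power
        )
        n_matched[energy] = len(match_peaks(q, ref, tol_da=tol_da))
    return MatchResult(
        predicted.compound_id,
        per_energy,
        float(sum(per_energy.values())),
        n_matched,
        no_predicted_data=False,
    )
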