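"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from specrank import (
    CompoundRecord,
    Peak,
    PredictedSpectrumSet,
    Spectrum,
    build_library,
)

BIG = 1.0e9  # penalty for out-of-tolerance pairs in the assignment oracle


def random_spectrum(
    rng: np.random.Generator,
    n_peaks: int | None = None,
    spectrum_id: str = "rand",
    mz_range: tuple[float, float] = (50.0, 500.0),
    collision_energy: float | None = None,
) -> Spectrum:
    if n_peaks is None:
        n_peaks = int(rng.integers(1, 12))
    mz = rng.uniform(*mz_range, size=n_peaks)
    intensity = rng.uniform(0.0, 100.0, size=n_peaks)
    return Spectrum(
        spectrum_id,
        float(rng.uniform(mz_range[1], mz_range[1] + 100)),
        "positive" if rng.random() < 0.5 else "negative",
        tuple(Peak(float(m), float(i)) for m, i in zip(mz, intensity)),
        collision_energy,
    )


def assignment_oracle(
    mz_q: np.ndarray, mz_r: np.ndarray, tol: float
) -> list[tuple[int, int]]:
    """Maximum-cardinality, minimum-total-|Δm/z| one-to-one matching.

    Brute force via the Hungarian algorithm on the |Δ| cost matrix with a
    large penalty on out-of-tolerance pairs, then stripping penalised pairs.
    Independent of the greedy implementation under test.
    """
    if len(mz_q) == 0 or len(mz_r) == 0:
        return []
    delta = np.abs(mz_q[:, None] - mz_r[None, :])
    cost = np.where(delta <= tol, delta, BIG)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if cost[i, j] < BIG]


def tolerance_clusters(mz_q: np.ndarray, mz_r: np.ndarray, tol: float) -> list[int]:
    """Sizes of connected components of the pooled peaks linked at gap <= tol."""
    pooled = np.sort(np.concatenate([mz_q, mz_r]))
    if len(pooled) == 0:
        return []
    sizes, current = [], 1
    for prev, nxt in zip(pooled[:-1], pooled[1:]):
        if nxt - prev <= tol:
            current += 1
        else:
            sizes.append(current)
            current = 1
    sizes.append(current)
    return sizes


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


@pytest.fixture
def tiny_library():
    """Three compounds, two with predicted spectra, one metadata-only."""

    def spec(cid, energy, pairs, precursor):
        return Spectrum(
            f"{cid}_e{energy}",
            precursor,
            "positive",
            tuple(Peak(*p) for p in pairs),
            energy,
        )

    records = [
        CompoundRecord("CMP_A", 180.063388, inchikey="AAAAAAAAAAAAAA-BBBBBBBBSA-N", ds_count=40),
        CompoundRecord("CMP_B", 180.063988, inchikey="AAAAAAAAAAAAAA-CCCCCCCCSA-N", ds_count=5),
        CompoundRecord("CMP_C", 300.100000, inchikey="DDDDDDDDDDDDDD-EEEEEEEESA-N", ds_count=900),
    ]
    predicted = [
        (
            "CMP_A",
            PredictedSpectrumSet(
                "CMP_A",
                {
                    10: spec("CMP_A", 10, [(181.070664, 100.0), (91.05, 10.0)], 181.070664),
                    20: spec("CMP_A", 20, [(181.070664, 45.0), (91.05, 100.0)], 181.070664),
                    40: spec("CMP_A", 40, [(91.05, 100.0), (55.02, 80.0)], 181.070664),
                },
            ),
        ),
        (
            "CMP_B",
            PredictedSpectrumSet(
                "CMP_B",
                {20: spec("CMP_B", 20, [(181.071264, 100.0), (120.08, 30.0)], 181.071264)},
            ),
        ),
    ]
    return build_library(records, predicted)
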