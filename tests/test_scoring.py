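"""Peak matching and cosine scoring against independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from specrank import (
    Peak,
    PredictedSpectrumSet,
    Spectrum,
    cosine_score,
    match_peaks,
    multi_energy_score,
)
from specrank.errors import UndefinedScoreError

from conftest import assignment_oracle, random_spectrum, tolerance_clusters


def spec(pairs, precursor=500.0, sid="s", energy=None):
    return Spectrum(sid, precursor, "positive", tuple(Peak(*p) for p in pairs), energy)


class TestMatchPeaks:
    def test_identical_lists_fully_matched_with_zero_delta(self):
        s = spec([(100.0, 1.0), (150.0, 2.0), (200.0, 3.0)])
        matches = match_peaks(s, s)
        assert [(m.query_index, m.ref_index, m.delta_mz) for m in matches] == [
            (0, 0, 0.0),
            (1, 1, 0.0),
            (2, 2, 0.0),
        ]

    def test_all_gaps_beyond_tolerance_gives_no_matches(self):
        q = spec([(100.0, 1.0), (200.0, 1.0)])
        r = spec([(100.5, 1.0), (199.0, 1.0)])
        assert match_peaks(q, r, tol_da=0.02) == []

    def test_smaller_delta_wins_contested_reference_peak(self):
        """query {100.00, 100.015} vs ref {100.01}: the 0.005 Da pair beats 0.01."""
        q = spec([(100.00, 1.0), (100.015, 1.0)])
        r = spec([(100.01, 1.0)])
        matches = match_peaks(q, r, tol_da=0.02)
        assert len(matches) == 1
        assert matches[0].query_index == 1 and matches[0].ref_index == 0
        assert matches[0].delta_mz == pytest.approx(-0.005)

    def test_greedy_equals_assignment_oracle_on_sparse_clusters(self, rng):
        """Where tolerance clusters hold <=2 peaks the matching is forced and
        must equal the minimum-total-|delta| assignment; everywhere it must be
        a valid maximal matching with at least half the oracle's pairs."""
        tol = 0.02
        checked_exact = 0
        for _ in range(300):
            nq, nr = rng.integers(1, 5, size=2)
            mz_q = np.sort(rng.uniform(100, 100.2, size=nq))
            mz_r = np.sort(rng.uniform(100, 100.2, size=nr))
            q = spec([(m, 1.0) for m in mz_q])
            r = spec([(m, 1.0) for m in mz_r])
            got = {(m.query_index, m.ref_index) for m in match_peaks(q, r, tol_da=tol)}
            oracle = set(assignment_oracle(mz_q, mz_r, tol))
            for i, j in got:
                assert abs(mz_q[i] - mz_r[j]) <= tol
            assert len({i for i, _ in got}) == len(got)
            assert len({j for _, j in got}) == len(got)
            assert 2 * len(got) >= len(oracle)
            if max(tolerance_clusters(mz_q, mz_r, tol)) <= 2:
                assert got == oracle
                checked_exact += 1
        assert checked_exact > 20  # the sparse regime was actually exercised


class TestCosineScore:
    def test_hand_computed_worked_example(self):
        """Two matched pairs at 0.02 Da; unmatched 200 Da peak penalises the norm."""
        q = spec([(100.0, 50.0), (150.0, 100.0)])
        r = spec([(100.01, 60.0), (150.005, 90.0), (200.0, 10.0)])
        expected = (50 * 60 + 100 * 90) / math.sqrt(
            (50**2 + 100**2) * (60**2 + 90**2 + 10**2)
        )
        assert abs(cosine_score(q, r, tol_da=0.02) - expected) <= 1e-12

    def test_spectrum_against_itself_scores_exactly_one(self, rng):
        for i in range(20):
            s = random_spectrum(rng, spectrum_id=f"s{i}")
            if not (s.intensity > 0).any():
                continue
            assert cosine_score(s, s) == 1.0

    def test_disjoint_spectra_score_zero(self):
        q = spec([(100.0, 50.0), (150.0, 100.0)])
        r = spec([(120.0, 60.0), (170.0, 90.0)])
        assert cosine_score(q, r, tol_da=0.02) == 0.0

    def test_invariant_to_uniform_intensity_scaling(self, rng):
        q = random_spectrum(rng, spectrum_id="q")
        r = random_spectrum(rng, spectrum_id="r", mz_range=(50.0, 505.0))
        scaled = Spectrum(
            "q7", q.precursor_mz, q.polarity,
            tuple(Peak(p.mz, p.intensity * 7.3) for p in q.peaks),
        )
        assert cosine_score(scaled, r) == pytest.approx(cosine_score(q, r), abs=1e-12)

    def test_invariant_to_peak_input_order(self, rng):
        pairs = [(float(m), float(i)) for m, i in
                 zip(rng.uniform(100, 200, 8), rng.uniform(1, 100, 8))]
        r = random_spectrum(rng, spectrum_id="r")
        baseline = cosine_score(spec(pairs), r)
        for _ in range(5):
            rng.shuffle(pairs)
            assert cosine_score(spec(pairs), r) == baseline

    def test_zero_intensity_peaks_excluded_from_scoring(self):
        q = spec([(100.0, 50.0), (150.0, 100.0)])
        q_padded = spec([(100.0, 50.0), (150.0, 100.0), (180.0, 0.0)])
        r = spec([(100.0, 60.0), (150.0, 90.0)])
        assert cosine_score(q_padded, r) == cosine_score(q, r)

    def test_all_zero_intensities_undefined(self):
        q = spec([(100.0, 0.0)])
        r = spec([(100.0, 1.0)])
        with pytest.raises(UndefinedScoreError):
            cosine_score(q, r)

    def test_scores_bounded_on_random_pairs(self, rng):
        for _ in range(100):
            q = random_spectrum(rng, spectrum_id="q", mz_range=(100, 100.5))
            r = random_spectrum(rng, spectrum_id="r", mz_range=(100, 100.5))
            if not (q.intensity > 0).any() or not (r.intensity > 0).any():
                continue
            assert 0.0 <= cosine_score(q, r) <= 1.0

    def test_agrees_with_matchms_on_well_separated_peaks(self, rng):
        """Independent cross-check: matchms CosineGreedy on spectra whose peaks
        have at most one in-tolerance partner (matching then unambiguous)."""
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import CosineGreedy

        for power_pair in [(0.0, 1.0), (1.0, 0.5)]:
            mz_power, intensity_power = power_pair
            for k in range(10):
                base = np.sort(rng.uniform(100, 400, size=8))
                base = base[np.diff(np.concatenate([[0], base])) > 1.0]  # >1 Da apart
                shift = rng.uniform(-0.015, 0.015, size=len(base))
                int_q = rng.uniform(1, 100, size=len(base))
                int_r = rng.uniform(1, 100, size=len(base))
                q = spec([(m, i) for m, i in zip(base, int_q)])
                r = spec([(m + s, i) for m, s, i in zip(base, shift, int_r)])
                ours = cosine_score(q, r, tol_da=0.02,
                                    mz_power=mz_power, intensity_power=intensity_power)
                mq = matchms.Spectrum(mz=q.mz, intensities=q.intensity,
                                      metadata={"precursor_mz": 500.0})
                mr = matchms.Spectrum(mz=r.mz, intensities=r.intensity,
                                      metadata={"precursor_mz": 500.0})
                sim = CosineGreedy(tolerance=0.02, mz_power=mz_power,
                                   intensity_power=intensity_power)
                theirs = float(sim.pair(mq, mr)["score"])
                assert ours == pytest.approx(theirs, abs=1e-9)


class TestMultiEnergyScore:
    def _pset(self, spectra):
        return PredictedSpectrumSet("CMP", spectra)

    def test_identical_query_at_all_three_energies_sums_to_three(self):
        s = spec([(100.0, 50.0), (150.0, 100.0)], sid="p")
        pset = self._pset({e: spec([(100.0, 50.0), (150.0, 100.0)],
                                   sid=f"p{e}", energy=e) for e in (10, 20, 40)})
        result = multi_energy_score(s, pset)
        assert result.raw_score == pytest.approx(3.0, abs=1e-12)
        assert set(result.per_energy_score) == {10, 20, 40}

    def test_single_energy_identity_scores_one(self):
        s = spec([(100.0, 50.0)])
        pset = self._pset({20: spec([(100.0, 50.0)], energy=20)})
        result = multi_energy_score(s, pset)
        assert result.raw_score == pytest.approx(1.0, abs=1e-12)
        assert result.per_energy_score.keys() == {20}

    def test_missing_predicted_data_flagged_with_zero_score(self):
        s = spec([(100.0, 50.0)])
        result = multi_energy_score(s, None)
        assert result.raw_score == 0.0 and result.no_predicted_data
        result = multi_energy_score(s, PredictedSpectrumSet("CMP", {}))
        assert result.raw_score == 0.0 and result.no_predicted_data

    def test_merged_raw_equals_sum_of_per_energy_cosines(self, tiny_library):
        pset = tiny_library.predicted["CMP_A"]
        query = spec([(181.070664, 45.0), (91.05, 100.0)], precursor=181.070664)
        result = multi_energy_score(query, pset)
        expected = sum(cosine_score(query, pset.spectra[e]) for e in (10, 20, 40))
        assert result.raw_score == pytest.approx(expected, abs=1e-12)
        assert result.per_energy_score[20] == pytest.approx(1.0, abs=1e-12)

    def test_paired_mode_scores_matching_energies_only(self):
        q20 = spec([(100.0, 50.0)], energy=20)
        pset = self._pset(
            {
                20: spec([(100.0, 50.0)], energy=20),
                40: spec([(60.0, 80.0)], energy=40),
            }
        )
        result = multi_energy_score({20: q20}, pset)
        assert result.per_energy_score == {20: 1.0}
        assert result.raw_score == 1.0

    def test_raw_score_bounded_by_three_on_random_inputs(self, rng):
        for _ in range(50):
            pset = self._pset(
                {e: random_spectrum(rng, spectrum_id=f"p{e}", collision_energy=e)
                 for e in (10, 20, 40)}
            )
            q = random_spectrum(rng, spectrum_id="q")
            if not (q.intensity > 0).any():
                continue
            result = multi_energy_score(q, pset)
            assert 0.0 <= result.raw_score <= 3.0
            assert result.raw_score == pytest.approx(
                sum(result.per_energy_score.values()), abs=1e-12
            )
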