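"""Water density, trial selection, Archimedes inversion and the fat transform."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hydrodensity.densitometry import (
    Condition,
    DensityComputationError,
    ProtocolConfig,
    TrialQuality,
    body_density,
    compute_participant,
    density_from_pbf,
    percent_body_fat,
    select_consistent_trials,
    select_sample_window,
    water_density,
)
from hydrodensity.participants import Participant


def oracle_consistent_subset(weights, tolerance=0.100):
    """From-definition search: best triple, else best pair, naive loops."""
    for size in (3, 2):
        best, best_range = None, None
        for idx in itertools.combinations(range(len(weights)), size):
            vals = [weights[i] for i in idx]
            r = max(vals) - min(vals)
            if r <= tolerance and (best_range is None or r < best_range):
                best, best_range = idx, r
        if best is not None:
            return best, sum(weights[i] for i in best) / size, size
    return None


class TestWaterDensity:
    def test_maximum_near_four_degrees(self):
        assert water_density(4.0) == pytest.approx(1.0000, abs=5e-4)
        assert water_density(4.0) > water_density(10.0)

    def test_tank_temperature_band(self):
        assert 0.9940 < water_density(33.0) < 0.9950

    def test_monotone_decreasing_over_tank_range(self):
        temps = np.linspace(4.0, 39.5, 40)
        dens = [water_density(float(t)) for t in temps]
        assert all(a > b for a, b in zip(dens, dens[1:]))

    @pytest.mark.parametrize("t", [-1.0, 0.0, 40.0, 55.0])
    def test_out_of_range_raises(self, t):
        with pytest.raises(ValueError):
            water_density(t)


class TestSampleWindow:
    def test_constant_stream_returns_its_value(self):
        res = select_sample_window([3.5] * 150)
        assert res.mean_kg == pytest.approx(3.5, abs=1e-12)
        assert 98 <= res.length <= 102

    def test_window_avoids_the_noisy_tail(self):
        stream = [3.5] * 100 + [3.3, 3.7] * 25
        res = select_sample_window(stream)
        assert res.start + res.length <= 100
        assert res.mean_kg == pytest.approx(3.5, abs=1e-12)

    def test_short_stream_raises(self):
        with pytest.raises(ValueError):
            select_sample_window([3.5] * 97)

    def test_matches_brute_force_on_random_streams(self, rng):
        for _ in range(25):
            n = int(rng.integers(12, 30))
            stream = rng.normal(3.5, 0.05, n)
            res = select_sample_window(stream, target_n=10, slack=2)
            # naive O(n^2) search with the same tie-break (longer, earlier)
            best = None
            for length in range(min(12, n), 7, -1):
                for start in range(n - length + 1):
                    sd = float(np.std(stream[start : start + length]))
                    if best is None or sd < best[0]:
                        best = (sd, start, length)
            assert (res.start, res.length) == (best[1], best[2])


class TestTrialSelection:
    @pytest.mark.parametrize(
        "weights,indices,mean,quality",
        [
            ([3.50, 3.62, 3.55, 3.58], (1, 2, 3), 3.5833333333, TrialQuality.TRIPLE),
            ([3.5, 3.5, 3.5], (0, 1, 2), 3.5, TrialQuality.TRIPLE),
            ([3.50, 3.58, 3.90], (0, 1), 3.54, TrialQuality.PAIR),
        ],
    )
    def test_tightest_subset_selected(self, weights, indices, mean, quality):
        sel = select_consistent_trials(weights)
        assert sel.indices == indices
        assert sel.quality is quality
        assert sel.mean_kg == pytest.approx(mean, abs=1e-9)

    def test_inconsistent_weights_yield_no_mean(self):
        sel = select_consistent_trials([3.0, 3.2, 3.4])
        assert sel.quality is TrialQuality.NONE
        assert sel.mean_kg is None and sel.indices == ()

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            select_consistent_trials([])

    @given(
        st.lists(
            st.sampled_from([3.00, 3.04, 3.08, 3.15, 3.30]), min_size=1, max_size=7
        )
    )
    def test_matches_from_definition_oracle(self, weights):
        sel = select_consistent_trials(weights)
        oracle = oracle_consistent_subset(weights)
        if oracle is None:
            assert sel.quality is TrialQuality.NONE
        else:
            idx, mean, size = oracle
            assert sel.mean_kg == pytest.approx(mean, abs=1e-12)
            assert len(sel.indices) == size


class TestBodyDensity:
    def test_hand_substitution_head_below_at_rv(self):
        db = body_density(Condition.HBW_RV, ma_kg=80, mw_kg=3.0, dw_kg_l=1.0, lung_volume_l=1.7)
        assert db == pytest.approx(80 / 75.2, abs=1e-9)

    def test_head_position_algebraic_cancellation(self):
        """Shifting MW by DW*HV and adding HV back gives the same density."""
        ma, dw, lung, hv = 78.0, 0.9947, 6.8, 4.2
        mw_hbw = 1.3
        db_hbw = body_density(Condition.HBW_TLC, ma, mw_hbw, dw, lung)
        db_haw = body_density(Condition.HAW_TLC, ma, mw_hbw + dw * hv, dw, lung, hv_pred_l=hv)
        assert db_haw == pytest.approx(db_hbw, abs=1e-12)

    def test_non_positive_volume_budget_names_offenders(self):
        with pytest.raises(DensityComputationError, match="lung"):
            body_density(Condition.HAW_TLC, 80, 79.9, 1.0, 7.0, hv_pred_l=4.0)

    def test_head_volume_contract_per_condition(self):
        with pytest.raises(ValueError, match="requires a predicted head volume"):
            body_density(Condition.HAW_TLC, 80, 3.0, 1.0, 6.0)
        with pytest.raises(ValueError, match="must not be given"):
            body_density(Condition.HBW_RV, 80, 3.0, 1.0, 1.7, hv_pred_l=4.0)

    def test_in_water_mass_must_be_below_dry_mass(self):
        with pytest.raises(ValueError, match="below dry mass"):
            body_density(Condition.HBW_RV, 80, 80.0, 1.0, 1.7)

    @given(
        st.floats(min_value=0.98, max_value=1.15),
        st.floats(min_value=45, max_value=150),
        st.floats(min_value=1.0, max_value=8.0),
        st.floats(min_value=2.0, max_value=7.0),
        st.floats(min_value=0.992, max_value=1.0),
    )
    def test_forward_inverse_identity(self, db_true, ma, lung, hv, dw):
        """Simulating the in-water mass by Archimedes and inverting recovers
        the true density, for both head positions."""
        vb = ma / db_true
        mw_hbw = ma - dw * (vb + lung + 0.1)
        assert body_density(Condition.HBW_TLC, ma, mw_hbw, dw, lung) == pytest.approx(
            db_true, abs=1e-9
        )
        mw_haw = ma - dw * (vb - hv + lung + 0.1)
        assert body_density(
            Condition.HAW_TLC, ma, mw_haw, dw, lung, hv_pred_l=hv
        ) == pytest.approx(db_true, abs=1e-9)

    def test_monotone_in_weight_and_lung_volume(self):
        base = body_density(Condition.HBW_RV, 80, 3.0, 0.995, 1.7)
        assert body_density(Condition.HBW_RV, 80, 3.5, 0.995, 1.7) > base
        assert body_density(Condition.HBW_RV, 80, 3.0, 0.995, 2.2) > base
        assert percent_body_fat(body_density(Condition.HBW_RV, 80, 3.5, 0.995, 1.7)) < percent_body_fat(base)


class TestPercentBodyFat:
    @pytest.mark.parametrize(
        "db,expected",
        [(4.570 / 4.142, 0.0), (80 / 75.2, 15.380), (1.0, 42.800)],
    )
    def test_brozek_hand_values(self, db, expected):
        assert percent_body_fat(db) == pytest.approx(expected, abs=1e-9)

    @given(st.floats(min_value=0.9, max_value=1.2))
    def test_round_trip_with_inverse(self, db):
        assert density_from_pbf(percent_body_fat(db)) == pytest.approx(db, abs=1e-12)

    def test_non_positive_density_raises(self):
        with pytest.raises(ValueError):
            percent_body_fat(0.0)


class TestComputeParticipant:
    @pytest.fixture
    def participant(self):
        return Participant("P1", "male", age_yr=25.0, height_cm=180.0, mass_kg=90.6)

    @pytest.fixture
    def girths(self):
        return {"HG": [583, 585], "FG": [677, 677]}

    def test_hand_composed_chain(self, participant, girths):
        """The end-to-end result equals the hand-chained worked examples."""
        config = ProtocolConfig(water_temp_c=33.0)
        dw = water_density(33.0)
        trials = {Condition.HBW_RV: [3.00, 3.02, 3.04]}
        (res,) = compute_participant(participant, girths, trials, config)
        rv = 1.676  # male, 1.80 m, 25 yr
        expected_db = 90.6 / ((90.6 - 3.02) / dw - rv - 0.1)
        assert res.db_kg_l == pytest.approx(expected_db, abs=1e-12)
        assert res.pbf_pct == pytest.approx(percent_body_fat(expected_db), abs=1e-12)
        assert res.quality is TrialQuality.TRIPLE

    def test_head_above_water_uses_qc_girths(self, participant, girths):
        trials = {Condition.HAW_TLC: [7.0, 7.02, 7.04]}
        (res,) = compute_participant(participant, girths, trials)
        # HG qc mean 584 mm -> 58.4 cm; FG 67.7 cm
        hv = 0.1294 * 58.4 + 0.0299 * 67.7 + 0.0055 * 90.6 - 5.7506
        assert res.hv_pred_l == pytest.approx(hv, abs=1e-12)

    def test_inconsistent_condition_is_omitted(self, participant, girths):
        trials = {
            Condition.HBW_RV: [3.00, 3.02, 3.04],
            Condition.HBW_TLC: [6.0, 6.3, 6.6],  # no subset within 100 g
        }
        results = compute_participant(participant, girths, trials)
        assert [r.condition for r in results] == [Condition.HBW_RV]

    def test_pair_quality_kept_by_default_dropped_in_strict(self, participant, girths):
        trials = {Condition.HBW_RV: [3.00, 3.05, 3.40]}
        (res,) = compute_participant(participant, girths, trials)
        assert res.quality is TrialQuality.PAIR
        strict = ProtocolConfig(include_pairs=False)
        assert compute_participant(participant, girths, trials, strict) == []

    def test_stage_errors_carry_participant_context(self, participant):
        trials = {Condition.HAW_TLC: [7.0, 7.0, 7.0]}
        with pytest.raises(ValueError, match="participant P1"):
            compute_participant(participant, {"HG": [583, 585]}, trials)

    def test_trial_cap_enforced(self, participant, girths):
        trials = {Condition.HBW_RV: [3.0] * 6}
        with pytest.raises(ValueError, match="cap"):
            compute_participant(participant, girths, trials)

    def test_belt_correction_shifts_tlc_conditions_only(self, participant, girths):
        trials = {
            Condition.HBW_TLC: [6.0, 6.0, 6.0],
            Condition.HBW_RV: [3.0, 3.0, 3.0],
        }
        plain = {r.condition: r for r in compute_participant(participant, girths, trials)}
        corrected = {
            r.condition: r
            for r in compute_participant(
                participant, girths, trials, ProtocolConfig(belt_correction=True)
            )
        }
        assert corrected[Condition.HBW_TLC].mw_kg < plain[Condition.HBW_TLC].mw_kg
        assert corrected[Condition.HBW_RV].mw_kg == plain[Condition.HBW_RV].mw_kg
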