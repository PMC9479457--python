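"""Condition grid, listener profiles, and sequence-timing rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import streamseg as ss
from streamseg.paradigm import (
    AM_LEVELS,
    SPECTRAL_LEVELS,
    ConfigurationError,
    offset_onset_gaps,
    round_half_up,
    timing_to_rows,
)


class TestConditionGrid:
    def test_grid_has_18_unique_conditions(self):
        grid = ss.build_condition_grid()
        assert len(grid) == 18
        assert len(set(grid)) == 18

    def test_grid_membership(self):
        grid = ss.build_condition_grid()
        assert grid.count(ss.Condition(9, "large", "AM0-0")) == 1
        # one unmodulated 3-pair condition per spectral level
        n = sum(1 for c in grid if c.n_pairs == 3 and c.am_sep == "AM0-0")
        assert n == 3

    def test_invalid_levels_rejected(self):
        with pytest.raises(ConfigurationError):
            ss.Condition(5, "large", "AM0-0")
        with pytest.raises(ConfigurationError):
            ss.Condition(9, "huge", "AM0-0")


class TestProfiles:
    def test_nh_band_table(self, nh_profile):
        expected_a = {"none": 1803, "moderate": 3022, "large": 6665}
        for level, a_cf in expected_a.items():
            row = nh_profile.band_table[level]
            assert row["b_cf"] == 1803
            assert row["a_cf"] == a_cf

    def test_ci2_matches_clinical_map(self, ci2_profile):
        mod = ci2_profile.band_table["moderate"]
        assert (mod["a_cf"], mod["a_electrode"]) == (2871, 8)
        assert (mod["b_cf"], mod["b_electrode"]) == (1683, 12)
        large = ci2_profile.band_table["large"]
        assert (large["a_cf"], large["a_electrode"]) == (6485, 2)

    def test_all_profiles_load(self):
        profiles = ss.load_profiles()
        assert set(profiles) == {"NH", "CI1", "CI2", "CI3", "CI4", "CI5", "CI6"}
        groups = {p.group for p in profiles.values()}
        assert groups == {"NH", "CI"}

    def test_unknown_profile_errors(self):
        with pytest.raises(ConfigurationError):
            ss.get_profile("CI99")


class TestBandSpecs:
    def test_nh_large_am300(self, nh_profile):
        a, b = ss.band_specs_for(nh_profile, "large", "AM300-50")
        assert (a.center_freq, a.bandwidth, a.am_rate) == (6665, 216, 300)
        assert (b.center_freq, b.bandwidth, b.am_rate) == (1803, 162, 50)
        assert b.level == 60

    def test_control_condition_identical_bands(self, nh_profile):
        a, b = ss.band_specs_for(nh_profile, "none", "AM0-0")
        assert a == b
        assert a.am_rate == 0

    def test_ci2_moderate(self, ci2_profile):
        a, b = ss.band_specs_for(ci2_profile, "moderate", "AM200-50")
        assert a.center_freq == 2871
        assert b.center_freq == 1683

    def test_unknown_level_errors(self, nh_profile):
        with pytest.raises(ConfigurationError):
            ss.band_specs_for(nh_profile, "extreme", "AM0-0")

    def test_invalid_band_spec(self):
        with pytest.raises(ValueError):
            ss.BandSpec(center_freq=-1, bandwidth=100)
        with pytest.raises(ValueError):
            ss.BandSpec(center_freq=100, bandwidth=200)


class TestSequenceTiming:
    def test_delayed_9pair_is_2325_ms(self, rng):
        t = ss.make_sequence_timing(ss.Condition(9, "large", "AM0-0"), "delayed", rng)
        assert ss.sequence_duration(t) == pytest.approx(2.325, abs=1e-12)
        final_b = t.events[-1]
        assert final_b.stream == "B"
        assert final_b.onset == pytest.approx(2245.0)

    def test_delayed_3pair_follows_timing_rules(self, rng):
        # the stated rules give 130 + 260*2 + 35 + 80 = 765 ms
        t = ss.make_sequence_timing(ss.Condition(3, "none", "AM0-0"), "delayed", rng)
        assert ss.sequence_duration(t) == pytest.approx(0.765)

    def test_no_delay_durations_within_advance_band(self, rng):
        c = ss.Condition(9, "large", "AM0-0")
        durs = [
            ss.sequence_duration(ss.make_sequence_timing(c, "no_delay", rng))
            for _ in range(500)
        ]
        assert all(2.28 <= d <= 2.29 for d in durs)

    @settings(max_examples=200, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1),
           n_pairs=st.sampled_from([3, 9]),
           trial_type=st.sampled_from(["delayed", "no_delay"]))
    def test_timing_invariants(self, seed, n_pairs, trial_type):
        """Alternation, grid positions, jitter bounds, and gap bounds hold
        for every seed."""
        rng = np.random.default_rng(seed)
        c = ss.Condition(n_pairs, "large", "AM0-0")
        t = ss.make_sequence_timing(c, trial_type, rng)
        assert len(t.events) == 2 * n_pairs
        streams = [e.stream for e in t.events]
        assert streams == ["A", "B"] * n_pairs
        assert t.events[0].onset == 0.0
        assert t.jitters[0] == 0.0
        assert all(abs(j) <= 40.0 for j in t.jitters)
        # non-final B bursts exactly on the 130 + 260k grid
        b_onsets = [e.onset for e in t.events if e.stream == "B"]
        for k, onset in enumerate(b_onsets[:-1]):
            assert onset == 130.0 + 260.0 * k
        if trial_type == "delayed":
            assert t.final_shift == 35.0
        else:
            assert -10.0 <= t.final_shift <= 0.0
        assert b_onsets[-1] == pytest.approx(130.0 + 260.0 * (n_pairs - 1) + t.final_shift)
        for g in offset_onset_gaps(t):
            assert 10.0 <= g <= 90.0

    def test_gap_bounds_are_tight(self, rng):
        """The jitter rule actually exercises the whole [10, 90] ms range."""
        c = ss.Condition(9, "large", "AM0-0")
        gaps = []
        for _ in range(3000):
            gaps.extend(offset_onset_gaps(ss.make_sequence_timing(c, "delayed", rng)))
        assert min(gaps) < 10.5
        assert max(gaps) > 89.5

    def test_max_jitter_gives_90ms_gap(self):
        """An A burst jittered +40 ms sits 90 ms after the preceding B."""
        c = ss.Condition(9, "large", "AM0-0")
        for seed in range(2000):
            t = ss.make_sequence_timing(c, "delayed", np.random.default_rng(seed))
            if any(j > 39.9 for j in t.jitters):
                gaps = offset_onset_gaps(t)
                assert max(gaps) > 89.9
                return
        pytest.fail("no near-maximal jitter drawn in 2000 sequences")

    def test_invalid_trial_type(self, rng):
        with pytest.raises(ValueError):
            ss.make_sequence_timing(ss.Condition(9, "none", "AM0-0"), "late", rng)

    def test_empty_timing_duration_errors(self):
        t = ss.SequenceTiming((), "delayed", (), 35.0)
        with pytest.raises(ValueError):
            ss.sequence_duration(t)

    def test_csv_rows(self, rng):
        t = ss.make_sequence_timing(ss.Condition(3, "none", "AM0-0"), "delayed", rng)
        rows = timing_to_rows(t)
        assert len(rows) == 6
        assert rows[0] == {"stream": "A", "onset_ms": 0.0, "duration_ms": 80.0,
                           "trial_type": "delayed"}


class TestOctaves:
    @pytest.mark.parametrize("f1,f2,expected", [
        (3022, 1803, 0.75),
        (6665, 1803, 1.89),
        (1803, 1803, 0.0),
        (7352, 1632, 2.17),
    ])
    def test_separations_match_quoted_values(self, f1, f2, expected):
        assert round_half_up(ss.octave_separation(f1, f2)) == expected

    def test_symmetry(self):
        assert ss.octave_separation(100, 400) == ss.octave_separation(400, 100) == 2.0

    def test_nonpositive_frequency_errors(self):
        with pytest.raises(ValueError):
            ss.octave_separation(0, 1000)


class TestConditionOrder:
    def test_36_slots_with_adjacent_repetitions(self, rng):
        order = ss.pseudorandom_condition_order(rng)
        assert len(order) == 36
        for i in range(0, 36, 2):
            assert order[i] == order[i + 1]
        assert len(set(order)) == 18

    def test_am_nested_within_duration_spectral_cells(self, rng):
        order = ss.pseudorandom_condition_order(rng)
        cells = [(c.n_pairs, c.spectral_sep) for c in order[::6]]
        assert len(set(cells)) == 6  # each cell's 3 AM conditions are contiguous

    def test_deterministic_under_seed(self):
        o1 = ss.pseudorandom_condition_order(np.random.default_rng(9))
        o2 = ss.pseudorandom_condition_order(np.random.default_rng(9))
        assert o1 == o2
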