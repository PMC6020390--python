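"""Per-ear metric rules: PTA, HFA, classification, SII, ear ranking."""

import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

from wfs_hearing.audiometry import (
    OCTAVE_FREQUENCIES,
    ConfigurationError,
    SiiConstants,
    Threshold,
    ValidationError,
    band_audibility,
    classify_hearing,
    compute_ear_metrics,
    hfa,
    pta,
    rank_ears,
    sii_unaided,
)

from conftest import make_ear, make_session

LEVELS = st.sampled_from([-10, -5, 0, 5, 10, 15, 20, 25, 40, 60, 85, 100])


class TestThreshold:
    def test_level_xor_no_response(self):
        with pytest.raises(ValidationError):
            Threshold(1000, level=20, no_response=True)
        with pytest.raises(ValidationError):
            Threshold(1000)

    @pytest.mark.parametrize("bad", [12, 7.5, -12, 125])
    def test_off_grid_or_out_of_range_level_rejected(self, bad):
        with pytest.raises(ValidationError):
            Threshold(1000, level=bad)

    def test_unsupported_frequency_rejected(self):
        with pytest.raises(ValidationError):
            Threshold(1234, level=20)


class TestPta:
    @pytest.mark.parametrize(
        "mids, expected",
        [((10, 10, 10), 10.0), ((20, 25, 30), 25.0), ((80, 85, 90), 85.0)],
    )
    def test_mean_of_speech_frequencies(self, mids, expected):
        ear = make_ear({250: 10, 500: mids[0], 1000: mids[1], 2000: mids[2],
                        4000: 10, 8000: 10})
        assert pta(ear) == pytest.approx(expected)

    def test_profound_flag_from_high_pta(self, constants):
        ear = make_ear({250: 80, 500: 80, 1000: 85, 2000: 90, 4000: 90, 8000: 95})
        metrics = compute_ear_metrics(ear, constants)
        assert metrics.pta == pytest.approx(85.0)
        assert metrics.profound and metrics.category == "hearing_loss"

    def test_missing_frequency_names_it(self):
        thresholds = {f: Threshold(f, level=10) for f in OCTAVE_FREQUENCIES}
        del thresholds[1000]
        with pytest.raises(ValidationError, match="1000"):
            make_ear({f: 10 for f in OCTAVE_FREQUENCIES if f != 1000})

    def test_no_response_substitutes_95(self):
        ear = make_ear({250: 10, 500: None, 1000: 10, 2000: 10, 4000: 10, 8000: 10})
        assert pta(ear) == pytest.approx((95 + 10 + 10) / 3)


class TestHfa:
    @pytest.mark.parametrize(
        "f4, f8, expected",
        [(40, 60, 50.0), (70, None, 82.5), (-5, -5, -5.0)],
    )
    def test_high_frequency_average(self, f4, f8, expected):
        ear = make_ear({250: 10, 500: 10, 1000: 10, 2000: 10, 4000: f4, 8000: f8})
        assert hfa(ear) == pytest.approx(expected)

    def test_no_response_at_4k_also_substituted(self):
        ear = make_ear({250: 10, 500: 10, 1000: 10, 2000: 10, 4000: None, 8000: 60})
        assert hfa(ear) == pytest.approx((95 + 60) / 2)


class TestClassification:
    def test_all_quiet_is_normal(self):
        assert classify_hearing(make_ear(10)) == ("normal", False)

    def test_single_high_frequency_loss_still_normal(self):
        # an isolated elevated 8 kHz threshold does not reach the
        # more-than-two-frequencies criterion
        ear = make_ear({250: 10, 500: 10, 1000: 10, 2000: 10, 4000: 10, 8000: 25})
        assert classify_hearing(ear) == ("normal", False)

    def test_three_elevated_frequencies_is_loss_despite_low_pta(self):
        ear = make_ear({250: 15, 500: 15, 1000: 15, 2000: 25, 4000: 25, 8000: 25})
        category, profound = classify_hearing(ear)
        assert category == "hearing_loss" and not profound
        assert pta(ear) < 20

    def test_invalid_flag_refuses_classification(self):
        with pytest.raises(ValidationError, match="refused"):
            classify_hearing(make_ear(10, invalid=True))

    def test_matches_brute_force_over_level_grid(self):
        """Exhaustive check against a naive reimplementation."""
        for levels in itertools.product((0, 15, 25, 85), repeat=6):
            ear = make_ear(levels)
            category, profound = classify_hearing(ear)
            mean3 = (levels[1] + levels[2] + levels[3]) / 3
            expect_loss = mean3 > 20 or sum(1 for x in levels if x > 20) >= 3
            assert category == ("hearing_loss" if expect_loss else "normal")
            assert profound == (mean3 >= 80)


class TestSii:
    @pytest.mark.parametrize("offset, expected", [(-15, 1.0), (15, 0.0), (0, 0.5)])
    def test_band_audibility_boundaries(self, constants, offset, expected):
        assert band_audibility(40.0 + offset, 40.0, constants) == pytest.approx(expected)

    def test_fully_audible_speech(self, constants):
        levels = {f: 5 * math.floor((lv - 15) / 5)
                  for f, lv in zip(constants.bands, constants.band_speech_level)}
        assert sii_unaided(make_ear(levels), constants) == pytest.approx(1.0)

    def test_no_response_everywhere_gives_zero(self, constants):
        assert sii_unaided(make_ear(None), constants) == pytest.approx(0.0)

    def test_thresholds_at_band_levels_give_half(self, constants):
        levels = dict(zip(constants.bands, constants.band_speech_level))
        assert sii_unaided(make_ear(levels), constants) == pytest.approx(0.5)

    def test_importance_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            SiiConstants(bands=(250, 500), importance=(0.6, 0.5),
                         band_speech_level=(45, 45))

    def test_full_audibility_at_minus_10(self):
        constants = SiiConstants(
            bands=OCTAVE_FREQUENCIES,
            importance=(1 / 6,) * 6,
            band_speech_level=(5.0, 9.0, 12.0, 20.0, 33.0, 47.0),
        )
        assert sii_unaided(make_ear(-10), constants) == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(levels=st.lists(LEVELS, min_size=6, max_size=6),
           band=st.integers(0, 5), bump=st.sampled_from([5, 10, 25]))
    def test_monotone_nonincreasing_in_each_threshold(self, constants, levels,
                                                      band, bump):
        base = dict(zip(OCTAVE_FREQUENCIES, levels))
        raised = dict(base)
        raised[OCTAVE_FREQUENCIES[band]] = min(120, base[OCTAVE_FREQUENCIES[band]] + bump)
        assert sii_unaided(make_ear(raised), constants) <= sii_unaided(
            make_ear(base), constants) + 1e-12

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(levels=st.lists(LEVELS, min_size=6, max_size=6), bump=st.sampled_from([5, 20]))
    def test_pta_hfa_nondecreasing_in_thresholds(self, levels, bump):
        base = dict(zip(OCTAVE_FREQUENCIES, levels))
        raised = {f: min(120, lv + bump) for f, lv in base.items()}
        assert pta(make_ear(raised)) >= pta(make_ear(base))
        assert hfa(make_ear(raised)) >= hfa(make_ear(base))


class TestRankEars:
    def test_lower_sii_is_worse(self, constants):
        session = make_session(
            {250: 60, 500: 60, 1000: 60, 2000: 60, 4000: 70, 8000: 70}, 10)
        worse, better = rank_ears(session, constants)
        assert worse.ear == "left" and better.ear == "right"

    def test_sii_tie_breaks_on_hfa(self, constants):
        # both ears inaudible in every band (SII 0) but different HFA
        left = {f: 100 for f in OCTAVE_FREQUENCIES}
        right = {**left, 4000: 90, 8000: 90}
        session = make_session(left, right)
        worse, _ = rank_ears(session, constants)
        assert worse.ear == "left"

    def test_full_tie_designates_left(self, constants):
        session = make_session(30, 30)
        worse, better = rank_ears(session, constants)
        assert worse.ear == "left" and better.ear == "right"

    def test_invalid_ear_blocks_ranking(self, constants):
        session = make_session(10, 10)
        session.right.invalid_flag = True
        with pytest.raises(ValidationError):
            rank_ears(session, constants)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(left=st.lists(LEVELS, min_size=6, max_size=6),
           right=st.lists(LEVELS, min_size=6, max_size=6))
    def test_antisymmetric_under_ear_swap(self, constants, left, right):
        s1 = make_session(left, right)
        s2 = make_session(right, left)
        w1, _ = rank_ears(s1, constants)
        w2, _ = rank_ears(s2, constants)

        def key(ear):
            return (-sii_unaided(ear, constants), hfa(ear), pta(ear))

        if key(s1.left) == key(s1.right):
            # metric tie (possibly different audiograms after clipping):
            # the left slot is designated worse on both orderings
            assert w1.ear == "left" and w2.ear == "left"
        else:
            # the same physical ear wins regardless of the side it sits on
            assert dict(
                (f, t.level) for f, t in w1.thresholds.items()
            ) == dict((f, t.level) for f, t in w2.thresholds.items())
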