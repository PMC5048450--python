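import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import renalmri as rm
from renalmri.study_stats import (
    PairedMeasurements,
    TimecourseMeasurements,
    bold_timecourse_test,
    cov_repeatability,
    correlate_adc_d,
    paired_test,
    percent_change,
)

from _oracles import wilcoxon_exact_two_sided_p


def pairs_from(values):
    return [PairedMeasurements(f"k{i}", "d", a, b) for i, (a, b) in enumerate(values)]


class TestCov:
    def test_identical_pairs_zero(self):
        assert cov_repeatability(pairs_from([(10, 10), (7, 7)])) == 0.0

    def test_single_pair_hand_value(self):
        # 100*sqrt((10/105)^2 / 2) ~ 6.734%
        cov = cov_repeatability(pairs_from([(100, 110)]))
        assert cov == pytest.approx(100 * np.sqrt((10 / 105) ** 2 / 2), rel=1e-12)
        assert cov == pytest.approx(6.734, abs=0.001)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        scale=st.floats(0.1, 100),
        values=st.lists(
            st.tuples(st.floats(1, 100), st.floats(1, 100)), min_size=1, max_size=8
        ),
    )
    def test_scale_and_swap_invariance(self, scale, values):
        base = cov_repeatability(pairs_from(values))
        scaled = cov_repeatability(pairs_from([(a * scale, b * scale) for a, b in values]))
        swapped = cov_repeatability(pairs_from([(b, a) for a, b in values]))
        assert scaled == pytest.approx(base, rel=1e-9)
        assert swapped == pytest.approx(base, rel=1e-9)

    def test_nonpositive_mean_dropped(self):
        with pytest.warns(UserWarning, match="non-positive mean"):
            cov = cov_repeatability(pairs_from([(10, 11), (-5, 5)]))
        assert cov == pytest.approx(cov_repeatability(pairs_from([(10, 11)])))
        with pytest.raises(ValueError, match="all pairs dropped"):
            with pytest.warns(UserWarning):
                cov_repeatability(pairs_from([(-5, 5)]))


class TestPairedTest:
    def test_all_equal_degenerate(self):
        res = paired_test(pairs_from([(5, 5), (7, 7), (9, 9)]))
        assert res.p_value == 1.0 and not res.significant
        assert "degenerate" in res.note

    def test_six_uniform_signs_exact_p(self):
        values = [(10, 11), (20, 22), (30, 33), (40, 44), (50, 55), (60, 66)]
        res = paired_test(pairs_from(values))
        assert res.p_value == pytest.approx(2 / 64)
        assert res.significant  # 0.03125 < 0.05

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(10, 20, 7)
        b = a + rng.normal(0.5, 1.0, 7)
        res = paired_test(pairs_from(list(zip(a, b))))
        assert res.p_value == pytest.approx(wilcoxon_exact_two_sided_p(b - a), rel=1e-9)

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            paired_test(pairs_from([(1, 2)]))


def make_timecourses(n_units, baseline, post, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_units):
        jitter = rng.normal(0, noise, 4) if noise else np.zeros(4)
        out.append(
            TimecourseMeasurements(
                unit_id=f"k{i}",
                baseline=baseline + jitter[0],
                post=tuple(np.asarray(post) + jitter[1:]),
            )
        )
    return out


class TestBoldTimecourse:
    def test_flat_timecourse_not_significant(self):
        tcs = make_timecourses(4, 33.0, (33.0, 33.0, 33.0))
        res = bold_timecourse_test(tcs)
        assert res.omnibus_p == 1.0
        assert all(flag == "" for flag in res.flags.values())

    def test_injected_step_flags_later_timepoints(self):
        # large step at the second post timepoint, small within-unit noise
        tcs = make_timecourses(6, 38.5, (38.6, 48.5, 48.4), noise=0.3, seed=2)
        res = bold_timecourse_test(tcs)
        assert res.omnibus_p < 0.05
        assert "a" in res.flags["6m51s"]
        assert "b" in res.flags["6m51s"]   # step vs previous timepoint
        assert "a" in res.flags["11m24s"]

    def test_omnibus_agrees_with_permutation_oracle(self):
        tcs = make_timecourses(5, 38.5, (40.0, 44.0, 43.0), noise=1.0, seed=4)
        res = bold_timecourse_test(tcs)
        # permutation of timepoint labels within units
        values = np.array([tc.series for tc in tcs])
        rng = np.random.default_rng(0)

        def f_stat(v):
            grand = v.mean()
            ms_time = v.shape[0] * ((v.mean(axis=0) - grand) ** 2).sum() / (v.shape[1] - 1)
            resid = v - v.mean(axis=1, keepdims=True) - v.mean(axis=0) + grand
            ms_err = (resid**2).sum() / ((v.shape[0] - 1) * (v.shape[1] - 1))
            return ms_time / ms_err

        obs = f_stat(values)
        perm = [
            f_stat(np.array([row[rng.permutation(4)] for row in values]))
            for _ in range(500)
        ]
        p_perm = np.mean([p >= obs for p in perm])
        assert res.omnibus_f == pytest.approx(obs, rel=1e-6)
        assert (res.omnibus_p < 0.05) == (p_perm < 0.05)

    def test_incomplete_unit_dropped(self):
        tcs = make_timecourses(3, 38.5, (40.0, 44.0, 43.0), noise=1.0, seed=1)
        bad = TimecourseMeasurements(unit_id="bad", baseline=38.0, post=(np.nan, 40.0, 41.0))
        with pytest.warns(UserWarning, match="incomplete"):
            res = bold_timecourse_test(tcs + [bad])
        assert res.n_units == 3


class TestPercentChange:
    def test_constant_timecourse_is_100(self):
        out = percent_change(make_timecourses(3, 33.0, (33.0, 33.0, 33.0)))
        assert np.allclose(out.percent, 100.0)

    def test_furosemide_style_rise(self):
        out = percent_change(make_timecourses(2, 38.5, (44.7, 48.5, 47.8)))
        cohort = out[(out.unit_id == "cohort") & (out.timepoint == "6m51s")]
        assert cohort.percent.iloc[0] == pytest.approx(100 * 48.5 / 38.5, rel=1e-9)  # ~126%

    def test_baseline_always_100(self):
        out = percent_change(make_timecourses(4, 36.0, (30.0, 29.0, 31.0), noise=2.0, seed=3))
        assert np.allclose(out[out.timepoint == "baseline"].percent, 100.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            TimecourseMeasurements(unit_id="x", baseline=0.0, post=(1.0, 1.0, 1.0))


class TestCorrelation:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert correlate_adc_d(x, x).r == pytest.approx(1.0)
        assert correlate_adc_d(x, -x).r == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        res = correlate_adc_d([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not res.defined and np.isnan(res.r)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            correlate_adc_d([1.0, 2.0], [1.0, 2.0])
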