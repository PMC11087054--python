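"""Unit and property tests of the vesicle-pool simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmpools.kinetics import (K_FAST_1HZ, K_SLOW_1HZ, ModelSpec, apply_pulse,
                              closed_form_biexp, default_lifo,
                              default_parallel, default_serial, evolve_rest,
                              initial_state, pulse_prob_to_rate,
                              rate_to_pulse_prob, simulate, single_pool)
from fmpools.protocols import StimSegment


def seg(kind, f, dur, dye=None):
    return StimSegment(kind, f, dur, dye)


class TestClosedFormBiexp:
    def test_degenerates_to_single_exponential_when_rates_equal(self):
        t = np.linspace(0, 30, 50)
        for w in (0.0, 0.39, 1.0):
            np.testing.assert_allclose(closed_form_biexp(w, 0.1, 0.1, t),
                                       np.exp(-0.1 * t), rtol=1e-12)

    def test_normalized_to_one_at_time_zero(self):
        assert closed_form_biexp(0.39, 0.2, 0.032, 0.0) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # 0.5 e^-2 + 0.5 e^-0.2 = 0.4770330182...
        assert closed_form_biexp(0.5, 0.2, 0.02, 10.0) == \
            pytest.approx(0.4770330182, abs=1e-9)

    @pytest.mark.parametrize("w,kf,ks", [(-0.1, 0.2, 0.1), (1.1, 0.2, 0.1),
                                         (0.5, 0.1, 0.2), (0.5, 0.1, -0.01)])
    def test_rejects_invalid_parameters(self, w, kf, ks):
        with pytest.raises(ValueError):
            closed_form_biexp(w, kf, ks, 1.0)


class TestRateConversions:
    def test_round_trip(self):
        for k in (0.03, 0.2, 1.0):
            for f in (1.0, 20.0):
                q = rate_to_pulse_prob(k, f)
                assert pulse_prob_to_rate(q, f) == pytest.approx(k, rel=1e-12)


class TestApplyPulse:
    def test_releases_p_times_rrp_stained_content(self):
        # 3 fully stained readily releasable vesicles, p = 0.5, no dye:
        # 1.5 stained vesicles destain on this pulse
        m = ModelSpec(topology="parallel", n_paths=1,
                      rrp_size_per_path=(3.0,), reserve_size_per_path=(10.0,),
                      p_release=(0.5,), p_release_hf=(0.5,))
        st0 = initial_state(m, stained_with=0)
        st1 = apply_pulse(st0, m)
        assert st1.cum_exo[1] == pytest.approx(1.5)
        assert st1.fluorescence(0) == pytest.approx(13.0 - 1.5)

    def test_zero_release_probability_is_identity(self):
        m = default_parallel()
        m = ModelSpec(**{**{k: getattr(m, k) for k in m.__dataclass_fields__},
                         "p_release": (0.0, 0.0)})
        st0 = initial_state(m, stained_with=0)
        st1 = apply_pulse(st0, m)
        np.testing.assert_allclose(st1.rrp_labeled, st0.rrp_labeled)
        np.testing.assert_allclose(st1.reserve_labeled, st0.reserve_labeled)

    def test_invalid_negative_state_raises(self):
        m = default_parallel()
        st0 = initial_state(m, stained_with=0)
        st0.rrp_total[0] = -1.0
        with pytest.raises(ValueError):
            apply_pulse(st0, m)

    def test_80_pulses_at_20hz_empty_rrp_but_spare_reserves(self):
        # high-frequency trains drive both RRP subdivisions to a near-empty
        # steady state while the reserves stay largely intact
        m = default_parallel()
        st = initial_state(m, stained_with=0)
        from fmpools.kinetics import _evolve
        for _ in range(80):
            st = apply_pulse(st, m, frequency_hz=20.0)
            st = _evolve(st, m, 0.05, 20.0)
        occ = st.rrp_total / np.asarray(m.rrp_size_per_path)
        assert np.all(occ < 0.20)
        reserve_stain = st.reserve_labeled[:, 0].sum()
        assert reserve_stain > 0.85 * sum(m.reserve_size_per_path)


class TestEvolveRest:
    def test_zero_duration_is_identity(self):
        m = default_parallel()
        st0 = initial_state(m, stained_with=0)
        st1 = evolve_rest(st0, m, 0.0)
        np.testing.assert_allclose(st1.rrp_total, st0.rrp_total)
        np.testing.assert_allclose(st1.reserve_labeled, st0.reserve_labeled)

    def test_rrp_refills_from_reserve_within_a_minute(self):
        # empty RRP, recruitment 1/28 s^-1: >= 88% refilled after 60 s
        m = default_parallel()
        st = initial_state(m)
        st.rrp_total[:] = 0.0
        st = evolve_rest(st, m, 60.0)
        occ = st.rrp_total.sum() / sum(m.rrp_size_per_path)
        assert occ >= 0.88
        # refill only moves vesicles from the reserves; nothing is created
        assert st.total_vesicles == pytest.approx(40.0)

    def test_rest_without_mixing_preserves_path_stained_fractions(self):
        m = default_parallel()  # mixing_rate 0
        st = initial_state(m, stained_with=0)
        st.reserve_labeled[0, 0] *= 0.2  # asymmetric staining across paths
        st.rrp_labeled[0, 0] *= 0.2

        def path_frac(s):
            return (s.reserve_labeled[:, 0] + s.rrp_labeled[:, 0]) \
                / (s.reserve_total + s.rrp_total)

        frac0 = path_frac(st)
        st1 = evolve_rest(st, m, 300.0)
        np.testing.assert_allclose(path_frac(st1), frac0, rtol=1e-9)

    def test_mixing_relaxes_reserve_fractions_toward_pooled(self):
        m = default_parallel(mixing_rate=1 / 60.0)
        st = initial_state(m, stained_with=0)
        st.reserve_labeled[0, 0] *= 0.2
        st1 = evolve_rest(st, m, 600.0)  # 10 tau
        f = st1.reserve_labeled[:, 0] / st1.reserve_total
        assert abs(f[0] - f[1]) < 1e-3


class TestSimulate:
    def test_1hz_parallel_trace_equals_closed_form_biexp(self):
        # source-path recycling, labels homogenized within paths: the
        # simulated 1 Hz destaining is exactly the weighted two-exponential
        m = default_parallel(recycle_rule="return_to_source_path")
        res = simulate(m, [seg("stim", 1.0, 1500.0)], initial_stain=0)
        F = res.F["dye1"] / res.F["dye1"][0]
        expect = closed_form_biexp(0.39, K_FAST_1HZ, K_SLOW_1HZ,
                                   res.times / 60.0)
        assert np.max(np.abs(F - expect)) < 1e-6

    def test_single_pool_destains_as_single_exponential(self):
        m = single_pool(k=0.05)
        res = simulate(m, [seg("stim", 1.0, 1500.0)], initial_stain=0)
        F = res.F["dye1"] / res.F["dye1"][0]
        np.testing.assert_allclose(F, np.exp(-0.05 * res.times / 60.0),
                                   atol=1e-9)

    def test_20hz_destaining_is_recruitment_limited_single_exponential(self):
        # after the RRP empties, destaining follows the shared recruitment
        # clock (tau ~ 28 s) regardless of path, i.e. a single exponential
        m = default_parallel()
        res = simulate(m, [seg("stim", 20.0, 100.0)], initial_stain=0)
        t = res.times
        F = res.F["dye1"] / res.F["dye1"][0]
        late = t >= 20.0  # skip the RRP-drain transient
        slope = np.polyfit(t[late], np.log(F[late]), 1)[0]
        assert -1 / slope == pytest.approx(28.0, rel=0.05)
        # log-linearity: residuals of the exponential fit are tiny
        resid = np.log(F[late]) - np.polyval(
            np.polyfit(t[late], np.log(F[late]), 1), t[late])
        assert np.max(np.abs(resid)) < 0.01

    def test_rrp_occupancy_regimes(self):
        # 1 Hz: release-limited, RRP > 90% occupied; 20 Hz: < 20%
        m = default_parallel()
        r1 = simulate(m, [seg("stim", 1.0, 300.0)], initial_stain=0)
        occ1 = r1.final_state.rrp_total.sum() / sum(m.rrp_size_per_path)
        assert occ1 > 0.90
        r20 = simulate(m, [seg("stim", 20.0, 20.0)], initial_stain=0)
        occ20 = r20.final_state.rrp_total.sum() / sum(m.rrp_size_per_path)
        assert occ20 < 0.20

    def test_total_vesicles_conserved_through_stain_protocol(self):
        m = default_parallel()
        res = simulate(m, [seg("stim", 20.0, 60.0, dye=0), seg("rest", 0, 60.0),
                           seg("stim", 1.0, 300.0, dye=1)])
        assert res.final_state.total_vesicles == pytest.approx(46.0, rel=1e-9)

    def test_noiseless_fluorescence_non_increasing_during_destain(self):
        m = default_parallel()
        res = simulate(m, [seg("stim", 1.0, 600.0), seg("stim", 20.0, 60.0)],
                       initial_stain=0)
        assert np.all(np.diff(res.F["dye1"]) <= 1e-12)

    def test_invalid_dye_channel_rejected(self):
        m = default_parallel()
        bad = seg("stim", 1.0, 60.0, dye=2)
        with pytest.raises(ValueError):
            simulate(m, [bad])

    def test_deterministic_for_fixed_inputs(self):
        m = default_parallel()
        p = [seg("stim", 20.0, 60.0, dye=0), seg("stim", 1.0, 120.0)]
        a = simulate(m, p)
        b = simulate(m, p)
        np.testing.assert_array_equal(a.F["dye1"], b.F["dye1"])

    def test_stochastic_mode_matches_mean_field_on_average(self, rng):
        kw = dict(topology="parallel", n_paths=1,
                  rrp_size_per_path=(200.0,), reserve_size_per_path=(2000.0,),
                  p_release=(0.02,), p_release_hf=(0.15,))
        det = simulate(ModelSpec(**kw), [seg("stim", 1.0, 300.0)],
                       initial_stain=0)
        sto = simulate(ModelSpec(**kw, stochastic=True),
                       [seg("stim", 1.0, 300.0)], initial_stain=0, rng=rng)
        rel_err = np.abs(sto.F["dye1"][-1] - det.F["dye1"][-1]) \
            / det.F["dye1"][-1]
        assert rel_err < 0.05


class TestTopologyComparators:
    def test_serial_model_requires_zero_rrp_on_deep_compartment(self):
        with pytest.raises(ValueError):
            ModelSpec(topology="serial", n_paths=2,
                      rrp_size_per_path=(3.0, 3.0),
                      reserve_size_per_path=(15.0, 25.0),
                      p_release=(0.02, 0.0), p_release_hf=(0.1, 0.0))

    def test_lifo_rundown_is_extreme_at_1hz(self):
        # recycled (unlabeled) vesicles cap the stack and are mobilized
        # first, so fractional destaining collapses during a 1 Hz train
        m = default_lifo()
        res = simulate(m, [seg("stim", 1.0, 1500.0)], initial_stain=0)
        F = res.F["dye1"]
        early = (F[0] - F[22]) / F[0]
        late = (F[315] - F[337]) / F[315]
        assert early > 0.1
        assert late < 0.1 * early

    def test_serial_deep_reserve_retains_stain_behind_slow_maturation(self):
        m = default_serial()
        res = simulate(m, [seg("stim", 1.0, 1500.0)], initial_stain=0)
        st = res.final_state
        deep_frac = st.reserve_labeled[1, 0] / st.reserve_total[1]
        prox_frac = (st.reserve_labeled[0, 0] + st.rrp_labeled[0, 0]) \
            / (st.reserve_total[0] + st.rrp_total[0])
        assert deep_frac > 2 * prox_frac


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n1=st.integers(0, 30), rest=st.floats(0.0, 120.0), n2=st.integers(0, 30),
    dye=st.sampled_from([None, 0, 1]),
    rule=st.sampled_from(["quick_first", "return_to_source_path",
                          "proportional_split"]),
)
def test_conservation_and_label_bounds_under_arbitrary_protocols(
        n1, rest, n2, dye, rule):
    """Total vesicles are conserved and labels stay within pool totals."""
    from fmpools.kinetics import _evolve

    m = default_parallel(recycle_rule=rule)
    st0 = initial_state(m, stained_with=0)
    st = st0
    for _ in range(n1):
        st = apply_pulse(st, m, dye_in_bath=dye, frequency_hz=20.0)
        st = _evolve(st, m, 0.05, 20.0)
    st = evolve_rest(st, m, rest)
    for _ in range(n2):
        st = apply_pulse(st, m, dye_in_bath=None, frequency_hz=1.0)
        st = _evolve(st, m, 1.0, 1.0)
    assert st.total_vesicles == pytest.approx(st0.total_vesicles, rel=1e-9)
    assert np.all(st.rrp_labeled.sum(axis=1) <= st.rrp_total + 1e-9)
    assert np.all(st.reserve_labeled.sum(axis=1) <= st.reserve_total + 1e-9)
    assert np.all(st.rrp_labeled >= -1e-9)
    # labeled content never increases during dye-free stimulation
    if dye is None and (n1 or n2):
        assert st.fluorescence(0) <= st0.fluorescence(0) + 1e-9
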