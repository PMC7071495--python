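import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selset import head_model
from selset.actr import (
    ActivationProfile,
    Buffer,
    Chunk,
    Production,
    StallError,
    build_schedule,
    coarse_code,
    polyspike,
    run_model,
    simulate_condition,
)


class TestSchedule:
    def test_default_completion_times(self):
        sched = build_schedule()
        assert [p.completion_ms for p in sched] == [150, 250, 350, 450, 550, 650]

    def test_zero_cycle(self):
        sched = build_schedule(cycle_ms=0.0)
        assert [p.completion_ms for p in sched] == [100, 200, 300, 400, 500, 600]

    def test_custom_bin_and_modules(self):
        sched = build_schedule(bin_ms=200.0, cycle_ms=50.0,
                               modules=(("a", "r1"), ("b", "r2"), ("c", "r3")))
        assert [p.completion_ms for p in sched] == [250, 450, 650]

    def test_empty_modules_rejected(self):
        with pytest.raises(ValueError):
            build_schedule(modules=())

    def test_default_module_order(self):
        sched = build_schedule()
        assert [p.module for p in sched] == [
            "visual", "spatial-attention", "declarative",
            "executive", "procedural", "manual",
        ]
        assert sched[4].region == "basal-ganglia"
        assert sched[4].completion_ms == 550.0


class TestRunModel:
    def test_target_run(self, dipoles):
        trace = run_model("target", dipoles=dipoles)
        assert len(trace.firings) == 6
        assert trace.firings[-1].time_ms == 650.0
        assert trace.response == "release"
        assert [f.dipole for f in trace.firings] == [
            "precuneus", "supramarginal_gyrus", "middle_frontal_gyrus",
            "insula", "thalamus_md", "caudate_body",
        ]

    def test_distractor_run(self, dipoles):
        trace = run_model("distractor", dipoles=dipoles)
        assert trace.response == "withhold"
        events = {f.time_ms: f.dipole for f in trace.firings if f.dipole}
        assert events == {250.0: "middle_temporal_gyrus", 550.0: "claustrum"}

    def test_serial_firing_distinct_times(self, dipoles):
        trace = run_model("target", dipoles=dipoles)
        times = trace.times
        assert len(set(times)) == len(times)
        assert times == sorted(times)

    def test_stall_on_unmatched_pattern(self):
        prod = Production(
            name="orphan",
            module="visual",
            region="occipital",
            completion_ms=150.0,
            requires=(("nonexistent-buffer", (("kind", "anything"),)),),
            effect=lambda buffers, stimulus: None,
        )
        with pytest.raises(StallError):
            run_model("target", schedule=[prod], dipoles=[])

    def test_duplicate_completion_times_rejected(self):
        sched = build_schedule()
        clone = Production(
            name="dup", module="visual", region="occipital",
            completion_ms=150.0, requires=sched[0].requires,
            effect=sched[0].effect,
        )
        with pytest.raises(ValueError, match="distinct"):
            run_model("target", schedule=[sched[0], clone], dipoles=[])

    def test_invalid_stimulus(self):
        with pytest.raises(ValueError):
            run_model("banana")

    def test_buffer_holds_single_chunk(self):
        buf = Buffer("visual")
        buf.set(Chunk(kind="percept"))
        assert buf.content.get("kind") == "percept"
        with pytest.raises(TypeError):
            buf.set("not-a-chunk")


class TestActivationProfile:
    def test_peak_at_firing(self):
        prof = ActivationProfile()
        assert prof.level(0.0, 100.0) == pytest.approx(prof.intensity(100.0))

    def test_exponential_decay_half_life(self):
        prof = ActivationProfile(decay_half_life_ms=50.0)
        peak = prof.level(0.0, 100.0)
        assert prof.level(50.0, 100.0) == pytest.approx(peak / 2.0)

    def test_rest_before_rise(self):
        prof = ActivationProfile()
        far_before = prof.level(-500.0, 100.0)
        assert far_before == pytest.approx(
            prof.rest_fraction * prof.intensity(100.0), rel=0.05
        )

    def test_faster_productions_more_intense(self):
        prof = ActivationProfile()
        assert prof.intensity(50.0) > prof.intensity(100.0)
        assert prof.decay_rate(50.0) > prof.decay_rate(100.0)


class TestPolyspike:
    def test_six_spikes_per_electrode(self, dipoles, montage):
        trace = run_model("target", dipoles=dipoles)
        patterns = polyspike(trace, dipoles, montage)
        assert len(patterns) == 12
        for p in patterns:
            assert p.times.size >= 6

    def test_single_production_background_at_rest(self, montage):
        d = head_model.Dipole.radial("solo", np.array([0.0, 0.0, 0.5]),
                                     peak_time=150.0, condition="target")
        sched = build_schedule()
        trace = run_model("target", schedule=sched, dipoles=[d])
        patterns = polyspike(trace, [d], montage)
        prof = ActivationProfile()
        for p in patterns:
            gain = head_model.dipole_potential(d, [e for e in montage if e.label == p.electrode][0])
            # spike 0 is the firing; later spikes decay toward zero
            assert p.amplitudes[0] == pytest.approx(gain * prof.intensity(100.0))
            assert np.all(np.abs(p.amplitudes[1:]) <= abs(p.amplitudes[0]) + 1e-12)

    def test_zero_rest_faraway_spikes_zero(self, montage):
        d = head_model.Dipole.radial("solo", np.array([0.0, 0.0, 0.5]),
                                     peak_time=650.0, condition="target")
        prof = ActivationProfile(rest_fraction=0.0)
        trace = run_model("target", dipoles=[d])
        patterns = polyspike(trace, [d], montage, profile=prof)
        for p in patterns:
            # all spikes well before the rise window must be exactly rest = 0
            assert np.allclose(p.amplitudes[:3], 0.0, atol=1e-9)

    def test_matches_forward_field_oracle(self, dipoles, montage):
        # at each firing time, the firing dipole contributes task level and
        # the others rest/decay: check the full aggregation against a
        # hand-rolled loop over dipole_potential
        prof = ActivationProfile()
        trace = run_model("target", dipoles=dipoles)
        patterns = polyspike(trace, dipoles, montage, profile=prof)
        events = {f.dipole: f.time_ms for f in trace.firings if f.dipole}
        cond = [d for d in dipoles if d.condition == "target"]
        for p, e in zip(patterns, montage):
            for i, t in enumerate(p.times):
                expected = 0.0
                for d in cond:
                    level = prof.level(t - events[d.label], 100.0)
                    expected += head_model.dipole_potential(d, e) * level * d.strength
                assert p.amplitudes[i] == pytest.approx(expected, rel=1e-12)

    def test_unmapped_firing_rejected(self, dipoles, montage):
        trace = run_model("target", dipoles=dipoles)
        target_only = [d for d in dipoles if d.condition == "target"][1:]
        with pytest.raises(ValueError, match="unmapped"):
            polyspike(trace, target_only, montage)


class TestCoarseCode:
    def _patterns(self, dipoles, montage):
        trace = run_model("target", dipoles=dipoles)
        return polyspike(trace, dipoles, montage)

    def test_extremes_map_to_scale_bounds(self, dipoles, montage):
        patterns = self._patterns(dipoles, montage)
        coarse_code(patterns)
        allv = np.concatenate([p.scaled_uv for p in patterns])
        assert allv.max() == pytest.approx(6.0) or allv.min() == pytest.approx(-6.0)
        assert np.all(allv <= 6.0) and np.all(allv >= -6.0)

    def test_zero_maps_to_middle(self, dipoles, montage):
        patterns = self._patterns(dipoles, montage)
        patterns[0].amplitudes[2] = 0.0
        coarse_code(patterns, n_levels=13)
        assert patterns[0].scaled_uv[2] == pytest.approx(0.0)
        assert patterns[0].codes[2] == 6  # middle of 13 ordered levels

    def test_round_trip_idempotent(self, dipoles, montage):
        patterns = self._patterns(dipoles, montage)
        coarse_code(patterns, n_levels=13)
        step = 12.0 / 12.0
        for p in patterns:
            decoded = -6.0 + p.codes * step
            recoded = np.rint((decoded + 6.0) / step).astype(int)
            assert np.array_equal(recoded, p.codes)

    def test_order_preserving(self, dipoles, montage):
        patterns = self._patterns(dipoles, montage)
        coarse_code(patterns)
        allamp = np.concatenate([p.amplitudes for p in patterns])
        allcode = np.concatenate([p.codes for p in patterns])
        order = np.argsort(allamp)
        assert np.all(np.diff(allcode[order]) >= 0)

    def test_degenerate_scale_rejected(self, dipoles, montage):
        with pytest.raises(ValueError, match="scale"):
            coarse_code(self._patterns(dipoles, montage), scale=(2.0, 2.0))
        with pytest.raises(ValueError):
            coarse_code(self._patterns(dipoles, montage), n_levels=1)

    @given(st.integers(3, 25))
    @settings(max_examples=10, deadline=None)
    def test_monotone_for_any_level_count(self, n_levels):
        montage = head_model.standard_montage()
        from selset.fixtures import default_dipoles

        patterns = self._patterns(default_dipoles(), montage)
        coarse_code(patterns, n_levels=n_levels)
        for p in patterns:
            order = np.argsort(p.amplitudes)
            assert np.all(np.diff(p.codes[order]) >= 0)


class TestEndToEnd:
    def test_maps_at_firing_times(self, dipoles, montage):
        trace, patterns, maps = simulate_condition("target", dipoles=dipoles,
                                                   montage=montage)
        assert [m.time_ms for m in maps] == [150, 250, 350, 450, 550, 650]
        for m in maps:
            assert len(m.values) == 12
            assert np.all(np.abs(m.values) <= 6.0)

    def test_noise_free_self_fit_is_perfect(self, dipoles, montage):
        from selset.homology import topo_fit
        from selset.actr import TopoMap

        _, _, maps = simulate_condition("target", dipoles=dipoles, montage=montage)
        for m in maps:
            actual = TopoMap(
                time_ms=m.time_ms, condition=m.condition, provenance="actual",
                electrodes=list(m.electrodes), values=m.values.copy(),
            )
            fit = topo_fit(actual, m)
            assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
            assert fit.slope == pytest.approx(1.0, abs=1e-9)
            assert fit.intercept == pytest.approx(0.0, abs=1e-9)
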