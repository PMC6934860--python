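"""Generator contracts: kinetics closed form, determinism, ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcsmdr.quantification import uptake_timeseries
from mcsmdr.synthetic import (
    FlowSpec,
    PHENOTYPES,
    PlateSpec,
    SpheroidGeometry,
    SyntheticPhenotype,
    make_flow_events,
    make_monolayer_stack,
    make_plate,
    make_spheroid_stack,
    uptake_curve,
)


def pheno(u=10.0, e=0.0, **kw):
    args = dict(name="custom", u=u, e=e, delta_max=1.0, k_p=0.5,
                ros_init=0.0, ros_decay=0.0)
    args.update(kw)
    return SyntheticPhenotype(**args)


class TestUptakeCurve:
    def test_linear_limit_without_efflux(self):
        assert np.allclose(uptake_curve(pheno(u=2.0, e=0.0), [0, 1, 2]), [0, 2, 4])

    def test_plateau_is_u_over_e(self):
        c = uptake_curve(pheno(u=10.0, e=1.0), [1000.0])
        assert c[0] == pytest.approx(10.0, rel=1e-6)

    def test_saturating_closed_form(self):
        # (10/0.5) * (1 - exp(-0.5*2)) evaluated independently = 12.6424...
        c = uptake_curve(pheno(u=10.0, e=0.5), [2.0])
        assert c[0] == pytest.approx(20.0 * (1.0 - np.exp(-1.0)), rel=1e-12)
        assert c[0] == pytest.approx(12.642, abs=5e-4)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            uptake_curve(pheno(), [-1.0, 0.0])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(u=st.floats(0.1, 100), e=st.floats(0.01, 5), tmax=st.floats(0.5, 48))
    def test_nondecreasing_and_bounded(self, u, e, tmax):
        t = np.linspace(0, tmax, 25)
        c = uptake_curve(pheno(u=u, e=e), t)
        assert np.all(np.diff(c) >= -1e-9)
        assert np.all(c <= u / e + 1e-9)

    def test_phenotype_invariants_enforced(self):
        with pytest.raises(ValueError):
            pheno(u=-1.0)
        with pytest.raises(ValueError):
            pheno(delta_max=1.5)


class TestSpheroidStack:
    def test_same_seed_bit_identical(self, sensitive, geometry128):
        s1, m1 = make_spheroid_stack(sensitive, geometry128, seed=7, image_size=128,
                                     duration_h=2.0)
        s2, m2 = make_spheroid_stack(sensitive, geometry128, seed=7, image_size=128,
                                     duration_h=2.0)
        assert np.array_equal(s1.phase, s2.phase)
        assert np.array_equal(s1.green, s2.green)
        assert all(np.array_equal(a.pixels, b.pixels) for a, b in zip(m1, m2))

    def test_sensitive_mean_green_nondecreasing(self, geometry128):
        ph = pheno(u=1500.0, e=0.0, delta_max=1.0)
        stack, masks = make_spheroid_stack(ph, geometry128, seed=3, image_size=128,
                                           duration_h=6.0, frame_interval_min=60.0)
        series = uptake_timeseries(stack, masks)
        # noise sd 60 on means over ~5000 px: allow a tiny slack
        assert np.all(np.diff(series.mean_fluorescence) > -5.0)

    def test_resistant_accumulates_less_than_sensitive(
            self, sensitive, resistant, geometry128):
        acc = {}
        for ph in (sensitive, resistant):
            stack, masks = make_spheroid_stack(ph, geometry128, seed=5,
                                               image_size=128, duration_h=12.0)
            acc[ph.name] = uptake_timeseries(stack, masks).accumulated
        assert acc["resistant"] < acc["sensitive"]

    def test_mask_is_exact_disk(self, sensitive):
        geo = SpheroidGeometry(center=(64, 64), radius=30.0, boundary_softness=0.0,
                               inhomogeneity_amplitude=0.0, background_noise_sd=0.0)
        _, masks = make_spheroid_stack(sensitive, geo, seed=0, image_size=128,
                                       duration_h=0.0)
        area = masks[0].area
        assert area == pytest.approx(np.pi * 30.0**2, rel=0.02)

    def test_oversized_geometry_rejected(self, sensitive):
        geo = SpheroidGeometry(center=(64, 64), radius=80.0)
        with pytest.raises(ValueError):
            make_spheroid_stack(sensitive, geo, seed=0, image_size=128)


class TestMonolayerStack:
    def test_determinism_and_frame_count(self, sensitive):
        s1 = make_monolayer_stack(sensitive, n_cells=30, seed=2, image_size=96,
                                  duration_h=1.0, frame_interval_min=20.0)
        s2 = make_monolayer_stack(sensitive, n_cells=30, seed=2, image_size=96,
                                  duration_h=1.0, frame_interval_min=20.0)
        assert np.array_equal(s1.green, s2.green)
        assert s1.n_frames == 4  # 0, 20, 40, 60 min

    def test_zero_duration_single_frame(self, sensitive):
        s = make_monolayer_stack(sensitive, n_cells=10, seed=0, image_size=64,
                                 duration_h=0.0)
        assert s.n_frames == 1

    def test_zero_cells_rejected(self, sensitive):
        with pytest.raises(ValueError):
            make_monolayer_stack(sensitive, n_cells=0, seed=0)


class TestPlate:
    def spec(self, **kw):
        args = dict(drug="cisplatin", concentrations=tuple(np.geomspace(3.33, 333, 8)),
                    true_ic50=50.0, hill=1.0, noise_sd=0.0)
        args.update(kw)
        return PlateSpec(**args)

    def test_midpoint_gives_half_viability(self):
        from mcsmdr.dose_response import plate_to_viability

        spec = self.spec(concentrations=(10.0, 25.0, 50.0, 100.0), true_ic50=50.0)
        viab = plate_to_viability(make_plate(spec, seed=0))
        at_ic50 = viab.loc[viab.conc_uM == 50.0, "viability_pct"]
        assert np.allclose(at_ic50, 50.0)

    def test_same_seed_identical(self):
        spec = self.spec(noise_sd=0.05)
        p1, p2 = make_plate(spec, seed=4), make_plate(spec, seed=4)
        assert p1.equals(p2)

    def test_spec_invariants(self):
        with pytest.raises(ValueError):
            self.spec(concentrations=(5.0, 3.0, 10.0, 20.0))
        with pytest.raises(ValueError):
            self.spec(replicates=0)


class TestFlowEvents:
    def test_no_dead_events_all_pi_low(self):
        spec = FlowSpec(n_events=2000, dead_fraction=0.0)
        ev = make_flow_events(spec, seed=0)
        assert ev.pi.max() < spec.dead_pi_median / 10

    def test_control_median_matches_baseline(self):
        spec = FlowSpec(n_events=10_000, dead_fraction=0.0, baseline_mfi=500.0)
        ev = make_flow_events(spec, seed=1)
        ctrl = ev[ev.tube == "control"].green
        # 2 SE of the median of a log-normal sample
        se = 1.2533 * ctrl.std() / np.sqrt(len(ctrl))
        assert abs(ctrl.median() - 500.0) < 2 * se + 5.0

    def test_same_seed_identical(self):
        spec = FlowSpec(n_events=500)
        assert make_flow_events(spec, seed=9).equals(make_flow_events(spec, seed=9))

    def test_control_ratio_must_be_one(self):
        with pytest.raises(ValueError):
            FlowSpec(retention_ratio={"control": 2.0, "MDR1_verapamil": 1.5,
                                      "MRP1_MK571": 2.0, "BCRP_novobiocin": 3.0})


def test_default_phenotypes_cover_three_classes():
    assert set(PHENOTYPES) == {"sensitive", "moderate", "resistant"}
    assert PHENOTYPES["sensitive"].ros_init > 0
    assert PHENOTYPES["resistant"].ros_init == 0
    assert PHENOTYPES["resistant"].delta_max < PHENOTYPES["sensitive"].delta_max
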