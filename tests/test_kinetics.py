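"""Forward-model correctness: limits, oracle agreement, frame averaging and
distribution-volume formulas."""

import numpy as np
import pytest

import duokin as dk
from duokin.data import ValidationError
from conftest import ode_tissue


@pytest.fixture(scope="module")
def inputs():
    _, inputs, _ = dk.generate_plasma(seed=5, species="human")
    return inputs


class TestModelSpec:
    @pytest.mark.parametrize(
        "kind,n_free",
        [("2TSI_k4fix", 4), ("1TDI", 5), ("2TDI", 7), ("2TDI_k4fix", 6)],
    )
    def test_free_parameter_counts(self, kind, n_free):
        fixed = {"k4": 0.1} if kind.endswith("_k4fix") else {}
        assert dk.ModelSpec(kind, fixed).n_free == n_free

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            dk.ModelSpec("3TDI")

    def test_k4fix_requires_value(self):
        with pytest.raises(ValidationError):
            dk.ModelSpec("2TDI_k4fix")


class TestSimulateTissue:
    def test_blood_only_limit(self, inputs):
        params = dk.KineticParameters(vb=1.0, K1p=0.0, k2p=0.0, k3=0.0, k4=0.0,
                                      K1m=0.0, k2m=0.0)
        curve = dk.simulate_tissue(params, inputs, dk.ModelSpec("2TDI"))
        np.testing.assert_allclose(curve, inputs.whole_blood, atol=1e-14)

    def test_dual_input_reduces_to_single_when_k1m_zero(self, inputs):
        pd = dict(vb=0.07, K1p=0.05, k2p=0.4, k3=0.05, k4=0.12)
        dual = dk.simulate_tissue(
            dk.KineticParameters(**pd, K1m=0.0, k2m=0.3), inputs, dk.ModelSpec("2TDI")
        )
        single = dk.simulate_tissue(
            dk.KineticParameters(**pd), inputs, dk.ModelSpec("2TSI")
        )
        np.testing.assert_allclose(dual, single, atol=1e-14)

    def test_linearity_in_inputs(self, inputs):
        params = dk.KineticParameters(vb=0.05, K1p=0.06, k2p=0.5, k3=0.04, k4=0.15,
                                      K1m=0.04, k2m=0.1)
        spec = dk.ModelSpec("2TDI")
        doubled = dk.InputFunctionSet(
            t_s=inputs.t_s,
            whole_blood=2 * inputs.whole_blood,
            total_plasma=2 * inputs.total_plasma,
            parent_plasma=2 * inputs.parent_plasma,
            metabolite_plasma=2 * inputs.metabolite_plasma,
        )
        c1 = dk.simulate_tissue(params, inputs, spec)
        c2 = dk.simulate_tissue(params, doubled, spec)
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-12)

    def test_matches_ode_oracle_2tdi(self, inputs):
        rng = np.random.default_rng(17)
        for _ in range(3):
            params = dk.KineticParameters(
                vb=rng.uniform(0.02, 0.15),
                K1p=rng.uniform(0.01, 0.3),
                k2p=rng.uniform(0.05, 0.8),
                k3=rng.uniform(0.01, 0.3),
                k4=rng.uniform(0.02, 0.4),
                K1m=rng.uniform(0.005, 0.2),
                k2m=rng.uniform(0.02, 0.5),
            )
            analytic = dk.simulate_tissue(params, inputs, dk.ModelSpec("2TDI"))
            numeric = ode_tissue(params, inputs, "2TDI")
            assert np.max(np.abs(analytic - numeric)) < 1e-6 * np.max(analytic)

    def test_late_rise_phenotype_controlled_by_k1m(self, inputs, schedule):
        base = dict(vb=0.07, K1p=0.054, k2p=0.5, k3=0.045, k4=0.15, k2m=0.06)
        spec = dk.ModelSpec("2TDI")
        mid_min = schedule.mid / 60.0
        win = (mid_min >= 20) & (mid_min <= 40)

        high = dk.simulate_tissue(
            dk.KineticParameters(**base, K1m=0.06), inputs, spec
        )
        f_high = dk.frame_average(high, inputs.t_s, schedule).activity
        assert np.mean(f_high[-3:]) > np.mean(f_high[win])

        none = dk.simulate_tissue(
            dk.KineticParameters(**base, K1m=0.0), inputs, spec
        )
        f_none = dk.frame_average(none, inputs.t_s, schedule).activity
        assert np.mean(f_none[-3:]) < np.mean(f_none[win])
        # monotone late washout without metabolite influx
        assert np.all(np.diff(f_none[-6:]) < 0)


class TestFrameAverage:
    def test_constant_curve(self, schedule):
        t = np.arange(0.0, 5401.0)
        out = dk.frame_average(np.full(t.size, 3.3), t, schedule)
        np.testing.assert_allclose(out.activity, 3.3, rtol=1e-12)

    def test_linear_curve_gives_mid_times(self, schedule):
        t = np.arange(0.0, 5401.0)
        a = 0.01
        out = dk.frame_average(a * t, t, schedule)
        np.testing.assert_allclose(out.activity, a * schedule.mid, rtol=1e-12)

    def test_exponential_curve_matches_closed_form(self):
        sched = dk.make_frame_schedule([(3, 20.0), (2, 60.0)])
        lam = 0.001  # per second
        t = np.arange(0.0, 180.01, 0.05)
        out = dk.frame_average(np.exp(-lam * t), t, sched)
        exact = (np.exp(-lam * sched.start) - np.exp(-lam * sched.end)) / (
            lam * sched.duration
        )
        np.testing.assert_allclose(out.activity, exact, atol=1e-8)

    def test_curve_must_cover_schedule(self, schedule):
        t = np.arange(0.0, 100.0)
        with pytest.raises(ValidationError):
            dk.frame_average(np.ones(t.size), t, schedule)


class TestDistributionVolume:
    def test_two_tissue_formula(self):
        params = dk.KineticParameters(vb=0.07, K1p=0.1, k2p=0.5, k3=0.2, k4=0.1,
                                      K1m=0.01, k2m=0.1)
        vols = dk.distribution_volume(params, dk.ModelSpec("2TDI"))
        assert vols.vt == pytest.approx(0.6, rel=1e-12)
        assert vols.label == "VTp"

    def test_printed_range_example(self):
        params = dk.KineticParameters(vb=0.07, K1p=0.03, k2p=0.3, k3=0.06, k4=0.15,
                                      K1m=0.01, k2m=0.1)
        vols = dk.distribution_volume(params, dk.ModelSpec("2TDI"))
        assert vols.vt == pytest.approx(0.14, rel=1e-12)

    def test_no_binding_reduces_to_k1_over_k2(self):
        params = dk.KineticParameters(vb=0.07, K1p=0.1, k2p=0.5, k3=0.0, k4=0.1)
        vols = dk.distribution_volume(params, dk.ModelSpec("2TSI"))
        assert vols.vt == pytest.approx(0.2, rel=1e-12)
        assert vols.label == "VT"

    def test_metabolite_parameters_never_enter(self):
        a = dk.KineticParameters(vb=0.07, K1p=0.1, k2p=0.5, k3=0.2, k4=0.1,
                                 K1m=0.01, k2m=0.1)
        b = dk.KineticParameters(vb=0.07, K1p=0.1, k2p=0.5, k3=0.2, k4=0.1,
                                 K1m=0.5, k2m=0.9)
        spec = dk.ModelSpec("2TDI")
        assert dk.distribution_volume(a, spec).vt == dk.distribution_volume(b, spec).vt

    def test_undefined_cases_raise(self):
        with pytest.raises(ValidationError):
            dk.distribution_volume(
                dk.KineticParameters(vb=0.0, K1p=0.1, k2p=0.0), dk.ModelSpec("1TDI")
            )
        with pytest.raises(ValidationError):
            dk.distribution_volume(
                dk.KineticParameters(vb=0.0, K1p=0.1, k2p=0.5, k3=0.1, k4=0.0),
                dk.ModelSpec("2TSI"),
            )

    def test_monotone_in_binding_rates(self):
        def vt(k3, k4):
            p = dk.KineticParameters(vb=0.05, K1p=0.1, k2p=0.5, k3=k3, k4=k4)
            return dk.distribution_volume(p, dk.ModelSpec("2TSI")).vt

        k3s = np.linspace(0.01, 0.5, 20)
        assert np.all(np.diff([vt(k3, 0.15) for k3 in k3s]) > 0)
        k4s = np.linspace(0.05, 0.5, 20)
        assert np.all(np.diff([vt(0.1, k4) for k4 in k4s]) < 0)
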