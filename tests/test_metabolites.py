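"""HPLC fraction integration, parent-fraction modelling and input building."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import duokin as dk
from duokin.data import ValidationError
from duokin.metabolites import DEFAULT_METABOLITE_SPLIT


def gaussian_trace(areas, centres=(2.5, 5.0, 7.5, 9.5), sd=0.08):
    """Synthetic chromatogram with one Gaussian peak per Rt window."""
    rt = np.linspace(0.0, 12.0, 4001)
    sig = np.zeros_like(rt)
    for area, mu in zip(areas, centres):
        sig += area / (sd * np.sqrt(2 * np.pi)) * np.exp(-((rt - mu) ** 2) / (2 * sd**2))
    return dk.Chromatogram(rt_min=rt, signal=sig)


class TestChromatogramIntegration:
    def test_equal_peaks_give_quarter_each(self):
        fracs = dk.integrate_chromatogram(gaussian_trace([1, 1, 1, 1]))
        for name in ("met1", "met2", "met3", "parent"):
            assert fracs[name] == pytest.approx(0.25, abs=1e-6)

    def test_known_area_ratios(self):
        fracs = dk.integrate_chromatogram(gaussian_trace([1, 2, 3, 4]))
        assert fracs["met1"] == pytest.approx(0.10, abs=1e-5)
        assert fracs["met2"] == pytest.approx(0.20, abs=1e-5)
        assert fracs["met3"] == pytest.approx(0.30, abs=1e-5)
        assert fracs["parent"] == pytest.approx(0.40, abs=1e-5)

    def test_parent_only_trace(self):
        fracs = dk.integrate_chromatogram(gaussian_trace([0, 0, 0, 2]))
        assert fracs["parent"] == pytest.approx(1.0, abs=1e-9)

    def test_zero_trace_rejected(self):
        chrom = dk.Chromatogram(rt_min=np.linspace(0, 12, 100), signal=np.zeros(100))
        with pytest.raises(ValidationError, match="total"):
            dk.integrate_chromatogram(chrom)

    def test_window_outside_trace_rejected(self):
        chrom = gaussian_trace([1, 1, 1, 1])
        bad = dk.RtWindows(met1=(-5.0, 3.5))
        with pytest.raises(ValidationError, match="outside"):
            dk.integrate_chromatogram(chrom, bad)

    @given(st.lists(st.floats(0.01, 100.0), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_fractions_always_sum_to_one(self, areas):
        fracs = dk.integrate_chromatogram(gaussian_trace(areas))
        assert sum(fracs.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(0.0 <= v <= 1.0 for v in fracs.values())

    def test_baseline_subtraction_removes_linear_drift(self):
        rt = np.linspace(0, 12, 2001)
        peak = np.exp(-((rt - 9.5) ** 2) / (2 * 0.15**2))
        drift = 0.5 + 0.1 * rt
        chrom = dk.subtract_linear_baseline(rt, peak + drift)
        fracs = dk.integrate_chromatogram(chrom)
        assert fracs["parent"] > 0.95


class TestParentFractionModel:
    def test_pf_is_one_at_injection(self):
        model = dk.HillParentFraction(b=0.3, c=51.6, h=2.0)
        assert model(0.0) == 1.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            dk.HillParentFraction(b=0.3, c=51.6, h=2.0)(-1.0)

    @given(
        b=st.floats(0.0, 1.0),
        c=st.floats(0.5, 200.0),
        h=st.floats(0.2, 6.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_pf_monotone_non_increasing_and_bounded(self, b, c, h):
        model = dk.HillParentFraction(b=b, c=c, h=h)
        t = np.linspace(0.0, 120.0, 600)
        pf = model(t)
        assert np.all(np.diff(pf) <= 1e-12)
        assert np.all((pf >= b - 1e-12) & (pf <= 1.0 + 1e-12))

    def test_noiseless_recovery_of_generating_parameters(self):
        truth = dk.HillParentFraction(b=0.3, c=51.6, h=2.0)
        t = np.array([2.0, 5.0, 10.0, 20.0, 40.0, 60.0, 75.0, 90.0])
        fit = dk.fit_parent_fraction(t, truth(t))
        assert fit.converged
        assert fit.model.b == pytest.approx(0.3, abs=1e-6)
        assert fit.model.c == pytest.approx(51.6, abs=1e-4)
        assert fit.model.h == pytest.approx(2.0, abs=1e-6)

    def test_no_metabolism_gives_flat_unit_curve(self):
        t = np.array([2.0, 10.0, 40.0, 90.0])
        fit = dk.fit_parent_fraction(t, np.ones_like(t))
        assert np.allclose(fit.model(np.linspace(0, 90, 50)), 1.0, atol=1e-6)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            dk.fit_parent_fraction([10.0, 40.0], [0.8, 0.5])

    def test_human_preset_hits_90_min_anchor(self):
        assert dk.human_parent_fraction()(90.0) == pytest.approx(0.473, abs=1e-12)

    def test_mouse_preset_hits_both_anchors(self):
        m = dk.mouse_parent_fraction()
        assert 1.0 - m(10.0) == pytest.approx(0.521, abs=1e-3)
        assert m(45.0) == pytest.approx(0.237, abs=1e-3)


def make_ftc(times=None, pf_model=None):
    times = np.asarray(times if times is not None else [2, 5, 10, 20, 40, 60, 75, 90], float)
    pf_model = pf_model or dk.human_parent_fraction()
    fp = pf_model(times)
    met = 1.0 - fp
    split = DEFAULT_METABOLITE_SPLIT
    return dk.FractionTimeCourse(
        times_min=times,
        f_parent=fp,
        f_met1=split["met1"] * met,
        f_met2=split["met2"] * met,
        f_met3=split["met3"] * met,
    )


class TestCombineMetabolites:
    def test_zero_selected_fractions_give_zero_curve(self):
        t = np.array([5.0, 20.0, 60.0])
        ftc = dk.FractionTimeCourse(
            times_min=t,
            f_parent=np.array([0.9, 0.7, 0.5]),
            f_met1=np.zeros(3),
            f_met2=np.array([0.1, 0.3, 0.5]),
            f_met3=np.zeros(3),
        )
        curve = dk.combine_metabolite_fractions(ftc)
        assert np.allclose(curve(np.linspace(0, 90, 20)), 0.0, atol=1e-12)

    def test_pointwise_sum_at_samples(self):
        t = np.array([5.0, 20.0, 60.0])
        ftc = dk.FractionTimeCourse(
            times_min=t,
            f_parent=np.array([0.7, 0.7, 0.7]),
            f_met1=np.full(3, 0.2),
            f_met2=np.zeros(3),
            f_met3=np.full(3, 0.1),
        )
        curve = dk.combine_metabolite_fractions(ftc)
        np.testing.assert_allclose(curve.sample_values, 0.3, atol=1e-12)

    def test_all_metabolites_recover_closure(self):
        ftc = make_ftc()
        pf = dk.human_parent_fraction()
        curve = dk.combine_metabolite_fractions(
            ftc, penetrant=("met1", "met2", "met3"), parent_model=pf
        )
        t = np.linspace(0, 120, 200)
        np.testing.assert_allclose(curve(t), 1.0 - pf(t), atol=1e-9)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValidationError):
            dk.combine_metabolite_fractions(make_ftc(), penetrant=())

    def test_fraction_table_round_trip(self, tmp_path):
        ftc = make_ftc()
        dk.write_fraction_table(ftc, tmp_path / "f.tsv")
        back = dk.read_fraction_table(tmp_path / "f.tsv")
        np.testing.assert_array_equal(back.f_parent, ftc.f_parent)
        np.testing.assert_array_equal(back.f_met3, ftc.f_met3)


class TestBuildInputSet:
    def _blood(self):
        blood, _, _ = dk.generate_plasma(seed=3, species="human")
        return blood

    def test_no_metabolism_limit(self):
        pf = dk.HillParentFraction(b=1.0, c=10.0, h=2.0)  # pf == 1 everywhere
        inputs = dk.build_input_set(self._blood(), pf, lambda t: np.zeros_like(np.asarray(t, float)))
        np.testing.assert_allclose(inputs.metabolite_plasma, 0.0, atol=1e-12)
        np.testing.assert_allclose(inputs.parent_plasma, inputs.total_plasma, rtol=1e-12)

    def test_parent_plus_metabolite_closure(self):
        pf = dk.human_parent_fraction()
        inputs = dk.build_input_set(
            self._blood(), pf, met_curve=None, metabolite_mode="all_metabolites"
        )
        np.testing.assert_allclose(
            inputs.parent_plasma + inputs.metabolite_plasma,
            inputs.total_plasma,
            atol=1e-9 * np.max(inputs.total_plasma),
        )

    def test_parent_share_at_90_min(self):
        pf = dk.human_parent_fraction()
        curve = dk.MetaboliteFractionCurve(
            parent_model=pf, share=0.75, sample_times_min=np.array([90.0]),
            sample_values=np.array([0.75 * (1 - 0.473)]),
        )
        inputs = dk.build_input_set(self._blood(), pf, curve)
        i90 = int(np.searchsorted(inputs.t_s, 5400.0))
        assert inputs.parent_plasma[i90] == pytest.approx(
            0.473 * inputs.total_plasma[i90], rel=1e-9
        )

    def test_input_set_tsv_round_trip(self, tmp_path):
        pf = dk.human_parent_fraction()
        inputs = dk.build_input_set(self._blood(), pf, None, metabolite_mode="all_metabolites")
        inputs.write(tmp_path / "inputs.tsv")
        back = dk.InputFunctionSet.read(tmp_path / "inputs.tsv")
        np.testing.assert_array_equal(back.parent_plasma, inputs.parent_plasma)
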