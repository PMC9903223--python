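"""Estimation: recovery, uncertainty, dual-run k4 fixing and QC filtering."""

from types import SimpleNamespace

import numpy as np
import pytest

import duokin as dk
from duokin.model import FitConfig


FAST = FitConfig(n_starts=4, seed=1)


class TestFitRecovery:
    def test_noiseless_2tdi_recovers_truth(self, clean_subject):
        region = "thalamus"
        res = dk.KineticModel(
            clean_subject.tacs[region], clean_subject.inputs, "2TDI", config=FAST
        ).fit()
        truth = clean_subject.truth[region]
        assert res.converged
        for name in res.spec.free_names:
            est, tru = getattr(res.params, name), getattr(truth, name)
            assert est == pytest.approx(tru, rel=1e-3), name
        assert res.vt == pytest.approx(clean_subject.truth_vtp[region], rel=1e-3)

    def test_blood_only_data_recovers_vb(self, clean_subject, schedule):
        vb_true = 0.07
        curve = vb_true * clean_subject.inputs.whole_blood
        tac = dk.frame_average(curve, clean_subject.inputs.t_s, schedule, region="blood")
        res = dk.KineticModel(tac, clean_subject.inputs, "1TDI", config=FAST).fit()
        assert res.params.vb == pytest.approx(vb_true, abs=1e-3)
        # tracer exchange parameters collapse to the lower bound
        assert res.params.K1p <= 2e-4
        assert res.params.K1m <= 2e-4

    def test_fit_is_bit_reproducible(self, noisy_subject):
        m = lambda: dk.KineticModel(
            noisy_subject.tacs["putamen"], noisy_subject.inputs, "1TDI", config=FAST
        )
        r1, r2 = m().fit(), m().fit()
        np.testing.assert_array_equal(r1.theta, r2.theta)

    def test_percent_se_invariant_under_common_rescaling(self, noisy_subject):
        tac = noisy_subject.tacs["caudate"]
        inputs = noisy_subject.inputs
        res1 = dk.KineticModel(tac, inputs, "1TDI", config=FAST).fit()
        scale = 10.0
        tac2 = dk.TimeActivityCurve(
            activity=scale * tac.activity, schedule=tac.schedule, region=tac.region
        )
        inputs2 = dk.InputFunctionSet(
            t_s=inputs.t_s,
            whole_blood=scale * inputs.whole_blood,
            total_plasma=scale * inputs.total_plasma,
            parent_plasma=scale * inputs.parent_plasma,
            metabolite_plasma=scale * inputs.metabolite_plasma,
        )
        res2 = dk.KineticModel(tac2, inputs2, "1TDI", config=FAST).fit()
        for name in res1.spec.free_names:
            if name == "vb":
                continue
            assert res2.percent_se[name] == pytest.approx(
                res1.percent_se[name], rel=1e-4
            )
        assert res2.vt_percent_se == pytest.approx(res1.vt_percent_se, rel=1e-4)

    def test_summary_mentions_model_and_volume(self, noisy_subject):
        res = dk.KineticModel(
            noisy_subject.tacs["putamen"], noisy_subject.inputs, "1TDI", config=FAST
        ).fit()
        text = res.summary()
        assert "1TDI" in text and "VTp" in text and "putamen" in text


class TestNesting:
    def test_reduced_model_never_beats_full(self, noisy_subject):
        tac = noisy_subject.tacs["frontal_cortex"]
        inputs = noisy_subject.inputs
        red = dk.KineticModel(
            tac, inputs, "2TDI_k4fix", fixed={"k4": 0.15}, config=FAST
        ).fit()
        seed_full = list(red.theta[:4]) + [0.15] + list(red.theta[4:])
        full = dk.KineticModel(tac, inputs, "2TDI", config=FAST).fit(
            extra_starts=[seed_full]
        )
        assert full.rss_weighted <= red.rss_weighted + 1e-10 * red.rss_weighted

    def test_k4_fixed_at_truth_matches_free_fit_on_noiseless_data(self, clean_subject):
        region = "putamen"
        tac = clean_subject.tacs[region]
        truth = clean_subject.truth[region]
        red = dk.KineticModel(
            tac, clean_subject.inputs, "2TDI_k4fix", fixed={"k4": truth.k4}, config=FAST
        ).fit()
        full = dk.KineticModel(tac, clean_subject.inputs, "2TDI", config=FAST).fit()
        assert red.rss == pytest.approx(full.rss, abs=1e-10 + 1e-6 * full.rss)


class TestDualRun:
    def test_whole_brain_equal_to_region_reproduces_step1(self, clean_subject):
        wb = clean_subject.tacs["temporal_cortex"]
        dual = dk.dual_run_fit(
            wb, {"temporal_cortex": wb}, clean_subject.inputs, kind="2TDI", config=FAST
        )
        step2 = dual.regions["temporal_cortex"]
        assert step2.vt == pytest.approx(dual.whole_brain.vt, rel=1e-3)

    def test_shared_k4_cohort_regional_vtp_close_to_full_fit(self, clean_subject):
        # within a subject all regions share the generating k4, the regime the
        # dual-run procedure assumes
        regions = ["frontal_cortex", "caudate"]
        dual = dk.dual_run_fit(
            clean_subject.whole_brain,
            {r: clean_subject.tacs[r] for r in regions},
            clean_subject.inputs,
            kind="2TDI",
            config=FAST,
        )
        for r in regions:
            full = dk.KineticModel(
                clean_subject.tacs[r], clean_subject.inputs, "2TDI", config=FAST
            ).fit()
            assert dual.regions[r].vt == pytest.approx(full.vt, rel=0.02)

    def test_invalid_kind_rejected(self, clean_subject):
        with pytest.raises(dk.ValidationError):
            dk.dual_run_fit(
                clean_subject.whole_brain, {}, clean_subject.inputs, kind="1TDI"
            )


class TestQCFilter:
    @staticmethod
    def _fake(pse, converged=True):
        return SimpleNamespace(
            converged=converged, vt_percent_se=pse, qc_se_threshold=50.0
        )

    def test_nine_of_eighty_gives_11_3_percent(self):
        results = [self._fake(10.0)] * 71 + [self._fake(80.0)] * 9
        part = dk.qc_filter(results)
        assert len(part.excluded) == 9
        assert part.excluded_percentage == 11.3

    def test_all_pass(self):
        part = dk.qc_filter([self._fake(5.0)] * 10)
        assert part.excluded == []
        assert part.excluded_percentage == 0.0

    def test_zero_threshold_excludes_everything(self):
        part = dk.qc_filter([self._fake(5.0)] * 4, threshold=0.0)
        assert len(part.excluded) == 4
        assert part.excluded_percentage == 100.0

    def test_non_convergence_excluded_distinctly(self):
        results = [self._fake(5.0), self._fake(5.0, converged=False)]
        part = dk.qc_filter(results)
        assert len(part.excluded) == 1
        assert not part.excluded[0].converged

    def test_low_identifiability_fit_is_flagged(self, schedule):
        # near-irreversible specific binding (k4 ~ 0 with k3 > 0): the 90-min
        # scan carries almost no information on k4, the binding term 1+k3/k4
        # explodes, and the fit returns an unreliably high VTp with huge %SE
        _, inputs, _ = dk.generate_plasma(seed=21, species="human")
        truth = dk.KineticParameters(
            vb=0.07, K1p=0.05, k2p=0.5, k3=0.05, k4=0.002, K1m=0.02, k2m=0.06
        )
        clean = dk.frame_average(
            dk.simulate_tissue(truth, inputs, dk.ModelSpec("2TDI")),
            inputs.t_s,
            schedule,
            region="weak",
        ).activity
        rng = np.random.default_rng(4)
        sd = 0.5 * np.sqrt(np.clip(clean, 0, None) / schedule.duration)
        tac = dk.TimeActivityCurve(
            activity=np.clip(clean + rng.normal(0, 1, clean.size) * sd, 0, None),
            schedule=schedule,
            region="weak",
        )
        res = dk.KineticModel(tac, inputs, "2TDI", config=FAST).fit()
        assert res.vt_percent_se > 50.0
        assert not res.qc_pass
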