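"""Synthetic dynamic-PET studies with known ground truth.

Generates complete cohorts — bolus plasma/whole-blood curves, metabolite
fraction time-courses, regional tissue TACs and frame-dependent noise —
with the statistical structure the analysis assumes:

* plasma follows a Feng-type bolus model (linear rise to a sharp peak, then
  a sum of three decaying exponentials) with a constant plasma-to-whole-blood
  ratio;
* the parent fraction follows the species preset (human: 47.3% unchanged at
  90 min; mouse: 52.1% metabolites at 10 min, 23.7% parent at 45 min), with
  the metabolised fraction split in constant proportions over the three
  radiometabolites;
* every region is generated by the full dual-input two-tissue model (2TDI),
  so each fitted model is exactly correct, correctly nested, or deliberately
  misspecified;
* frame noise is zero-mean Gaussian with sd = noise_scale * sqrt(C / dt),
  the usual count-statistics approximation;
* half of the subjects (by default) carry an elevated metabolite influx
  K1m, reproducing the late-rising TAC phenotype seen alongside plain
  washout curves.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data import (
    HRRT_21_FRAME_SPEC,
    BloodSeries,
    FrameSchedule,
    TimeActivityCurve,
    ValidationError,
    make_frame_schedule,
)
from .io import write_blood_table, write_tac_table
from .kinetics import KineticParameters, ModelSpec, distribution_volume, frame_average, simulate_tissue
from .metabolites import (
    DEFAULT_METABOLITE_SPLIT,
    PENETRANT_METABOLITES,
    FractionTimeCourse,
    InputFunctionSet,
    MetaboliteFractionCurve,
    species_parent_fraction,
    write_fraction_table,
)

__all__ = [
    "FengPlasma",
    "MANUAL_SAMPLE_MINUTES",
    "REGION_TABLE",
    "CohortConfig",
    "SubjectData",
    "generate_plasma",
    "generate_subject",
    "generate_cohort",
]

#: Manual arterial sample times (minutes post injection).
MANUAL_SAMPLE_MINUTES: tuple[float, ...] = (2.0, 5.0, 10.0, 20.0, 40.0, 60.0, 75.0, 90.0)

#: Nominal VTp (mL/cm^3) and VOI volume (cm^3) per region; VTp values sit on
#: the reported dual-input medians (~0.10-0.16), volumes are nominal
#: grey-matter VOI sizes used only to weight the whole-brain curve.
REGION_TABLE: dict[str, tuple[float, float]] = {
    "frontal_cortex": (0.14, 170.0),
    "parietal_cortex": (0.15, 120.0),
    "temporal_cortex": (0.13, 130.0),
    "caudate": (0.10, 8.0),
    "putamen": (0.14, 10.0),
    "thalamus": (0.16, 15.0),
    "brainstem": (0.14, 30.0),
    "cerebellar_cortex": (0.13, 110.0),
}


@dataclass(frozen=True)
class FengPlasma:
    """Feng bolus model for the total-plasma curve.

    Cp(t) = (a1 (t - tau) - a2 - a3) e^{-l1 (t - tau)}
            + a2 e^{-l2 (t - tau)} + a3 e^{-l3 (t - tau)}   for t > tau, else 0.

    Times in minutes, amplitudes in kBq/mL (a1 in kBq/mL/min); the curve is
    continuous at the bolus arrival tau and non-negative for the default
    parameters.  ``plasma_to_wb_ratio`` converts to whole blood.
    """

    a1: float = 300.0
    a2: float = 10.0
    a3: float = 5.0
    l1: float = 4.0
    l2: float = 0.25
    l3: float = 0.008
    tau: float = 0.4  # bolus arrival, minutes
    plasma_to_wb_ratio: float = 1.25

    def __call__(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        u = t - self.tau
        cp = np.where(
            u > 0,
            (self.a1 * u - self.a2 - self.a3) * np.exp(-self.l1 * np.clip(u, 0, None))
            + self.a2 * np.exp(-self.l2 * np.clip(u, 0, None))
            + self.a3 * np.exp(-self.l3 * np.clip(u, 0, None)),
            0.0,
        )
        return np.clip(cp, 0.0, None)

    def whole_blood(self, t_min) -> np.ndarray:
        return self.__call__(t_min) / self.plasma_to_wb_ratio


def _base_parameters(vtp_target: float) -> KineticParameters:
    """Ground-truth 2TDI parameters hitting a target VTp.

    Shared kinetics: k2p = 0.5 min^-1, k4 = 0.15 min^-1, k3/k4 = 0.3
    (binding term 1.3), blood volume 0.07; K1p is solved from the target.
    Metabolite compartment: K1m = 0.02 (tripled in the late-rise phenotype)
    with slow efflux k2m = 0.06 min^-1, so the compartment integrates the
    rising metabolite input — elevated K1m then turns late washout into the
    slight steady climb of the second TAC phenotype.
    """
    k2p, k4, binding = 0.5, 0.15, 1.3
    k3 = (binding - 1.0) * k4
    return KineticParameters(
        vb=0.07,
        K1p=vtp_target * k2p / binding,
        k2p=k2p,
        k3=k3,
        k4=k4,
        K1m=0.02,
        k2m=0.06,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of a synthetic cohort."""

    n_subjects: int = 10
    species: str = "human"
    phenotype_fraction: float = 0.5  # subjects with elevated metabolite influx
    k1m_phenotype_factor: float = 3.0
    noise_scale: float = 0.3  # kBq/mL at C = 1 kBq/mL in a 1 s frame
    between_subject_sd: float = 0.2  # lognormal sd of parameter perturbations
    seed: int = 0
    frame_spec: tuple = HRRT_21_FRAME_SPEC
    grid_step_s: float = 1.0
    regions: tuple = tuple(REGION_TABLE)

    def __post_init__(self):
        if not (0.0 <= self.phenotype_fraction <= 1.0):
            raise ValidationError("phenotype fraction must lie in [0, 1]")
        if self.n_subjects < 1:
            raise ValidationError("need at least one subject")

    def phenotype_assignment(self) -> np.ndarray:
        """Deterministic high-K1m flags per subject (exact count, shuffled)."""
        n_high = int(round(self.phenotype_fraction * self.n_subjects))
        flags = np.zeros(self.n_subjects, dtype=bool)
        flags[:n_high] = True
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 7919]))
        return rng.permutation(flags)


@dataclass(frozen=True)
class SubjectData:
    """One synthetic subject: measurements plus generating truth."""

    subject_id: str
    blood: BloodSeries
    fractions: FractionTimeCourse
    inputs: InputFunctionSet  # exact generator input functions on the fine grid
    tacs: dict  # region -> noisy TimeActivityCurve
    whole_brain: TimeActivityCurve
    truth: dict  # region -> KineticParameters
    truth_vtp: dict  # region -> VTp from the defining formula on the truth
    phenotype_late_rise: bool
    n_clamped: int  # negative noisy activities clamped to zero
    seed_sequence: tuple


def generate_plasma(
    seed: int,
    species: str = "human",
    feng: FengPlasma | None = None,
    end_s: float = 5400.0,
    grid_step_s: float = 1.0,
    amplitude_jitter_sd: float = 0.15,
) -> tuple[BloodSeries, InputFunctionSet, FractionTimeCourse]:
    """Blood measurements, exact input functions and HPLC fraction table.

    The continuous (automated) sampling covers the first 10 min at 1 Hz;
    manual samples follow the ~2/5/10/20/40/60/75/90-min schedule.  The
    overall plasma amplitude is jittered log-normally between subjects.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    feng = feng or FengPlasma()
    amp = float(np.exp(rng.normal(0.0, amplitude_jitter_sd)))
    pf_model = species_parent_fraction(species)
    split = DEFAULT_METABOLITE_SPLIT
    share = sum(split[m] for m in PENETRANT_METABOLITES)
    met_curve = MetaboliteFractionCurve(
        parent_model=pf_model,
        share=share,
        sample_times_min=np.asarray(MANUAL_SAMPLE_MINUTES),
        sample_values=share * pf_model.metabolite_fraction(np.asarray(MANUAL_SAMPLE_MINUTES)),
    )

    t_cont_s = np.arange(1.0, 600.0 + 0.5, 1.0)
    t_man_s = np.asarray(MANUAL_SAMPLE_MINUTES) * 60.0
    times = np.concatenate([t_cont_s, t_man_s])
    source = np.array(["continuous"] * t_cont_s.size + ["manual"] * t_man_s.size)
    plasma = amp * feng(times / 60.0)
    wb = plasma / feng.plasma_to_wb_ratio
    blood = BloodSeries(times=times, whole_blood=wb, plasma=plasma, source=source)

    t_grid = np.arange(0.0, end_s + grid_step_s / 2, grid_step_s)
    t_min = t_grid / 60.0
    pl_g = amp * feng(t_min)
    pf = pf_model(t_min)
    inputs = InputFunctionSet(
        t_s=t_grid,
        whole_blood=pl_g / feng.plasma_to_wb_ratio,
        total_plasma=pl_g,
        parent_plasma=pl_g * pf,
        metabolite_plasma=pl_g * met_curve(t_min),
    )

    t_frac = np.asarray(MANUAL_SAMPLE_MINUTES)
    f_parent = pf_model(t_frac)
    metabolised = 1.0 - f_parent
    fractions = FractionTimeCourse(
        times_min=t_frac,
        f_parent=f_parent,
        f_met1=split["met1"] * metabolised,
        f_met2=split["met2"] * metabolised,
        f_met3=split["met3"] * metabolised,
    )
    return blood, inputs, fractions


def _perturb(rng, value: float, sd: float, lo: float = 2e-4, hi: float = 1.9) -> float:
    return float(np.clip(value * np.exp(rng.normal(0.0, sd)), lo, hi))


def generate_subject(config: CohortConfig, subject_index: int) -> SubjectData:
    """Generate one subject's regional TACs with ground truth.

    Truth parameters are log-normal perturbations (sd ``between_subject_sd``)
    of the regional base values; k4 is perturbed once per subject and shared
    by all regions (the homogeneous-k4 assumption behind the dual-run
    procedure).  TACs are 2TDI forward simulations, frame-averaged on the
    21-frame schedule, with frame-dependent Gaussian noise.
    """
    if not (0 <= subject_index < config.n_subjects):
        raise ValidationError("subject index out of range")
    seed_seq = (int(config.seed), int(subject_index))
    rng = np.random.default_rng(np.random.SeedSequence(list(seed_seq)))
    blood, inputs, fractions = generate_plasma(
        seed=config.seed * 100003 + subject_index,
        species=config.species,
        grid_step_s=config.grid_step_s,
    )
    schedule = make_frame_schedule(config.frame_spec)
    phenotype = bool(config.phenotype_assignment()[subject_index])
    sd = config.between_subject_sd
    k4_subject = _perturb(rng, 0.15, sd)

    spec = ModelSpec("2TDI")
    truth: dict[str, KineticParameters] = {}
    truth_vtp: dict[str, float] = {}
    noiseless: dict[str, np.ndarray] = {}
    for region in config.regions:
        vtp_target, _vol = REGION_TABLE[region]
        base = _base_parameters(vtp_target)
        k1m = base.K1m * (config.k1m_phenotype_factor if phenotype else 1.0)
        params = KineticParameters(
            vb=float(np.clip(base.vb * np.exp(rng.normal(0.0, sd)), 0.01, 0.18)),
            K1p=_perturb(rng, base.K1p, sd),
            k2p=_perturb(rng, base.k2p, sd),
            k3=_perturb(rng, base.k3, sd),
            k4=k4_subject,
            K1m=_perturb(rng, k1m, sd),
            k2m=_perturb(rng, base.k2m, sd),
        )
        truth[region] = params
        truth_vtp[region] = distribution_volume(params, spec).vt
        noiseless[region] = simulate_tissue(params, inputs, spec)

    volumes = np.array([REGION_TABLE[r][1] for r in config.regions])
    wb_curve = np.average(
        np.vstack([noiseless[r] for r in config.regions]), axis=0, weights=volumes
    )

    n_clamped = 0
    tacs: dict[str, TimeActivityCurve] = {}
    for region in config.regions:
        clean = frame_average(noiseless[region], inputs.t_s, schedule, region=region).activity
        noisy, nc = _add_frame_noise(rng, clean, schedule, config.noise_scale)
        n_clamped += nc
        tacs[region] = TimeActivityCurve(activity=noisy, schedule=schedule, region=region)
    wb_clean = frame_average(wb_curve, inputs.t_s, schedule, region="whole_brain").activity
    wb_noisy, nc = _add_frame_noise(rng, wb_clean, schedule, config.noise_scale)
    n_clamped += nc
    whole_brain = TimeActivityCurve(activity=wb_noisy, schedule=schedule, region="whole_brain")

    return SubjectData(
        subject_id=f"sub-{subject_index + 1:02d}",
        blood=blood,
        fractions=fractions,
        inputs=inputs,
        tacs=tacs,
        whole_brain=whole_brain,
        truth=truth,
        truth_vtp=truth_vtp,
        phenotype_late_rise=phenotype,
        n_clamped=n_clamped,
        seed_sequence=seed_seq,
    )


def _add_frame_noise(rng, clean: np.ndarray, schedule: FrameSchedule, noise_scale: float):
    """Zero-mean Gaussian frame noise, sd = noise_scale sqrt(C / dt)."""
    if noise_scale == 0.0:
        return clean.copy(), 0
    sd = noise_scale * np.sqrt(np.clip(clean, 0.0, None) / schedule.duration)
    noisy = clean + rng.normal(0.0, 1.0, clean.size) * sd
    n_clamped = int(np.sum(noisy < 0))
    return np.clip(noisy, 0.0, None), n_clamped


def generate_cohort(
    config: CohortConfig, out_dir=None, overwrite: bool = False
) -> list[SubjectData]:
    """Generate all subjects; optionally write the study bundle to disk.

    The on-disk layout is one folder per subject (``tacs.tsv``,
    ``blood.tsv``, ``fractions.tsv``, ``inputs.tsv``) plus a JSON manifest
    with seeds and ground truth; regeneration from the same master seed is
    byte-identical.
    """
    subjects = [generate_subject(config, i) for i in range(config.n_subjects)]
    if out_dir is not None:
        out = Path(out_dir)
        if out.exists() and any(out.iterdir()):
            if not overwrite:
                raise FileExistsError(f"{out} exists and is not empty (use overwrite)")
            shutil.rmtree(out)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "config": {
                **{
                    k: v
                    for k, v in asdict(config).items()
                    if k not in ("frame_spec", "regions")
                },
                "frame_spec": [list(g) for g in config.frame_spec],
                "regions": list(config.regions),
            },
            "subjects": {},
        }
        for sub in subjects:
            sdir = out / sub.subject_id
            sdir.mkdir()
            curves = [sub.tacs[r] for r in config.regions] + [sub.whole_brain]
            write_tac_table(curves, sdir / "tacs.tsv", {"isotope": "C-11"})
            write_blood_table(sub.blood, sdir / "blood.tsv")
            write_fraction_table(sub.fractions, sdir / "fractions.tsv")
            sub.inputs.write(sdir / "inputs.tsv")
            manifest["subjects"][sub.subject_id] = {
                "seed_sequence": list(sub.seed_sequence),
                "phenotype_late_rise": sub.phenotype_late_rise,
                "n_clamped": sub.n_clamped,
                "truth": {r: p.as_dict() for r, p in sub.truth.items()},
                "truth_vtp": dict(sub.truth_vtp),
            }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return subjects
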