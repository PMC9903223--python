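"""Forward compartment models for the parent tracer and its brain-penetrant
radiometabolites, with a fractional blood-volume term.

Model kinds
-----------
``2TSI`` / ``2TSI_k4fix``
    Two-tissue compartment model driven by the parent plasma input alone
    (free parameters VB, K1, k2, k3, k4; the ``_k4fix`` variant fixes k4).
``1TDI``
    One-tissue parent compartment plus a one-tissue metabolite compartment
    driven by the metabolite plasma input (VB, K1p, k2p, K1m, k2m).
``2TDI`` / ``2TDI_k4fix``
    Two-tissue parent kinetics plus the one-tissue metabolite compartment
    (VB, K1p, k2p, k3, k4, K1m, k2m).

The measured PET concentration mixes tissue and blood:

    C_model(t) = (1 - VB) * [C_parent_tissue(t) + C_met_tissue(t)]
                 + VB * C_whole_blood(t)

Tissue responses are computed by exact exponential convolution of the
piecewise-linear input with the analytic impulse response (the two-tissue
eigenvalues come from the k2 + k3 + k4 system), so the solution is exact for
a piecewise-linear input rather than subject to quadrature error.

Rate constants are per minute and K1 in mL·cm^-3·min^-1; grids are in
seconds and converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .data import FrameSchedule, TimeActivityCurve, ValidationError
from .metabolites import InputFunctionSet

__all__ = [
    "KineticParameters",
    "ModelSpec",
    "MODEL_KINDS",
    "DistributionVolumes",
    "exponential_convolution",
    "simulate_tissue",
    "frame_average",
    "distribution_volume",
]

#: Free-parameter names per model kind (fixed parameters in ``fixed`` of the
#: ModelSpec).  ``2TSI`` is the full single-input model used as step 1 of the
#: dual-run procedure.
MODEL_KINDS: dict[str, tuple[str, ...]] = {
    "2TSI": ("vb", "K1p", "k2p", "k3", "k4"),
    "2TSI_k4fix": ("vb", "K1p", "k2p", "k3"),
    "1TDI": ("vb", "K1p", "k2p", "K1m", "k2m"),
    "2TDI": ("vb", "K1p", "k2p", "k3", "k4", "K1m", "k2m"),
    "2TDI_k4fix": ("vb", "K1p", "k2p", "k3", "K1m", "k2m"),
}

_DUAL_KINDS = {"1TDI", "2TDI", "2TDI_k4fix"}
_TWO_TISSUE_KINDS = {"2TSI", "2TSI_k4fix", "2TDI", "2TDI_k4fix"}


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the dual-input model; absent parameters are None.

    vb is the unitless blood-volume fraction; K1p/K1m are plasma-to-tissue
    clearances (mL·cm^-3·min^-1); k2p, k3, k4, k2m are first-order rate
    constants (min^-1).  Parent-only models use K1p/k2p as their K1/k2.
    """

    vb: float
    K1p: float
    k2p: float
    k3: float | None = None
    k4: float | None = None
    K1m: float | None = None
    k2m: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.vb <= 1.0):
            raise ValidationError("blood volume fraction must lie in [0, 1]")
        for name in ("K1p", "k2p", "k3", "k4", "K1m", "k2m"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be non-negative")

    def as_dict(self) -> dict[str, float | None]:
        return {
            name: getattr(self, name)
            for name in ("vb", "K1p", "k2p", "k3", "k4", "K1m", "k2m")
        }


@dataclass(frozen=True)
class ModelSpec:
    """A model kind plus its fixed-parameter values (e.g. k4 in dual runs)."""

    kind: str
    fixed: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValidationError(
                f"unknown model kind {self.kind!r}; choose from {sorted(MODEL_KINDS)}"
            )
        free = MODEL_KINDS[self.kind]
        for name in self.fixed:
            if name in free:
                raise ValidationError(f"parameter {name} is free in kind {self.kind}")
        if self.kind.endswith("_k4fix") and "k4" not in self.fixed:
            raise ValidationError(f"kind {self.kind} requires a fixed k4 value")

    @property
    def free_names(self) -> tuple[str, ...]:
        return MODEL_KINDS[self.kind]

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    @property
    def uses_metabolite_input(self) -> bool:
        return self.kind in _DUAL_KINDS

    def build_parameters(self, free_values) -> KineticParameters:
        """Assemble full parameters from free values plus the fixed ones."""
        kw = dict(zip(self.free_names, (float(v) for v in free_values)))
        kw.update(self.fixed)
        return KineticParameters(**kw)


@dataclass(frozen=True)
class DistributionVolumes:
    """Total distribution volume and its factor decomposition."""

    vt: float  # VT (single input) or VTp (dual input), mL·cm^-3
    k1_over_k2: float
    binding_term: float  # 1 + k3/k4, or 1.0 for one-tissue models
    label: str  # "VT" | "VTp"


def exponential_convolution(c: np.ndarray, dt_min: float, lam: float) -> np.ndarray:
    """Exact ``int_0^t c(s) exp(-lam (t - s)) ds`` for piecewise-linear c.

    ``c`` is sampled on a uniform grid with spacing ``dt_min`` (minutes);
    ``lam`` is per minute.  Evaluated with a one-pole recursive filter, so the
    cost is linear in the grid length and the only approximation is the
    piecewise-linear representation of the input itself.
    """
    c = np.asarray(c, dtype=float)
    out = np.zeros_like(c)
    if c.size < 2:
        return out
    c0 = c[:-1]
    m = (c[1:] - c[:-1]) / dt_min
    x = lam * dt_min
    if abs(x) < 1e-8:
        seg = dt_min * (c0 + c[1:]) / 2.0
        out[1:] = np.cumsum(seg)
        return out
    e = np.exp(-x)
    alpha = -np.expm1(-x) / lam  # (1 - e^{-lam dt}) / lam, accurate for small x
    seg = c0 * alpha + m * (dt_min - alpha) / lam
    out[1:] = lfilter([1.0], [1.0, -e], seg)
    return out


def _two_tissue_response(cp, dt_min, K1, k2, k3, k4):
    """Analytic two-tissue solution C1 + C2 driven by input cp."""
    if k3 == 0.0:
        return K1 * exponential_convolution(cp, dt_min, k2)
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    if disc < 0:
        raise ValidationError("negative eigenvalue discriminant in two-tissue system")
    root = np.sqrt(disc)
    a1 = (s - root) / 2.0
    a2 = (s + root) / 2.0
    if a2 - a1 < 1e-12:  # k3 > 0 makes this unreachable except by rounding
        return K1 * exponential_convolution(cp, dt_min, k2)
    b1 = (k3 + k4 - a1) / (a2 - a1)
    b2 = (a2 - k3 - k4) / (a2 - a1)
    return K1 * (
        b1 * exponential_convolution(cp, dt_min, a1)
        + b2 * exponential_convolution(cp, dt_min, a2)
    )


def simulate_tissue(
    params: KineticParameters, inputs: InputFunctionSet, spec: ModelSpec
) -> np.ndarray:
    """Continuous model concentration on the input grid (kBq/mL).

    The parent tissue follows one- or two-tissue kinetics driven by the
    parent plasma input; dual-input kinds add a one-tissue metabolite
    compartment (K1m, k2m) driven by the metabolite plasma input; the blood
    volume fraction mixes in the whole-blood curve.
    """
    dt_min = inputs.dt_s / 60.0
    if inputs.dt_s > 1.0 + 1e-9:
        import warnings

        warnings.warn("input grid coarser than 1 s; early bolus frames may be inaccurate")
    if spec.kind in _TWO_TISSUE_KINDS:
        if params.k3 is None or params.k4 is None:
            raise ValidationError(f"kind {spec.kind} requires k3 and k4")
        ct_parent = _two_tissue_response(
            inputs.parent_plasma, dt_min, params.K1p, params.k2p, params.k3, params.k4
        )
    else:
        ct_parent = params.K1p * exponential_convolution(
            inputs.parent_plasma, dt_min, params.k2p
        )
    ct = ct_parent
    if spec.uses_metabolite_input:
        if params.K1m is None or params.k2m is None:
            raise ValidationError(f"kind {spec.kind} requires K1m and k2m")
        ct = ct + params.K1m * exponential_convolution(
            inputs.metabolite_plasma, dt_min, params.k2m
        )
    return (1.0 - params.vb) * ct + params.vb * inputs.whole_blood


def frame_average(
    curve: np.ndarray,
    t_s: np.ndarray,
    schedule: FrameSchedule,
    region: str = "",
) -> TimeActivityCurve:
    """Average a continuous curve over each frame interval.

    Frame values are time-averages (trapezoidal integral over the frame
    divided by its duration), matching how reconstructed frames integrate
    counts — not midpoint samples.  Exact for curves linear within a frame.
    """
    t_s = np.asarray(t_s, dtype=float)
    curve = np.asarray(curve, dtype=float)
    if schedule.total_duration > t_s[-1] + 1e-9 or schedule.start[0] < t_s[0] - 1e-9:
        raise ValidationError("curve does not cover the frame schedule")
    from scipy.integrate import cumulative_trapezoid

    cum = np.concatenate([[0.0], cumulative_trapezoid(curve, t_s)])
    lo = np.interp(schedule.start, t_s, cum)
    hi = np.interp(schedule.end, t_s, cum)
    means = (hi - lo) / schedule.duration
    return TimeActivityCurve(activity=means, schedule=schedule, region=region)


def distribution_volume(params: KineticParameters, spec: ModelSpec) -> DistributionVolumes:
    """Total distribution volume of the model.

    One-tissue: VTp = K1p / k2p.  Two-tissue: VT(p) = (K1 / k2)(1 + k3 / k4).
    Dual-input volumes are labelled VTp (unchanged-radioligand volume); the
    metabolite-compartment parameters never enter.
    """
    if params.k2p <= 0:
        raise ValidationError("distribution volume undefined for k2 = 0")
    ratio = params.K1p / params.k2p
    label = "VTp" if spec.uses_metabolite_input else "VT"
    if spec.kind in _TWO_TISSUE_KINDS:
        if params.k3 is None or params.k4 is None:
            raise ValidationError("two-tissue volume requires k3 and k4")
        if params.k3 > 0 and params.k4 <= 0:
            raise ValidationError("distribution volume undefined for k4 = 0 with k3 > 0")
        binding = 1.0 + (params.k3 / params.k4 if params.k3 > 0 else 0.0)
    else:
        binding = 1.0
    return DistributionVolumes(
        vt=ratio * binding, k1_over_k2=ratio, binding_term=binding, label=label
    )
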