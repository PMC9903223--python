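"""Weighted nonlinear least-squares estimation of the compartment models.

The public surface follows the statsmodels convention: build a
:class:`KineticModel` from a measured TAC plus input functions, call
``fit()``, and receive a :class:`KineticModelResults` carrying estimates,
their %SE, goodness-of-fit and QC flags, with ``summary()`` for a report.

Estimation details
------------------
* Frame-averaged model predictions are compared to the measured frame
  values under weights proportional to frame_duration / max(activity, floor)
  — an approximation to count statistics (long, low-activity frames are the
  most precise after decay correction).  Uniform weighting is available.
* The 5-7 parameter likelihood surface is multimodal, so fitting restarts
  from Latin-hypercube draws over the parameter bounds (rates drawn
  log-uniformly); the best weighted RSS wins, ties broken by the smaller
  parameter norm.  A fixed seed makes the procedure bit-reproducible.
* Parameter covariance is the scaled inverse Gauss-Newton information at
  the optimum, RSS_w / (n - p) * (J'J)^-1; %SE of the distribution volume
  follows by first-order (delta-method) propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares
from scipy.stats import qmc

from .data import TimeActivityCurve, ValidationError
from .kinetics import (
    MODEL_KINDS,
    DistributionVolumes,
    KineticParameters,
    ModelSpec,
    distribution_volume,
    simulate_tissue,
)
from .metabolites import InputFunctionSet
from .selection import aic as _aic

__all__ = [
    "DEFAULT_BOUNDS",
    "FitConfig",
    "KineticModel",
    "KineticModelResults",
    "fit_region",
    "dual_run_fit",
    "DualRunResults",
    "qc_filter",
    "QCPartition",
]

#: Generous physiologic bounds around the reported medians (VB median 0.07,
#: rate constants well under 2 min^-1 for this tracer).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "vb": (0.0, 0.2),
    "K1p": (1e-4, 2.0),
    "k2p": (1e-4, 2.0),
    "k3": (1e-4, 2.0),
    "k4": (1e-4, 2.0),
    "K1m": (1e-4, 2.0),
    "k2m": (1e-4, 2.0),
}


@dataclass(frozen=True)
class FitConfig:
    """Estimation settings shared across regions and models."""

    weighting: str = "duration_over_activity"  # or "uniform"
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    n_starts: int = 10
    seed: int = 0
    qc_se_threshold: float = 50.0  # % SE of VT/VTp above which a fit is flagged
    activity_floor_frac: float = 0.05
    xtol: float = 1e-10
    max_nfev: int | None = None

    def __post_init__(self):
        if self.qc_se_threshold <= 0:
            raise ValidationError("QC threshold must be positive")
        if self.weighting not in ("duration_over_activity", "uniform"):
            raise ValidationError(f"unknown weighting {self.weighting!r}")
        if self.n_starts < 1:
            raise ValidationError("need at least one start")


class KineticModel:
    """A compartment model bound to one measured regional TAC.

    Parameters
    ----------
    tac : TimeActivityCurve
        Frame-based, decay-corrected regional curve.
    inputs : InputFunctionSet
        Input functions on a uniform grid covering the frame schedule.
    kind : str or ModelSpec
        One of ``2TSI``, ``2TSI_k4fix``, ``1TDI``, ``2TDI``, ``2TDI_k4fix``;
        the ``_k4fix`` kinds require ``fixed={"k4": value}``.
    """

    def __init__(
        self,
        tac: TimeActivityCurve,
        inputs: InputFunctionSet,
        kind: str | ModelSpec,
        fixed: dict | None = None,
        config: FitConfig | None = None,
    ):
        if tac.schedule is None:
            raise ValidationError("fitting requires a frame-based TAC")
        if not tac.decay_corrected:
            raise ValidationError("decay-correct the TAC before fitting")
        self.tac = tac
        self.inputs = inputs
        self.spec = kind if isinstance(kind, ModelSpec) else ModelSpec(kind, fixed or {})
        self.config = config or FitConfig()
        sched = tac.schedule
        if sched.total_duration > inputs.t_s[-1] + 1e-9:
            raise ValidationError("input functions do not cover the frame schedule")
        # frame-averaging operator: cumulative-integral lookups at frame edges
        self._t_s = inputs.t_s
        self._dur = sched.duration
        self._edges_lo = sched.start
        self._edges_hi = sched.end
        self._y = tac.activity
        self._weights = self._make_weights()

    # -- internals ---------------------------------------------------------

    def _make_weights(self) -> np.ndarray:
        if self.config.weighting == "uniform":
            w = np.ones_like(self._y)
        else:
            floor = self.config.activity_floor_frac * float(np.max(self._y))
            floor = max(floor, 1e-12)
            w = (self._dur / 60.0) / np.maximum(self._y, floor)
        return w / np.mean(w)

    def _frame_means(self, curve: np.ndarray) -> np.ndarray:
        cum = np.concatenate([[0.0], cumulative_trapezoid(curve, self._t_s)])
        lo = np.interp(self._edges_lo, self._t_s, cum)
        hi = np.interp(self._edges_hi, self._t_s, cum)
        return (hi - lo) / self._dur

    def predict(self, free_values) -> np.ndarray:
        """Frame-averaged model prediction for a free-parameter vector."""
        params = self.spec.build_parameters(free_values)
        return self._frame_means(simulate_tissue(params, self.inputs, self.spec))

    def _residuals(self, theta, sqrt_w):
        return sqrt_w * (self.predict(theta) - self._y)

    def _bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for name in self.spec.free_names:
            b = self.config.bounds.get(name, DEFAULT_BOUNDS[name])
            lo.append(b[0])
            hi.append(b[1])
        return np.asarray(lo), np.asarray(hi)

    def _starting_points(self, lo, hi) -> np.ndarray:
        """One heuristic start plus Latin-hypercube draws over the bounds."""
        names = self.spec.free_names
        heuristic = []
        for name, l, h in zip(names, lo, hi):
            if name == "vb":
                heuristic.append(min(max(0.05, l), h))
            else:
                heuristic.append(np.sqrt(max(l, 1e-6) * h) / 4.0)
        starts = [np.clip(heuristic, lo, hi)]
        n_lhs = self.config.n_starts - 1
        if n_lhs > 0:
            sampler = qmc.LatinHypercube(d=len(names), seed=self.config.seed)
            u = sampler.random(n_lhs)
            for row in u:
                pt = []
                for name, l, h, ui in zip(names, lo, hi, row):
                    if name == "vb":
                        pt.append(l + ui * (h - l))
                    else:  # log-uniform over the positive range
                        ll, lh = np.log(max(l, 1e-6)), np.log(h)
                        pt.append(np.exp(ll + ui * (lh - ll)))
                starts.append(np.clip(pt, lo, hi))
        return np.asarray(starts)

    # -- fitting -----------------------------------------------------------

    def fit(self, extra_starts=None) -> "KineticModelResults":
        """Multi-start weighted least squares; returns the best fit found.

        ``extra_starts`` (sequence of free-parameter vectors) are appended to
        the default start set — used by the dual-run procedure and nested
        comparisons to seed the full model with a reduced-model solution.
        """
        lo, hi = self._bounds_arrays()
        sqrt_w = np.sqrt(self._weights)
        starts = list(self._starting_points(lo, hi))
        for s in extra_starts or []:
            starts.append(np.clip(np.asarray(s, dtype=float), lo, hi))

        best = None
        for theta0 in starts:
            try:
                sol = least_squares(
                    self._residuals,
                    theta0,
                    args=(sqrt_w,),
                    bounds=(lo, hi),
                    method="trf",
                    xtol=self.config.xtol,
                    ftol=1e-10,
                    gtol=1e-10,
                    max_nfev=self.config.max_nfev,
                )
            except Exception:
                continue
            rss_w = 2.0 * sol.cost
            if best is None:
                best = sol
            else:
                b_rss = 2.0 * best.cost
                if rss_w < b_rss - 1e-12 * max(b_rss, 1.0) or (
                    abs(rss_w - b_rss) <= 1e-12 * max(b_rss, 1.0)
                    and np.linalg.norm(sol.x) < np.linalg.norm(best.x)
                ):
                    best = sol
        if best is None:
            raise RuntimeError("all optimization starts failed")
        return self._package(best, lo, hi, sqrt_w)

    def _package(self, sol, lo, hi, sqrt_w) -> "KineticModelResults":
        theta = sol.x
        n, p = self._y.size, theta.size
        fitted = self.predict(theta)
        resid = fitted - self._y
        rss = float(np.sum(resid**2))
        rss_w = float(np.sum(self._weights * resid**2))
        dof = max(n - p, 1)
        J = sol.jac
        JtJ = J.T @ J
        try:
            cov = np.linalg.pinv(JtJ) * (rss_w / dof)
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        span = hi - lo
        at_bounds = [
            name
            for name, th, l, h, s in zip(self.spec.free_names, theta, lo, hi, span)
            if th - l < 1e-3 * s or h - th < 1e-3 * s
        ]
        converged = bool(sol.status > 0 and np.all(np.isfinite(theta)) and np.all(np.isfinite(se)))
        params = self.spec.build_parameters(theta)
        vols = distribution_volume(params, self.spec)
        vt_se = _delta_vt_se(self.spec, params, theta, cov)
        return KineticModelResults(
            model=self,
            spec=self.spec,
            theta=theta,
            params=params,
            cov=cov,
            se=se,
            rss=rss,
            rss_weighted=rss_w,
            n_frames=n,
            n_free=p,
            fitted=fitted,
            converged=converged,
            at_bounds=tuple(at_bounds),
            volumes=vols,
            vt_se=vt_se,
            qc_se_threshold=self.config.qc_se_threshold,
        )


def _delta_vt_se(spec: ModelSpec, params: KineticParameters, theta, cov) -> float:
    """Standard error of VT/VTp by first-order propagation through its formula."""
    vols = distribution_volume(params, spec)
    grads = {
        "K1p": vols.vt / params.K1p if params.K1p > 0 else 0.0,
        "k2p": -vols.vt / params.k2p,
    }
    if vols.binding_term != 1.0 or spec.kind in ("2TSI", "2TSI_k4fix", "2TDI", "2TDI_k4fix"):
        if params.k4 and params.k4 > 0:
            grads["k3"] = (params.K1p / params.k2p) / params.k4
            grads["k4"] = -(params.K1p / params.k2p) * (params.k3 or 0.0) / params.k4**2
    g = np.array([grads.get(name, 0.0) for name in spec.free_names])
    var = float(g @ cov @ g)
    return float(np.sqrt(max(var, 0.0)))


@dataclass(frozen=True)
class KineticModelResults:
    """Estimates, uncertainties and diagnostics of one regional fit."""

    model: KineticModel
    spec: ModelSpec
    theta: np.ndarray
    params: KineticParameters
    cov: np.ndarray
    se: np.ndarray
    rss: float
    rss_weighted: float
    n_frames: int
    n_free: int
    fitted: np.ndarray
    converged: bool
    at_bounds: tuple
    volumes: DistributionVolumes
    vt_se: float
    qc_se_threshold: float

    @property
    def vt(self) -> float:
        """VT (single input) or VTp (dual input), mL·cm^-3."""
        return self.volumes.vt

    @property
    def percent_se(self) -> dict[str, float]:
        """%SE of each free parameter (100 * SE / |estimate|)."""
        out = {}
        for name, th, s in zip(self.spec.free_names, self.theta, self.se):
            out[name] = float(100.0 * s / abs(th)) if abs(th) > 0 else np.inf
        return out

    @property
    def vt_percent_se(self) -> float:
        """%SE of the distribution volume via the delta method."""
        return float(100.0 * self.vt_se / self.vt) if self.vt > 0 else np.inf

    @property
    def aic(self) -> float:
        """Least-squares AIC, n ln(RSS/n) + 2p, on the unweighted RSS."""
        return _aic(self.rss, self.n_frames, self.n_free)

    @property
    def aic_weighted(self) -> float:
        """AIC variant computed on the weighted RSS."""
        return _aic(self.rss_weighted, self.n_frames, self.n_free)

    @property
    def qc_pass(self) -> bool:
        """True when the fit converged and %SE(VT) is within the QC threshold."""
        return bool(self.converged and self.vt_percent_se <= self.qc_se_threshold)

    @property
    def region(self) -> str:
        return self.model.tac.region

    def to_record(self) -> dict:
        """Flat record for fit tables (one row per region x model)."""
        rec = {
            "region": self.region,
            "model": self.spec.kind,
            "vt": self.vt,
            "vt_label": self.volumes.label,
            "pse_vt": self.vt_percent_se,
            "rss": self.rss,
            "rss_weighted": self.rss_weighted,
            "n_frames": self.n_frames,
            "n_free": self.n_free,
            "aic": self.aic,
            "converged": self.converged,
            "qc_pass": self.qc_pass,
        }
        for name, value in self.params.as_dict().items():
            if value is not None:
                rec[name] = value
        for name, pse in self.percent_se.items():
            rec[f"pse_{name}"] = pse
        return rec

    def summary(self) -> str:
        """Plain-text summary table in the spirit of statsmodels results."""
        lines = [
            f"Kinetic model fit: {self.spec.kind}"
            + (f"  [fixed: {self.spec.fixed}]" if self.spec.fixed else ""),
            f"Region: {self.region or '<unnamed>'}   frames: {self.n_frames}"
            f"   free parameters: {self.n_free}",
            f"RSS {self.rss:.5g}   weighted RSS {self.rss_weighted:.5g}"
            f"   AIC {self.aic:.2f}   converged: {self.converged}",
            "-" * 58,
            f"{'parameter':>10} {'estimate':>12} {'SE':>12} {'%SE':>8}",
        ]
        for name, th, s in zip(self.spec.free_names, self.theta, self.se):
            pse = self.percent_se[name]
            lines.append(f"{name:>10} {th:12.5g} {s:12.3g} {pse:8.1f}")
        lines.append("-" * 58)
        lines.append(
            f"{self.volumes.label:>10} {self.vt:12.5g} {self.vt_se:12.3g}"
            f" {self.vt_percent_se:8.1f}"
        )
        if self.at_bounds:
            lines.append(f"note: parameters at a bound: {', '.join(self.at_bounds)}")
        if not self.qc_pass:
            lines.append(
                f"QC: FLAGGED (%SE {self.volumes.label} > {self.qc_se_threshold:g}%"
                " or non-convergence)"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Measured frames vs fitted curve on a minutes axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sched = self.model.tac.schedule
        ax.plot(sched.mid / 60.0, self.model.tac.activity, "o", label="measured")
        ax.plot(sched.mid / 60.0, self.fitted, "-", label=f"{self.spec.kind} fit")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("activity (kBq/mL)")
        ax.legend()
        return ax


def fit_region(
    tac: TimeActivityCurve,
    inputs: InputFunctionSet,
    spec: str | ModelSpec,
    config: FitConfig | None = None,
    extra_starts=None,
) -> KineticModelResults:
    """Convenience wrapper: build the model and fit in one call."""
    fixed = spec.fixed if isinstance(spec, ModelSpec) else None
    kind = spec.kind if isinstance(spec, ModelSpec) else spec
    return KineticModel(tac, inputs, kind, fixed=fixed, config=config).fit(
        extra_starts=extra_starts
    )


@dataclass(frozen=True)
class DualRunResults:
    """Step-1 whole-brain fit plus k4-fixed regional fits."""

    whole_brain: KineticModelResults
    regions: dict
    k4_fixed: float
    k4_at_bound: bool


def dual_run_fit(
    whole_brain_tac: TimeActivityCurve,
    region_tacs: dict,
    inputs: InputFunctionSet,
    kind: str = "2TDI",
    config: FitConfig | None = None,
) -> DualRunResults:
    """Two-step k4-fixing procedure for 2TSI or 2TDI.

    Step 1 fits the full model on the whole-brain grey-matter TAC; step 2
    fixes k4 at the step-1 estimate and refits every region with the reduced
    parameter set (stabilising VT/VTp estimation in small regions).  The
    step-1 estimate also seeds the regional fits.
    """
    if kind not in ("2TSI", "2TDI"):
        raise ValidationError("dual-run procedure applies to 2TSI or 2TDI")
    config = config or FitConfig()
    step1 = KineticModel(whole_brain_tac, inputs, kind, config=config).fit()
    if not step1.converged:
        raise RuntimeError(
            "whole-brain (step 1) fit did not converge; cannot fix k4 "
            f"(status of {kind} fit: at_bounds={step1.at_bounds})"
        )
    k4_hat = float(step1.params.k4)
    k4_at_bound = "k4" in step1.at_bounds
    if k4_at_bound:
        import warnings

        warnings.warn("step-1 k4 estimate is at a bound; propagated to all regions")
    fixed_kind = kind + "_k4fix"
    names1 = MODEL_KINDS[kind]
    seed_start = [
        step1.theta[names1.index(n)] for n in MODEL_KINDS[fixed_kind]
    ]
    out = {}
    for region, tac in region_tacs.items():
        res = KineticModel(
            tac, inputs, fixed_kind, fixed={"k4": k4_hat}, config=config
        ).fit(extra_starts=[seed_start])
        out[region] = res
    return DualRunResults(
        whole_brain=step1, regions=out, k4_fixed=k4_hat, k4_at_bound=k4_at_bound
    )


@dataclass(frozen=True)
class QCPartition:
    kept: list
    excluded: list
    excluded_percentage: float  # rounded to one decimal


def qc_filter(results, threshold: float | None = None) -> QCPartition:
    """Partition fits by the %SE-of-VT reliability criterion.

    A region is excluded when %SE of its distribution volume exceeds the
    threshold (default: the fit's own configured threshold, 50%) or when the
    fit failed to converge (flagged distinctly via ``converged``).
    """
    kept, excluded = [], []
    for res in results:
        thr = threshold if threshold is not None else res.qc_se_threshold
        ok = res.converged and res.vt_percent_se <= thr
        (kept if ok else excluded).append(res)
    total = len(kept) + len(excluded)
    # report half-up to one decimal (9/80 -> 11.3%), not banker's rounding
    pct = float(np.floor(1000.0 * len(excluded) / total + 0.5) / 10.0) if total else 0.0
    return QCPartition(kept=kept, excluded=excluded, excluded_percentage=pct)
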