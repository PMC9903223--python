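"""Cohort-level orchestration: load a study bundle from disk, fit the
requested model kinds for every subject and region, and assemble the
model-comparison and agreement reports.

This is the library backing the command-line interface; every number in the
emitted reports is computed here and traceable to a TSV cell.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import TimeActivityCurve, ValidationError
from .io import read_blood_table, read_tac_table, write_fit_table
from .metabolites import (
    InputFunctionSet,
    build_input_set,
    combine_metabolite_fractions,
    fit_parent_fraction,
    read_fraction_table,
)
from .model import FitConfig, KineticModel, dual_run_fit, qc_filter
from .selection import (
    compare_estimates,
    cov_across,
    f_test_nested,
    percent_better_fit,
)

__all__ = [
    "DEFAULT_MODELS",
    "SubjectBundle",
    "load_subject_dir",
    "fit_cohort_dir",
    "summarize_fit_table",
    "compare_fit_table",
]

logger = logging.getLogger("duokin")

DEFAULT_MODELS: tuple[str, ...] = ("2TSI_k4fix", "2TDI", "2TDI_k4fix", "1TDI")

#: Model contrasts reported in the comparison table: reduced vs the full 2TDI.
_CONTRASTS: tuple[tuple[str, str], ...] = (("2TDI", "2TDI_k4fix"), ("2TDI", "1TDI"))


@dataclass
class SubjectBundle:
    subject_id: str
    tacs: dict  # region -> TimeActivityCurve (whole_brain excluded)
    whole_brain: TimeActivityCurve | None
    inputs: InputFunctionSet


def load_subject_dir(sdir: Path) -> SubjectBundle:
    """Load one subject folder (tacs + input functions).

    Prefers a pre-built ``inputs.tsv``; otherwise rebuilds the dual input
    functions from ``blood.tsv`` and ``fractions.tsv`` (Hill fit of the
    parent fraction, pooled penetrant-metabolite curve).  Raises
    FileNotFoundError when blood/plasma data are incomplete.
    """
    sdir = Path(sdir)
    tac_path = sdir / "tacs.tsv"
    if not tac_path.exists():
        raise FileNotFoundError("missing tacs.tsv")
    curves = read_tac_table(tac_path)
    tacs = {c.region: c for c in curves if c.region != "whole_brain"}
    whole_brain = next((c for c in curves if c.region == "whole_brain"), None)
    end_s = curves[0].schedule.total_duration + 15.0

    if (sdir / "inputs.tsv").exists():
        inputs = InputFunctionSet.read(sdir / "inputs.tsv")
    elif (sdir / "blood.tsv").exists() and (sdir / "fractions.tsv").exists():
        blood = read_blood_table(sdir / "blood.tsv")
        ftc = read_fraction_table(sdir / "fractions.tsv")
        pf_fit = fit_parent_fraction(ftc.times_min, ftc.f_parent)
        met_curve = combine_metabolite_fractions(ftc, parent_model=pf_fit.model)
        inputs = build_input_set(blood, pf_fit.model, met_curve, end_s=end_s)
    else:
        raise FileNotFoundError("incomplete blood and plasma data")
    if inputs.t_s[-1] < curves[0].schedule.total_duration:
        raise ValidationError("input functions do not cover the scan")
    return SubjectBundle(
        subject_id=sdir.name, tacs=tacs, whole_brain=whole_brain, inputs=inputs
    )


def _fit_subject(bundle: SubjectBundle, models, config: FitConfig) -> list[dict]:
    rows: list[dict] = []
    for kind in models:
        if kind.endswith("_k4fix"):
            if bundle.whole_brain is None:
                raise ValidationError(
                    f"{kind} needs a whole_brain TAC for the dual-run step 1"
                )
            base = kind.replace("_k4fix", "")
            dual = dual_run_fit(
                bundle.whole_brain, bundle.tacs, bundle.inputs, kind=base, config=config
            )
            logger.info(
                "%s %s: k4 fixed at %.5g from whole-brain fit%s",
                bundle.subject_id,
                kind,
                dual.k4_fixed,
                " (at bound)" if dual.k4_at_bound else "",
            )
            results = dual.regions.values()
        else:
            results = [
                KineticModel(tac, bundle.inputs, kind, config=config).fit()
                for tac in bundle.tacs.values()
            ]
        for res in results:
            rec = {"subject": bundle.subject_id}
            rec.update(res.to_record())
            rows.append(rec)
    return rows


def fit_cohort_dir(
    cohort_dir,
    models=DEFAULT_MODELS,
    config: FitConfig | None = None,
    out_path=None,
) -> tuple[pd.DataFrame, list[str]]:
    """Fit all requested model kinds for every complete subject folder.

    Subjects with incomplete blood/plasma data are skipped with a logged
    reason (mirroring cohort-level exclusions), not raised.  Returns the
    pooled long-format fit table and the exclusion log.
    """
    config = config or FitConfig()
    cohort_dir = Path(cohort_dir)
    subject_dirs = sorted(d for d in cohort_dir.iterdir() if d.is_dir() and d.name.startswith("sub-"))
    if not subject_dirs:
        raise FileNotFoundError(f"no subject folders (sub-*) under {cohort_dir}")
    rows: list[dict] = []
    exclusions: list[str] = []
    for sdir in subject_dirs:
        try:
            bundle = load_subject_dir(sdir)
        except (FileNotFoundError, ValidationError) as exc:
            msg = f"{sdir.name} excluded: {exc}"
            logger.warning(msg)
            exclusions.append(msg)
            continue
        rows.extend(_fit_subject(bundle, models, config))
    table = pd.DataFrame(rows)
    if out_path is not None:
        write_fit_table(
            table,
            out_path,
            {
                "models": ",".join(models),
                "n_subjects": str(len(subject_dirs) - len(exclusions)),
                "n_excluded": str(len(exclusions)),
            },
        )
    return table, exclusions


def _median_range(values, decimals: int) -> str:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return "n/a"
    return (
        f"{np.median(v):.{decimals}f} "
        f"({np.min(v):.{decimals}f}–{np.max(v):.{decimals}f})"
    )


def summarize_fit_table(table: pd.DataFrame) -> pd.DataFrame:
    """Region x model summary of distribution volumes and their %SE.

    Medians and ranges across subjects, volumes to 2 decimals and
    percentages to 1 decimal — the reporting convention of the fit tables.
    """
    rows = []
    for (region, model), grp in table.groupby(["region", "model"], sort=False):
        rows.append(
            {
                "region": region,
                "model": model,
                "vt_label": grp["vt_label"].iloc[0],
                "vt_median_range": _median_range(grp["vt"], 2),
                "pse_vt_median_range": _median_range(grp["pse_vt"], 1),
                "n_subjects": int(len(grp)),
                "n_qc_failed": int((~grp["qc_pass"].astype(bool)).sum()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class _ResultProxy:
    """Adapter giving qc_filter access to table rows."""

    converged: bool
    vt_percent_se: float
    qc_se_threshold: float
    row: pd.Series = field(repr=False, default=None)


def _qc_mask(table: pd.DataFrame, threshold: float) -> pd.Series:
    proxies = [
        _ResultProxy(bool(r.converged), float(r.pse_vt), threshold, r)
        for r in table.itertuples()
    ]
    part = qc_filter(proxies, threshold)
    kept_ids = {id(p) for p in part.kept}
    return pd.Series([id(p) in kept_ids for p in proxies], index=table.index)


def compare_fit_table(
    table: pd.DataFrame, qc_threshold: float = 50.0
) -> dict:
    """Model-comparison and agreement statistics from a pooled fit table.

    Produces the per-region comparison frame (AIC median/range per model,
    F statistics of the nested contrasts with their critical values,
    percentage of regions where the reduced model fits better by AIC), the
    pooled/per-region agreement report between dual-input VTp estimates, the
    COV of VT/VTp per model, and the QC exclusion summary for the full 2TDI.

    F-tests use the weighted RSS (the quantity the fits minimise); regions
    whose full-model fit failed QC are excluded from COV and agreement, as
    are their counterparts in the contrasted models.
    """
    models = list(dict.fromkeys(table["model"]))
    out: dict = {"models": models}

    # QC on the full dual-input model
    if "2TDI" in models:
        t2 = table[table["model"] == "2TDI"]
        kept = _qc_mask(t2, qc_threshold)
        n_excl = int((~kept).sum())
        out["qc"] = {
            "model": "2TDI",
            "n_regions": int(len(t2)),
            "n_excluded": n_excl,
            "excluded_percentage": float(np.floor(1000.0 * n_excl / len(t2) + 0.5) / 10.0)
            if len(t2)
            else 0.0,
        }
        bad_keys = set(
            map(tuple, t2.loc[~kept, ["subject", "region"]].itertuples(index=False))
        )
    else:
        bad_keys = set()

    def _kept(model):
        sub = table[table["model"] == model]
        mask = [
            (s, r) not in bad_keys
            for s, r in zip(sub["subject"], sub["region"])
        ]
        return sub[np.asarray(mask)]

    # COV of distribution volumes per model (pooled over regions and subjects)
    out["cov_percent"] = {
        m: cov_across(_kept(m)["vt"]) for m in models if len(_kept(m)) >= 2
    }

    # per-region comparison table
    comp_rows = []
    wide = {
        m: table[table["model"] == m].set_index(["subject", "region"]) for m in models
    }
    regions = list(dict.fromkeys(table["region"]))
    f_info: dict[str, dict] = {}
    for region in regions:
        row: dict = {"region": region}
        for m in models:
            grp = table[(table["model"] == m) & (table["region"] == region)]
            row[f"aic_{m}"] = _median_range(grp["aic"], 1)
        for full, reduced in _CONTRASTS:
            if full not in models or reduced not in models:
                continue
            fw, rw = wide[full], wide[reduced]
            common = fw.index.intersection(rw.index)
            common = [k for k in common if k[1] == region and k not in bad_keys]
            fvals = []
            for key in common:
                ft = f_test_nested(
                    rss_full=float(fw.loc[key, "rss_weighted"]),
                    p_full=int(fw.loc[key, "n_free"]),
                    rss_reduced=float(rw.loc[key, "rss_weighted"]),
                    p_reduced=int(rw.loc[key, "n_free"]),
                    n=int(fw.loc[key, "n_frames"]),
                )
                fvals.append(ft.f)
                f_info[f"{full}_vs_{reduced}"] = {
                    "df1": ft.df1,
                    "df2": ft.df2,
                    "critical_value": round(ft.critical_value, 2),
                }
            if fvals:
                row[f"F_{full}_vs_{reduced}"] = _median_range(fvals, 2)
                aic_r = [float(rw.loc[k, "aic"]) for k in common]
                aic_f = [float(fw.loc[k, "aic"]) for k in common]
                row[f"pct_better_{reduced}"] = percent_better_fit(aic_r, aic_f)
        comp_rows.append(row)
    out["comparison"] = pd.DataFrame(comp_rows)
    out["f_tests"] = f_info

    # agreement between dual-input VTp vectors (pooled and per region)
    dual = [m for m in ("2TDI", "2TDI_k4fix", "1TDI") if m in models]
    agree_rows = []
    for i in range(len(dual)):
        for j in range(i + 1, len(dual)):
            a_m, b_m = dual[i], dual[j]
            aw, bw = wide[a_m], wide[b_m]
            common = [k for k in aw.index.intersection(bw.index) if k not in bad_keys]
            if len(common) < 3:
                continue
            a = np.array([float(aw.loc[k, "vt"]) for k in common])
            b = np.array([float(bw.loc[k, "vt"]) for k in common])
            rep = compare_estimates(a, b)
            agree_rows.append(
                {
                    "pair": f"{a_m} vs {b_m}",
                    "region": "pooled",
                    "slope": round(rep.slope, 3),
                    "intercept": round(rep.intercept, 4),
                    "r_squared": round(rep.r_squared, 3),
                    "spearman_rho": round(rep.spearman_rho, 3),
                    "spearman_p": rep.spearman_p,
                    "n": rep.n,
                }
            )
            for region in regions:
                keys = [k for k in common if k[1] == region]
                if len(keys) < 3:
                    continue
                ar = np.array([float(aw.loc[k, "vt"]) for k in keys])
                br = np.array([float(bw.loc[k, "vt"]) for k in keys])
                try:
                    rr = compare_estimates(ar, br)
                except ValidationError:
                    continue
                agree_rows.append(
                    {
                        "pair": f"{a_m} vs {b_m}",
                        "region": region,
                        "slope": round(rr.slope, 3),
                        "intercept": round(rr.intercept, 4),
                        "r_squared": round(rr.r_squared, 3),
                        "spearman_rho": round(rr.spearman_rho, 3),
                        "spearman_p": rr.spearman_p,
                        "n": rr.n,
                    }
                )
    out["agreement"] = pd.DataFrame(agree_rows)
    return out


def write_comparison(out_dir, comparison: dict) -> None:
    """Write the comparison bundle: TSVs plus one JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fit_table(comparison["comparison"], out_dir / "model_comparison.tsv")
    if len(comparison.get("agreement", [])):
        write_fit_table(comparison["agreement"], out_dir / "agreement.tsv")
    summary = {
        "models": comparison["models"],
        "cov_percent": {k: round(v, 1) for k, v in comparison["cov_percent"].items()},
        "f_tests": comparison["f_tests"],
    }
    if "qc" in comparison:
        summary["qc"] = comparison["qc"]
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
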