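"""End-to-end orchestration: simulate/ingest -> fit -> classify -> analyze.

CSV is the interchange spine.  Whatever the front-end (synthetic cohort,
user-provided curves, or image stacks run through ROI extraction), the
pipeline converges on ``signals.csv`` (patient_id, timepoint, b_value,
mean_si) and ``staging.csv`` (patient_id, cT, cN, ypT, ypN — yp columns may
be empty for patients who never reached surgery), then produces
``adc.csv``, ``ivim.csv`` and a ``report/`` directory with the group
statistics.  ``report.json`` is a pure function of config + seed (no
timestamps), so identical runs are byte-identical; timing lives in
``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, generate_cohort, write_cohort
from .ivim import (
    BValueScheme,
    SignalCurve,
    fit_adc_monoexp,
    fit_ivim_full,
    fit_ivim_segmented,
)
from .roi import RoiDefinition, exclude_necrosis, extract_mean_signal, load_stack
from .stats import StatConfig, TNStage, classify_response, run_group_analysis

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "RunManifest",
    "ValidationReport",
    "run_pipeline",
    "validate_inputs",
    "fit_signals",
    "classify_staging",
    "read_signals",
    "read_staging",
]

ADC_SCALE = 1e-3  # adc.csv stores ADC in units of 1e-3 mm^2/s


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and record."""


@dataclass
class FitOptions:
    adc_b_subset: str = "all"  # {"all", "ge200"}
    segmented_threshold: float = 200.0
    d_cap: float = 5e-3
    d_star_cap: float = 100e-3

    def subset_for(self, scheme: BValueScheme) -> Sequence[float] | None:
        if self.adc_b_subset == "all":
            return None
        if self.adc_b_subset == "ge200":
            return [b for b in scheme.b_values if b >= 200]
        raise PipelineError(f"unknown adc_b_subset {self.adc_b_subset!r}")


@dataclass
class PipelineConfig:
    mode: str = "simulate"  # {"simulate", "csv", "images"}
    out_dir: str | Path = "out"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    fit: FitOptions = field(default_factory=FitOptions)
    stats: StatConfig = field(default_factory=StatConfig)
    signals_path: str | Path | None = None
    staging_path: str | Path | None = None
    images_dir: str | Path | None = None  # <patient>_<timepoint>.npz stacks
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in {"simulate", "csv", "images"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "csv" and (self.signals_path is None
                                   or self.staging_path is None):
            raise ValueError("csv mode needs signals_path and staging_path")
        if self.mode == "images" and (self.images_dir is None
                                      or self.staging_path is None):
            raise ValueError("images mode needs images_dir and staging_path")
        if self.seed is not None:
            self.cohort.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", {})
        if "group_adc_mean" in cohort_raw:
            cohort_raw["group_adc_mean"] = {
                (g, tp): float(v)
                for g, tps in cohort_raw["group_adc_mean"].items()
                for tp, v in tps.items()
            }
        if "group_adc_sd" in cohort_raw:
            cohort_raw["group_adc_sd"] = {
                (g, tp): float(v)
                for g, tps in cohort_raw["group_adc_sd"].items()
                for tp, v in tps.items()
            }
        for key in ("timepoints", "perfusion_fraction_range",
                    "pseudo_diffusion_multiplier_range", "roi_area_range"):
            if key in cohort_raw:
                cohort_raw[key] = tuple(cohort_raw[key])
        fit_raw = raw.pop("fit", {}) or {}
        stats_raw = raw.pop("stats", {}) or {}
        kwargs = dict(raw)
        kwargs["cohort"] = CohortConfig(**cohort_raw)
        kwargs["fit"] = FitOptions(**fit_raw)
        kwargs["stats"] = StatConfig(**stats_raw)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class ValidationReport:
    passed: bool
    violations: list[str] = field(default_factory=list)


@dataclass
class RunManifest:
    config: dict
    version: str
    started: float
    finished: float
    stage_counts: dict[str, int]
    warnings: list[str]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_signals(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "timepoint", "b_value", "mean_si"}
    if not required <= set(df.columns):
        raise PipelineError(f"signals table missing columns {required - set(df.columns)}")
    return df


def read_staging(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"ypT": "string", "ypN": "string"})
    required = {"patient_id", "cT", "cN", "ypT", "ypN"}
    if not required <= set(df.columns):
        raise PipelineError(f"staging table missing columns {required - set(df.columns)}")
    return df


def validate_inputs(
    signals: pd.DataFrame,
    staging: pd.DataFrame,
    scheme: BValueScheme,
    timepoints: Sequence[str] = ("pre", "during", "post"),
) -> ValidationReport:
    """Check b-value coverage, signal positivity, stage ranges, duplicates."""
    v: list[str] = []
    dup = signals.duplicated(subset=["patient_id", "timepoint", "b_value"])
    if dup.any():
        rows = signals[dup][["patient_id", "timepoint", "b_value"]]
        v.append(f"duplicate signal keys: {rows.to_dict(orient='records')}")
    bad = signals[signals["mean_si"] <= 0]
    for _, row in bad.iterrows():
        v.append(f"non-positive signal for patient {row['patient_id']} "
                 f"timepoint {row['timepoint']} b={row['b_value']}")
    want = set(float(b) for b in scheme.b_values)
    for (pid, tp), grp in signals.groupby(["patient_id", "timepoint"]):
        have = set(grp["b_value"].astype(float))
        if have != want:
            missing = sorted(want - have)
            extra = sorted(have - want)
            msg = f"patient {pid} timepoint {tp}:"
            if missing:
                msg += f" missing b-values {missing}"
            if extra:
                msg += f" unexpected b-values {extra}"
            v.append(msg)
    for pid, grp in signals.groupby("patient_id"):
        have_tp = set(grp["timepoint"])
        miss = [tp for tp in timepoints if tp not in have_tp]
        if miss:
            v.append(f"patient {pid} missing timepoints {miss}")
    if staging["patient_id"].duplicated().any():
        v.append("duplicate patient_id in staging table")
    for _, row in staging.iterrows():
        try:
            TNStage(int(row["cT"]), int(row["cN"]))
        except (ValueError, TypeError):
            v.append(f"patient {row['patient_id']}: invalid clinical stage "
                     f"cT={row['cT']} cN={row['cN']}")
        yp_t, yp_n = row.get("ypT"), row.get("ypN")
        if _present(yp_t) != _present(yp_n):
            v.append(f"patient {row['patient_id']}: ypT/ypN must both be "
                     "present or both absent")
        elif _present(yp_t):
            try:
                TNStage(int(yp_t), int(yp_n))
            except (ValueError, TypeError):
                v.append(f"patient {row['patient_id']}: invalid pathological "
                         f"stage ypT={yp_t} ypN={yp_n}")
    sig_pat = set(signals["patient_id"])
    stag_pat = set(staging["patient_id"])
    if sig_pat != stag_pat:
        v.append(f"patient sets differ between tables: signals-only="
                 f"{sorted(sig_pat - stag_pat)} staging-only={sorted(stag_pat - sig_pat)}")
    return ValidationReport(passed=not v, violations=v)


def _present(value) -> bool:
    return not (value is None or (isinstance(value, float) and np.isnan(value))
                or pd.isna(value) or str(value).strip() == "")


def fit_signals(
    signals: pd.DataFrame,
    scheme: BValueScheme,
    options: FitOptions = FitOptions(),
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Fit ADC and IVIM parameters per patient x timepoint.

    Returns (adc table with ADC in 1e-3 mm^2/s, ivim table, warnings).
    """
    adc_rows, ivim_rows, warns = [], [], []
    subset = options.subset_for(scheme)
    order = np.argsort(scheme.b_array)
    for (pid, tp), grp in signals.groupby(["patient_id", "timepoint"], sort=True):
        grp = grp.sort_values("b_value")
        b_obs = grp["b_value"].to_numpy()
        if b_obs.shape != scheme.b_array.shape or not np.allclose(
                b_obs, scheme.b_array[order]):
            raise PipelineError(
                f"fit stage: patient {pid} timepoint {tp} does not match scheme")
        curve = SignalCurve(scheme=scheme, s=grp["mean_si"].to_numpy())
        try:
            adc = fit_adc_monoexp(curve, subset)
            seg = fit_ivim_segmented(curve, options.segmented_threshold,
                                     options.d_star_cap)
            full = fit_ivim_full(curve, seg.params, options.d_cap,
                                 options.d_star_cap)
        except ValueError as exc:
            raise PipelineError(
                f"fit stage failed for patient {pid} timepoint {tp}: {exc}"
            ) from exc
        if not seg.converged:
            warns.append(f"segmented fit flagged for {pid}/{tp} (clamped f)")
        if not full.converged:
            warns.append(f"full fit did not converge for {pid}/{tp}")
        adc_rows.append({
            "patient_id": pid, "timepoint": tp,
            "adc": adc.adc / ADC_SCALE, "r2": adc.r_squared,
            "n_points": adc.n_points,
        })
        # both estimators are reported: the segmented D is the more precise
        # at clinical SNR (structural high-b constraint), the full fit is
        # the unconstrained optimum of the biexponential model
        for res in (seg, full):
            ivim_rows.append({
                "patient_id": pid, "timepoint": tp,
                "f": res.params.f, "D": res.params.D,
                "D_star": res.params.D_star, "method": res.method,
                "converged": res.converged,
                "residual_norm": res.residual_norm,
            })
    return pd.DataFrame(adc_rows), pd.DataFrame(ivim_rows), warns


def classify_staging(staging: pd.DataFrame, policy: str = "no_response"
                     ) -> pd.DataFrame:
    rows = []
    for _, row in staging.iterrows():
        baseline = TNStage(int(row["cT"]), int(row["cN"]))
        if _present(row["ypT"]):
            pathologic = TNStage(int(row["ypT"]), int(row["ypN"]))
        else:
            pathologic = None
        label = classify_response(baseline, pathologic, policy)
        rows.append({
            "patient_id": row["patient_id"],
            "cT": baseline.T, "cN": baseline.N,
            "ypT": pathologic.T if pathologic else "",
            "ypN": pathologic.N if pathologic else "",
            "class": label.klass, "responder": label.responder,
            "missing_pathology": label.missing_pathology,
        })
    return pd.DataFrame(rows)


def extract_signals_from_images(
    images_dir: str | Path,
    timepoints: Sequence[str],
    thresholds=None,
) -> pd.DataFrame:
    """Run ROI extraction over ``<patient>_<timepoint>.npz`` stacks.

    Each archive must carry a tumour mask; necrotic voxels are excluded with
    the default (or given) thresholds before the mean curve is taken.
    """
    from .roi import NecrosisThresholds

    thresholds = thresholds or NecrosisThresholds()
    rows = []
    paths = sorted(Path(images_dir).glob("*.npz"))
    if not paths:
        raise PipelineError(f"no .npz stacks found in {images_dir}")
    for path in paths:
        stem = path.stem
        pid, _, tp = stem.rpartition("_")
        if not pid or tp not in timepoints:
            raise PipelineError(
                f"stack {path.name} does not follow <patient>_<timepoint>.npz")
        stack, tumour_mask, _ = load_stack(path)
        if tumour_mask is None:
            raise PipelineError(f"stack {path.name} has no tumour mask")
        roi = RoiDefinition.from_mask(tumour_mask,
                                      reference_b=min(800.0, stack.scheme.b_max))
        reduced, _ = exclude_necrosis(stack, roi, thresholds)
        curve = extract_mean_signal(stack, reduced.voxels)
        for b, s in zip(curve.scheme.b_values, curve.s):
            rows.append({"patient_id": pid, "timepoint": tp,
                         "b_value": float(b), "mean_si": float(s)})
    return pd.DataFrame(rows)


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = dataclasses.asdict(config)
    snap["out_dir"] = str(config.out_dir)
    for key in ("signals_path", "staging_path", "images_dir"):
        if snap[key] is not None:
            snap[key] = str(snap[key])
    snap["cohort"]["group_adc_mean"] = {
        f"{g}:{tp}": v for (g, tp), v in config.cohort.group_adc_mean.items()}
    snap["cohort"]["group_adc_sd"] = {
        f"{g}:{tp}": v for (g, tp), v in config.cohort.group_adc_sd.items()}
    return snap


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage and write all artifacts under ``out_dir``."""
    started = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)
    scheme = BValueScheme.default()
    counts: dict[str, int] = {}
    warns: list[str] = []

    if config.mode == "simulate":
        records = generate_cohort(config.cohort)
        write_cohort(records, out)
        signals = read_signals(out / "signals.csv")
        staging = read_staging(out / "staging.csv")
    elif config.mode == "csv":
        signals = read_signals(config.signals_path)
        staging = read_staging(config.staging_path)
    else:
        signals = extract_signals_from_images(config.images_dir,
                                              config.cohort.timepoints)
        (out / "signals.csv").write_text(signals.to_csv(index=False))
        staging = read_staging(config.staging_path)
    counts["signals_rows"] = len(signals)
    counts["patients"] = signals["patient_id"].nunique()

    check = validate_inputs(signals, staging, scheme, config.cohort.timepoints)
    if not check.passed:
        raise PipelineError(
            "input validation failed:\n  " + "\n  ".join(check.violations))

    adc_df, ivim_df, fit_warns = fit_signals(signals, scheme, config.fit)
    warns.extend(fit_warns)
    adc_df.to_csv(out / "adc.csv", index=False)
    ivim_df.to_csv(out / "ivim.csv", index=False)
    counts["adc_rows"] = len(adc_df)
    counts["ivim_rows"] = len(ivim_df)

    classification = classify_staging(staging,
                                      config.stats.missing_pathology_policy)
    classification.to_csv(report_dir / "classification.csv", index=False)
    counts["classified"] = len(classification)

    analysis = run_group_analysis(
        adc_df, classification[["patient_id", "responder"]],
        config.stats, config.cohort.timepoints)
    warns.extend(f"group {g} skipped (fewer than 2 patients)"
                 for g in analysis.skipped_groups)
    analysis.summary.to_csv(report_dir / "table1.csv", index=False)
    lsd_rows = [
        {"group": g, "pair_a": r.pair[0], "pair_b": r.pair[1],
         "T": r.T_stat, "df": r.df, "p_value": r.p_value,
         "significant": r.significant}
        for g, results in analysis.lsd.items() for r in results
    ]
    pd.DataFrame(lsd_rows).to_csv(report_dir / "lsd.csv", index=False)
    counts["lsd_rows"] = len(lsd_rows)
    counts["anova_groups"] = len(analysis.anova)

    # report.json must be a pure function of config+seed: strip paths,
    # which vary between otherwise-identical runs (they stay in the manifest)
    report_config = _config_snapshot(config)
    for key in ("out_dir", "signals_path", "staging_path", "images_dir"):
        report_config.pop(key, None)
    report = {
        "config": report_config,
        "classification": classification.to_dict(orient="records"),
        "analysis": analysis.to_report(),
        "n_patients": int(counts["patients"]),
    }
    with open(report_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)

    manifest = RunManifest(
        config=_config_snapshot(config), version=__version__,
        started=started, finished=time.time(),
        stage_counts=counts, warnings=warns,
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=1, sort_keys=True)
    return manifest
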