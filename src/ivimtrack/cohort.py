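"""Synthetic cohort generator for longitudinal DW-MRI response monitoring.

Emulates a small neoadjuvant-radiochemotherapy rectal-cancer cohort: each
patient carries a clinical baseline TN stage, a post-treatment pathological
stage consistent with their responder/nonresponder label, and one mean-ROI
signal curve per treatment time point (pre / during / post), synthesised
from latent IVIM parameters through the biexponential forward model with
magnitude-MRI (Rician) noise.

The measurand the analysis reports is the monoexponential ADC, so the
generator is calibrated on ADC, not on the latent D: a target ADC is drawn
per patient x timepoint from the configured group mean/SD (truncated at a
positive floor), and D is then solved numerically so that a noise-free
log-linear ADC fit of the biexponential curve returns exactly that target.
Perfusion fraction f and the D*/D multiplier are nuisance draws from
configured ranges.

ADC values of the same patient are correlated across time points through a
shared subject-level random effect (intra-subject correlation
``adc_within_subject_corr``); the marginal per-timepoint moments are
unchanged by this. See docs/methods.md for why the default is 0.60.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .ivim import BValueScheme, IvimParams, SignalCurve, forward_signal
from .roi import ImageStack
from .stats import TNStage

__all__ = [
    "ConfigurationError",
    "CohortConfig",
    "PatientRecord",
    "generate_cohort",
    "simulate_signal",
    "generate_image_fixture",
    "write_cohort",
]

GROUPS = ("responder", "nonresponder")
DEFAULT_TIMEPOINTS = ("pre", "during", "post")

# Group ADC moments (mm^2/s) at each treatment time point; the defaults are
# the cohort summary statistics the generator is asked to reproduce.
DEFAULT_ADC_MEAN: dict[tuple[str, str], float] = {
    ("responder", "pre"): 0.87e-3,
    ("responder", "during"): 1.13e-3,
    ("responder", "post"): 1.28e-3,
    ("nonresponder", "pre"): 0.75e-3,
    ("nonresponder", "during"): 1.03e-3,
    ("nonresponder", "post"): 1.18e-3,
}
DEFAULT_ADC_SD: dict[tuple[str, str], float] = {
    ("responder", "pre"): 0.23e-3,
    ("responder", "during"): 0.26e-3,
    ("responder", "post"): 0.32e-3,
    ("nonresponder", "pre"): 0.14e-3,
    ("nonresponder", "during"): 0.10e-3,
    ("nonresponder", "post"): 0.38e-3,
}


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults describe a 22-patient cohort (15 responders, 7 nonresponders)
    imaged at three time points with the default 11-b-value scheme at
    b=0 SNR 50, with 60% of responders reaching pathological complete
    response.
    """

    n_responders: int = 15
    n_nonresponders: int = 7
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    group_adc_mean: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_ADC_MEAN))
    group_adc_sd: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_ADC_SD))
    perfusion_fraction_range: tuple[float, float] = (0.05, 0.20)
    pseudo_diffusion_multiplier_range: tuple[float, float] = (5.0, 20.0)
    snr: float = 50.0
    noise_model: str = "rician"  # {"rician", "gaussian", "none"}
    roi_area_range: tuple[float, float] = (100.0, 230.0)  # mm^2
    adc_floor: float = 0.1e-3  # mm^2/s truncation floor for drawn ADC
    adc_within_subject_corr: float = 0.60
    pcr_fraction: float = 0.60  # fraction of responders with ypT0N0
    n_missing_pathology: int = 0  # patients who never reach surgery
    s0: float = 1000.0  # arbitrary-unit b=0 signal level
    seed: int = 0

    def validate(self) -> None:
        if self.n_responders < 0 or self.n_nonresponders < 0:
            raise ConfigurationError("group sizes must be non-negative")
        if self.n_responders + self.n_nonresponders < 1:
            raise ConfigurationError("cohort must contain at least one patient")
        if len(self.timepoints) == 0:
            raise ConfigurationError("timepoints must be non-empty")
        for group in GROUPS:
            for tp in self.timepoints:
                key = (group, tp)
                if key not in self.group_adc_mean or key not in self.group_adc_sd:
                    raise ConfigurationError(f"missing ADC moments for {key}")
                if self.group_adc_mean[key] <= 0:
                    raise ConfigurationError(f"ADC mean for {key} must be > 0")
                if self.group_adc_sd[key] <= 0:
                    raise ConfigurationError(f"ADC SD for {key} must be > 0")
        for name, (lo, hi) in (
            ("perfusion_fraction_range", self.perfusion_fraction_range),
            ("pseudo_diffusion_multiplier_range",
             self.pseudo_diffusion_multiplier_range),
            ("roi_area_range", self.roi_area_range),
        ):
            if not lo <= hi:
                raise ConfigurationError(f"{name} is empty")
        lo, hi = self.perfusion_fraction_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ConfigurationError("perfusion fractions must lie in [0, 1]")
        if self.pseudo_diffusion_multiplier_range[0] <= 1.0:
            raise ConfigurationError("D*/D multiplier range must be strictly > 1")
        if self.noise_model not in {"rician", "gaussian", "none"}:
            raise ConfigurationError(f"unknown noise model {self.noise_model!r}")
        if self.noise_model != "none" and self.snr <= 0:
            raise ConfigurationError("SNR must be positive")
        if not 0.0 <= self.adc_within_subject_corr < 1.0:
            raise ConfigurationError("adc_within_subject_corr must be in [0, 1)")
        if not 0.0 <= self.pcr_fraction <= 1.0:
            raise ConfigurationError("pcr_fraction must be in [0, 1]")
        if self.adc_floor <= 0:
            raise ConfigurationError("adc_floor must be positive")
        if not 0 <= self.n_missing_pathology <= self.n_nonresponders:
            raise ConfigurationError(
                "n_missing_pathology must not exceed the nonresponder count")


@dataclass
class PatientRecord:
    patient_id: str
    group: str  # {"responder", "nonresponder"}
    baseline_stage: TNStage
    pathologic_stage: TNStage | None
    curves: dict[str, SignalCurve]
    true_params: dict[str, IvimParams]
    target_adc: dict[str, float]  # mm^2/s, the calibrated noise-free ADC
    roi_area_mm2: float


def simulate_signal(
    params: IvimParams,
    scheme: BValueScheme,
    snr: float | None = None,
    noise_model: str = "rician",
    seed: "int | np.random.Generator | None" = None,
) -> SignalCurve:
    """Synthesise one signal curve from the biexponential forward model.

    Rician noise models magnitude MRI: the clean signal is perturbed by a
    complex Gaussian with per-channel SD S0/snr and the magnitude is taken,
    which biases low-SNR signals upward.  Gaussian and noise-free variants
    exist for tractable tests.
    """
    if noise_model not in {"rician", "gaussian", "none"}:
        raise ValueError(f"unknown noise model {noise_model!r}")
    b = scheme.b_array
    clean = params.S0 * forward_signal(params, b)
    if noise_model == "none":
        return SignalCurve(scheme=scheme, s=clean)
    if snr is None or snr <= 0:
        raise ValueError("snr must be positive for noisy simulation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = params.S0 / snr
    if noise_model == "gaussian":
        s = clean + rng.normal(0.0, sigma, size=clean.shape)
    else:
        s = np.hypot(clean + rng.normal(0.0, sigma, size=clean.shape),
                     rng.normal(0.0, sigma, size=clean.shape))
    return SignalCurve(scheme=scheme, s=s)


def _adc_slope_weights(b: np.ndarray) -> np.ndarray:
    bc = b - b.mean()
    return bc / float(np.sum(bc * bc))


def _noise_free_adc(f: float, d: float, d_star: float,
                    b: np.ndarray, w: np.ndarray) -> float:
    y = np.log((1.0 - f) * np.exp(-b * d) + f * np.exp(-b * (d + d_star)))
    return float(-(w @ y))


def calibrate_d(target_adc: float, f: float, d_star_multiplier: float,
                scheme: BValueScheme) -> float:
    """Solve for the latent D whose noise-free log-linear ADC equals target.

    Because the perfusion term steepens the low-b decay, the fitted ADC
    exceeds D whenever f > 0; the solution is bracketed by (0, target_adc].
    """
    b = scheme.b_array
    w = _adc_slope_weights(b)

    def g(d: float) -> float:
        return _noise_free_adc(f, d, d_star_multiplier * d, b, w) - target_adc

    hi = target_adc
    if g(hi) <= 0.0:  # f == 0 edge: ADC == D exactly
        return hi
    return float(optimize.brentq(g, 1e-8, hi, xtol=1e-15, rtol=1e-14))


def _draw_truncated(rng: np.random.Generator, mu: float, sd: float,
                    sqrt_rho: float, sqrt_resid: float, u: float,
                    floor: float) -> float:
    for _ in range(1000):
        val = mu + sd * (sqrt_rho * u + sqrt_resid * rng.standard_normal())
        if val > floor:
            return val
    return floor


def _draw_stages(rng: np.random.Generator, group: str, is_pcr: bool
                 ) -> tuple[TNStage, TNStage]:
    """Baseline (locally advanced: T3-4) and a group-consistent yp stage."""
    c_t = int(rng.integers(3, 5))
    c_n = int(rng.integers(0, 3))
    baseline = TNStage(T=c_t, N=c_n)
    if group == "responder":
        if is_pcr:
            return baseline, TNStage(T=0, N=0)
        yp_t = int(rng.integers(1, c_t))  # 1..cT-1: downstaged, not complete
        yp_n = int(rng.integers(0, c_n + 1))
        return baseline, TNStage(T=yp_t, N=yp_n)
    yp_t = min(4, c_t + int(rng.integers(0, 2)))  # stable or progressive
    yp_n = min(2, c_n + int(rng.integers(0, 2)))
    return baseline, TNStage(T=yp_t, N=yp_n)


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate the full synthetic cohort, deterministically from the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    scheme = BValueScheme.default()
    rho = config.adc_within_subject_corr
    sqrt_rho, sqrt_resid = math.sqrt(rho), math.sqrt(1.0 - rho)

    n_pcr = round(config.pcr_fraction * config.n_responders)
    pcr_flags = np.zeros(config.n_responders, dtype=bool)
    pcr_flags[:n_pcr] = True
    rng.shuffle(pcr_flags)

    missing_flags = np.zeros(config.n_nonresponders, dtype=bool)
    if config.n_missing_pathology:
        missing_flags[-config.n_missing_pathology:] = True

    records: list[PatientRecord] = []
    roster = [("responder", bool(pcr_flags[i]), False)
              for i in range(config.n_responders)]
    roster += [("nonresponder", False, bool(missing_flags[i]))
               for i in range(config.n_nonresponders)]
    for idx, (group, is_pcr, missing) in enumerate(roster):
        pid = f"P{idx + 1:03d}"
        u = rng.standard_normal()  # shared subject effect
        roi_area = float(rng.uniform(*config.roi_area_range))
        curves: dict[str, SignalCurve] = {}
        true_params: dict[str, IvimParams] = {}
        targets: dict[str, float] = {}
        for tp in config.timepoints:
            mu = config.group_adc_mean[(group, tp)]
            sd = config.group_adc_sd[(group, tp)]
            target = _draw_truncated(rng, mu, sd, sqrt_rho, sqrt_resid, u,
                                     config.adc_floor)
            f = float(rng.uniform(*config.perfusion_fraction_range))
            mult = float(rng.uniform(*config.pseudo_diffusion_multiplier_range))
            d = calibrate_d(target, f, mult, scheme)
            params = IvimParams(f=f, D=d, D_star=mult * d, S0=config.s0)
            curves[tp] = simulate_signal(params, scheme, config.snr,
                                         config.noise_model, rng)
            true_params[tp] = params
            targets[tp] = target
        baseline, pathologic = _draw_stages(rng, group, is_pcr)
        records.append(PatientRecord(
            patient_id=pid, group=group, baseline_stage=baseline,
            pathologic_stage=None if missing else pathologic,
            curves=curves, true_params=true_params, target_adc=targets,
            roi_area_mm2=roi_area,
        ))
    return records


def generate_image_fixture(
    shape: tuple[int, ...],
    tumour_params: IvimParams,
    necrosis_params: IvimParams,
    scheme: BValueScheme,
    seed: "int | np.random.Generator | None" = None,
    snr: float | None = None,
    noise_model: str = "none",
    tumour_mask: np.ndarray | None = None,
    necrosis_mask: np.ndarray | None = None,
    background_level: float = 0.05,
) -> tuple[ImageStack, np.ndarray, np.ndarray]:
    """Build a small labelled image stack for testing ROI extraction.

    Default masks are a centred tumour block spanning half the grid with a
    necrotic core spanning a quarter.  Tumour voxels follow
    ``tumour_params``; necrotic voxels follow ``necrosis_params`` (give them
    higher D — suppressed high-b signal — and a higher S0 for the
    T2-hyperintense appearance); background is a constant low signal at
    ``background_level`` of the tumour S0.
    """
    if len(shape) not in (2, 3):
        raise ValueError("grid must be 2-D or 3-D")
    if tumour_mask is None:
        tumour_mask = np.zeros(shape, dtype=bool)
        tumour_mask[tuple(slice(n // 4, 3 * n // 4) for n in shape)] = True
    else:
        tumour_mask = np.asarray(tumour_mask, dtype=bool)
    if necrosis_mask is None:
        necrosis_mask = np.zeros(shape, dtype=bool)
        necrosis_mask[tuple(slice(3 * n // 8, 5 * n // 8) for n in shape)] = True
        necrosis_mask &= tumour_mask
    else:
        necrosis_mask = np.asarray(necrosis_mask, dtype=bool)
    if np.any(necrosis_mask & ~tumour_mask):
        raise ValueError("necrosis mask must be contained in the tumour mask")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b = scheme.b_array
    n_b = b.size
    data = np.full((n_b,) + tuple(shape),
                   background_level * tumour_params.S0, dtype=float)
    viable = tumour_mask & ~necrosis_mask
    for region_mask, params in ((viable, tumour_params),
                                (necrosis_mask, necrosis_params)):
        n_vox = int(region_mask.sum())
        if n_vox == 0:
            continue
        clean = params.S0 * forward_signal(params, b)  # (n_b,)
        tile = np.repeat(clean[:, None], n_vox, axis=1)
        if noise_model == "none":
            noisy = tile
        elif noise_model == "gaussian":
            noisy = tile + rng.normal(0.0, params.S0 / snr, size=tile.shape)
        elif noise_model == "rician":
            sigma = params.S0 / snr
            noisy = np.hypot(tile + rng.normal(0.0, sigma, size=tile.shape),
                             rng.normal(0.0, sigma, size=tile.shape))
        else:
            raise ValueError(f"unknown noise model {noise_model!r}")
        data[(slice(None),) + tuple(np.argwhere(region_mask).T)] = noisy
    return ImageStack(scheme=scheme, data=data), tumour_mask, necrosis_mask


def _stage_str(stage: TNStage | None) -> tuple[str, str]:
    if stage is None:
        return "", ""
    return str(stage.T), str(stage.N)


def write_cohort(records: Sequence[PatientRecord], out_dir: str | Path,
                 include_truth: bool = True) -> dict[str, Path]:
    """Serialize a cohort to signals.csv, staging.csv and truth.json.

    truth.json retains the latent parameters and group labels and exists for
    tests only; the analysis pipeline never reads it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sig_rows = []
    stage_rows = []
    truth: dict[str, dict] = {}
    for rec in records:
        for tp, curve in rec.curves.items():
            for b, s in zip(curve.scheme.b_values, curve.s):
                sig_rows.append({"patient_id": rec.patient_id, "timepoint": tp,
                                 "b_value": float(b), "mean_si": float(s)})
        yp_t, yp_n = _stage_str(rec.pathologic_stage)
        stage_rows.append({
            "patient_id": rec.patient_id,
            "cT": rec.baseline_stage.T, "cN": rec.baseline_stage.N,
            "ypT": yp_t, "ypN": yp_n,
        })
        truth[rec.patient_id] = {
            "group": rec.group,
            "roi_area_mm2": rec.roi_area_mm2,
            "timepoints": {
                tp: {**asdict(rec.true_params[tp]),
                     "target_adc": rec.target_adc[tp]}
                for tp in rec.curves
            },
        }
    paths = {
        "signals": out / "signals.csv",
        "staging": out / "staging.csv",
    }
    pd.DataFrame(sig_rows).to_csv(paths["signals"], index=False)
    pd.DataFrame(stage_rows).to_csv(paths["staging"], index=False)
    if include_truth:
        paths["truth"] = out / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    return paths
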