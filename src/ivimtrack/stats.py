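"""Response classification and longitudinal ADC statistics.

Classification compares the baseline clinical TN stage (cT, cN) with the
post-treatment pathological stage (ypT, ypN):

* pathological complete response (pCR): ypT0 ypN0;
* partial response (downstaging): reduction of at least one level in T or N;
* no response: stable or progressive disease.

A patient is a *responder* when the class is pCR or partial response.

The longitudinal protocol compares group mean ADC across the three treatment
time points with a one-way ANOVA F-test (independent-groups or
repeated-measures decomposition), followed by pairwise Fisher least
significant difference (LSD) tests that reuse the ANOVA error mean square as
the pooled variance.  Two alpha levels are used: 0.05 for the omnibus F and a
stricter 0.005 for the pairwise LSD contrasts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TNStage",
    "ResponseLabel",
    "StatConfig",
    "AnovaResult",
    "LsdResult",
    "CohortAnalysis",
    "classify_response",
    "anova_oneway",
    "anova_repeated",
    "lsd_test",
    "run_group_analysis",
]

T_LEVELS = range(5)  # T0..T4
N_LEVELS = range(3)  # N0..N2


@dataclass(frozen=True)
class TNStage:
    """Plain TN tumour/node stage (no substages; T3a/b collapse to T3)."""

    T: int
    N: int

    def __post_init__(self) -> None:
        if self.T not in T_LEVELS:
            raise ValueError(f"T stage {self.T} outside 0-4")
        if self.N not in N_LEVELS:
            raise ValueError(f"N stage {self.N} outside 0-2")

    def __str__(self) -> str:  # e.g. "T3N1"
        return f"T{self.T}N{self.N}"


@dataclass(frozen=True)
class ResponseLabel:
    klass: str  # {"pCR", "partial_response", "no_response"}
    responder: bool
    missing_pathology: bool = False

    def __post_init__(self) -> None:
        if self.klass not in {"pCR", "partial_response", "no_response"}:
            raise ValueError(f"unknown response class {self.klass!r}")
        if self.klass == "pCR" and not self.responder:
            raise ValueError("pCR implies responder")


@dataclass(frozen=True)
class StatConfig:
    alpha_anova: float = 0.05
    alpha_lsd: float = 0.005
    design: str = "repeated"  # {"repeated", "independent"}
    protected_lsd: bool = True
    missing_pathology_policy: str = "no_response"  # or "error"

    def __post_init__(self) -> None:
        for a in (self.alpha_anova, self.alpha_lsd):
            if not 0.0 < a < 1.0:
                raise ValueError("alpha levels must be in (0, 1)")
        if self.design not in {"repeated", "independent"}:
            raise ValueError(f"unknown design {self.design!r}")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_error: int
    p_value: float
    ms_between: float
    ms_error: float
    design: str


@dataclass(frozen=True)
class LsdResult:
    T_stat: float
    df: int
    p_value: float
    pair: tuple[str, str]
    significant: bool


def classify_response(
    baseline: TNStage,
    pathologic: TNStage | None,
    missing_policy: str = "no_response",
) -> ResponseLabel:
    """Classify one patient from baseline clinical vs pathological stage.

    Absent pathology (patient never reached surgery) is handled per
    ``missing_policy``: the default conservatively labels the patient
    no_response and raises the ``missing_pathology`` flag; "error" refuses.
    """
    if pathologic is None:
        if missing_policy == "error":
            raise ValueError("pathologic stage absent")
        return ResponseLabel("no_response", responder=False, missing_pathology=True)
    if pathologic.T == 0 and pathologic.N == 0:
        return ResponseLabel("pCR", responder=True)
    if pathologic.T < baseline.T or pathologic.N < baseline.N:
        return ResponseLabel("partial_response", responder=True)
    return ResponseLabel("no_response", responder=False)


def _f_pvalue(F: float, df1: int, df2: int) -> float:
    if np.isinf(F):
        return 0.0
    return float(sps.f.sf(F, df1, df2))


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Independent-groups one-way ANOVA from raw values per group."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {k!r} has fewer than two values")
    all_vals = np.concatenate(list(arrays.values()))
    grand = all_vals.mean()
    k = len(arrays)
    n_total = all_vals.size
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values()))
    ss_within = float(sum(np.sum((a - a.mean()) ** 2) for a in arrays.values()))
    df_b, df_e = k - 1, n_total - k
    ms_b = ss_between / df_b
    ms_e = ss_within / df_e
    if ms_e == 0.0:
        F = 0.0 if ms_b == 0.0 else float("inf")
    else:
        F = ms_b / ms_e
    return AnovaResult(
        F=float(F), df_between=df_b, df_error=df_e,
        p_value=1.0 if F == 0.0 else _f_pvalue(F, df_b, df_e),
        ms_between=ms_b, ms_error=ms_e, design="independent",
    )


def anova_repeated(matrix) -> AnovaResult:
    """One-way repeated-measures ANOVA on a subjects x timepoints matrix.

    Decomposition: SS_total = SS_time + SS_subject + SS_error;
    F = MS_time / MS_error with df = (t - 1, (t - 1)(n - 1)).
    Missing cells are an error; no imputation is attempted.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D subjects x timepoints matrix")
    n, t = m.shape
    if n < 2 or t < 2:
        raise ValueError("need >= 2 subjects and >= 2 timepoints")
    if np.any(~np.isfinite(m)):
        raise ValueError("missing or non-finite cells in repeated-measures matrix")
    grand = m.mean()
    ss_total = float(np.sum((m - grand) ** 2))
    ss_time = float(n * np.sum((m.mean(axis=0) - grand) ** 2))
    ss_subject = float(t * np.sum((m.mean(axis=1) - grand) ** 2))
    ss_error = ss_total - ss_time - ss_subject
    df_t, df_e = t - 1, (t - 1) * (n - 1)
    ms_t = ss_time / df_t
    ms_e = max(ss_error, 0.0) / df_e
    if ms_e == 0.0:
        F = 0.0 if ms_t == 0.0 else float("inf")
    else:
        F = ms_t / ms_e
    return AnovaResult(
        F=float(F), df_between=df_t, df_error=df_e,
        p_value=1.0 if F == 0.0 else _f_pvalue(F, df_t, df_e),
        ms_between=ms_t, ms_error=ms_e, design="repeated",
    )


def lsd_test(
    mean_a: float,
    mean_b: float,
    n_a: int,
    n_b: int,
    ms_error: float,
    df_error: int,
    config: StatConfig = StatConfig(),
    pair: tuple[str, str] = ("a", "b"),
) -> LsdResult:
    """Fisher LSD pairwise contrast using the ANOVA error mean square.

    T = |mean_a - mean_b| / sqrt(MS_error * (1/n_a + 1/n_b)), two-sided p
    from the t distribution with the ANOVA error df.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("group sizes must be positive")
    if ms_error < 0:
        raise ValueError("ms_error must be non-negative")
    diff = abs(mean_a - mean_b)
    if ms_error == 0.0:
        T = 0.0 if diff == 0.0 else float("inf")
        p = 1.0 if diff == 0.0 else 0.0
    else:
        T = diff / np.sqrt(ms_error * (1.0 / n_a + 1.0 / n_b))
        p = float(2.0 * sps.t.sf(T, df_error))
    return LsdResult(
        T_stat=float(T), df=int(df_error), p_value=p, pair=pair,
        significant=bool(p < config.alpha_lsd),
    )


@dataclass
class CohortAnalysis:
    """Per-group ANOVA + LSD results with a summary table."""

    anova: dict[str, AnovaResult]
    lsd: dict[str, list[LsdResult]]
    summary: pd.DataFrame
    skipped_groups: list[str] = field(default_factory=list)
    config: StatConfig = StatConfig()

    def to_report(self) -> dict:
        groups = {}
        for g, a in self.anova.items():
            groups[g] = {
                "F": a.F, "df_between": a.df_between, "df_error": a.df_error,
                "p_value": a.p_value, "ms_between": a.ms_between,
                "ms_error": a.ms_error, "design": a.design,
                "lsd": [
                    {
                        "pair": list(r.pair), "T": r.T_stat, "df": r.df,
                        "p_value": r.p_value, "significant": r.significant,
                    }
                    for r in self.lsd[g]
                ],
            }
        return {
            "groups": groups,
            "skipped_groups": list(self.skipped_groups),
            "summary": self.summary.to_dict(orient="records"),
            "config": {
                "alpha_anova": self.config.alpha_anova,
                "alpha_lsd": self.config.alpha_lsd,
                "design": self.config.design,
                "protected_lsd": self.config.protected_lsd,
            },
        }


def run_group_analysis(
    adc_table: pd.DataFrame,
    responder_labels: Mapping[str, bool] | pd.DataFrame,
    config: StatConfig = StatConfig(),
    timepoints: Sequence[str] = ("pre", "during", "post"),
) -> CohortAnalysis:
    """Run the full per-group longitudinal protocol on an ADC table.

    ``adc_table`` needs columns patient_id, timepoint, adc (any consistent
    unit).  ``responder_labels`` maps patient_id to the responder boolean (a
    DataFrame with those two columns is also accepted).  Every patient must
    have an ADC at every configured timepoint.  Groups with fewer than two
    patients are skipped with a warning.  With ``protected_lsd`` the pairwise
    contrasts are only flagged significant when the group's omnibus F passes
    ``alpha_anova``.
    """
    if isinstance(responder_labels, pd.DataFrame):
        responder_labels = dict(
            zip(responder_labels["patient_id"], responder_labels["responder"])
        )
    df = adc_table.copy()
    missing = set(df["patient_id"]) - set(responder_labels)
    if missing:
        raise ValueError(f"patients without responder label: {sorted(missing)}")
    df["group"] = df["patient_id"].map(
        lambda p: "responders" if responder_labels[p] else "nonresponders"
    )

    anova_out: dict[str, AnovaResult] = {}
    lsd_out: dict[str, list[LsdResult]] = {}
    skipped: list[str] = []
    summary_rows: list[dict] = []

    for group in ("responders", "nonresponders"):
        sub = df[df["group"] == group]
        if sub.empty:
            continue
        wide = sub.pivot(index="patient_id", columns="timepoint", values="adc")
        absent = [tp for tp in timepoints if tp not in wide.columns]
        if absent or wide[list(timepoints)].isna().any().any():
            raise ValueError(
                f"group {group!r} has patients missing timepoints {absent or 'values'}"
            )
        wide = wide[list(timepoints)]
        for tp in timepoints:
            col = wide[tp]
            summary_rows.append({
                "group": group, "timepoint": tp, "n": int(col.size),
                "mean": float(col.mean()),
                "sd": float(col.std(ddof=1)) if col.size > 1 else float("nan"),
            })
        if len(wide) < 2:
            warnings.warn(f"group {group!r} smaller than 2; skipped", stacklevel=2)
            skipped.append(group)
            continue
        if config.design == "repeated":
            res = anova_repeated(wide.to_numpy())
        else:
            res = anova_oneway({tp: wide[tp].to_numpy() for tp in timepoints})
        anova_out[group] = res
        omnibus_pass = res.p_value < config.alpha_anova
        pairs = list(itertools.combinations(timepoints, 2))
        results = []
        for a, b in pairs:
            r = lsd_test(
                float(wide[a].mean()), float(wide[b].mean()),
                int(wide[a].size), int(wide[b].size),
                res.ms_error, res.df_error, config, pair=(a, b),
            )
            if config.protected_lsd and not omnibus_pass:
                r = LsdResult(r.T_stat, r.df, r.p_value, r.pair, significant=False)
            results.append(r)
        lsd_out[group] = results

    summary = pd.DataFrame(summary_rows)
    if not summary.empty:
        fmap = {g: a.F for g, a in anova_out.items()}
        pmap = {g: a.p_value for g, a in anova_out.items()}
        summary["F"] = summary["group"].map(fmap)
        summary["p_value"] = summary["group"].map(pmap)
    return CohortAnalysis(
        anova=anova_out, lsd=lsd_out, summary=summary,
        skipped_groups=skipped, config=config,
    )
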