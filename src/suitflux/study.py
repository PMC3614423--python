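"""Multi-cohort recovery study: the closed loop generator -> pipeline.

Runs many independently seeded synthetic cohorts end to end (simulate ->
analyze -> compare, all in memory) and aggregates the quantities the study
design is built to recover: per-state FCR group differences, FCR and CS
dispersion, technical duplicate variation, the emergent RCR percent
difference and the CII_ETS significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .pipeline import RunConfig, SampleInput, analyze_cohort, compare_cohort
from .suit_protocol import REFERENCE_STATE, RespState
from .synthetic_cohort import SimConfig, simulate_cohort

__all__ = ["CohortSummary", "StudyResult", "run_cohort", "run_study"]

_EFFECT_STATES = (
    RespState.CI_CII_OXPHOS,
    RespState.CII_ETS,
    RespState.CIV_MAX,
)

_NON_REF_STATES = tuple(s for s in RespState if s is not REFERENCE_STATE)
_CS_NORM_STATES = tuple(s for s in RespState if s is not RespState.ROX)


@dataclass(frozen=True)
class CohortSummary:
    """Pipeline-side summary of one simulated cohort."""

    seed: int
    n_samples: int
    n_qc_failed: int
    fcr_mean_diff: dict[RespState, float]       # control - affected
    fcr_p: dict[RespState, float]
    rcr_pct_diff: float
    fcr_cv_pct: float          # per-state per-group CV, averaged
    cs_cv_pct: float           # pooled across groups
    dup_variation_control_pct: float
    dup_variation_affected_pct: float
    cs_dup_variation_pct: float
    cs_norm_sd_exceeds_fcr_sd: bool
    sig_states: tuple[str, ...]                 # states with p < 0.05


@dataclass
class StudyResult:
    cohorts: list[CohortSummary] = field(default_factory=list)

    def _arr(self, getter) -> np.ndarray:
        return np.array([getter(c) for c in self.cohorts], dtype=float)

    def mean_effect(self, state: RespState) -> float:
        return float(np.mean(self._arr(lambda c: c.fcr_mean_diff[state])))

    def median_p(self, state: RespState, n_cohorts: int | None = None) -> float:
        ps = self._arr(lambda c: c.fcr_p[state])
        if n_cohorts is not None:
            ps = ps[:n_cohorts]
        return float(np.median(ps))

    def summary(self) -> dict[str, float]:
        return {
            "fcr_diff_ci_cii_oxphos": self.mean_effect(RespState.CI_CII_OXPHOS),
            "fcr_diff_cii_ets": self.mean_effect(RespState.CII_ETS),
            "fcr_diff_civ_max": self.mean_effect(RespState.CIV_MAX),
            "fcr_cv_pct": float(np.mean(self._arr(lambda c: c.fcr_cv_pct))),
            "cs_cv_pct": float(np.mean(self._arr(lambda c: c.cs_cv_pct))),
            "dup_variation_control_pct": float(
                np.mean(self._arr(lambda c: c.dup_variation_control_pct))
            ),
            "cs_dup_variation_pct": float(
                np.mean(self._arr(lambda c: c.cs_dup_variation_pct))
            ),
            "rcr_pct_diff": float(np.mean(self._arr(lambda c: c.rcr_pct_diff))),
            "median_p_cii_ets_100": self.median_p(RespState.CII_ETS, 100),
        }


def _grouped_cv(df: pd.DataFrame, col: str) -> list[float]:
    out = []
    for _, sub in df.groupby("group"):
        v = sub[col].to_numpy(float)
        m = np.mean(v)
        if m != 0 and len(v) > 1:
            out.append(100.0 * np.std(v, ddof=1) / m)
    return out


def run_cohort(config: SimConfig, run_config: RunConfig | None = None) -> CohortSummary:
    """Simulate one cohort and push it through analyze + compare."""
    rc = run_config or RunConfig()
    sim = simulate_cohort(config)
    inputs = [
        SampleInput(s.sample_id, s.group, s.traces, s.cs) for s in sim.samples
    ]
    samples_df, _ = analyze_cohort(inputs, sim.blank, rc)
    comparison = compare_cohort(samples_df, rc)

    fcr_rows = comparison[comparison["mode"] == "fcr"].set_index("state")
    mean_diff = {
        s: float(fcr_rows.loc[s.value, "mean_diff"]) for s in _NON_REF_STATES
    }
    p_vals = {s: float(fcr_rows.loc[s.value, "p_value"]) for s in _NON_REF_STATES}
    rcr_pct = float(
        comparison.loc[comparison["mode"] == "rcr", "pct_diff"].iloc[0]
    )

    used = samples_df
    if rc.exclude_qc_failures:
        used = samples_df[samples_df["qc_pass"].astype(bool)]
    fcr_cvs = [
        cv for s in _NON_REF_STATES for cv in _grouped_cv(used, f"fcr_{s.value}")
    ]
    cs = used["cs_activity"].to_numpy(float)
    cs_cv = 100.0 * np.std(cs, ddof=1) / np.mean(cs)

    dup_ctl = float(
        used.loc[used["group"] == "control", "dup_variation_pct"].mean()
    )
    dup_aff = float(
        used.loc[used["group"] == "affected", "dup_variation_pct"].mean()
    )
    cs_dup = float(used["cs_dup_variation_pct"].mean())

    # the normalization-sensitivity contrast: per state and group, the CS-
    # normalized flux must scatter more (relative SD) than the internally
    # normalized FCR
    exceeds = True
    for s in _CS_NORM_STATES:
        cv_cs = _grouped_cv(used, f"jcs_{s.value}")
        cv_fcr = _grouped_cv(used, f"fcr_{s.value}") if s is not REFERENCE_STATE else [0.0, 0.0]
        if len(cv_cs) == len(cv_fcr):
            exceeds &= all(a > b for a, b in zip(cv_cs, cv_fcr))

    return CohortSummary(
        seed=config.seed,
        n_samples=len(samples_df),
        n_qc_failed=int((~samples_df["qc_pass"].astype(bool)).sum()),
        fcr_mean_diff=mean_diff,
        fcr_p=p_vals,
        rcr_pct_diff=rcr_pct,
        fcr_cv_pct=float(np.mean(fcr_cvs)),
        cs_cv_pct=float(cs_cv),
        dup_variation_control_pct=dup_ctl,
        dup_variation_affected_pct=dup_aff,
        cs_dup_variation_pct=cs_dup,
        cs_norm_sd_exceeds_fcr_sd=bool(exceeds),
        sig_states=tuple(s.value for s in _NON_REF_STATES if p_vals[s] < 0.05),
    )


def run_study(
    base_seed: int,
    n_cohorts: int = 200,
    config: SimConfig | None = None,
    run_config: RunConfig | None = None,
    seeds: Sequence[int] | None = None,
) -> StudyResult:
    """Run ``n_cohorts`` cohorts with seeds base_seed, base_seed+1, ...

    Ground-truth flux series are not retained (they are only needed by the
    oracle tests, not by the recovery study).
    """
    template = config or SimConfig()
    cohort_seeds = (
        list(seeds) if seeds is not None
        else [base_seed + i for i in range(n_cohorts)]
    )
    result = StudyResult()
    for seed in cohort_seeds:
        cfg = replace(template, seed=int(seed), store_flux_series=False)
        result.cohorts.append(run_cohort(cfg, run_config))
    return result
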