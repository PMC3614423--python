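"""Flux control ratios, duplicate averaging and two-group comparison.

The flux control ratio (FCR) normalizes each corrected state flux to the
maximal uncoupled respiration (CI+CII ETS capacity), removing every
between-sample scale factor — chamber volume, tissue amount, mitochondrial
content — so FCRs are invariant under any positive rescaling of a sample's
absolute fluxes.  The respiratory control ratio (RCR) is CI+CII OXPHOS over
LEAK.  Normalizing absolute flux to citrate synthase activity instead imports
the CS assay's analytical variance; the two normalizations are computed side
by side precisely so that contrast is measurable.

Group comparison follows the classical recipe: D'Agostino-Pearson omnibus
normality check per group, pooled-variance (Student) two-sample t-test,
differences reported as mean difference ± SEM of the difference, significance
at p < 0.05 and trends at p < 0.1.  Normality failures warn but do not switch
the test, and no multiple-testing correction is applied; reports carry the
number of tests performed.  Percent differences are computed from group means
with the SEM propagated by the delta method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .suit_protocol import REFERENCE_STATE, RespState, StateFluxes

__all__ = [
    "FCRProfile",
    "DuplicateVariation",
    "NormalityResult",
    "TTestResult",
    "GroupComparison",
    "compute_fcr",
    "average_duplicates",
    "normalize_to_cs",
    "dagostino_pearson",
    "students_t_two_sample",
    "compare_groups",
    "classify_p",
    "cohort_mean_sem",
]

#: aggregation set for the per-sample duplicate-variation scalar: all states
#: except the FCR reference (whose ratio is identically 1)
NON_REFERENCE_STATES = tuple(s for s in RespState if s is not REFERENCE_STATE)


@dataclass
class FCRProfile:
    """Per-sample dimensionless respiratory profile."""

    sample_id: str
    group: str
    fcr: dict[RespState, float] | None
    rcr: float | None
    flux_per_cs: dict[RespState, float] | None = None
    usable: bool = True
    note: str = ""


@dataclass(frozen=True)
class DuplicateVariation:
    """Technical duplicate agreement: per-state and aggregated percent."""

    per_state_pct: dict[RespState, float]
    scalar_pct: float


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    applicable: bool
    reason: str = ""


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_value: float


@dataclass(frozen=True)
class GroupComparison:
    """Two-group summary for one state (or RCR): A = control, B = affected."""

    state: str
    n_A: int
    n_B: int
    mean_A: float
    sd_A: float
    sem_A: float
    mean_B: float
    sd_B: float
    sem_B: float
    mean_diff: float       # A - B
    sem_diff: float        # sqrt(sem_A^2 + sem_B^2)
    pct_diff: float        # 100*(mean_B - mean_A)/mean_A, signed
    pct_diff_sem: float    # delta-method SEM of pct_diff
    t: float
    df: int
    p_value: float
    normality_p_A: float
    normality_p_B: float
    cls: str               # ns | trend | sig05 | sig01


def classify_p(p: float) -> str:
    if p < 0.01:
        return "sig01"
    if p < 0.05:
        return "sig05"
    if p < 0.1:
        return "trend"
    return "ns"


# ---------------------------------------------------------------------------
# per-sample ratios

def _corrected_map(x: StateFluxes | Mapping[RespState, float]) -> dict[RespState, float]:
    if isinstance(x, StateFluxes):
        if x.corrected is None:
            raise ValueError("state fluxes have not been corrected yet")
        return dict(x.corrected)
    return dict(x)


def compute_fcr(
    corrected: StateFluxes | Mapping[RespState, float],
    sample_id: str = "",
    group: str = "control",
) -> FCRProfile:
    """Flux control ratios (reference CI+CII_ETS) and the RCR for one sample.

    A non-positive reference flux makes the sample unusable; a non-positive
    LEAK leaves the RCR undefined (reported missing) without invalidating the
    FCRs.
    """
    c = _corrected_map(corrected)
    if isinstance(corrected, StateFluxes) and not sample_id:
        sample_id = corrected.sample_id
    ref = c[REFERENCE_STATE]
    if not np.isfinite(ref) or ref <= 0:
        return FCRProfile(
            sample_id=sample_id,
            group=group,
            fcr=None,
            rcr=None,
            usable=False,
            note=f"reference flux (CI+CII ETS) is {ref}; sample unusable",
        )
    fcr = {s: c[s] / ref for s in RespState if s in c}
    fcr[REFERENCE_STATE] = 1.0
    leak = c.get(RespState.LEAK, float("nan"))
    oxphos = c.get(RespState.CI_CII_OXPHOS, float("nan"))
    rcr = oxphos / leak if np.isfinite(leak) and leak > 0 else None
    return FCRProfile(sample_id=sample_id, group=group, fcr=fcr, rcr=rcr)


class PairingError(ValueError):
    """Duplicate runs do not belong to the same sample."""


def _pair_variation(
    m1: Mapping[RespState, float], m2: Mapping[RespState, float]
) -> DuplicateVariation:
    per_state: dict[RespState, float] = {}
    for s in RespState:
        if s in m1 and s in m2:
            x1, x2 = m1[s], m2[s]
            mean = 0.5 * (x1 + x2)
            per_state[s] = 0.0 if mean == 0 else 100.0 * abs(x1 - x2) / mean
    scalar = float(
        np.mean([per_state[s] for s in NON_REFERENCE_STATES if s in per_state])
    )
    return DuplicateVariation(per_state_pct=per_state, scalar_pct=scalar)


def average_duplicates(
    run1: StateFluxes | FCRProfile,
    run2: StateFluxes | FCRProfile,
) -> tuple[dict[RespState, float] | FCRProfile, DuplicateVariation]:
    """Element-wise mean of technical duplicates + their percent variation.

    Accepts either two corrected :class:`StateFluxes` (returns the averaged
    corrected flux map) or two :class:`FCRProfile` (returns an averaged
    profile).  The variation scalar is the mean of 100*|x1-x2|/mean over the
    seven non-reference states (the reference FCR is identically 1).
    """
    if isinstance(run1, StateFluxes) and isinstance(run2, StateFluxes):
        if run1.sample_id != run2.sample_id:
            raise PairingError(
                f"duplicates belong to different samples: "
                f"{run1.sample_id!r} vs {run2.sample_id!r}"
            )
        m1, m2 = _corrected_map(run1), _corrected_map(run2)
        averaged = {s: 0.5 * (m1[s] + m2[s]) for s in m1 if s in m2}
        return averaged, _pair_variation(m1, m2)

    if isinstance(run1, FCRProfile) and isinstance(run2, FCRProfile):
        if run1.sample_id != run2.sample_id:
            raise PairingError(
                f"duplicates belong to different samples: "
                f"{run1.sample_id!r} vs {run2.sample_id!r}"
            )
        if run1.fcr is None or run2.fcr is None:
            raise ValueError("cannot average unusable FCR profiles")
        fcr = {s: 0.5 * (run1.fcr[s] + run2.fcr[s]) for s in run1.fcr}
        rcr = (
            0.5 * (run1.rcr + run2.rcr)
            if run1.rcr is not None and run2.rcr is not None
            else None
        )
        prof = FCRProfile(
            sample_id=run1.sample_id, group=run1.group, fcr=fcr, rcr=rcr
        )
        return prof, _pair_variation(run1.fcr, run2.fcr)

    raise TypeError("average_duplicates expects two StateFluxes or two FCRProfile")


def normalize_to_cs(
    corrected: StateFluxes | Mapping[RespState, float],
    cs_mean_activity: float,
) -> dict[RespState, float]:
    """Absolute flux per CS unit: corrected[s] / activity, for every state."""
    if not np.isfinite(cs_mean_activity) or cs_mean_activity <= 0:
        raise ValueError(
            f"CS activity must be > 0 to normalize (got {cs_mean_activity})"
        )
    c = _corrected_map(corrected)
    return {s: v / cs_mean_activity for s, v in c.items()}


# ---------------------------------------------------------------------------
# statistics

def dagostino_pearson(sample: Sequence[float]) -> NormalityResult:
    """D'Agostino-Pearson omnibus K2 test (skewness + kurtosis, chi2 df=2)."""
    x = np.asarray(sample, dtype=float)
    if len(x) < 8:
        return NormalityResult(
            float("nan"), float("nan"), False,
            f"n={len(x)} < 8: omnibus test not applicable",
        )
    if float(np.std(x)) == 0.0:
        return NormalityResult(
            float("nan"), float("nan"), False, "degenerate constant sample"
        )
    with warnings.catch_warnings():
        # scipy warns that kurtosistest is approximate for n < 20; the
        # omnibus test is still the procedure of record at n = 12
        warnings.simplefilter("ignore")
        k2, p = stats.normaltest(x)
    return NormalityResult(float(k2), float(p), True)


def students_t_two_sample(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> TTestResult:
    """Pooled-variance (Student) two-sample t-test, two-tailed."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 observations")
    df = len(a) + len(b) - 2
    pooled = (
        (len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1)
    ) / df
    if pooled == 0.0:
        if np.mean(a) == np.mean(b):
            return TTestResult(0.0, df, 1.0)
        warnings.warn(
            "zero pooled variance with unequal means: degenerate t-test (p=0)",
            stacklevel=2,
        )
        return TTestResult(math.copysign(math.inf, np.mean(a) - np.mean(b)), df, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(t), df, float(p))


def _compare_one(
    state: str, a: np.ndarray, b: np.ndarray
) -> GroupComparison:
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    sd_a = float(np.std(a, ddof=1))
    sd_b = float(np.std(b, ddof=1))
    sem_a = sd_a / math.sqrt(len(a))
    sem_b = sd_b / math.sqrt(len(b))
    sem_diff = math.sqrt(sem_a**2 + sem_b**2)
    tt = students_t_two_sample(a, b)
    norm_a = dagostino_pearson(a)
    norm_b = dagostino_pearson(b)
    for grp, res in (("A", norm_a), ("B", norm_b)):
        if res.applicable and res.p_value < 0.05:
            warnings.warn(
                f"{state}: group {grp} fails normality (p={res.p_value:.3g}); "
                "Student's t-test applied regardless",
                stacklevel=3,
            )
    if mean_a != 0:
        pct = 100.0 * (mean_b - mean_a) / mean_a
        pct_sem = (
            100.0
            / abs(mean_a)
            * math.sqrt(sem_b**2 + (mean_b / mean_a * sem_a) ** 2)
        )
    else:
        pct, pct_sem = float("nan"), float("nan")
    return GroupComparison(
        state=state,
        n_A=len(a),
        n_B=len(b),
        mean_A=mean_a,
        sd_A=sd_a,
        sem_A=sem_a,
        mean_B=mean_b,
        sd_B=sd_b,
        sem_B=sem_b,
        mean_diff=mean_a - mean_b,
        sem_diff=sem_diff,
        pct_diff=pct,
        pct_diff_sem=pct_sem,
        t=tt.t,
        df=tt.df,
        p_value=tt.p_value,
        normality_p_A=norm_a.p_value,
        normality_p_B=norm_b.p_value,
        cls=classify_p(tt.p_value),
    )


def compare_groups(
    profiles_a: Iterable[FCRProfile],
    profiles_b: Iterable[FCRProfile],
    which: str = "fcr",
) -> list[GroupComparison]:
    """One GroupComparison per state for the chosen normalization mode.

    ``which`` selects the per-sample quantity: ``fcr`` (states except the
    reference, whose ratio is identically 1 in every sample), ``flux_per_cs``
    (states except ROX, identically 0 after correction) or ``rcr`` (a single
    row).  Samples missing the quantity are dropped per state; a state with
    fewer than 2 values in either group is excluded with a warning.
    """
    pa = [p for p in profiles_a if p.usable]
    pb = [p for p in profiles_b if p.usable]
    if len(pa) < 2 or len(pb) < 2:
        raise ValueError("need at least 2 usable samples per group")

    def collect(profiles: list[FCRProfile], getter) -> np.ndarray:
        vals = [getter(p) for p in profiles]
        return np.array([v for v in vals if v is not None and np.isfinite(v)])

    if which == "rcr":
        a = collect(pa, lambda p: p.rcr)
        b = collect(pb, lambda p: p.rcr)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("fewer than 2 RCR values per group")
        return [_compare_one("RCR", a, b)]

    if which == "fcr":
        states = [s for s in RespState if s is not REFERENCE_STATE]
        getter = lambda p, s: None if p.fcr is None else p.fcr.get(s)
    elif which == "flux_per_cs":
        states = [s for s in RespState if s is not RespState.ROX]
        getter = lambda p, s: (
            None if p.flux_per_cs is None else p.flux_per_cs.get(s)
        )
    else:
        raise ValueError(f"unknown comparison mode {which!r}")

    out: list[GroupComparison] = []
    for s in states:
        a = collect(pa, lambda p: getter(p, s))
        b = collect(pb, lambda p: getter(p, s))
        if len(a) < 2 or len(b) < 2:
            warnings.warn(
                f"state {s.value} excluded from {which} comparison: fewer "
                "than 2 values in a group",
                stacklevel=2,
            )
            continue
        out.append(_compare_one(s.value, a, b))
    return out


def cohort_mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """Mean ± SEM of a cohort-level summary sequence."""
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        return (float("nan"), float("nan"))
    sem = float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else float("nan")
    return (float(np.mean(x)), sem)
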