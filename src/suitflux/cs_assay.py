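"""Citrate synthase activity from DTNB-coupled 412 nm kinetics.

Citrate synthase (CS) releases CoA-SH, which cleaves DTNB into TNB; TNB
absorbs at 412 nm with extinction coefficient ~13.6 mM^-1 cm^-1, so the
initial linear rise of A412 is proportional to enzyme activity:

    activity [umol/ml/min] = (dA/dt) / (epsilon * pathlength)
                             * dilution_factor * assay_to_sample_volume_ratio

(1 mM == 1 umol/ml, hence the unit collapse).  The rate comes from an
ordinary least-squares fit over the early linear phase; a negative fitted
rate marks a failed well and is clamped to zero activity with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .trace_model import CSKinetics

__all__ = [
    "CSActivity",
    "CohortDuplicateSummary",
    "DEFAULT_EPSILON_TNB_mM_cm",
    "DEFAULT_RATE_WINDOW_MIN",
    "cs_activity_from_kinetics",
    "duplicate_variation_pct",
    "summarize_cs_duplicates",
]

DEFAULT_EPSILON_TNB_mM_cm = 13.6
DEFAULT_RATE_WINDOW_MIN = (0.0, 1.5)


@dataclass(frozen=True)
class CSActivity:
    """Per-sample CS result: duplicate activities, their mean and spread."""

    sample_id: str
    replicate_activities: tuple[float, ...]
    mean_activity: float           # umol/ml/min
    duplicate_variation_pct: float


@dataclass(frozen=True)
class CohortDuplicateSummary:
    """Mean +/- SEM of the per-sample duplicate variation across a cohort."""

    mean_pct: float
    sem_pct: float
    n_samples: int


def cs_activity_from_kinetics(
    kin: CSKinetics,
    epsilon_mM_cm: float = DEFAULT_EPSILON_TNB_mM_cm,
    rate_window_min: tuple[float, float] = DEFAULT_RATE_WINDOW_MIN,
) -> float:
    """CS activity (umol/ml/min) from one absorbance-vs-time curve."""
    if epsilon_mM_cm <= 0:
        raise ValueError("extinction coefficient must be > 0")
    lo, hi = rate_window_min
    mask = (kin.time_min >= lo) & (kin.time_min <= hi)
    if int(mask.sum()) < 3:
        raise ValueError(
            f"rate window [{lo}, {hi}] min contains only {int(mask.sum())} "
            "points; need at least 3"
        )
    rate_au_per_min = float(
        np.polyfit(kin.time_min[mask], kin.absorbance_412[mask], 1)[0]
    )
    if rate_au_per_min < 0:
        warnings.warn(
            f"negative A412 rate for sample {kin.sample_id!r} "
            f"r{kin.replicate}; clamping activity to 0 (assay failure)",
            stacklevel=2,
        )
        return 0.0
    return (
        rate_au_per_min
        / (epsilon_mM_cm * kin.pathlength_cm)
        * kin.dilution_factor
        * kin.assay_to_sample_volume_ratio
    )


def duplicate_variation_pct(a1: float, a2: float) -> float:
    """100*|a1-a2|/mean(a1,a2); symmetric and scale-invariant; 0 for (0,0)."""
    mean = 0.5 * (a1 + a2)
    if mean == 0:
        return 0.0
    return 100.0 * abs(a1 - a2) / mean


def summarize_cs_duplicates(
    records: Iterable[tuple[str, int, float]],
) -> tuple[list[CSActivity], CohortDuplicateSummary]:
    """Per-sample duplicate summaries + cohort duplicate-variation mean ± SEM.

    ``records`` are (sample_id, replicate, activity) triples; each sample
    must appear with exactly replicates 1 and 2, otherwise it is excluded
    with a warning.
    """
    by_sample: dict[str, dict[int, float]] = {}
    for sample_id, replicate, activity in records:
        by_sample.setdefault(sample_id, {})[int(replicate)] = float(activity)

    results: list[CSActivity] = []
    for sample_id, reps in by_sample.items():
        if set(reps) != {1, 2}:
            warnings.warn(
                f"sample {sample_id!r} lacks a complete CS duplicate pair "
                f"(replicates {sorted(reps)}); excluded",
                stacklevel=2,
            )
            continue
        a1, a2 = reps[1], reps[2]
        results.append(
            CSActivity(
                sample_id=sample_id,
                replicate_activities=(a1, a2),
                mean_activity=0.5 * (a1 + a2),
                duplicate_variation_pct=duplicate_variation_pct(a1, a2),
            )
        )

    variations = np.array([r.duplicate_variation_pct for r in results])
    if len(variations) == 0:
        summary = CohortDuplicateSummary(float("nan"), float("nan"), 0)
    else:
        sem = (
            float(np.std(variations, ddof=1) / np.sqrt(len(variations)))
            if len(variations) > 1
            else float("nan")
        )
        summary = CohortDuplicateSummary(
            mean_pct=float(np.mean(variations)),
            sem_pct=sem,
            n_samples=len(variations),
        )
    return results, summary
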