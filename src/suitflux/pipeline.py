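"""Run orchestration: analyze (traces -> per-sample table) and compare.

``analyze`` drives each chamber run through flux computation, SUIT state
extraction, ROX/autoxidation corrections and the cytochrome-c check,
averages technical duplicates, computes FCR/RCR and CS-normalized fluxes,
and emits ``samples.tsv`` + ``qc.tsv``.  ``compare`` turns the per-sample
table into ``comparison.tsv`` with one row per state and normalization mode
(flux control ratios, flux per CS unit) plus the RCR row, and optionally
bar-chart figures.  Failed-QC samples are flagged in analyze but retained;
exclusion happens (by default) at the comparison stage.  Both stages are
pure functions of their inputs — re-running is bit-identical — and every
output row carries the run-config hash and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cs_assay import cs_activity_from_kinetics, summarize_cs_duplicates
from .flux_engine import DEFAULT_SMOOTHING_HALFWIDTH_S, PlateauParams
from .group_stats import (
    FCRProfile,
    average_duplicates,
    compare_groups,
    compute_fcr,
    normalize_to_cs,
)
from .suit_protocol import (
    DEFAULT_CYTC_THRESHOLD_PCT,
    ProtocolError,
    RespState,
    StateFluxes,
    apply_corrections,
    cytc_quality_check,
    extract_from_trace,
    fit_autoxidation,
)
from .trace_model import (
    ChamberTrace,
    CSKinetics,
    TraceFormatError,
    ValidationError,
    read_cs_kinetics,
    read_manifest,
    read_trace,
)

__all__ = [
    "RunConfig",
    "SampleInput",
    "analyze",
    "analyze_cohort",
    "analyze_run",
    "compare",
    "compare_cohort",
    "load_cohort_inputs",
]

log = logging.getLogger("suitflux")

STATE_ORDER = list(RespState)


@dataclass
class RunConfig:
    """Everything a reproducible analyze/compare run needs."""

    manifest: str | None = None
    out_dir: str = "."
    blank_trace: str | None = None
    blank_events: str | None = None
    smoothing_halfwidth_s: float = DEFAULT_SMOOTHING_HALFWIDTH_S
    plateau: PlateauParams = field(default_factory=PlateauParams)
    cytc_threshold_pct: float = DEFAULT_CYTC_THRESHOLD_PCT
    autox_mode: str = "blank"          # blank | constants | off
    autox_a0: float = 0.0
    autox_a1: float = 0.0
    autox_halfwidth_s: float = 120.0
    autox_settle_s: float = 150.0
    civ_subtract_rox: bool = True
    cs_epsilon_mM_cm: float = 13.6
    cs_rate_window_min: tuple[float, float] = (0.0, 1.5)
    exclude_qc_failures: bool = True
    figures: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        plateau = PlateauParams(**raw.pop("plateau", {}))
        if "cs_rate_window_min" in raw:
            raw["cs_rate_window_min"] = tuple(raw["cs_rate_window_min"])
        return cls(plateau=plateau, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cs_rate_window_min"] = list(self.cs_rate_window_min)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:10]


@dataclass
class SampleInput:
    """One biological sample: duplicate chamber runs + duplicate CS wells."""

    sample_id: str
    group: str
    traces: tuple[ChamberTrace, ChamberTrace]
    cs: tuple[CSKinetics, CSKinetics] | None = None


# ---------------------------------------------------------------------------
# core (in-memory) pipeline

def analyze_run(
    trace: ChamberTrace,
    config: RunConfig,
    autox: tuple[float, float],
) -> StateFluxes:
    """Flux -> states -> corrections -> cytochrome-c QC for one chamber run."""
    sf = extract_from_trace(
        trace,
        params=config.plateau,
        smoothing_halfwidth_s=config.smoothing_halfwidth_s,
    )
    apply_corrections(
        sf,
        autox_a0=autox[0],
        autox_a1=autox[1],
        civ_subtract_rox=config.civ_subtract_rox,
    )
    cytc_quality_check(sf, config.cytc_threshold_pct)
    return sf


def _resolve_autox(
    config: RunConfig, blank: ChamberTrace | None
) -> tuple[float, float]:
    if config.autox_mode == "blank":
        if blank is None:
            log.warning(
                "autox_mode is 'blank' but no blank run provided; CIV "
                "autoxidation correction disabled"
            )
            return (0.0, 0.0)
        a0, a1 = fit_autoxidation(
            blank,
            smoothing_halfwidth_s=config.autox_halfwidth_s,
            settle_s=config.autox_settle_s,
        )
        log.info("autoxidation background from blank: a0=%.3f a1=%.4f", a0, a1)
        return (a0, a1)
    if config.autox_mode == "constants":
        return (config.autox_a0, config.autox_a1)
    if config.autox_mode == "off":
        log.warning("CIV autoxidation correction disabled by configuration")
        return (0.0, 0.0)
    raise ValueError(f"unknown autox_mode {config.autox_mode!r}")


def analyze_cohort(
    samples: Iterable[SampleInput],
    blank: ChamberTrace | None = None,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample analysis table + QC table for a whole cohort.

    A failing sample (unreadable trace, protocol violation, unusable
    reference flux) is recorded in the QC table and the run continues.
    """
    rc = config or RunConfig()
    autox = _resolve_autox(rc, blank)
    meta = {"config_hash": rc.config_hash(), "version": __version__}

    rows: list[dict] = []
    qc_rows: list[dict] = []
    for sample in samples:
        try:
            row, qcs = _analyze_sample(sample, rc, autox)
        except (ValidationError, TraceFormatError, ProtocolError, ValueError) as exc:
            log.error("sample %s failed: %s", sample.sample_id, exc)
            qc_rows.append(
                {
                    "sample_id": sample.sample_id,
                    "group": sample.group,
                    "status": "failed",
                    "detail": str(exc),
                    **meta,
                }
            )
            continue
        rows.append(row | meta)
        qc_rows.extend(q | meta for q in qcs)

    samples_df = pd.DataFrame(rows)
    qc_df = pd.DataFrame(qc_rows)
    if samples_df.empty:
        warnings.warn("analyze produced no usable samples", stacklevel=2)
    return samples_df, qc_df


def _analyze_sample(
    sample: SampleInput, rc: RunConfig, autox: tuple[float, float]
) -> tuple[dict, list[dict]]:
    sfs = [analyze_run(tr, rc, autox) for tr in sample.traces]
    averaged, dup_var = average_duplicates(sfs[0], sfs[1])
    profile = compute_fcr(averaged, sample_id=sample.sample_id, group=sample.group)
    if not profile.usable:
        raise ValueError(profile.note)

    qc_pass = all(bool(sf.qc_pass) for sf in sfs)
    row: dict = {
        "sample_id": sample.sample_id,
        "group": sample.group,
        "qc_pass": qc_pass,
        "dup_variation_pct": dup_var.scalar_pct,
        "cytc_increase_pct": float(
            np.mean([sf.cytc_increase_pct for sf in sfs])
        ),
        "rcr": profile.rcr if profile.rcr is not None else np.nan,
    }
    for s in STATE_ORDER:
        row[f"j_{s.value}"] = averaged[s]
        row[f"fcr_{s.value}"] = profile.fcr[s]

    cs_activity = np.nan
    cs_dup = np.nan
    if sample.cs is not None:
        acts = [
            (k.sample_id, k.replicate, cs_activity_from_kinetics(
                k, rc.cs_epsilon_mM_cm, rc.cs_rate_window_min))
            for k in sample.cs
        ]
        per_sample, _ = summarize_cs_duplicates(acts)
        if per_sample:
            cs_activity = per_sample[0].mean_activity
            cs_dup = per_sample[0].duplicate_variation_pct
    row["cs_activity"] = cs_activity
    row["cs_dup_variation_pct"] = cs_dup
    if np.isfinite(cs_activity) and cs_activity > 0:
        per_cs = normalize_to_cs(averaged, cs_activity)
        for s in STATE_ORDER:
            if s is not RespState.ROX:
                row[f"jcs_{s.value}"] = per_cs[s]
    else:
        for s in STATE_ORDER:
            if s is not RespState.ROX:
                row[f"jcs_{s.value}"] = np.nan

    qcs = [
        {
            "sample_id": sample.sample_id,
            "group": sample.group,
            "replicate": sf.replicate,
            "status": "ok" if sf.qc_pass else "flagged",
            "cytc_increase_pct": sf.cytc_increase_pct,
            "rox_flux": sf.rox_flux,
            "autox_a0": sf.autox_params_used[0],
            "autox_a1": sf.autox_params_used[1],
            "detail": "; ".join(sf.qc_notes),
        }
        for sf in sfs
    ]
    return row, qcs


def profiles_from_table(samples_df: pd.DataFrame) -> list[FCRProfile]:
    """Rebuild per-sample profiles from a samples table (round-trip safe)."""
    profiles = []
    for r in samples_df.itertuples(index=False):
        fcr = {s: getattr(r, f"fcr_{s.value}") for s in STATE_ORDER}
        per_cs = {
            s: getattr(r, f"jcs_{s.value}")
            for s in STATE_ORDER
            if s is not RespState.ROX
        }
        has_cs = all(np.isfinite(v) for v in per_cs.values())
        profiles.append(
            FCRProfile(
                sample_id=r.sample_id,
                group=r.group,
                fcr=fcr,
                rcr=None if not np.isfinite(r.rcr) else float(r.rcr),
                flux_per_cs=per_cs if has_cs else None,
            )
        )
    return profiles


def compare_cohort(
    samples_df: pd.DataFrame, config: RunConfig | None = None
) -> pd.DataFrame:
    """GroupComparison rows for FCR, flux-per-CS and RCR normalizations."""
    rc = config or RunConfig()
    df = samples_df
    if rc.exclude_qc_failures and "qc_pass" in df.columns:
        dropped = int((~df["qc_pass"].astype(bool)).sum())
        if dropped:
            log.info("excluding %d QC-failed sample(s) from comparison", dropped)
        df = df[df["qc_pass"].astype(bool)]
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        warnings.warn("fewer than two groups: comparison skipped", stacklevel=2)
        return pd.DataFrame()

    prof = profiles_from_table(df)
    prof_a = [p for p in prof if p.group == "control"]
    prof_b = [p for p in prof if p.group == "affected"]

    rows = []
    meta = {"config_hash": rc.config_hash(), "version": __version__}
    for mode in ("fcr", "flux_per_cs"):
        try:
            comps = compare_groups(prof_a, prof_b, which=mode)
        except ValueError as exc:
            log.warning("%s comparison skipped: %s", mode, exc)
            continue
        rows.extend({"mode": mode, **asdict(c), **meta} for c in comps)
    try:
        (rcr_comp,) = compare_groups(prof_a, prof_b, which="rcr")
        rows.append({"mode": "rcr", **asdict(rcr_comp), **meta})
    except ValueError as exc:
        log.warning("RCR comparison skipped: %s", exc)

    out = pd.DataFrame(rows)
    if len(out):
        out["n_tests"] = len(out)   # no multiple-testing correction applied
    return out


# ---------------------------------------------------------------------------
# file-based front ends

def load_cohort_inputs(
    config: RunConfig,
) -> tuple[list[SampleInput], ChamberTrace | None, list[dict]]:
    """Materialize SampleInputs from the manifest (and the blank pair).

    An unreadable or invalid per-sample file does not abort the load: the
    sample is reported in the returned failure records instead.
    """
    if config.manifest is None:
        raise ValueError("run config has no manifest path")
    manifest_path = Path(config.manifest)
    base = manifest_path.parent
    mdf = read_manifest(manifest_path)

    inputs: list[SampleInput] = []
    failures: list[dict] = []
    for sample_id, sub in mdf.groupby("sample_id", sort=False):
        sub = sub.sort_values("replicate")
        try:
            traces = []
            wells = []
            for r in sub.itertuples(index=False):
                meta = {
                    "sample_id": sample_id,
                    "group": r.group,
                    "replicate": int(r.replicate),
                    "tissue_mass_mg": float(r.tissue_mass_mg),
                }
                traces.append(
                    read_trace(base / r.trace_path, base / r.events_path, meta)
                )
                if "cs_path" in sub.columns and isinstance(r.cs_path, str):
                    wells.append(read_cs_kinetics(base / r.cs_path, meta))
            if len(traces) != 2:
                raise ValidationError(
                    f"sample {sample_id!r} has {len(traces)} runs; "
                    "duplicates required"
                )
        except (ValidationError, TraceFormatError, OSError) as exc:
            log.error("cannot load sample %s: %s", sample_id, exc)
            failures.append(
                {
                    "sample_id": str(sample_id),
                    "group": str(sub["group"].iloc[0]),
                    "status": "failed",
                    "detail": str(exc),
                }
            )
            continue
        inputs.append(
            SampleInput(
                sample_id=str(sample_id),
                group=str(sub["group"].iloc[0]),
                traces=(traces[0], traces[1]),
                cs=(wells[0], wells[1]) if len(wells) == 2 else None,
            )
        )

    blank = None
    if config.blank_trace and config.blank_events:
        blank = read_trace(
            config.blank_trace,
            config.blank_events,
            {"sample_id": "blank", "group": "blank"},
        )
    return inputs, blank, failures


def analyze(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """File-based analyze: manifest -> samples.tsv + qc.tsv in out_dir."""
    inputs, blank, failures = load_cohort_inputs(config)
    samples_df, qc_df = analyze_cohort(inputs, blank, config)
    if failures:
        meta = {"config_hash": config.config_hash(), "version": __version__}
        qc_df = pd.concat(
            [qc_df, pd.DataFrame([f | meta for f in failures])],
            ignore_index=True,
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples_df.to_csv(out / "samples.tsv", sep="\t", index=False)
    qc_df.to_csv(out / "qc.tsv", sep="\t", index=False)
    log.info(
        "analyze: %d sample(s), %d QC record(s)", len(samples_df), len(qc_df)
    )
    return samples_df, qc_df


def compare(
    config: RunConfig, samples_df: pd.DataFrame | None = None
) -> pd.DataFrame:
    """File-based compare: samples.tsv -> comparison.tsv (+ figures)."""
    out = Path(config.out_dir)
    if samples_df is None:
        path = out / "samples.tsv"
        if not path.exists():
            raise FileNotFoundError(f"{path} not found; run analyze first")
        samples_df = pd.read_csv(path, sep="\t")
    comparison = compare_cohort(samples_df, config)
    out.mkdir(parents=True, exist_ok=True)
    comparison.to_csv(out / "comparison.tsv", sep="\t", index=False)
    if config.figures and len(comparison):
        from .figures import make_figures

        make_figures(samples_df, comparison, out)
    return comparison
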