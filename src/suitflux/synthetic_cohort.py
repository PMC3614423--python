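"""Synthetic oxygraph cohorts with stored ground truth.

The generator is phenomenological at the state-flux level: each sample owns a
true flux-control-ratio vector and an absolute respiratory scale, each
chamber run realizes the SUIT titration schedule as a piecewise-relaxing O2
consumption curve, and the chamber O2 concentration is obtained by
integrating the flux and adding white measurement noise.  Defaults encode the
statistical structure of a two-group (control vs. affected) striatal
homogenate comparison:

* group effects: -5.2% CI+CII_OXPHOS, -11.7% CII_ETS, -11.1% CIV_MAX FCR in
  the affected group, nothing on LEAK or CI_OXPHOS;
* inter-sample FCR dispersion 10.5% CV, applied multiplicatively
  (lognormal, mean 1) to the seven non-reference states — the reference
  state CI+CII_ETS instead carries the 25% CV absolute-scale noise, which
  FCR normalization must cancel;
* technical duplicates perturbed per state by 0.9% (control) / 2.3%
  (affected) CV;
* citrate synthase activity with 38.5% CV across samples, 3.6% CV between
  duplicates and no group effect.

Ground truth (true FCRs, true per-duplicate state fluxes, true CS
activities, noise-free flux series) is stored alongside, so every pipeline
output has an exact counterpart to diff against.  Reproducibility: each
sample draws from an independent child stream of the cohort seed keyed by
(group, sample index), so changing ``n_per_group`` never reshuffles earlier
samples, and the same config + seed is byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .cs_assay import DEFAULT_EPSILON_TNB_mM_cm as _EPSILON_TNB
from .suit_protocol import RespState
from .trace_model import (
    ChamberTrace,
    CSKinetics,
    TitrationEvent,
    write_cs_kinetics,
    write_manifest,
    write_trace,
)

__all__ = [
    "SimConfig",
    "SampleGroundTruth",
    "GroundTruth",
    "SampleSim",
    "CohortSim",
    "simulate_sample",
    "simulate_blank",
    "simulate_cohort",
]

#: SUIT schedule: per-segment durations in seconds.  Chosen so that the
#: steady-state extraction noise floor sits well below the technical
#: duplicate variation at every state; low-flux states (LEAK, ROX) get the
#: longest windows (see docs/methods.md for the noise budget).
SCHEDULE_S = {
    "baseline": 120.0,
    "malate": 60.0,
    "pyruvate": 60.0,
    "leak": 1200.0,       # glutamate -> adp
    "ci_oxphos": 420.0,
    "cytc": 420.0,
    "ci_cii_oxphos": 420.0,
    "fccp_step": 300.0,
    "cii_ets": 600.0,
    "rox": 1500.0,
    "tmpd_to_ascorbate": 20.0,
    "civ": 480.0,
}

BLANK_DURATION_S = 9000.0
BLANK_TMPD_S = 120.0

#: fractional approach of LEAK respiration after each CI substrate
_CI_SUBSTRATE_RAMP = {"malate": 0.3, "pyruvate": 0.7, "glutamate": 1.0}
#: CIV flux fraction reached on TMPD alone, before ascorbate
_TMPD_PARTIAL = 0.6

_EVENT_AMOUNTS = {
    # titrated final concentrations, recorded verbatim and never computed on
    "malate": (0.8, "mM"),
    "pyruvate": (2.0, "mM"),
    "glutamate": (10.0, "mM"),
    "adp": (2.25, "mM"),
    "cytochrome_c": (10.0, "mM"),
    "succinate": (10.0, "mM"),
    "fccp": (1.0, "pmol/step"),
    "rotenone": (2.5, "uM"),
    "antimycin_a": (2.5, "mM"),
    "tmpd": (0.5, "mM"),
    "ascorbate": (2.0, "mM"),
}

_NOISED_STATES = (
    RespState.LEAK,
    RespState.CI_OXPHOS,
    RespState.CI_CII_OXPHOS,
    RespState.CII_ETS,
    RespState.CIV_MAX,
)


def _default_baseline_fcr() -> dict[RespState, float]:
    return {
        RespState.LEAK: 0.08,
        RespState.CI_OXPHOS: 0.55,
        RespState.CI_OXPHOS_CYTC: 0.55,
        RespState.CI_CII_OXPHOS: 0.673,
        RespState.CI_CII_ETS: 1.0,
        RespState.CII_ETS: 0.350,
        RespState.CIV_MAX: 1.342,
    }


def _default_effect_pct() -> dict[RespState, float]:
    return {
        RespState.CI_CII_OXPHOS: 5.2,
        RespState.CII_ETS: 11.7,
        RespState.CIV_MAX: 11.1,
    }


@dataclass
class SimConfig:
    """Full generative model for one synthetic cohort.

    The LEAK and CI_OXPHOS baseline FCRs (0.08 / 0.55) are declared
    assumptions anchoring states without a configured group effect; the
    CI+CII_OXPHOS, CII_ETS and CIV_MAX baselines follow from the effect
    profile (absolute difference / fractional difference).
    """

    n_per_group: int = 12
    baseline_fcr: dict[RespState, float] = field(default_factory=_default_baseline_fcr)
    effect_pct: dict[RespState, float] = field(default_factory=_default_effect_pct)
    fcr_cv_pct: float = 10.5
    duplicate_cv_pct: dict[str, float] = field(
        default_factory=lambda: {"control": 0.9, "affected": 2.3}
    )
    abs_scale_flux: float = 80.0       # pmol/(s*ml) for CI+CII_ETS
    abs_scale_cv_pct: float = 25.0
    rox_flux_frac: float = 0.05        # ROX as fraction of the sample's ETS flux
    cytc_effect_pct: float = 0.0       # flux change on exogenous cytochrome c
    cs_mean: float = 0.12              # umol/ml/min
    cs_cv_pct: float = 38.5
    cs_duplicate_cv_pct: float = 3.6
    autox_a0: float = 10.0             # pmol/(s*ml)
    autox_a1: float = 0.05             # pmol/(s*ml) per uM O2
    dt_s: float = 2.0
    sigma_o2_uM: float = 0.2
    tau_s: float = 20.0                # chamber mixing/response time constant
    initial_o2_uM: float = 190.0
    reox_threshold_uM: float = 20.0
    fccp_steps: int = 3
    fccp_step_multipliers: tuple[float, ...] = (0.85, 1.0, 0.97)
    cs_sigma_au: float = 0.002
    cs_n_points: int = 10
    cs_window_min: float = 1.5
    cs_pathlength_cm: float = 1.0
    cs_dilution_factor: float = 1.0
    cs_assay_volume_ratio: float = 10.0
    seed: int = 0
    store_flux_series: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if abs(self.baseline_fcr[RespState.CI_CII_ETS] - 1.0) > 1e-12:
            raise ValueError("the reference baseline FCR (CI+CII_ETS) must be 1")
        for name, cv in [
            ("fcr_cv_pct", self.fcr_cv_pct),
            ("abs_scale_cv_pct", self.abs_scale_cv_pct),
            ("cs_cv_pct", self.cs_cv_pct),
            ("cs_duplicate_cv_pct", self.cs_duplicate_cv_pct),
            *[(f"duplicate_cv_pct[{g}]", v) for g, v in self.duplicate_cv_pct.items()],
        ]:
            if cv < 0:
                raise ValueError(f"{name} must be >= 0, got {cv}")
        if len(self.fccp_step_multipliers) != self.fccp_steps:
            raise ValueError("need one FCCP multiplier per step")
        for s, base in self.baseline_fcr.items():
            if base <= 0:
                raise ValueError(f"baseline FCR for {s} must be > 0")
            eff = self.effect_pct.get(s, 0.0)
            if base * (1 - eff / 100.0) < 0:
                raise ValueError(f"effect for {s} implies a negative flux")
        if self.abs_scale_flux <= 0 or self.rox_flux_frac < 0:
            raise ValueError("abs_scale_flux must be > 0 and rox_flux_frac >= 0")


@dataclass
class SampleGroundTruth:
    sample_id: str
    group: str
    scale: float                                  # true CI+CII_ETS flux
    true_fcr: dict[RespState, float]
    rox_flux: float
    true_state_flux: dict[int, dict[RespState, float]]   # per duplicate, mito
    true_raw_flux: dict[int, dict[RespState, float]]     # per duplicate, + ROX
    cs_activity: float
    cs_replicates: tuple[float, float]
    flux_series: dict[int, np.ndarray] | None = None     # noise-free chamber flux


@dataclass
class GroundTruth:
    config: SimConfig
    autox: tuple[float, float]
    samples: list[SampleGroundTruth] = field(default_factory=list)


@dataclass
class SampleSim:
    sample_id: str
    group: str
    traces: tuple[ChamberTrace, ChamberTrace]
    cs: tuple[CSKinetics, CSKinetics]
    truth: SampleGroundTruth


@dataclass
class CohortSim:
    config: SimConfig
    samples: list[SampleSim]
    blank: ChamberTrace
    truth: GroundTruth


# ---------------------------------------------------------------------------
# low-level draws

def _lognormal_factor(rng: np.random.Generator, cv_pct: float, size=None):
    """Multiplicative lognormal noise with mean exactly 1."""
    cv = cv_pct / 100.0
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def _sample_rng(config: SimConfig, group: str, sample_index: int) -> np.random.Generator:
    gi = {"control": 0, "affected": 1}[group]
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(gi, sample_index))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# schedule and chamber physics

def _build_schedule(config: SimConfig) -> tuple[list[tuple[float, str, int]], float]:
    """(event time, agent, step_index) list and total run duration."""
    s = SCHEDULE_S
    t = s["baseline"]
    out: list[tuple[float, str, int]] = [(t, "malate", 1)]
    t += s["malate"]
    out.append((t, "pyruvate", 1))
    t += s["pyruvate"]
    out.append((t, "glutamate", 1))
    t += s["leak"]
    out.append((t, "adp", 1))
    t += s["ci_oxphos"]
    out.append((t, "cytochrome_c", 1))
    t += s["cytc"]
    out.append((t, "succinate", 1))
    t += s["ci_cii_oxphos"]
    for k in range(config.fccp_steps):
        out.append((t, "fccp", k + 1))
        t += s["fccp_step"]
    out.append((t, "rotenone", 1))
    t += s["cii_ets"]
    out.append((t, "antimycin_a", 1))
    t += s["rox"]
    out.append((t, "tmpd", 1))
    t += s["tmpd_to_ascorbate"]
    out.append((t, "ascorbate", 1))
    t += s["civ"]
    return out, t


def _segment_targets(
    schedule: list[tuple[float, str, int]],
    flux: dict[RespState, float],
    rox: float,
) -> list[tuple[float, float, bool]]:
    """(segment start, baseline observed flux, autoxidation active) list."""
    segs: list[tuple[float, float, bool]] = [(0.0, rox, False)]
    leak = flux[RespState.LEAK]
    for t, agent, step in schedule:
        if agent in _CI_SUBSTRATE_RAMP:
            segs.append((t, rox + _CI_SUBSTRATE_RAMP[agent] * leak, False))
        elif agent == "adp":
            segs.append((t, rox + flux[RespState.CI_OXPHOS], False))
        elif agent == "cytochrome_c":
            segs.append((t, rox + flux[RespState.CI_OXPHOS_CYTC], False))
        elif agent == "succinate":
            segs.append((t, rox + flux[RespState.CI_CII_OXPHOS], False))
        elif agent == "fccp":
            segs.append((t, rox + flux[RespState.CI_CII_ETS], False))
        elif agent == "rotenone":
            segs.append((t, rox + flux[RespState.CII_ETS], False))
        elif agent == "antimycin_a":
            segs.append((t, rox, False))
        elif agent == "tmpd":
            segs.append((t, rox + _TMPD_PARTIAL * flux[RespState.CIV_MAX], True))
        elif agent == "ascorbate":
            segs.append((t, rox + flux[RespState.CIV_MAX], True))
    return segs


def _integrate_chamber(
    t: np.ndarray,
    segments: list[tuple[float, float, bool]],
    config: SimConfig,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Relaxation flux dynamics + O2 integration + reoxygenation resets.

    Flux relaxes exponentially (time constant tau) toward each segment's
    target; in autoxidation segments the target additionally carries
    a0 + a1*C(t), handled by fixed-point iteration (the O2 feedback on the
    autoxidation rate is weak, three iterations converge far below the
    measurement noise).  Whenever the noise-free O2 would fall below the
    reoxygenation threshold it is reset to the initial concentration and the
    reset time is recorded.
    """
    dt = config.dt_s
    n = len(t)
    c_est = np.full(n, config.initial_o2_uM)
    bounds = [s[0] for s in segments] + [t[-1] + dt]
    reox: list[float] = []
    jflux = np.zeros(n)
    for _ in range(3):
        j0 = segments[0][1]
        for k, (ts, base, ax) in enumerate(segments):
            i0 = int(np.searchsorted(t, ts))
            i1 = int(np.searchsorted(t, bounds[k + 1]))
            if i1 <= i0:
                continue
            target = base + (
                np.maximum(0.0, config.autox_a0 + config.autox_a1 * c_est[i0:i1])
                if ax
                else 0.0
            )
            rel = np.exp(-(t[i0:i1] - ts) / config.tau_s)
            jflux[i0:i1] = target + (j0 - target) * rel
            j0 = float(jflux[i1 - 1])
        # O2 balance: C[i] = C0 - sum_{k<i} J[k]*dt/1000  (uM; flux in pmol/(s*ml))
        c_nf = config.initial_o2_uM - np.concatenate(
            ([0.0], np.cumsum(jflux[:-1]))
        ) * dt / 1000.0
        reox = []
        while True:
            below = np.nonzero(c_nf < config.reox_threshold_uM)[0]
            if len(below) == 0:
                break
            i = int(below[0])
            reox.append(float(t[i]))
            c_nf[i:] += config.initial_o2_uM - c_nf[i]
        c_est = c_nf
    return jflux, c_est, reox


def _make_events(
    schedule: list[tuple[float, str, int]], reox_times: list[float], config: SimConfig
) -> list[TitrationEvent]:
    events = [
        TitrationEvent(
            time_s=t,
            agent=agent,
            amount=_EVENT_AMOUNTS[agent][0],
            unit=_EVENT_AMOUNTS[agent][1],
            step_index=step,
        )
        for t, agent, step in schedule
    ]
    sched_times = {t for t, _, _ in schedule}
    for r in reox_times:
        while r in sched_times:   # avoid exact collision with a titration
            r += 0.5 * config.dt_s
        events.append(
            TitrationEvent(
                time_s=r,
                agent="reoxygenation",
                amount=config.initial_o2_uM,
                unit="uM",
            )
        )
    return sorted(events, key=lambda e: e.time_s)


# ---------------------------------------------------------------------------
# sample and cohort generation

def _true_fcr_vector(
    config: SimConfig, group: str, rng: np.random.Generator
) -> dict[RespState, float]:
    affected = group == "affected"
    fcr: dict[RespState, float] = {}
    for s in _NOISED_STATES:
        base = config.baseline_fcr[s]
        if affected:
            base *= 1.0 - config.effect_pct.get(s, 0.0) / 100.0
        fcr[s] = base * float(_lognormal_factor(rng, config.fcr_cv_pct))
    # the cytochrome-c state tracks the sample's CI_OXPHOS flux: the check
    # probes membrane integrity, not an independent respiratory capacity
    fcr[RespState.CI_OXPHOS_CYTC] = fcr[RespState.CI_OXPHOS] * (
        1.0 + config.cytc_effect_pct / 100.0
    )
    fcr[RespState.CI_CII_ETS] = 1.0
    return fcr


def simulate_sample(
    config: SimConfig, group: str, sample_index: int
) -> SampleSim:
    """Generate one sample: duplicate chamber runs, duplicate CS wells, truth.

    Deterministic in (config.seed, group, sample_index) via an independent
    child random stream per sample.
    """
    if group not in ("control", "affected"):
        raise ValueError(f"group must be 'control' or 'affected', got {group!r}")
    rng = _sample_rng(config, group, sample_index)
    sample_id = f"{'ctl' if group == 'control' else 'aff'}{sample_index + 1:02d}"

    scale = config.abs_scale_flux * float(
        _lognormal_factor(rng, config.abs_scale_cv_pct)
    )
    fcr_true = _true_fcr_vector(config, group, rng)
    rox = config.rox_flux_frac * scale * float(
        _lognormal_factor(rng, config.fcr_cv_pct)
    )
    cs_true = config.cs_mean * float(_lognormal_factor(rng, config.cs_cv_pct))
    tissue_mass = float(rng.uniform(5.0, 10.0))

    schedule, duration = _build_schedule(config)
    t = np.arange(0.0, duration + 0.5 * config.dt_s, config.dt_s)
    dup_cv = config.duplicate_cv_pct[group]

    traces: list[ChamberTrace] = []
    cs_wells: list[CSKinetics] = []
    cs_replicate_truth: list[float] = []
    true_state: dict[int, dict[RespState, float]] = {}
    true_raw: dict[int, dict[RespState, float]] = {}
    series: dict[int, np.ndarray] = {}
    for replicate in (1, 2):
        flux_r = {
            s: fcr_true[s] * scale * float(_lognormal_factor(rng, dup_cv))
            for s in RespState
            if s is not RespState.ROX
        }
        rox_r = rox * float(_lognormal_factor(rng, dup_cv))
        segments = _segment_targets(schedule, flux_r, rox_r)
        jflux, c_nf, reox_times = _integrate_chamber(t, segments, config)
        c_obs = np.maximum(
            0.0, c_nf + rng.normal(0.0, config.sigma_o2_uM, len(t))
        )
        events = _make_events(schedule, reox_times, config)
        traces.append(
            ChamberTrace(
                sample_id=sample_id,
                group=group,
                replicate=replicate,
                time_s=t.copy(),
                o2_conc_uM=c_obs,
                events=events,
                tissue_mass_mg=tissue_mass,
            )
        )
        true_state[replicate] = dict(flux_r) | {RespState.ROX: 0.0}
        true_raw[replicate] = {s: v + rox_r for s, v in flux_r.items()} | {
            RespState.ROX: rox_r
        }
        if config.store_flux_series:
            series[replicate] = jflux.copy()

        cs_act = cs_true * float(_lognormal_factor(rng, config.cs_duplicate_cv_pct))
        cs_replicate_truth.append(cs_act)
        # invert the analysis formula: dA/dt = activity * eps * path /
        # (dilution * volume ratio)
        rate_au_min = (
            cs_act
            * _EPSILON_TNB
            * config.cs_pathlength_cm
            / (config.cs_dilution_factor * config.cs_assay_volume_ratio)
        )
        t_min = np.linspace(0.0, config.cs_window_min, config.cs_n_points)
        a412 = (
            0.05
            + rate_au_min * t_min
            + rng.normal(0.0, config.cs_sigma_au, len(t_min))
        )
        cs_wells.append(
            CSKinetics(
                sample_id=sample_id,
                replicate=replicate,
                time_min=t_min,
                absorbance_412=a412,
                pathlength_cm=config.cs_pathlength_cm,
                dilution_factor=config.cs_dilution_factor,
                assay_to_sample_volume_ratio=config.cs_assay_volume_ratio,
            )
        )

    truth = SampleGroundTruth(
        sample_id=sample_id,
        group=group,
        scale=scale,
        true_fcr=fcr_true,
        rox_flux=rox,
        true_state_flux=true_state,
        true_raw_flux=true_raw,
        cs_activity=cs_true,
        cs_replicates=(cs_replicate_truth[0], cs_replicate_truth[1]),
        flux_series=series if config.store_flux_series else None,
    )
    return SampleSim(
        sample_id=sample_id,
        group=group,
        traces=(traces[0], traces[1]),
        cs=(cs_wells[0], cs_wells[1]),
        truth=truth,
    )


def simulate_blank(config: SimConfig) -> ChamberTrace:
    """Tissue-free chemical blank carrying only TMPD/ascorbate autoxidation."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(99,))
    )
    t = np.arange(0.0, BLANK_DURATION_S + 0.5 * config.dt_s, config.dt_s)
    schedule = [
        (BLANK_TMPD_S, "tmpd", 1),
        (BLANK_TMPD_S + SCHEDULE_S["tmpd_to_ascorbate"], "ascorbate", 1),
    ]
    segments = [
        (0.0, 0.0, False),
        (schedule[0][0], 0.0, True),
        (schedule[1][0], 0.0, True),
    ]
    _, c_nf, reox_times = _integrate_chamber(t, segments, config)
    c_obs = np.maximum(0.0, c_nf + rng.normal(0.0, config.sigma_o2_uM, len(t)))
    events = _make_events(schedule, reox_times, config)
    return ChamberTrace(
        sample_id="blank",
        group="blank",
        replicate=1,
        time_s=t,
        o2_conc_uM=c_obs,
        events=events,
        tissue_mass_mg=math.nan,
    )


def iter_samples(config: SimConfig) -> Iterator[SampleSim]:
    for group in ("control", "affected"):
        for i in range(config.n_per_group):
            yield simulate_sample(config, group, i)


def simulate_cohort(
    config: SimConfig, out_dir: str | Path | None = None
) -> CohortSim:
    """Generate the full two-group cohort (+ one chemical blank).

    With ``out_dir`` the cohort is written to disk in the package's tabular
    dialect: one trace/events CSV pair per chamber run, one CS kinetics CSV
    per assay well, a manifest CSV, the blank pair, and the scalar ground
    truth as JSON.  Without it everything stays in memory.
    """
    samples = list(iter_samples(config))
    blank = simulate_blank(config)
    truth = GroundTruth(
        config=config,
        autox=(config.autox_a0, config.autox_a1),
        samples=[s.truth for s in samples],
    )
    cohort = CohortSim(config=config, samples=samples, blank=blank, truth=truth)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: CohortSim, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in cohort.samples:
        for trace, kin in zip(sample.traces, sample.cs):
            trace_path, events_path = write_trace(trace, out)
            cs_path = write_cs_kinetics(kin, out)
            rows.append(
                {
                    "sample_id": sample.sample_id,
                    "group": sample.group,
                    "replicate": trace.replicate,
                    "trace_path": trace_path.name,
                    "events_path": events_path.name,
                    "tissue_mass_mg": trace.tissue_mass_mg,
                    "cs_path": cs_path.name,
                }
            )
    manifest_path = write_manifest(rows, out / "manifest.csv")
    blank_trace, blank_events = write_trace(cohort.blank, out)
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(ground_truth_record(cohort.truth), fh, indent=1)
    with open(out / "cohort.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "manifest": manifest_path.name,
                "blank_trace": blank_trace.name,
                "blank_events": blank_events.name,
                "seed": cohort.config.seed,
            },
            fh,
            indent=1,
        )
    return manifest_path


def sim_config_from_dict(raw: dict) -> SimConfig:
    """Build a SimConfig from a plain (e.g. YAML-loaded) mapping.

    State-keyed maps (baseline_fcr, effect_pct) use the state names as keys;
    unknown keys are rejected.
    """
    d = dict(raw)
    for key in ("baseline_fcr", "effect_pct"):
        if key in d:
            d[key] = {RespState(k): float(v) for k, v in d[key].items()}
    if "fccp_step_multipliers" in d:
        d["fccp_step_multipliers"] = tuple(d["fccp_step_multipliers"])
    known = set(SimConfig.__dataclass_fields__)
    unknown = sorted(set(d) - known)
    if unknown:
        raise ValueError(f"unknown simulation config keys: {unknown}")
    return SimConfig(**d)


def ground_truth_record(truth: GroundTruth) -> dict:
    """Scalar ground truth as a JSON-serializable record (flux series omitted)."""

    def state_map(d: dict[RespState, float]) -> dict[str, float]:
        return {s.value: float(v) for s, v in d.items()}

    return {
        "autox": list(truth.autox),
        "seed": truth.config.seed,
        "samples": [
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "scale": s.scale,
                "rox_flux": s.rox_flux,
                "true_fcr": state_map(s.true_fcr),
                "true_state_flux": {
                    str(r): state_map(d) for r, d in s.true_state_flux.items()
                },
                "cs_activity": s.cs_activity,
                "cs_replicates": list(s.cs_replicates),
            }
            for s in truth.samples
        ],
    }
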