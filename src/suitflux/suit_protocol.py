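"""SUIT protocol interpretation: titration events -> respiratory states.

The substrate-uncoupler-inhibitor titration steps a homogenate through eight
respiratory states:

=================  =========================================================
LEAK               CI substrates (malate, pyruvate, glutamate), no ADP
CI_OXPHOS          + ADP: coupled respiration through complex I
CI_OXPHOS_CYTC     + cytochrome c: outer-membrane integrity check
CI_CII_OXPHOS      + succinate: convergent CI+CII coupled respiration
CI_CII_ETS         stepwise FCCP: maximal uncoupled respiration (reference)
CII_ETS            + rotenone: uncoupled respiration through CII alone
ROX                + antimycin A: residual (non-mitochondrial) O2 consumption
CIV_MAX            + TMPD/ascorbate: maximal complex IV activity
=================  =========================================================

Corrections: ROX is subtracted from every state flux; CIV_MAX additionally
loses the TMPD/ascorbate autoxidation background, modelled linearly in the
chamber O2 concentration, autox(C) = a0 + a1*C (clamped at >= 0), with (a0,
a1) fitted on a tissue-free chemical blank.  Subtraction commutes, so the
composition order of the two CIV corrections is immaterial; both are applied.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

from .flux_engine import (
    DEFAULT_SMOOTHING_HALFWIDTH_S,
    FluxSeries,
    PlateauEstimate,
    PlateauParams,
    compute_flux,
    estimate_plateau,
)
from .trace_model import ChamberTrace, TitrationEvent

__all__ = [
    "RespState",
    "StateFluxes",
    "ProtocolError",
    "assign_states",
    "extract_state_fluxes",
    "apply_corrections",
    "fit_autoxidation",
    "cytc_quality_check",
    "DEFAULT_CYTC_THRESHOLD_PCT",
]


class RespState(enum.Enum):
    """The eight respiratory states, in protocol order."""

    LEAK = "LEAK"
    CI_OXPHOS = "CI_OXPHOS"
    CI_OXPHOS_CYTC = "CI_OXPHOS_CYTC"
    CI_CII_OXPHOS = "CI_CII_OXPHOS"
    CI_CII_ETS = "CI_CII_ETS"
    CII_ETS = "CII_ETS"
    ROX = "ROX"
    CIV_MAX = "CIV_MAX"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: reference (denominator) state for flux control ratios
REFERENCE_STATE = RespState.CI_CII_ETS

#: states that receive the plain ROX subtraction
_ROX_SUBTRACTED = [
    RespState.LEAK,
    RespState.CI_OXPHOS,
    RespState.CI_OXPHOS_CYTC,
    RespState.CI_CII_OXPHOS,
    RespState.CI_CII_ETS,
    RespState.CII_ETS,
]

DEFAULT_CYTC_THRESHOLD_PCT = 10.0


class ProtocolError(ValueError):
    """The titration sequence violates the SUIT protocol."""


StateWindows = dict[RespState, list[tuple[float, float]]]


@dataclass
class StateFluxes:
    """Per-state steady-state fluxes for one chamber run, raw and corrected."""

    sample_id: str
    replicate: int
    raw: dict[RespState, PlateauEstimate]
    ets_step_estimates: list[PlateauEstimate] = field(default_factory=list)
    mean_o2_civ_window: float | None = None
    rox_flux: float | None = None
    corrected: dict[RespState, float] | None = None
    cytc_increase_pct: float | None = None
    qc_pass: bool | None = None
    qc_notes: list[str] = field(default_factory=list)
    autox_params_used: tuple[float, float] = (0.0, 0.0)

    def raw_flux(self, state: RespState) -> float:
        return self.raw[state].mean_flux

    def all_stable(self) -> bool:
        return all(est.stable for est in self.raw.values())


# ---------------------------------------------------------------------------
# event sequence -> state windows

_CI_SUBSTRATES = {"malate", "pyruvate", "glutamate"}
_CIV_AGENTS = {"tmpd", "ascorbate"}


def _protocol_events(events: list[TitrationEvent]) -> dict[str, object]:
    """Validate the mandatory SUIT order and index the anchor events."""
    seq = [e for e in events if e.agent != "reoxygenation"]
    i = 0

    seen_ci: set[str] = set()
    while i < len(seq) and seq[i].agent in _CI_SUBSTRATES:
        seen_ci.add(seq[i].agent)
        i += 1
    if seen_ci != _CI_SUBSTRATES:
        missing = sorted(_CI_SUBSTRATES - seen_ci)
        raise ProtocolError(
            f"CI substrates {missing} expected before ADP (got "
            f"{[e.agent for e in seq[:i+1]]})"
        )
    last_ci_time = seq[i - 1].time_s

    def expect(agent: str, context: str) -> TitrationEvent:
        nonlocal i
        if i >= len(seq) or seq[i].agent != agent:
            found = seq[i].agent if i < len(seq) else "end of run"
            raise ProtocolError(f"{agent} expected after {context}, found {found}")
        ev = seq[i]
        i += 1
        return ev

    adp = expect("adp", "CI substrates")
    cytc = expect("cytochrome_c", "adp")
    succ = expect("succinate", "cytochrome_c")

    fccp: list[TitrationEvent] = []
    while i < len(seq) and seq[i].agent == "fccp":
        fccp.append(seq[i])
        i += 1
    if not fccp:
        found = seq[i].agent if i < len(seq) else "end of run"
        raise ProtocolError(f"fccp expected after succinate, found {found}")
    steps = [e.step_index for e in fccp]
    if steps != list(range(1, len(fccp) + 1)):
        raise ProtocolError(
            f"fccp step_index values must be consecutive from 1, got {steps}"
        )

    rot = expect("rotenone", "fccp titration")
    anti = expect("antimycin_a", "rotenone")

    civ: list[TitrationEvent] = []
    while i < len(seq) and seq[i].agent in _CIV_AGENTS:
        civ.append(seq[i])
        i += 1
    if {e.agent for e in civ} != _CIV_AGENTS:
        missing = sorted(_CIV_AGENTS - {e.agent for e in civ})
        raise ProtocolError(f"{missing} expected after antimycin_a")
    if i < len(seq):
        raise ProtocolError(
            f"unexpected event {seq[i].agent!r} after the TMPD/ascorbate step"
        )
    return {
        "last_ci_time": last_ci_time,
        "adp": adp,
        "cytc": cytc,
        "succ": succ,
        "fccp": fccp,
        "rot": rot,
        "anti": anti,
        "civ_start": max(e.time_s for e in civ),
        "civ_first": min(e.time_s for e in civ),
    }


def _truncate_at_reox(
    window: tuple[float, float], reox_times: list[float]
) -> tuple[float, float]:
    """Cut a window at any contained reoxygenation, keeping the longer piece."""
    ws, we = window
    for r in reox_times:
        if ws < r < we:
            if (r - ws) >= (we - r):
                we = r
            else:
                ws = r
    return (ws, we)


def assign_states(
    events: list[TitrationEvent], trace_end_s: float
) -> StateWindows:
    """Map the titration sequence to per-state trace windows.

    Pure function of the event list: the returned windows are pairwise
    disjoint and in protocol order.  ``CI_CII_ETS`` maps to one sub-window per
    FCCP step (the state flux is later taken as the max over steps); windows
    containing a reoxygenation are truncated to exclude the concentration
    jump.
    """
    anchors = _protocol_events(events)
    reox = [e.time_s for e in events if e.agent == "reoxygenation"]

    fccp = anchors["fccp"]
    ets_bounds = [e.time_s for e in fccp] + [anchors["rot"].time_s]
    windows: StateWindows = {
        RespState.LEAK: [(anchors["last_ci_time"], anchors["adp"].time_s)],
        RespState.CI_OXPHOS: [(anchors["adp"].time_s, anchors["cytc"].time_s)],
        RespState.CI_OXPHOS_CYTC: [
            (anchors["cytc"].time_s, anchors["succ"].time_s)
        ],
        RespState.CI_CII_OXPHOS: [(anchors["succ"].time_s, fccp[0].time_s)],
        RespState.CI_CII_ETS: [
            (ets_bounds[k], ets_bounds[k + 1]) for k in range(len(fccp))
        ],
        RespState.CII_ETS: [(anchors["rot"].time_s, anchors["anti"].time_s)],
        RespState.ROX: [(anchors["anti"].time_s, anchors["civ_first"])],
        RespState.CIV_MAX: [(anchors["civ_start"], trace_end_s)],
    }
    if reox:
        windows = {
            s: [_truncate_at_reox(w, reox) for w in ws]
            for s, ws in windows.items()
        }
    return windows


# ---------------------------------------------------------------------------
# steady-state extraction

def _extraction_window(
    window: tuple[float, float], p: PlateauParams, halfwidth_s: float
) -> tuple[float, float]:
    """Usable plateau span: drop the settling transient after the titration
    and keep clear of the next injection by lag + derivative halfwidth."""
    ws, we = window
    end = we - p.lag_s - halfwidth_s
    start = ws + p.settle_s
    if end - start < p.min_window_s:
        # degraded window (e.g. reoxygenation truncation): keep the second
        # half of whatever remains rather than failing outright
        start = min(ws + 0.5 * (end - ws), end - p.min_window_s)
    return (start, end)


def _nan_estimate(window: tuple[float, float]) -> PlateauEstimate:
    return PlateauEstimate(
        window_start_s=window[0],
        window_end_s=window[1],
        mean_flux=float("nan"),
        flux_sd=float("nan"),
        slope=float("nan"),
        stable=False,
        n_points=0,
    )


def extract_state_fluxes(
    flux: FluxSeries,
    state_windows: StateWindows,
    params: PlateauParams | None = None,
    sample_id: str = "",
    replicate: int = 1,
    o2_time_s: np.ndarray | None = None,
    o2_conc_uM: np.ndarray | None = None,
) -> StateFluxes:
    """One plateau estimate per respiratory state (raw fluxes only).

    The CI_CII_ETS flux is the maximum over the per-FCCP-step plateau means
    (standard uncoupler-titration practice).  Unstable plateaus are flagged,
    not raised; QC is resolved downstream.  If the trace O2 arrays are given,
    the mean O2 of the CIV window is recorded for the autoxidation correction.
    """
    p = params or PlateauParams()
    hw = flux.smoothing_halfwidth_s
    raw: dict[RespState, PlateauEstimate] = {}
    ets_steps: list[PlateauEstimate] = []
    civ_window: tuple[float, float] | None = None

    for state, wins in state_windows.items():
        ests: list[PlateauEstimate] = []
        for w in wins:
            ew = _extraction_window(w, p, hw)
            try:
                est = estimate_plateau(flux, ew[0], ew[1], p)
            except ValueError:
                est = _nan_estimate(ew)
            ests.append(est)
        if state is RespState.CI_CII_ETS:
            ets_steps = ests
            finite = [e for e in ests if np.isfinite(e.mean_flux)]
            raw[state] = (
                max(finite, key=lambda e: e.mean_flux) if finite else ests[0]
            )
        else:
            raw[state] = ests[0]
        if state is RespState.CIV_MAX:
            civ_window = (raw[state].window_start_s, raw[state].window_end_s)

    mean_o2 = None
    if o2_time_s is not None and o2_conc_uM is not None and civ_window is not None:
        m = (o2_time_s >= civ_window[0]) & (o2_time_s <= civ_window[1])
        if m.any():
            mean_o2 = float(np.mean(o2_conc_uM[m]))

    return StateFluxes(
        sample_id=sample_id,
        replicate=replicate,
        raw=raw,
        ets_step_estimates=ets_steps,
        mean_o2_civ_window=mean_o2,
    )


def extract_from_trace(
    trace: ChamberTrace,
    params: PlateauParams | None = None,
    smoothing_halfwidth_s: float | None = None,
) -> StateFluxes:
    """Convenience composition: flux -> state windows -> raw state fluxes."""
    hw = smoothing_halfwidth_s or DEFAULT_SMOOTHING_HALFWIDTH_S
    flux = compute_flux(trace, hw)
    windows = assign_states(trace.events, float(trace.time_s[-1]))
    return extract_state_fluxes(
        flux,
        windows,
        params,
        sample_id=trace.sample_id,
        replicate=trace.replicate,
        o2_time_s=trace.time_s,
        o2_conc_uM=trace.o2_conc_uM,
    )


# ---------------------------------------------------------------------------
# corrections and QC

def autox_flux(a0: float, a1: float, o2_uM: float) -> float:
    """Linear TMPD/ascorbate autoxidation background, clamped at >= 0."""
    return max(0.0, a0 + a1 * o2_uM)


def apply_corrections(
    state_fluxes: StateFluxes,
    autox_a0: float = 0.0,
    autox_a1: float = 0.0,
    mean_o2_civ_window: float | None = None,
    civ_subtract_rox: bool = True,
) -> StateFluxes:
    """ROX subtraction for every state + autoxidation subtraction for CIV_MAX.

    corrected[ROX] is identically 0; corrected[CIV_MAX] = raw - ROX -
    autox(a0, a1, mean O2 over the CIV window).  A negative corrected flux in
    an OXPHOS/ETS state signals over-correction or a dead preparation and
    flags QC instead of raising.
    """
    sf = state_fluxes
    missing = [s for s in RespState if s not in sf.raw]
    if missing:
        raise ValueError(f"raw fluxes missing for states {missing}")

    rox = sf.raw_flux(RespState.ROX)
    corrected: dict[RespState, float] = {}
    for s in _ROX_SUBTRACTED:
        corrected[s] = sf.raw_flux(s) - rox
    corrected[RespState.ROX] = 0.0

    o2 = mean_o2_civ_window if mean_o2_civ_window is not None else sf.mean_o2_civ_window
    if (autox_a0 != 0.0 or autox_a1 != 0.0) and o2 is None:
        raise ValueError(
            "autoxidation correction requested but the mean O2 of the CIV "
            "window is unknown"
        )
    civ = sf.raw_flux(RespState.CIV_MAX)
    if civ_subtract_rox:
        civ -= rox
    civ -= autox_flux(autox_a0, autox_a1, o2 if o2 is not None else 0.0)
    corrected[RespState.CIV_MAX] = civ

    notes = list(sf.qc_notes)
    if not sf.all_stable():
        unstable = [s.value for s in RespState if not sf.raw[s].stable]
        notes.append(f"unstable plateau(s): {', '.join(unstable)}")
    negative = [
        s.value
        for s in RespState
        if s is not RespState.ROX and corrected[s] < 0
    ]
    if negative:
        msg = (
            f"negative corrected flux in {negative} for sample "
            f"{sf.sample_id!r} r{sf.replicate} (over-correction or dead sample)"
        )
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)

    sf.rox_flux = rox
    sf.corrected = corrected
    sf.autox_params_used = (autox_a0, autox_a1)
    sf.qc_notes = notes
    sf.qc_pass = sf.all_stable() and not negative
    return sf


def fit_autoxidation(
    blank_trace: ChamberTrace,
    smoothing_halfwidth_s: float = 120.0,
    settle_s: float = 150.0,
) -> tuple[float, float]:
    """Fit the linear autoxidation background on a tissue-free chemical blank.

    Regresses the blank's O2 flux on its (smoothed) O2 concentration over the
    post-TMPD window: jv = a0 + a1*C.  The slope is clamped at a1 >= 0 (a
    chemical autoxidation cannot be promoted by O2 depletion); with a
    degenerate (constant-C) blank the intercept falls back to the mean flux.

    The wide default halfwidth is deliberate: the blank flux is small, so the
    regression needs a low flux-noise floor rather than time resolution.
    """
    tmpd = [e for e in blank_trace.events if e.agent == "tmpd"]
    if not tmpd:
        raise ProtocolError("chemical blank has no tmpd event")
    start = tmpd[0].time_s + settle_s

    flux = compute_flux(blank_trace, smoothing_halfwidth_s)
    mask = flux.time_s >= start
    if int(mask.sum()) < 3:
        raise ValueError(
            f"only {int(mask.sum())} flux samples after TMPD + settle; "
            "need at least 3 to fit the autoxidation background"
        )
    jv = flux.jv_pmol_s_ml[mask]

    # smoothed O2 on the flux grid (moving average over the same window)
    t = blank_trace.time_s
    c = blank_trace.o2_conc_uM
    dt = float(np.median(np.diff(t)))
    m = int(round(flux.smoothing_halfwidth_s / dt))
    kernel = np.ones(2 * m + 1) / (2 * m + 1)
    c_smooth = np.convolve(c, kernel, mode="valid")
    c_fit = c_smooth[mask]

    if float(np.var(c_fit)) < 1e-12:
        return (float(np.mean(jv)), 0.0)
    a1, a0 = np.polyfit(c_fit, jv, 1)
    if a1 < 0:
        return (float(np.mean(jv)), 0.0)
    return (float(a0), float(a1))


def cytc_quality_check(
    state_fluxes: StateFluxes,
    threshold_pct: float = DEFAULT_CYTC_THRESHOLD_PCT,
) -> tuple[float, bool]:
    """Outer-membrane integrity check from the exogenous cytochrome c step.

    A flux increase above ``threshold_pct`` after cytochrome c addition means
    the outer membranes leaked cytochrome c during preparation; the run fails
    QC.  Computed on corrected fluxes when available, else raw.
    """
    sf = state_fluxes

    def value(s: RespState) -> float:
        if sf.corrected is not None:
            return sf.corrected[s]
        return sf.raw_flux(s)

    j_ci = value(RespState.CI_OXPHOS)
    j_cytc = value(RespState.CI_OXPHOS_CYTC)
    if not np.isfinite(j_ci) or j_ci <= 0:
        sf.cytc_increase_pct = float("nan")
        sf.qc_notes.append("cytochrome c check impossible: CI_OXPHOS flux <= 0")
        sf.qc_pass = False
        return (float("nan"), False)

    increase = 100.0 * (j_cytc - j_ci) / j_ci
    ok = increase <= threshold_pct
    sf.cytc_increase_pct = increase
    if not ok:
        sf.qc_notes.append(
            f"cytochrome c response +{increase:.1f}% exceeds {threshold_pct}% "
            "(outer-membrane damage)"
        )
    sf.qc_pass = bool(ok if sf.qc_pass is None else (sf.qc_pass and ok))
    return (float(increase), bool(ok))
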