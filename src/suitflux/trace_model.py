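"""Domain types and tabular I/O for oxygraph runs and citrate synthase assays.

An oxygraph run is a time series of chamber O2 concentration (uM = nmol/ml)
plus an ordered table of titration events (substrates, uncoupler, inhibitors).
The on-disk dialect is plain UTF-8 CSV with a header row and '.' decimals:

* trace CSV:    ``time_s,o2_uM``
* events CSV:   ``time_s,agent,amount,unit,step_index``
* manifest CSV: ``sample_id,group,replicate,trace_path,events_path,
  tissue_mass_mg[,cs_path]``
* CS kinetics CSV: ``time_min,absorbance_412``

Times are seconds from run start (0-based); O2 stays in uM throughout — no
unit conversion happens on read.  Titration agents form a closed vocabulary:
the SUIT state machine downstream depends on exact agent identity, so an
unknown agent is an error, never a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AGENTS",
    "GROUPS",
    "TraceFormatError",
    "ValidationError",
    "TitrationEvent",
    "ChamberTrace",
    "CSKinetics",
    "read_trace",
    "write_trace",
    "read_cs_kinetics",
    "write_cs_kinetics",
    "read_manifest",
    "write_manifest",
]

#: Closed vocabulary of titration agents.  ``reoxygenation`` marks a chamber
#: re-oxygenation (stirrer lift / O2 re-equilibration), which the simulator
#: records so that analysis windows can exclude the concentration jump.
AGENTS = (
    "malate",
    "pyruvate",
    "glutamate",
    "adp",
    "cytochrome_c",
    "succinate",
    "fccp",
    "rotenone",
    "antimycin_a",
    "tmpd",
    "ascorbate",
    "reoxygenation",
)

GROUPS = ("control", "affected")

TISSUE_MASS_PLAUSIBLE_MG = (1.0, 50.0)


class TraceFormatError(ValueError):
    """A file does not conform to the documented CSV dialect."""


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


@dataclass(frozen=True)
class TitrationEvent:
    """One chamber addition.

    ``amount``/``unit`` record the titrated final concentration verbatim and
    are never used in computation; ``step_index`` distinguishes consecutive
    uncoupler (FCCP) steps and is 1 for everything else.
    """

    time_s: float
    agent: str
    amount: float = math.nan
    unit: str = ""
    step_index: int = 1

    def __post_init__(self) -> None:
        if self.agent not in AGENTS:
            raise ValidationError(
                f"unknown titration agent {self.agent!r}; expected one of {AGENTS}"
            )
        if not (self.time_s >= 0):
            raise ValidationError(f"event time must be >= 0, got {self.time_s}")
        if self.step_index < 1:
            raise ValidationError(f"step_index must be >= 1, got {self.step_index}")


def _as_float_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass
class ChamberTrace:
    """A single oxygraph chamber run: O2 time series + titration events."""

    sample_id: str
    group: str
    replicate: int
    time_s: np.ndarray
    o2_conc_uM: np.ndarray
    events: list[TitrationEvent] = field(default_factory=list)
    chamber_volume_ml: float = 2.0
    temperature_C: float = 37.0
    tissue_mass_mg: float = math.nan

    def __post_init__(self) -> None:
        self.time_s = _as_float_array(self.time_s, "time_s")
        self.o2_conc_uM = _as_float_array(self.o2_conc_uM, "o2_conc_uM")
        self.validate()

    def validate(self) -> None:
        if self.group not in GROUPS and self.group != "blank":
            raise ValidationError(
                f"group must be one of {GROUPS} (or 'blank'), got {self.group!r}"
            )
        if self.replicate not in (1, 2):
            raise ValidationError(f"replicate must be 1 or 2, got {self.replicate}")
        n = len(self.time_s)
        if n != len(self.o2_conc_uM) or n < 2:
            raise ValidationError(
                "time_s and o2_conc_uM must have equal length >= 2 "
                f"(got {n} and {len(self.o2_conc_uM)})"
            )
        if not np.all(np.isfinite(self.time_s)):
            raise ValidationError("non-finite values in time_s")
        if not np.all(np.isfinite(self.o2_conc_uM)):
            raise ValidationError("non-finite values in o2_conc_uM")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValidationError("time_s must be strictly increasing")
        if np.any(self.o2_conc_uM < 0):
            raise ValidationError("o2_conc_uM must be >= 0 everywhere")
        t0, t1 = self.time_s[0], self.time_s[-1]
        last = -math.inf
        for ev in self.events:
            if not (t0 <= ev.time_s <= t1):
                raise ValidationError(
                    f"event {ev.agent!r} at t={ev.time_s}s lies outside the "
                    f"trace range [{t0}, {t1}]"
                )
            if ev.time_s <= last:
                raise ValidationError(
                    "event times must be strictly increasing "
                    f"({ev.agent!r} at t={ev.time_s}s)"
                )
            last = ev.time_s
        lo, hi = TISSUE_MASS_PLAUSIBLE_MG
        if math.isfinite(self.tissue_mass_mg) and not (lo <= self.tissue_mass_mg <= hi):
            warnings.warn(
                f"tissue mass {self.tissue_mass_mg} mg outside plausible "
                f"range {lo}-{hi} mg for sample {self.sample_id!r}",
                stacklevel=2,
            )

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    def titrations(self) -> list[TitrationEvent]:
        """Events excluding reoxygenation marks."""
        return [e for e in self.events if e.agent != "reoxygenation"]

    def reoxygenations(self) -> list[TitrationEvent]:
        return [e for e in self.events if e.agent == "reoxygenation"]


@dataclass
class CSKinetics:
    """412 nm absorbance kinetics of one citrate synthase assay well."""

    sample_id: str
    replicate: int
    time_min: np.ndarray
    absorbance_412: np.ndarray
    pathlength_cm: float = 1.0
    dilution_factor: float = 1.0
    assay_to_sample_volume_ratio: float = 1.0

    def __post_init__(self) -> None:
        self.time_min = _as_float_array(self.time_min, "time_min")
        self.absorbance_412 = _as_float_array(self.absorbance_412, "absorbance_412")
        n = len(self.time_min)
        if n != len(self.absorbance_412) or n < 3:
            raise ValidationError(
                "time_min and absorbance_412 must have equal length >= 3"
            )
        if np.any(np.diff(self.time_min) <= 0):
            raise ValidationError("time_min must be strictly increasing")
        if not (np.all(np.isfinite(self.time_min)) and np.all(np.isfinite(self.absorbance_412))):
            raise ValidationError("non-finite values in CS kinetics")
        if self.pathlength_cm <= 0 or self.dilution_factor <= 0 \
                or self.assay_to_sample_volume_ratio <= 0:
            raise ValidationError("pathlength, dilution and volume ratio must be > 0")


# ---------------------------------------------------------------------------
# readers / writers

_TRACE_COLS = ["time_s", "o2_uM"]
_EVENT_COLS = ["time_s", "agent", "amount", "unit", "step_index"]
_MANIFEST_COLS = [
    "sample_id",
    "group",
    "replicate",
    "trace_path",
    "events_path",
    "tissue_mass_mg",
]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        # round_trip parsing: repr-serialized floats must come back bit-exact
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TraceFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path} is missing required columns {missing}")
    return df


def read_trace(
    path_trace: str | Path,
    path_events: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> ChamberTrace:
    """Read a chamber run from a trace CSV + events CSV pair.

    ``metadata`` supplies the non-tabular fields (sample_id, group, replicate,
    tissue_mass_mg, ...).  The returned object is fully validated; malformed
    input raises :class:`TraceFormatError` or :class:`ValidationError` and
    never yields a partially constructed trace.
    """
    meta = dict(metadata or {})
    tdf = _read_csv(path_trace, _TRACE_COLS)
    edf = _read_csv(path_events, _EVENT_COLS)
    events = [
        TitrationEvent(
            time_s=float(r.time_s),
            agent=str(r.agent),
            amount=float(r.amount),
            unit=str(r.unit) if not pd.isna(r.unit) else "",
            step_index=int(r.step_index),
        )
        for r in edf.itertuples(index=False)
    ]
    return ChamberTrace(
        sample_id=str(meta.get("sample_id", "")),
        group=str(meta.get("group", "control")),
        replicate=int(meta.get("replicate", 1)),
        time_s=tdf["time_s"].to_numpy(float),
        o2_conc_uM=tdf["o2_uM"].to_numpy(float),
        events=events,
        chamber_volume_ml=float(meta.get("chamber_volume_ml", 2.0)),
        temperature_C=float(meta.get("temperature_C", 37.0)),
        tissue_mass_mg=float(meta.get("tissue_mass_mg", math.nan)),
    )


def write_trace(trace: ChamberTrace, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a validated trace as a (trace CSV, events CSV) pair.

    Floats are serialized with ``repr`` so that a read-back round-trip is
    bit-exact.  The trace is re-validated first: non-finite values are refused
    before anything touches disk.
    """
    trace.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"{trace.sample_id}_r{trace.replicate}"
    trace_path = out / f"{stem}_trace.csv"
    events_path = out / f"{stem}_events.csv"

    with open(trace_path, "w", encoding="utf-8") as fh:
        fh.write(",".join(_TRACE_COLS) + "\n")
        for t, c in zip(trace.time_s, trace.o2_conc_uM):
            fh.write(f"{float(t)!r},{float(c)!r}\n")
    with open(events_path, "w", encoding="utf-8") as fh:
        fh.write(",".join(_EVENT_COLS) + "\n")
        for ev in trace.events:
            fh.write(
                f"{float(ev.time_s)!r},{ev.agent},{float(ev.amount)!r},"
                f"{ev.unit},{ev.step_index}\n"
            )
    return trace_path, events_path


def read_cs_kinetics(
    path: str | Path, metadata: Mapping[str, object] | None = None
) -> CSKinetics:
    meta = dict(metadata or {})
    df = _read_csv(path, ["time_min", "absorbance_412"])
    return CSKinetics(
        sample_id=str(meta.get("sample_id", "")),
        replicate=int(meta.get("replicate", 1)),
        time_min=df["time_min"].to_numpy(float),
        absorbance_412=df["absorbance_412"].to_numpy(float),
        pathlength_cm=float(meta.get("pathlength_cm", 1.0)),
        dilution_factor=float(meta.get("dilution_factor", 1.0)),
        assay_to_sample_volume_ratio=float(
            meta.get("assay_to_sample_volume_ratio", 1.0)
        ),
    )


def write_cs_kinetics(kin: CSKinetics, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / f"{kin.sample_id}_r{kin.replicate}_cs.csv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time_min,absorbance_412\n")
        for t, a in zip(kin.time_min, kin.absorbance_412):
            fh.write(f"{float(t)!r},{float(a)!r}\n")
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest; one row per chamber run (sample x replicate)."""
    df = _read_csv(path, _MANIFEST_COLS)
    bad = sorted(set(df["group"].astype(str)) - set(GROUPS))
    if bad:
        raise ValidationError(f"manifest contains unknown groups {bad}")
    return df


def write_manifest(rows: Iterable[Mapping[str, object]], path: str | Path) -> Path:
    df = pd.DataFrame(list(rows))
    missing = [c for c in _MANIFEST_COLS if c not in df.columns]
    if missing and len(df):
        raise ValidationError(f"manifest rows missing fields {missing}")
    path = Path(path)
    df.to_csv(path, index=False)
    return path
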