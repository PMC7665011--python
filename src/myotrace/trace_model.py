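"""Core data types and file I/O for event-annotated isometric tension traces.

A recording is a pair of files:

* ``<name>.csv`` — two columns, ``time_s,tension_mN``, uniformly sampled;
* ``<name>.yaml`` — sidecar with the event annotations (KCl application
  window, EFS trains, drug windows) and strip metadata.

Times are seconds from recording start (0-based); all windows are half-open
``[t_on, t_off)``. Tension is in mN and is stored to full float precision so
that write/read round-trips bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import AnnotationError, TraceFormatError

#: maximum allowed relative jitter of the sampling step before a trace is
#: rejected as non-uniformly sampled
STEP_JITTER_TOL = 0.01


@dataclass
class StripMeta:
    """Identity and preparation metadata of one DSM strip."""

    group: str = "control"            # "control" | "cancer"
    urothelium: str = "intact"        # "intact" | "denuded"
    preload_mN: float = 5.0           # initial stretch load applied to the strip
    strip_id: str = "strip-0"
    animal_id: str = "animal-0"


@dataclass
class TensionTrace:
    """Uniformly sampled isometric tension record (mN)."""

    samples: np.ndarray
    sampling_rate: float              # Hz
    start_time: float = 0.0           # s
    strip_meta: StripMeta = field(default_factory=StripMeta)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise TraceFormatError("sampling_rate must be positive")
        if self.samples.size < 2:
            raise TraceFormatError("trace must contain at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise TraceFormatError("trace contains non-finite tension values")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Sample index of time ``t`` (clipped into the trace)."""
        i = int(round((t - self.start_time) * self.sampling_rate))
        return min(max(i, 0), self.n_samples)

    def slice(self, t0: float, t1: float) -> np.ndarray:
        """Samples in the half-open window ``[t0, t1)``."""
        return self.samples[self.index_at(t0):self.index_at(t1)]


@dataclass
class KClWindow:
    t_start: float
    t_end: float
    concentration_mM: float = 60.0


@dataclass
class EFSTrain:
    """One electric-field-stimulation pulse train."""

    onset: float                      # s
    train_duration: float             # s
    pulse_width_ms: float = 0.5
    frequency_hz: float = 10.0
    amplitude_v: float = 100.0


@dataclass
class DrugWindow:
    name: str
    concentration: float              # in the unit conventional for the drug (uM, mM)
    t_on: float
    t_off: float


@dataclass
class EventLog:
    """Timed annotations attached to one trace."""

    kcl: Optional[KClWindow] = None
    efs_trains: list = field(default_factory=list)
    drug_windows: list = field(default_factory=list)

    def active_drugs(self, t: float) -> set:
        """Names of drugs whose window contains time ``t``."""
        return {d.name for d in self.drug_windows if d.t_on <= t < d.t_off}

    def windows_named(self, name: str) -> list:
        return [d for d in self.drug_windows if d.name == name]


@dataclass
class TraceBundle:
    """A trace plus its annotations, and (for synthetic data) the ground truth."""

    trace: TensionTrace
    events: EventLog = field(default_factory=EventLog)
    ground_truth: Optional[object] = None   # synthetic.GroundTruth when present


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------

def _sidecar_path(trace_path: Path) -> Path:
    return trace_path.with_suffix(".yaml")


def _events_to_dict(events: EventLog) -> dict:
    d = {"kcl": None, "efs_trains": [], "drugs": []}
    if events.kcl is not None:
        d["kcl"] = asdict(events.kcl)
    d["efs_trains"] = [asdict(t) for t in sorted(events.efs_trains, key=lambda t: t.onset)]
    d["drugs"] = [asdict(w) for w in events.drug_windows]
    return d


def _events_from_dict(d: dict) -> EventLog:
    kcl = KClWindow(**d["kcl"]) if d.get("kcl") else None
    trains = [EFSTrain(**t) for t in d.get("efs_trains") or []]
    drugs = [DrugWindow(**w) for w in d.get("drugs") or []]
    return EventLog(kcl=kcl, efs_trains=trains, drug_windows=drugs)


def write_bundle(bundle: TraceBundle, path) -> Path:
    """Write ``bundle`` as ``path``(.csv) plus a YAML sidecar.

    Inverse of :func:`read_bundle`: tension is written with 17 significant
    digits so the round-trip is bit-exact.
    """
    path = Path(path)
    if path.suffix != ".csv":
        path = path.with_suffix(".csv")
    tr = bundle.trace
    df = pd.DataFrame({"time_s": tr.times, "tension_mN": tr.samples})
    df.to_csv(path, index=False, float_format="%.17g")

    side = {
        "strip_meta": asdict(tr.strip_meta),
        "sampling_rate_hz": float(tr.sampling_rate),
        **_events_to_dict(bundle.events),
    }
    if bundle.ground_truth is not None:
        side["ground_truth"] = bundle.ground_truth.to_dict()
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(side, fh, sort_keys=False)
    return path


def read_bundle(path) -> TraceBundle:
    """Read a trace CSV + annotation sidecar into a validated :class:`TraceBundle`.

    The sampling rate is inferred from the median time step; sampling-step
    jitter beyond 1% is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise TraceFormatError(f"trace file not found: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise AnnotationError(f"annotation sidecar not found: {sidecar}")

    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns[:2]) != ["time_s", "tension_mN"]:
        raise TraceFormatError(
            f"expected columns time_s,tension_mN; got {list(df.columns)}")
    t = df["time_s"].to_numpy(float)
    x = df["tension_mN"].to_numpy(float)
    if t.size < 2:
        raise TraceFormatError("trace must contain at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise TraceFormatError("time column is not strictly increasing")
    if np.any(~np.isfinite(x)):
        raise TraceFormatError("NaN/inf tension values in trace")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) / med > STEP_JITTER_TOL:
        raise TraceFormatError(
            f"non-uniform sampling: step jitter exceeds {STEP_JITTER_TOL:.0%}")

    with open(sidecar) as fh:
        side = yaml.safe_load(fh) or {}
    meta = StripMeta(**(side.get("strip_meta") or {}))
    trace = TensionTrace(samples=x, sampling_rate=1.0 / med,
                         start_time=float(t[0]), strip_meta=meta)
    events = _events_from_dict(side)

    gt = None
    if side.get("ground_truth") is not None:
        from .synthetic import GroundTruth
        gt = GroundTruth.from_dict(side["ground_truth"])
    return TraceBundle(trace=trace, events=events, ground_truth=gt)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _overlap(a0, a1, b0, b1) -> bool:
    return a0 < b1 and b0 < a1


def validate(bundle: TraceBundle) -> list:
    """Check every bundle invariant; return one finding string per violation.

    Reports, never raises: an empty list means the bundle conforms.
    """
    findings = []
    tr = bundle.trace
    ev = bundle.events
    t0 = tr.start_time
    t1 = tr.start_time + tr.duration_s

    if tr.sampling_rate <= 0:
        findings.append("sampling_rate must be positive")
    if not np.all(np.isfinite(tr.samples)):
        findings.append("trace contains non-finite samples")
    if tr.n_samples < 2:
        findings.append("trace shorter than 2 samples")
    if tr.strip_meta.preload_mN is None:
        findings.append("preload not recorded in strip metadata")
    if tr.strip_meta.group not in ("control", "cancer"):
        findings.append(f"unknown group label {tr.strip_meta.group!r}")

    if ev.kcl is not None:
        if not (t0 <= ev.kcl.t_start < ev.kcl.t_end <= t1):
            findings.append("KCl window outside trace span")
    trains = sorted(ev.efs_trains, key=lambda t: t.onset)
    for tr_i in trains:
        if not (t0 <= tr_i.onset and tr_i.onset + tr_i.train_duration <= t1):
            findings.append(f"EFS train at {tr_i.onset} s outside trace span")
    for a, b in zip(trains, trains[1:]):
        if _overlap(a.onset, a.onset + a.train_duration,
                    b.onset, b.onset + b.train_duration):
            findings.append(
                f"EFS trains at {a.onset} s and {b.onset} s overlap")
    for w in ev.drug_windows:
        if not (t0 <= w.t_on < w.t_off <= t1):
            findings.append(f"drug window {w.name} [{w.t_on}, {w.t_off}) "
                            "outside trace span")
    by_name = {}
    for w in ev.drug_windows:
        by_name.setdefault(w.name, []).append(w)
    for name, ws in by_name.items():
        ws = sorted(ws, key=lambda w: w.t_on)
        for a, b in zip(ws, ws[1:]):
            if _overlap(a.t_on, a.t_off, b.t_on, b.t_off):
                findings.append(f"drug {name} applied twice concurrently")

    if bundle.ground_truth is not None:
        findings.extend(bundle.ground_truth.params.check())
    return findings
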