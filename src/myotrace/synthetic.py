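"""Forward generative model of DSM organ-bath recordings with known ground truth.

The generator emulates the standard experiment on a pre-stretched detrusor
strip: a 60 mM KCl reference contraction early in the recording, quasi-
periodic spontaneous contractions (a renewal process of smooth force bumps),
duration-saturating EFS-evoked contractions split into a fast non-cholinergic
and a slow m-cholinergic component, drug transients (alpha-function baseline
shifts) with multiplicative effects on spontaneous and EFS activity, white
measurement noise and optional slow drift.

The noiseless construction is exact: every configured amplitude is realized
to machine precision, so the analysis modules can be verified by parameter
recovery. Group defaults ("control" / "cancer", urothelium "intact" /
"denuded") are anchored to the published control-vs-cancer values:
A_SC 4.6 -> 2.8 % of KCl, f_SC 0.047 -> 0.027 Hz, cholinergic EFS plateau
fraction 0.52 in control with a 3.54-fold (cholinergic) and 1.38-fold
(non-cholinergic) reduction in cancer, TRPV4-agonist (GSK1016790A) A_SC
enhancement 2.2-fold intact / 1.3-fold denuded / 1.3-fold cancer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np

from .errors import DomainError
from .trace_model import (DrugWindow, EFSTrain, EventLog, KClWindow, StripMeta,
                          TensionTrace, TraceBundle)

#: minimum sampling rate, in multiples of the spontaneous frequency
MIN_RATE_PER_FSC = 10.0

#: washout margin after the KCl window before rhythmic activity resumes (s)
KCL_WASHOUT_S = 180.0

#: EFS response window extension past the end of the train (s)
EFS_RESPONSE_TAIL_S = 30.0


@dataclass
class DrugEffectParams:
    """Generator-side effect of one drug while its window is active."""

    tension_amp_pct: float = 0.0    # peak baseline shift, % of KCl (negative = relaxant)
    tension_tau_s: float = 60.0     # alpha-function time constant of the transient
    asc_fold: float = 1.0           # multiplies spontaneous event height
    fsc_fold: float = 1.0           # multiplies spontaneous event rate
    efs_fold: float = 1.0           # multiplies EFS response amplitude (0 = full block)


@dataclass
class StripParams:
    """Complete parameter set of one simulated strip.

    Amplitudes of spontaneous/EFS/drug responses are expressed as % of the
    strip's own KCl (60 mM) reference contraction, mirroring the
    normalization used in the analysis.
    """

    group: str = "control"
    urothelium: str = "intact"
    baseline_mN: float = 5.0        # preload
    kcl_amp_mN: float = 10.0        # height of the KCl reference contraction
    asc_true: float = 4.6           # spontaneous amplitude, % of KCl
    fsc_true: float = 0.047         # spontaneous frequency, Hz
    period_cv: float = 0.1          # CV of inter-event intervals (renewal jitter)
    event_duty: float = 0.5         # fraction of the period occupied by an event
    event_plateau: float = 0.35     # fraction of the event width spent at peak
    efs_Amax: float = 60.0          # EFS plateau amplitude, % of KCl
    efs_tauD: float = 1.3           # duration-saturation constant, s
    chol_fraction_plateau: float = 0.52
    chol_rise_s: float = 2.0        # slow (cholinergic) kernel rise constant
    nonchol_rise_s: float = 0.5     # fast (non-cholinergic) kernel rise constant
    efs_decay_s: float = 5.0        # post-train decay constant
    purinergic_share: float = 0.85  # of the non-cholinergic component (bookkeeping)
    drug_effects: dict = field(default_factory=dict)   # name -> DrugEffectParams
    noise_sd_mN: float = 0.02
    drift_mN_per_min: float = 0.0
    seed: int = 0

    def check(self) -> list:
        """Return invariant-violation messages (empty when conforming)."""
        out = []
        if self.asc_true < 0:
            out.append("asc_true must be >= 0")
        if self.fsc_true <= 0:
            out.append("fsc_true must be > 0")
        if not (0.0 <= self.chol_fraction_plateau <= 1.0):
            out.append("chol_fraction_plateau must be in [0, 1]")
        if self.period_cv < 0:
            out.append("period_cv must be >= 0")
        if not (0.0 < self.event_duty < 1.0):
            out.append("event_duty must be in (0, 1)")
        if not (0.0 <= self.event_plateau < 1.0):
            out.append("event_plateau must be in [0, 1)")
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drug_effects"] = {k: asdict(v) for k, v in self.drug_effects.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StripParams":
        d = dict(d)
        d["drug_effects"] = {k: DrugEffectParams(**v)
                             for k, v in (d.get("drug_effects") or {}).items()}
        return cls(**d)


@dataclass
class GroundTruth:
    """Realized generator state: parameters plus the drawn event schedule."""

    params: StripParams
    event_times: np.ndarray         # spontaneous event onsets, s
    event_heights: np.ndarray       # realized event heights, mN
    train_onsets: np.ndarray        # EFS train onsets, s
    train_peaks_mN: np.ndarray      # realized response peaks above baseline, mN

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "event_times": [float(v) for v in self.event_times],
            "event_heights": [float(v) for v in self.event_heights],
            "train_onsets": [float(v) for v in self.train_onsets],
            "train_peaks_mN": [float(v) for v in self.train_peaks_mN],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(params=StripParams.from_dict(d["params"]),
                   event_times=np.asarray(d["event_times"], float),
                   event_heights=np.asarray(d["event_heights"], float),
                   train_onsets=np.asarray(d["train_onsets"], float),
                   train_peaks_mN=np.asarray(d["train_peaks_mN"], float))


# ---------------------------------------------------------------------------
# group defaults
# ---------------------------------------------------------------------------

# cancer reductions of the two EFS components relative to control
_CHOL_FOLD_CANCER = 3.54
_NONCHOL_FOLD_CANCER = 1.38


def _default_drug_effects(group: str, urothelium: str) -> dict:
    """Per-drug generator effects for the four probe drugs plus atropine.

    Atropine carries no numeric effect here; the generator special-cases it
    by zeroing the cholinergic EFS component while its window is active.
    """
    control = group == "control"
    intact = urothelium == "intact"
    if control:
        gsk = DrugEffectParams(tension_amp_pct=7.0 if intact else 4.5,
                               asc_fold=2.2 if intact else 1.3, fsc_fold=1.0)
        tea = DrugEffectParams(tension_amp_pct=5.0, asc_fold=2.0, fsc_fold=2.0)
        cap = DrugEffectParams(tension_amp_pct=3.0, efs_fold=1.15)
        cbd = DrugEffectParams(tension_amp_pct=5.0, asc_fold=1.5)
    else:
        gsk = DrugEffectParams(tension_amp_pct=7.0, asc_fold=1.3, fsc_fold=1.0)
        tea = DrugEffectParams(tension_amp_pct=5.0, asc_fold=2.0, fsc_fold=1.0)
        cap = DrugEffectParams(tension_amp_pct=6.0, efs_fold=1.3)
        cbd = DrugEffectParams(tension_amp_pct=4.5, asc_fold=1.4)
    return {
        "GSK1016790A": gsk,
        "TEA": tea,
        "CAP": cap,
        "CBD": cbd,
        "ATR": DrugEffectParams(),
    }


def default_params(group: str, urothelium: str = "intact", seed: int = 0) -> StripParams:
    """Paper-anchored default parameters for one strip of the given condition."""
    if group not in ("control", "cancer"):
        raise DomainError(f"unknown group {group!r}: expected 'control' or 'cancer'")
    if urothelium not in ("intact", "denuded"):
        raise DomainError(f"unknown urothelium state {urothelium!r}")

    p = StripParams(group=group, urothelium=urothelium, seed=seed,
                    drug_effects=_default_drug_effects(group, urothelium))
    if group == "cancer":
        p.asc_true = 2.8
        p.fsc_true = 0.027
        # component-wise reduction of the EFS plateau relative to control
        ctrl_chol = 0.52 * 60.0
        ctrl_non = (1.0 - 0.52) * 60.0
        chol = ctrl_chol / _CHOL_FOLD_CANCER
        non = ctrl_non / _NONCHOL_FOLD_CANCER
        p.efs_Amax = chol + non
        p.chol_fraction_plateau = chol / (chol + non)
    return p


# ---------------------------------------------------------------------------
# stimulation / application protocols
# ---------------------------------------------------------------------------

#: EFS train durations used in the duration-response experiment (s)
EFS_DURATIONS = (0.4, 1.6, 3.2, 4.0, 6.0, 8.0, 9.0, 10.0)


def spontaneous_protocol(duration_s: float = 1800.0) -> EventLog:
    """KCl reference contraction only; the rest of the trace is spontaneous."""
    return EventLog(kcl=KClWindow(t_start=60.0, t_end=150.0))


def efs_dissection_protocol(durations=EFS_DURATIONS, spacing_s: float = 180.0,
                            atr_settle_s: float = 120.0) -> EventLog:
    """Duration series pre- and post-atropine on the same strip.

    Trains are applied every ``spacing_s`` (the standard inter-train
    interval); after the first series atropine is applied and the series is
    repeated. Needs a trace of at least :func:`efs_dissection_duration`
    seconds.
    """
    first = KCL_WASHOUT_S + 150.0 + 60.0     # first train onset, s
    trains = []
    t = first
    for d in durations:
        trains.append(EFSTrain(onset=t, train_duration=float(d)))
        t += spacing_s
    atr_on = t
    t += atr_settle_s
    for d in durations:
        trains.append(EFSTrain(onset=t, train_duration=float(d)))
        t += spacing_s
    atr_off = t + 60.0
    return EventLog(kcl=KClWindow(t_start=60.0, t_end=150.0),
                    efs_trains=trains,
                    drug_windows=[DrugWindow("ATR", 1.0, atr_on, atr_off)])


def efs_dissection_duration(durations=EFS_DURATIONS, spacing_s: float = 180.0,
                            atr_settle_s: float = 120.0) -> float:
    """Trace length needed by :func:`efs_dissection_protocol`."""
    ev = efs_dissection_protocol(durations, spacing_s, atr_settle_s)
    return ev.drug_windows[0].t_off + 60.0


def drug_protocol(drug: str, concentration: float = 1.0,
                  duration_s: float = 1800.0, t_on: float = 780.0,
                  t_off: float = 1680.0, with_efs: bool = False,
                  atr_background: bool = False) -> EventLog:
    """Single drug application after a long pre-drug baseline.

    ``with_efs`` adds trains of the standard 2 s duration on both sides of
    the drug onset (for EFS fold-change measurements); ``atr_background``
    applies atropine throughout, as done for capsaicin.
    """
    trains = []
    if with_efs:
        for onset in (300.0, 420.0, 540.0, 660.0):
            trains.append(EFSTrain(onset=onset, train_duration=2.0))
        for onset in (t_on + 120.0, t_on + 240.0, t_on + 360.0, t_on + 480.0):
            trains.append(EFSTrain(onset=onset, train_duration=2.0))
    drugs = [DrugWindow(drug, concentration, t_on, t_off)]
    if atr_background:
        drugs.insert(0, DrugWindow("ATR", 1.0, 240.0, duration_s))
    return EventLog(kcl=KClWindow(t_start=60.0, t_end=150.0),
                    efs_trains=trains, drug_windows=drugs)


# ---------------------------------------------------------------------------
# waveform primitives
# ---------------------------------------------------------------------------

def _bump(t_rel: np.ndarray, width: float, plateau: float) -> np.ndarray:
    """Flat-topped tapered-cosine bump, unit peak, support [0, width].

    ``plateau`` is the fraction of the width held at the peak; raised-cosine
    ramps occupy the rest symmetrically. ``plateau=0`` gives the pure
    raised-cosine bump.
    """
    ramp = 0.5 * (1.0 - plateau) * width
    y = np.zeros_like(t_rel)
    m = (t_rel >= 0) & (t_rel <= width)
    x = t_rel[m]
    yy = np.ones_like(x)
    up = x < ramp
    yy[up] = 0.5 * (1.0 - np.cos(np.pi * x[up] / ramp))
    dn = x > width - ramp
    yy[dn] = 0.5 * (1.0 - np.cos(np.pi * (width - x[dn]) / ramp))
    y[m] = yy
    return y


def _efs_component(t_rel: np.ndarray, rise_tau: float, t_peak: float,
                   decay_tau: float) -> np.ndarray:
    """Saturating rise to ``1 - exp(-t_peak/rise_tau)`` then exponential decay."""
    y = np.zeros_like(t_rel)
    m = t_rel >= 0
    x = t_rel[m]
    rising = x <= t_peak
    yy = np.empty_like(x)
    yy[rising] = 1.0 - np.exp(-x[rising] / rise_tau)
    peak = 1.0 - np.exp(-t_peak / rise_tau)
    yy[~rising] = peak * np.exp(-(x[~rising] - t_peak) / decay_tau)
    y[m] = yy
    return y


def _alpha(t_rel: np.ndarray, tau: float) -> np.ndarray:
    """Alpha function (t/tau) * exp(1 - t/tau), unit peak at t = tau."""
    y = np.zeros_like(t_rel)
    m = t_rel >= 0
    x = t_rel[m] / tau
    y[m] = x * np.exp(1.0 - x)
    return y


def _gamma_interval(rng: np.random.Generator, mean: float, cv: float) -> float:
    """One renewal interval with the given mean and CV (degenerate at cv=0)."""
    if cv <= 0:
        return mean
    shape = 1.0 / cv ** 2
    return float(rng.gamma(shape, mean / shape))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _fold_product(events: EventLog, params: StripParams, t: float, attr: str) -> float:
    fold = 1.0
    for name in events.active_drugs(t):
        eff = params.drug_effects.get(name)
        if eff is not None:
            fold *= getattr(eff, attr)
    return fold


def simulate_strip(params: StripParams, duration_s: float = 1800.0,
                   sampling_rate: float = 10.0,
                   protocol: Optional[EventLog] = None) -> TraceBundle:
    """Simulate one strip recording under the given application protocol.

    The tension signal is
    ``baseline + drift*t + KCl pulse + spontaneous events + EFS responses +
    drug transients + white noise``. Identical ``params.seed`` gives a
    bit-identical bundle.
    """
    bad = params.check()
    if bad:
        raise DomainError("; ".join(bad))
    if sampling_rate < MIN_RATE_PER_FSC * params.fsc_true:
        raise DomainError(
            f"sampling rate {sampling_rate} Hz below {MIN_RATE_PER_FSC} x "
            f"fsc_true = {MIN_RATE_PER_FSC * params.fsc_true} Hz")
    events = protocol if protocol is not None else spontaneous_protocol(duration_s)

    rng = np.random.default_rng(params.seed)
    n = int(round(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate
    x = np.full(n, params.baseline_mN, dtype=float)
    x += params.drift_mN_per_min / 60.0 * t

    # --- KCl reference contraction -------------------------------------
    activity_start = 0.0
    if events.kcl is not None:
        k = events.kcl
        rise, wash = 2.0, 20.0
        m = (t >= k.t_start) & (t < k.t_end)
        x[m] += params.kcl_amp_mN * (1.0 - np.exp(-(t[m] - k.t_start) / rise))
        level = params.kcl_amp_mN * (1.0 - np.exp(-(k.t_end - k.t_start) / rise))
        m2 = t >= k.t_end
        x[m2] += level * np.exp(-(t[m2] - k.t_end) / wash)
        activity_start = k.t_end + KCL_WASHOUT_S

    # --- forbidden intervals for spontaneous events ---------------------
    # trains own [onset - 12, onset + D + 30]: the 10 s pre-stimulus baseline
    # window and the response window stay free of spontaneous bumps
    forbidden = [(tr.onset - 12.0, tr.onset + tr.train_duration + EFS_RESPONSE_TAIL_S)
                 for tr in events.efs_trains]

    def _blocked(t0: float, t1: float) -> bool:
        return any(a < t1 and t0 < b for a, b in forbidden)

    # --- spontaneous events (renewal process of bumps) ------------------
    ev_times, ev_heights = [], []
    cur = activity_start
    # burn in a fraction of a period so the first event is not phase-locked
    cur += rng.uniform(0.0, 1.0 / params.fsc_true) if params.period_cv > 0 else 0.0
    while True:
        fsc = params.fsc_true * _fold_product(events, params, cur, "fsc_fold")
        period = 1.0 / fsc
        width = params.event_duty * period
        if cur + width > duration_s:
            break
        if not _blocked(cur, cur + width):
            height = (params.asc_true / 100.0 * params.kcl_amp_mN
                      * _fold_product(events, params, cur, "asc_fold"))
            x += height * _bump(t - cur, width, params.event_plateau)
            ev_times.append(cur)
            ev_heights.append(height)
        cur += _gamma_interval(rng, period, params.period_cv)

    # --- EFS responses ---------------------------------------------------
    tr_onsets, tr_peaks = [], []
    c = params.chol_fraction_plateau
    for train in events.efs_trains:
        D = train.train_duration
        amp = (params.efs_Amax / 100.0 * params.kcl_amp_mN
               * (1.0 - math.exp(-D / params.efs_tauD))
               * _fold_product(events, params, train.onset, "efs_fold"))
        atr_on = "ATR" in events.active_drugs(train.onset)
        t_pk = D + 2.0
        rel = t - train.onset
        non = (1.0 - c) * amp * _efs_component(rel, params.nonchol_rise_s,
                                               t_pk, params.efs_decay_s)
        chol = 0.0 if atr_on else c * amp * _efs_component(
            rel, params.chol_rise_s, t_pk, params.efs_decay_s)
        resp = non + chol
        x += resp
        tr_onsets.append(train.onset)
        tr_peaks.append(float(np.max(resp)) if n else 0.0)

    # --- drug transients -------------------------------------------------
    for w in events.drug_windows:
        eff = params.drug_effects.get(w.name)
        if eff is None or eff.tension_amp_pct == 0.0:
            continue
        amp = eff.tension_amp_pct / 100.0 * params.kcl_amp_mN
        x += amp * _alpha(t - w.t_on, eff.tension_tau_s)

    # --- noise -----------------------------------------------------------
    if params.noise_sd_mN > 0:
        x += rng.normal(0.0, params.noise_sd_mN, n)

    meta = StripMeta(group=params.group, urothelium=params.urothelium,
                     preload_mN=params.baseline_mN,
                     strip_id=f"{params.group}-{params.urothelium}-s{params.seed}",
                     animal_id=f"{params.group}-a{params.seed % 5}")
    trace = TensionTrace(samples=x, sampling_rate=sampling_rate, strip_meta=meta)
    gt = GroundTruth(params=params,
                     event_times=np.asarray(ev_times),
                     event_heights=np.asarray(ev_heights),
                     train_onsets=np.asarray(tr_onsets),
                     train_peaks_mN=np.asarray(tr_peaks))
    return TraceBundle(trace=trace, events=events, ground_truth=gt)


def jitter_params(params: StripParams, rng: np.random.Generator,
                  strip_cv: float) -> StripParams:
    """One strip-level random-effect draw around cohort-level parameters.

    Multiplies asc_true, fsc_true, kcl_amp_mN and efs_Amax by independent
    unit-mean lognormal factors with coefficient of variation ``strip_cv``.
    """
    if strip_cv <= 0:
        return replace(params)
    sigma2 = math.log(1.0 + strip_cv ** 2)
    mu = -0.5 * sigma2

    def draw() -> float:
        return float(rng.lognormal(mu, math.sqrt(sigma2)))

    return replace(params,
                   asc_true=params.asc_true * draw(),
                   fsc_true=params.fsc_true * draw(),
                   kcl_amp_mN=params.kcl_amp_mN * draw(),
                   efs_Amax=params.efs_Amax * draw())


def simulate_cohort(n: int, params: StripParams, master_seed: int,
                    duration_s: float = 1800.0, sampling_rate: float = 10.0,
                    protocol: Optional[EventLog] = None,
                    strip_cv: float = 0.10) -> list:
    """Simulate ``n`` strips with strip-level random effects.

    Child seeds are spawned from ``master_seed`` so cohorts are reproducible
    and strips are mutually decorrelated. Strip-level variability is a
    unit-mean lognormal multiplier (CV ``strip_cv``) on the amplitude and
    frequency parameters, so cohort means are unbiased for the configured
    values.
    """
    if n < 1:
        raise DomainError("cohort size must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n)
    bundles = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        child_seed = int(child.generate_state(1, np.uint32)[0]) % (2 ** 31)
        p = jitter_params(params, rng, strip_cv)
        p = replace(p, seed=child_seed)
        b = simulate_strip(p, duration_s=duration_s, sampling_rate=sampling_rate,
                           protocol=protocol)
        b.trace.strip_meta.strip_id = f"{params.group}-{params.urothelium}-s{i:02d}"
        b.trace.strip_meta.animal_id = f"{params.group}-a{i % 3}"
        bundles.append(b)
    return bundles
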