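"""EFS-evoked contraction quantification and cholinergic dissection.

Contraction amplitudes are normalized per strip to the 60 mM KCl reference
contraction (A_EFS in % of KCl). The duration-response experiment applies
trains of increasing length before and after atropine; the atropine-blockable
share of the amplitude is the m-cholinergic component and its mean over
train durations >= 4 s is the plateau fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import (AmbiguousWindowError, DomainError, NormalizationError,
                     QualityError)
from .trace_model import EFSTrain, TraceBundle

#: response window extension past the end of the train (captures the slow
#: cholinergic peak), s
RESPONSE_TAIL_S = 30.0

#: pre-stimulus baseline window, s
BASELINE_S = 10.0

#: train durations at and above which the cholinergic fraction has plateaued
PLATEAU_MIN_DURATION_S = 4.0


@dataclass
class EFSResponse:
    """One train's measured contraction."""

    train_onset: float
    train_duration: float
    raw_peak: float            # mN, absolute
    pre_stim_baseline: float   # mN
    A_EFS: float               # % of KCl, clamped at 0
    drug_context: set = field(default_factory=set)


@dataclass
class DurationResponseCurve:
    durations: np.ndarray      # s, ascending
    mean_A_EFS: np.ndarray     # % of KCl
    sd_A_EFS: np.ndarray       # NaN where n = 1
    n: np.ndarray
    condition: str = ""
    flags: list = field(default_factory=list)


@dataclass
class CholinergicDissection:
    durations: np.ndarray
    fraction: np.ndarray           # (A_pre - A_ATR)/A_pre per duration, in [0,1]
    plateau_fraction: Optional[float]   # mean over durations >= 4 s
    chol_amplitude: Optional[float]     # mean plateau A_pre - A_ATR, % of KCl
    nonchol_amplitude: Optional[float]  # mean plateau A_ATR, % of KCl
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# amplitudes
# ---------------------------------------------------------------------------

def kcl_reference_amplitude(bundle: TraceBundle, pre_s: float = 30.0) -> float:
    """Peak tension in the KCl window minus the median of the 30 s before it."""
    kcl = bundle.events.kcl
    if kcl is None:
        raise NormalizationError("no KCl window annotated")
    tr = bundle.trace
    pre = tr.slice(kcl.t_start - pre_s, kcl.t_start)
    inside = tr.slice(kcl.t_start, kcl.t_end)
    if pre.size == 0 or inside.size == 0:
        raise NormalizationError("KCl window or its pre-window is empty")
    amp = float(np.max(inside) - np.median(pre))
    if amp <= 0:
        raise QualityError(f"non-positive KCl amplitude ({amp:.3g} mN)")
    return amp


def efs_amplitude(bundle: TraceBundle, train: EFSTrain,
                  kcl_amp: Optional[float] = None,
                  response_tail_s: float = RESPONSE_TAIL_S,
                  baseline_s: float = BASELINE_S) -> EFSResponse:
    """Normalized peak amplitude of one EFS-evoked contraction.

    ``A_EFS = 100 * (peak in [onset, onset + D + 30 s] - median of the 10 s
    pre-stimulus) / KCl``; negative differences clamp to 0. Raises
    :class:`AmbiguousWindowError` when another train intrudes into the
    response window.
    """
    if kcl_amp is None:
        kcl_amp = kcl_reference_amplitude(bundle)
    tr = bundle.trace
    t0 = train.onset
    t1 = train.onset + train.train_duration + response_tail_s
    for other in bundle.events.efs_trains:
        if other is train or other.onset == train.onset:
            continue
        if t0 < other.onset + other.train_duration and other.onset < t1:
            raise AmbiguousWindowError(
                f"train at {other.onset} s overlaps the response window "
                f"[{t0}, {t1}) of the train at {train.onset} s")
    base = tr.slice(t0 - baseline_s, t0)
    resp = tr.slice(t0, t1)
    baseline = float(np.median(base)) if base.size else float("nan")
    peak = float(np.max(resp))
    a = max(peak - baseline, 0.0)
    return EFSResponse(train_onset=train.onset,
                       train_duration=train.train_duration,
                       raw_peak=peak, pre_stim_baseline=baseline,
                       A_EFS=100.0 * a / kcl_amp,
                       drug_context=bundle.events.active_drugs(train.onset))


def _condition_match(ctx: set, condition: str) -> bool:
    if condition in ("pre-ATR", "pre"):
        return "ATR" not in ctx
    if condition in ("post-ATR", "ATR", "post"):
        return "ATR" in ctx
    raise DomainError(f"unknown condition {condition!r}")


def duration_response(bundles: Sequence[TraceBundle],
                      condition: str) -> DurationResponseCurve:
    """Group per-train amplitudes by train duration across strips.

    ``condition`` selects trains by drug context: ``"pre-ATR"`` (no
    atropine) or ``"post-ATR"``. Returns mean +- SD (sample SD, NaN and a
    flag where n = 1) per duration, durations ascending.
    """
    groups: dict = {}
    for b in bundles:
        kcl = kcl_reference_amplitude(b)
        for train in b.events.efs_trains:
            r = efs_amplitude(b, train, kcl_amp=kcl)
            if _condition_match(r.drug_context, condition):
                groups.setdefault(round(train.train_duration, 6), []).append(r.A_EFS)
    if not groups:
        raise DomainError(f"no trains match condition {condition!r}")
    durations = np.array(sorted(groups))
    means = np.array([np.mean(groups[d]) for d in durations])
    ns = np.array([len(groups[d]) for d in durations])
    sds = np.array([np.std(groups[d], ddof=1) if len(groups[d]) > 1 else np.nan
                    for d in durations])
    flags = ["sd_undefined_n1"] if np.any(ns == 1) else []
    return DurationResponseCurve(durations=durations, mean_A_EFS=means,
                                 sd_A_EFS=sds, n=ns, condition=condition,
                                 flags=flags)


# ---------------------------------------------------------------------------
# dissection
# ---------------------------------------------------------------------------

def cholinergic_dissection(pre_curve: DurationResponseCurve,
                           atr_curve: DurationResponseCurve,
                           plateau_min_duration: float = PLATEAU_MIN_DURATION_S
                           ) -> CholinergicDissection:
    """Atropine-blockable (cholinergic) fraction per train duration.

    ``fraction(D) = (A_pre(D) - A_ATR(D)) / A_pre(D)``, clamped to [0, 1];
    durations where ``A_pre = 0`` are undefined (NaN) and excluded from the
    plateau mean. The plateau fraction is defined only when at least two
    durations >= ``plateau_min_duration`` carry a defined fraction.
    """
    if (pre_curve.durations.size != atr_curve.durations.size
            or not np.allclose(pre_curve.durations, atr_curve.durations)):
        raise DomainError("pre- and post-ATR curves must share a duration grid")
    d = pre_curve.durations
    pre = pre_curve.mean_A_EFS
    atr = atr_curve.mean_A_EFS
    frac = np.full(d.size, np.nan)
    ok = pre > 0
    frac[ok] = np.clip((pre[ok] - atr[ok]) / pre[ok], 0.0, 1.0)

    flags = []
    plat = (d >= plateau_min_duration) & np.isfinite(frac)
    if np.count_nonzero(plat) >= 2:
        plateau = float(np.mean(frac[plat]))
        chol = float(np.mean(pre[plat] - atr[plat]))
        non = float(np.mean(atr[plat]))
    else:
        plateau = chol = non = None
        flags.append("plateau_undefined")
    if np.any(~ok):
        flags.append("zero_pre_amplitude_excluded")
    return CholinergicDissection(durations=d, fraction=frac,
                                 plateau_fraction=plateau,
                                 chol_amplitude=chol, nonchol_amplitude=non,
                                 flags=flags)


def component_fold_changes(control: CholinergicDissection,
                           cancer: CholinergicDissection) -> dict:
    """Control/cancer fold reductions of the two plateau components."""
    if None in (control.chol_amplitude, cancer.chol_amplitude):
        raise DomainError("both dissections need a defined plateau")
    chol_fold = control.chol_amplitude / cancer.chol_amplitude
    non_fold = control.nonchol_amplitude / cancer.nonchol_amplitude
    return {
        "cholinergic_fold": chol_fold,
        "noncholinergic_fold": non_fold,
        "cholinergic_pct_decrease": fold_to_percent(chol_fold),
        "noncholinergic_pct_decrease": fold_to_percent(non_fold),
    }


def fold_to_percent(fold: float) -> float:
    """Percent decrease equivalent to an x-fold reduction: 100*(1 - 1/fold).

    Reported rounded to one decimal; folds below 1 are a percent *increase*
    and rejected here.
    """
    if fold < 1.0:
        raise DomainError(
            f"fold {fold} < 1: use the percent-increase pathway instead")
    return round(100.0 * (1.0 - 1.0 / fold), 1)
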