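"""Drug-application quantification: baseline-tension shift and fold changes.

For a drug window the module measures (1) the peak shift of the
lower-envelope baseline relative to the pre-drug baseline, normalized to
KCl, and (2) post/pre fold changes of the spontaneous parameters (A_SC,
f_SC, via independent runs of the spontaneous quantifier on segments before
and inside the window) and of the EFS amplitude (mean post / mean pre).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ResolutionError, StageError
from .spontaneous import quantify_spontaneous
from .efs import efs_amplitude, kcl_reference_amplitude
from .trace_model import DrugWindow, TraceBundle

#: lower-envelope percentile filter window (skips over spontaneous bumps), s
ENVELOPE_WINDOW_S = 30.0
ENVELOPE_PERCENTILE = 10.0

#: settling margin past drug onset before spontaneous parameters are read, s
SETTLE_S = 90.0

#: f_SC search band used for pre/post comparisons (shorter segments than the
#: full-trace quantification, hence a higher low edge)
DRUG_BAND = (0.015, 0.4)


@dataclass
class DrugEffect:
    """Measured effect of one drug window on one strip."""

    drug: str
    concentration: float
    delta_tension: float            # % of KCl; negative = relaxation
    asc_fold: float                 # NaN when not estimable
    fsc_fold: float
    efs_fold: float
    pre_window: tuple
    post_window: tuple
    flags: list = field(default_factory=list)


def lower_envelope(bundle: TraceBundle, window_s: float = ENVELOPE_WINDOW_S,
                   percentile: float = ENVELOPE_PERCENTILE) -> np.ndarray:
    """Rolling lower-percentile baseline with EFS response windows masked.

    Spontaneous bumps occupy at most about half of each window, so the 10th
    percentile tracks the inter-event baseline; EFS spikes are excluded
    outright by masking their response windows to NaN.
    """
    tr = bundle.trace
    x = tr.samples.astype(float).copy()
    for train in bundle.events.efs_trains:
        i0 = tr.index_at(train.onset - 2.0)
        i1 = tr.index_at(train.onset + train.train_duration + 30.0)
        x[i0:i1] = np.nan
    wlen = int(round(window_s * tr.sampling_rate))
    env = (pd.Series(x)
           .rolling(wlen, center=True, min_periods=max(wlen // 4, 1))
           .quantile(percentile / 100.0)
           .to_numpy())
    return env


def baseline_tension_change(bundle: TraceBundle, drug_window: DrugWindow,
                            kcl_amp: Optional[float] = None,
                            pre_s: float = 120.0,
                            window_s: float = ENVELOPE_WINDOW_S) -> float:
    """Peak drug-induced baseline shift, % of KCl.

    ``delta = 100 * (max envelope inside the window - pre-drug envelope
    median) / KCl``; for a relaxant the extremum is the minimum, so the
    signed larger-magnitude excursion is reported.
    """
    if kcl_amp is None:
        kcl_amp = kcl_reference_amplitude(bundle)
    tr = bundle.trace
    if drug_window.t_off - drug_window.t_on < window_s:
        raise ResolutionError(
            f"drug window shorter than the {window_s:.0f} s envelope window")
    if drug_window.t_on - pre_s < 0:
        raise ResolutionError(f"need {pre_s:.0f} s of pre-drug trace")
    env = lower_envelope(bundle, window_s=window_s)
    pre = env[tr.index_at(drug_window.t_on - pre_s):tr.index_at(drug_window.t_on)]
    inside = env[tr.index_at(drug_window.t_on):tr.index_at(drug_window.t_off)]
    pre_level = float(np.nanmedian(pre))
    hi = float(np.nanmax(inside)) - pre_level
    lo = float(np.nanmin(inside)) - pre_level
    delta = hi if abs(hi) >= abs(lo) else lo
    return 100.0 * delta / kcl_amp


def pre_post_spontaneous(bundle: TraceBundle, drug_window: DrugWindow,
                         settle_s: float = SETTLE_S,
                         band: tuple = DRUG_BAND,
                         min_len_s: float = 350.0) -> tuple:
    """(asc_fold, fsc_fold) across a drug window.

    Runs the spontaneous quantifier independently on a stationary segment
    before the window and on one inside it (after ``settle_s`` past onset,
    skipping the drug transient). A side without a resolvable histogram or
    dominant rhythm leaves the corresponding fold NaN, with a flag.
    """
    kcl = kcl_reference_amplitude(bundle)
    flags = []
    sides = {}
    for label, interval in (
            ("pre", (0.0, drug_window.t_on)),
            ("post", (drug_window.t_on + settle_s, drug_window.t_off))):
        try:
            sides[label] = quantify_spontaneous(
                bundle, band=band, min_len_s=min_len_s,
                search_interval=interval, ignore_drug_windows=True,
                kcl_amp=kcl)
        except StageError as exc:
            sides[label] = None
            flags.append(f"{label}_{exc.stage}_failed")
    asc_fold = fsc_fold = float("nan")
    pre, post = sides["pre"], sides["post"]
    if pre is not None and post is not None:
        if pre.A_SC > 0 and post.A_SC >= 0 and "unimodal_histogram" not in (
                pre.flags + post.flags):
            asc_fold = post.A_SC / pre.A_SC
        else:
            flags.append("asc_fold_undefined")
        fsc_fold = post.f_SC / pre.f_SC
    return (asc_fold, fsc_fold,
            {"flags": flags, "pre": pre, "post": post})


def pre_post_efs(bundle: TraceBundle, drug_window: DrugWindow) -> tuple:
    """Mean post-drug A_EFS over mean pre-drug A_EFS.

    Requires at least one train on each side of the drug onset. A zero
    pre-drug mean leaves the fold NaN; a zero post-drug response over a
    positive pre-drug one is flagged as a full block.
    """
    kcl = kcl_reference_amplitude(bundle)
    pre_vals, post_vals = [], []
    for train in bundle.events.efs_trains:
        r = efs_amplitude(bundle, train, kcl_amp=kcl)
        if train.onset < drug_window.t_on:
            pre_vals.append(r.A_EFS)
        elif drug_window.t_on <= train.onset < drug_window.t_off:
            post_vals.append(r.A_EFS)
    flags = []
    if not pre_vals or not post_vals:
        return float("nan"), {"flags": ["missing_trains"],
                              "n_pre": len(pre_vals), "n_post": len(post_vals)}
    pre_mean = float(np.mean(pre_vals))
    post_mean = float(np.mean(post_vals))
    if pre_mean == 0:
        return float("nan"), {"flags": ["zero_pre_mean"],
                              "n_pre": len(pre_vals), "n_post": len(post_vals)}
    fold = post_mean / pre_mean
    if post_mean == 0:
        flags.append("zero_response_full_block")
    return fold, {"flags": flags, "n_pre": len(pre_vals),
                  "n_post": len(post_vals)}


def quantify_drug_effect(bundle: TraceBundle, drug: str,
                         settle_s: float = SETTLE_S,
                         band: tuple = DRUG_BAND) -> DrugEffect:
    """All measurable effects of the named drug on one strip."""
    windows = bundle.events.windows_named(drug)
    if not windows:
        raise StageError("drug_lookup",
                         ValueError(f"no window for drug {drug!r}"))
    w = windows[0]
    kcl = kcl_reference_amplitude(bundle)
    delta = baseline_tension_change(bundle, w, kcl_amp=kcl)
    asc_fold, fsc_fold, sp_info = pre_post_spontaneous(
        bundle, w, settle_s=settle_s, band=band)
    has_trains = bool(bundle.events.efs_trains)
    if has_trains:
        efs_fold, efs_info = pre_post_efs(bundle, w)
        flags = sp_info["flags"] + efs_info["flags"]
    else:
        efs_fold = float("nan")
        flags = sp_info["flags"] + ["no_efs_trains"]
    return DrugEffect(drug=drug, concentration=w.concentration,
                      delta_tension=delta, asc_fold=asc_fold,
                      fsc_fold=fsc_fold, efs_fold=efs_fold,
                      pre_window=(0.0, w.t_on),
                      post_window=(w.t_on + settle_s, w.t_off),
                      flags=flags)
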