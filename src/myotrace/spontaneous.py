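"""Quantification of spontaneous contractions: A_SC and f_SC.

The scheme mirrors the classical organ-bath workflow:

1. select a stationary stretch of the recording (stable basal tension,
   away from KCl / EFS / drug applications);
2. build the amplitude histogram of the segment and fit a two-Gaussian
   model — the distance between the Gaussian means is the spontaneous
   contraction amplitude A_SC, normalized to the strip's KCl contraction;
3. estimate the frequency f_SC as the main harmonic of the averaged
   periodogram of the segment (T_SC = 1/f_SC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, signal

from .errors import (DegenerateHistogramError, DomainError,
                     FitConvergenceError, NoDominantRhythmError,
                     NonStationaryError, NormalizationError, ResolutionError,
                     StageError)
from .trace_model import EventLog, TensionTrace, TraceBundle

#: default f_SC search band (Hz); brackets 0.027-0.047 Hz with margin
DEFAULT_BAND = (0.005, 0.5)

#: peak power must exceed this multiple of the band median power
PROMINENCE_FACTOR = 4.0

#: stationarity scan defaults
STATION_WINDOW_S = 60.0
STATION_STEP_S = 10.0
MIN_SEGMENT_S = 300.0
BASELINE_PERCENTILE = 10.0
WASHOUT_MARGIN_S = 180.0

#: histogram bin-count clamp around the Freedman-Diaconis rule
MIN_BINS, MAX_BINS = 30, 200


@dataclass
class Histogram:
    centers: np.ndarray
    counts: np.ndarray
    bin_width: float


@dataclass
class GaussFit:
    """Two-Gaussian least-squares fit to an amplitude histogram."""

    mu1: float
    mu2: float
    sd1: float
    sd2: float
    w1: float
    w2: float
    fit_residual: float
    unimodal: bool = False


@dataclass
class Spectrum:
    freqs: np.ndarray
    power: np.ndarray          # one-sided PSD, (input units)^2 / Hz
    df: float
    n_segments: int


@dataclass
class SpontaneousStats:
    """Per-strip spontaneous-contraction summary."""

    A_SC: float                # % of KCl
    f_SC: float                # Hz
    T_SC: float                # s
    segment: tuple             # (t_start, t_end)
    gauss_fit: GaussFit
    spectrum_peak: dict
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# stationary-segment selection
# ---------------------------------------------------------------------------

def _eligibility_mask(trace: TensionTrace, events: Optional[EventLog],
                      washout_margin_s: float,
                      ignore_drug_windows: bool) -> np.ndarray:
    mask = np.ones(trace.n_samples, dtype=bool)
    if events is None:
        return mask

    def knock(t0, t1):
        mask[trace.index_at(t0):trace.index_at(t1)] = False

    if events.kcl is not None:
        knock(events.kcl.t_start - 30.0, events.kcl.t_end + washout_margin_s)
    for tr in events.efs_trains:
        knock(tr.onset - 12.0, tr.onset + tr.train_duration + 30.0)
    if not ignore_drug_windows:
        for w in events.drug_windows:
            knock(w.t_on, w.t_off + washout_margin_s)
    return mask


def select_stationary_segment(trace: TensionTrace,
                              events: Optional[EventLog] = None,
                              min_len_s: float = MIN_SEGMENT_S,
                              slope_tol_mN_per_min: float = 0.1,
                              window_s: float = STATION_WINDOW_S,
                              step_s: float = STATION_STEP_S,
                              search_interval: Optional[tuple] = None,
                              washout_margin_s: float = WASHOUT_MARGIN_S,
                              ignore_drug_windows: bool = False) -> tuple:
    """Longest contiguous stretch with stable basal tension.

    The trace is scanned with sliding windows (``window_s`` long, every
    ``step_s``); each window's baseline is its lower-envelope
    (10th-percentile) level, so spontaneous bumps do not register as drift.
    A run of windows is stationary when the step-to-step baseline slope
    stays below ``slope_tol_mN_per_min``. KCl/EFS/drug windows (plus a
    washout margin) are excluded from the search.

    Returns ``(t_start, t_end)`` of the longest qualifying run; raises
    :class:`NonStationaryError` when none reaches ``min_len_s``.
    """
    if trace.duration_s <= min_len_s:
        raise NonStationaryError(
            f"trace ({trace.duration_s:.0f} s) shorter than min segment "
            f"{min_len_s:.0f} s")
    mask = _eligibility_mask(trace, events, washout_margin_s, ignore_drug_windows)
    if search_interval is not None:
        t0, t1 = search_interval
        keep = np.zeros_like(mask)
        keep[trace.index_at(t0):trace.index_at(t1)] = True
        mask &= keep

    fs = trace.sampling_rate
    wlen = int(round(window_s * fs))
    step = int(round(step_s * fs))
    tol_per_s = slope_tol_mN_per_min / 60.0

    # maximal eligible spans
    spans = []
    idx = np.flatnonzero(mask)
    if idx.size:
        brk = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([idx[0]], idx[brk + 1]))
        ends = np.concatenate((idx[brk] + 1, [idx[-1] + 1]))
        spans = list(zip(starts, ends))

    best = None  # (length_s, t_start, t_end)
    for s0, s1 in spans:
        starts = np.arange(s0, s1 - wlen + 1, step)
        if starts.size < 2:
            continue
        base = np.array([np.percentile(trace.samples[a:a + wlen],
                                       BASELINE_PERCENTILE) for a in starts])
        slopes = np.diff(base) / step_s
        flat = np.abs(slopes) < tol_per_s
        # longest run of consecutive flat steps
        k = 0
        while k < flat.size:
            if not flat[k]:
                k += 1
                continue
            j = k
            while j < flat.size and flat[j]:
                j += 1
            a = starts[k]
            b = starts[j - 1 + 1] + wlen  # window j is the last flat-ending one
            seg_len = (b - a) / fs
            if seg_len >= min_len_s and (best is None or seg_len > best[0]):
                best = (seg_len, trace.start_time + a / fs,
                        trace.start_time + b / fs)
            k = j
    if best is None:
        raise NonStationaryError(
            "non-stationary recording: no segment with stable basal tension "
            f">= {min_len_s:.0f} s at tolerance {slope_tol_mN_per_min} mN/min")
    return best[1], best[2]


# ---------------------------------------------------------------------------
# amplitude histogram + two-Gaussian fit
# ---------------------------------------------------------------------------

def amplitude_histogram(samples: Sequence[float],
                        n_bins: Optional[int] = None) -> Histogram:
    """Equal-width amplitude histogram of a segment.

    Bin centers span [min, max] of the segment (edges half a bin beyond),
    so the extreme values fall at bin centers rather than on edges. The
    default bin count follows the Freedman-Diaconis rule clamped to
    [30, 200].
    """
    x = np.asarray(samples, float)
    if x.size < 100:
        raise DegenerateHistogramError(
            f"need >= 100 samples for a histogram, got {x.size}")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise DegenerateHistogramError("constant segment: zero amplitude range")
    if n_bins is None:
        q75, q25 = np.percentile(x, [75, 25])
        iqr = q75 - q25
        if iqr > 0:
            fd_width = 2.0 * iqr / x.size ** (1.0 / 3.0)
            n_bins = int(np.clip(round((hi - lo) / fd_width), MIN_BINS, MAX_BINS))
        else:
            n_bins = MIN_BINS
    if n_bins < 2:
        raise DegenerateHistogramError("need at least 2 bins")
    w = (hi - lo) / (n_bins - 1)
    edges = lo - w / 2 + w * np.arange(n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    centers = lo + w * np.arange(n_bins)
    return Histogram(centers=centers, counts=counts.astype(float), bin_width=w)


def _two_gauss(x, a1, mu1, s1, a2, mu2, s2):
    return (a1 * np.exp(-0.5 * ((x - mu1) / s1) ** 2)
            + a2 * np.exp(-0.5 * ((x - mu2) / s2) ** 2))


def fit_two_gaussians(hist: Histogram) -> GaussFit:
    """Least-squares two-Gaussian fit to the histogram bin counts.

    Means are initialized at the 10th/90th amplitude percentiles (with a
    couple of perturbed restarts); the components are returned with
    ``mu1 < mu2``. A unimodality flag is set when the means are closer than
    the mean of the two widths — such a histogram does not resolve distinct
    baseline and peak levels.
    """
    # the fit is over (center, count) pairs and must not assume bin order
    order = np.argsort(hist.centers)
    x, c = hist.centers[order], hist.counts[order]
    w = hist.bin_width
    total = float(c.sum())
    cdf = np.cumsum(c) / total
    lo, hi = x[0], x[-1]
    span = hi - lo

    def q(p):
        return float(np.interp(p, cdf, x))

    inits = [(q(0.10), q(0.90)), (q(0.05), q(0.95)), (q(0.20), q(0.80))]
    # means are levels of the signal, so they must lie inside the observed
    # amplitude range; unbounded means drift off-support on histograms with
    # near-point-mass bins (noise-free plateaus)
    bounds = ([0.0, lo, w / 4, 0.0, lo, w / 4],
              [2.0 * c.max(), hi, span, 2.0 * c.max(), hi, span])
    best = None
    diag = {}
    for m1, m2 in inits:
        a1 = max(float(np.interp(m1, x, c)), 1.0)
        a2 = max(float(np.interp(m2, x, c)), 1.0)
        p0 = [a1, m1, span / 10, a2, m2, span / 10]
        try:
            popt, _ = optimize.curve_fit(_two_gauss, x, c, p0=p0,
                                         bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError) as exc:
            diag[f"init {m1:.3g}/{m2:.3g}"] = str(exc)
            continue
        resid = float(np.sqrt(np.mean((_two_gauss(x, *popt) - c) ** 2)))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise FitConvergenceError(
            "two-Gaussian fit did not converge after restarts", diagnostics=diag)
    (a1, m1, s1, a2, m2, s2), resid = best
    if m1 > m2:
        a1, m1, s1, a2, m2, s2 = a2, m2, s2, a1, m1, s1
    # unresolved when the means are closer than the component widths, or when
    # one component carries a negligible share of the fitted area (a narrow
    # spurious bump in the tail of a single-mode histogram)
    mass1, mass2 = abs(a1 * s1), abs(a2 * s2)
    minor_share = min(mass1, mass2) / max(mass1 + mass2, 1e-300)
    unimodal = (abs(m2 - m1) < 0.5 * (abs(s1) + abs(s2))) or minor_share < 0.05
    return GaussFit(mu1=float(m1), mu2=float(m2), sd1=float(abs(s1)),
                    sd2=float(abs(s2)), w1=float(a1), w2=float(a2),
                    fit_residual=resid / total, unimodal=unimodal)


def estimate_asc(gauss_fit: GaussFit, kcl_amp: float) -> float:
    """A_SC = 100 * (mu2 - mu1) / KCl amplitude, in % of KCl.

    A unimodal fit (no resolvable spontaneous activity) reports 0 with a
    warning — a quiescent strip is a valid observation, not an error.
    """
    if kcl_amp <= 0:
        raise DomainError("KCl reference amplitude must be positive")
    if gauss_fit.unimodal:
        warnings.warn("unimodal amplitude histogram: reporting A_SC = 0",
                      stacklevel=2)
        return 0.0
    return 100.0 * (gauss_fit.mu2 - gauss_fit.mu1) / kcl_amp


# ---------------------------------------------------------------------------
# power spectrum + main harmonic
# ---------------------------------------------------------------------------

def power_spectrum(samples: Sequence[float], sampling_rate: float,
                   band_low: float = DEFAULT_BAND[0],
                   window: str = "hann",
                   nperseg_s: Optional[float] = None,
                   detrend: str = "linear") -> Spectrum:
    """Detrended, tapered, averaged periodogram (Welch) of a segment.

    The per-segment length is chosen so the frequency resolution is at
    least ``band_low / 5``; a segment too short for that resolution raises
    :class:`ResolutionError`.
    """
    x = np.asarray(samples, float)
    T = x.size / sampling_rate
    required = 5.0 / band_low
    if T < required:
        raise ResolutionError(
            f"segment of {T:.0f} s cannot resolve {band_low} Hz: "
            f"need >= {required:.0f} s")
    if nperseg_s is None:
        nperseg_s = min(T, required)
    nperseg = min(int(round(nperseg_s * sampling_rate)), x.size)
    freqs, pxx = signal.welch(x, fs=sampling_rate, window=window,
                              nperseg=nperseg, noverlap=nperseg // 2,
                              detrend=detrend, scaling="density")
    n_seg = max(1, (x.size - nperseg // 2) // (nperseg - nperseg // 2))
    return Spectrum(freqs=freqs, power=pxx, df=float(freqs[1] - freqs[0]),
                    n_segments=int(n_seg))


def estimate_fsc(spectrum: Spectrum, band: tuple = DEFAULT_BAND,
                 prominence_factor: float = PROMINENCE_FACTOR) -> tuple:
    """Frequency of the main harmonic within ``band``.

    The peak bin must exceed ``prominence_factor`` times the band median
    power; its position is refined by parabolic interpolation across the
    three bins around the maximum. Returns ``(f_SC, peak_info)``.
    """
    f, p = spectrum.freqs, spectrum.power
    m = (f >= band[0]) & (f <= band[1]) & (f > 0)
    if not np.any(m):
        raise DomainError(f"spectrum does not cover the band {band}")
    fb, pb = f[m], p[m]
    med = float(np.median(pb))
    i = int(np.argmax(pb))
    if med <= 0 or pb[i] < prominence_factor * med:
        raise NoDominantRhythmError(
            "no dominant rhythm: peak power "
            f"{pb[i]:.3g} < {prominence_factor} x band median {med:.3g}")
    # parabolic interpolation on the three bins around the maximum
    j = int(np.flatnonzero(m)[i])
    f_peak = float(f[j])
    if 0 < j < f.size - 1:
        a, b, c = p[j - 1], p[j], p[j + 1]
        denom = a - 2 * b + c
        if denom < 0:
            delta = 0.5 * (a - c) / denom
            f_peak = float(f[j] + np.clip(delta, -0.5, 0.5) * spectrum.df)
    peak = {"freq": f_peak, "power": float(p[j]), "band": tuple(band),
            "median_power": med}
    return f_peak, peak


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def quantify_spontaneous(bundle: TraceBundle, band: tuple = DEFAULT_BAND,
                         min_len_s: float = MIN_SEGMENT_S,
                         n_bins: Optional[int] = None,
                         search_interval: Optional[tuple] = None,
                         ignore_drug_windows: bool = False,
                         kcl_amp: Optional[float] = None) -> SpontaneousStats:
    """Full spontaneous-activity quantification of one bundle.

    Composes KCl normalization -> stationary-segment selection -> amplitude
    histogram -> two-Gaussian fit -> A_SC, and detrended averaged
    periodogram -> main harmonic -> f_SC. Stage failures are re-raised as
    :class:`StageError` carrying the stage name.
    """
    from .efs import kcl_reference_amplitude  # circular-at-module-load guard

    flags = []
    if kcl_amp is None:
        if bundle.events.kcl is None:
            raise NormalizationError(
                "bundle lacks a KCl window: amplitudes cannot be normalized")
        try:
            kcl_amp = kcl_reference_amplitude(bundle)
        except Exception as exc:
            raise StageError("kcl_normalization", exc) from exc

    tol = 0.01 * kcl_amp  # 1% of KCl per minute
    try:
        seg = select_stationary_segment(
            bundle.trace, bundle.events, min_len_s=min_len_s,
            slope_tol_mN_per_min=tol, search_interval=search_interval,
            ignore_drug_windows=ignore_drug_windows)
    except Exception as exc:
        raise StageError("segment_selection", exc) from exc
    x = bundle.trace.slice(*seg)

    try:
        hist = amplitude_histogram(x, n_bins=n_bins)
        fit = fit_two_gaussians(hist)
    except Exception as exc:
        raise StageError("histogram_fit", exc) from exc
    if fit.unimodal:
        flags.append("unimodal_histogram")
        a_sc = 0.0
    else:
        a_sc = estimate_asc(fit, kcl_amp)

    try:
        spec = power_spectrum(x, bundle.trace.sampling_rate, band_low=band[0])
        f_sc, peak = estimate_fsc(spec, band=band)
    except Exception as exc:
        raise StageError("spectrum", exc) from exc

    return SpontaneousStats(A_SC=float(a_sc), f_SC=float(f_sc),
                            T_SC=float(1.0 / f_sc), segment=seg,
                            gauss_fit=fit, spectrum_peak=peak, flags=flags)
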