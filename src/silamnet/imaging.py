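"""Ca²⁺ / glutamate-sensor trace analytics.

The chain mirrors a standard wide-field network-activity analysis:

* ΔF/F₀ normalization against a running-median local baseline (with an
  extra FIR smoothing pass for acute-slice recordings);
* per-ROI peak detection by prominence (default thresholds 15% culture,
  20% slice, 1% glutamate sensor);
* a Monte-Carlo permutation null for co-activation — each ROI's peaks are
  redistributed uniformly in time (count-preserving), the frame-wise
  co-active counts of all permutations are pooled, and the co-activity
  threshold is the 99.9th percentile of that null;
* network-event segmentation as contiguous supra-threshold epochs, with the
  number of distinct recruited ROIs and the event frequency;
* synchrony statistics: pairwise Pearson correlation of the continuous
  ΔF/F₀ traces and mean nearest-event delays within ±2.1 s;
* evoked (KCl) response metrics: peak amplitude, area under the curve and
  the decay half-life T₁/₂ from a one-phase exponential fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, signal

from .containers import EventRaster, TraceMatrix

__all__ = [
    "DEFAULT_PEAK_THRESHOLDS",
    "normalize_dff",
    "detect_peaks",
    "mc_coactivity_threshold",
    "MCThresholdResult",
    "detect_network_events",
    "NetworkEventSet",
    "pairwise_correlation",
    "SynchronyStats",
    "pairwise_delay",
    "split_synchrony_events",
    "evoked_response",
    "EvokedResponse",
]

#: minimum ΔF/F₀ variation above baseline for a detected event, by recording kind
DEFAULT_PEAK_THRESHOLDS = {
    "calcium_culture": 0.15,
    "calcium_slice": 0.20,
    "glutamate": 0.01,
}

#: symmetric FIR kernel applied to slice recordings after normalization
SLICE_SMOOTHING_KERNEL = np.hanning(7)[1:-1] / np.hanning(7)[1:-1].sum()


def normalize_dff(raw: TraceMatrix, baseline_window_s: float = 30.0) -> TraceMatrix:
    """Convert raw fluorescence to ΔF/F₀ against a running-median baseline.

    F₀ is the running median over ``baseline_window_s`` (≥ 3 frames,
    nearest-edge padding) computed per ROI; the output is (F − F₀)/F₀.
    Slice recordings are additionally smoothed with a fixed symmetric FIR
    kernel after normalization.  Raw traces must be positive — a
    non-positive baseline anywhere is an error.
    """
    if raw.units == "dff":
        return raw
    win = int(round(baseline_window_s * raw.fs))
    if win < 3:
        raise ValueError("baseline_window_s must span at least 3 frames")
    if win % 2 == 0:
        win += 1
    f0 = ndimage.median_filter(raw.traces, size=(1, win), mode="nearest")
    if (f0 <= 0).any():
        raise ValueError("baseline F0 <= 0; raw traces must be positive fluorescence")
    dff = (raw.traces - f0) / f0
    if raw.kind == "calcium_slice":
        dff = np.apply_along_axis(
            lambda x: np.convolve(x, SLICE_SMOOTHING_KERNEL, mode="same"), 1, dff
        )
    return TraceMatrix(traces=dff, fs=raw.fs, kind=raw.kind, units="dff")


def _detect_peaks_1d(x: np.ndarray, fs: float, min_amplitude: float):
    peaks, props = signal.find_peaks(x, prominence=min_amplitude)
    widths = signal.peak_widths(x, peaks, rel_height=0.5)[0] / fs
    return peaks, x[peaks], widths


def detect_peaks(dff: TraceMatrix, min_amplitude: float | None = None) -> EventRaster:
    """Detect fluorescence transients per ROI.

    Local maxima with prominence ≥ ``min_amplitude`` (default by recording
    kind, see :data:`DEFAULT_PEAK_THRESHOLDS`).  The reported amplitude is
    the ΔF/F₀ value at the peak — (F − F₀)/F₀ — and the half-width is the
    width at half-prominence in seconds.  An empty raster is a valid
    result.
    """
    if dff.units != "dff":
        raise ValueError("detect_peaks expects ΔF/F₀ traces; call normalize_dff first")
    if min_amplitude is None:
        min_amplitude = DEFAULT_PEAK_THRESHOLDS[dff.kind]
    if not min_amplitude > 0:
        raise ValueError("min_amplitude must be positive")
    raster = np.zeros(dff.traces.shape, dtype=bool)
    meta = {"roi": [], "peak_frame": [], "amplitude": [], "halfwidth_s": []}
    for roi in range(dff.n_rois):
        peaks, amps, widths = _detect_peaks_1d(dff.traces[roi], dff.fs, min_amplitude)
        raster[roi, peaks] = True
        meta["roi"].extend([roi] * len(peaks))
        meta["peak_frame"].extend(peaks.tolist())
        meta["amplitude"].extend(amps.tolist())
        meta["halfwidth_s"].extend(widths.tolist())
    return EventRaster(raster=raster, fs=dff.fs, events=pd.DataFrame(meta))


@dataclass
class MCThresholdResult:
    """Permutation-null co-activity threshold."""

    threshold: int
    percentile_value: float
    n_perm: int
    pct: float
    empty_raster: bool = False


def mc_coactivity_threshold(raster: EventRaster, n_perm: int = 1000,
                            pct: float = 99.9,
                            seed: int | np.random.Generator | None = None,
                            scheme: str = "redistribute",
                            pooling: str = "pooled") -> MCThresholdResult:
    """Minimal co-active ROI count that exceeds chance.

    Each permutation independently randomizes every ROI's peak times while
    preserving its event count: ``scheme="redistribute"`` places the peaks
    uniformly at random without replacement (the default, weakest-assumption
    null); ``scheme="circular"`` applies an independent circular shift per
    ROI, preserving within-ROI inter-event structure.  Frame-wise co-active
    counts are pooled over all frames × permutations (``pooling="pooled"``)
    or reduced to one maximum per permutation (``pooling="per_perm_max"``),
    and the threshold is the ceiling of the ``pct`` percentile of that null
    distribution.  Deterministic for a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scheme not in ("redistribute", "circular"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if pooling not in ("pooled", "per_perm_max"):
        raise ValueError(f"unknown pooling {pooling!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    counts_per_roi = raster.raster.sum(axis=1)
    n_frames = raster.n_frames
    if counts_per_roi.sum() == 0:
        return MCThresholdResult(threshold=0, percentile_value=0.0, n_perm=n_perm,
                                 pct=pct, empty_raster=True)
    null_counts = np.zeros((n_perm, n_frames), dtype=np.int32)
    for roi, c in enumerate(counts_per_roi):
        c = int(c)
        if c == 0:
            continue
        if scheme == "redistribute":
            # c smallest entries of a random row = uniform draw without replacement
            u = rng.random((n_perm, n_frames))
            idx = np.argpartition(u, c - 1, axis=1)[:, :c]
        else:
            frames = np.flatnonzero(raster.raster[roi])
            shifts = rng.integers(0, n_frames, size=n_perm)
            idx = (frames[None, :] + shifts[:, None]) % n_frames
        np.put_along_axis(null_counts, idx,
                          np.take_along_axis(null_counts, idx, axis=1) + 1, axis=1)
    pool = null_counts.max(axis=1) if pooling == "per_perm_max" else null_counts.ravel()
    pv = float(np.percentile(pool, pct))
    return MCThresholdResult(threshold=int(math.ceil(pv)), percentile_value=pv,
                             n_perm=n_perm, pct=pct)


@dataclass
class NetworkEventSet:
    """Supra-threshold co-activation epochs."""

    events: pd.DataFrame  # start_frame, end_frame (inclusive), n_coactive
    threshold: int
    fs: float
    n_frames: int

    @property
    def frequency_per_min(self) -> float:
        return len(self.events) / (self.n_frames / self.fs / 60.0)


def detect_network_events(raster: EventRaster, threshold: int) -> NetworkEventSet:
    """Segment network events as contiguous runs of frames with ≥ threshold co-active ROIs.

    Each maximal run is one event; its size is the number of distinct ROIs
    peaking anywhere inside the run (no gap bridging between runs).
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    counts = raster.coactive_counts()
    above = counts >= threshold
    rows = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        seg = raster.raster[:, start:stop]
        rows.append({"start_frame": int(start), "end_frame": int(stop - 1),
                     "n_coactive": int(seg.any(axis=1).sum())})
    events = pd.DataFrame(rows, columns=["start_frame", "end_frame", "n_coactive"])
    return NetworkEventSet(events=events, threshold=threshold, fs=raster.fs,
                           n_frames=raster.n_frames)


@dataclass
class SynchronyStats:
    """Pairwise Pearson correlation of ΔF/F₀ traces."""

    pairwise_r: np.ndarray  # (n, n), NaN where a trace is constant
    mean_r: float
    excluded_rois: list[int] = field(default_factory=list)


def pairwise_correlation(dff: TraceMatrix) -> SynchronyStats:
    """Pearson R for all ROI pairs on the continuous traces.

    Constant traces have undefined correlation: their rows/columns are NaN
    and the ROIs are listed in ``excluded_rois``.  ``mean_r`` averages the
    defined upper-triangle entries.
    """
    if dff.n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    x = dff.traces
    sd = x.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, 1.0)
    iu = np.triu_indices(dff.n_rois, k=1)
    vals = r[iu]
    mean_r = float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")
    return SynchronyStats(pairwise_r=r, mean_r=mean_r,
                          excluded_rois=constant.tolist())


def pairwise_delay(raster: EventRaster, window_s: float = 2.1):
    """Mean nearest-event delay per ROI pair within ±``window_s``.

    For each event of ROI a, the nearest event of ROI b within the window
    contributes |Δt|; a pair's value averages the contributions of both
    directions, and pairs with no in-window match are excluded from the
    summary mean.

    Returns
    -------
    mean_delay_s : float
        Mean over included pairs (NaN if no pair has matches).
    pair_delays : ndarray (n, n)
        Symmetric per-pair mean |Δt| in seconds, NaN for excluded pairs.
    """
    if not window_s > 0:
        raise ValueError("window_s must be positive")
    n = raster.n_rois
    times = [np.flatnonzero(raster.raster[i]) / raster.fs for i in range(n)]
    out = np.full((n, n), np.nan)
    for a in range(n):
        for b in range(a + 1, n):
            ta, tb = times[a], times[b]
            if ta.size == 0 or tb.size == 0:
                continue
            deltas = []
            for src, dst in ((ta, tb), (tb, ta)):
                pos = np.searchsorted(dst, src)
                left = np.clip(pos - 1, 0, dst.size - 1)
                right = np.clip(pos, 0, dst.size - 1)
                d = np.minimum(np.abs(src - dst[left]), np.abs(src - dst[right]))
                deltas.extend(d[d <= window_s].tolist())
            if deltas:
                out[a, b] = out[b, a] = float(np.mean(deltas))
    np.fill_diagonal(out, 0.0)
    iu = np.triu_indices(n, k=1)
    vals = out[iu]
    mean_delay = float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")
    return mean_delay, out


def split_synchrony_events(network_trace: np.ndarray, fs: float, cut: float = 0.2,
                           min_prominence: float = 0.05) -> dict[str, pd.DataFrame]:
    """Partition population-trace peaks into high- and low-synchrony classes.

    Peaks of the mean ΔF/F₀ trace (prominence ≥ ``min_prominence``) with
    amplitude strictly above ``cut`` are "high"; the rest, including an
    amplitude of exactly ``cut``, are "low".  Each class carries amplitude,
    half-width and frequency summaries.
    """
    x = np.asarray(network_trace, dtype=float)
    peaks, amps, widths = _detect_peaks_1d(x, fs, min_prominence)
    df = pd.DataFrame({"peak_frame": peaks, "amplitude": amps, "halfwidth_s": widths})
    minutes = x.size / fs / 60.0
    out = {}
    for name, sel in (("high", df["amplitude"] > cut), ("low", df["amplitude"] <= cut)):
        cls = df[sel].reset_index(drop=True)
        cls.attrs["frequency_per_min"] = len(cls) / minutes
        out[name] = cls
    return out


@dataclass
class EvokedResponse:
    """Stimulus-evoked response metrics (ΔF/F₀ over pre-stimulus baseline)."""

    peak_amplitude: float
    auc: float  # ΔF/F₀ · s
    t_half_s: float  # NaN when the decay fit did not converge
    fit_failed: bool = False


def evoked_response(trace: np.ndarray, fs: float, stim_frame: int,
                    baseline_frames: int = 50) -> EvokedResponse:
    """Quantify a depolarization-evoked fluorescence response.

    The trace is normalized by the mean of the first ``baseline_frames``
    frames; amplitude is the post-stimulus maximum of F/F₀ − 1, AUC the
    trapezoidal area of the post-stimulus response, and T₁/₂ = ln2/k from a
    one-phase exponential fit A·exp(−k·t) + C to the post-peak decay.  A
    failed fit flags ``t_half_s`` as NaN; amplitude and AUC are still
    returned.
    """
    x = np.asarray(trace, dtype=float)
    if stim_frame <= baseline_frames:
        raise ValueError("stim_frame must follow the baseline window")
    f0 = x[:baseline_frames].mean()
    if f0 <= 0:
        raise ValueError("baseline fluorescence must be positive")
    norm = x / f0 - 1.0
    post = norm[stim_frame:]
    peak_idx = int(np.argmax(post))
    amplitude = float(post[peak_idx])
    auc = float(np.trapezoid(post, dx=1.0 / fs))
    decay = post[peak_idx:]
    t = np.arange(decay.size) / fs
    t_half = float("nan")
    failed = True
    if decay.size >= 4 and amplitude > 0:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    lambda tt, a, k, c: a * np.exp(-k * tt) + c,
                    t, decay, p0=(amplitude, 1.0, 0.0), maxfev=5000,
                )
            a, k, c = popt
            if k > 0 and a > 0:
                t_half = float(math.log(2.0) / k)
                failed = False
        except RuntimeError:
            pass
    return EvokedResponse(peak_amplitude=amplitude, auc=auc, t_half_s=t_half,
                          fit_failed=failed)
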