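"""Breath segmentation and selection on the summed lung impedance signal.

The global signal is the per-frame sum of impedance over all lung pixels.
Breaths are delimited by trough-peak-trough triplets of that signal:
onset = trough preceding inspiration, end-inspiration = peak,
end-expiration = following trough. Detection runs on a lightly smoothed
copy (to suppress cardiac-frequency oscillation) and every extremum is
then refined on the raw signal, so on noise-free signals the reported
indices are exactly the discrete extrema of the raw series.

Tie-breaks on flat extrema: a flat peak takes the first index of the
maximal run; a flat trough is split — end-expiration takes the first index
of the minimal run and the next breath's onset takes the last, so an
end-expiratory pause belongs to neither inspiration.

Artefact flagging is algorithmic (the field's practice of hand-picking
"artefact-free" breaths is not reproducible): a breath is flagged when its
amplitude is a robust outlier, its baseline shifts abruptly, or its
duration is physiologically implausible. All thresholds are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io_formats import FrameSequence, LungMasks, SegmentationParams

__all__ = [
    "Breath",
    "PhaseUnanalysableError",
    "global_signal",
    "segment_breaths",
    "flag_artefacts",
    "select_breath_run",
    "breath_table",
]


class PhaseUnanalysableError(RuntimeError):
    """No run of enough consecutive artefact-free breaths exists."""


@dataclass(frozen=True)
class Breath:
    """Frame indices delimiting one breath in the parent sequence."""

    onset: int   # start of inspiration (trough)
    peak: int    # end of inspiration
    end: int     # end of expiration (trough)
    flagged: bool = False
    reason: str | None = None

    def __post_init__(self) -> None:
        if not (self.onset < self.peak < self.end):
            raise ValueError(
                f"breath indices must satisfy onset < peak < end, got "
                f"({self.onset}, {self.peak}, {self.end})")

    def duration_frames(self) -> int:
        return self.end - self.onset


def global_signal(seq: FrameSequence, masks: LungMasks) -> np.ndarray:
    """Summed impedance over right+left lung pixels, one value per frame."""
    if masks.grid_shape != seq.grid_shape:
        raise ValueError(
            f"mask grid {masks.grid_shape} does not match frames {seq.grid_shape}")
    union = masks.union
    return seq.frames[:, union].sum(axis=1, dtype=np.float64)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; the window shrinks symmetrically near the
    edges (half-width min(h, i, n-1-i)) so the smoothed series keeps
    following the signal into the first and last breath instead of
    flattening there. Window forced odd."""
    if window <= 1:
        return x.astype(float)
    if window % 2 == 0:
        window += 1
    half = window // 2
    x = x.astype(float)
    n = len(x)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo, hi = idx - h, idx + h
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def _alternating_extrema(x: np.ndarray, prominence: float
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Peak and trough locations with a shared prominence floor, forced to
    alternate (of two same-type neighbours the more extreme survives)."""
    peaks, _ = sps.find_peaks(x, prominence=prominence)
    troughs, _ = sps.find_peaks(-x, prominence=prominence)
    events = sorted([(int(i), +1) for i in peaks] + [(int(i), -1) for i in troughs])
    cleaned: list[tuple[int, int]] = []
    for idx, kind in events:
        if cleaned and cleaned[-1][1] == kind:
            prev_idx = cleaned[-1][0]
            better = (x[idx] > x[prev_idx]) if kind > 0 else (x[idx] < x[prev_idx])
            if better:
                cleaned[-1] = (idx, kind)
        else:
            cleaned.append((idx, kind))
    p = np.array([i for i, k in cleaned if k > 0], dtype=int)
    t = np.array([i for i, k in cleaned if k < 0], dtype=int)
    return p, t


def _refine_peak(x: np.ndarray, idx: int, half: int) -> int:
    lo, hi = max(0, idx - half), min(len(x), idx + half + 1)
    w = x[lo:hi]
    return lo + int(np.argmax(w))  # first index of a flat maximal run


def _refine_trough(x: np.ndarray, idx: int, half: int) -> tuple[int, int]:
    """(first, last) index of the minimal run around ``idx`` in the raw
    signal — first serves as end-expiration, last as the next onset."""
    lo, hi = max(0, idx - half), min(len(x), idx + half + 1)
    w = x[lo:hi]
    m = w.min()
    flat = np.flatnonzero(w == m)
    # contiguous flat run of the minimum nearest the detected location
    runs = np.split(flat, np.flatnonzero(np.diff(flat) > 1) + 1)
    run = min(runs, key=lambda r: abs(lo + int(r[0]) - idx))
    return lo + int(run[0]), lo + int(run[-1])


def segment_breaths(signal: np.ndarray, frame_rate: float,
                    params: SegmentationParams | None = None) -> list[Breath]:
    """Segment the global signal into complete breaths.

    Extrema are found on a smoothed copy with a prominence floor of
    ``min_prominence_frac`` x the median candidate breath amplitude, then
    refined to exact raw-signal extrema. Partial breaths at the edges are
    discarded. Raises if the frame rate cannot resolve the minimum breath
    duration (at least two frames per ``min_breath_s``).
    """
    params = params or SegmentationParams()
    signal = np.asarray(signal, dtype=float)
    if len(signal) < 2 * frame_rate:
        raise ValueError("signal must cover at least 2 s")
    if frame_rate * params.min_breath_s < 2.0:
        raise ValueError(
            f"frame rate {frame_rate} Hz too low to resolve breaths of "
            f"{params.min_breath_s} s")
    window = max(1, int(round(params.smooth_window_s * frame_rate)))
    smoothed = _smooth(signal, window)

    # first pass: prominence floor from a robust signal range (immune to
    # residual cardiac ripple), to estimate the typical breath amplitude
    lo, hi = np.percentile(smoothed, [2.5, 97.5])
    floor0 = params.min_prominence_frac * max(hi - lo, 0.0)
    if floor0 <= 0:
        return []
    peaks0, troughs0 = _alternating_extrema(smoothed, prominence=floor0)
    amp0 = []
    for p in peaks0:
        left = troughs0[troughs0 < p]
        if len(left):
            amp0.append(smoothed[p] - smoothed[left[-1]])
    if not amp0:
        return []
    floor = params.min_prominence_frac * float(np.median(amp0))

    peaks, troughs = _alternating_extrema(smoothed, prominence=floor)
    if len(troughs) < 2:
        return []
    # refinement radius: wide enough for the smoothing shift, but never
    # reaching a neighbouring breath's extremum
    med_spacing = float(np.median(np.diff(troughs)))
    half = max(1, min(window // 2, int(0.3 * med_spacing)))
    breaths: list[Breath] = []
    for p in peaks:
        left = troughs[troughs < p]
        right = troughs[troughs > p]
        if not len(left) or not len(right):
            continue  # partial breath at an edge
        _, onset = _refine_trough(signal, int(left[-1]), half)
        end, _ = _refine_trough(signal, int(right[0]), half)
        peak = _refine_peak(signal, int(p), half)
        if not (onset < peak < end):
            continue
        if breaths and onset < breaths[-1].end:
            continue  # keep breaths ordered and non-overlapping
        breaths.append(Breath(onset=onset, peak=peak, end=end))
    return breaths


# ---------------------------------------------------------------------------
# Artefact flagging and run selection
# ---------------------------------------------------------------------------

def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    return (pd.Series(x).rolling(window, center=True, min_periods=1)
            .median().to_numpy())


def flag_artefacts(breaths: list[Breath], signal: np.ndarray,
                   frame_rate: float,
                   params: SegmentationParams | None = None) -> list[Breath]:
    """Return breaths with artefact flags set (input order preserved).

    Flag reasons, checked in this order:

    ``amplitude``
        |TIV - rolling median TIV| exceeds ``max(k * MAD, floor * median
        TIV)`` where MAD is the median of those deviations over the whole
        recording. A global MAD resists masking when several artefacted
        breaths fall in one rolling window; the floor keeps ordinary
        breath-to-breath variability from being flagged.
    ``baseline``
        the end-expiratory trough level shifts by more than
        ``d * median TIV`` relative to the breath's onset trough.
    ``duration``
        breath duration outside [min_breath_s, max_breath_s].
    """
    params = params or SegmentationParams()
    if not breaths:
        return []
    signal = np.asarray(signal, dtype=float)
    tiv = np.array([signal[b.peak] - signal[b.onset] for b in breaths])
    med_tiv = float(np.median(tiv))
    roll_med = _rolling_median(tiv, params.rolling_window)
    # truncated edge windows estimate the local level poorly (one outlier
    # can dominate them); fall back to the recording-wide median there
    half = params.rolling_window // 2
    if half > 0 and len(tiv) > 2 * half:
        roll_med[:half] = med_tiv
        roll_med[-half:] = med_tiv
    dev = np.abs(tiv - roll_med)
    mad = float(np.median(dev))
    amp_threshold = max(params.amplitude_k_mad * mad,
                        params.amplitude_floor_frac * med_tiv)
    out: list[Breath] = []
    for i, b in enumerate(breaths):
        reason = None
        if dev[i] > amp_threshold:
            reason = "amplitude"
        elif abs(signal[b.end] - signal[b.onset]) > params.baseline_d_frac * med_tiv:
            reason = "baseline"
        else:
            dur = b.duration_frames() / frame_rate
            if not (params.min_breath_s <= dur <= params.max_breath_s):
                reason = "duration"
        out.append(replace(b, flagged=reason is not None, reason=reason))
    return out


def select_breath_run(breaths: list[Breath], min_run: int = 6,
                      max_run: int = 10) -> list[Breath]:
    """Earliest run of >= ``min_run`` consecutive unflagged breaths,
    truncated to ``max_run``. Deterministic; raises
    :class:`PhaseUnanalysableError` when no qualifying run exists."""
    run: list[Breath] = []
    for b in breaths:
        if b.flagged:
            if len(run) >= min_run:
                break
            run = []
        else:
            run.append(b)
    if len(run) < min_run:
        raise PhaseUnanalysableError(
            f"no run of {min_run} consecutive artefact-free breaths "
            f"(longest usable run: {len(run)})")
    return run[:max_run]


def breath_table(breaths: list[Breath], frame_rate: float,
                 meta=None) -> pd.DataFrame:
    """Audit table: one row per breath with timings and flags."""
    rows = []
    for i, b in enumerate(breaths):
        row = {
            "breath": i,
            "onset_s": b.onset / frame_rate,
            "peak_s": b.peak / frame_rate,
            "end_s": b.end / frame_rate,
            "flagged": b.flagged,
            "reason": b.reason or "",
        }
        if meta is not None:
            row = {"animal": meta.animal, "session": meta.session,
                   "phase": meta.phase, **row}
        rows.append(row)
    return pd.DataFrame(rows)
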