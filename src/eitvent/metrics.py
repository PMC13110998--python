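"""Per-breath functional EIT ventilation variables and phase aggregation.

For each selected breath the functional image is the per-pixel inspiratory
impedance change Z(end-inspiration) - Z(onset). From it come the centre of
ventilation (CoV) along the right-left and ventral-dorsal axes and the
right/left region-of-interest split; from the summed lung signal come the
tidal impedance variation (TIV), inspiratory time (TI) and end-expiratory
lung impedance (EELI); the selected run yields the tidal rate and the
minute impedance variation (MIV = tidal rate x mean TIV).

Conventions
-----------
* CoV is the impedance-weighted centroid over *lung pixels only*, linearly
  rescaled so the rightmost (most ventral) lung-pixel centre maps to 0% and
  the leftmost (most dorsal) to 100% — both axes are anchored at the lung
  extremities, not the image border.
* TIV is literally Z at end-inspiration minus Z at onset; since impedance
  rises on inspiration this is positive, and a non-positive value marks a
  mis-segmented breath and raises.
* Negative pixels in a functional image (local out-of-phase impedance
  change) are clamped to 0 for centroid and ROI purposes; the clamp count
  is reported.
* All impedance quantities stay in arbitrary units (AU); no volume
  calibration is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .breaths import (Breath, flag_artefacts, global_signal, segment_breaths,
                      select_breath_run)
from .io_formats import (FrameSequence, LungMasks, SegmentationParams,
                         SequenceMeta)

__all__ = [
    "FunctionalImage",
    "BreathMetrics",
    "PhaseObservation",
    "functional_image",
    "cov",
    "roi_split",
    "breath_scalars",
    "run_rates",
    "aggregate_phase",
    "analyse_run",
    "analyse_sequence",
]


@dataclass(frozen=True)
class FunctionalImage:
    """Per-pixel inspiratory impedance change for one breath."""

    pixels: np.ndarray   # 2-D, non-negative after clamping
    n_clamped: int       # pixels whose raw change was negative


@dataclass(frozen=True)
class BreathMetrics:
    """The per-breath variables (run-level rate/MIV live on the run)."""

    tiv: float      # AU
    ti: float       # s
    eeli: float     # AU
    cov_rl: float   # %
    cov_vd: float   # %
    roi_r: float    # %
    roi_l: float    # %


@dataclass(frozen=True)
class PhaseObservation:
    """One animal x session x phase row: run means of each variable."""

    animal: str
    session: int
    phase: str
    n_breaths: int
    cov_rl: float
    cov_vd: float
    roi_r: float
    roi_l: float
    tiv: float
    miv: float
    eeli: float
    tidal_rate: float
    ti: float

    def __post_init__(self) -> None:
        if not (1 <= self.n_breaths):
            raise ValueError("n_breaths must be positive")


def functional_image(seq: FrameSequence, breath: Breath) -> FunctionalImage:
    if breath.end >= seq.n_frames:
        raise ValueError("breath indices exceed sequence length")
    delta = (seq.frames[breath.peak].astype(np.float64)
             - seq.frames[breath.onset].astype(np.float64))
    n_clamped = int((delta < 0).sum())
    return FunctionalImage(pixels=np.clip(delta, 0.0, None), n_clamped=n_clamped)


def _axis_pct(masks: LungMasks, axis: str) -> np.ndarray:
    """Percent coordinate of every pixel along ``axis`` ('rl' or 'vd'),
    anchored at the extreme lung-pixel centres."""
    union = masks.union
    n_rows, n_cols = union.shape
    if axis == "rl":
        extent = np.flatnonzero(union.any(axis=0))
        coord = np.broadcast_to(np.arange(n_cols), (n_rows, n_cols))
    elif axis == "vd":
        extent = np.flatnonzero(union.any(axis=1))
        coord = np.broadcast_to(np.arange(n_rows)[:, None], (n_rows, n_cols))
    else:
        raise ValueError(f"axis must be 'rl' or 'vd', got {axis!r}")
    if len(extent) < 2:
        raise ValueError("lung region spans a single row/column; CoV undefined")
    return 100.0 * (coord - extent[0]) / (extent[-1] - extent[0])


def cov(image: FunctionalImage | np.ndarray, masks: LungMasks, axis: str) -> float:
    """Centre of ventilation in percent along ``axis``.

    0% is the right (``axis='rl'``) or ventral (``axis='vd'``) lung
    extreme, 100% the left or dorsal one. Raises on an all-zero map.
    """
    pixels = image.pixels if isinstance(image, FunctionalImage) else np.asarray(image)
    if pixels.shape != masks.grid_shape:
        raise ValueError("map shape does not match mask grid")
    pct = _axis_pct(masks, axis)
    union = masks.union
    w = np.where(union, pixels, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("no ventilation signal (all-zero functional image)")
    return float((w * pct).sum() / total)


def roi_split(image: FunctionalImage | np.ndarray, masks: LungMasks
              ) -> tuple[float, float]:
    """(ROI_R, ROI_L): percent of total inspiratory impedance change in the
    right and left lung; sums to 100 exactly."""
    pixels = image.pixels if isinstance(image, FunctionalImage) else np.asarray(image)
    if pixels.shape != masks.grid_shape:
        raise ValueError("map shape does not match mask grid")
    right = float(pixels[masks.right_mask].sum())
    left = float(pixels[masks.left_mask].sum())
    total = right + left
    if total <= 0:
        raise ValueError("no ventilation signal (all-zero functional image)")
    roi_r = 100.0 * right / total
    return roi_r, 100.0 - roi_r


def breath_scalars(signal: np.ndarray, breath: Breath, frame_rate: float
                   ) -> tuple[float, float, float]:
    """(TIV, TI, EELI) of one breath from the summed lung signal."""
    signal = np.asarray(signal, dtype=float)
    tiv = float(signal[breath.peak] - signal[breath.onset])
    if tiv <= 0:
        raise ValueError(
            f"non-positive TIV for breath at frames "
            f"({breath.onset}, {breath.peak}, {breath.end}); mis-segmented?")
    ti = (breath.peak - breath.onset) / frame_rate
    eeli = float(signal[breath.end])
    return tiv, ti, eeli


def run_rates(run: list[Breath], frame_rate: float, tivs: np.ndarray
              ) -> tuple[float, float]:
    """(tidal rate in breaths/min, MIV in AU/min) of a selected run.

    Breath duration is onset-to-onset; the last breath contributes its
    onset-to-end duration (identical when breaths are contiguous).
    """
    if len(run) < 2:
        raise ValueError("run must contain at least two breaths")
    onsets = np.array([b.onset for b in run], dtype=float)
    durations = np.diff(onsets)
    durations = np.append(durations, run[-1].end - run[-1].onset)
    mean_dur_s = durations.mean() / frame_rate
    tidal_rate = 60.0 / mean_dur_s
    miv = tidal_rate * float(np.mean(tivs))
    return tidal_rate, miv


def aggregate_phase(per_breath: list[BreathMetrics], tidal_rate: float,
                    miv: float, meta: SequenceMeta) -> PhaseObservation:
    """Arithmetic means of the per-breath variables over the selected run."""
    if not per_breath:
        raise ValueError("no breath metrics to aggregate")
    mean = lambda attr: float(np.mean([getattr(m, attr) for m in per_breath]))
    return PhaseObservation(
        animal=meta.animal, session=meta.session, phase=meta.phase,
        n_breaths=len(per_breath),
        cov_rl=mean("cov_rl"), cov_vd=mean("cov_vd"),
        roi_r=mean("roi_r"), roi_l=mean("roi_l"),
        tiv=mean("tiv"), miv=miv, eeli=mean("eeli"),
        tidal_rate=tidal_rate, ti=mean("ti"))


def analyse_run(seq: FrameSequence, masks: LungMasks, run: list[Breath],
                signal: np.ndarray) -> tuple[PhaseObservation, list[BreathMetrics]]:
    """Compute all variables for a selected breath run and aggregate them."""
    per_breath: list[BreathMetrics] = []
    for b in run:
        img = functional_image(seq, b)
        tiv, ti, eeli = breath_scalars(signal, b, seq.frame_rate)
        c_rl = cov(img, masks, "rl")
        c_vd = cov(img, masks, "vd")
        r, l = roi_split(img, masks)
        per_breath.append(BreathMetrics(tiv=tiv, ti=ti, eeli=eeli,
                                        cov_rl=c_rl, cov_vd=c_vd,
                                        roi_r=r, roi_l=l))
    tivs = np.array([m.tiv for m in per_breath])
    tidal_rate, miv = run_rates(run, seq.frame_rate, tivs)
    obs = aggregate_phase(per_breath, tidal_rate, miv, seq.meta)
    return obs, per_breath


def analyse_sequence(seq: FrameSequence, masks: LungMasks,
                     params: SegmentationParams | None = None,
                     min_run: int = 6, max_run: int = 10,
                     ) -> tuple[PhaseObservation, list[Breath], list[Breath]]:
    """Full per-recording pipeline: signal -> breaths -> flags -> selected
    run -> one phase observation.

    Returns the observation, all flagged breaths (audit), and the selected
    run. Propagates :class:`~eitvent.breaths.PhaseUnanalysableError` when
    no acceptable run exists, mirroring recordings dropped from analysis.
    """
    params = params or SegmentationParams()
    sig = global_signal(seq, masks)
    breaths = segment_breaths(sig, seq.frame_rate, params)
    breaths = flag_artefacts(breaths, sig, seq.frame_rate, params)
    run = select_breath_run(breaths, min_run=min_run, max_run=max_run)
    obs, _ = analyse_run(seq, masks, run, sig)
    return obs, breaths, run
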