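"""Synthetic EIT frame generator with known ground truth.

Real peri-anaesthetic recordings from live animals are not portable; this
module emulates them. It renders frame sequences whose breath geometry
(onset, inspiratory/expiratory durations, amplitude, baseline) and spatial
ventilation distribution (a non-negative weight map with known centroid and
right/left mass split) are set explicitly, so every downstream metric has
an analytic ground truth. The default study layout is six animals, two
sessions, seven protocol phases, with 5-minute recording windows while
standing and 2-minute windows in sternal recumbency, and per-phase
physiology drawn around the phase means/SDs in
:data:`eitvent.io_formats.DEFAULT_PHASE_PARAMS`.

Signal model per pixel p and frame time t::

    Z(p, t) = baseline(p) * b(t)  +  weight(p) * g(t)  +  artefact terms

where ``g`` is a train of raised-cosine breath pulses (monotone half-cosine
rise over TI seconds to the breath amplitude, half-cosine decay over TE)
and ``weight`` sums to 1 over lung pixels, so the breath amplitude is the
tidal impedance variation of the summed lung signal. Artefacts (baseline
drift, cardiac-frequency oscillation, motion spikes) are additive and
individually switchable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .io_formats import (
    CANONICAL_ORIENTATION,
    PHASES,
    ArtefactSpec,
    FrameSequence,
    LungMasks,
    SequenceMeta,
    StudyConfig,
)

__all__ = [
    "BreathGroundTruth",
    "SequenceTruth",
    "StudyRecord",
    "make_lung_masks",
    "weight_map_for_targets",
    "weight_map_centroids",
    "generate_sequence",
    "draw_phase_table",
    "generate_study",
]

ANIMALS = tuple(f"A{i}" for i in range(1, 7))

#: Variables drawn at phase level (ROI-L and per-breath noise are derived).
_PHASE_VARIABLES = ("cov_rl", "cov_vd", "roi_r", "tiv", "miv", "eeli",
                    "tidal_rate", "ti")

_CLIPS = {
    "cov_rl": (20.0, 80.0),
    "cov_vd": (20.0, 80.0),
    "roi_r": (10.0, 90.0),
    "tiv": (0.05, np.inf),
    "miv": (0.5, np.inf),
    "eeli": (5.0, np.inf),
    # a 2-min recording window needs several complete breaths and the CMV
    # protocol bounds ventilator rates to 10-18/min, so draws below ~6/min
    # are incompatible with the recorded study conditions
    "tidal_rate": (6.0, 60.0),
    "ti": (0.2, 25.0),
}

#: Missingness pattern mirrored from the study: one animal lost its last
#: four phases in one session (device software failure), another its final
#: standing phase (uncooperative animal).
MISSING_ROWS = tuple(
    [("A4", 2, ph) for ph in PHASES[3:]] + [("A6", 1, "Stand_post")]
)


@dataclass(frozen=True)
class BreathGroundTruth:
    """One injected breath: timing, amplitude and baseline."""

    onset_s: float
    ti_s: float
    te_s: float
    amplitude: float   # TIV, AU
    eeli: float        # baseline level at this breath, AU

    def __post_init__(self) -> None:
        if self.ti_s <= 0 or self.te_s <= 0:
            raise ValueError("TI and TE must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    @property
    def peak_s(self) -> float:
        return self.onset_s + self.ti_s

    @property
    def end_s(self) -> float:
        return self.onset_s + self.ti_s + self.te_s


@dataclass
class SequenceTruth:
    """Everything injected into one generated sequence."""

    breaths: list[BreathGroundTruth]
    weight_map: np.ndarray
    cov_rl: float          # analytic centroid of the weight map, %
    cov_vd: float
    roi_r: float           # right-lung mass fraction of the weight map, %
    spike_breaths: list[int] = field(default_factory=list)
    phase_values: dict = field(default_factory=dict)  # drawn phase-level physiology


@dataclass
class StudyRecord:
    sequence: FrameSequence
    truth: SequenceTruth
    masks: LungMasks


# ---------------------------------------------------------------------------
# Masks and weight maps
# ---------------------------------------------------------------------------

def make_lung_masks(shape: tuple[int, int] = (32, 32)) -> LungMasks:
    """Two elliptical lung fields on the reconstruction raster.

    Rows run ventral (0) to dorsal, columns right (0) to left; the
    anatomical midline sits at the centre column.
    """
    n_rows, n_cols = shape
    if n_rows < 8 or n_cols < 8:
        raise ValueError("grid too small for elliptical lung masks")
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    midline = n_cols // 2
    r_center = ((n_rows - 1) / 2, midline - 1 - 0.22 * n_cols)
    l_center = ((n_rows - 1) / 2, midline + 0.22 * n_cols)
    a_row = 0.33 * n_rows           # vertical semi-axis
    b_right = 0.205 * n_cols        # right lung slightly wider
    b_left = 0.19 * n_cols
    right = (((rows - r_center[0]) / a_row) ** 2
             + ((cols - r_center[1]) / b_right) ** 2) <= 1.0
    left = (((rows - l_center[0]) / a_row) ** 2
            + ((cols - l_center[1]) / b_left) ** 2) <= 1.0
    right &= cols < midline
    left &= cols >= midline
    return LungMasks(right_mask=right, left_mask=left, midline_col=midline)


def _pct_coords(masks: LungMasks) -> tuple[np.ndarray, np.ndarray]:
    """Percentage coordinates of every grid pixel along the lateral and
    vertical axes, anchored at the extreme lung-pixel centres (0% = right /
    ventral extreme, 100% = left / dorsal extreme)."""
    union = masks.union
    rows_any = np.flatnonzero(union.any(axis=1))
    cols_any = np.flatnonzero(union.any(axis=0))
    if len(cols_any) < 2 or len(rows_any) < 2:
        raise ValueError("lung region must span at least two rows and columns")
    n_rows, n_cols = union.shape
    rr, cc = np.mgrid[0:n_rows, 0:n_cols]
    pct_c = 100.0 * (cc - cols_any[0]) / (cols_any[-1] - cols_any[0])
    pct_v = 100.0 * (rr - rows_any[0]) / (rows_any[-1] - rows_any[0])
    return pct_c, pct_v


def weight_map_centroids(weight_map: np.ndarray, masks: LungMasks
                         ) -> tuple[float, float, float]:
    """Analytic (CoV_RL, CoV_VD, ROI_R) of a weight map, in percent."""
    pct_c, pct_v = _pct_coords(masks)
    union = masks.union
    w = np.where(union, weight_map, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("weight map carries no mass on lung pixels")
    cov_rl = float((w * pct_c).sum() / total)
    cov_vd = float((w * pct_v).sum() / total)
    roi_r = float(100.0 * w[masks.right_mask].sum() / total)
    return cov_rl, cov_vd, roi_r


def weight_map_for_targets(masks: LungMasks, cov_rl: float, cov_vd: float,
                           roi_r: float, clip: bool = False) -> np.ndarray:
    """Non-negative weight map (sum 1 over lung pixels) realising the given
    right-lung mass fraction exactly and the two centroids to solver
    precision.

    The map is uniform per lung scaled to the ROI split, modulated by
    linear tilts along each axis whose slopes are solved so the weighted
    centroid lands on the requested CoV values; per-lung renormalisation
    after tilting keeps the ROI split exact.

    The ROI split pins most of the lateral centroid, so an extreme split
    and a conflicting CoV_RL can be jointly infeasible on a fixed lung
    geometry; by default that raises, with ``clip=True`` the nearest
    feasible map is returned instead (the study generator uses this — the
    recorded ground truth is always the map's actual centroid).
    """
    if not (0 < roi_r < 100):
        raise ValueError("roi_r must be in (0, 100)")
    pct_c, pct_v = _pct_coords(masks)
    u_c = (pct_c - 50.0) / 50.0
    u_v = (pct_v - 50.0) / 50.0
    base = np.zeros(masks.grid_shape)
    base[masks.right_mask] = (roi_r / 100.0) / masks.right_mask.sum()
    base[masks.left_mask] = (1.0 - roi_r / 100.0) / masks.left_mask.sum()

    def build(params: np.ndarray) -> np.ndarray:
        alpha, gamma = params
        w = base * np.clip(1.0 + alpha * u_c, 1e-6, None) \
                 * np.clip(1.0 + gamma * u_v, 1e-6, None)
        for m, mass in ((masks.right_mask, roi_r / 100.0),
                        (masks.left_mask, 1.0 - roi_r / 100.0)):
            s = w[m].sum()
            w[m] *= mass / s
        return w

    def residual(params: np.ndarray) -> np.ndarray:
        got_rl, got_vd, _ = weight_map_centroids(build(params), masks)
        return np.array([got_rl - cov_rl, got_vd - cov_vd])

    sol = optimize.least_squares(residual, x0=[0.0, 0.0],
                                 bounds=([-0.95, -0.95], [0.95, 0.95]),
                                 xtol=1e-12, ftol=1e-12, gtol=1e-12)
    if not clip and np.abs(sol.fun).max() > 0.1:
        raise ValueError(
            f"targets CoV_RL={cov_rl}, CoV_VD={cov_vd}, ROI_R={roi_r} not "
            f"realisable on this lung geometry (residual {sol.fun})")
    return build(sol.x)


# ---------------------------------------------------------------------------
# Sequence synthesis
# ---------------------------------------------------------------------------

def _breath_pulse(t: np.ndarray, breath: BreathGroundTruth) -> np.ndarray:
    """Raised-cosine pulse: 0 at onset, amplitude at onset+TI, 0 at end."""
    g = np.zeros_like(t)
    insp = (t >= breath.onset_s) & (t <= breath.peak_s)
    g[insp] = 0.5 * breath.amplitude * (
        1.0 - np.cos(np.pi * (t[insp] - breath.onset_s) / breath.ti_s))
    exp_ = (t > breath.peak_s) & (t <= breath.end_s)
    g[exp_] = 0.5 * breath.amplitude * (
        1.0 + np.cos(np.pi * (t[exp_] - breath.peak_s) / breath.te_s))
    return g


def generate_sequence(truth: Sequence[BreathGroundTruth],
                      artefacts: ArtefactSpec,
                      masks: LungMasks,
                      frame_rate: float,
                      seed: int | np.random.SeedSequence,
                      meta: SequenceMeta | None = None,
                      weight_map: np.ndarray | None = None,
                      duration_s: float | None = None,
                      ) -> tuple[FrameSequence, list[int]]:
    """Render a frame sequence from injected breaths.

    Returns the sequence together with the indices (into ``truth``) of
    breaths that received a motion spike, so artefact-flagging can be
    checked against the injected locations. Fully deterministic for a fixed
    seed. ``truth`` may be empty, giving a constant-baseline recording.
    """
    truth = sorted(truth, key=lambda b: b.onset_s)
    for prev, nxt in zip(truth, truth[1:]):
        if nxt.onset_s < prev.end_s - 1e-9:
            raise ValueError("breaths overlap")
    if weight_map is None:
        weight_map = np.where(masks.union, 1.0 / masks.union.sum(), 0.0)
    weight_map = np.asarray(weight_map, dtype=float)
    if weight_map.shape != masks.grid_shape:
        raise ValueError(
            f"weight map shape {weight_map.shape} does not match mask grid "
            f"{masks.grid_shape}")
    if duration_s is None:
        duration_s = (truth[-1].end_s + 1.0) if truth else 10.0
    n_frames = int(round(duration_s * frame_rate))
    t = np.arange(n_frames) / frame_rate
    rng = np.random.default_rng(seed)

    g = np.zeros(n_frames)
    for b in truth:
        g += _breath_pulse(t, b)

    # baseline: piecewise-linear through per-breath EELI levels
    if truth:
        onsets = np.array([b.onset_s for b in truth])
        eelis = np.array([b.eeli for b in truth])
        baseline = np.interp(t, onsets, eelis)
    else:
        baseline = np.zeros(n_frames)

    baseline = baseline + artefacts.drift_slope * t
    if artefacts.cardiac_amplitude > 0:
        baseline = baseline + artefacts.cardiac_amplitude * np.sin(
            2.0 * np.pi * artefacts.cardiac_rate_hz * t)

    spike_breaths: list[int] = []
    if artefacts.spike_prob > 0:
        draws = rng.random(len(truth))
        for i, b in enumerate(truth):
            if draws[i] < artefacts.spike_prob:
                spike_breaths.append(i)
                baseline = baseline + artefacts.spike_magnitude * np.exp(
                    -0.5 * ((t - b.peak_s) / 0.15) ** 2)

    union = masks.union
    baseline_unit = np.where(union, 1.0 / union.sum(), 0.0)
    frames = (np.multiply.outer(baseline, baseline_unit)
              + np.multiply.outer(g, weight_map)).astype(np.float32)
    if meta is None:
        meta = SequenceMeta(animal="A1", session=1, phase="Stand_pre",
                            duration_s=n_frames / frame_rate)
    seq = FrameSequence(frames=frames, frame_rate=frame_rate,
                        orientation=CANONICAL_ORIENTATION, meta=meta)
    return seq, spike_breaths


# ---------------------------------------------------------------------------
# Study layout
# ---------------------------------------------------------------------------

def draw_phase_table(config: StudyConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw true phase-level physiology for every animal x session x phase.

    Each variable is phase mean + a stable animal effect + session-level
    noise; the animal effect carries ``between_animal_var_frac`` of the
    tabulated variance and is shared across phases and sessions, so the
    drawn table has the random-intercept structure the mixed model assumes.
    With ``emulate_missingness`` the dropped recordings are absent rows.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    f = config.between_animal_var_frac
    n_a, n_s = config.n_animals, config.n_sessions
    animals = [f"A{i}" for i in range(1, n_a + 1)]
    z_animal = rng.standard_normal((n_a, len(_PHASE_VARIABLES)))
    z_noise = rng.standard_normal((n_a, n_s, len(config.phases),
                                   len(_PHASE_VARIABLES)))
    rows = []
    for ai, animal in enumerate(animals):
        for si in range(n_s):
            session = si + 1
            for pi, phase in enumerate(config.phases):
                pp = config.phase_params[phase]
                row = {"animal": animal, "session": session, "phase": phase}
                for vi, var in enumerate(_PHASE_VARIABLES):
                    mean = getattr(pp, var)
                    sd = getattr(pp, f"{var}_sd")
                    value = mean + sd * (np.sqrt(f) * z_animal[ai, vi]
                                         + np.sqrt(1.0 - f) * z_noise[ai, si, pi, vi])
                    lo, hi = _CLIPS[var]
                    row[var] = float(np.clip(value, lo, hi))
                row["roi_l"] = 100.0 - row["roi_r"]
                rows.append(row)
    df = pd.DataFrame(rows)
    if config.emulate_missingness:
        keys = set(MISSING_ROWS)
        df = df[~df.apply(
            lambda r: (r["animal"], r["session"], r["phase"]) in keys, axis=1)]
        df = df.reset_index(drop=True)
    return df


def _synthesize_breaths(rng: np.random.Generator, tidal_rate: float, ti: float,
                        tiv: float, eeli: float, duration_s: float,
                        tiv_cv: float, duration_cv: float,
                        start_s: float = 0.8) -> list[BreathGroundTruth]:
    """Contiguous breath train filling the recording window.

    Expiration runs to the next onset (no end-expiratory pause), so the
    summed lung signal is a clean alternation of troughs and peaks.
    """
    base = 60.0 / tidal_rate
    breaths = []
    onset = start_s
    while True:
        d = base * float(np.clip(1.0 + duration_cv * rng.standard_normal(),
                                 0.5, 1.8))
        t_i = ti * float(np.clip(1.0 + 0.05 * rng.standard_normal(), 0.7, 1.3))
        t_i = min(t_i, 0.8 * d)
        amp = tiv * float(np.clip(1.0 + tiv_cv * rng.standard_normal(),
                                  0.1, 3.0))
        if onset + d > duration_s - 0.3:
            break
        breaths.append(BreathGroundTruth(onset_s=onset, ti_s=t_i, te_s=d - t_i,
                                         amplitude=amp, eeli=eeli))
        onset += d
    return breaths


def generate_study(config: StudyConfig, seed: int | None = None
                   ) -> Iterator[StudyRecord]:
    """Lazily generate the full study: one frame sequence per animal x
    session x phase with its injected ground truth attached.

    A full default study is several hundred MB of frames, so records are
    yielded one at a time; materialise with ``list(...)`` when small enough.
    Per-sequence seeds are derived from the study seed and the sequence
    identity, so any subset regenerates identically.
    """
    if seed is None:
        seed = config.seed
    masks = make_lung_masks(config.grid_shape)
    table = draw_phase_table(config, seed)
    phase_index = {ph: i for i, ph in enumerate(config.phases)}
    for _, row in table.iterrows():
        animal_idx = int(row["animal"][1:]) - 1
        child = np.random.SeedSequence(
            entropy=seed,
            spawn_key=(animal_idx, int(row["session"]), phase_index[row["phase"]]))
        rng = np.random.default_rng(child)
        weight_map = weight_map_for_targets(
            masks, row["cov_rl"], row["cov_vd"], row["roi_r"], clip=True)
        cov_rl, cov_vd, roi_r = weight_map_centroids(weight_map, masks)
        duration = config.duration_for(row["phase"])
        breaths = _synthesize_breaths(
            rng, row["tidal_rate"], row["ti"], row["tiv"], row["eeli"],
            duration, config.breath_tiv_cv, config.breath_duration_cv)
        meta = SequenceMeta(animal=row["animal"], session=int(row["session"]),
                            phase=row["phase"], duration_s=duration)
        seq, spikes = generate_sequence(
            breaths, config.artefacts, masks, config.frame_rate,
            seed=child.spawn(1)[0], meta=meta, weight_map=weight_map,
            duration_s=duration)
        truth = SequenceTruth(breaths=breaths, weight_map=weight_map,
                              cov_rl=cov_rl, cov_vd=cov_vd, roi_r=roi_r,
                              spike_breaths=spikes,
                              phase_values=row.to_dict())
        yield StudyRecord(sequence=seq, truth=truth, masks=masks)


def ground_truth_frame(truth: SequenceTruth) -> pd.DataFrame:
    """One row per injected breath, for the ground-truth CSV."""
    return pd.DataFrame([
        {"breath": i, "onset_s": b.onset_s, "ti_s": b.ti_s, "te_s": b.te_s,
         "amplitude": b.amplitude, "eeli": b.eeli,
         "spiked": i in truth.spike_breaths}
        for i, b in enumerate(truth.breaths)])
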