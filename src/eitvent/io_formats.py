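"""Portable containers and file formats for reconstructed EIT frame data.

The package works on *reconstructed* impedance images: a time series of
pixel grids (time x rows x cols, arbitrary units) produced by an EIT
device's reconstruction step, plus lung-region masks and study metadata.
Vendor-native raw formats are out of scope; sequences travel in a
self-describing HDF5 container (datasets/attributes listed below) and tiny
test fixtures may use a plain delimited-text format.

Canonical image orientation
---------------------------
Row 0 is the animal's ventral edge, the last row is dorsal; column 0 is the
animal's RIGHT side (radiological convention, viewed from the front). Every
file must declare its orientation explicitly; readers flip the pixel axes
to the canonical convention on load, so all in-memory arrays share it.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PHASES",
    "STANDING_PHASES",
    "CANONICAL_ORIENTATION",
    "FormatError",
    "SequenceMeta",
    "FrameSequence",
    "LungMasks",
    "PhaseParams",
    "ArtefactSpec",
    "SegmentationParams",
    "StudyConfig",
    "read_frame_sequence",
    "write_frame_sequence",
    "read_lung_masks",
    "write_lung_masks",
    "write_metric_table",
    "read_metric_table",
    "load_study_config",
    "dump_study_config",
]

#: The seven study phases, in protocol order: awake standing baseline,
#: sedated sternal recumbency, mechanical ventilation with head high/low,
#: spontaneous breathing with and without endotracheal tube, and standing
#: after recovery.
PHASES: tuple[str, ...] = (
    "Stand_pre",
    "Sternal_sed",
    "Sternal_CMVhigh",
    "Sternal_CMVlow",
    "Sternal_spontETT",
    "Sternal_spont",
    "Stand_post",
)

STANDING_PHASES = frozenset({"Stand_pre", "Stand_post"})

CANONICAL_ORIENTATION = "row0=ventral,col0=right"

#: Orientation strings accepted in files, mapped to the axis flips needed
#: to bring the frames to the canonical convention.
_ORIENTATIONS: dict[str, tuple[bool, bool]] = {
    "row0=ventral,col0=right": (False, False),
    "row0=ventral,col0=left": (False, True),
    "row0=dorsal,col0=right": (True, False),
    "row0=dorsal,col0=left": (True, True),
}


class FormatError(ValueError):
    """Malformed or inconsistent container content. Readers reject, never repair."""


@dataclass(frozen=True)
class SequenceMeta:
    animal: str
    session: int
    phase: str
    duration_s: float

    def __post_init__(self) -> None:
        if self.session not in (1, 2):
            raise FormatError(f"session must be 1 or 2, got {self.session!r}")
        if self.phase not in PHASES:
            raise FormatError(f"unknown phase {self.phase!r}; expected one of {PHASES}")


@dataclass
class FrameSequence:
    """A reconstructed impedance image time series (the raw signal Z).

    ``frames`` has shape (n_frames, n_rows, n_cols) in arbitrary units,
    already in the canonical orientation.
    """

    frames: np.ndarray
    frame_rate: float
    orientation: str
    meta: SequenceMeta

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError(
                f"frames must be 3-D (time, rows, cols); got shape {self.frames.shape}"
            )
        if not self.frame_rate > 0:
            raise FormatError("frame_rate must be > 0")
        if self.orientation not in _ORIENTATIONS:
            raise FormatError(
                f"unknown orientation {self.orientation!r}; "
                f"expected one of {sorted(_ORIENTATIONS)}"
            )
        bad = ~np.isfinite(self.frames)
        if bad.any():
            idx = int(np.flatnonzero(bad.any(axis=(1, 2)))[0])
            raise FormatError(f"non-finite frame values (first at frame index {idx})")
        # duration must agree with frame count to within one frame period
        expected = self.n_frames / self.frame_rate
        if abs(self.meta.duration_s - expected) > 1.0 / self.frame_rate:
            raise FormatError(
                f"declared duration {self.meta.duration_s} s inconsistent with "
                f"{self.n_frames} frames at {self.frame_rate} Hz"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class LungMasks:
    """Right/left lung pixel sets plus the anatomical midline column.

    Under the canonical orientation the right lung occupies columns strictly
    below ``midline_col`` and the left lung columns at or above it (the
    vertical midline runs between columns ``midline_col - 1`` and
    ``midline_col``).
    """

    right_mask: np.ndarray
    left_mask: np.ndarray
    midline_col: int

    def __post_init__(self) -> None:
        self.right_mask = np.asarray(self.right_mask, dtype=bool)
        self.left_mask = np.asarray(self.left_mask, dtype=bool)
        if self.right_mask.shape != self.left_mask.shape:
            raise FormatError("right and left masks must share a grid shape")
        if not self.right_mask.any() or not self.left_mask.any():
            raise FormatError("lung masks must be non-empty")
        if (self.right_mask & self.left_mask).any():
            raise FormatError("lung masks must be disjoint")
        r_cols = np.flatnonzero(self.right_mask.any(axis=0))
        l_cols = np.flatnonzero(self.left_mask.any(axis=0))
        if r_cols.max() >= self.midline_col:
            raise FormatError("right mask crosses the midline")
        if l_cols.min() < self.midline_col:
            raise FormatError("left mask crosses the midline")

    @property
    def union(self) -> np.ndarray:
        return self.right_mask | self.left_mask

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.right_mask.shape


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseParams:
    """Target phase-level physiology for the synthetic generator.

    Means and SDs are on the scale of the per-phase summary metrics: CoV in
    percent, ROI-R in percent, TIV/EELI in arbitrary units, tidal rate in
    breaths/min, inspiratory time in seconds. ``miv`` is the phase-level
    minute impedance variation used by the statistical simulations; in frame
    synthesis MIV emerges as tidal rate x TIV rather than being injected.
    """

    cov_rl: float
    cov_rl_sd: float
    cov_vd: float
    cov_vd_sd: float
    roi_r: float
    roi_r_sd: float
    tiv: float
    tiv_sd: float
    miv: float
    miv_sd: float
    eeli: float
    eeli_sd: float
    tidal_rate: float
    tidal_rate_sd: float
    ti: float
    ti_sd: float


#: Per-phase means and SDs of the eight summary metrics in healthy adult
#: alpacas across the peri-anaesthetic protocol (ROI-L is 100 - ROI-R).
#: These are the generator's default study conditions.
DEFAULT_PHASE_PARAMS: dict[str, PhaseParams] = {
    "Stand_pre": PhaseParams(50.7, 2.6, 46.9, 3.2, 47.9, 7.5, 1.0, 0.3, 33.7, 16.7, 27.2, 3.4, 34.2, 12.0, 0.7, 0.2),
    "Sternal_sed": PhaseParams(49.9, 2.1, 45.5, 2.4, 50.1, 6.2, 0.8, 0.2, 14.8, 7.6, 26.0, 3.1, 16.5, 4.9, 1.5, 0.4),
    "Sternal_CMVhigh": PhaseParams(48.3, 3.1, 46.2, 1.9, 54.7, 9.5, 0.8, 0.3, 10.6, 3.1, 28.0, 2.8, 13.0, 3.8, 2.1, 0.5),
    "Sternal_CMVlow": PhaseParams(48.3, 2.5, 47.5, 2.1, 54.7, 7.7, 0.9, 0.2, 11.7, 4.5, 28.2, 2.9, 12.0, 3.3, 2.3, 0.9),
    "Sternal_spontETT": PhaseParams(48.3, 3.2, 46.2, 1.7, 54.7, 10.0, 0.8, 0.2, 13.2, 5.0, 26.7, 2.6, 15.2, 2.7, 2.0, 0.5),
    "Sternal_spont": PhaseParams(49.9, 3.2, 45.4, 2.8, 49.6, 9.9, 1.2, 0.5, 17.5, 9.5, 26.2, 2.8, 14.0, 2.7, 2.2, 0.4),
    "Stand_post": PhaseParams(48.7, 3.2, 49.2, 3.3, 53.7, 9.5, 1.2, 0.6, 15.4, 5.3, 26.6, 3.4, 14.0, 4.8, 1.8, 0.6),
}


@dataclass(frozen=True)
class ArtefactSpec:
    """Additive disturbances layered on the clean ventilation signal."""

    drift_slope: float = 0.0          # AU/s, slow baseline trend
    cardiac_amplitude: float = 0.0    # AU, cardiac-frequency oscillation
    cardiac_rate_hz: float = 1.3      # ~80 beats/min
    spike_prob: float = 0.0           # per-breath motion-spike probability
    spike_magnitude: float = 2.0      # AU, added at the affected breath's peak

    def __post_init__(self) -> None:
        for name in ("drift_slope", "cardiac_amplitude", "cardiac_rate_hz",
                     "spike_prob", "spike_magnitude"):
            if getattr(self, name) < 0:
                raise FormatError(f"ArtefactSpec.{name} must be non-negative")
        if self.spike_prob > 1:
            raise FormatError("spike_prob must be <= 1")

    @classmethod
    def none(cls) -> "ArtefactSpec":
        return cls()

    @classmethod
    def mild(cls) -> "ArtefactSpec":
        """Realistic low-level disturbances: slow drift, cardiac cross-talk,
        occasional motion spikes."""
        return cls(drift_slope=0.002, cardiac_amplitude=0.05,
                   cardiac_rate_hz=1.3, spike_prob=0.03, spike_magnitude=2.0)


@dataclass(frozen=True)
class SegmentationParams:
    """Breath detection and artefact-flagging thresholds."""

    #: moving-average window before extrema search. A window near one
    #: cardiac period nulls the cardiac-frequency oscillation (a 0.75 s
    #: average attenuates >= 1.2 Hz by ~90%) while breath peaks, relocated
    #: exactly on the raw signal afterwards, survive it.
    smooth_window_s: float = 0.75
    min_prominence_frac: float = 0.1  # of the median breath amplitude
    min_breath_s: float = 0.5
    max_breath_s: float = 30.0
    amplitude_k_mad: float = 4.0      # flag (a): |TIV - rolling median| > k*MAD
    amplitude_floor_frac: float = 0.25  # floor on the flag-(a) threshold, x median TIV
    baseline_d_frac: float = 0.5      # flag (b): trough shift > d * median TIV
    rolling_window: int = 7           # breaths, for rolling median/MAD


@dataclass
class StudyConfig:
    """Layout and generator parameters for one synthetic study."""

    n_animals: int = 6
    n_sessions: int = 2
    phases: tuple[str, ...] = PHASES
    phase_params: dict[str, PhaseParams] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_PARAMS))
    grid_shape: tuple[int, int] = (32, 32)
    frame_rate: float = 20.0
    standing_duration_s: float = 300.0
    recumbent_duration_s: float = 120.0
    #: fraction of each Table-level variance attributed to stable
    #: between-animal differences (the LMM's random intercept); the rest is
    #: session-to-session (residual) variation.
    between_animal_var_frac: float = 0.5
    #: breath-to-breath coefficient of variation within a recording
    breath_tiv_cv: float = 0.05
    breath_duration_cv: float = 0.05
    artefacts: ArtefactSpec = field(default_factory=ArtefactSpec.mild)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    emulate_missingness: bool = False
    min_run: int = 6
    max_run: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(self.phases) != PHASES:
            raise FormatError(f"phases must be exactly {PHASES} in protocol order")
        if not (0.0 <= self.between_animal_var_frac <= 1.0):
            raise FormatError("between_animal_var_frac must be in [0, 1]")
        if not (1 <= self.min_run <= self.max_run):
            raise FormatError("need 1 <= min_run <= max_run")
        missing = set(self.phases) - set(self.phase_params)
        if missing:
            raise FormatError(f"phase_params missing phases: {sorted(missing)}")

    def duration_for(self, phase: str) -> float:
        return (self.standing_duration_s if phase in STANDING_PHASES
                else self.recumbent_duration_s)


# ---------------------------------------------------------------------------
# Frame-sequence I/O
# ---------------------------------------------------------------------------

def write_frame_sequence(seq: FrameSequence, path: str | Path) -> Path:
    """Write a sequence to the HDF5 container (dataset /frames + attributes)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("frames", data=seq.frames)
        d.attrs["units"] = "AU"
        f.attrs["frame_rate"] = float(seq.frame_rate)
        f.attrs["orientation"] = seq.orientation
        f.attrs["animal"] = seq.meta.animal
        f.attrs["session"] = int(seq.meta.session)
        f.attrs["phase"] = seq.meta.phase
        f.attrs["duration_s"] = float(seq.meta.duration_s)
    return path


def _require_attr(attrs, name: str):
    if name not in attrs:
        raise FormatError(f"missing required attribute {name!r}")
    return attrs[name]


def read_frame_sequence(path: str | Path) -> FrameSequence:
    """Read and validate a frame sequence.

    HDF5 containers are recognised by content; anything else is parsed as
    the delimited-text fixture format (``# key: value`` header lines, then
    one whitespace-delimited row block per frame, frames separated by blank
    lines). Frames are flipped to the canonical orientation on load.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if h5py.is_hdf5(path):
        with h5py.File(path, "r") as f:
            if "frames" not in f:
                raise FormatError("container has no /frames dataset")
            frames = f["frames"][...]
            frame_rate = float(_require_attr(f.attrs, "frame_rate"))
            orientation = str(_require_attr(f.attrs, "orientation"))
            meta = SequenceMeta(
                animal=str(_require_attr(f.attrs, "animal")),
                session=int(_require_attr(f.attrs, "session")),
                phase=str(_require_attr(f.attrs, "phase")),
                duration_s=float(_require_attr(f.attrs, "duration_s")),
            )
    else:
        frames, frame_rate, orientation, meta = _read_text_fixture(path)
    if not frame_rate > 0:
        raise FormatError("frame_rate must be > 0")
    if orientation not in _ORIENTATIONS:
        raise FormatError(
            f"unknown orientation {orientation!r}; expected one of {sorted(_ORIENTATIONS)}")
    flip_rows, flip_cols = _ORIENTATIONS[orientation]
    frames = np.asarray(frames, dtype=float)
    if flip_rows:
        frames = frames[:, ::-1, :]
    if flip_cols:
        frames = frames[:, :, ::-1]
    return FrameSequence(frames=frames, frame_rate=frame_rate,
                         orientation=CANONICAL_ORIENTATION, meta=meta)


def _read_text_fixture(path: Path):
    header: dict[str, str] = {}
    frame_blocks: list[list[str]] = [[]]
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if line.startswith("#"):
            key, _, value = line.lstrip("#").partition(":")
            header[key.strip()] = value.strip()
        elif not line:
            if frame_blocks[-1]:
                frame_blocks.append([])
        else:
            frame_blocks[-1].append(line)
    if not frame_blocks[-1]:
        frame_blocks.pop()
    if not frame_blocks:
        raise FormatError("text fixture contains no frame data")
    for req in ("frame_rate", "orientation", "animal", "session", "phase"):
        if req not in header:
            raise FormatError(f"missing required attribute {req!r}")
    try:
        frames = np.array(
            [[[float(v) for v in row.split()] for row in block]
             for block in frame_blocks], dtype=float)
    except ValueError as exc:  # ragged rows
        raise FormatError(f"inconsistent frame grid in text fixture: {exc}") from None
    if frames.ndim != 3:
        raise FormatError("inconsistent frame grid in text fixture")
    frame_rate = float(header["frame_rate"])
    duration = float(header.get("duration_s", frames.shape[0] / frame_rate
                                if frame_rate > 0 else 0.0))
    meta = SequenceMeta(animal=header["animal"], session=int(header["session"]),
                        phase=header["phase"], duration_s=duration)
    return frames, frame_rate, header["orientation"], meta


def write_lung_masks(masks: LungMasks, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("right", data=masks.right_mask)
        f.create_dataset("left", data=masks.left_mask)
        f.attrs["midline_col"] = int(masks.midline_col)
        f.attrs["orientation"] = CANONICAL_ORIENTATION
    return path


def read_lung_masks(path: str | Path) -> LungMasks:
    with h5py.File(path, "r") as f:
        return LungMasks(right_mask=f["right"][...], left_mask=f["left"][...],
                         midline_col=int(_require_attr(f.attrs, "midline_col")))


# ---------------------------------------------------------------------------
# Metric tables
# ---------------------------------------------------------------------------

#: Stable column order of the phase-observation table.
METRIC_COLUMNS = [
    "animal", "session", "phase", "n_breaths",
    "cov_rl", "cov_vd", "roi_r", "roi_l",
    "tiv", "miv", "eeli", "tidal_rate", "ti",
]

KEY_COLUMNS = ["animal", "session", "phase"]


def metric_frame(rows: Iterable) -> pd.DataFrame:
    """Assemble phase observations into a DataFrame with stable column order."""
    records = []
    for row in rows:
        records.append(dataclasses.asdict(row) if dataclasses.is_dataclass(row)
                       else dict(row))
    df = pd.DataFrame.from_records(records)
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metric rows lack columns: {missing}")
    df = df[METRIC_COLUMNS]
    dup = df.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        key = df.loc[dup.idxmax(), KEY_COLUMNS].tolist()
        raise FormatError(f"duplicate (animal, session, phase) key: {key}")
    return df


def write_metric_table(rows: Sequence, path: str | Path) -> Path:
    """One CSV row per animal x session x phase; duplicate keys are an error."""
    if len(rows) == 0:
        raise FormatError("metric table must contain at least one row")
    df = metric_frame(rows)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_metric_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metric table lacks columns: {missing}")
    if df.duplicated(subset=KEY_COLUMNS).any():
        raise FormatError("metric table has duplicate (animal, session, phase) keys")
    return df


# ---------------------------------------------------------------------------
# Study configuration file
# ---------------------------------------------------------------------------

def dump_study_config(config: StudyConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_config_to_dict(config), sort_keys=True))
    return path


def load_study_config(path: str | Path) -> StudyConfig:
    data = yaml.safe_load(Path(path).read_text())
    return _config_from_dict(data)


def _config_to_dict(config: StudyConfig) -> dict:
    d = dataclasses.asdict(config)
    d["phases"] = list(config.phases)
    d["grid_shape"] = list(config.grid_shape)
    return d


def _config_from_dict(data: dict) -> StudyConfig:
    data = dict(data)
    if "phase_params" in data:
        data["phase_params"] = {
            ph: PhaseParams(**pp) for ph, pp in data["phase_params"].items()}
    if "artefacts" in data:
        data["artefacts"] = ArtefactSpec(**data["artefacts"])
    if "segmentation" in data:
        data["segmentation"] = SegmentationParams(**data["segmentation"])
    if "phases" in data:
        data["phases"] = tuple(data["phases"])
    if "grid_shape" in data:
        data["grid_shape"] = tuple(data["grid_shape"])
    return StudyConfig(**data)


def config_hash(config: StudyConfig) -> str:
    """Stable hash of the full configuration, for run manifests."""
    import hashlib

    payload = json.dumps(_config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()
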