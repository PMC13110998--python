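import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eitvent.io_formats import ArtefactSpec, SequenceMeta
from eitvent.synthetic import BreathGroundTruth, generate_sequence, make_lung_masks

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("det")


@pytest.fixture(scope="session")
def masks():
    return make_lung_masks((32, 32))


def brute_force_breaths(x: np.ndarray) -> list[tuple[int, int, int]]:
    """Independent segmentation oracle: walk the discrete series for
    plateau-aware local extrema, then read trough-peak-trough triplets.

    Tie-breaks on flat runs follow the documented convention: a flat peak
    contributes its first index, a flat trough its first index as
    end-expiration and its last index as the next onset.
    """
    x = np.asarray(x, dtype=float)
    runs = []
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[j + 1] == x[i]:
            j += 1
        runs.append((i, j, x[i]))
        i = j + 1
    events = []
    for k in range(1, len(runs) - 1):
        s, e, v = runs[k]
        if runs[k - 1][2] < v > runs[k + 1][2]:
            events.append((s, e, "peak"))
        elif runs[k - 1][2] > v < runs[k + 1][2]:
            events.append((s, e, "trough"))
    out = []
    for a, b, c in zip(events, events[1:], events[2:]):
        if a[2] == "trough" and b[2] == "peak" and c[2] == "trough":
            out.append((a[1], b[0], c[0]))
    return out


def random_breath_train(rng: np.random.Generator, duration_s: float = 60.0,
                        rate_range=(10.0, 35.0)) -> list[BreathGroundTruth]:
    """Clean randomized breath train: varying durations, TI fractions and
    amplitudes, contiguous breaths, constant baseline."""
    rate = rng.uniform(*rate_range)
    base = 60.0 / rate
    breaths = []
    onset = float(rng.uniform(0.6, 1.2))
    while True:
        d = base * rng.uniform(0.8, 1.25)
        ti = d * rng.uniform(0.25, 0.55)
        if onset + d > duration_s - 0.5:
            break
        breaths.append(BreathGroundTruth(
            onset_s=onset, ti_s=ti, te_s=d - ti,
            amplitude=float(rng.uniform(0.5, 1.5)), eeli=27.0))
        onset += d
    return breaths


def render(breaths, masks, frame_rate=20.0, artefacts=None, seed=0,
           duration_s=None, weight_map=None, phase="Sternal_sed"):
    meta_duration = duration_s
    if meta_duration is None:
        meta_duration = (breaths[-1].end_s + 1.0) if breaths else 10.0
    meta = SequenceMeta(animal="A1", session=1, phase=phase,
                        duration_s=round(meta_duration * frame_rate) / frame_rate)
    return generate_sequence(breaths, artefacts or ArtefactSpec.none(), masks,
                             frame_rate, seed, meta=meta,
                             weight_map=weight_map, duration_s=duration_s)
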