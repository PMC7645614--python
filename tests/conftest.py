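import numpy as np
import pytest

from ictalhfo.classify import BHF_BAND
from ictalhfo.detect import (
    detect_mua,
    detect_discharges_mea,
    firing_rate,
    normalize_minmax,
    recruitment_time,
)
from ictalhfo.spectral import band_envelope
from ictalhfo.synthgen import SimConfig, simulate_recording

DETECT_FS = 1000.0


@pytest.fixture(scope="session")
def seizure():
    """One default synthetic seizure with ground truth."""
    return simulate_recording(SimConfig(seed=42))


@pytest.fixture(scope="session")
def detection(seizure):
    """Detection products on the default seizure: multiunit trains,
    recruitment-time estimate, and the matched MEA discharge table with
    normalized BHF (95-200 Hz) peaks."""
    rec, gt = seizure
    fs = rec.fs_micro
    duration = rec.micro.shape[1] / fs
    trains = [detect_mua(ch, fs) for ch in rec.micro]
    rt = recruitment_time(trains, duration_s=duration)
    n_det = int(duration * DETECT_FS)
    step = int(fs // DETECT_FS)
    rates = np.stack(
        [firing_rate(t, 0.010, DETECT_FS, duration_s=duration)[1] for t in trains]
    )
    hg = np.stack(
        [
            normalize_minmax(band_envelope(ch, fs, (50.0, 200.0))[::step][:n_det])
            for ch in rec.micro
        ]
    )
    mea = detect_discharges_mea(rates[:, :n_det], hg, DETECT_FS)
    bhf95 = np.mean(
        [
            normalize_minmax(band_envelope(ch, fs, BHF_BAND)[::step][:n_det])
            for ch in rec.micro
        ],
        axis=0,
    )
    mea["bhf95_peak"] = [
        bhf95[max(0, int((t - 0.025) * DETECT_FS)) : int((t + 0.025) * DETECT_FS)].max()
        for t in mea["time_s"]
    ]
    return {"trains": trains, "recruitment_time": rt, "mea": mea, "duration": duration}
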