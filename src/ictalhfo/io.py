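"""HDF5 recording container.

Layout (units: volts, seconds, Hz):

    /micro/traces        (n_channels, n_samples) float64, attrs: fs
    /macro/traces        (n_channels, n_samples) float64, attrs: fs
    /ground_truth/...    optional: recruitment times, discharge table,
                         per-channel spike trains with coupling-mode
                         labels, macro domain labels, dominant-frequency
                         truth series

Round trips are lossless (bitwise-equal arrays).  Macro signals at
higher rates are resampled to 500 S/s on ingest (4th-order zero-phase
Butterworth low-pass, then decimation) to mirror clinical practice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import h5py
from scipy.signal import butter, sosfiltfilt, resample_poly

from .synthgen import GroundTruth, SyntheticRecording

__all__ = ["write_recording", "read_recording", "resample_macro"]

MACRO_FS = 500.0


def resample_macro(signal: np.ndarray, fs_in: float, fs_out: float = MACRO_FS) -> np.ndarray:
    """Anti-alias (4th-order zero-phase Butterworth at 0.48 fs_out) and
    resample a macro trace to the clinical 500 S/s rate."""
    x = np.asarray(signal, dtype=float)
    if fs_in == fs_out:
        return x
    if fs_in < fs_out:
        raise ValueError("upsampling macro data is not supported")
    sos = butter(4, 0.48 * fs_out, btype="lowpass", fs=fs_in, output="sos")
    y = sosfiltfilt(sos, x, axis=-1)
    ratio = fs_in / fs_out
    if abs(ratio - round(ratio)) < 1e-9:
        return y[..., :: int(round(ratio))]
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return resample_poly(y, frac.numerator, frac.denominator, axis=-1)


def write_recording(path, rec: SyntheticRecording, gt: GroundTruth | None = None) -> None:
    with h5py.File(path, "w") as h5:
        for grp_name, traces, fs, ids in (
            ("micro", rec.micro, rec.fs_micro, rec.micro_channel_ids),
            ("macro", rec.macro, rec.fs_macro, rec.macro_channel_ids),
        ):
            g = h5.create_group(grp_name)
            g.create_dataset("traces", data=np.asarray(traces))
            g.attrs["fs"] = float(fs)
            g.attrs["units"] = "volts"
            g.create_dataset("channel_ids", data=np.asarray(ids, dtype=int))
        if gt is not None:
            g = h5.create_group("ground_truth")
            g.create_dataset("recruitment_time_s", data=gt.recruitment_time_s)
            g.create_dataset("discharge_times_s", data=gt.discharge_times_s)
            g.create_dataset("discharge_table_time_s", data=gt.discharges["time_s"].to_numpy())
            g.create_dataset(
                "discharge_table_channel", data=gt.discharges["channel"].to_numpy(dtype=int)
            )
            g.create_dataset(
                "discharge_table_epoch",
                data=np.array(gt.discharges["epoch"], dtype="S8"),
            )
            g.create_dataset(
                "macro_channel_domain", data=np.array(gt.macro_channel_domain, dtype="S16")
            )
            g.create_dataset("dominant_freq_truth_hz", data=gt.dominant_freq_truth_hz)
            g.create_dataset("dominant_freq_times_s", data=gt.dominant_freq_times_s)
            sp = g.create_group("spikes")
            for ch, ev in gt.spike_times_s.items():
                sp.create_dataset(f"times_{ch}", data=ev)
                sp.create_dataset(f"labels_{ch}", data=np.array(gt.spike_labels[ch], dtype="S16"))


def read_recording(path) -> tuple[SyntheticRecording, GroundTruth | None]:
    with h5py.File(path, "r") as h5:
        for grp in ("micro", "macro"):
            if grp not in h5:
                raise ValueError(f"malformed container: missing group /{grp}")
        for grp in ("micro", "macro"):
            if "traces" not in h5[grp]:
                raise ValueError(f"malformed container: missing dataset /{grp}/traces")
            if "fs" not in h5[grp].attrs:
                raise ValueError(f"malformed container: missing attribute /{grp}@fs")
        fs_macro = float(h5["macro"].attrs["fs"])
        macro = h5["macro/traces"][()]
        if fs_macro > MACRO_FS:
            macro = resample_macro(macro, fs_macro, MACRO_FS)
            fs_macro = MACRO_FS
        rec = SyntheticRecording(
            micro=h5["micro/traces"][()],
            fs_micro=float(h5["micro"].attrs["fs"]),
            macro=macro,
            fs_macro=fs_macro,
            micro_channel_ids=list(h5["micro/channel_ids"][()]),
            macro_channel_ids=list(h5["macro/channel_ids"][()]),
        )
        gt = None
        if "ground_truth" in h5:
            g = h5["ground_truth"]
            spikes: dict[int, np.ndarray] = {}
            labels: dict[int, np.ndarray] = {}
            for name in g["spikes"]:
                if name.startswith("times_"):
                    ch = int(name.removeprefix("times_"))
                    spikes[ch] = g[f"spikes/{name}"][()]
                    labels[ch] = g[f"spikes/labels_{ch}"][()].astype("U16")
            gt = GroundTruth(
                recruitment_time_s=g["recruitment_time_s"][()],
                discharges=pd.DataFrame(
                    {
                        "time_s": g["discharge_table_time_s"][()],
                        "channel": g["discharge_table_channel"][()],
                        "epoch": g["discharge_table_epoch"][()].astype("U8"),
                    }
                ),
                discharge_times_s=g["discharge_times_s"][()],
                spike_times_s=spikes,
                spike_labels=labels,
                macro_channel_domain=list(g["macro_channel_domain"][()].astype("U16")),
                dominant_freq_truth_hz=g["dominant_freq_truth_hz"][()],
                dominant_freq_times_s=g["dominant_freq_times_s"][()],
            )
    return rec, gt
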