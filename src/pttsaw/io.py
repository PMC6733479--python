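"""Readers and writers for recordings, beat tables, PTT series and TF maps.

Recordings travel as a single long-format CSV (columns: channel,
sample_index, value) whose comment header carries the per-channel sampling
rate and start time; ground truth, beat tables and uniform PTT series are
plain CSVs; TF matrices are HDF5 with explicit time/frequency grids.  Every
writer has a matching reader and round-trips bit-identically (floats are
serialized at full precision).
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import GroundTruth, PTTSeries, TFRepresentation, Waveform

__all__ = [
    "write_recording",
    "read_recording",
    "write_ground_truth",
    "read_ground_truth",
    "write_beat_table",
    "write_ptt_uniform",
    "read_ptt_uniform",
    "write_tf",
    "read_tf",
    "write_spectrum",
    "load_config",
    "save_heatmap",
]

_HEADER_RE = re.compile(
    r"#\s*channel=(?P<label>\S+)\s+fs=(?P<fs>\S+)\s+t0=(?P<t0>\S+)"
)

CONFIG_SCHEMA_VERSION = 1


def write_recording(path: str | Path, channels: list[Waveform]) -> Path:
    """Write channels to the project CSV recording format."""
    path = Path(path)
    with open(path, "w") as fh:
        for ch in channels:
            fh.write(
                f"# channel={ch.label} fs={float(ch.fs)!r} t0={float(ch.t0)!r}\n"
            )
        fh.write("channel,sample_index,value\n")
        for ch in channels:
            for i, v in enumerate(ch.samples):
                fh.write(f"{ch.label},{i},{float(v)!r}\n")
    return path


def read_recording(path: str | Path, require: tuple[str, ...] = ("ECG", "PPG")) -> dict[str, Waveform]:
    """Read a project CSV recording; returns a dict of channel label -> Waveform.

    Channels beyond ``require`` are ignored with a warning; a missing required
    channel or a channel without an fs header is an error.
    """
    path = Path(path)
    meta: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = _HEADER_RE.match(line)
            if m:
                fs = float(m.group("fs"))
                if fs <= 0:
                    raise ValueError(f"non-positive fs in header for {m.group('label')}")
                meta[m.group("label")] = (fs, float(m.group("t0")))
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if not {"channel", "sample_index", "value"} <= set(df.columns):
        raise ValueError(f"{path} is not a recording CSV")
    out: dict[str, Waveform] = {}
    for label, grp in df.groupby("channel", sort=False):
        if label not in meta:
            raise ValueError(f"channel {label!r} has no fs header line")
        if label not in require:
            warnings.warn(f"ignoring extra channel {label!r}", stacklevel=2)
            continue
        grp = grp.sort_values("sample_index")
        if not np.array_equal(grp["sample_index"].to_numpy(), np.arange(len(grp))):
            raise ValueError(f"channel {label!r} has gaps in sample_index")
        fs, t0 = meta[label]
        out[label] = Waveform(grp["value"].to_numpy(), fs, label=str(label), t0=t0)
    for label in require:
        if label not in out:
            raise ValueError(f"required channel {label!r} missing from {path}")
    return out


def write_ground_truth(directory: str | Path, truth: GroundTruth) -> None:
    directory = Path(directory)
    pd.DataFrame(
        {"beat_time_s": truth.beat_times, "true_ptt_s": truth.true_ptt}
    ).to_csv(directory / "ground_truth.csv", index=False, float_format="%.17g")
    pd.DataFrame({"correction_time_s": truth.correction_times}).to_csv(
        directory / "corrections.csv", index=False, float_format="%.17g"
    )


def read_ground_truth(directory: str | Path) -> GroundTruth:
    directory = Path(directory)
    gt = pd.read_csv(directory / "ground_truth.csv", float_precision="round_trip")
    corr_path = directory / "corrections.csv"
    corr = (
        pd.read_csv(corr_path, float_precision="round_trip")["correction_time_s"].to_numpy()
        if corr_path.exists()
        else np.empty(0)
    )
    return GroundTruth(gt["beat_time_s"].to_numpy(), gt["true_ptt_s"].to_numpy(), corr)


def write_beat_table(path: str | Path, r_times, arrival_times, ptt) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"r_time_s": r_times, "arrival_time_s": arrival_times, "ptt_s": ptt}
    ).to_csv(path, index=False, float_format="%.17g")
    return path


def write_ptt_uniform(path: str | Path, series: PTTSeries) -> Path:
    path = Path(path)
    pd.DataFrame({"t_s": series.t_uniform, "ptt_s": series.ptt_uniform}).to_csv(
        path, index=False, float_format="%.17g"
    )
    return path


def read_ptt_uniform(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    return df["t_s"].to_numpy(), df["ptt_s"].to_numpy()


def write_tf(path: str | Path, tf: TFRepresentation) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=tf.times)
        fh.create_dataset("freqs", data=tf.freqs)
        fh.create_dataset("values", data=tf.values)
        params = fh.create_group("params")
        for k, v in tf.meta.items():
            params.attrs[k] = v
    return path


def read_tf(path: str | Path) -> TFRepresentation:
    with h5py.File(path, "r") as fh:
        meta = dict(fh["params"].attrs) if "params" in fh else {}
        return TFRepresentation(
            fh["times"][...], fh["freqs"][...], fh["values"][...], meta
        )


def write_spectrum(path: str | Path, freqs, power) -> Path:
    path = Path(path)
    pd.DataFrame({"freq_hz": freqs, "power": power}).to_csv(
        path, index=False, float_format="%.17g"
    )
    return path


def write_report(path: str | Path, report: dict) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def load_config(path: str | Path) -> dict:
    """Load a YAML pipeline configuration and check its schema version."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    version = cfg.pop("schema_version", CONFIG_SCHEMA_VERSION)
    if version != CONFIG_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported config schema_version {version}; "
            f"expected {CONFIG_SCHEMA_VERSION}"
        )
    return cfg


def save_heatmap(path: str | Path, tf: TFRepresentation, title: str = "") -> Path:
    """Render a TF map to PNG (time on x, frequency on y)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.pcolormesh(tf.times, tf.freqs, tf.values.T, shading="auto", cmap="magma")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
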