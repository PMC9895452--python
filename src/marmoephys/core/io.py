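"""On-disk formats and session-bundle round-tripping.

Raw traces are flat binary (little-endian int16 by default, channel-major)
with a JSON sidecar carrying rate, channel count, dtype, µV-per-count scale
and the channel map. Trials are CSV with a fixed header; eye traces are CSV
(t, x, y, blink); spike clusters live in one HDF5 file with one group per
unit. A ``manifest.json`` records which artifacts a bundle contains.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import (
    TRIAL_COLUMNS,
    ChannelInfo,
    EyeTrace,
    FormatError,
    RecordingBlock,
    SessionBundle,
    SpikeCluster,
    TrialTable,
)

__all__ = [
    "save_recording",
    "load_recording",
    "save_trials",
    "load_trials",
    "save_eye",
    "load_eye",
    "save_clusters",
    "load_clusters",
    "save_bundle",
    "load_bundle",
]

_SIDECAR_REQUIRED = ("rate", "n_channels", "dtype", "scale_uV", "channel_map")


def save_recording(block: RecordingBlock, path: Path, name: str = "raw",
                   dtype: str = "int16", scale_uV: float | None = None) -> None:
    """Write ``<name>.bin`` + ``<name>.json`` sidecar under ``path``.

    With the default int16 dtype, voltages are quantized to ``scale_uV``
    per count (auto-scaled to the data range when ``scale_uV`` is None);
    ``dtype="float64"`` stores losslessly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    data = block.samples
    if dtype == "int16":
        if scale_uV is None:
            peak = float(np.max(np.abs(data))) if data.size else 0.0
            scale_uV = peak / 32000.0 if peak > 0 else 1.0
        raw = np.round(data / scale_uV).astype("<i2")
    elif dtype == "float64":
        scale_uV = 1.0
        raw = data.astype("<f8")
    else:
        raise FormatError(f"unsupported dtype {dtype!r}")
    raw.tofile(path / f"{name}.bin")  # channel-major: C order of (ch, time)
    sidecar = {
        "rate": block.rate,
        "n_channels": block.n_channels,
        "n_samples": block.n_samples,
        "dtype": dtype,
        "scale_uV": scale_uV,
        "order": "channel_major",
        "t0": block.t0,
        "channel_map": [
            {"shank": c.shank, "index": c.index, "depth_um": c.depth_um}
            for c in block.channel_map
        ],
    }
    (path / f"{name}.json").write_text(json.dumps(sidecar, indent=1))


def load_recording(path: Path, name: str = "raw") -> RecordingBlock:
    path = Path(path)
    sidecar_path = path / f"{name}.json"
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in _SIDECAR_REQUIRED:
        if key not in meta:
            raise FormatError(f"sidecar missing required key {key!r}")
    np_dtype = {"int16": "<i2", "float64": "<f8"}.get(meta["dtype"])
    if np_dtype is None:
        raise FormatError(f"unsupported dtype {meta['dtype']!r} in sidecar")
    raw = np.fromfile(path / f"{name}.bin", dtype=np_dtype)
    n_ch = int(meta["n_channels"])
    if "n_samples" in meta and raw.size != n_ch * int(meta["n_samples"]):
        raise FormatError(
            f"{name}.bin holds {raw.size} values; sidecar implies "
            f"{n_ch} x {meta['n_samples']}"
        )
    if n_ch > 0 and raw.size % n_ch:
        raise FormatError(f"{name}.bin size not divisible by n_channels={n_ch}")
    samples = raw.reshape(n_ch, -1).astype(np.float64) * float(meta["scale_uV"])
    cmap = [
        ChannelInfo(int(c["shank"]), int(c["index"]), float(c["depth_um"]))
        for c in meta["channel_map"]
    ]
    return RecordingBlock(samples, float(meta["rate"]), cmap, float(meta.get("t0", 0.0)))


def save_trials(table: TrialTable, path: Path) -> None:
    table.df.to_csv(path, index=False, columns=list(TRIAL_COLUMNS))


def load_trials(path: Path) -> TrialTable:
    df = pd.read_csv(path, dtype={"outcome": str, "condition": str})
    return TrialTable(df)


def save_eye(eye: EyeTrace, path: Path) -> None:
    df = pd.DataFrame(
        {"t": eye.t, "x": eye.x, "y": eye.y, "blink": eye.blink.astype(int)}
    )
    with open(path, "w") as fh:
        fh.write(f"# rate={eye.rate}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def load_eye(path: Path) -> EyeTrace:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# rate="):
            raise FormatError("eye CSV missing '# rate=' header line")
        rate = float(header.strip().split("=", 1)[1])
        df = pd.read_csv(fh)
    return EyeTrace(
        t=df["t"].to_numpy(),
        x=df["x"].to_numpy(),
        y=df["y"].to_numpy(),
        rate=rate,
        blink=df["blink"].to_numpy().astype(bool),
    )


def save_clusters(clusters: list[SpikeCluster], path: Path) -> None:
    with h5py.File(path, "w") as f:
        for cl in clusters:
            g = f.create_group(f"unit_{cl.unit_id:04d}")
            g.attrs["unit_id"] = cl.unit_id
            g.create_dataset("spike_times", data=cl.spike_times)
            if cl.snippets is not None:
                g.create_dataset("snippets", data=cl.snippets)
            if cl.mean_waveform is not None:
                g.create_dataset("mean_waveform", data=cl.mean_waveform)
                g.attrs["peak_channel"] = cl.peak_channel


def load_clusters(path: Path) -> list[SpikeCluster]:
    out: list[SpikeCluster] = []
    with h5py.File(path, "r") as f:
        for key in sorted(f):
            g = f[key]
            out.append(
                SpikeCluster(
                    unit_id=int(g.attrs["unit_id"]),
                    spike_times=g["spike_times"][()],
                    snippets=g["snippets"][()] if "snippets" in g else None,
                    mean_waveform=(
                        g["mean_waveform"][()] if "mean_waveform" in g else None
                    ),
                    peak_channel=(
                        int(g.attrs["peak_channel"])
                        if "peak_channel" in g.attrs
                        else None
                    ),
                )
            )
    return out


def save_bundle(bundle: SessionBundle, path: Path,
                recording_dtype: str = "float64") -> None:
    """Persist a session bundle to ``path`` (created if needed).

    The default float64 trace encoding keeps the round trip lossless; pass
    ``recording_dtype="int16"`` for the compact quantized form.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    if bundle.recording is not None:
        save_recording(bundle.recording, path, "raw", dtype=recording_dtype)
        manifest["recording"] = "raw"
    if bundle.trials is not None:
        save_trials(bundle.trials, path / "trials.csv")
        manifest["trials"] = "trials.csv"
    if bundle.eye is not None:
        save_eye(bundle.eye, path / "eye.csv")
        manifest["eye"] = "eye.csv"
    if bundle.clusters:
        save_clusters(bundle.clusters, path / "spikes.h5")
        manifest["clusters"] = "spikes.h5"
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_bundle(path: Path) -> SessionBundle:
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"missing manifest.json in {path}")
    manifest = json.loads(manifest_path.read_text())
    bundle = SessionBundle()
    if "recording" in manifest:
        bundle.recording = load_recording(path, manifest["recording"])
    if "trials" in manifest:
        bundle.trials = load_trials(path / manifest["trials"])
    if "eye" in manifest:
        bundle.eye = load_eye(path / manifest["eye"])
    if "clusters" in manifest:
        bundle.clusters = load_clusters(path / manifest["clusters"])
    return bundle
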