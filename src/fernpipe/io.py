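"""File interchange: EDF, HDF5 lossless containers, TSV event tables, YAML configs.

EDF export is a minimal 16-bit EDF writer (one data record per second,
per-channel physical scaling in microvolts); reading external EDF goes through
``mne.io.read_raw_edf``. HDF5 (via h5py) is the bit-exact container for
continuous data, epoch sets, leadfields and source estimates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ContinuousEEG, EpochSet, Montage

__all__ = [
    "write_events_tsv",
    "read_events_tsv",
    "write_edf",
    "read_edf",
    "save_continuous_h5",
    "load_continuous_h5",
    "save_epochs_h5",
    "load_epochs_h5",
    "save_config_yaml",
    "load_config_yaml",
]


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# EDF


def _pad(text: str, n: int) -> bytes:
    b = text.encode("ascii", "replace")[:n]
    return b + b" " * (n - len(b))


def write_edf(raw: ContinuousEEG, path: str | Path, patient_id: str = "X") -> None:
    """Write a 16-bit EDF file (physical units microvolts, 1-s data records).

    The final partial record is zero-padded; the companion event TSV and JSON
    metadata remain authoritative for the exact sample count.
    """
    fs = raw.fs
    spr = int(round(fs))  # samples per 1-s record
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_ch = raw.n_channels
    n_rec = int(np.ceil(raw.n_samples / spr))
    data = np.zeros((n_ch, n_rec * spr))
    data[:, : raw.n_samples] = raw.data

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (2 * phys_max)
    digital = np.clip(
        np.round((data + phys_max[:, None]) * scale[:, None]) + dig_min,
        dig_min,
        dig_max,
    ).astype("<i2")

    header_len = 256 + 256 * n_ch
    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad(patient_id, 80))
        f.write(_pad("fernpipe synthetic recording", 80))
        f.write(_pad("01.01.00", 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(header_len), 8))
        f.write(_pad("", 44))
        f.write(_pad(str(n_rec), 8))
        f.write(_pad("1", 8))  # record duration, seconds
        f.write(_pad(str(n_ch), 4))
        for name in raw.montage.names:
            f.write(_pad(name, 16))
        for _ in range(n_ch):
            f.write(_pad("AgAgCl electrode", 80))
        for _ in range(n_ch):
            f.write(_pad("uV", 8))
        for pm in phys_max:
            f.write(_pad(f"{-pm:.6g}"[:8], 8))
        for pm in phys_max:
            f.write(_pad(f"{pm:.6g}"[:8], 8))
        f.write(_pad(str(dig_min), 8) * n_ch)
        f.write(_pad(str(dig_max), 8) * n_ch)
        for _ in range(n_ch):
            f.write(_pad("", 80))  # prefiltering
        f.write(_pad(str(spr), 8) * n_ch)
        for _ in range(n_ch):
            f.write(_pad("", 32))  # reserved
        # data records: per record, channel-major blocks
        for r in range(n_rec):
            f.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(path: str | Path, montage: Montage, events: pd.DataFrame | None = None) -> ContinuousEEG:
    """Read an EDF recording into a ContinuousEEG (channels matched by name)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    picks = [raw.ch_names.index(n) for n in montage.names]
    data = raw.get_data()[picks] * 1e6  # volts -> microvolts
    if events is None:
        events = pd.DataFrame({"sample": [], "condition": []})
    return ContinuousEEG(data=data, fs=float(raw.info["sfreq"]), montage=montage, events=events)


# ---------------------------------------------------------------------------
# HDF5 containers


def _montage_to_group(g, montage: Montage) -> None:
    g.create_dataset("channel_names", data=np.array(montage.names, dtype="S"))
    g.create_dataset("positions", data=montage.positions)
    g.attrs["mastoids"] = ",".join(montage.mastoids)


def _montage_from_group(g) -> Montage:
    names = tuple(n.decode() for n in g["channel_names"][()])
    mast = tuple(g.attrs["mastoids"].split(","))
    return Montage(names=names, positions=g["positions"][()], mastoids=mast)  # type: ignore[arg-type]


def save_continuous_h5(raw: ContinuousEEG, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=raw.data, compression="gzip")
        f.attrs["fs"] = raw.fs
        _montage_to_group(f.create_group("montage"), raw.montage)
        f.attrs["events_json"] = raw.events.to_json(orient="split")


def load_continuous_h5(path: str | Path) -> ContinuousEEG:
    import h5py
    from io import StringIO

    with h5py.File(path, "r") as f:
        events = pd.read_json(StringIO(f.attrs["events_json"]), orient="split")
        return ContinuousEEG(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            montage=_montage_from_group(f["montage"]),
            events=events,
        )


def save_epochs_h5(epochs: EpochSet, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("labels", data=np.array(epochs.labels.tolist(), dtype="S"))
        f.create_dataset("rejected", data=epochs.rejected)
        f.create_dataset(
            "rejection_reason", data=np.array(epochs.rejection_reason.tolist(), dtype="S")
        )
        f.attrs["fs"] = epochs.fs
        f.attrs["baseline_applied"] = epochs.baseline_applied
        _montage_to_group(f.create_group("montage"), epochs.montage)


def load_epochs_h5(path: str | Path) -> EpochSet:
    import h5py

    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            labels=np.array([s.decode() for s in f["labels"][()]], dtype=object),
            montage=_montage_from_group(f["montage"]),
            fs=float(f.attrs["fs"]),
            baseline_applied=bool(f.attrs["baseline_applied"]),
            rejected=f["rejected"][()],
            rejection_reason=np.array(
                [s.decode() for s in f["rejection_reason"][()]], dtype=object
            ),
        )


def write_permtest_tsv(result, path: str | Path) -> None:
    """Pointwise test curves (t, p, corrected p, masks) as a TSV table."""
    pd.DataFrame(
        {
            "time_ms": result.times,
            "t": result.t_obs,
            "p": result.p,
            "p_corrected": result.p_corrected,
            "significant": result.mask.astype(int),
            "significant_corrected": result.mask_corrected.astype(int),
            "mean_difference": result.diff,
        }
    ).to_csv(path, sep="\t", index=False)


def save_leadfield_h5(lead, path: str | Path) -> None:
    """Leadfield + geometry sidecar (montage, source space, ROIs) in one file."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=lead.gain, compression="gzip")
        f.attrs["reference"] = lead.reference
        _montage_to_group(f.create_group("montage"), lead.montage)
        g = f.create_group("space")
        g.create_dataset("positions", data=lead.space.positions)
        g.create_dataset("orientations", data=lead.space.orientations)
        g.attrs["rois_json"] = json.dumps(
            {k: np.asarray(v).tolist() for k, v in lead.space.rois.items()}
        )


def load_leadfield_h5(path: str | Path):
    import h5py

    from .headmodel import Leadfield, SourceSpace

    with h5py.File(path, "r") as f:
        rois = {
            k: np.asarray(v, dtype=int)
            for k, v in json.loads(f["space"].attrs["rois_json"]).items()
        }
        space = SourceSpace(
            positions=f["space/positions"][()],
            orientations=f["space/orientations"][()],
            rois=rois,
        )
        return Leadfield(
            gain=f["gain"][()],
            montage=_montage_from_group(f["montage"]),
            space=space,
            reference=f.attrs["reference"],
        )


def write_source_map_tsv(values: np.ndarray, space, path: str | Path) -> None:
    """Per-source scalar map (e.g. a condition-difference map) as TSV."""
    df = pd.DataFrame(
        {
            "x_m": space.positions[:, 0],
            "y_m": space.positions[:, 1],
            "z_m": space.positions[:, 2],
            "value": np.asarray(values, float),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_roi_json(space, path: str | Path) -> None:
    save_json({k: np.asarray(v).tolist() for k, v in space.rois.items()}, path)


def save_config_yaml(obj: dict, path: str | Path) -> None:
    import yaml

    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=False)


def load_config_yaml(path: str | Path) -> dict:
    """Load a YAML (or, by extension, TOML) configuration mapping."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        with open(path, "rb") as f:
            return tomllib.load(f)
    import yaml

    with open(path) as f:
        return yaml.safe_load(f)


def save_json(obj, path: str | Path) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
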