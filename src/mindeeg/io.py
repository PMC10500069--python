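"""Reading and writing recordings and trial sets (HDF5 and EDF).

HDF5 is the package's native container and round-trips bit-exactly,
including the montage and annotations.  EDF export uses the standard
16-bit integer encoding (physical unit µV), so values are reproduced to
within one quantisation step of the physical range; EDF files are read
back through :mod:`mne`.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .containers import Recording, State, TrialSet
from .montage import MontageSpec

__all__ = [
    "write_recording",
    "read_recording",
    "write_trialset",
    "read_trialset",
]

_STR = h5py.string_dtype(encoding="utf-8")


def _write_montage(group: h5py.Group, montage: MontageSpec) -> None:
    group.create_dataset("channel_labels", data=np.array(montage.channel_labels, dtype=_STR))
    group.create_dataset("positions", data=montage.positions)
    group.create_dataset("bad_channels", data=np.array(montage.bad_channels, dtype=_STR))
    rois = group.create_group("rois")
    for name, labels in montage.rois.items():
        rois.create_dataset(name, data=np.array(labels, dtype=_STR))


def _read_montage(group: h5py.Group) -> MontageSpec:
    labels = [s.decode() if isinstance(s, bytes) else s for s in group["channel_labels"][()]]
    bad = [s.decode() if isinstance(s, bytes) else s for s in group["bad_channels"][()]]
    rois = {
        name: [s.decode() if isinstance(s, bytes) else s for s in ds[()]]
        for name, ds in group["rois"].items()
    }
    return MontageSpec(labels, group["positions"][()], rois, bad)


def write_recording(rec: Recording, path) -> None:
    """Write a Recording as HDF5 (``.h5``/``.hdf5``) or EDF (``.edf``)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=rec.data)
            f.create_dataset("rate", data=float(rec.rate))
            f.attrs["subject_id"] = rec.subject_id
            f.attrs["state"] = rec.state.value
            f.attrs["stage"] = rec.stage
            _write_montage(f.create_group("montage"), rec.montage)
    elif suffix == ".edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unsupported recording format {suffix!r} (use .h5 or .edf)")


def read_recording(path, montage: MontageSpec | None = None) -> Recording:
    """Read a Recording from HDF5 or EDF.

    For EDF, the channel labels come from the file; pass ``montage`` to
    reattach ROI definitions (its labels must match).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        try:
            with h5py.File(path, "r") as f:
                data = f["data"][()]
                rate = float(f["rate"][()])
                rec_montage = _read_montage(f["montage"])
                return Recording(data, rate, rec_montage,
                                 subject_id=str(f.attrs["subject_id"]),
                                 state=State(f.attrs["state"]))
        except (OSError, KeyError) as err:
            raise OSError(f"malformed HDF5 recording {path}: {err}") from err
    if suffix == ".edf":
        return _read_edf(path, montage)
    raise ValueError(f"unsupported recording format {suffix!r} (use .h5 or .edf)")


def write_trialset(ts: TrialSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("trials", data=ts.trials)
        f.create_dataset("rate", data=float(ts.rate))
        f.create_dataset("states", data=np.array([str(s) for s in ts.states], dtype=_STR))
        f.create_dataset("stages", data=ts.stages)
        f.create_dataset("subjects", data=np.array([str(s) for s in ts.subjects], dtype=_STR))
        if ts.montage is not None:
            _write_montage(f.create_group("montage"), ts.montage)


def read_trialset(path) -> TrialSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with h5py.File(path, "r") as f:
            montage = _read_montage(f["montage"]) if "montage" in f else None
            return TrialSet(
                f["trials"][()],
                np.array([s.decode() if isinstance(s, bytes) else s
                          for s in f["states"][()]], dtype=object),
                np.array([s.decode() if isinstance(s, bytes) else s
                          for s in f["subjects"][()]], dtype=object),
                float(f["rate"][()]),
                montage,
                f["stages"][()],
            )
    except (OSError, KeyError) as err:
        raise OSError(f"malformed HDF5 trial set {path}: {err}") from err


# ---------------------------------------------------------------------------
# EDF (16-bit, one 1-second data record per block)

def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF writer: µV physical unit, symmetric physical range,
    1-second data records.  The trailing partial record (if any) is dropped,
    so lengths are truncated to a whole number of seconds."""
    spr = int(round(rec.rate))  # samples per record (1-s records)
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one 1-second EDF data record")
    data = np.asarray(rec.data[:, :n_records * spr], dtype=np.float64)
    n_sig = rec.n_channels
    phys_max = max(1e-3, float(np.abs(data).max()))
    phys_max = float(f"{phys_max * 1.001:.6g}")  # headroom, 8-char printable
    dig_max = 32767
    scaled = np.clip(np.round(data / phys_max * dig_max), -dig_max, dig_max)
    digital = scaled.astype("<i2")

    header_bytes = 256 + 256 * n_sig
    annotation = f"subject={rec.subject_id} state={rec.state.value} stage={rec.stage}"
    with open(path, "wb") as f:
        f.write(_ascii("0", 8))
        f.write(_ascii("X X X X", 80))  # local patient identification
        f.write(_ascii(annotation, 80))  # local recording identification
        f.write(_ascii("01.01.00", 8))
        f.write(_ascii("00.00.00", 8))
        f.write(_ascii(header_bytes, 8))
        f.write(_ascii("", 44))
        f.write(_ascii(n_records, 8))
        f.write(_ascii("1", 8))  # record duration, seconds
        f.write(_ascii(n_sig, 4))
        labels = rec.montage.channel_labels
        for lab in labels:
            f.write(_ascii(lab, 16))
        for _ in labels:
            f.write(_ascii("", 80))  # transducer
        for _ in labels:
            f.write(_ascii("uV", 8))
        for _ in labels:
            f.write(_ascii(f"{-phys_max:.6g}", 8))
        for _ in labels:
            f.write(_ascii(f"{phys_max:.6g}", 8))
        for _ in labels:
            f.write(_ascii(-dig_max, 8))
        for _ in labels:
            f.write(_ascii(dig_max, 8))
        for _ in labels:
            f.write(_ascii("", 80))  # prefiltering
        for _ in labels:
            f.write(_ascii(spr, 8))
        for _ in labels:
            f.write(_ascii("", 32))
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            f.write(block.tobytes())


def _parse_recording_field(path: Path) -> dict:
    with open(path, "rb") as f:
        header = f.read(256)
    if len(header) < 256:
        raise OSError(f"truncated EDF file {path}")
    field = header[88:168].decode("ascii", errors="replace").strip()
    out = {}
    for token in field.split():
        if "=" in token:
            key, _, value = token.partition("=")
            out[key] = value
    return out


def _read_edf(path: Path, montage: MontageSpec | None) -> Recording:
    import mne

    meta = _parse_recording_field(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as err:
        raise OSError(f"malformed EDF file {path}: {err}") from err
    data = raw.get_data() * 1e6  # mne loads EEG in volts
    labels = list(raw.ch_names)
    if montage is None:
        from .montage import _disc_positions

        montage = MontageSpec(labels, _disc_positions(len(labels)))
    elif montage.channel_labels != labels:
        raise ValueError("provided montage does not match the EDF channel labels")
    return Recording(
        data, float(raw.info["sfreq"]), montage,
        subject_id=meta.get("subject", "S00"),
        state=State(meta.get("state", "REST1")),
    )
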