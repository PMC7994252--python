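"""Recording containers and on-disk formats.

Two interchange formats are supported:

* **SNIRF** (HDF5), the community standard for near-infrared spectroscopy
  data.  A documented subset of the layout is written (``/nirs/data1`` with
  one measurement-list entry per channel plane, ``/nirs/stim<k>`` per event
  class) and the reader accepts both processed series (``dataTypeLabel``
  of ``dOD`` / ``HbO`` / ``HbR``) and raw continuous-wave intensity, which
  is converted to optical-density change as ``-log10(I / mean(I))``.
* An **internal NPZ archive** (arrays + a JSON metadata blob), one file per
  subject, used by the rest of the package because it is much faster than
  HDF5 round trips.

Axis conventions, fixed package-wide:

* optical density: ``od[sample, channel, wavelength]`` with wavelengths
  ascending ``(780, 805, 830)`` nm;
* hemoglobin: ``hb[sample, channel, chromophore]`` with chromophore order
  ``(HbO, HbR)`` (indices :data:`HBO`, :data:`HBR`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "HBO",
    "HBR",
    "CHROMOPHORES",
    "WAVELENGTHS_NM",
    "CLASSES",
    "OpticalDensityRecording",
    "HemodynamicRecording",
    "DatasetManifest",
    "read_snirf",
    "write_snirf",
    "save_recording",
    "load_recording",
    "save_dataset",
    "load_dataset",
    "FormatError",
]

#: chromophore axis indices, constant package-wide
HBO, HBR = 0, 1
CHROMOPHORES = ("HbO", "HbR")
#: measurement wavelengths in nm, ascending, matching the conversion matrix columns
WAVELENGTHS_NM = (780.0, 805.0, 830.0)
#: class labels: idle state and mental arithmetic
CLASSES = ("IS", "MA")


class FormatError(ValueError):
    """Raised for malformed or unsupported on-disk layouts."""


def _check_events(events, n_samples):
    prev = -1
    for onset, label in events:
        if not (0 <= int(onset) < n_samples):
            raise ValueError(f"event onset {onset} outside [0, {n_samples})")
        if int(onset) < prev:
            raise ValueError("events must be sorted by onset sample")
        if label not in CLASSES:
            raise ValueError(f"unknown event label {label!r}; expected one of {CLASSES}")
        prev = int(onset)


@dataclass
class OpticalDensityRecording:
    """Continuous optical-density change at three wavelengths.

    ``od`` has shape ``(n_samples, n_channels, 3)`` and is dimensionless;
    ``events`` is a sorted list of ``(onset_sample, label)`` with labels in
    ``("IS", "MA")``.
    """

    subject_id: str
    sampling_rate_hz: float
    od: np.ndarray
    events: list[tuple[int, str]] = field(default_factory=list)
    channel_names: list[str] | None = None
    wavelengths_nm: tuple[float, float, float] = WAVELENGTHS_NM

    def __post_init__(self):
        self.od = np.asarray(self.od, dtype=float)
        if self.od.ndim != 3 or self.od.shape[2] != 3:
            raise ValueError(f"od must be (n_samples, n_channels, 3); got {self.od.shape}")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if tuple(self.wavelengths_nm) != WAVELENGTHS_NM:
            raise ValueError(f"wavelengths must be {WAVELENGTHS_NM} nm, ascending")
        if self.channel_names is None:
            self.channel_names = [f"ch{i + 1}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length does not match od channel axis")
        self.events = [(int(o), str(l)) for o, l in self.events]
        _check_events(self.events, self.n_samples)

    @property
    def n_samples(self) -> int:
        return self.od.shape[0]

    @property
    def n_channels(self) -> int:
        return self.od.shape[1]


@dataclass
class HemodynamicRecording:
    """Continuous hemoglobin-concentration change per channel.

    ``hb`` has shape ``(n_samples, n_channels, 2)`` in mM·cm with chromophore
    order ``(HbO, HbR)``.  ``filter_log`` is append-only: every filtering pass
    is recorded, including repeats, so the log reflects exactly what was
    applied.
    """

    subject_id: str
    sampling_rate_hz: float
    hb: np.ndarray
    events: list[tuple[int, str]] = field(default_factory=list)
    channel_names: list[str] | None = None
    filter_log: list[dict] = field(default_factory=list)

    def __post_init__(self):
        self.hb = np.asarray(self.hb, dtype=float)
        if self.hb.ndim != 3 or self.hb.shape[2] != 2:
            raise ValueError(f"hb must be (n_samples, n_channels, 2); got {self.hb.shape}")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.channel_names is None:
            self.channel_names = [f"ch{i + 1}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length does not match hb channel axis")
        self.events = [(int(o), str(l)) for o, l in self.events]
        _check_events(self.events, self.n_samples)

    @property
    def n_samples(self) -> int:
        return self.hb.shape[0]

    @property
    def n_channels(self) -> int:
        return self.hb.shape[1]


@dataclass
class DatasetManifest:
    """Index of a multi-subject dataset on disk."""

    subjects: list[str]
    trials_per_class: int
    classes: tuple[str, str] = CLASSES
    source: str = "synthetic"  # synthetic | snirf | figshare
    paths: dict[str, str] = field(default_factory=dict)
    unbalanced: bool = False

    def __post_init__(self):
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("duplicate subject ids in manifest")

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "subjects": self.subjects,
            "trials_per_class": self.trials_per_class,
            "classes": list(self.classes),
            "source": self.source,
            "paths": self.paths,
            "unbalanced": self.unbalanced,
        }, indent=1))
        return path

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        d = json.loads(Path(path).read_text())
        d["classes"] = tuple(d["classes"])
        return cls(**d)


# ---------------------------------------------------------------------------
# SNIRF (HDF5)
# ---------------------------------------------------------------------------

def _write_measurement(nirs, idx, source, detector, *, wavelength_index=None,
                       data_type, data_type_label=None):
    ml = nirs.create_group(f"data1/measurementList{idx}")
    ml.create_dataset("sourceIndex", data=np.int32(source))
    ml.create_dataset("detectorIndex", data=np.int32(detector))
    ml.create_dataset("dataType", data=np.int32(data_type))
    if wavelength_index is not None:
        ml.create_dataset("wavelengthIndex", data=np.int32(wavelength_index))
    if data_type_label is not None:
        ml.create_dataset("dataTypeLabel", data=np.bytes_(data_type_label))


def write_snirf(rec: OpticalDensityRecording | HemodynamicRecording, path) -> Path:
    """Write a recording as a SNIRF file; returns the path written.

    Optical-density recordings are stored as processed ``dOD`` measurements
    (one per channel × wavelength), hemodynamic recordings as ``HbO`` /
    ``HbR`` measurements.  Events become one ``stim`` group per class with
    onsets in seconds.
    """
    path = Path(path)
    is_od = isinstance(rec, OpticalDensityRecording)
    data = rec.od if is_od else rec.hb
    n_samples, n_channels, n_planes = data.shape
    fs = rec.sampling_rate_hz

    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=np.bytes_("1.0"))
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=np.bytes_(rec.subject_id))
        meta.create_dataset("MeasurementDate", data=np.bytes_("unknown"))
        meta.create_dataset("MeasurementTime", data=np.bytes_("unknown"))
        meta.create_dataset("LengthUnit", data=np.bytes_("cm"))
        meta.create_dataset("TimeUnit", data=np.bytes_("s"))
        meta.create_dataset("FrequencyUnit", data=np.bytes_("Hz"))
        meta.create_dataset("ChannelNames", data=np.array(
            [np.bytes_(c) for c in rec.channel_names]))
        if not is_od:
            meta.create_dataset("FilterLog", data=np.bytes_(json.dumps(rec.filter_log)))

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(WAVELENGTHS_NM))
        # nominal geometry: one source/detector pair per channel
        pos = np.zeros((n_channels, 3))
        pos[:, 0] = np.arange(n_channels)
        probe.create_dataset("sourcePos3D", data=pos)
        probe.create_dataset("detectorPos3D", data=pos + [0.0, 3.0, 0.0])

        nirs.create_group("data1")
        flat = data.reshape(n_samples, n_channels * n_planes)
        nirs["data1"].create_dataset("dataTimeSeries", data=flat)
        nirs["data1"].create_dataset("time", data=np.arange(n_samples) / fs)
        k = 1
        for ch in range(n_channels):
            for p in range(n_planes):
                if is_od:
                    _write_measurement(nirs, k, ch + 1, ch + 1,
                                       wavelength_index=p + 1,
                                       data_type=99999, data_type_label="dOD")
                else:
                    _write_measurement(nirs, k, ch + 1, ch + 1,
                                       data_type=99999,
                                       data_type_label=CHROMOPHORES[p])
                k += 1

        by_class: dict[str, list[int]] = {}
        for onset, label in rec.events:
            by_class.setdefault(label, []).append(onset)
        for i, label in enumerate(sorted(by_class), start=1):
            stim = nirs.create_group(f"stim{i}")
            stim.create_dataset("name", data=np.bytes_(label))
            onsets = np.asarray(by_class[label], dtype=float) / fs
            stim.create_dataset(
                "data", data=np.column_stack([onsets, np.full_like(onsets, 10.0),
                                              np.ones_like(onsets)]))
    return path


def read_snirf(path) -> OpticalDensityRecording | HemodynamicRecording:
    """Read a SNIRF file written by :func:`write_snirf` or a compatible subset.

    Raw continuous-wave intensity (``dataType`` 1) is converted to
    optical-density change per channel as ``-log10(I / mean(I))``.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "nirs" not in f:
            raise FormatError(f"{path}: missing /nirs group; not a SNIRF file")
        nirs = f["nirs"]
        data1 = nirs["data1"]
        flat = np.asarray(data1["dataTimeSeries"], dtype=float)
        time = np.asarray(data1["time"], dtype=float)
        if time.size == 2:  # SNIRF allows [start, step]
            fs = 1.0 / time[1]
        else:
            steps = np.diff(time)
            if steps.size and np.ptp(steps) > 1e-6 * steps.mean():
                raise FormatError(f"{path}: non-uniform sampling not supported")
            fs = 1.0 / steps.mean()

        keys = sorted((k for k in data1 if k.startswith("measurementList")),
                      key=lambda k: int(k[len("measurementList"):]))
        labels, dtypes, wl_idx = [], [], []
        for k in keys:
            ml = data1[k]
            dtypes.append(int(ml["dataType"][()]))
            lab = ml["dataTypeLabel"][()].decode() if "dataTypeLabel" in ml else None
            labels.append(lab)
            wl_idx.append(int(ml["wavelengthIndex"][()]) if "wavelengthIndex" in ml else 0)

        subject = "unknown"
        channel_names = None
        filter_log = []
        if "metaDataTags" in nirs:
            meta = nirs["metaDataTags"]
            if "SubjectID" in meta:
                subject = meta["SubjectID"][()].decode()
            if "ChannelNames" in meta:
                channel_names = [c.decode() for c in meta["ChannelNames"][()]]
            if "FilterLog" in meta:
                filter_log = json.loads(meta["FilterLog"][()].decode())

        events = []
        for k in sorted(k for k in nirs if k.startswith("stim")):
            stim = nirs[k]
            label = stim["name"][()].decode()
            for row in np.atleast_2d(np.asarray(stim["data"], dtype=float)):
                events.append((int(round(row[0] * fs)), label))
        events.sort(key=lambda e: e[0])

        n_meas = flat.shape[1]
        is_hb = all(l in CHROMOPHORES for l in labels)
        is_raw = all(d == 1 for d in dtypes)
        if is_hb:
            n_channels = n_meas // 2
            hb = flat.reshape(flat.shape[0], n_channels, 2)
            return HemodynamicRecording(subject, fs, hb, events, channel_names,
                                        filter_log)
        n_channels = n_meas // 3
        od = flat.reshape(flat.shape[0], n_channels, 3)
        if is_raw:
            mean = od.mean(axis=0, keepdims=True)
            if np.any(mean <= 0):
                raise FormatError(f"{path}: non-positive mean intensity")
            od = -np.log10(od / mean)
        # order wavelength planes ascending if indices present
        if any(wl_idx):
            order = np.argsort(wl_idx[:3])
            od = od[:, :, order]
        return OpticalDensityRecording(subject, fs, od, events, channel_names)


# ---------------------------------------------------------------------------
# Internal NPZ archive
# ---------------------------------------------------------------------------

def save_recording(rec: HemodynamicRecording | OpticalDensityRecording, path) -> Path:
    """Save a recording as a compressed NPZ archive (the fast internal format)."""
    path = Path(path)
    is_od = isinstance(rec, OpticalDensityRecording)
    meta = {
        "subject_id": rec.subject_id,
        "sampling_rate_hz": rec.sampling_rate_hz,
        "channel_names": rec.channel_names,
        "kind": "od" if is_od else "hb",
        "filter_log": [] if is_od else rec.filter_log,
    }
    events = np.array([(o, l) for o, l in rec.events], dtype=object).reshape(-1, 2)
    np.savez_compressed(path,
                        data=rec.od if is_od else rec.hb,
                        event_onsets=np.array([int(o) for o, _ in rec.events]),
                        event_labels=np.array([l for _, l in rec.events]),
                        meta=np.bytes_(json.dumps(meta)))
    del events
    return path


def load_recording(path) -> HemodynamicRecording | OpticalDensityRecording:
    path = Path(path)
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        data = z["data"]
        events = list(zip((int(o) for o in z["event_onsets"]),
                          (str(l) for l in z["event_labels"])))
    if meta["kind"] == "od":
        return OpticalDensityRecording(meta["subject_id"], meta["sampling_rate_hz"],
                                       data, events, meta["channel_names"])
    return HemodynamicRecording(meta["subject_id"], meta["sampling_rate_hz"],
                                data, events, meta["channel_names"],
                                meta["filter_log"])


def save_dataset(recordings, directory, *, trials_per_class, source="synthetic") -> DatasetManifest:
    """Save one NPZ per subject plus a JSON manifest in ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for rec in recordings:
        p = directory / f"{rec.subject_id}.npz"
        save_recording(rec, p)
        paths[rec.subject_id] = p.name
    manifest = DatasetManifest(subjects=[r.subject_id for r in recordings],
                               trials_per_class=trials_per_class,
                               source=source, paths=paths)
    manifest.save(directory / "manifest.json")
    return manifest


def load_dataset(manifest: DatasetManifest | str | Path,
                 directory=None) -> list[HemodynamicRecording]:
    """Load every subject listed in a manifest, in manifest order.

    A missing subject file raises ``FileNotFoundError`` naming the subject.
    """
    if not isinstance(manifest, DatasetManifest):
        mpath = Path(manifest)
        directory = directory or mpath.parent
        manifest = DatasetManifest.load(mpath)
    directory = Path(directory) if directory is not None else Path(".")
    out = []
    for sid in manifest.subjects:
        p = directory / manifest.paths.get(sid, f"{sid}.npz")
        if not p.exists():
            raise FileNotFoundError(f"recording for subject {sid!r} not found at {p}")
        out.append(load_recording(p))
    return out


def load_figshare_mat(path) -> dict:
    """Best-effort loader for a MATLAB ``.mat`` export of the public deposit.

    The deposit's internal structure is not standardized; this returns the
    raw variable dictionary for manual adaptation and is intentionally not
    part of the tested surface.
    """
    from scipy.io import loadmat

    return loadmat(str(path), squeeze_me=True, struct_as_record=False)
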