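"""Probe montage, channel atlas, raw recordings and clinical (CRS-R) tables.

The measurement model is a continuous-wave fNIRS cap over the frontal lobe:
16 laser sources and 16 detectors, nominally 3 cm apart, forming 53
source-detector channels sampled at two wavelengths (690 and 830 nm).
Channels are numbered 1..53; three of them (25, 28, 29) straddle the
midsagittal line and belong to neither hemisphere.  The remaining 50
channels partition into ten hemisphere x region groups over five frontal
regions: premotor/supplementary motor area, frontal eye fields, Broca's
area, frontopolar area and dorsolateral prefrontal cortex.

The CRS-R (Coma Recovery Scale-Revised) table carries one row per subject
with six subscale scores (auditory, visual, motor, oromotor, communication,
arousal); the total is always recomputed as the subscale sum, and rows whose
stored total disagrees are flagged rather than silently corrected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ProbeMontage",
    "ChannelAtlas",
    "RawIntensitySeries",
    "SubjectRecord",
    "ROI_NAMES",
    "load_montage",
    "default_montage",
    "load_intensity",
    "write_intensity",
    "parse_crsr_table",
    "write_crsr_table",
    "demographics_summary",
]

ROI_NAMES = ("PreM_SMA", "FEF", "BROCA", "FPA", "DLPFC")
HEMISPHERES = ("left", "right", "midline")
WAVELENGTHS_NM = (690.0, 830.0)
N_CHANNELS = 53

# CRS-R subscale maxima (auditory 0-4, visual 0-5, motor 0-6, oromotor 0-3,
# communication 0-2, arousal 0-3)
CRSR_SUBSCALES = ("auditory", "visual", "motor", "oromotor", "communication", "arousal")
CRSR_MAXIMA = {"auditory": 4, "visual": 5, "motor": 6, "oromotor": 3,
               "communication": 2, "arousal": 3}


class ValidationError(ValueError):
    """An input file violated a structural invariant; the message names the row."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeMontage:
    """Probe geometry: source/detector coordinates (mm) and the channel list."""

    sources: Mapping[str, np.ndarray]
    detectors: Mapping[str, np.ndarray]
    channels: tuple[tuple[str, str, int], ...]  # (source id, detector id, index 1..53)
    reference_points: Mapping[str, np.ndarray]
    source_detector_distance: float = 30.0  # nominal, mm

    def channel_distance(self, index: int) -> float:
        for s, d, i in self.channels:
            if i == index:
                return float(np.linalg.norm(self.sources[s] - self.detectors[d]))
        raise KeyError(index)

    def validate(self, distance_tol_mm: float = 5.0) -> None:
        if len(self.sources) != 16:
            raise ValidationError(f"expected 16 sources, found {len(self.sources)}")
        if len(self.detectors) != 16:
            raise ValidationError(f"expected 16 detectors, found {len(self.detectors)}")
        if len(self.channels) != N_CHANNELS:
            raise ValidationError(
                f"expected {N_CHANNELS} channels, found {len(self.channels)}")
        indices = [i for _, _, i in self.channels]
        if sorted(indices) != list(range(1, N_CHANNELS + 1)):
            dupes = {i for i in indices if indices.count(i) > 1}
            raise ValidationError(
                f"channel indices must be unique and contiguous 1..{N_CHANNELS}; "
                f"duplicates/gaps around {sorted(dupes) or indices[:5]}")
        for s, d, i in self.channels:
            if s not in self.sources:
                raise ValidationError(f"channel {i}: unknown source {s!r}")
            if d not in self.detectors:
                raise ValidationError(f"channel {i}: unknown detector {d!r}")
            dist = float(np.linalg.norm(self.sources[s] - self.detectors[d]))
            if abs(dist - self.source_detector_distance) > distance_tol_mm:
                raise ValidationError(
                    f"channel {i}: source-detector distance {dist:.2f} mm outside "
                    f"{self.source_detector_distance:.0f}±{distance_tol_mm:g} mm")


@dataclass(frozen=True)
class ChannelAtlas:
    """Channel -> (hemisphere, region) lookup for the ten frontal ROIs."""

    mapping: Mapping[int, tuple[str, str]]

    @property
    def midline_channels(self) -> tuple[int, ...]:
        return tuple(sorted(c for c, (h, _) in self.mapping.items() if h == "midline"))

    @property
    def lateral_channels(self) -> tuple[int, ...]:
        """The 50 non-midline channels, in channel-index order."""
        return tuple(sorted(c for c, (h, _) in self.mapping.items() if h != "midline"))

    def roi_groups(self) -> dict[tuple[str, str], tuple[int, ...]]:
        groups: dict[tuple[str, str], list[int]] = {}
        for c, (h, r) in sorted(self.mapping.items()):
            if h == "midline":
                continue
            groups.setdefault((h, r), []).append(c)
        return {k: tuple(v) for k, v in groups.items()}

    def roi_of(self, channel: int) -> tuple[str, str]:
        return self.mapping[channel]

    def validate(self) -> None:
        if set(self.mapping) != set(range(1, N_CHANNELS + 1)):
            missing = set(range(1, N_CHANNELS + 1)) - set(self.mapping)
            extra = set(self.mapping) - set(range(1, N_CHANNELS + 1))
            raise ValidationError(
                f"atlas must cover channels 1..{N_CHANNELS}; "
                f"missing={sorted(missing)} extra={sorted(extra)}")
        for c, (h, r) in self.mapping.items():
            if h not in HEMISPHERES:
                raise ValidationError(f"channel {c}: unknown hemisphere {h!r}")
            if r not in ROI_NAMES:
                raise ValidationError(f"channel {c}: unknown ROI {r!r}")
        if self.midline_channels != (25, 28, 29):
            raise ValidationError(
                f"midline channels must be (25, 28, 29), found {self.midline_channels}")
        groups = self.roi_groups()
        if len(groups) != 10:
            raise ValidationError(
                f"lateral channels must span 10 hemisphere x ROI groups, found "
                f"{len(groups)}: {sorted(groups)}")
        for key, members in groups.items():
            if not members:
                raise ValidationError(f"ROI group {key} is empty")


@dataclass
class RawIntensitySeries:
    """One subject's raw light intensities: channels x wavelengths x samples."""

    subject_id: str
    data: np.ndarray  # (53, 2, T), strictly positive
    sampling_rate: float  # Hz

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != 2:
            raise ValidationError(
                f"{self.subject_id}: intensity array must be (channels, 2, samples), "
                f"got {self.data.shape}")
        if self.sampling_rate <= 0:
            raise ValidationError(f"{self.subject_id}: sampling rate must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError(f"{self.subject_id}: non-finite intensity values")
        if np.any(self.data <= 0):
            ch, wl, t = np.argwhere(self.data <= 0)[0]
            raise ValidationError(
                f"{self.subject_id}: non-positive intensity at channel {ch + 1}, "
                f"wavelength {WAVELENGTHS_NM[wl]:.0f} nm, sample {t}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class SubjectRecord:
    """Clinical record: demographics plus six CRS-R subscales.

    ``crsr_total`` is always the recomputed subscale sum; if the source file
    stored a different total it is kept in ``stored_total`` and
    ``total_mismatch`` is set.
    """

    id: str
    group: str  # "MCS" | "HC"
    mcs_subtype: str  # "MCS-" | "MCS+" | "none"
    gender: str  # "M" | "F"
    age: float
    etiology: str
    duration_months: float
    crsr_subscales: dict[str, int] = field(default_factory=dict)
    stored_total: int | None = None

    @property
    def crsr_total(self) -> int:
        return int(sum(self.crsr_subscales.values()))

    @property
    def total_mismatch(self) -> bool:
        return self.stored_total is not None and self.stored_total != self.crsr_total

    def validate(self) -> None:
        if self.group not in ("MCS", "HC"):
            raise ValidationError(f"{self.id}: unknown group {self.group!r}")
        if self.gender not in ("M", "F"):
            raise ValidationError(f"{self.id}: unknown gender {self.gender!r}")
        for name in CRSR_SUBSCALES:
            if name not in self.crsr_subscales:
                raise ValidationError(f"{self.id}: missing CRS-R subscale {name!r}")
            v = self.crsr_subscales[name]
            if not (0 <= v <= CRSR_MAXIMA[name]):
                raise ValidationError(
                    f"{self.id}: CRS-R {name} score {v} outside 0..{CRSR_MAXIMA[name]}")


# ---------------------------------------------------------------------------
# montage / atlas loading
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("fnirsnet.data") / name))


def default_montage_path() -> Path:
    return _data_path("montage_53ch.json")


def default_atlas_path() -> Path:
    return _data_path("atlas_53ch.tsv")


def default_clinical_path() -> Path:
    return _data_path("mcs_clinical.tsv")


def _read_atlas(atlas_file: str | Path) -> ChannelAtlas:
    df = pd.read_csv(atlas_file, sep="\t")
    required = {"channel", "hemisphere", "roi"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"atlas {atlas_file}: expected columns {sorted(required)}, "
            f"found {list(df.columns)}")
    mapping: dict[int, tuple[str, str]] = {}
    for row in df.itertuples(index=False):
        c = int(row.channel)
        if c in mapping:
            raise ValidationError(f"atlas {atlas_file}: duplicate channel {c}")
        mapping[c] = (str(row.hemisphere), str(row.roi))
    atlas = ChannelAtlas(mapping)
    atlas.validate()
    return atlas


def _read_montage(montage_file: str | Path, distance_tol_mm: float) -> ProbeMontage:
    with open(montage_file) as fh:
        raw = json.load(fh)
    try:
        montage = ProbeMontage(
            sources={k: np.asarray(v, dtype=float) for k, v in raw["sources"].items()},
            detectors={k: np.asarray(v, dtype=float)
                       for k, v in raw["detectors"].items()},
            channels=tuple((ch["source"], ch["detector"], int(ch["index"]))
                           for ch in raw["channels"]),
            reference_points={k: np.asarray(v, dtype=float)
                              for k, v in raw.get("reference_points", {}).items()},
            source_detector_distance=float(raw.get("nominal_distance_mm", 30.0)),
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"montage {montage_file}: malformed entry ({exc})") from exc
    montage.validate(distance_tol_mm=distance_tol_mm)
    return montage


def load_montage(
    montage_file: str | Path | None = None,
    atlas_file: str | Path | None = None,
    distance_tol_mm: float = 5.0,
) -> tuple[ProbeMontage, ChannelAtlas]:
    """Load and validate the probe montage and channel->ROI atlas.

    With no arguments the packaged defaults are used.  Any violated
    structural invariant raises :class:`ValidationError` naming the
    offending row.
    """
    montage = _read_montage(montage_file or default_montage_path(), distance_tol_mm)
    atlas = _read_atlas(atlas_file or default_atlas_path())
    return montage, atlas


def default_montage() -> tuple[ProbeMontage, ChannelAtlas]:
    return load_montage()


# ---------------------------------------------------------------------------
# raw intensity I/O (CSV dialect and minimal SNIRF container)
# ---------------------------------------------------------------------------

def _csv_header(n_channels: int) -> list[str]:
    return [f"ch{c}_{int(wl)}nm" for c in range(1, n_channels + 1)
            for wl in WAVELENGTHS_NM]


def write_intensity_csv(series: RawIntensitySeries, file: str | Path) -> None:
    """CSV dialect: one row per sample, one column per (channel, wavelength)."""
    n_ch, _, n_t = series.data.shape
    flat = series.data.transpose(2, 0, 1).reshape(n_t, n_ch * 2)
    with open(file, "w", newline="") as fh:
        fh.write(f"# subject_id={series.subject_id}\n")
        fh.write(f"# sampling_rate_hz={float(series.sampling_rate)!r}\n")
        fh.write(",".join(_csv_header(n_ch)) + "\n")
        np.savetxt(fh, flat, delimiter=",", fmt="%.17g")


def _load_intensity_csv(file: str | Path) -> RawIntensitySeries:
    subject_id = Path(file).stem
    sampling_rate = None
    with open(file) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            if key.strip() == "subject_id":
                subject_id = value.strip()
            elif key.strip() == "sampling_rate_hz":
                sampling_rate = float(value)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    if sampling_rate is None:
        raise ValidationError(f"{file}: missing '# sampling_rate_hz=' header line")
    n_ch = len(df.columns) // 2
    expected = _csv_header(n_ch)
    if list(df.columns) != expected:
        raise ValidationError(
            f"{file}: column header mismatch (expected ch<i>_690nm/ch<i>_830nm pairs)")
    arr = df.to_numpy(dtype=float).reshape(len(df), n_ch, 2).transpose(1, 2, 0)
    return RawIntensitySeries(subject_id=subject_id, data=arr,
                              sampling_rate=sampling_rate)


def write_intensity_snirf(
    series: RawIntensitySeries,
    file: str | Path,
    montage: ProbeMontage | None = None,
) -> None:
    """Write a minimal SNIRF v1.0 (HDF5) continuous-wave raw-intensity file."""
    if montage is None:
        montage, _ = default_montage()
    n_ch, _, n_t = series.data.shape
    src_order = sorted(montage.sources, key=lambda s: int(s[1:]))
    det_order = sorted(montage.detectors, key=lambda d: int(d[1:]))
    src_index = {s: k + 1 for k, s in enumerate(src_order)}
    det_index = {d: k + 1 for k, d in enumerate(det_order)}
    chan_by_index = {i: (s, d) for s, d, i in montage.channels}
    def ds(group, name, data):
        # track_times=False keeps the file byte-identical across rewrites
        group.create_dataset(name, data=data, track_times=False)

    with h5py.File(file, "w", track_order=True) as f:
        ds(f, "formatVersion", "1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        ds(meta, "SubjectID", series.subject_id)
        ds(meta, "MeasurementDate", "unknown")
        ds(meta, "MeasurementTime", "unknown")
        ds(meta, "LengthUnit", "mm")
        ds(meta, "TimeUnit", "s")
        ds(meta, "FrequencyUnit", "Hz")
        probe = nirs.create_group("probe")
        ds(probe, "wavelengths", np.asarray(WAVELENGTHS_NM))
        ds(probe, "sourcePos3D", np.array([montage.sources[s] for s in src_order]))
        ds(probe, "detectorPos3D",
           np.array([montage.detectors[d] for d in det_order]))
        data1 = nirs.create_group("data1")
        flat = series.data.transpose(2, 0, 1).reshape(n_t, n_ch * 2)
        ds(data1, "dataTimeSeries", flat)
        ds(data1, "time", np.arange(n_t, dtype=float) / series.sampling_rate)
        col = 0
        for c in range(1, n_ch + 1):
            s, d = chan_by_index[c]
            for wl_idx in (1, 2):
                col += 1
                ml = data1.create_group(f"measurementList{col}")
                ds(ml, "sourceIndex", src_index[s])
                ds(ml, "detectorIndex", det_index[d])
                ds(ml, "wavelengthIndex", wl_idx)
                ds(ml, "dataType", 1)  # CW amplitude
                ds(ml, "dataTypeIndex", 1)


def _load_intensity_snirf(file: str | Path) -> RawIntensitySeries:
    with h5py.File(file, "r") as f:
        data1 = f["nirs/data1"]
        flat = np.asarray(data1["dataTimeSeries"], dtype=float)
        time = np.asarray(data1["time"], dtype=float)
        if time.size < 2:
            raise ValidationError(f"{file}: SNIRF time vector too short")
        sampling_rate = 1.0 / float(np.median(np.diff(time)))
        subject_id = Path(file).stem
        tags = f["nirs"].get("metaDataTags")
        if tags is not None and "SubjectID" in tags:
            raw_id = tags["SubjectID"][()]
            subject_id = raw_id.decode() if isinstance(raw_id, bytes) else str(raw_id)
        n_cols = flat.shape[1]
        if n_cols % 2:
            raise ValidationError(f"{file}: odd number of measurement columns")
        n_ch = n_cols // 2
        # columns are channel-major (690 then 830), as written by this package;
        # verify via the wavelengthIndex of each measurementList
        for col in range(n_cols):
            ml = data1[f"measurementList{col + 1}"]
            expected_wl = col % 2 + 1
            if int(ml["wavelengthIndex"][()]) != expected_wl:
                raise ValidationError(
                    f"{file}: measurementList{col + 1} wavelength order not supported")
    arr = flat.reshape(-1, n_ch, 2).transpose(1, 2, 0)
    return RawIntensitySeries(subject_id=subject_id, data=arr,
                              sampling_rate=sampling_rate)


def load_intensity(file: str | Path, dialect: str = "csv") -> RawIntensitySeries:
    """Load a raw recording (``dialect`` = ``"csv"`` or ``"snirf"``)."""
    if dialect == "csv":
        return _load_intensity_csv(file)
    if dialect == "snirf":
        return _load_intensity_snirf(file)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_intensity(
    series: RawIntensitySeries,
    file: str | Path,
    dialect: str = "csv",
    montage: ProbeMontage | None = None,
) -> None:
    if dialect == "csv":
        write_intensity_csv(series, file)
    elif dialect == "snirf":
        write_intensity_snirf(series, file, montage=montage)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

_CLINICAL_COLUMNS = ["id", "group", "mcs_subtype", "gender", "age", "etiology",
                     "duration_months", *CRSR_SUBSCALES, "crsr_total"]


def parse_crsr_table(file: str | Path | None = None) -> list[SubjectRecord]:
    """Parse the clinical TSV; totals are recomputed from the six subscales.

    Rows whose stored total differs from the subscale sum keep both values
    and are flagged (``record.total_mismatch``); the sum takes precedence.
    """
    df = pd.read_csv(file or default_clinical_path(), sep="\t")
    missing = [c for c in _CLINICAL_COLUMNS if c not in df.columns and c != "crsr_total"]
    if missing:
        raise ValidationError(f"clinical table: missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        subscales = {name: int(getattr(row, name)) for name in CRSR_SUBSCALES}
        stored = int(row.crsr_total) if "crsr_total" in df.columns else None
        rec = SubjectRecord(
            id=str(row.id),
            group=str(row.group),
            mcs_subtype=str(getattr(row, "mcs_subtype", "none")),
            gender=str(row.gender),
            age=float(row.age),
            etiology=str(row.etiology),
            duration_months=float(row.duration_months),
            crsr_subscales=subscales,
            stored_total=stored,
        )
        rec.validate()
        records.append(rec)
    return records


def write_crsr_table(records: Sequence[SubjectRecord], file: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "id": r.id, "group": r.group, "mcs_subtype": r.mcs_subtype,
            "gender": r.gender, "age": r.age, "etiology": r.etiology,
            "duration_months": r.duration_months,
            **r.crsr_subscales,
            "crsr_total": r.stored_total if r.stored_total is not None
            else r.crsr_total,
        })
    pd.DataFrame(rows, columns=_CLINICAL_COLUMNS).to_csv(file, sep="\t", index=False)


def demographics_summary(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Per-group means/SDs (sample, n-1) of age, duration, CRS-R and gender counts."""
    if not records:
        raise ValidationError("no records")
    rows = {}
    groups = sorted({r.group for r in records})
    for g in groups:
        sub = [r for r in records if r.group == g]
        if len(sub) < 2:
            raise ValidationError(f"group {g}: need >=2 records for SDs, got {len(sub)}")
        ages = np.array([r.age for r in sub], dtype=float)
        dur = np.array([r.duration_months for r in sub], dtype=float)
        tot = np.array([r.crsr_total for r in sub], dtype=float)
        rows[g] = {
            "n": len(sub),
            "male": sum(r.gender == "M" for r in sub),
            "female": sum(r.gender == "F" for r in sub),
            "age_mean": ages.mean(), "age_sd": ages.std(ddof=1),
            "duration_mean": dur.mean(), "duration_sd": dur.std(ddof=1),
            "crsr_mean": tot.mean(), "crsr_sd": tot.std(ddof=1),
        }
    return pd.DataFrame(rows).T
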