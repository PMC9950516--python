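"""Synthetic two-group resting-state fNIRS cohort with known ground truth.

The generator emulates the acquisition this package analyzes: 53 channels,
two wavelengths (690/830 nm), 20 Hz, 5 minutes per subject.  Each subject's
"neural" HbO signal is band-limited (0.01-0.1 Hz) Gaussian noise with a
block-structured inter-channel correlation matrix: high correlation within
each hemisphere x ROI group, lower between groups.  Patient-group (MCS)
subjects have the blocks of designated ROIs (frontopolar and right DLPFC by
default) attenuated by a per-subject factor, which is also coupled to the
simulated CRS-R auditory subscale — so connectivity strength, network
topology and clinical score share a known ground truth.

On top of the neural signal the forward model adds HbR (anticorrelated with
HbO), sinusoidal physiological components (Mayer ~0.1 Hz, respiration
~0.4 Hz, cardiac ~1.1 Hz) with random phases, slow drift, and sparse
step-and-decay motion artifacts, then maps hemoglobin to optical density
via the modified Beer-Lambert model and to strictly positive intensities
via I = I0 * exp(-OD).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import signal

from .montage import (ChannelAtlas, RawIntensitySeries, SubjectRecord,
                      ValidationError, default_montage, write_crsr_table,
                      write_intensity)
from .preprocess import HemoSeries, MbllCoefficients, hemoglobin_to_od

__all__ = ["SynthConfig", "CohortManifest", "Cohort", "build_truth",
           "simulate_subject", "generate_cohort"]

_ETIOLOGIES = ("Traumatic brain injury", "Intracerebral infarction",
               "Intracerebral hemorrhage")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the simulated cohort (defaults match the design
    the package is validated against: 16 HC vs 15 MCS, 5-min 20 Hz
    recordings, attenuation 0.6 of the left-FPA and right-DLPFC blocks)."""

    n_hc: int = 16
    n_mcs: int = 15
    duration_s: float = 300.0
    sampling_rate: float = 20.0
    n_channels: int = 53
    # ground-truth correlation levels (per group; MCS overrides default to HC's)
    r_within: float = 0.85
    r_between: float = 0.45
    mcs_r_within: float | None = None
    mcs_r_between: float | None = None
    # group effect: blocks of these ROIs are scaled by `attenuation` in MCS
    attenuation: float = 0.6
    attenuated_rois: tuple[tuple[str, str], ...] = (("left", "FPA"),
                                                    ("right", "DLPFC"))
    attenuation_jitter: float = 0.15  # per-subject SD of the MCS attenuation
    subject_scale_sd: float = 0.12  # per-subject global coupling variability
    # signal amplitudes (uM unless noted)
    neural_amp_um: float = 0.8
    mayer_amp_um: float = 0.08
    resp_amp_um: float = 0.25
    cardiac_amp_um: float = 0.6
    mayer_hz: float = 0.1
    resp_hz: float = 0.4
    cardiac_hz: float = 1.1
    hbr_ratio: float = -0.3
    hbr_noise_um: float = 0.08
    drift_amp_od: float = 0.02
    # motion artifacts: step + exponential decay, Poisson-placed
    spike_rate_per_min: float = 0.3  # per channel
    spike_amp_od: float = 0.8
    spike_decay_s: float = 2.0
    baseline_intensity: float = 1000.0
    # CRS-R auditory <-> attenuation coupling (latent correlation)
    crsr_coupling: float = 0.75
    seed: int = 0

    def validate(self) -> None:
        if self.n_hc < 2 or self.n_mcs < 2:
            raise ValidationError("each group needs >= 2 subjects")
        if not (0 <= self.r_between <= self.r_within < 1):
            raise ValidationError("need 0 <= r_between <= r_within < 1")
        if not (0 < self.attenuation <= 1):
            raise ValidationError("attenuation must be in (0, 1]")
        if self.duration_s <= 0 or self.sampling_rate <= 0:
            raise ValidationError("duration and sampling rate must be positive")


@dataclass
class CohortManifest:
    """Everything needed to regenerate the cohort exactly."""

    config: dict
    subjects: list[dict]  # id, group, seed, file, attenuation, crsr subscales

    def to_json(self) -> str:
        return json.dumps({"config": self.config, "subjects": self.subjects},
                          indent=1, sort_keys=True)


@dataclass
class Cohort:
    config: SynthConfig
    raws: list[RawIntensitySeries]
    records: list[SubjectRecord]
    manifest: CohortManifest

    def write(self, outdir: str | Path, dialect: str = "csv") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ext = "csv" if dialect == "csv" else "snirf"
        montage, _ = default_montage()
        for raw, entry in zip(self.raws, self.manifest.subjects):
            path = outdir / f"{raw.subject_id}.{ext}"
            write_intensity(raw, path, dialect=dialect, montage=montage)
            entry["file"] = path.name
        write_crsr_table(self.records, outdir / "clinical.tsv")
        (outdir / "manifest.json").write_text(self.manifest.to_json())


# ---------------------------------------------------------------------------
# ground-truth correlation structure
# ---------------------------------------------------------------------------

def _nearest_psd(r: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Eigenvalue clipping followed by re-normalization to unit diagonal."""
    vals, vecs = np.linalg.eigh((r + r.T) / 2)
    vals = np.clip(vals, 0.0, None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.clip(np.diag(out), 1e-12, None))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    if np.linalg.eigvalsh(out).min() < -tol:
        raise ValidationError("PSD projection did not converge")
    return out


def _block_matrix(atlas: ChannelAtlas, r_within: float, r_between: float,
                  n_channels: int) -> np.ndarray:
    """Block-constant 53x53 correlation target from the atlas grouping
    (the three midline channels form their own block)."""
    group_of = {}
    for c, (h, roi) in atlas.mapping.items():
        group_of[c] = ("midline", "midline") if h == "midline" else (h, roi)
    r = np.full((n_channels, n_channels), r_between)
    for i in range(n_channels):
        for j in range(n_channels):
            if group_of[i + 1] == group_of[j + 1]:
                r[i, j] = r_within
    np.fill_diagonal(r, 1.0)
    return r


def _attenuate(r: np.ndarray, atlas: ChannelAtlas,
               rois: tuple[tuple[str, str], ...], factor: float) -> np.ndarray:
    """Scale every off-diagonal entry involving a channel of the given ROIs."""
    targets = [c - 1 for c, (h, roi) in atlas.mapping.items() if (h, roi) in rois]
    out = r.copy()
    if not targets or factor == 1.0:
        return out
    mask = np.zeros(len(r), dtype=bool)
    mask[targets] = True
    involved = mask[:, None] | mask[None, :]
    np.fill_diagonal(involved, False)
    out[involved] *= factor
    return out


def _truth_full(config: SynthConfig, atlas: ChannelAtlas, group: str,
                attenuation: float | None = None) -> np.ndarray:
    """53x53 target correlation matrix for one group (PSD-projected)."""
    if group == "MCS":
        rw = config.mcs_r_within if config.mcs_r_within is not None else config.r_within
        rb = (config.mcs_r_between if config.mcs_r_between is not None
              else config.r_between)
        a = config.attenuation if attenuation is None else attenuation
    else:
        rw, rb, a = config.r_within, config.r_between, 1.0
    r = _block_matrix(atlas, rw, rb, config.n_channels)
    r = _attenuate(r, atlas, config.attenuated_rois, a)
    return _nearest_psd(r)


def build_truth(config: SynthConfig, atlas: ChannelAtlas | None = None
                ) -> dict[str, np.ndarray]:
    """Per-group 50x50 target correlation matrices (midline channels dropped)."""
    config.validate()
    if atlas is None:
        _, atlas = default_montage()
    keep = [c - 1 for c in atlas.lateral_channels]
    out = {}
    for group in ("HC", "MCS"):
        full = _truth_full(config, atlas, group)
        out[group] = full[np.ix_(keep, keep)]
    return out


# ---------------------------------------------------------------------------
# per-subject forward simulation
# ---------------------------------------------------------------------------

def _band_limited_noise(rng: np.random.Generator, n_ch: int, n_t: int,
                        fs: float, band: tuple[float, float]) -> np.ndarray:
    """Band-limited Gaussian sources with *exact* identity sample covariance.

    The filtered noise is whitened in-sample (empirical covariance raised to
    the -1/2 power) so that Cholesky mixing reproduces the target
    correlation matrix exactly over the full record; recovered-correlation
    error downstream then reflects the processing pipeline rather than the
    generator's own sampling noise.
    """
    pad = int(round(60 * fs))
    white = rng.standard_normal((n_ch, n_t + 2 * pad))
    sos = signal.butter(3, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white, axis=1)[:, pad:pad + n_t]
    x = x - x.mean(axis=1, keepdims=True)
    cov = (x @ x.T) / n_t
    vals, vecs = np.linalg.eigh(cov)
    w = (vecs / np.sqrt(np.clip(vals, 1e-12, None))) @ vecs.T
    return w @ x


def simulate_subject(
    truth: np.ndarray,
    config: SynthConfig,
    seed: int,
    subject_id: str = "sim",
    subject_scale: float = 1.0,
    mbll: MbllCoefficients | None = None,
) -> RawIntensitySeries:
    """Forward-simulate one raw dual-wavelength recording.

    ``truth`` is the 53x53 target correlation of the band-limited neural
    HbO signal; ``subject_scale`` multiplies all off-diagonal correlations
    (between-subject coupling variability).
    """
    rng = np.random.default_rng(seed)
    fs = config.sampling_rate
    n_t = int(round(config.duration_s * fs))
    n_ch = config.n_channels
    t = np.arange(n_t) / fs

    r = truth * subject_scale
    np.fill_diagonal(r, 1.0)
    if subject_scale > 1.0:
        r = _nearest_psd(np.clip(r, -1.0, 1.0))
    chol = np.linalg.cholesky(r + 1e-8 * np.eye(n_ch))

    neural = chol @ _band_limited_noise(rng, n_ch, n_t, fs, (0.01, 0.1))
    hbo = config.neural_amp_um * neural
    for amp, freq in ((config.mayer_amp_um, config.mayer_hz),
                      (config.resp_amp_um, config.resp_hz),
                      (config.cardiac_amp_um, config.cardiac_hz)):
        phase = rng.uniform(0, 2 * np.pi, size=(n_ch, 1))
        jitter = 1.0 + 0.05 * rng.standard_normal((n_ch, 1))
        hbo = hbo + amp * np.sin(2 * np.pi * freq * jitter * t[None, :] + phase)
    hbr = config.hbr_ratio * hbo + config.hbr_noise_um * rng.standard_normal(hbo.shape)

    hemo = HemoSeries(subject_id, np.stack([hbo, hbr], axis=1), fs)
    od = hemoglobin_to_od(hemo, mbll).data  # (n_ch, 2, n_t)

    # slow drift (removed by the band-pass; realism of the raw traces)
    phase = rng.uniform(0, 2 * np.pi, size=(n_ch, 2, 1))
    slope = rng.uniform(-1, 1, size=(n_ch, 2, 1))
    od = od + config.drift_amp_od * (
        np.sin(2 * np.pi * 0.002 * t[None, None, :] + phase)
        + slope * (t[None, None, :] / max(t[-1], 1.0)))

    # sparse motion artifacts: step with exponential decay, same on both
    # wavelengths (motion moves the whole optode)
    rate = config.spike_rate_per_min * config.duration_s / 60.0
    for ch in range(n_ch):
        for _ in range(rng.poisson(rate)):
            t0 = int(rng.uniform(0, n_t))
            amp = (config.spike_amp_od * (0.5 + rng.random())
                   * (1 if rng.random() < 0.5 else -1))
            tail = np.arange(n_t - t0) / fs
            shape = amp * np.exp(-tail / config.spike_decay_s)
            od[ch, :, t0:] += shape[None, :]

    base = config.baseline_intensity * np.exp(
        0.1 * rng.standard_normal((n_ch, 2, 1)))
    intensity = base * np.exp(-od)
    return RawIntensitySeries(subject_id=subject_id, data=intensity,
                              sampling_rate=fs)


# ---------------------------------------------------------------------------
# cohort-level generation (recordings + clinical table + manifest)
# ---------------------------------------------------------------------------

def _simulate_clinical(rng: np.random.Generator, config: SynthConfig,
                       attenuations: np.ndarray) -> tuple[list[dict], np.ndarray]:
    """MCS clinical covariates; the auditory subscale is coupled to the
    per-subject attenuation with latent correlation ``crsr_coupling``."""
    n = config.n_mcs
    rho = config.crsr_coupling
    a_std = (attenuations - attenuations.mean())
    sd = a_std.std()
    a_std = a_std / sd if sd > 0 else a_std * 0.0
    latent = rho * a_std + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n)
    auditory = np.clip(np.round(1.5 + 1.2 * latent), 0, 4).astype(int)
    rows = []
    for i in range(n):
        rows.append({
            "age": float(np.clip(np.round(rng.normal(67.5, 16.5)), 25, 92)),
            "gender": "M" if i < round(n * 8 / 15) else "F",
            "etiology": _ETIOLOGIES[rng.integers(0, len(_ETIOLOGIES))],
            "duration": float(np.clip(np.round(2 * rng.lognormal(0.3, 1.0)) / 2,
                                      0.5, 12.0)),
            "auditory": int(auditory[i]),
            "visual": int(rng.integers(0, 4)),
            "motor": int(rng.integers(2, 6)),
            "oromotor": int(rng.integers(0, 4)),
            "communication": int(rng.integers(0, 2)),
            "arousal": int(rng.integers(1, 3)),
        })
    return rows, auditory


def generate_cohort(
    config: SynthConfig | None = None,
    atlas: ChannelAtlas | None = None,
    outdir: str | Path | None = None,
    dialect: str = "csv",
) -> Cohort:
    """Generate the full two-group cohort (recordings, clinical table,
    manifest).  Deterministic: the same config yields identical output."""
    config = config or SynthConfig()
    config.validate()
    if atlas is None:
        _, atlas = default_montage()

    ss = np.random.SeedSequence(config.seed)
    meta_rng = np.random.default_rng(ss.spawn(1)[0])
    subject_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                     for s in ss.spawn(config.n_hc + config.n_mcs)]

    # per-subject MCS attenuation (the quantity the auditory score tracks)
    atten = np.clip(
        config.attenuation
        + config.attenuation_jitter * meta_rng.standard_normal(config.n_mcs),
        0.2, 0.95)
    if config.attenuation == 1.0:
        atten = np.ones(config.n_mcs)
    clin_rows, _ = _simulate_clinical(meta_rng, config, atten)

    raws: list[RawIntensitySeries] = []
    records: list[SubjectRecord] = []
    entries: list[dict] = []

    hc_truth = _truth_full(config, atlas, "HC")
    n_hc_male = int(round(config.n_hc * 9 / 16))
    for i in range(config.n_hc):
        sid = f"HC{i + 1:02d}"
        seed = subject_seeds[i]
        scale = float(np.clip(
            1.0 + config.subject_scale_sd * meta_rng.standard_normal(), 0.6, 1.3))
        raws.append(simulate_subject(hc_truth, config, seed, sid,
                                     subject_scale=scale))
        records.append(SubjectRecord(
            id=sid, group="HC", mcs_subtype="none",
            gender="M" if i < n_hc_male else "F",
            age=float(np.clip(np.round(meta_rng.normal(58.6, 14.5)), 25, 85)),
            etiology="none", duration_months=0.0,
            crsr_subscales={"auditory": 4, "visual": 5, "motor": 6,
                            "oromotor": 3, "communication": 2, "arousal": 3}))
        entries.append({"id": sid, "group": "HC", "seed": seed,
                        "subject_scale": scale, "attenuation": 1.0,
                        "file": None})

    for i in range(config.n_mcs):
        sid = f"MCS{i + 1:02d}"
        seed = subject_seeds[config.n_hc + i]
        scale = float(np.clip(
            1.0 + config.subject_scale_sd * meta_rng.standard_normal(), 0.6, 1.3))
        truth = _truth_full(config, atlas, "MCS", attenuation=float(atten[i]))
        raws.append(simulate_subject(truth, config, seed, sid,
                                     subject_scale=scale))
        row = clin_rows[i]
        records.append(SubjectRecord(
            id=sid, group="MCS", mcs_subtype="MCS-",
            gender=row["gender"], age=row["age"], etiology=row["etiology"],
            duration_months=row["duration"],
            crsr_subscales={k: row[k] for k in
                            ("auditory", "visual", "motor", "oromotor",
                             "communication", "arousal")}))
        entries.append({"id": sid, "group": "MCS", "seed": seed,
                        "subject_scale": scale,
                        "attenuation": float(atten[i]), "file": None})

    manifest = CohortManifest(config=asdict(config), subjects=entries)
    cohort = Cohort(config=config, raws=raws, records=records,
                    manifest=manifest)
    if outdir is not None:
        cohort.write(outdir, dialect=dialect)
    return cohort
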