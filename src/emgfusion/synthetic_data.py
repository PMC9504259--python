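"""Synthetic subject-distinguishable EMG-like datasets.

Each record is band-limited Gaussian noise per channel, shaped by a
rest-burst-rest amplitude envelope and scaled by per-channel gains,
plus white measurement noise.  Subject identity is encoded in the
spectral bands and channel-gain pattern (inter-individual differences
in muscle composition and electrode coupling show up as spectral and
amplitude signatures); motion identity is encoded in the envelope's
burst timing.  ``subject_separation`` scales the between-subject
dispersion of the profiles (0 makes all subjects identical, so any
classifier must fall to chance); ``noise_level`` scales trial-to-trial
gain jitter and additive measurement noise.

Randomness is hierarchical: profiles derive from ``seed`` alone and
each trial from ``(seed, subject, motion, trial)``, so enlarging the
dataset never perturbs existing records.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from emgfusion.data_model import (
    DatasetManifest,
    ManifestEntry,
    MultichannelEmgRecord,
    write_manifest,
    write_record,
)

__all__ = [
    "GeneratorConfig",
    "SubjectProfile",
    "generate_profiles",
    "synth_record",
    "generate_records",
    "generate_dataset",
    "PRESETS",
]

BASE_AMPLITUDE = 0.2  # volts, burst-level RMS scale


@dataclass(frozen=True)
class GeneratorConfig:
    """Dataset layout and signal-model parameters.

    The default fixture is 10 subjects x 3 motions x 5 trials of
    8-channel, 640-sample records at 200 Hz — the small-armband-style
    geometry whose framing at (85, 12) yields 9 segments.  The
    ``cu_mini`` preset emulates the 2-channel, 8-second
    rest(2s)-burst(4s)-rest(2s) geometry downsampled to 1500 samples.
    """

    n_subjects: int = 10
    n_motions: int = 3
    n_trials: int = 5
    n_channels: int = 8
    sampling_rate: float = 200.0
    n_samples: int = 640
    subject_separation: float = 1.0
    noise_level: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_motions", "n_trials", "n_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_samples < 16:
            raise ValueError("n_samples must be >= 16")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.subject_separation < 0 or self.noise_level < 0:
            raise ValueError("subject_separation and noise_level must be >= 0")

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


PRESETS: dict[str, GeneratorConfig] = {
    "angeles-mini": GeneratorConfig(),
    "cu-mini": GeneratorConfig(n_channels=2, sampling_rate=187.5, n_samples=1500),
}


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject signal signature: spectral bands, gains, envelope shape."""

    subject_index: int
    band_centers: np.ndarray  # Hz, one per channel
    band_widths: np.ndarray  # Hz
    gains: np.ndarray  # dimensionless, > 0
    attack_frac: float
    release_frac: float
    rest_level: float

    def __post_init__(self) -> None:
        if np.any(self.gains <= 0):
            raise ValueError("gains must be positive")


def generate_profiles(config: GeneratorConfig) -> list[SubjectProfile]:
    """Draw one profile per subject, deterministically from the seed.

    Between-subject dispersion of every profile parameter scales with
    ``subject_separation``; at separation 0 all profiles coincide.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    nyq = config.sampling_rate / 2.0
    m = config.n_channels
    # channel-dependent base grid shared by all subjects
    base_centers = np.linspace(0.3 * nyq, 0.75 * nyq, m)
    base_width = 0.2 * nyq
    sep = config.subject_separation
    profiles = []
    for s in range(config.n_subjects):
        centers = base_centers + sep * rng.normal(0.0, 0.08 * nyq, size=m)
        widths = base_width * np.clip(1.0 + sep * rng.normal(0.0, 0.25, size=m), 0.4, 2.0)
        widths = np.minimum(widths, 0.5 * nyq)
        centers = np.clip(centers, widths / 2 + 0.02 * nyq, nyq - widths / 2 - 0.02 * nyq)
        gains = np.exp(sep * rng.normal(0.0, 0.5, size=m))
        attack = float(np.clip(0.08 * (1.0 + sep * rng.normal(0.0, 0.4)), 0.02, 0.2))
        release = float(np.clip(0.08 * (1.0 + sep * rng.normal(0.0, 0.4)), 0.02, 0.2))
        rest = float(np.clip(0.08 * (1.0 + sep * rng.normal(0.0, 0.4)), 0.02, 0.3))
        profiles.append(
            SubjectProfile(
                subject_index=s,
                band_centers=centers,
                band_widths=widths,
                gains=gains,
                attack_frac=attack,
                release_frac=release,
                rest_level=rest,
            )
        )
    return profiles


def _motion_envelope_params(config: GeneratorConfig, motion_index: int) -> tuple[float, float]:
    """Burst start/duration fractions for a motion (dataset-level constants)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23, motion_index]))
    start = float(np.clip(0.25 + rng.uniform(-0.12, 0.12), 0.05, 0.45))
    dur = float(np.clip(0.5 + rng.uniform(-0.18, 0.18), 0.25, 0.7))
    dur = min(dur, 0.95 - start)
    return start, dur


def _envelope(n: int, start_frac: float, dur_frac: float, attack: float, release: float, rest: float) -> np.ndarray:
    """Rest-burst-rest envelope with raised-cosine attack/release ramps."""
    t = np.arange(n) / n
    b0, b1 = start_frac, start_frac + dur_frac
    a, r = max(attack, 1.0 / n), max(release, 1.0 / n)
    rise = (t - b0) / a
    fall = (b1 - t) / r
    ramp = np.minimum(np.clip(rise, 0.0, 1.0), np.clip(fall, 0.0, 1.0))
    smooth = 0.5 - 0.5 * np.cos(np.pi * ramp)
    return rest + (1.0 - rest) * smooth


def synth_record(
    profile: SubjectProfile, motion_index: int, trial: int, config: GeneratorConfig
) -> MultichannelEmgRecord:
    """Synthesize one labelled record for (subject profile, motion, trial).

    Per channel: white noise band-passed to the profile's band
    (4th-order Butterworth, zero-phase), normalized to unit RMS,
    multiplied by the motion envelope and the channel gain at the base
    amplitude (0.2 V), plus ``noise_level``-scaled gain jitter and
    additive white measurement noise.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 31, profile.subject_index, motion_index, trial])
    )
    n = config.n_samples
    rate = config.sampling_rate
    start, dur = _motion_envelope_params(config, motion_index)
    env = _envelope(n, start, dur, profile.attack_frac, profile.release_frac, profile.rest_level)
    channels = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        lo = profile.band_centers[ch] - profile.band_widths[ch] / 2
        hi = profile.band_centers[ch] + profile.band_widths[ch] / 2
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
        carrier = sps.sosfiltfilt(sos, rng.standard_normal(n))
        carrier /= np.sqrt(np.mean(carrier**2)) + 1e-30
        gain = profile.gains[ch] * (1.0 + config.noise_level * rng.normal(0.0, 0.2))
        meas = config.noise_level * 0.05 * rng.standard_normal(n)
        channels[ch] = BASE_AMPLITUDE * abs(gain) * env * carrier + BASE_AMPLITUDE * meas
    return MultichannelEmgRecord(
        subject_id=f"s{profile.subject_index + 1:02d}",
        motion_id=f"m{motion_index + 1:02d}",
        trial=trial,
        sampling_rate=rate,
        signal=channels,
    )


def generate_records(config: GeneratorConfig) -> DatasetManifest:
    """Generate the full subjects x motions x trials dataset in memory."""
    profiles = generate_profiles(config)
    entries = []
    for profile in profiles:
        for mo in range(config.n_motions):
            for tr in range(1, config.n_trials + 1):
                rec = synth_record(profile, mo, tr, config)
                entries.append(
                    ManifestEntry(
                        subject_id=rec.subject_id,
                        motion_id=rec.motion_id,
                        trial=tr,
                        sampling_rate=rec.sampling_rate,
                        record=rec,
                    )
                )
    return DatasetManifest(entries)


def generate_dataset(config: GeneratorConfig, out_dir) -> DatasetManifest:
    """Generate the dataset and write it as delimited text plus a manifest CSV.

    Returns a manifest whose entries point at the written files, so it
    round-trips through :func:`emgfusion.data_model.read_manifest`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mem = generate_records(config)
    entries = []
    for e in mem.entries:
        rec = e.record
        rel = Path("records") / f"{rec.subject_id}_{rec.motion_id}_t{rec.trial}.csv"
        write_record(out_dir / rel, rec)
        entries.append(
            ManifestEntry(
                subject_id=e.subject_id,
                motion_id=e.motion_id,
                trial=e.trial,
                sampling_rate=e.sampling_rate,
                path=out_dir / rel,
            )
        )
    manifest = DatasetManifest(entries)
    write_manifest(out_dir / "manifest.csv", manifest)
    return manifest
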