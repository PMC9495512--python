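"""Synthetic single-lead ECG generation.

Produces labeled records at 300 Hz carrying the two cues that separate
atrial fibrillation (AF) from sinus rhythm on a single lead:

* **RR-interval regularity** — sinus beats arrive nearly periodically while
  AF beats arrive with a large, positively-skewed spread;
* **P-wave presence** — the atrial deflection before each QRS complex is
  present in sinus rhythm and replaced in AF by a continuous low-amplitude
  fibrillatory ("f-wave") oscillation.

Each beat is a sum of Gaussian bumps (one per P/Q/R/S/T deflection), the AF
f-wave is a phase-diffusing sinusoid, and records are finished with additive
white Gaussian sensor noise.  Everything is driven by explicit seeds so a
record is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "BeatComponent",
    "BeatModel",
    "RhythmSpec",
    "SyntheticRecord",
    "DEFAULT_BEAT_MODEL",
    "normal_spec",
    "af_spec",
    "draw_rr_sequence",
    "render_beat_train",
    "add_fibrillatory_wave",
    "generate_record",
    "generate_dataset",
    "default_label_counts",
]

#: Sampling rate of the target recording device (Hz).
DEFAULT_FS = 300.0

#: Duration bounds of the emulated recordings (seconds).
DURATION_RANGE = (9.0, 61.0)

#: AF : non-AF record ratio of the emulated population (771 : 7,757).
AF_FRACTION = 771 / 8528

_WAVE_NAMES = ("P", "Q", "R", "S", "T")


@dataclass(frozen=True)
class BeatComponent:
    """One Gaussian deflection of the PQRST complex.

    ``center`` is the offset of the bump peak relative to the R peak in
    seconds, ``width`` its Gaussian sigma in seconds and ``amplitude`` its
    peak value in millivolts.
    """

    name: str
    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.name not in _WAVE_NAMES:
            raise ValueError(f"unknown wave name {self.name!r}; expected one of {_WAVE_NAMES}")
        if not self.width > 0:
            raise ValueError(f"component {self.name}: width must be > 0, got {self.width}")


@dataclass(frozen=True)
class BeatModel:
    """A beat as a sum of Gaussian bumps, one per named deflection."""

    components: tuple[BeatComponent, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("beat model needs at least one component")
        n_r = sum(1 for c in self.components if c.name == "R")
        if n_r != 1:
            raise ValueError(f"beat model must contain exactly one R component, got {n_r}")

    def without_p(self) -> "BeatModel":
        """The same beat with the atrial (P) deflection removed."""
        kept = tuple(c for c in self.components if c.name != "P")
        return BeatModel(kept)


#: Textbook-proportioned PQRST defaults (offsets s, widths s, amplitudes mV).
DEFAULT_BEAT_MODEL = BeatModel(
    (
        BeatComponent("P", -0.20, 0.025, 0.15),
        BeatComponent("Q", -0.05, 0.010, -0.10),
        BeatComponent("R", 0.00, 0.012, 1.20),
        BeatComponent("S", 0.04, 0.010, -0.25),
        BeatComponent("T", 0.30, 0.060, 0.35),
    )
)


@dataclass(frozen=True)
class RhythmSpec:
    """Statistical description of one rhythm class.

    Parameters
    ----------
    label
        ``"normal"`` (sinus rhythm) or ``"af"``.
    mean_hr
        Mean heart rate in beats/min (must lie in [30, 220]).
    rr_cv
        Coefficient of variation of the RR intervals (dimensionless).
    fwave_amp, fwave_freq
        Amplitude (mV) and base frequency (Hz) of the fibrillatory wave;
        zero amplitude for sinus rhythm.
    noise_sd
        Standard deviation of additive white sensor noise (mV).
    fs
        Sampling rate in Hz.
    """

    label: str
    mean_hr: float
    rr_cv: float
    fwave_amp: float = 0.0
    fwave_freq: float = 7.0
    noise_sd: float = 0.05
    fs: float = DEFAULT_FS
    beat_model: BeatModel = DEFAULT_BEAT_MODEL

    def __post_init__(self) -> None:
        if self.label not in ("normal", "af"):
            raise ValueError(f"label must be 'normal' or 'af', got {self.label!r}")
        if not 30.0 <= self.mean_hr <= 220.0:
            raise ValueError(f"mean_hr must lie in [30, 220], got {self.mean_hr}")
        if self.rr_cv < 0:
            raise ValueError("rr_cv must be >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.fwave_amp < 0 or self.noise_sd < 0:
            raise ValueError("fwave_amp and noise_sd must be >= 0")

    @property
    def binary_label(self) -> int:
        return 1 if self.label == "af" else 0


def normal_spec(**overrides) -> RhythmSpec:
    """Default sinus-rhythm spec: 70 bpm, RR CV 0.05, no f-wave."""
    base = dict(label="normal", mean_hr=70.0, rr_cv=0.05, fwave_amp=0.0)
    base.update(overrides)
    return RhythmSpec(**base)


def af_spec(**overrides) -> RhythmSpec:
    """Default AF spec: 100 bpm, RR CV 0.25, 0.08 mV f-wave at 7 Hz."""
    base = dict(label="af", mean_hr=100.0, rr_cv=0.25, fwave_amp=0.08)
    base.update(overrides)
    return RhythmSpec(**base)


@dataclass(frozen=True)
class SyntheticRecord:
    """One simulated single-lead ECG trace with its ground truth."""

    samples: np.ndarray  # mV
    fs: float
    duration: float  # seconds
    label: int  # 0 = non-AF, 1 = AF
    rr: np.ndarray  # RR intervals, seconds
    seed: int
    name: str = ""

    def __post_init__(self) -> None:
        expected = int(round(self.duration * self.fs))
        if len(self.samples) != expected:
            raise ValueError(
                f"record length {len(self.samples)} != round(duration * fs) = {expected}"
            )


# Refractory floor for RR intervals: ventricles cannot re-excite faster.
_RR_FLOOR = 0.25


def draw_rr_sequence(
    spec: RhythmSpec, duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw RR intervals (seconds) whose cumulative sum covers ``duration``.

    Sinus rhythm: ``RR = 60/mean_hr * (1 + eps)`` with ``eps ~ N(0, rr_cv)``.
    AF: RR is log-normal with the same mean and CV equal to ``rr_cv`` —
    log-normality guarantees positivity and gives the positively-skewed
    spread characteristic of fibrillation.  Both are floored at 0.25 s.
    """
    if not duration > 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    mean_rr = 60.0 / spec.mean_hr
    out: list[np.ndarray] = []
    total = 0.0
    # Draw in batches; expected count plus slack keeps this to 1-2 rounds.
    batch = max(8, int(duration / mean_rr * 1.5) + 4)
    while total < duration:
        if spec.label == "af" and spec.rr_cv > 0:
            sigma2 = math.log1p(spec.rr_cv**2)
            mu = math.log(mean_rr) - sigma2 / 2.0
            rr = rng.lognormal(mu, math.sqrt(sigma2), batch)
        else:
            rr = mean_rr * (1.0 + rng.normal(0.0, spec.rr_cv, batch) if spec.rr_cv > 0 else np.ones(batch))
        rr = np.maximum(rr, _RR_FLOOR)
        out.append(rr)
        total += float(rr.sum())
    rr_all = np.concatenate(out)
    # Trim to the first prefix whose sum covers the duration.
    stop = int(np.searchsorted(np.cumsum(rr_all), duration) + 1)
    return rr_all[:stop]


def render_beat_train(
    rr: np.ndarray,
    beats: BeatModel = DEFAULT_BEAT_MODEL,
    fs: float = DEFAULT_FS,
    include_p: bool = True,
) -> np.ndarray:
    """Render a beat train as a sum of Gaussian bumps.

    The j-th R peak is placed at ``cumsum(rr)[j] - rr[0]/2`` so that every
    beat, including the first and last, lies inside the trace.  The output
    has exactly ``round(sum(rr) * fs)`` samples.  Bumps are evaluated out to
    eight sigma, below 1e-9 mV truncation error for millivolt amplitudes.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size == 0:
        raise ValueError("rr must be non-empty")
    if fs <= 0:
        raise ValueError("fs must be > 0")
    n = int(round(float(rr.sum()) * fs))
    wave = np.zeros(n)
    r_times = np.cumsum(rr) - rr[0] / 2.0
    components = beats.components if include_p else beats.without_p().components
    for comp in components:
        if comp.amplitude == 0.0:
            continue
        half = 8.0 * comp.width
        for t_r in r_times:
            c = t_r + comp.center
            lo = max(0, int(math.ceil((c - half) * fs)))
            hi = min(n, int(math.floor((c + half) * fs)) + 1)
            if hi <= lo:
                continue
            t = np.arange(lo, hi) / fs
            wave[lo:hi] += comp.amplitude * np.exp(-0.5 * ((t - c) / comp.width) ** 2)
    return wave


def add_fibrillatory_wave(
    waveform: np.ndarray,
    amp: float,
    freq: float,
    fs: float,
    rng: np.random.Generator,
    phase_walk_sd: float = 0.05,
    amp_jitter: float = 0.25,
) -> np.ndarray:
    """Superimpose a fibrillatory oscillation on ``waveform``.

    The f-wave is a sinusoid at ``freq`` whose phase performs a random walk
    (sd ``phase_walk_sd`` rad/sample) and whose envelope wanders slowly by
    ``amp_jitter`` relative amplitude (AR(1) with a 1 s time constant) —
    mimicking the disorganized but band-limited atrial activity of AF.
    """
    waveform = np.asarray(waveform, dtype=float)
    if amp < 0:
        raise ValueError("amp must be >= 0")
    if not 0 < freq < fs / 2:
        raise ValueError(f"freq must satisfy 0 < freq < fs/2 = {fs / 2} Hz (aliasing), got {freq}")
    if amp == 0.0:
        return waveform.copy()
    n = len(waveform)
    t = np.arange(n) / fs
    phase = 2.0 * np.pi * freq * t + np.cumsum(rng.normal(0.0, phase_walk_sd, n))
    # Slow unit-variance AR(1) envelope modulation, time constant 1 s.
    rho = math.exp(-1.0 / fs)
    eps = rng.normal(0.0, 1.0, n)
    slow = lfilter([math.sqrt(1.0 - rho**2)], [1.0, -rho], eps)
    envelope = np.clip(1.0 + amp_jitter * slow, 0.0, None)
    return waveform + amp * envelope * np.sin(phase)


def generate_record(
    spec: RhythmSpec,
    duration: float | None = None,
    seed: int = 0,
    name: str = "",
) -> SyntheticRecord:
    """Generate one labeled synthetic record.

    With ``duration=None`` the duration is drawn uniformly from [9, 61] s,
    the span of the emulated recordings.  The P wave is rendered only for
    sinus rhythm; the f-wave only when ``spec.fwave_amp > 0``.
    """
    rng = np.random.default_rng(seed)
    if duration is None:
        duration = float(rng.uniform(*DURATION_RANGE))
    if not duration > 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    rr = draw_rr_sequence(spec, duration, rng)
    wave = render_beat_train(rr, spec.beat_model, spec.fs, include_p=(spec.label == "normal"))
    if spec.fwave_amp > 0:
        wave = add_fibrillatory_wave(wave, spec.fwave_amp, spec.fwave_freq, spec.fs, rng)
    if spec.noise_sd > 0:
        wave = wave + rng.normal(0.0, spec.noise_sd, len(wave))
    n = int(round(duration * spec.fs))
    return SyntheticRecord(
        samples=wave[:n],
        fs=spec.fs,
        duration=duration,
        label=spec.binary_label,
        rr=rr,
        seed=seed,
        name=name,
    )


def default_label_counts(n_total: int) -> tuple[int, int]:
    """Split ``n_total`` records in the emulated 771 : 7,757 AF : non-AF ratio."""
    n_af = int(round(n_total * AF_FRACTION))
    return n_af, n_total - n_af


def generate_dataset(
    n_af: int,
    n_non_af: int,
    seed: int = 0,
    normal: RhythmSpec | None = None,
    af: RhythmSpec | None = None,
    duration: float | None = None,
    out_dir=None,
) -> list[SyntheticRecord]:
    """Generate a labeled dataset of ``n_af + n_non_af`` records.

    Per-record seeds derive deterministically from the master seed, the
    label order is shuffled (seeded), and record names follow the
    ``A#####`` convention of the emulated archive.  With ``out_dir`` the
    records are also written to disk in the archive layout
    (``<name>.mat`` files plus ``REFERENCE.csv``).
    """
    if n_af < 0 or n_non_af < 0:
        raise ValueError("record counts must be >= 0")
    normal = normal or normal_spec()
    af = af or af_spec()
    n = n_af + n_non_af
    ss = np.random.SeedSequence(seed)
    per_record = ss.generate_state(n) if n else np.empty(0, dtype=np.uint32)
    labels = np.array([1] * n_af + [0] * n_non_af, dtype=int)
    order = np.random.default_rng(ss.spawn(1)[0]).permutation(n)
    labels = labels[order]
    records = []
    for i in range(n):
        spec = af if labels[i] == 1 else normal
        records.append(
            generate_record(spec, duration=duration, seed=int(per_record[i]), name=f"A{i + 1:05d}")
        )
    if out_dir is not None:
        from .dataio import write_dataset

        write_dataset(records, out_dir)
    return records
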