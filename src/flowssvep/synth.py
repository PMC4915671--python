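"""Forward model of multichannel SSVEP recordings with known ground truth.

The measurement model is the one a steady-state phase-locked analysis
assumes: each channel's deterministic part is a sum of sinusoids at the
analysis harmonics,

    x_c(t) = sum_h [ re_{c,h} cos(2 pi f_h t) + im_{c,h} sin(2 pi f_h t) ] + noise,

where (re, im) is the condition-specific mean response of channel c at
harmonic h plus a per-subject complex random intercept drawn once per
subject and shared across that subject's trials.  Noise is stationary
pink (1/f^alpha) plus white Gaussian, independent across channels; there
are no transient onset dynamics.  High-amplitude square transients can be
injected into randomly chosen coherence cycles to exercise the 60 microvolt
artifact-rejection rule.

Defaults reproduce the study conditions: 128 vertex-referenced channels
sampled at 432.43 Hz, 29 subjects, 3 flow patterns x 3 speeds
(2/4/8 deg/s), 5 trials per condition, trials of 10 coherence cycles.

Randomness is driven by a single top-level seed; per-subject and per-trial
child streams are derived with ``numpy.random.SeedSequence.spawn`` so any
trial is independently reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .preprocess import cycle_slices
from .stimulus import StimulusSpec

__all__ = [
    "HARMONICS",
    "harmonic_frequencies",
    "ResponseTopography",
    "EEGRecording",
    "StudyDesign",
    "pink_noise",
    "forward_signal",
    "inject_artifacts",
    "iter_study",
    "generate_study",
    "demo_topography",
    "simulate_subject_components",
    "save_recording",
    "load_recording",
]

SAMPLING_RATE = 432.43  # Hz
N_CHANNELS = 128
HARMONICS = ("1F1", "2F1", "3F1", "1F2")

PATTERNS = ("radial", "rotation", "translation")
SPEEDS = (2.0, 4.0, 8.0)


def harmonic_frequencies(spec: StimulusSpec) -> dict[str, float]:
    """Analysis harmonic frequencies implied by a stimulus spec.

    1F1/2F1/3F1 are harmonics of the coherence-modulation frequency and 1F2
    is the dot update rate ({1.2, 2.4, 3.6, 24} Hz for the defaults).
    """
    return {
        "1F1": spec.f1,
        "2F1": 2 * spec.f1,
        "3F1": 3 * spec.f1,
        "1F2": spec.f2,
    }


@dataclass(frozen=True)
class ResponseTopography:
    """Ground-truth mean responses plus noise and artifact parameters.

    ``responses`` is a tidy table (channel, harmonic, pattern, speed, re, im)
    in microvolts; absent combinations mean zero response.  The subject
    intercept is isotropic complex Gaussian: each of (re, im) ~
    N(0, subject_intercept_sd^2), independently per channel and harmonic,
    drawn once per subject — circular symmetry matches the null assumption
    of the frequency-domain statistics.
    """

    responses: pd.DataFrame
    subject_intercept_sd: float = 0.25   # uV per component
    pink_exponent: float = 1.0           # PSD ~ 1/f^exponent
    pink_sd: float = 6.0                 # uV, broadband pink noise sd
    white_sd: float = 3.0                # uV
    artifact_rate: float = 0.05          # per cycle
    artifact_amplitude: float = 120.0    # uV (2x the rejection threshold)

    def __post_init__(self) -> None:
        for name in ("subject_intercept_sd", "pink_sd", "white_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate must be in [0, 1]")
        required = {"channel", "harmonic", "pattern", "speed", "re", "im"}
        if not required.issubset(self.responses.columns):
            raise ValueError(f"responses table needs columns {sorted(required)}")

    def mean_responses(
        self, pattern: str, speed: float, harmonics=HARMONICS,
        n_channels: int = N_CHANNELS,
    ) -> np.ndarray:
        """Complex (n_channels, n_harmonics) mean response for one condition."""
        out = np.zeros((n_channels, len(harmonics)), dtype=complex)
        r = self.responses
        sel = r[(r.pattern == pattern) & (r.speed == speed)]
        hindex = {h: j for j, h in enumerate(harmonics)}
        for row in sel.itertuples():
            j = hindex.get(row.harmonic)
            # responses on channels beyond the simulated montage are ignored
            if j is not None and int(row.channel) <= n_channels:
                out[int(row.channel) - 1, j] += row.re + 1j * row.im
        return out


@dataclass
class EEGRecording:
    """Multichannel vertex-referenced time series for one trial (microvolts)."""

    samples: np.ndarray               # (n_channels, n_samples)
    sampling_rate: float = SAMPLING_RATE
    t0: float = 0.0                   # s relative to trial onset
    pattern: str | None = None
    speed: float | None = None
    subject: str | int | None = None
    trial: int | None = None
    ground_truth: dict | None = None  # harmonic -> (n_channels,) complex
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def with_samples(self, samples: np.ndarray) -> "EEGRecording":
        return replace(self, samples=samples)


@dataclass(frozen=True)
class StudyDesign:
    """Sample sizes of a synthetic study."""

    n_subjects: int = 29
    patterns: tuple = PATTERNS
    speeds: tuple = SPEEDS
    trials_per_condition: int = 5

    def __post_init__(self) -> None:
        if not 1 <= self.trials_per_condition <= 10:
            raise ValueError("trials_per_condition must be within [1, 10]")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")

    @property
    def n_conditions(self) -> int:
        return len(self.patterns) * len(self.speeds)

    @property
    def subjects(self) -> list[str]:
        return [f"s{i + 1:02d}" for i in range(self.n_subjects)]

    def conditions(self) -> list[tuple[str, float]]:
        return [(p, s) for p in self.patterns for s in self.speeds]


def pink_noise(
    n_samples: int,
    rng: np.random.Generator,
    exponent: float = 1.0,
    sd: float = 1.0,
    n_channels: int | None = None,
    sampling_rate: float = SAMPLING_RATE,
) -> np.ndarray:
    """Gaussian noise with power spectral density ~ 1/f^exponent.

    Synthesized in the frequency domain (amplitude ~ f^(-exponent/2), zero
    DC) and scaled to the requested broadband standard deviation.
    """
    shape = (n_samples,) if n_channels is None else (n_channels, n_samples)
    if sd == 0:
        return np.zeros(shape)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    k = freqs.size
    cshape = (k,) if n_channels is None else (n_channels, k)
    spec = (rng.standard_normal(cshape) + 1j * rng.standard_normal(cshape)) * amp
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    x *= sd / x.std(axis=-1, keepdims=True)
    return x


def forward_signal(
    topography: ResponseTopography,
    spec: StimulusSpec,
    subject_offset: np.ndarray | None,
    pattern: str,
    speed: float,
    seed,
    duration: float | None = None,
    n_channels: int = N_CHANNELS,
    sampling_rate: float = SAMPLING_RATE,
    subject=None,
    trial: int | None = None,
    noise: bool = True,
) -> EEGRecording:
    """Generate one trial recording for one condition.

    ``subject_offset`` is a complex (n_channels, n_harmonics) array added to
    the condition mean (the subject's random intercept); None means zero.
    ``duration`` must be an integer number of f1 cycles (default: one trial,
    cycles_per_trial / f1) — this protects exact-frequency extraction.
    The planted coefficients are stored in ``ground_truth``.
    """
    if duration is None:
        duration = spec.trial_duration
    n_cyc = duration * spec.f1
    if abs(n_cyc - round(n_cyc)) > 1e-9:
        raise ValueError(
            f"duration {duration} s is not an integer number of f1 cycles"
        )
    rng = np.random.default_rng(seed)
    freqs = harmonic_frequencies(spec)
    coef = topography.mean_responses(
        pattern, speed, harmonics=tuple(freqs), n_channels=n_channels
    )
    if subject_offset is not None:
        coef = coef + subject_offset
    n = int(np.floor(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    x = np.zeros((n_channels, n))
    for j, f in enumerate(freqs.values()):
        w = 2 * np.pi * f * t
        x += np.outer(coef[:, j].real, np.cos(w))
        x += np.outer(coef[:, j].imag, np.sin(w))
    if noise:
        if topography.pink_sd > 0:
            x += pink_noise(
                n, rng, topography.pink_exponent, topography.pink_sd,
                n_channels, sampling_rate,
            )
        if topography.white_sd > 0:
            x += topography.white_sd * rng.standard_normal((n_channels, n))
    truth = {h: coef[:, j].copy() for j, h in enumerate(freqs)}
    return EEGRecording(
        samples=x,
        sampling_rate=sampling_rate,
        pattern=pattern,
        speed=speed,
        subject=subject,
        trial=trial,
        ground_truth=truth,
    )


def inject_artifacts(
    recording: EEGRecording,
    spec: StimulusSpec,
    rate: float,
    amplitude: float,
    seed,
) -> tuple[EEGRecording, np.ndarray]:
    """Add square transients to randomly chosen coherence cycles.

    Each cycle independently receives an artifact with probability ``rate``:
    a ~50 ms square pulse of the given amplitude on one randomly chosen
    channel.  Returns the modified recording and the ground-truth per-cycle
    flags.  An amplitude above twice the rejection threshold guarantees the
    peak-to-peak rule fires on the affected cycle.
    """
    if not 0 <= rate <= 1:
        raise ValueError("artifact rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    slices = cycle_slices(
        recording.n_samples, recording.sampling_rate, spec.f1,
        spec.cycles_per_trial,
    )
    flags = rng.random(len(slices)) < rate
    if not flags.any():
        return recording, flags
    x = recording.samples.copy()
    width = max(1, int(round(0.05 * recording.sampling_rate)))
    for k, (start, stop) in enumerate(slices):
        if not flags[k]:
            continue
        ch = int(rng.integers(recording.n_channels))
        off = int(rng.integers(start, max(start + 1, stop - width)))
        x[ch, off:off + width] += amplitude
    return recording.with_samples(x), flags


def _study_seeds(design: StudyDesign, seed) -> list[np.random.SeedSequence]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return ss.spawn(design.n_subjects + 1)  # one per subject + one for intercepts


def _subject_intercepts(
    design: StudyDesign, topography: ResponseTopography,
    intercept_ss: np.random.SeedSequence, n_channels: int,
) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(intercept_ss)
    sd = topography.subject_intercept_sd
    out = {}
    for subj in design.subjects:
        z = rng.standard_normal((n_channels, len(HARMONICS), 2))
        out[subj] = sd * (z[..., 0] + 1j * z[..., 1])
    return out


def iter_study(
    design: StudyDesign,
    topography: ResponseTopography,
    spec: StimulusSpec,
    seed,
    n_channels: int = N_CHANNELS,
    with_artifacts: bool = True,
) -> Iterator[tuple[EEGRecording, np.ndarray]]:
    """Stream (recording, ground-truth artifact flags) for a whole study.

    One recording per subject x condition x trial.  Each subject's complex
    intercept is drawn once and shared across all of that subject's trials
    (the random-intercept structure of the analysis model).  Streaming keeps
    memory flat; :func:`generate_study` materializes the same sequence.
    """
    seeds = _study_seeds(design, seed)
    intercepts = _subject_intercepts(design, topography, seeds[-1], n_channels)
    for si, subj in enumerate(design.subjects):
        trial_seeds = seeds[si].spawn(
            design.n_conditions * design.trials_per_condition * 2
        )
        k = 0
        for pattern, speed in design.conditions():
            for trial in range(design.trials_per_condition):
                cond_spec = replace(spec, pattern=pattern, speed=speed)
                rec = forward_signal(
                    topography, cond_spec, intercepts[subj], pattern, speed,
                    trial_seeds[k], n_channels=n_channels, subject=subj,
                    trial=trial,
                )
                if with_artifacts and topography.artifact_rate > 0:
                    rec, flags = inject_artifacts(
                        rec, cond_spec, topography.artifact_rate,
                        topography.artifact_amplitude, trial_seeds[k + 1],
                    )
                else:
                    flags = np.zeros(spec.cycles_per_trial, dtype=bool)
                k += 2
                yield rec, flags


def generate_study(
    design: StudyDesign,
    topography: ResponseTopography,
    spec: StimulusSpec,
    seed,
    n_channels: int = N_CHANNELS,
    with_artifacts: bool = True,
) -> list[tuple[EEGRecording, np.ndarray]]:
    """Materialized version of :func:`iter_study` (beware memory at full scale)."""
    est_gb = (
        design.n_subjects * design.n_conditions * design.trials_per_condition
        * n_channels * spec.trial_duration * SAMPLING_RATE * 8 / 1e9
    )
    if est_gb > 2:
        warnings.warn(
            f"materializing ~{est_gb:.1f} GB of recordings; consider iter_study",
            ResourceWarning,
            stacklevel=2,
        )
    return list(
        iter_study(design, topography, spec, seed, n_channels, with_artifacts)
    )


# ---------------------------------------------------------------------------
# Effect presets and component-level simulation
# ---------------------------------------------------------------------------

def demo_topography(
    channel_map,
    spec: StimulusSpec | None = None,
    **overrides,
) -> ResponseTopography:
    """Ground-truth preset mirroring the study's effect topology.

    - a broad posterior response at 2F1 in all conditions (coherence
      on/off transients are pattern- and speed-unselective),
    - a pattern effect at 1F1 over a right-lateral channel group,
    - a speed effect at 3F1 and 1F2 over a posterior midline group
      (faster speeds produce larger responses).
    """
    from .channels import midline_posterior_group, right_lateral_group

    spec = spec or StimulusSpec()
    pattern_ch = right_lateral_group(channel_map)
    speed_ch = midline_posterior_group(channel_map)
    posterior = channel_map.frame.index[channel_map.frame.y < -0.3].to_numpy()

    rows = []

    def add(channels, harmonic, pattern, speed, re, im):
        for c in np.atleast_1d(channels):
            rows.append(
                dict(channel=int(c), harmonic=harmonic, pattern=pattern,
                     speed=float(speed), re=re, im=im)
            )

    pattern_means = {
        "radial": (1.0, 0.4),
        "rotation": (-0.2, 1.0),
        "translation": (0.15, 0.1),
    }
    speed_means_3f1 = {2.0: (0.2, 0.1), 4.0: (0.7, 0.35), 8.0: (0.9, 0.45)}
    speed_means_1f2 = {2.0: (0.3, 0.0), 4.0: (0.9, 0.2), 8.0: (1.0, 0.3)}
    for p in PATTERNS:
        for s in SPEEDS:
            add(posterior, "2F1", p, s, 0.8, 0.5)
            add(pattern_ch, "1F1", p, s, *pattern_means[p])
            add(speed_ch, "3F1", p, s, *speed_means_3f1[s])
            add(speed_ch, "1F2", p, s, *speed_means_1f2[s])
    return ResponseTopography(responses=pd.DataFrame(rows), **overrides)


def simulate_subject_components(
    design: StudyDesign,
    topography: ResponseTopography,
    spec: StimulusSpec | None = None,
    seed=None,
    noise_sd: float = 0.35,
    n_channels: int = N_CHANNELS,
    harmonics=HARMONICS,
) -> pd.DataFrame:
    """Simulate subject-level complex components directly.

    This is the coefficient-stage shortcut for statistics calibration and
    power studies: each subject x condition x channel x harmonic component
    is (condition mean) + (subject intercept) + isotropic complex Gaussian
    noise with per-component sd ``noise_sd`` (the residual scatter left
    after cycle- and trial-level coherent averaging).  Returns the tidy
    subject-level component table the stats layer consumes.
    """
    spec = spec or StimulusSpec()
    rng = np.random.default_rng(seed)
    freqs = harmonic_frequencies(spec)
    subjects = design.subjects
    conds = design.conditions()
    H = len(harmonics)
    sd_i = topography.subject_intercept_sd
    intercepts = sd_i * (
        rng.standard_normal((len(subjects), n_channels, H))
        + 1j * rng.standard_normal((len(subjects), n_channels, H))
    )
    means = {
        cond: topography.mean_responses(
            *cond, harmonics=harmonics, n_channels=n_channels
        )
        for cond in conds
    }
    rows = []
    for si, subj in enumerate(subjects):
        for pattern, speed in conds:
            z = (
                means[(pattern, speed)]
                + intercepts[si]
                + noise_sd * (
                    rng.standard_normal((n_channels, H))
                    + 1j * rng.standard_normal((n_channels, H))
                )
            )
            for j, h in enumerate(harmonics):
                rows.append(
                    pd.DataFrame(
                        {
                            "subject": subj,
                            "pattern": pattern,
                            "speed": speed,
                            "channel": np.arange(1, n_channels + 1),
                            "harmonic": h,
                            "freq_hz": freqs[h],
                            "re": z[:, j].real,
                            "im": z[:, j].imag,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Recording container I/O: columnar array + JSON sidecar
# ---------------------------------------------------------------------------

def save_recording(directory, recording: EEGRecording, name: str | None = None):
    """Write one trial as <name>.npy (channels x time) + <name>.json sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if name is None:
        name = (
            f"{recording.subject or 'subject'}_{recording.pattern}_"
            f"{recording.speed}_t{recording.trial or 0}"
        )
    np.save(directory / f"{name}.npy", recording.samples)
    sidecar = {
        "sampling_rate": recording.sampling_rate,
        "t0": recording.t0,
        "pattern": recording.pattern,
        "speed": recording.speed,
        "subject": recording.subject,
        "trial": recording.trial,
        "meta": recording.meta,
        "ground_truth": None
        if recording.ground_truth is None
        else {
            h: {"re": v.real.tolist(), "im": v.imag.tolist()}
            for h, v in recording.ground_truth.items()
        },
    }
    (directory / f"{name}.json").write_text(json.dumps(sidecar))
    return directory / f"{name}.npy"


def load_recording(directory, name: str) -> EEGRecording:
    directory = Path(directory)
    samples = np.load(directory / f"{name}.npy")
    sidecar = json.loads((directory / f"{name}.json").read_text())
    truth = sidecar.pop("ground_truth", None)
    if truth is not None:
        truth = {
            h: np.array(v["re"]) + 1j * np.array(v["im"])
            for h, v in truth.items()
        }
    return EEGRecording(samples=samples, ground_truth=truth, **sidecar)
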