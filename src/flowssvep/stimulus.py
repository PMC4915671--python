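"""Limited-lifetime random-dot optic-flow displays.

The display alternates between a globally coherent phase (all dots follow one
of three flow patterns: radial expansion/contraction, rotation, translation)
and a globally incoherent phase (each dot takes a fresh uniform-random
direction on every update), at a coherence-modulation frequency ``f1``
(default 1.2 Hz, i.e. an 833 ms on/off cycle with 417 ms halves).  Dot
positions update at ``f2 = refresh_rate / updates_per_refresh_divisor``
(72 Hz / 3 = 24 Hz), and the direction of coherent motion reverses every
other cycle (0.6 Hz) to limit adaptation.

Dots live in an annulus (24 deg outer / 4.8 deg inner diameter), are
repositioned after a maximum lifetime of 100 updates, and an additional 1%
cohort is repositioned on each update on a fixed round-robin schedule so that
dot deaths are staggered and no dot survives past the maximum lifetime.

Coordinates are screen-centered degrees of visual angle, x rightward,
y upward; angles follow math convention (counter-clockwise positive).
Kinematics are continuous — pixel geometry is treated as display metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
import pandas as pd

__all__ = [
    "Pattern",
    "StimulusSpec",
    "DotField",
    "Schedule",
    "coherent_direction",
    "init_field",
    "build_schedule",
    "step_dots",
    "simulate_trial",
]

Pattern = Literal["radial", "rotation", "translation"]
_PATTERNS = ("radial", "rotation", "translation")


@dataclass(frozen=True)
class StimulusSpec:
    """Parametric description of one optic-flow display condition.

    Defaults reproduce the study conditions; ``pattern`` and ``speed`` select
    one of the nine pattern x speed cells.
    """

    pattern: Pattern = "radial"
    speed: float = 8.0                       # deg/s, one of {2, 4, 8}
    refresh_rate: float = 72.0               # Hz
    updates_per_refresh_divisor: int = 3     # dot update every 3 refreshes
    f1: float = 1.2                          # coherence modulation, Hz
    annulus_outer_diameter: float = 24.0     # deg
    annulus_inner_diameter: float = 4.8      # deg
    dot_diameter: float = 0.12               # deg (7 arcmin)
    dot_density: float = 7.35                # dots / deg^2
    max_lifetime: int = 100                  # dot updates
    reposition_fraction: float = 0.01        # fixed-schedule cohort per update
    cycles_per_trial: int = 10
    dot_luminance: float = 79.4              # cd/m^2, metadata only
    background_luminance: float = 6.0        # cd/m^2, metadata only
    coherent_first: bool = True              # phase order within a cycle

    def __post_init__(self) -> None:
        if self.pattern not in _PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.dot_density <= 0:
            raise ValueError("dot density must be positive")
        if not self.annulus_inner_diameter < self.annulus_outer_diameter:
            raise ValueError("inner diameter must be smaller than outer")
        if self.cycles_per_trial < 1:
            raise ValueError("cycles_per_trial must be >= 1")
        if self.f1 <= 0 or self.refresh_rate <= 0:
            raise ValueError("frequencies must be positive")
        fpc = self.f2 / self.f1
        if abs(fpc - round(fpc)) > 1e-9:
            raise ValueError(
                f"update rate {self.f2} Hz is not an integer multiple of "
                f"f1 = {self.f1} Hz; frames per cycle would be {fpc}"
            )

    # ---- derived quantities -------------------------------------------------
    @property
    def f2(self) -> float:
        """Dot update rate in Hz (refresh rate / update divisor)."""
        return self.refresh_rate / self.updates_per_refresh_divisor

    @property
    def reversal_frequency(self) -> float:
        """Direction-reversal rate: one flip per full coherence cycle."""
        return self.f1 / 2.0

    @property
    def outer_radius(self) -> float:
        return self.annulus_outer_diameter / 2.0

    @property
    def inner_radius(self) -> float:
        return self.annulus_inner_diameter / 2.0

    @property
    def annulus_area(self) -> float:
        """Annulus area in deg^2."""
        return float(np.pi * (self.outer_radius**2 - self.inner_radius**2))

    @property
    def n_dots(self) -> int:
        """Dot count: density x annulus area, rounded to an integer."""
        return int(round(self.dot_density * self.annulus_area))

    @property
    def frames_per_cycle(self) -> int:
        return int(round(self.f2 / self.f1))

    @property
    def frames_per_trial(self) -> int:
        return self.cycles_per_trial * self.frames_per_cycle

    @property
    def displacement_per_update(self) -> float:
        """Per-update dot displacement magnitude, deg (speed / f2)."""
        return self.speed / self.f2

    @property
    def trial_duration(self) -> float:
        """Trial length in seconds (cycles_per_trial / f1)."""
        return self.cycles_per_trial / self.f1


@dataclass
class DotField:
    """The dot population at one update frame.

    ``repositioned`` records which dots were re-seeded by the *previous*
    :func:`step_dots` call (lifetime expiry, the fixed 1% cohort, or exit
    from the annulus); it is diagnostic only.
    """

    xy: np.ndarray                 # (n, 2) deg, screen-centered
    ages: np.ndarray               # (n,) updates since (re)birth
    rng: np.random.Generator
    update_index: int = 0
    repositioned: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_dots(self) -> int:
        return self.xy.shape[0]

    def radii(self) -> np.ndarray:
        return np.hypot(self.xy[:, 0], self.xy[:, 1])


@dataclass(frozen=True)
class Schedule:
    """Per-update-frame coherence phase and coherent-motion direction sign."""

    coherent: np.ndarray        # (F,) bool
    direction_sign: np.ndarray  # (F,) int, +1 / -1
    frame_time: np.ndarray      # (F,) s from trial onset

    def __len__(self) -> int:
        return self.coherent.shape[0]

    def __iter__(self) -> Iterator[tuple[bool, int, float]]:
        for c, s, t in zip(self.coherent, self.direction_sign, self.frame_time):
            yield bool(c), int(s), float(t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "time_s": self.frame_time,
                "phase": np.where(self.coherent, "coherent", "incoherent"),
                "direction_sign": self.direction_sign,
            }
        )


def coherent_direction(
    pattern: Pattern, direction_sign: int, position: np.ndarray
) -> np.ndarray:
    """Unit motion direction at ``position`` during the coherent phase.

    radial: +/- the radial unit vector (positive sign = expansion, outward);
    rotation: +/- the tangent (positive sign = counter-clockwise);
    translation: +/- (1, 0), independent of position.

    ``position`` may be a single (2,) point or an (n, 2) array.
    """
    pos = np.asarray(position, dtype=float)
    single = pos.ndim == 1
    pos = np.atleast_2d(pos)
    if pattern == "translation":
        out = np.zeros_like(pos)
        out[:, 0] = float(direction_sign)
        return out[0] if single else out
    r = np.hypot(pos[:, 0], pos[:, 1])
    if np.any(r == 0):
        raise ValueError(
            f"direction of {pattern} flow is undefined at the exact center"
        )
    radial_unit = pos / r[:, None]
    if pattern == "radial":
        out = direction_sign * radial_unit
    elif pattern == "rotation":
        # CCW tangent at (x, y) is (-y, x)/r
        out = direction_sign * np.column_stack(
            (-radial_unit[:, 1], radial_unit[:, 0])
        )
    else:  # pragma: no cover - guarded by StimulusSpec
        raise ValueError(f"unknown pattern {pattern!r}")
    return out[0] if single else out


def _uniform_annulus(
    n: int, inner: float, outer: float, rng: np.random.Generator
) -> np.ndarray:
    """n points uniform by area over the annulus inner <= r <= outer."""
    u = rng.random(n)
    r = np.sqrt(inner**2 + u * (outer**2 - inner**2))
    theta = rng.random(n) * 2 * np.pi
    return np.column_stack((r * np.cos(theta), r * np.sin(theta)))


def init_field(spec: StimulusSpec, seed: int | np.random.SeedSequence) -> DotField:
    """Create the initial dot population.

    Positions are uniform over the annulus; ages are initialized uniformly on
    ``[0, max_lifetime)`` so lifetime expiries are staggered across updates.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_dots
    if n < 1:
        raise ValueError("dot density too low: zero dots")
    xy = _uniform_annulus(n, spec.inner_radius, spec.outer_radius, rng)
    ages = rng.integers(0, spec.max_lifetime, size=n)
    return DotField(xy=xy, ages=ages, rng=rng)


def build_schedule(spec: StimulusSpec) -> Schedule:
    """Coherence/direction schedule for one trial.

    Each f1 cycle consists of one coherent and one incoherent half (order set
    by ``spec.coherent_first``); the coherent-motion direction sign is
    constant within a cycle and flips on the next, i.e. reverses at
    ``spec.reversal_frequency``.
    """
    fpc = spec.frames_per_cycle
    half = fpc // 2
    if fpc % 2:
        raise ValueError("frames per cycle must be even to split into halves")
    one_cycle = np.zeros(fpc, dtype=bool)
    if spec.coherent_first:
        one_cycle[:half] = True
    else:
        one_cycle[half:] = True
    coherent = np.tile(one_cycle, spec.cycles_per_trial)
    cycle_idx = np.repeat(np.arange(spec.cycles_per_trial), fpc)
    direction_sign = np.where(cycle_idx % 2 == 0, 1, -1)
    frame_time = np.arange(spec.frames_per_trial) / spec.f2
    return Schedule(coherent, direction_sign, frame_time)


def step_dots(
    field: DotField,
    spec: StimulusSpec,
    coherent: bool,
    direction_sign: int,
) -> DotField:
    """Advance the dot field by one update frame.

    Every dot moves by exactly ``spec.displacement_per_update`` along its
    direction: the analytic flow field during the coherent phase, a fresh
    uniform-random direction per dot during the incoherent phase.  Dots are
    then repositioned uniformly within the annulus (with age reset) if they
    (a) left the annulus, (b) reached the maximum lifetime, or (c) fall in
    this update's fixed-schedule 1% cohort (round-robin over dot indices,
    ``floor(0.01 n)`` dots per update).
    """
    rng = field.rng
    n = field.n_dots
    if coherent:
        direction = coherent_direction(spec.pattern, direction_sign, field.xy)
    else:
        theta = rng.random(n) * 2 * np.pi
        direction = np.column_stack((np.cos(theta), np.sin(theta)))
    xy = field.xy + spec.displacement_per_update * direction
    ages = field.ages + 1

    r = np.hypot(xy[:, 0], xy[:, 1])
    out_of_annulus = (r < spec.inner_radius) | (r > spec.outer_radius)
    expired = ages >= spec.max_lifetime
    m = int(np.floor(spec.reposition_fraction * n))
    cohort = np.zeros(n, dtype=bool)
    if m > 0:
        idx = (field.update_index * m + np.arange(m)) % n
        cohort[idx] = True
    reposition = out_of_annulus | expired | cohort
    k = int(reposition.sum())
    if k:
        xy[reposition] = _uniform_annulus(
            k, spec.inner_radius, spec.outer_radius, rng
        )
        ages[reposition] = 0
    return DotField(
        xy=xy,
        ages=ages,
        rng=rng,
        update_index=field.update_index + 1,
        repositioned=reposition,
    )


def simulate_trial(
    spec: StimulusSpec,
    seed: int | np.random.SeedSequence,
    trial: int = 0,
) -> pd.DataFrame:
    """Simulate one trial and return the full dot trajectory.

    Columns: trial, frame, time_s, phase, direction_sign, dot_id, x_deg,
    y_deg — the trajectory-export layout.  With a fixed seed the output is
    bit-identical across runs.
    """
    field_state = init_field(spec, seed)
    schedule = build_schedule(spec)
    frames = []
    n = field_state.n_dots
    dot_id = np.arange(n)
    for f, (coherent, sign, t) in enumerate(schedule):
        frames.append(
            pd.DataFrame(
                {
                    "trial": trial,
                    "frame": f,
                    "time_s": t,
                    "phase": "coherent" if coherent else "incoherent",
                    "direction_sign": sign,
                    "dot_id": dot_id,
                    "x_deg": field_state.xy[:, 0],
                    "y_deg": field_state.xy[:, 1],
                }
            )
        )
        field_state = step_dots(field_state, spec, coherent, sign)
    return pd.concat(frames, ignore_index=True)
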