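"""128-channel sensor layout for topographic plots and channel groups.

The layout is a schematic head diagram approximating a 128-channel geodesic
sensor net: channels on concentric rings inside the unit circle, x toward the
right ear, y toward the nose.  It is generated deterministically in code (and
round-trips through CSV); it is a plotting schematic, not a scalp-accurate
digitization.  A handful of channels carry 10-20 analogue labels (e.g. index
75 as the Oz analogue) matching the conventional correspondence for this net.

Channel groups used by the synthetic-effect presets are derived from the
layout coordinates: a right-lateral group (pattern-selective responses at the
first coherence harmonic cluster over right lateral sites) and a posterior
midline group (speed-selective responses at the third harmonic and the dot
update rate cluster over the midline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ChannelMap",
    "hydrocel_like_layout",
    "right_lateral_group",
    "midline_posterior_group",
]

N_CHANNELS = 128

# ring sizes sum to 128; radii grow outward
_RING_SIZES = (4, 8, 12, 16, 20, 24, 26, 18)
_RING_RADII = (0.12, 0.25, 0.38, 0.51, 0.64, 0.77, 0.90, 1.0)

# 10-20 analogue anchors: channel index -> schematic position (x right, y nose)
_ANCHORS = {
    75: (0.00, -0.95, "Oz"),
    70: (-0.33, -0.88, "O1"),
    83: (0.33, -0.88, "O2"),
    65: (-0.62, -0.72, "PO7"),
    90: (0.62, -0.72, "PO8"),
    62: (0.00, -0.55, "Pz"),
    11: (0.00, 0.55, "Fz"),
}


@dataclass(frozen=True)
class ChannelMap:
    """Channel indices 1-128 with 2D schematic coordinates and labels."""

    frame: pd.DataFrame  # index: channel (1..128); columns: x, y, label

    def __post_init__(self) -> None:
        idx = self.frame.index.to_numpy()
        if sorted(idx.tolist()) != list(range(1, N_CHANNELS + 1)):
            raise ValueError("channel map must cover indices 1..128 exactly once")
        if not np.all(np.isfinite(self.frame[["x", "y"]].to_numpy())):
            raise ValueError("channel coordinates must be finite")

    @property
    def channels(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    def coords(self, channel: int | np.ndarray) -> np.ndarray:
        return self.frame.loc[channel, ["x", "y"]].to_numpy(dtype=float)

    def label(self, channel: int) -> str:
        return str(self.frame.loc[channel, "label"])

    def to_csv(self, path) -> None:
        out = self.frame.reset_index().rename(columns={"index": "channel"})
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ChannelMap":
        df = pd.read_csv(path)
        df["label"] = df["label"].fillna("")
        return cls(df.set_index("channel")[["x", "y", "label"]])


def _ring_positions() -> np.ndarray:
    pts = []
    for ring, (size, radius) in enumerate(zip(_RING_SIZES, _RING_RADII)):
        # stagger ring start angles; begin at the front (+y) and go clockwise
        offset = np.pi / 2 + (np.pi / size) * (ring % 2)
        ang = offset - 2 * np.pi * np.arange(size) / size
        pts.append(np.column_stack((radius * np.cos(ang), radius * np.sin(ang))))
    return np.vstack(pts)


def hydrocel_like_layout() -> ChannelMap:
    """Deterministic schematic 128-channel layout.

    Anchor channels are assigned to the ring position nearest their canonical
    10-20 analogue location; remaining indices fill the remaining positions in
    angular order (front, clockwise), outer rings first.
    """
    pts = _ring_positions()
    n = pts.shape[0]
    assert n == N_CHANNELS
    assigned = np.full(n, -1, dtype=int)  # position -> channel index
    used_pos = np.zeros(n, dtype=bool)
    for ch, (ax, ay, _) in sorted(_ANCHORS.items()):
        d = np.hypot(pts[:, 0] - ax, pts[:, 1] - ay)
        d[used_pos] = np.inf
        pos = int(np.argmin(d))
        assigned[pos] = ch
        used_pos[pos] = True
    remaining_ch = [c for c in range(1, N_CHANNELS + 1) if c not in _ANCHORS]
    # deterministic fill order: by angle from +y clockwise, then radius
    ang = (np.pi / 2 - np.arctan2(pts[:, 1], pts[:, 0])) % (2 * np.pi)
    rad = np.hypot(pts[:, 0], pts[:, 1])
    order = np.lexsort((-rad, np.round(ang, 9)))
    free_pos = [p for p in order if not used_pos[p]]
    for ch, pos in zip(remaining_ch, free_pos):
        assigned[pos] = ch
    labels = {ch: lab for ch, (_, _, lab) in _ANCHORS.items()}
    df = pd.DataFrame(
        {
            "channel": assigned,
            "x": pts[:, 0],
            "y": pts[:, 1],
            "label": [labels.get(c, "") for c in assigned],
        }
    ).sort_values("channel")
    return ChannelMap(df.set_index("channel")[["x", "y", "label"]])


def _nearest(cm: ChannelMap, target: tuple[float, float], k: int,
             x_weight: float = 1.0) -> np.ndarray:
    xy = cm.frame[["x", "y"]].to_numpy()
    d = np.hypot(x_weight * (xy[:, 0] - target[0]), xy[:, 1] - target[1])
    order = np.lexsort((cm.channels, np.round(d, 12)))
    return np.sort(cm.channels[order[:k]])


def right_lateral_group(cm: ChannelMap, k: int = 11) -> np.ndarray:
    """k channels clustered over the right lateral scalp (sorted indices)."""
    return _nearest(cm, (0.85, -0.05), k)


def midline_posterior_group(cm: ChannelMap, k: int = 12) -> np.ndarray:
    """k channels clustered around the posterior midline (sorted indices).

    |x| is weighted double so the group hugs the midline.
    """
    return _nearest(cm, (0.0, -0.55), k, x_weight=2.0)
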