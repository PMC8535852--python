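"""Speed profiles of the computerized running wheel.

A recording session is an ordered sequence of constant-speed blocks.  The
standard paradigm holds each speed for 2 minutes: the ascending session runs
0, 15, 30, 45, 60 mm/s followed by a final rest block, and the descending
session starts at rest, jumps to 60 mm/s and steps back down to rest.  The
:class:`SpeedProfile` is the experiment clock shared by every downstream
stage: it knows block boundaries, speed-transition times, and how to convert
between seconds and frame indices at any sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpeedProfile", "gen_speed_profile"]

#: Wheel speeds (mm/s) of the standard ascending session, one 2-min block each.
ASCENDING_SPEEDS = (0.0, 15.0, 30.0, 45.0, 60.0, 0.0)
#: Wheel speeds of the standard descending session.
DESCENDING_SPEEDS = (0.0, 60.0, 45.0, 30.0, 15.0, 0.0)
#: Standard block duration in seconds (2 minutes per speed).
DEFAULT_BLOCK_S = 120.0


@dataclass(frozen=True)
class SpeedProfile:
    """Ordered constant-speed blocks with derived transition times.

    Parameters
    ----------
    speeds
        Wheel speed of each block in mm/s, in temporal order.
    block_duration_s
        Duration of every block in seconds.
    """

    speeds: tuple[float, ...]
    block_duration_s: float = DEFAULT_BLOCK_S

    def __post_init__(self) -> None:
        if len(self.speeds) == 0:
            raise ValueError("speed profile needs at least one block")
        if any(s < 0 for s in self.speeds):
            raise ValueError("wheel speeds must be nonnegative")
        if self.block_duration_s <= 0:
            raise ValueError("block_duration_s must be positive")
        object.__setattr__(self, "speeds", tuple(float(s) for s in self.speeds))

    @property
    def n_blocks(self) -> int:
        return len(self.speeds)

    @property
    def total_duration_s(self) -> float:
        return self.n_blocks * self.block_duration_s

    @property
    def block_starts_s(self) -> np.ndarray:
        return np.arange(self.n_blocks) * self.block_duration_s

    @property
    def transition_times_s(self) -> np.ndarray:
        """Times (s) of block boundaries where the speed actually changes."""
        speeds = np.asarray(self.speeds)
        change = np.nonzero(np.diff(speeds) != 0)[0]
        return (change + 1) * self.block_duration_s

    @property
    def n_transitions(self) -> int:
        return len(self.transition_times_s)

    @property
    def increasing_transition_times_s(self) -> np.ndarray:
        """Boundaries where the wheel speeds up (e.g. 0->15 or 0->60)."""
        speeds = np.asarray(self.speeds)
        up = np.nonzero(np.diff(speeds) > 0)[0]
        return (up + 1) * self.block_duration_s

    def transition_speeds(self) -> list[tuple[float, float]]:
        """(speed before, speed after) for each transition, in order."""
        speeds = np.asarray(self.speeds)
        change = np.nonzero(np.diff(speeds) != 0)[0]
        return [(speeds[i], speeds[i + 1]) for i in change]

    def n_frames(self, frame_rate: float) -> int:
        return int(round(self.total_duration_s * frame_rate))

    def transition_frames(self, frame_rate: float) -> np.ndarray:
        return np.round(self.transition_times_s * frame_rate).astype(int)

    def block_slices(self, frame_rate: float) -> list[slice]:
        """Frame-index slice of each block at the given sampling rate."""
        edges = np.round(
            np.arange(self.n_blocks + 1) * self.block_duration_s * frame_rate
        ).astype(int)
        return [slice(edges[i], edges[i + 1]) for i in range(self.n_blocks)]

    def block_of_frame(self, frame: int, frame_rate: float) -> int:
        """Block index containing ``frame``; raises if out of range."""
        for i, sl in enumerate(self.block_slices(frame_rate)):
            if sl.start <= frame < sl.stop:
                return i
        raise IndexError(f"frame {frame} outside the {self.n_frames(frame_rate)}-frame profile")

    @classmethod
    def ascending(cls, block_duration_s: float = DEFAULT_BLOCK_S) -> "SpeedProfile":
        return cls(ASCENDING_SPEEDS, block_duration_s)

    @classmethod
    def descending(cls, block_duration_s: float = DEFAULT_BLOCK_S) -> "SpeedProfile":
        return cls(DESCENDING_SPEEDS, block_duration_s)


def gen_speed_profile(
    block_duration_s: float = DEFAULT_BLOCK_S,
    speeds: tuple[float, ...] | list[float] = ASCENDING_SPEEDS,
) -> SpeedProfile:
    """Build a :class:`SpeedProfile` from block duration and speed sequence."""
    return SpeedProfile(tuple(speeds), block_duration_s)
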