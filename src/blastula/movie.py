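"""Calibrated 4D multi-channel movie container with TIFF round-trip.

Axis order is ``(T, C, Z, Y, X)``; physical calibration is carried as a
voxel size in µm (x, y, z) and a frame interval in seconds.  Movies are
written as OME-TIFF plus a small JSON sidecar holding the calibration and
channel names, so the tables downstream never depend on TIFF metadata
quirks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class Movie:
    data: np.ndarray                       # (T, C, Z, Y, X), non-negative
    channel_names: tuple[str, ...]
    voxel_size_um: tuple[float, float, float]   # (x, y, z)
    frame_interval_s: float

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError("movie data must be 5-axis (T, C, Z, Y, X)")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names must match the channel axis")
        if self.frame_interval_s <= 0 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("calibration must be positive")
        if np.issubdtype(self.data.dtype, np.floating) and (self.data < 0).any():
            raise ValueError("intensities must be non-negative")

    # ------------------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def voxel_volume_um3(self) -> float:
        vx, vy, vz = self.voxel_size_um
        return vx * vy * vz

    def channel_index(self, channel) -> int:
        if isinstance(channel, (int, np.integer)):
            if not 0 <= channel < self.data.shape[1]:
                raise ValueError(f"channel index {channel} out of range")
            return int(channel)
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise ValueError(
                f"unknown channel {channel!r}; have {self.channel_names}") from None

    def volume(self, frame: int, channel) -> np.ndarray:
        """One (Z, Y, X) volume."""
        return self.data[frame, self.channel_index(channel)]

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, self.data, metadata={"axes": "TCZYX"})
        sidecar = {
            "channel_names": list(self.channel_names),
            "voxel_size_um": list(self.voxel_size_um),
            "frame_interval_s": self.frame_interval_s,
            "shape": list(self.data.shape),
        }
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, path) -> "Movie":
        path = Path(path)
        data = tifffile.imread(path)
        meta_path = path.with_suffix(path.suffix + ".json")
        with open(meta_path) as fh:
            meta = json.load(fh)
        data = data.reshape(meta["shape"])
        return cls(
            data=data,
            channel_names=tuple(meta["channel_names"]),
            voxel_size_um=tuple(meta["voxel_size_um"]),
            frame_interval_s=meta["frame_interval_s"],
        )
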