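"""Calibrated image containers shared by the generators and the quantification code.

A :class:`ZStack` is a two-channel confocal-like stack (nuclei + a second
marker channel) stored as independent 2D planes; a :class:`SectionImage` is a
single two-channel optical mid-section.  Both carry a per-pixel µm
calibration.  On disk a stack is a multi-page TIFF in channel-first page
order (all planes of channel 0, then all planes of channel 1) with a JSON
sidecar holding the calibration, which keeps the files readable by any TIFF
viewer without OME metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ZStack", "SectionImage", "read_zstack", "read_section"]


@dataclass
class ZStack:
    """Two-channel image stack with µm/px calibration.

    ``data`` has shape ``(2, n_planes, height, width)``; planes are treated
    as independent 2D sections.
    """

    data: np.ndarray
    pixel_size_um: float
    channel_names: tuple[str, str] = ("nuclei", "edu")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[0] != 2:
            raise ValueError("ZStack data must have shape (2, n_planes, H, W)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_planes(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return one channel as an ``(n_planes, H, W)`` array."""
        if isinstance(name_or_index, str):
            idx = self.channel_names.index(name_or_index)
        else:
            idx = int(name_or_index)
        return self.data[idx]

    def write(self, tiff_path: str | Path) -> None:
        """Write channel-first TIFF pages plus a ``.json`` sidecar."""
        tiff_path = Path(tiff_path)
        pages = self.data.reshape(-1, *self.data.shape[2:])
        tifffile.imwrite(tiff_path, pages.astype(np.float32),
                         photometric="minisblack")
        sidecar = {
            "pixel_size_um": float(self.pixel_size_um),
            "n_channels": 2,
            "n_planes": int(self.n_planes),
            "channel_names": list(self.channel_names),
        }
        tiff_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


@dataclass
class SectionImage:
    """Single two-channel optical section, shape ``(2, H, W)``."""

    data: np.ndarray
    pixel_size_um: float
    channel_names: tuple[str, str] = ("gata4", "oct4")
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or self.data.shape[0] != 2:
            raise ValueError("SectionImage data must have shape (2, H, W)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    def channel(self, name_or_index: str | int) -> np.ndarray:
        if isinstance(name_or_index, str):
            idx = self.channel_names.index(name_or_index)
        else:
            idx = int(name_or_index)
        return self.data[idx]

    def write(self, tiff_path: str | Path) -> None:
        tiff_path = Path(tiff_path)
        tifffile.imwrite(tiff_path, self.data.astype(np.float32),
                         photometric="minisblack")
        sidecar = {
            "pixel_size_um": float(self.pixel_size_um),
            "n_channels": 2,
            "n_planes": 1,
            "channel_names": list(self.channel_names),
        }
        tiff_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def _read_sidecar(tiff_path: Path) -> dict:
    sidecar_path = tiff_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"calibration sidecar not found: {sidecar_path}")
    return json.loads(sidecar_path.read_text())


def read_zstack(tiff_path: str | Path) -> ZStack:
    """Read a channel-first two-channel TIFF stack and its JSON sidecar."""
    tiff_path = Path(tiff_path)
    meta = _read_sidecar(tiff_path)
    pages = tifffile.imread(tiff_path)
    n_planes = int(meta["n_planes"])
    data = np.asarray(pages).reshape(2, n_planes, *pages.shape[-2:])
    return ZStack(
        data=data,
        pixel_size_um=float(meta["pixel_size_um"]),
        channel_names=tuple(meta.get("channel_names", ("nuclei", "edu"))),
    )


def read_section(tiff_path: str | Path) -> SectionImage:
    tiff_path = Path(tiff_path)
    meta = _read_sidecar(tiff_path)
    pages = np.asarray(tifffile.imread(tiff_path))
    data = pages.reshape(2, *pages.shape[-2:])
    return SectionImage(
        data=data,
        pixel_size_um=float(meta["pixel_size_um"]),
        channel_names=tuple(meta.get("channel_names", ("gata4", "oct4"))),
    )
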