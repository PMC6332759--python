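"""Multi-page TIFF reading and writing for volumes, masks, and time series.

Internally volumes are indexed ``[ix, iy, iz]``; TIFF pages are (z, y, x),
so axes are transposed on the way in and out. Voxel sizes are supplied by
the caller (confocal metadata conventions vary too much to guess).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

__all__ = ["read_stack", "write_stack", "write_mask"]


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF into an ``[ix, iy, iz]`` float array."""
    pages = tifffile.imread(str(path))
    if pages.ndim == 2:
        pages = pages[None, ...]
    return np.ascontiguousarray(np.transpose(pages, (2, 1, 0)).astype(float))


def write_stack(volume: np.ndarray, path: str | Path) -> None:
    """Write an ``[ix, iy, iz]`` volume as a multi-page float32 TIFF."""
    pages = np.transpose(np.asarray(volume), (2, 1, 0)).astype(np.float32)
    tifffile.imwrite(str(path), pages, photometric="minisblack")


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit multi-page TIFF (255 = foreground)."""
    pages = np.transpose(np.asarray(mask, dtype=bool), (2, 1, 0))
    tifffile.imwrite(str(path), (pages * np.uint8(255)), photometric="minisblack")
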