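"""Reading and writing angiogram images, masks and their JSON sidecars.

Images travel as 16-bit grayscale TIFF (or PNG); binary masks as 8-bit
{0, 255} PNG; scan metadata (field of view, grid size, generator config) as a
JSON sidecar.  Intensities are stored as integer counts so a write/read
round-trip is exact.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .angiogram import EnFaceAngiogram

__all__ = [
    "MetadataError",
    "write_image",
    "read_image",
    "write_mask",
    "read_mask",
    "read_angiogram",
]

DEFAULT_FOV_MM = 6.0


class MetadataError(RuntimeError):
    """A required JSON sidecar is missing or unusable."""


def write_image(path: Path | str, angio: EnFaceAngiogram) -> None:
    """Write intensities as 16-bit grayscale TIFF/PNG (clipped, rounded)."""
    path = Path(path)
    arr = np.rint(np.clip(angio.intensities, 0, 65535)).astype(np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_image(path: Path | str) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    return np.asarray(arr)


def write_mask(path: Path | str, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit {0, 255} image."""
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def read_mask(path: Path | str) -> np.ndarray:
    return read_image(path) > 0


def _sidecar_candidates(image_path: Path) -> list[Path]:
    return [image_path.with_suffix(".json"), image_path.parent / "scene.json"]


def read_angiogram(
    path: Path | str, fov_mm: float | None = None, require_sidecar: bool = False
) -> EnFaceAngiogram:
    """Load an en-face image together with its field-of-view metadata.

    The field of view is taken, in order of precedence, from the explicit
    ``fov_mm`` argument, a ``<stem>.json`` sidecar next to the image, or a
    ``scene.json`` in the same directory.  When none is available the scan is
    assumed to be the default 6.0 mm protocol (with a warning), unless
    ``require_sidecar`` is set, in which case a :class:`MetadataError` is
    raised.
    """
    path = Path(path)
    arr = read_image(path).astype(np.float64)
    if fov_mm is None:
        for cand in _sidecar_candidates(path):
            if cand.exists():
                meta = json.loads(cand.read_text())
                try:
                    fov_mm = float(meta["fov_mm"])
                except (KeyError, TypeError, ValueError) as exc:
                    raise MetadataError(f"sidecar {cand} lacks a usable 'fov_mm'") from exc
                break
    if fov_mm is None:
        if require_sidecar:
            raise MetadataError(
                f"no JSON sidecar with 'fov_mm' found for {path} "
                f"(looked for {[str(c) for c in _sidecar_candidates(path)]})"
            )
        warnings.warn(
            f"no sidecar metadata for {path}; assuming fov_mm={DEFAULT_FOV_MM}",
            stacklevel=2,
        )
        fov_mm = DEFAULT_FOV_MM
    return EnFaceAngiogram(intensities=arr, fov_mm=fov_mm)
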