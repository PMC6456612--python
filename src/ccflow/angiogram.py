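"""En-face angiogram container.

An en-face OCTA angiogram is a square, single-channel intensity grid obtained
by projecting the decorrelation (flow) signal over a depth slab.  The physical
scan geometry matters downstream because the Gaussian smoothing kernel is
specified in micrometres: a 6.0 mm field sampled at 304 A-scans gives
6000/304 ~ 19.74 um per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EnFaceAngiogram"]


@dataclass(frozen=True)
class EnFaceAngiogram:
    """A square en-face flow image plus its physical field of view.

    Parameters
    ----------
    intensities
        ``(N, N)`` array of finite, non-negative flow intensities.  Stored as
        ``float64`` regardless of the source bit depth; the adaptive
        threshold downstream is shift/scale covariant, so no normalisation is
        applied.
    fov_mm
        Physical width (= height) of the scan in millimetres.  Default 6.0,
        the macular scan protocol this package targets.
    """

    intensities: np.ndarray
    fov_mm: float = 6.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"intensities must be 2-D, got ndim={arr.ndim}")
        if arr.shape[0] != arr.shape[1]:
            raise ValueError(f"en-face grid must be square, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities contain non-finite values")
        if np.any(arr < 0):
            raise ValueError("intensities must be non-negative")
        if not (self.fov_mm > 0):
            raise ValueError(f"fov_mm must be positive, got {self.fov_mm}")
        object.__setattr__(self, "intensities", arr)

    @property
    def grid_size(self) -> int:
        return self.intensities.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    @property
    def um_per_px(self) -> float:
        """Micrometres per pixel: 1000 * fov_mm / grid width."""
        return 1000.0 * self.fov_mm / self.intensities.shape[1]

    def with_intensities(self, intensities: np.ndarray) -> "EnFaceAngiogram":
        """Same geometry, new pixel values."""
        return EnFaceAngiogram(intensities=intensities, fov_mm=self.fov_mm)
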