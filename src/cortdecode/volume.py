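"""4D BOLD volume container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VolumeTimeSeries"]


@dataclass(frozen=True)
class VolumeTimeSeries:
    """A 4D BOLD run: (X, Y, Z, T) data, voxel-to-world affine, TR.

    The affine follows the NIfTI convention: it maps 0-based voxel indices
    to world millimetre coordinates.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float
    session: int = 1
    run: int = 1

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (X, Y, Z, T)")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape
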