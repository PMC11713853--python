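"""Acquisition grid and hybrid image stack containers.

Conventions used throughout the package:

* rows of a pixel matrix index echo time (TE, ms), columns index the
  diffusion weighting (b-value, s/mm^2);
* a :class:`HybridStack` stores the signal as a 5-D array with shape
  ``(X, Y, Z, M, N)`` where ``M = len(tes)`` and ``N = len(bvalues)``;
* on disk the TE/b axes are flattened TE-major into the 4th NIfTI dimension
  (index ``i * N + j`` holds TE ``i``, b-value ``j``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["AcquisitionGrid", "HybridStack"]


@dataclass(frozen=True)
class AcquisitionGrid:
    """The TE x b sampling grid of a hybrid acquisition.

    Parameters
    ----------
    tes
        Echo times in milliseconds, strictly increasing, all positive.
    bvalues
        Diffusion weightings in s/mm^2, strictly increasing, all
        non-negative (b = 0 is the unweighted spin-echo image).
    """

    tes: tuple[float, ...]
    bvalues: tuple[float, ...]

    def __post_init__(self) -> None:
        tes = tuple(float(t) for t in self.tes)
        bvalues = tuple(float(b) for b in self.bvalues)
        object.__setattr__(self, "tes", tes)
        object.__setattr__(self, "bvalues", bvalues)
        if len(tes) < 2:
            raise ValueError(f"need at least 2 echo times, got {len(tes)}")
        if len(bvalues) < 2:
            raise ValueError(f"need at least 2 b-values, got {len(bvalues)}")
        if any(t <= 0 for t in tes):
            raise ValueError(f"echo times must be positive: {tes}")
        if any(b < 0 for b in bvalues):
            raise ValueError(f"b-values must be non-negative: {bvalues}")
        if any(a >= b for a, b in zip(tes, tes[1:])):
            raise ValueError(f"echo times must be strictly increasing: {tes}")
        if any(a >= b for a, b in zip(bvalues, bvalues[1:])):
            raise ValueError(f"b-values must be strictly increasing: {bvalues}")

    @property
    def m(self) -> int:
        """Number of echo times (matrix rows)."""
        return len(self.tes)

    @property
    def n(self) -> int:
        """Number of b-values (matrix columns)."""
        return len(self.bvalues)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.m, self.n)

    def subset(self, keep_tes, keep_bs) -> "AcquisitionGrid":
        """Return the sub-grid restricted to the given TE / b-value subsets."""
        missing_t = [t for t in keep_tes if t not in self.tes]
        if missing_t:
            raise ValueError(
                f"echo times {missing_t} not in grid; available: {list(self.tes)}"
            )
        missing_b = [b for b in keep_bs if b not in self.bvalues]
        if missing_b:
            raise ValueError(
                f"b-values {missing_b} not in grid; available: {list(self.bvalues)}"
            )
        tes = tuple(t for t in self.tes if t in set(keep_tes))
        bs = tuple(b for b in self.bvalues if b in set(keep_bs))
        return AcquisitionGrid(tes, bs)


@dataclass
class HybridStack:
    """A 4-D hybrid MRI acquisition: one TE x b signal matrix per pixel.

    Attributes
    ----------
    signal
        Array of shape ``(X, Y, Z, M, N)``; arbitrary scanner units.
    grid
        The :class:`AcquisitionGrid` matching the trailing two axes.
    masks
        Optional named binary ROI masks, each of shape ``(X, Y, Z)``.
    """

    signal: np.ndarray
    grid: AcquisitionGrid
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 5:
            raise ValueError(
                f"signal must be 5-D (X, Y, Z, M, N), got shape {self.signal.shape}"
            )
        if self.signal.shape[3:] != self.grid.shape:
            raise ValueError(
                f"signal TE/b axes {self.signal.shape[3:]} do not match "
                f"grid shape {self.grid.shape}"
            )
        for name, mask in self.masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.spatial_shape:
                raise ValueError(
                    f"mask {name!r} shape {mask.shape} does not match "
                    f"spatial shape {self.spatial_shape}"
                )
            self.masks[name] = mask

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    def pixel(self, x: int, y: int, z: int = 0) -> np.ndarray:
        """The M x N signal matrix at one pixel."""
        return self.signal[x, y, z]

    def subset(self, keep_tes, keep_bs) -> "HybridStack":
        """Restrict the stack to a sub-grid (used by grid harmonization)."""
        sub = self.grid.subset(keep_tes, keep_bs)
        ti = [self.grid.tes.index(t) for t in sub.tes]
        bi = [self.grid.bvalues.index(b) for b in sub.bvalues]
        sig = self.signal[:, :, :, ti][:, :, :, :, bi]
        return replace(self, signal=sig, grid=sub, masks=dict(self.masks))
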