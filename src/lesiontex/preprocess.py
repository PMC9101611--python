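"""Intensity normalization and gray-level quantization.

Each ROI is normalized to its own mean +/- 3 standard deviations of optical
density and requantized to ``Ng`` gray levels.  This per-ROI windowing makes
the texture statistics invariant to global brightness and contrast shifts
(an affine rescaling of intensities changes neither the window position in
units of sigma nor the resulting level array), so ROIs from differently
exposed photographs share a common level scale.

The mapping is

    level(v) = clamp(1 + floor((v - (mu - 3 sigma)) / (6 sigma) * Ng), 1, Ng)

with population (divide-by-N) sigma over all ROI pixels.  Values at or
below ``mu - 3 sigma`` clamp to level 1, at or above ``mu + 3 sigma`` to
level ``Ng``.  A constant ROI (sigma = 0) maps every pixel to the mid
level ``round((Ng + 1) / 2)`` (half-up), so constant images stay constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lesiontex.imaging_io import ROI, GroupLabel, Lighting


@dataclass(frozen=True)
class QuantizedROI:
    """ROI after mu +/- 3 sigma windowing and gray-level reduction.

    Attributes
    ----------
    levels
        ``(side, side)`` integer array with values in ``[1, Ng]``.
    ng
        Number of gray levels.
    mu, sigma
        Mean and population standard deviation of the raw ROI intensities;
        recorded so the window is reproducible.
    """

    levels: np.ndarray
    ng: int
    mu: float
    sigma: float
    origin: tuple[int, int] = (0, 0)
    source_id: str = ""
    lighting: Lighting = Lighting.POLARIZED
    group_label: GroupLabel = GroupLabel.UNKNOWN

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if lv.ndim != 2 or lv.size == 0:
            raise ValueError("levels must be a nonempty 2-D array")
        if self.ng < 2:
            raise ValueError(f"Ng must be >= 2, got {self.ng}")
        if lv.min() < 1 or lv.max() > self.ng:
            raise ValueError("levels out of range [1, Ng]")
        if not (np.isfinite(self.mu) and np.isfinite(self.sigma) and self.sigma >= 0):
            raise ValueError("mu/sigma must be finite with sigma >= 0")
        object.__setattr__(self, "levels", lv.astype(np.int64))

    @property
    def side(self) -> int:
        return self.levels.shape[0]


def normalize_and_quantize(roi: ROI | np.ndarray, ng: int = 64) -> QuantizedROI:
    """Window an ROI to mu +/- 3 sigma and quantize to ``ng`` levels.

    Parameters
    ----------
    roi
        An :class:`~lesiontex.imaging_io.ROI`, or a bare 2-D array (then
        provenance fields are left at their defaults).
    ng
        Gray-level count, default 64.

    Returns
    -------
    QuantizedROI
        Levels in ``[1, ng]``; deterministic for a given input.
    """
    if ng < 2:
        raise ValueError(f"Ng must be >= 2, got {ng}")
    if isinstance(roi, ROI):
        pixels = roi.pixels
        prov = dict(
            origin=roi.origin,
            source_id=roi.source_id,
            lighting=roi.lighting,
            group_label=roi.group_label,
        )
    else:
        pixels = np.asarray(roi)
        if pixels.ndim != 2 or pixels.size == 0:
            raise ValueError("ROI must be a nonempty 2-D array")
        prov = {}
    v = pixels.astype(np.float64)
    mu = float(v.mean())
    sigma = float(v.std())  # population sigma: whole-ROI density statistic
    if sigma == 0.0:
        mid = int(np.floor((ng + 1) / 2 + 0.5))
        levels = np.full(v.shape, mid, dtype=np.int64)
    else:
        lo = mu - 3.0 * sigma
        levels = 1 + np.floor((v - lo) / (6.0 * sigma) * ng).astype(np.int64)
        np.clip(levels, 1, ng, out=levels)
    return QuantizedROI(levels, ng=ng, mu=mu, sigma=sigma, **prov)
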