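"""Synthetic lesion-like ROI textures.

The study images behind the texture statistics are not publicly deposited,
so this module generates 450x450 8-bit grayscale ROIs whose *statistical*
structure carries the same signals the analysis targets:

1. a Gaussian random field (white noise smoothed at ``correlation_length``)
   models the quasi-regular pigment pattern of nevi -- longer correlation
   means smoother texture, longer runs of equal gray level and a more
   concentrated co-occurrence distribution;
2. uniformly dark elliptical patches model the solid black areas of
   advanced lesions; their intensity sits below the mu - 3 sigma window
   edge, so they quantize to level 1 and produce the long-run signal;
3. in non-polarized mode, surface reflection is modelled by compressing
   the subsurface field's contrast and adding bright glare blobs, which
   masks the class differences carried by the fine texture while the gross
   dark patches remain visible -- reproducing the weaker group separation
   seen without cross-polarization;
4. Gaussian pixel noise, clamping to [0, 255].

Class presets (``PRESETS``) are calibration artifacts: parameter values
chosen so that a 166-ROI-per-group cohort reproduces the qualitative
benign / dysplastic / melanoma feature orderings, not measurements of real
lesions.  Per-ROI lognormal jitter of the correlation length provides the
within-group heterogeneity of real cohorts.

Seeding is hierarchical: each cohort image derives its seed from
``(base_seed, class index, lighting index, image index)`` via
``numpy.random.SeedSequence``, so any single image can be regenerated
without the rest of the cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from lesiontex.imaging_io import (
    METADATA_COLUMNS,
    GroupLabel,
    Lighting,
    ROI,
    save_image,
)

__all__ = [
    "GeneratorParams",
    "PRESETS",
    "class_preset",
    "generate_roi",
    "iter_cohort",
    "generate_cohort",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Full parameter set of one synthetic ROI.

    Attributes
    ----------
    correlation_length
        Gaussian smoothing sigma (pixels) of the base random field; 0
        leaves the field as white noise.
    correlation_jitter
        Sigma of a per-ROI lognormal factor on ``correlation_length``
        (within-group heterogeneity); 0 disables.
    base_mean, base_sd
        Intensity mean and SD of the rescaled base field (8-bit units).
    patch_count, patch_radius_range, patch_darkness
        Dark uniform ellipses: count, semi-axis range (pixels) and drop
        below ``base_mean``; each patch is stamped at the constant value
        ``base_mean - patch_darkness`` (+-10% jitter), deep enough to fall
        below the mu - 3 sigma quantization window.
    glare_count, glare_amplitude, glare_sigma
        Specular-highlight blobs, used only in non-polarized mode.
    contrast_compression
        Multiplier (< 1 in non-polarized mode) on the base field's
        deviations from its mean, applied before noise; models surface
        reflection washing out subsurface detail.
    noise_sd
        Gaussian pixel noise sigma (8-bit units).
    noise_jitter
        Sigma of a per-ROI lognormal factor on ``noise_sd`` (exposure /
        illumination variability between photographs); 0 disables.
    """

    class_label: GroupLabel = GroupLabel.UNKNOWN
    lighting: Lighting = Lighting.POLARIZED
    side: int = 450
    correlation_length: float = 2.0
    correlation_jitter: float = 0.0
    base_mean: float = 150.0
    base_sd: float = 22.0
    patch_count: int = 0
    patch_radius_range: tuple[float, float] = (6.0, 14.0)
    patch_darkness: float = 120.0
    glare_count: int = 0
    glare_amplitude: float = 0.0
    glare_sigma: float = 14.0
    contrast_compression: float = 1.0
    noise_sd: float = 5.0
    noise_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side < 64:
            raise ValueError(f"side must be >= 64, got {self.side}")
        if self.correlation_length < 0:
            raise ValueError("correlation_length must be >= 0")
        if self.patch_count < 0 or self.glare_count < 0:
            raise ValueError("counts must be >= 0")
        if not 0 < self.contrast_compression <= 1:
            raise ValueError("contrast_compression must be in (0, 1]")


# Calibration artifacts: frozen preset parameters per (group, lighting).
#
# Polarized presets separate the classes through both the correlation
# length of the fine pigment texture and the dark-patch load (count, size
# and depth all increase from benign to melanoma).
#
# Non-polarized presets model the masking effect of surface reflection:
# all classes share one correlation length (the fine-texture differences
# are invisible through glare), BN and DN are identical, and the melanoma
# signal is purely morphological -- the same total pigmented area arranged
# as 2 large structureless blotches instead of ~23 small globules.  Equal
# dark area keeps the intensity window (and hence both entropies) matched
# across groups while the blotch geometry still drives long-run emphasis;
# glare blobs, contrast compression and per-ROI exposure jitter supply the
# higher within-group variance of non-polarized photography.
PRESETS: dict[tuple[GroupLabel, Lighting], dict] = {
    (GroupLabel.BN, Lighting.POLARIZED): dict(
        correlation_length=1.6, correlation_jitter=0.25,
        patch_count=3, patch_radius_range=(4.0, 10.0), patch_darkness=115.0,
    ),
    (GroupLabel.DN, Lighting.POLARIZED): dict(
        correlation_length=2.2, correlation_jitter=0.25,
        patch_count=6, patch_radius_range=(6.0, 14.0), patch_darkness=120.0,
    ),
    (GroupLabel.MM, Lighting.POLARIZED): dict(
        correlation_length=3.0, correlation_jitter=0.25,
        patch_count=12, patch_radius_range=(8.0, 22.0), patch_darkness=125.0,
    ),
    (GroupLabel.BN, Lighting.NONPOLARIZED): dict(
        correlation_length=2.0, correlation_jitter=0.3,
        patch_count=12, patch_radius_range=(4.5, 7.5), patch_darkness=85.0,
        glare_count=8, glare_amplitude=70.0, glare_sigma=14.0,
        contrast_compression=0.55, noise_jitter=0.2,
    ),
    (GroupLabel.DN, Lighting.NONPOLARIZED): dict(
        correlation_length=2.0, correlation_jitter=0.3,
        patch_count=12, patch_radius_range=(4.5, 7.5), patch_darkness=85.0,
        glare_count=8, glare_amplitude=70.0, glare_sigma=14.0,
        contrast_compression=0.55, noise_jitter=0.2,
    ),
    (GroupLabel.MM, Lighting.NONPOLARIZED): dict(
        correlation_length=2.0, correlation_jitter=0.3,
        patch_count=2, patch_radius_range=(14.0, 20.5), patch_darkness=68.0,
        glare_count=8, glare_amplitude=70.0, glare_sigma=14.0,
        contrast_compression=0.55, noise_jitter=0.2,
    ),
}


def class_preset(
    class_label: GroupLabel | str,
    lighting: Lighting | str,
    side: int = 450,
    seed: int = 0,
) -> GeneratorParams:
    """The frozen calibration preset for one (lesion group, lighting) cell."""
    key = (GroupLabel(class_label), Lighting(lighting))
    if key not in PRESETS:
        raise KeyError(f"no preset for {key}")
    return GeneratorParams(
        class_label=key[0], lighting=key[1], side=side, seed=seed, **PRESETS[key]
    )


def _ellipse_mask(
    side: int, center: tuple[float, float], radii: tuple[float, float], angle: float
) -> np.ndarray:
    rr, cc = np.mgrid[0:side, 0:side]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / radii[0]) ** 2 + (v / radii[1]) ** 2 <= 1.0


def generate_roi(params: GeneratorParams) -> ROI:
    """Render one synthetic ROI; bit-identical for identical params."""
    rng = np.random.default_rng(params.seed)
    side = params.side

    corr = params.correlation_length
    if params.correlation_jitter > 0:
        corr *= float(rng.lognormal(0.0, params.correlation_jitter))

    base = rng.standard_normal((side, side))
    if corr > 0:
        base = gaussian_filter(base, sigma=corr, mode="reflect")
    sd = base.std()
    if sd > 0:
        base = (base - base.mean()) / sd
    field = params.base_mean + params.base_sd * base

    # surface-reflection masking of subsurface detail (non-polarized mode)
    if params.contrast_compression < 1.0:
        field = params.base_mean + params.contrast_compression * (field - params.base_mean)

    # dark uniform patches: stamped after compression so pigment-dense
    # areas stay dark under either illumination
    lo, hi = params.patch_radius_range
    for _ in range(params.patch_count):
        center = rng.uniform(0, side, size=2)
        radii = rng.uniform(lo, hi, size=2)
        angle = rng.uniform(0, np.pi)
        value = params.base_mean - params.patch_darkness * rng.uniform(0.9, 1.1)
        field[_ellipse_mask(side, tuple(center), tuple(radii), angle)] = value

    if params.glare_count > 0 and params.glare_amplitude > 0:
        rr, cc = np.mgrid[0:side, 0:side]
        for _ in range(params.glare_count):
            center = rng.uniform(0, side, size=2)
            amp = params.glare_amplitude * rng.uniform(0.7, 1.3)
            g2 = 2.0 * params.glare_sigma**2
            field = field + amp * np.exp(
                -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / g2
            )

    if params.noise_sd > 0:
        noise_sd = params.noise_sd
        if params.noise_jitter > 0:
            noise_sd *= float(rng.lognormal(0.0, params.noise_jitter))
        field = field + rng.normal(0.0, noise_sd, size=field.shape)

    pixels = np.clip(np.floor(field + 0.5), 0, 255).astype(np.uint8)
    if pixels.min() == pixels.max():
        warnings.warn(
            "generated ROI is fully saturated/constant; parameters degenerate",
            stacklevel=2,
        )
    return ROI(
        pixels,
        origin=(0, 0),
        source_id=f"synthetic_{params.class_label.value}_{params.lighting.value}_{params.seed}",
        lighting=params.lighting,
        group_label=params.class_label,
    )


_CLASSES = (GroupLabel.BN, GroupLabel.DN, GroupLabel.MM)
_LIGHTINGS = (Lighting.POLARIZED, Lighting.NONPOLARIZED)


def _derived_seed(base_seed: int, class_idx: int, light_idx: int, index: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), class_idx, light_idx, index])
    return int(ss.generate_state(1)[0])


def iter_cohort(
    n_per_group: int,
    base_seed: int,
    lighting_modes: Sequence[Lighting | str] = _LIGHTINGS,
    classes: Sequence[GroupLabel | str] = _CLASSES,
    side: int = 450,
) -> Iterator[tuple[str, ROI]]:
    """Yield ``(roi_id, ROI)`` for a full synthetic cohort, in memory.

    Iteration order is class-major then lighting then index; every image's
    seed is derived hierarchically from ``base_seed`` so the cohort is
    reproducible piecewise.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    classes = [GroupLabel(c) for c in classes]
    lighting_modes = [Lighting(l) for l in lighting_modes]
    for ci, cls in enumerate(classes):
        for li, light in enumerate(lighting_modes):
            light_idx = list(_LIGHTINGS).index(light)
            class_idx = list(_CLASSES).index(cls)
            for i in range(n_per_group):
                seed = _derived_seed(base_seed, class_idx, light_idx, i)
                params = class_preset(cls, light, side=side, seed=seed)
                roi_id = f"{cls.value}_{light.value}_{i:03d}"
                yield roi_id, replace(generate_roi(params), source_id=roi_id)


def generate_cohort(
    out_dir: str | Path,
    n_per_group: int = 166,
    base_seed: int = 0,
    lighting_modes: Sequence[Lighting | str] = _LIGHTINGS,
    classes: Sequence[GroupLabel | str] = _CLASSES,
    side: int = 450,
) -> pd.DataFrame:
    """Write a synthetic cohort as PNGs plus a metadata CSV.

    Produces ``n_per_group`` images per class per lighting mode under
    ``out_dir/images/`` and ``out_dir/metadata.csv`` in the ROI-metadata
    schema; returns the metadata table.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    try:
        img_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {img_dir}: {exc}") from exc
    rows = []
    for roi_id, roi in iter_cohort(
        n_per_group, base_seed, lighting_modes=lighting_modes, classes=classes, side=side
    ):
        rel = f"images/{roi_id}.png"
        save_image(roi, out_dir / rel)
        rows.append(
            {
                "source_path": rel,
                "source_id": roi_id,
                "lighting": roi.lighting.value,
                "group_label": roi.group_label.value,
                "roi_row": 0,
                "roi_col": 0,
                "roi_side": side,
            }
        )
    meta = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    meta.to_csv(out_dir / "metadata.csv", index=False)
    return meta
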