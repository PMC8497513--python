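"""Synthetic two-channel nuclear images with known ground truth.

These generators emulate the statistical structure of the live-cell
acquisitions the imaging metrics are designed for — an elliptical nucleus
with excluded nucleoli and an inactive-X region, smooth microscopy-like
texture (low-pass-filtered white noise), channel pairs with a prescribed
Pearson correlation, images with a prescribed inactive-X partition
coefficient, and condensation time series whose pixel variance rises while
condensates nucleate and either relaxes or persists after dissolution.

They exist so every metric is testable end to end with no experimental
data; they do not model optics (PSF, camera noise) or photobleaching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .imaging import ChannelImage, RegionMasks

#: Intensity offset applied before emitting 16-bit-range images, so noisy
#: fields round-trip through unsigned integer TIFF without clipping.
INTENSITY_OFFSET = 1000.0
INTENSITY_SCALE = 2000.0


@dataclass
class SyntheticImageSpec:
    """Geometry and statistics of one synthetic nucleus image."""

    shape: tuple[int, int] = (256, 256)
    nucleus_axes: tuple[float, float] = (0.42, 0.36)  # fractions of the grid
    n_nucleoli: int = 2
    nucleolus_radius: float = 0.06
    xi_axes: tuple[float, float] | None = (0.08, 0.05)
    target_pcc: float = 0.7
    target_partition: float = 2.0
    n_spots: int = 30
    spot_radius: float = 2.5
    spot_intensity: float = 3.0
    noise_sd: float = 0.0
    smooth_sigma: float = 2.0  # correlation length of the random fields, px
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.target_pcc) > 1:
            raise ValueError("target_pcc must lie in [-1, 1]")
        if self.target_partition <= 0:
            raise ValueError("target_partition must be positive")
        if min(self.shape) < 8:
            raise ValueError("image too small")


@dataclass
class CondensationSeriesSpec:
    """Shape of a synthetic condensate-nucleation time series."""

    shape: tuple[int, int] = (128, 128)
    n_frames: int = 60
    activation_window: tuple[int, int] = (10, 35)
    growth_rate: float = 0.25
    chromatin_response_lag: int = 5
    persistence_after_off: bool = True
    n_spots: int = 25
    spot_sigma: float = 2.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.activation_window
        if not (0 <= lo <= hi <= self.n_frames):
            raise ValueError("activation_window must lie within [0, n_frames]")


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((yy - center[0]) / axes[0]) ** 2 + ((xx - center[1]) / axes[1]) ** 2 <= 1.0


def make_masks(spec: SyntheticImageSpec, rng: np.random.Generator) -> RegionMasks:
    """Elliptical nucleus with interior, mutually disjoint nucleoli and Xi."""
    h, w = spec.shape
    cy, cx = h / 2.0, w / 2.0
    ay = spec.nucleus_axes[0] * h
    ax = spec.nucleus_axes[1] * w
    nucleus = _ellipse_mask(spec.shape, (cy, cx), (ay, ax))

    nucleoli = np.zeros(spec.shape, dtype=bool)
    r = spec.nucleolus_radius * min(h, w)
    for _ in range(spec.n_nucleoli):
        for _attempt in range(100):
            theta = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.2, 0.6)
            c = (cy + rad * ay * np.sin(theta), cx + rad * ax * np.cos(theta))
            disk = _ellipse_mask(spec.shape, c, (r, r))
            if not np.any(disk & ~nucleus) and not np.any(disk & nucleoli):
                nucleoli |= disk
                break
        else:
            raise ValueError("could not place a nucleolus inside the nucleus")

    xi = np.zeros(spec.shape, dtype=bool)
    if spec.xi_axes is not None:
        bx = (spec.xi_axes[0] * h, spec.xi_axes[1] * w)
        for _attempt in range(200):
            theta = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.1, 0.55)
            c = (cy + rad * ay * np.sin(theta), cx + rad * ax * np.cos(theta))
            cand = _ellipse_mask(spec.shape, c, bx)
            if cand.any() and not np.any(cand & ~nucleus) and not np.any(cand & nucleoli):
                xi = cand
                break
        else:
            raise ValueError("could not place the inactive-X region")

    return RegionMasks(nucleus=nucleus, nucleoli=nucleoli, xi=xi)


def _smooth_field(shape, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance low-pass-filtered white noise."""
    f = gaussian_filter(rng.standard_normal(shape), sigma)
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def make_correlated_pair(
    spec: SyntheticImageSpec, rng: np.random.Generator
) -> tuple[ChannelImage, ChannelImage, RegionMasks]:
    """Two channels whose masked PCC is ``target_pcc`` in expectation.

    Built by Gaussian mixing: with independent smooth fields s and e,
    channel x = s and channel y = rho s + sqrt(1 - rho^2) e, then an
    affine offset/gain maps both into a non-negative 16-bit-style range
    (which leaves the correlation untouched).
    """
    rho = spec.target_pcc
    masks = make_masks(spec, rng)
    s = _smooth_field(spec.shape, spec.smooth_sigma, rng)
    e = _smooth_field(spec.shape, spec.smooth_sigma, rng)
    x = s
    y = rho * s + np.sqrt(max(0.0, 1.0 - rho * rho)) * e
    gain = INTENSITY_SCALE / 8.0
    xi_img = INTENSITY_OFFSET + gain * x
    yi_img = INTENSITY_OFFSET + gain * y
    return (
        ChannelImage(np.clip(xi_img, 0, None), label="channel_a"),
        ChannelImage(np.clip(yi_img, 0, None), label="channel_b"),
        masks,
    )


def make_partition_image(
    spec: SyntheticImageSpec, rng: np.random.Generator
) -> tuple[ChannelImage, RegionMasks]:
    """Image whose inactive-X mean is ``target_partition`` times the rest.

    Noise (if any) has identical statistics inside and outside the region,
    so the expected measured coefficient equals the target exactly.
    """
    masks = make_masks(spec, rng)
    base = np.zeros(spec.shape)
    base[masks.nucleus] = INTENSITY_OFFSET
    base[masks.xi] = INTENSITY_OFFSET * spec.target_partition
    if spec.noise_sd > 0:
        noise = rng.normal(scale=spec.noise_sd * INTENSITY_OFFSET, size=spec.shape)
        base = np.where(masks.nucleus, base + noise, base)
    return ChannelImage(np.clip(base, 0, None), label="partition"), masks


def _spot_field(shape, centers, sigma) -> np.ndarray:
    field_img = np.zeros(shape)
    for cy, cx in centers:
        field_img[int(cy) % shape[0], int(cx) % shape[1]] += 1.0
    return gaussian_filter(field_img, sigma) * (2 * np.pi * sigma**2)


def make_condensation_timeseries(
    spec: CondensationSeriesSpec, rng: np.random.Generator
) -> tuple[list[ChannelImage], list[ChannelImage], RegionMasks]:
    """Condensate and chromatin channel stacks with known variance shapes.

    The condensate channel grows bright spots during the activation window
    and dissolves them immediately after (fast rise, fast fall of pixel
    variance).  The chromatin channel develops spatial heterogeneity with a
    lag, as an integrated (history-dependent) response; if
    ``persistence_after_off`` it retains that heterogeneity to the final
    frame, otherwise it relaxes back.
    """
    img_spec = SyntheticImageSpec(
        shape=spec.shape, n_nucleoli=1, xi_axes=None, seed=spec.seed
    )
    masks = make_masks(img_spec, rng)
    inside = masks.nucleus & ~masks.nucleoli
    coords = np.argwhere(inside)
    centers = coords[rng.choice(len(coords), size=spec.n_spots, replace=False)]
    spots = _spot_field(spec.shape, centers, spec.spot_sigma)
    spots /= max(spots.max(), 1e-12)
    chrom_texture = _smooth_field(spec.shape, spec.spot_sigma, rng)

    lo, hi = spec.activation_window
    cond_amp = np.zeros(spec.n_frames)
    for f in range(lo, spec.n_frames):
        if f < hi:
            cond_amp[f] = 1.0 - np.exp(-spec.growth_rate * (f - lo + 1))
        else:
            cond_amp[f] = cond_amp[hi - 1] * np.exp(-0.8 * (f - hi + 1))

    # chromatin response: lagged, saturating integral of condensate presence
    chrom_amp = np.zeros(spec.n_frames)
    acc = 0.0
    for f in range(spec.n_frames):
        drive = cond_amp[max(0, f - spec.chromatin_response_lag)]
        acc += 0.15 * drive
        if spec.persistence_after_off:
            chrom_amp[f] = min(1.0, acc)
        else:
            chrom_amp[f] = cond_amp[max(0, f - spec.chromatin_response_lag)]

    cond_stack, chrom_stack = [], []
    for f in range(spec.n_frames):
        noise_c = spec.noise_sd * rng.standard_normal(spec.shape)
        noise_h = spec.noise_sd * rng.standard_normal(spec.shape)
        cond = INTENSITY_OFFSET * (1.0 + cond_amp[f] * spots + noise_c)
        chrom = INTENSITY_OFFSET * (1.0 + 0.6 * chrom_amp[f] * chrom_texture + noise_h)
        cond_stack.append(ChannelImage(np.clip(cond, 0, None), label="condensate"))
        chrom_stack.append(ChannelImage(np.clip(chrom, 0, None), label="chromatin"))
    return cond_stack, chrom_stack, masks
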