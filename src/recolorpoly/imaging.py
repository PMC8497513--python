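"""Quantitative imaging statistics for two-channel nuclear micrographs.

Implements the metrics used to quantify condensate formation and chromatin
compaction in live-cell data: the masked Pearson colocalization
coefficient, per-frame pixel-intensity variance (sample variance, n-1) and
its 0-1 normalized trace and time integral, the partition coefficient on
the inactive X-chromosome, mean-intensity (FRAP-style) region traces, and
phase-diagram assembly from per-cell concentration/valence records.

Segmentation is an input: metrics operate on boolean region masks
(nucleus, nucleoli, inactive X).  Which regions are excluded depends on
the analysis: colocalization excludes nucleoli and the inactive X (both
skew the correlation); co-expression and variance analyses exclude only
nucleoli.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid


@dataclass
class ChannelImage:
    """One grayscale channel: a 2-D non-negative intensity grid."""

    intensities: np.ndarray
    pixel_size: float = 1.0  # micrometres per pixel
    label: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D grid")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass
class RegionMasks:
    """Boolean region masks sharing the image grid.

    Invariants: nucleoli and the inactive X (``xi``) are subsets of the
    nucleus.
    """

    nucleus: np.ndarray
    nucleoli: np.ndarray | None = None
    xi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nucleus = np.asarray(self.nucleus, dtype=bool)
        if self.nucleoli is None:
            self.nucleoli = np.zeros_like(self.nucleus)
        if self.xi is None:
            self.xi = np.zeros_like(self.nucleus)
        self.nucleoli = np.asarray(self.nucleoli, dtype=bool)
        self.xi = np.asarray(self.xi, dtype=bool)
        if self.nucleoli.shape != self.nucleus.shape or self.xi.shape != self.nucleus.shape:
            raise ValueError("mask shapes differ")
        if np.any(self.nucleoli & ~self.nucleus):
            raise ValueError("nucleoli mask extends outside the nucleus")
        if np.any(self.xi & ~self.nucleus):
            raise ValueError("xi mask extends outside the nucleus")


@dataclass
class VarianceTrace:
    """Pixel-variance time series of one channel."""

    times: np.ndarray
    values: np.ndarray
    normalized: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(self.values < -1e-12):
            raise ValueError("variance values must be non-negative")
        if self.normalized and len(self.values):
            if not (
                abs(float(self.values.min())) < 1e-9
                and abs(float(self.values.max()) - 1.0) < 1e-9
            ):
                raise ValueError("normalized trace must span [0, 1]")


@dataclass
class CellPhaseRecord:
    """Per-cell phase-diagram entry: concentrations, valence and label.

    ``valence`` is the ratio of sspB-fused protein to ferritin core
    concentration; ``phase_separated`` is the (human) classification and
    may be None for cells excluded because observers disagreed.
    """

    core_conc: float
    sspb_conc: float
    phase_separated: bool | None
    cell_id: str = ""
    valence: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.core_conc <= 0 or self.sspb_conc <= 0:
            raise ValueError("concentrations must be positive")
        ratio = self.sspb_conc / self.core_conc
        if self.valence is None:
            self.valence = ratio
        elif not np.isclose(self.valence, ratio, rtol=1e-6):
            raise ValueError("valence inconsistent with sspb_conc / core_conc")


def analysis_mask(masks: RegionMasks, mode: str) -> np.ndarray:
    """Resolve which pixels enter an analysis.

    ``"colocalization"``: nucleus minus nucleoli minus inactive X;
    ``"coexpression"``: nucleus minus nucleoli (the inactive X stays in);
    ``"variance"``: nucleus minus nucleoli.
    """
    if mode == "colocalization":
        out = masks.nucleus & ~masks.nucleoli & ~masks.xi
    elif mode in ("coexpression", "variance"):
        out = masks.nucleus & ~masks.nucleoli
    else:
        raise ValueError(f"unknown analysis mode {mode!r}")
    if not out.any():
        raise ValueError(f"analysis mask for mode {mode!r} is empty")
    return out


def pearson_cc(x: ChannelImage, y: ChannelImage, mask: np.ndarray) -> float:
    """Masked pixel-by-pixel Pearson correlation coefficient.

    PCC = sum (x_i - xbar)(y_i - ybar) / sqrt(sum (x_i - xbar)^2) /
    sqrt(sum (y_i - ybar)^2), over the masked pixels only.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != x.shape or mask.shape != y.shape:
        raise ValueError("image and mask shapes differ")
    xv = x.intensities[mask]
    yv = y.intensities[mask]
    if xv.size < 2:
        raise ValueError("need at least 2 masked pixels")
    dx = xv - xv.mean()
    dy = yv - yv.mean()
    sx = float(np.sqrt(np.sum(dx * dx)))
    sy = float(np.sqrt(np.sum(dy * dy)))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined: a channel is constant in the mask")
    return float(np.sum(dx * dy) / (sx * sy))


def pixel_variance(img: ChannelImage, mask: np.ndarray) -> float:
    """Sample variance (denominator n-1) of masked pixel intensities."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError("image and mask shapes differ")
    vals = img.intensities[mask]
    if vals.size < 2:
        raise ValueError("need at least 2 masked pixels for a variance")
    return float(np.var(vals, ddof=1))


def variance_trace(
    stack: Sequence[ChannelImage],
    masks: RegionMasks | Sequence[RegionMasks],
    times: np.ndarray | None = None,
    label: str = "",
) -> VarianceTrace:
    """Per-frame masked pixel variance of an image stack.

    ``masks`` may be a single RegionMasks (static segmentation) or one per
    frame; the variance mode (nucleus minus nucleoli) is applied per frame.
    """
    if times is None:
        times = np.arange(len(stack), dtype=float)
    if isinstance(masks, RegionMasks):
        masks = [masks] * len(stack)
    if len(masks) != len(stack):
        raise ValueError("need one mask (set) per frame")
    values = [
        pixel_variance(img, analysis_mask(m, "variance"))
        for img, m in zip(stack, masks)
    ]
    return VarianceTrace(times=np.asarray(times, dtype=float), values=np.array(values), label=label)


def normalize_trace(trace: VarianceTrace) -> VarianceTrace:
    """Min-max normalize a trace to span [0, 1]; idempotent."""
    v = trace.values
    if len(v) < 2:
        raise ValueError("need at least 2 points to normalize")
    lo = float(v.min())
    hi = float(v.max())
    if hi == lo:
        raise ValueError("normalization undefined for a constant trace")
    return VarianceTrace(
        times=trace.times.copy(),
        values=(v - lo) / (hi - lo),
        normalized=True,
        label=trace.label,
    )


def variance_integral(trace: VarianceTrace) -> VarianceTrace:
    """Cumulative trapezoidal time integral of a trace (starts at 0)."""
    t = trace.times
    if len(t) < 2:
        raise ValueError("need at least 2 points to integrate")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    integral = cumulative_trapezoid(trace.values, t, initial=0.0)
    return VarianceTrace(
        times=t.copy(), values=integral, normalized=False, label=trace.label
    )


def partition_coefficient(
    img: ChannelImage, xi_mask: np.ndarray, nucleus_mask: np.ndarray
) -> float:
    """Mean intensity on the inactive X over the mean elsewhere in the nucleus.

    A value of 1 means equal amounts of fluorescent protein on the inactive
    X and elsewhere; 2 means twice as much on the inactive X.
    """
    xi_mask = np.asarray(xi_mask, dtype=bool)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if xi_mask.shape != img.shape or nucleus_mask.shape != img.shape:
        raise ValueError("image and mask shapes differ")
    elsewhere = nucleus_mask & ~xi_mask
    if not xi_mask.any() or not elsewhere.any():
        raise ValueError("both regions must be non-empty")
    denom = float(img.intensities[elsewhere].mean())
    if denom == 0.0:
        raise ValueError("mean intensity outside the inactive X is zero")
    return float(img.intensities[xi_mask].mean()) / denom


def region_mean_trace(
    stack: Sequence[ChannelImage],
    region_mask: np.ndarray,
    times: np.ndarray | None = None,
) -> VarianceTrace:
    """Mean intensity in a fixed region per frame (FRAP recovery curves)."""
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("region mask is empty")
    if times is None:
        times = np.arange(len(stack), dtype=float)
    values = []
    for img in stack:
        if img.shape != region_mask.shape:
            raise ValueError("image and mask shapes differ")
        values.append(float(img.intensities[region_mask].mean()))
    return VarianceTrace(times=np.asarray(times, dtype=float), values=np.array(values))


def assemble_phase_diagram(records: Iterable[CellPhaseRecord]) -> pd.DataFrame:
    """Tabulate per-cell records for a concentration/valence phase diagram.

    Cells without a classification (observers disagreed) are dropped.
    Columns: cell_id, core_conc, sspb_conc, valence, phase_separated.
    """
    rows = [
        {
            "cell_id": r.cell_id,
            "core_conc": r.core_conc,
            "sspb_conc": r.sspb_conc,
            "valence": r.valence,
            "phase_separated": bool(r.phase_separated),
        }
        for r in records
        if r.phase_separated is not None
    ]
    return pd.DataFrame(
        rows, columns=["cell_id", "core_conc", "sspb_conc", "valence", "phase_separated"]
    )


def threshold_mask(img: ChannelImage, method: str = "otsu") -> np.ndarray:
    """Convenience intensity thresholder for synthetic images.

    Real segmentations are inputs; this helper exists only to produce quick
    masks on generated data.
    """
    from skimage.filters import threshold_otsu

    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    return img.intensities > threshold_otsu(img.intensities)
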