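"""Trajectory observables: Rg^2, local density, and replica aggregation.

The headline observable is the squared local chromatin density: for each
chromatin bead, the number of chromatin beads (itself included) within a
sphere of radius 2 sigma (60 nm) divided by that sphere's volume, averaged
over beads and then squared.  Its time evolution, averaged over replicas,
is the simulation analogue of the pixel-variance trace measured on images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels


@dataclass
class ObservableSeries:
    """Per-replica time series of the standard observables.

    ``rg2`` is the squared radius of gyration (sigma^2), ``mean_density``
    the spatial mean local density (sigma^-3), ``density_sq`` its square,
    ``n_ub`` the Ub-bearing bead count.
    """

    times: np.ndarray
    rg2: np.ndarray
    mean_density: np.ndarray
    density_sq: np.ndarray
    n_ub: np.ndarray
    replica_id: int | None = None

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("rg2", "mean_density", "density_sq", "n_ub"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from times")
        if np.any(self.mean_density < 0):
            raise ValueError("densities must be non-negative")
        if np.any(np.diff(self.n_ub) < 0):
            raise ValueError("n_ub must be non-decreasing")

    @classmethod
    def from_samples(cls, times, rg2, mean_density, n_ub, replica_id=None):
        mean_density = np.asarray(mean_density, dtype=float)
        return cls(
            times=np.asarray(times, dtype=float),
            rg2=np.asarray(rg2, dtype=float),
            mean_density=mean_density,
            density_sq=mean_density**2,
            n_ub=np.asarray(n_ub, dtype=np.int64),
            replica_id=replica_id,
        )

    def observable_names(self) -> tuple[str, ...]:
        return ("rg2", "mean_density", "density_sq", "n_ub")


@dataclass
class EnsembleSummary:
    """Pointwise mean and sample SD of each observable across replicas."""

    times: np.ndarray
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    n_replicas: int = 0


def radius_of_gyration_sq(positions: np.ndarray) -> float:
    """Squared radius of gyration (1/N) sum (r_i - r_CM)^2, in sigma^2.

    ``positions`` must be unwrapped coordinates.  The printed definition of
    the monitoring observable is this squared length; use
    :func:`radius_of_gyration` for its square root.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        raise ValueError("empty position array")
    d = pos - pos.mean(axis=0)
    return float(np.einsum("ij,ij->", d, d) / len(pos))


def radius_of_gyration(positions: np.ndarray) -> float:
    """Convenience square root of :func:`radius_of_gyration_sq`."""
    return float(np.sqrt(radius_of_gyration_sq(positions)))


def local_density(
    positions: np.ndarray, radius: float = 2.0, box_side: float = np.inf
) -> np.ndarray:
    """Per-bead local density in sigma^-3.

    For each bead, the number of beads within ``radius`` (minimum image;
    the central bead counts itself) divided by the volume of the sphere of
    that radius.  ``positions`` should be the *chromatin* coordinates;
    protein beads are excluded from the density by simply not passing them.
    """
    pos = np.ascontiguousarray(positions, dtype=np.float64)
    if pos.size == 0:
        raise ValueError("empty position array")
    if np.isfinite(box_side) and radius >= box_side / 2.0:
        raise ValueError("radius must be smaller than half the box side")
    box = box_side if np.isfinite(box_side) else 1e30
    counts = _kernels.local_density_counts(pos, box, radius)
    volume = 4.0 / 3.0 * np.pi * radius**3
    return counts / volume


def density_series(
    trajectory,
    radius: float = 2.0,
    square_mode: str = "square_of_mean",
) -> ObservableSeries:
    """Recompute the observable series from stored trajectory frames.

    ``square_mode`` selects whether ``density_sq`` is the square of the
    spatial mean density (default, one curve per replica) or the spatial
    mean of squared per-bead densities (``"mean_of_squares"``).
    """
    if len(trajectory) == 0:
        raise ValueError("trajectory has no frames")
    if square_mode not in ("square_of_mean", "mean_of_squares"):
        raise ValueError(f"unknown square_mode {square_mode!r}")
    times, rg2s, means, sqs, nubs = [], [], [], [], []
    nc = None
    for t, pos, img, states in trajectory.frames:
        nc = len(states)
        unwrapped = pos + img * trajectory.box_side
        times.append(t)
        rg2s.append(radius_of_gyration_sq(unwrapped[:nc]))
        dens = local_density(pos[:nc], radius=radius, box_side=trajectory.box_side)
        means.append(float(dens.mean()))
        sqs.append(
            float(dens.mean()) ** 2
            if square_mode == "square_of_mean"
            else float((dens**2).mean())
        )
        nubs.append(int(np.count_nonzero(states & 2)))
    return ObservableSeries(
        times=np.array(times),
        rg2=np.array(rg2s),
        mean_density=np.array(means),
        density_sq=np.array(sqs),
        n_ub=np.array(nubs, dtype=np.int64),
        replica_id=trajectory.seed,
    )


def aggregate_replicas(series_list) -> EnsembleSummary:
    """Pointwise mean and sample SD (ddof=1) across replicas."""
    if not series_list:
        raise ValueError("no series to aggregate")
    times = series_list[0].times
    for s in series_list[1:]:
        if len(s.times) != len(times) or not np.allclose(s.times, times):
            raise ValueError("replica series are not on a common sampling grid")
    summary = EnsembleSummary(times=times.copy(), n_replicas=len(series_list))
    for name in series_list[0].observable_names():
        stack = np.stack([np.asarray(getattr(s, name), dtype=float) for s in series_list])
        summary.mean[name] = stack.mean(axis=0)
        summary.sd[name] = (
            stack.std(axis=0, ddof=1)
            if len(series_list) > 1
            else np.zeros(len(times))
        )
    return summary


def bond_tangent_correlation(chain_positions_list, s_max: int = 10) -> np.ndarray:
    """Mean tangent-tangent correlation <t_i . t_{i+s}> for s = 0..s_max.

    ``chain_positions_list`` is an iterable of unwrapped (N, 3) chromatin
    coordinate snapshots; correlations are averaged over bond pairs and
    snapshots.
    """
    acc = np.zeros(s_max + 1)
    cnt = np.zeros(s_max + 1)
    for pos in chain_positions_list:
        bonds = np.diff(np.asarray(pos, dtype=float), axis=0)
        t = bonds / np.linalg.norm(bonds, axis=1, keepdims=True)
        nb = len(t)
        for s in range(min(s_max, nb - 1) + 1):
            dots = np.einsum("ij,ij->i", t[: nb - s], t[s:])
            acc[s] += dots.sum()
            cnt[s] += len(dots)
    if np.any(cnt == 0):
        raise ValueError("chain too short for the requested s_max")
    return acc / cnt


def fit_persistence_length(correlation: np.ndarray, spacing: float = 1.0) -> float:
    """Persistence length from an exponential fit of tangent correlations.

    Fits ``log C(s) = -s * spacing / l_p`` by least squares through the
    origin over the lags with positive correlation, and returns ``l_p`` in
    the units of ``spacing`` (sigma by default).
    """
    c = np.asarray(correlation, dtype=float)
    s = np.arange(len(c)) * spacing
    good = c > 0
    good[0] = True
    s = s[good][1:]
    logc = np.log(c[good][1:])
    if len(s) < 2:
        raise ValueError("not enough positive correlations to fit")
    slope = float(np.sum(s * logc) / np.sum(s * s))
    if slope >= 0:
        raise ValueError("tangent correlations do not decay")
    return -1.0 / slope
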