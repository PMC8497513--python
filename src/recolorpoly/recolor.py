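"""The epigenetic read-write state machine (recoloring Monte Carlo).

Proteins *read* H3K27me3 (they bind marked beads) and *write* H2AK119Ub:
every ``recolor_interval`` Brownian times a sweep of random bead selections
is attempted, and a selected bead acquires the Ub mark if a writer protein
sits within the writing radius (2 sigma = 60 nm).  Writing is irreversible
and never touches the K27me3 mark, so the Ub set only grows and the
K27me3-bearing count stays exactly ``n_marked`` for the whole run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import SimulationParams
from .potentials import minimum_image
from .states import EpigeneticState
from .system import Configuration


@dataclass
class RecolorEvent:
    """Record of one recoloring sweep."""

    time: float
    n_selected: int
    n_written: int
    indices_written: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    def __post_init__(self) -> None:
        if self.n_written > self.n_selected:
            raise ValueError("n_written cannot exceed n_selected")
        if self.n_written != len(self.indices_written):
            raise ValueError("n_written inconsistent with indices_written")


def mark_initial_states(
    params: SimulationParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw the initial state array: ``n_marked`` K27me3 beads in the window.

    Exactly ``n_marked`` chromatin beads with indices in
    ``[marked_lo, marked_hi)`` are set to K27ME3, chosen uniformly without
    replacement; all other beads are NEUTRAL.
    """
    window = params.marked_hi - params.marked_lo
    if params.n_marked > window:
        raise ValueError("marked window too small for n_marked")
    states = np.full(params.n_chromatin, EpigeneticState.NEUTRAL, dtype=np.uint8)
    chosen = rng.choice(window, size=params.n_marked, replace=False)
    states[params.marked_lo + chosen] = EpigeneticState.K27ME3
    return states


def _min_image_dist2(a: np.ndarray, b: np.ndarray, box: float) -> np.ndarray:
    """Squared minimum-image distances between rows of a (m,3) and b (k,3)."""
    d = minimum_image(a[:, None, :] - b[None, :, :], box)
    return np.einsum("ijk,ijk->ij", d, d)


def bound_protein_positions(
    config: Configuration, params: SimulationParams
) -> np.ndarray:
    """Indices (into the protein block) of proteins engaged with K27me3.

    A protein counts as bound when it lies within ``rc_attr`` (minimum
    image) of at least one K27me3-bearing bead.  This is the writer set
    under the default ``write_condition = "bound_protein"``.
    """
    prot = config.protein_positions()
    if len(prot) == 0:
        return np.empty(0, dtype=np.int64)
    marked = (config.states & 1).astype(bool)
    if not marked.any():
        return np.empty(0, dtype=np.int64)
    marked_pos = config.positions[: config.n_chromatin][marked]
    d2 = _min_image_dist2(prot, marked_pos, config.box_side)
    near = (d2 < params.rc_attr**2).any(axis=1)
    return np.nonzero(near)[0].astype(np.int64)


def recolor_sweep(
    config: Configuration,
    params: SimulationParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, RecolorEvent]:
    """One recoloring sweep: N random selections, write Ub near writers.

    Each of ``n_chromatin`` independent uniform selections (with
    replacement by default; a permutation sweep via
    ``params.sweep_mode = "permutation"``) ubiquitinates the selected bead
    iff a writer protein lies within ``recolor_radius`` (minimum image).
    NEUTRAL becomes UB, K27ME3 becomes K27ME3_UB; Ub-bearing beads are
    unchanged and K27me3 is never removed.  Returns the updated state
    array (a copy) and the event record.
    """
    n = config.n_chromatin
    if params.sweep_mode == "permutation":
        selected = rng.permutation(n)
    else:
        selected = rng.integers(0, n, size=n)

    if params.write_condition == "bound_protein":
        writer_idx = bound_protein_positions(config, params)
        writers = config.protein_positions()[writer_idx]
    else:
        writers = config.protein_positions()

    states = config.states.copy()
    if len(writers) > 0:
        candidates = np.unique(selected)
        candidates = candidates[(states[candidates] & 2) == 0]
        if len(candidates):
            d2 = _min_image_dist2(
                config.positions[candidates], writers, config.box_side
            )
            hit = (d2 < params.recolor_radius**2).any(axis=1)
            written = candidates[hit]
        else:
            written = np.empty(0, dtype=np.int64)
    else:
        written = np.empty(0, dtype=np.int64)

    states[written] |= 2
    event = RecolorEvent(
        time=config.time,
        n_selected=len(selected),
        n_written=len(written),
        indices_written=np.sort(written).astype(np.int64),
    )
    return states, event


def ub_fraction(states: np.ndarray) -> float:
    """Fraction of chromatin beads bearing the Ub mark."""
    states = np.asarray(states)
    if states.size == 0:
        raise ValueError("empty state array")
    return float(np.count_nonzero(states & 2)) / states.size


def ub_count(states: np.ndarray) -> int:
    """Number of chromatin beads bearing the Ub mark."""
    return int(np.count_nonzero(np.asarray(states) & 2))


def k27me3_count(states: np.ndarray) -> int:
    """Number of chromatin beads bearing the K27me3 mark (with or without Ub)."""
    return int(np.count_nonzero(np.asarray(states) & 1))
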