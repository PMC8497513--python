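"""Epigenetic bead states and the pair-interaction dispatch table.

Chromatin beads carry a "colour" encoding their histone-mark state.  Marked
(H3K27me3) beads recruit the protein bridges; ubiquitinated (H2AK119Ub)
beads attract one another.  The two marks are independent bits, which gives
four states; writing Ub never erases K27me3, so the only transitions ever
produced are NEUTRAL -> UB and K27ME3 -> K27ME3_UB.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Literal, Union

Species = Literal["chromatin", "protein"]

#: Species codes used in packed arrays.
CHROMATIN = 0
PROTEIN = 1


class EpigeneticState(IntEnum):
    """Histone-mark state of a chromatin bead (bit 0 = K27me3, bit 1 = Ub)."""

    NEUTRAL = 0
    K27ME3 = 1
    UB = 2
    K27ME3_UB = 3


StateLike = Union[EpigeneticState, int]


def bears_k27me3(state: StateLike) -> bool:
    """True if the bead carries the H3K27me3 (read) mark."""
    return bool(int(state) & 1)


def bears_ub(state: StateLike) -> bool:
    """True if the bead carries the H2AK119Ub (written) mark."""
    return bool(int(state) & 2)


def write_ub(state: StateLike) -> EpigeneticState:
    """Apply the writing rule: add the Ub mark, never remove anything."""
    return EpigeneticState(int(state) | 2)


@dataclass(frozen=True)
class PairInteraction:
    """Resolved non-bonded interaction between one pair of beads.

    ``kind`` is ``"wca"`` (purely repulsive, cutoff 2^(1/6) sigma),
    ``"lj_attractive"`` (truncated Lennard-Jones with well depth ``eps``)
    or ``"none"``.
    """

    kind: Literal["wca", "lj_attractive", "none"]
    eps: float
    rc: float


def pair_interaction_spec(
    species_i: Species,
    state_i: StateLike | None,
    species_j: Species,
    state_j: StateLike | None,
    params,
    binding_on: bool = True,
) -> PairInteraction:
    """Resolve which pair potential acts between two beads.

    Rules, symmetric in the two arguments:

    * protein x marked chromatin (K27ME3 or K27ME3_UB): attractive LJ with
      well depth ``eps_bind`` and cutoff ``rc_attr`` — this is the
      reader-domain binding, and it is switched off (downgraded to WCA)
      when ``binding_on`` is false, i.e. after the protocol terminates
      protein binding;
    * Ub-bearing chromatin x Ub-bearing chromatin: attractive LJ with well
      depth ``eps_ub`` and cutoff ``rc_attr`` — ubiquitinated regions stick
      to each other, and this self-attraction never switches off;
    * everything else (protein x protein, protein x neutral chromatin,
      any pair involving an unmarked bead): WCA excluded volume.
    """
    if species_i not in ("chromatin", "protein") or species_j not in (
        "chromatin",
        "protein",
    ):
        raise ValueError(f"unknown species pair ({species_i!r}, {species_j!r})")

    if species_i == "protein" and species_j == "chromatin":
        return pair_interaction_spec(
            species_j, state_j, species_i, state_i, params, binding_on
        )

    if species_i == "chromatin" and species_j == "protein":
        if binding_on and state_i is not None and bears_k27me3(state_i):
            return PairInteraction("lj_attractive", params.eps_bind, params.rc_attr)
        return PairInteraction("wca", 1.0, params.rc_wca)

    if species_i == "chromatin" and species_j == "chromatin":
        if (
            state_i is not None
            and state_j is not None
            and bears_ub(state_i)
            and bears_ub(state_j)
        ):
            return PairInteraction("lj_attractive", params.eps_ub, params.rc_attr)
        return PairInteraction("wca", 1.0, params.rc_wca)

    # protein x protein
    return PairInteraction("wca", 1.0, params.rc_wca)
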