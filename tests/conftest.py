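import numpy as np
import pytest

from recolorpoly import Configuration, SimulationParams
from recolorpoly.states import CHROMATIN, PROTEIN


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_test_config(
    n_chrom: int,
    n_prot: int,
    box: float,
    rng: np.random.Generator,
    params: SimulationParams | None = None,
    min_sep: float = 0.9,
) -> Configuration:
    """Random configuration with safe bond lengths and no extreme overlaps.

    The chain is laid as a mildly kinked walk with bonds ~0.97 sigma;
    proteins are placed at least ``min_sep`` from every other bead so that
    finite-difference force checks are not dominated by r^-12 curvature.
    """
    bonds = rng.normal(size=(n_chrom - 1, 3))
    bonds /= np.linalg.norm(bonds, axis=1, keepdims=True)
    # soften kinks so consecutive beads stay ~1 sigma apart but non-collinear
    for k in range(1, len(bonds)):
        bonds[k] = 0.6 * bonds[k - 1] + 0.4 * bonds[k]
        bonds[k] /= np.linalg.norm(bonds[k])
    chain = np.zeros((n_chrom, 3))
    chain[1:] = np.cumsum(0.97 * bonds, axis=0)
    chain += box / 2.0 - chain.mean(axis=0)

    prot = []
    attempts = 0
    while len(prot) < n_prot:
        cand = rng.uniform(0, box, size=3)
        pts = np.vstack([chain] + [np.asarray(prot)] if prot else [chain])
        d = pts - cand
        d -= box * np.round(d / box)
        if np.min(np.linalg.norm(d, axis=1)) > min_sep:
            prot.append(cand)
        attempts += 1
        if attempts > 2000:
            raise RuntimeError("could not place proteins")
    pos = np.vstack([chain] + ([np.asarray(prot)] if prot else []))
    species = np.concatenate(
        [np.full(n_chrom, CHROMATIN, np.uint8), np.full(n_prot, PROTEIN, np.uint8)]
    )
    states = np.zeros(n_chrom, dtype=np.uint8)
    return Configuration(
        positions=np.mod(pos, box),
        velocities=np.zeros((n_chrom + n_prot, 3)),
        species=species,
        states=states,
        box_side=box,
    )


@pytest.fixture
def small_params():
    return SimulationParams(
        n_chromatin=10,
        n_proteins=3,
        box_side=12.0,
        marked_lo=2,
        marked_hi=8,
        n_marked=3,
    )
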