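import numpy as np
import pytest

from ligfid import LigaseModel, PairCountMatrix
from ligfid.overhangs import OVERHANG_INDEX


@pytest.fixture
def uniform_model():
    """Watson-Crick-only, no weights, no annealing bias."""
    return LigaseModel(name="uniform")


@pytest.fixture
def gt_edge_model():
    """Only G:T mismatches at the edge are tolerated (tolerance 0.3)."""
    return LigaseModel(name="gt-edge", mismatch_tolerance={("G:T", "edge"): 0.3})


@pytest.fixture
def gc_biased_model():
    """WC-only with a positive annealing boost per G:C pair."""
    return LigaseModel(name="gc", anneal_coeff=0.5)


@pytest.fixture
def permissive_model():
    """Several tolerated mismatch types at both position classes."""
    return LigaseModel(
        name="permissive",
        anneal_coeff=0.2,
        mismatch_tolerance={
            ("G:T", "edge"): 0.30,
            ("G:T", "middle"): 0.08,
            ("G:A", "edge"): 0.15,
            ("G:G", "edge"): 0.12,
            ("C:T", "middle"): 0.03,
        },
    )


@pytest.fixture
def anneal_coupled_model():
    """Uniform tolerance for every mismatch type, with annealing-coupled
    mismatch acceptance (beta > 0): GC-rich pairs tolerate mismatches more."""
    from ligfid.overhangs import COMPLEMENT

    tol = {
        (f"{a}:{b}", cls): 0.1
        for a in "ACGT"
        for b in "ACGT"
        if COMPLEMENT[a] != b
        for cls in ("edge", "middle")
    }
    return LigaseModel(
        name="coupled",
        anneal_coeff=0.3,
        mismatch_tolerance=tol,
        mismatch_anneal_coeff=0.3,
    )


def matrix_from_pairs(pairs, metadata=None):
    """Build a dual-orientation count matrix from (top, bottom, n_products)."""
    counts = np.zeros((256, 256), dtype=np.int64)
    for top, bottom, n in pairs:
        counts[OVERHANG_INDEX[top], OVERHANG_INDEX[bottom]] += n
        counts[OVERHANG_INDEX[bottom], OVERHANG_INDEX[top]] += n
    return PairCountMatrix(counts=counts, metadata=metadata or {})


@pytest.fixture
def toy_matrix():
    """3 Watson-Crick products + 1 single-mismatch product (fidelity 0.75)."""
    return matrix_from_pairs(
        [("CTAT", "ATAG", 2), ("GTGA", "TCAC", 1), ("TGGA", "TCCG", 1)]
    )
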