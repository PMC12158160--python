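from __future__ import annotations

import numpy as np
import pytest

from isoenrich import AnnotationTable, IonAnnotation, SetCollection


@pytest.fixture
def unambiguous_table() -> AnnotationTable:
    """Every ion has exactly one candidate: bootstrapping has no effect."""
    return AnnotationTable(tuple(
        IonAnnotation(f"ion{i}", (f"M{i:02d}",)) for i in range(12)
    ))


@pytest.fixture
def unambiguous_sets(unambiguous_table) -> SetCollection:
    universe = [f"M{i:02d}" for i in range(40)]
    terms = {
        "hit": [f"M{i:02d}" for i in range(8)],         # mostly sampled
        "miss": [f"M{i:02d}" for i in range(30, 38)],   # never sampled
        "half": [f"M{i:02d}" for i in range(10, 18)],   # partially sampled
    }
    return SetCollection.build(terms, universe=universe)


def make_ambiguous_toy() -> tuple[AnnotationTable, SetCollection]:
    """Minority-candidate construction: term A is supported only as 1 of 4
    equal-weight candidates per ion (ambiguity score 0.25), term B is
    supported unambiguously, term C not at all.  Standard ORA calls both A
    and B; bootstrapping keeps only B."""
    termA = [f"A{i}" for i in range(8)]
    termB = [f"B{i}" for i in range(8)]
    termC = [f"C{i}" for i in range(8)]
    fillers = [f"F{i:02d}" for i in range(24)]
    pad = [f"P{i:02d}" for i in range(72)]
    universe = termA + termB + termC + fillers + pad
    ions = [IonAnnotation(f"b{i}", (termB[i],)) for i in range(8)]
    ions += [
        IonAnnotation(f"a{i}", (termA[i], *fillers[3 * i : 3 * i + 3]))
        for i in range(8)
    ]
    table = AnnotationTable(tuple(ions))
    sets = SetCollection.build({"A": termA, "B": termB, "C": termC}, universe=universe)
    return table, sets


@pytest.fixture
def ambiguous_toy():
    return make_ambiguous_toy()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
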