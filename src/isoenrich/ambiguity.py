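"""Per-term ambiguity score.

For a term, consider every ion with at least one candidate inside the term
("supporting" ions).  Each such ion contributes the fraction of its candidate
weight mass lying inside the term; the ambiguity score is the mean of those
fractions over supporting ions.  A score of 1 means every supporting ion
supports the term unambiguously; values below 0.5 flag terms whose apparent
enrichment rests on ambiguous candidates — exactly the terms that standard
ORA calls significant but bootstrapping suppresses.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

from .annotations import AnnotationTable, SetCollection, normalize_weights

__all__ = ["ambiguity_score", "collection_ambiguity"]


def ambiguity_score(term_members: Iterable[str], table: AnnotationTable) -> float:
    """Mean in-term candidate-mass fraction over the term's supporting ions.

    Raises if no ion supports the term at all.
    """
    members = frozenset(term_members)
    fractions: list[float] = []
    for ion in table:
        ion = normalize_weights(ion)
        in_mass = sum(w for c, w in zip(ion.candidates, ion.weights) if c in members)
        if any(c in members for c in ion.candidates):
            fractions.append(in_mass)
    if not fractions:
        raise ValueError("no ion supports this term")
    return float(sum(fractions) / len(fractions))


def collection_ambiguity(sets: SetCollection, table: AnnotationTable) -> dict[str, float]:
    """Ambiguity score per term; NaN for terms with no supporting ion."""
    out: dict[str, float] = {}
    for term, members in sets.terms.items():
        try:
            out[term] = ambiguity_score(members, table)
        except ValueError:
            out[term] = math.nan
    return out
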