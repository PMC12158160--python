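"""Synthetic annotation tables, set collections, and single-cell intensity
matrices with known ground truth.

The generator emulates the inputs of an imaging-MS enrichment study: a
molecular universe carved into disjoint terms, ions carrying ambiguous
candidate lists (tunable multiplicity), terms with planted overrepresentation
(a chosen fraction of each supporting ion's candidate mass lies in the term),
and a two-condition single-cell matrix in which the planted terms' ions are
intensity-shifted in the first condition — a stand-in for a perturbation
vs control contrast.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotations import AnnotationTable, IonAnnotation, SetCollection
from .msea import IntensityMatrix

__all__ = ["SimDesign", "SimTruth", "simulate_annotations", "simulate_matrix",
           "expected_intersection"]


@dataclass(frozen=True)
class SimDesign:
    """Design of a synthetic enrichment study.

    ``candidates_per_ion`` is either a fixed count or an inclusive
    ``(lo, hi)`` range sampled per ion.  ``planted_terms`` lists
    ``(term_name, enrichment_strength)`` pairs, where the strength is the
    fraction of each planted ion's candidate weight mass lying inside the
    term (1 = unambiguous support).  ``effect_size`` is the log2 intensity
    shift applied to planted ions in the first condition.
    """

    universe_size: int = 500
    n_terms: int = 20
    term_size_range: tuple[int, int] = (10, 25)
    n_ions: int = 150
    candidates_per_ion: int | tuple[int, int] = 4
    planted_terms: tuple[tuple[str, float], ...] = ()
    ions_per_planted_term: int = 12
    effect_size: float = 0.0
    noise_sd: float = 0.3
    n_cells_per_group: int = 50
    conditions: tuple[str, str] = ("F", "U")
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid term_size_range")
        if isinstance(self.candidates_per_ion, tuple):
            clo, chi = self.candidates_per_ion
            if not (1 <= clo <= chi):
                raise ValueError("invalid candidates_per_ion range")
        elif self.candidates_per_ion < 1:
            raise ValueError("candidates_per_ion must be >= 1")
        for name, s in self.planted_terms:
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"enrichment_strength for {name!r} outside [0, 1]")
        if self.universe_size < 1 or self.n_terms < 0 or self.n_ions < 1:
            raise ValueError("invalid design sizes")
        if self.noise_sd < 0 or self.n_cells_per_group < 1:
            raise ValueError("invalid matrix design")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated study: term memberships, and per planted
    term its strength and the ions generated to support it."""

    term_members: dict[str, frozenset[str]]
    planted: dict[str, tuple[float, tuple[str, ...]]]

    @property
    def planted_ion_ids(self) -> frozenset[str]:
        out: set[str] = set()
        for _, ions in self.planted.values():
            out.update(ions)
        return frozenset(out)


def _candidate_count(design: SimDesign, rng: np.random.Generator) -> int:
    c = design.candidates_per_ion
    if isinstance(c, tuple):
        return int(rng.integers(c[0], c[1] + 1))
    return int(c)


def simulate_annotations(design: SimDesign) -> tuple[AnnotationTable, SetCollection, SimTruth]:
    """Generate an annotation table and set collection with planted terms.

    Terms are disjoint slices of the shuffled universe.  Each planted term
    gets ``ions_per_planted_term`` supporting ions whose in-term candidate
    count is floor(s*c) plus a Bernoulli on the fractional part, so the
    expected in-term candidate mass equals the enrichment strength exactly;
    in-term candidates tile a shuffled cycle of the term members so distinct
    ions tend to support distinct molecules.  Remaining ions draw their
    candidates uniformly from the universe.  Equal weights throughout.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(design.seed), 0)))
    universe = [f"M{i:04d}" for i in range(design.universe_size)]
    shuffled = list(universe)
    rng.shuffle(shuffled)

    lo, hi = design.term_size_range
    sizes = rng.integers(lo, hi + 1, size=design.n_terms)
    if int(sizes.sum()) > design.universe_size:
        raise ValueError("universe too small for the requested disjoint terms")
    terms: dict[str, frozenset[str]] = {}
    pos = 0
    for t, size in enumerate(sizes):
        terms[f"term_{t:02d}"] = frozenset(shuffled[pos:pos + int(size)])
        pos += int(size)

    planted_names = {name for name, _ in design.planted_terms}
    unknown = planted_names - set(terms)
    if unknown:
        raise ValueError(f"planted term(s) not in collection: {sorted(unknown)}")

    universe_arr = np.array(universe)
    ions: list[IonAnnotation] = []
    planted: dict[str, tuple[float, tuple[str, ...]]] = {}
    ion_counter = 0

    for name, strength in design.planted_terms:
        members = sorted(terms[name])
        cycle = list(members)
        rng.shuffle(cycle)
        cursor = 0
        outside = np.array(sorted(set(universe) - set(members)))
        ion_ids: list[str] = []
        for _ in range(design.ions_per_planted_term):
            c = _candidate_count(design, rng)
            n_in = int(np.floor(strength * c))
            frac = strength * c - n_in
            if frac > 0 and rng.random() < frac:
                n_in += 1
            n_in = min(n_in, c)
            if n_in > len(members):
                raise ValueError(
                    f"infeasible design: term {name!r} has {len(members)} members, "
                    f"ion requests {n_in} in-term candidates"
                )
            in_cands: list[str] = []
            while len(in_cands) < n_in:
                if cursor >= len(cycle):
                    rng.shuffle(cycle)
                    cursor = 0
                mol = cycle[cursor]
                cursor += 1
                if mol not in in_cands:
                    in_cands.append(mol)
            out_cands = list(rng.choice(outside, size=c - n_in, replace=False))
            cands = in_cands + out_cands
            rng.shuffle(cands)
            ion_id = f"ion_{ion_counter:04d}"
            ion_counter += 1
            ion_ids.append(ion_id)
            ions.append(IonAnnotation(ion_id, tuple(cands)))
        planted[name] = (float(strength), tuple(ion_ids))

    n_background = design.n_ions - ion_counter
    if n_background < 0:
        raise ValueError("n_ions smaller than the planted ions requested")
    for _ in range(n_background):
        c = _candidate_count(design, rng)
        cands = rng.choice(universe_arr, size=c, replace=False)
        ions.append(IonAnnotation(f"ion_{ion_counter:04d}", tuple(cands)))
        ion_counter += 1

    table = AnnotationTable(tuple(ions))
    sets = SetCollection.build(terms, universe=universe, min_term_size=3)
    return table, sets, SimTruth(term_members=dict(terms), planted=planted)


def simulate_matrix(
    design: SimDesign,
    table: AnnotationTable,
    truth: SimTruth,
) -> tuple[IntensityMatrix, dict[str, str]]:
    """Generate a metabolites x cells intensity matrix for the design.

    Baseline log2 intensities per metabolite are uniform on [8, 14];
    ions of planted terms gain ``effect_size`` (log2) in the first condition;
    Gaussian noise with sd ``noise_sd`` is added on the log scale, and the
    matrix holds ``2**log2`` values, hence non-negative (log-normal).
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(design.seed), 1)))
    cond_a, cond_b = design.conditions
    m = design.n_cells_per_group
    cell_ids = tuple(f"cell_{i:04d}" for i in range(2 * m))
    conditions = {c: (cond_a if i < m else cond_b) for i, c in enumerate(cell_ids)}
    is_a = np.array([conditions[c] == cond_a for c in cell_ids])

    ion_ids = table.ion_ids
    shifted = np.array([i in truth.planted_ion_ids for i in ion_ids])
    base = rng.uniform(8.0, 14.0, size=len(ion_ids))
    log2 = (
        base[:, None]
        + design.effect_size * np.outer(shifted, is_a)
        + rng.normal(0.0, design.noise_sd, size=(len(ion_ids), len(cell_ids)))
    )
    matrix = IntensityMatrix(
        values=np.power(2.0, log2),
        metabolite_ids=ion_ids,
        cell_ids=cell_ids,
        conditions=conditions,
    )
    return matrix, conditions


def expected_intersection(table: AnnotationTable, members: Sequence[str] | frozenset[str]) -> float:
    """Exact expected |sampled_set ∩ members| in the infinite-bootstrap limit.

    For each in-term molecule, the probability it is sampled by at least one
    ion is 1 - prod over ions of (1 - its normalized weight for that ion).
    """
    members = frozenset(members)
    miss: dict[str, float] = {mol: 1.0 for mol in members}
    for ion in table:
        total = sum(ion.weights)
        for c, w in zip(ion.candidates, ion.weights):
            if c in miss:
                miss[c] *= 1.0 - w / total
    return float(sum(1.0 - v for v in miss.values()))
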