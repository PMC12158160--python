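"""Domain types for ambiguous MS1 ion annotations, metabolite sets, and the
molecular universe.

Imaging mass spectrometry acquires MS1 spectra only, so an annotated ion
(molecular formula + adduct) cannot be resolved below the level of its
isomeric and isobaric candidates.  An :class:`IonAnnotation` therefore carries
an ordered list of candidate molecule identifiers together with non-negative
sampling weights expressing their relative likelihood; by default all
candidates are weighted equally.  The :class:`AnnotationTable` is the unit of
input for the bootstrapped enrichment engines, and a :class:`SetCollection`
holds the term -> molecule-set mapping (GMT dialect) plus the molecular
universe against which overrepresentation is judged.

Molecule identifiers are opaque, case-sensitive strings; no chemical
normalisation is attempted here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IonAnnotation",
    "AnnotationTable",
    "SetCollection",
    "BootstrapDraw",
    "ValidationReport",
    "normalize_weights",
    "validate_annotations",
    "filter_table_to_universe",
    "read_annotation_table",
    "write_annotation_table",
    "read_gmt",
    "write_gmt",
    "read_universe",
    "write_universe",
]

_WEIGHT_TOL = 1e-12


@dataclass(frozen=True)
class IonAnnotation:
    """One annotated ion and its isomeric/isobaric candidate structures.

    Parameters
    ----------
    ion_id
        Opaque identifier, typically ``formula+adduct``; unique per table.
    candidates
        Candidate molecule identifiers, length >= 1, unique within the ion.
    weights
        Non-negative sampling weights, one per candidate, summing to > 0.
        ``None`` assigns equal weights to every candidate.
    """

    ion_id: str
    candidates: tuple[str, ...]
    weights: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        cands = tuple(str(c) for c in self.candidates)
        if not cands:
            raise ValueError(f"ion {self.ion_id!r} has zero candidates")
        if len(set(cands)) != len(cands):
            raise ValueError(f"ion {self.ion_id!r} has duplicate candidate IDs")
        if self.weights is None:
            w = tuple(1.0 for _ in cands)
        else:
            w = tuple(float(x) for x in self.weights)
            if len(w) != len(cands):
                raise ValueError(
                    f"ion {self.ion_id!r}: {len(w)} weights for {len(cands)} candidates"
                )
            if any(x < 0 for x in w):
                raise ValueError(f"ion {self.ion_id!r} has negative weights")
            if sum(w) <= 0:
                raise ValueError(f"ion {self.ion_id!r} has all-zero weights")
        object.__setattr__(self, "candidates", cands)
        object.__setattr__(self, "weights", w)

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    def normalized(self) -> "IonAnnotation":
        """Alias for :func:`normalize_weights` on this ion."""
        return normalize_weights(self)


def normalize_weights(ion: IonAnnotation) -> IonAnnotation:
    """Return a copy of *ion* whose weights sum to 1 (within 1e-12).

    Weights remain proportional to the input.  Idempotent.  All-zero weights
    are rejected at construction time already.
    """
    total = sum(ion.weights)
    if total <= 0:  # unreachable for a valid IonAnnotation; defensive
        raise ValueError(f"ion {ion.ion_id!r} has all-zero weights")
    if abs(total - 1.0) <= _WEIGHT_TOL:
        return ion
    return replace(ion, weights=tuple(w / total for w in ion.weights))


@dataclass(frozen=True)
class AnnotationTable:
    """An ordered collection of :class:`IonAnnotation` keyed by ``ion_id``."""

    ions: tuple[IonAnnotation, ...]

    def __post_init__(self) -> None:
        ions = tuple(self.ions)
        ids = [i.ion_id for i in ions]
        if len(set(ids)) != len(ids):
            dupes = sorted({x for x in ids if ids.count(x) > 1})
            raise ValueError(f"duplicate ion_id(s): {dupes}")
        object.__setattr__(self, "ions", ions)

    def __len__(self) -> int:
        return len(self.ions)

    def __iter__(self):
        return iter(self.ions)

    @property
    def ion_ids(self) -> tuple[str, ...]:
        return tuple(i.ion_id for i in self.ions)

    def by_id(self) -> dict[str, IonAnnotation]:
        return {i.ion_id: i for i in self.ions}

    def candidate_union(self) -> frozenset[str]:
        """Union of all candidates of all ions (the standard-ORA sample set)."""
        out: set[str] = set()
        for ion in self.ions:
            out.update(ion.candidates)
        return frozenset(out)

    def normalized(self) -> "AnnotationTable":
        return AnnotationTable(tuple(normalize_weights(i) for i in self.ions))


@dataclass(frozen=True)
class SetCollection:
    """Metabolite sets (term -> molecule IDs) plus the molecular universe.

    Term member sets are stored already intersected with the universe; terms
    whose in-universe membership falls below ``min_term_size`` are dropped at
    construction.  Raising ``min_term_size`` can therefore only remove terms.
    """

    terms: dict[str, frozenset[str]]
    universe: frozenset[str]
    min_term_size: int = 3

    @classmethod
    def build(
        cls,
        terms: Mapping[str, Iterable[str]],
        universe: Iterable[str] | None = None,
        min_term_size: int = 3,
        extra_universe: Iterable[str] = (),
    ) -> "SetCollection":
        """Construct a collection, filtering terms against the universe.

        If *universe* is ``None`` it falls back to the union of all term
        members plus *extra_universe* (typically the candidates of an
        annotation table), representing the annotation database.
        """
        if min_term_size < 1:
            raise ValueError("min_term_size must be a positive integer")
        raw = {str(t): frozenset(str(m) for m in ms) for t, ms in terms.items()}
        if universe is None:
            uni: frozenset[str] = frozenset().union(*raw.values(), frozenset(extra_universe)) \
                if raw or extra_universe else frozenset()
        else:
            uni = frozenset(str(m) for m in universe)
        kept: dict[str, frozenset[str]] = {}
        for name, members in raw.items():
            inside = members & uni
            if len(inside) >= min_term_size:
                kept[name] = inside
            else:
                logger.debug("dropping term %r: %d in-universe members < %d",
                             name, len(inside), min_term_size)
        return cls(terms=kept, universe=uni, min_term_size=min_term_size)

    def __post_init__(self) -> None:
        if self.min_term_size < 1:
            raise ValueError("min_term_size must be a positive integer")
        for name, members in self.terms.items():
            if len(members & self.universe) < self.min_term_size:
                raise ValueError(
                    f"term {name!r} has fewer than min_term_size in-universe members"
                )

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(self.terms)


@dataclass(frozen=True)
class BootstrapDraw:
    """One resolution of the annotation ambiguity: ion -> single molecule."""

    assignment: dict[str, str]
    sampled_set: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sampled_set is None:
            object.__setattr__(self, "sampled_set", frozenset(self.assignment.values()))
        elif self.sampled_set != frozenset(self.assignment.values()):
            raise ValueError("sampled_set inconsistent with assignment")


@dataclass(frozen=True)
class ValidationReport:
    """Counts produced by :func:`validate_annotations`."""

    n_ions: int
    n_candidates: int
    n_usable: int
    n_excluded: int
    n_candidates_outside_universe: int
    excluded_ions: tuple[str, ...]


def validate_annotations(table: AnnotationTable, sets: SetCollection) -> ValidationReport:
    """Check an annotation table against a set collection's universe.

    Ions whose entire candidate list lies outside the universe are flagged as
    excluded (they cannot contribute to enrichment).  The input is never
    mutated.  An empty table is an error.
    """
    if len(table) == 0:
        raise ValueError("annotation table is empty")
    excluded: list[str] = []
    n_cand = 0
    n_outside = 0
    for ion in table:
        n_cand += ion.n_candidates
        inside = sum(1 for c in ion.candidates if c in sets.universe)
        n_outside += ion.n_candidates - inside
        if inside == 0:
            excluded.append(ion.ion_id)
    return ValidationReport(
        n_ions=len(table),
        n_candidates=n_cand,
        n_usable=len(table) - len(excluded),
        n_excluded=len(excluded),
        n_candidates_outside_universe=n_outside,
        excluded_ions=tuple(excluded),
    )


def filter_table_to_universe(
    table: AnnotationTable, universe: frozenset[str]
) -> AnnotationTable:
    """Drop out-of-universe candidates (renormalising weights) and ions left
    with no candidate at all.  Database mismatches are routine, so this warns
    rather than fails."""
    kept: list[IonAnnotation] = []
    n_dropped_cand = 0
    dropped_ions = 0
    for ion in table:
        pairs = [(c, w) for c, w in zip(ion.candidates, ion.weights) if c in universe]
        n_dropped_cand += ion.n_candidates - len(pairs)
        if not pairs:
            dropped_ions += 1
            continue
        if sum(w for _, w in pairs) <= 0:
            # only zero-weight candidates survive; fall back to equal weights
            pairs = [(c, 1.0) for c, _ in pairs]
        if len(pairs) == ion.n_candidates:
            kept.append(ion)
        else:
            kept.append(
                normalize_weights(
                    IonAnnotation(
                        ion.ion_id,
                        tuple(c for c, _ in pairs),
                        tuple(w for _, w in pairs),
                    )
                )
            )
    if n_dropped_cand or dropped_ions:
        logger.warning(
            "universe filter: dropped %d candidate(s) and %d ion(s) with no "
            "in-universe candidate", n_dropped_cand, dropped_ions,
        )
    return AnnotationTable(tuple(kept))


# ---------------------------------------------------------------------------
# I/O — delimited text formats


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_annotation_table(path: str | Path) -> AnnotationTable:
    """Read a long-format annotation table (one row per ion/candidate pair).

    Columns: ``ion_id``, ``candidate_id``, optional ``weight``.  Comma- vs
    tab-delimited is chosen by extension (``.csv`` -> comma).  Header required.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"ion_id": str, "candidate_id": str})
    required = {"ion_id", "candidate_id"}
    if not required.issubset(df.columns):
        missing = sorted(required - set(df.columns))
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise ValueError(f"{path}: annotation table is empty")
    has_w = "weight" in df.columns
    ions: list[IonAnnotation] = []
    for ion_id, grp in df.groupby("ion_id", sort=False):
        weights = tuple(float(x) for x in grp["weight"]) if has_w else None
        ions.append(IonAnnotation(str(ion_id), tuple(grp["candidate_id"]), weights))
    return AnnotationTable(tuple(ions))


def write_annotation_table(table: AnnotationTable, path: str | Path) -> None:
    path = Path(path)
    rows = [
        (ion.ion_id, c, w)
        for ion in table
        for c, w in zip(ion.candidates, ion.weights)
    ]
    df = pd.DataFrame(rows, columns=["ion_id", "candidate_id", "weight"])
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GMT-dialect set collection: term <tab> description <tab> members..."""
    terms: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected term, description, members")
        name = parts[0]
        if name in terms:
            raise ValueError(f"{path}:{lineno}: duplicate term {name!r}")
        members = frozenset(p for p in parts[2:] if p)
        terms[name] = members
    return terms


def write_gmt(terms: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    lines = []
    for name, members in terms.items():
        desc = (descriptions or {}).get(name, "")
        lines.append("\t".join([name, desc, *sorted(members)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_universe(path: str | Path) -> frozenset[str]:
    """Read a universe file: one molecule ID per line; blank lines ignored."""
    ids = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return frozenset(x for x in ids if x)


def write_universe(universe: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(universe)) + "\n")
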