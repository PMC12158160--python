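"""Per-bootstrap overrepresentation analysis (ORA).

Each bootstrap draw yields a sample set of molecules; every retained term is
tested for overrepresentation against the molecular universe with a
one-tailed (greater) Fisher's exact test on the 2x2 table

    =============  ==========  ============
                   in term     not in term
    sampled        k           n - k
    not sampled    K - k       N - K - n + k
    =============  ==========  ============

i.e. p = P(X >= k) for X ~ Hypergeometric(N, K, n).  P-values are adjusted
per bootstrap across the terms tested in that bootstrap with the
Benjamini-Hochberg step-up procedure, and fold enrichment (k/n)/(K/N) and the
intersection size k are reported per term.

The standard, ambiguity-ignoring baseline (:func:`standard_ora`) uses the
union of all candidates of all ions as the sample set; when every ion has a
single candidate the two analyses coincide exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotations import AnnotationTable, BootstrapDraw, SetCollection
from .sampler import SamplerConfig, draw_all

__all__ = [
    "ContingencyCounts",
    "SingleOraRow",
    "fisher_one_tailed",
    "bh_adjust",
    "fold_enrichment",
    "ora_single",
    "standard_ora",
    "bootstrap_ora",
]


@dataclass(frozen=True)
class ContingencyCounts:
    """Counts of the 2x2 overrepresentation table.

    k: sampled molecules in the term; n: sampled molecules total;
    K: universe molecules in the term; N: universe size.
    """

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self) -> None:
        k, n, K, N = self.k, self.n, self.K, self.N
        if any(int(x) != x for x in (k, n, K, N)):
            raise ValueError("contingency counts must be integers")
        if N < 1 or n < 0 or K < 0 or k < 0:
            raise ValueError(f"negative or empty margins: k={k} n={n} K={K} N={N}")
        if n > N or K > N or k > min(n, K):
            raise ValueError(f"inconsistent contingency counts: k={k} n={n} K={K} N={N}")


def fisher_one_tailed(c: ContingencyCounts) -> float:
    """Upper-tail Fisher exact p-value, p = P(X >= k), X ~ Hypergeom(N, K, n)."""
    return float(hypergeom.sf(c.k - 1, c.N, c.K, c.n))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D sequence of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_enrichment(c: ContingencyCounts) -> float:
    """Fold enrichment (k/n)/(K/N); 0 when the intersection is empty."""
    if c.n == 0 or c.K == 0:
        raise ValueError("fold enrichment undefined for n=0 or K=0")
    return (c.k / c.n) / (c.K / c.N)


@dataclass(frozen=True)
class SingleOraRow:
    """One term's statistics from a single (bootstrap or standard) ORA."""

    term: str
    p: float
    q: float
    fold: float
    intersection: int


def _ora_rows(sample_ids, sets: SetCollection, *, n: int | None = None,
              multiplicity: Sequence[str] | None = None) -> list[SingleOraRow]:
    """Shared core: test every retained term against one sample.

    With *multiplicity* (the full list of sampled assignments, duplicates
    kept) k and n count ion->molecule assignments rather than distinct
    molecules.
    """
    N = len(sets.universe)
    if multiplicity is None:
        sample = frozenset(sample_ids) & sets.universe
        if not sample:
            raise ValueError("empty sample set after universe filtering")
        n_eff = len(sample)
        ks = np.array([len(sample & members) for members in sets.terms.values()])
    else:
        vals = [m for m in multiplicity if m in sets.universe]
        if not vals:
            raise ValueError("empty sample set after universe filtering")
        n_eff = len(vals)
        ks = np.array([sum(v in members for v in vals) for members in sets.terms.values()])
    Ks = np.array([len(members) for members in sets.terms.values()])
    # validate before the vectorised tail call (k > K only possible without dedup)
    counts = [ContingencyCounts(int(k), n_eff, int(K), N) for k, K in zip(ks, Ks)]
    ps = hypergeom.sf(ks - 1, N, Ks, n_eff)
    qs = bh_adjust(ps)
    folds = np.where(ks > 0, (ks / n_eff) / (Ks / N), 0.0)
    return [
        SingleOraRow(term=t, p=float(p), q=float(q), fold=float(f), intersection=int(k))
        for t, p, q, f, k in zip(sets.terms, ps, qs, folds, ks)
    ]


def ora_single(draw: BootstrapDraw, sets: SetCollection, dedup: bool = True) -> list[SingleOraRow]:
    """ORA of one bootstrap draw against every retained term.

    With ``dedup`` (default) the sample is the deduplicated set of sampled
    molecules; without it, assignments are counted with multiplicity (one per
    ion), which can produce inconsistent contingency tables if many ions
    collapse onto few molecules — those raise.
    """
    if not draw.assignment:
        raise ValueError("empty bootstrap draw")
    if dedup:
        return _ora_rows(draw.sampled_set, sets)
    return _ora_rows(None, sets, multiplicity=list(draw.assignment.values()))


def standard_ora(table: AnnotationTable, sets: SetCollection) -> list[SingleOraRow]:
    """Ambiguity-ignoring baseline: the sample is the union of every
    candidate of every ion (each molecule once)."""
    union = table.candidate_union() & sets.universe
    if not union:
        raise ValueError("no candidate falls inside the universe")
    return _ora_rows(union, sets)


def bootstrap_ora(
    table: AnnotationTable,
    sets: SetCollection,
    cfg: SamplerConfig | None = None,
    dedup: bool = True,
) -> list[list[SingleOraRow]]:
    """Run a full bootstrapped ORA: one complete per-term result list per draw."""
    cfg = cfg or SamplerConfig()
    return [ora_single(d, sets, dedup=dedup) for d in draw_all(table, cfg)]
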