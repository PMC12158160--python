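"""Cross-bootstrap aggregation of per-term enrichment results.

Each bootstrap is a complete enrichment analysis; the aggregate reports, per
term, the median p/q, the fraction of bootstraps in which the term was called
significant (q <= fdr_cutoff), the median and interquartile range of the
effect statistic (fold enrichment for ORA, ES for MSEA), the median
intersection/leading-edge size, and the number of bootstraps in which the
term was actually tested.  Medians are used throughout as the robust central
statistic.  Terms absent from some bootstraps (e.g. sampled MSEA membership
below the size filter) aggregate over their effective bootstraps only and
report that count, so unstable terms stay visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ora import SingleOraRow

__all__ = [
    "TermResult",
    "DiscordantTerm",
    "aggregate_terms",
    "compare_standard_vs_bootstrap",
    "ora_results_frame",
    "msea_results_frame",
    "discordance_frame",
]


@dataclass(frozen=True)
class TermResult:
    """Aggregated statistics for one term across bootstraps."""

    term: str
    median_p: float
    median_q: float
    fraction_significant: float
    median_effect: float        # fold enrichment (ORA) or ES (MSEA)
    effect_q25: float
    effect_q75: float
    median_size: float          # intersection k (ORA) or leading edge (MSEA)
    n_effective_bootstraps: int
    n_bootstraps: int
    ambiguity_score: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_significant <= 1.0):
            raise ValueError("fraction_significant must lie in [0, 1]")
        if self.n_effective_bootstraps > self.n_bootstraps:
            raise ValueError("n_effective_bootstraps exceeds n_bootstraps")


def aggregate_terms(
    per_bootstrap_rows: Sequence[Sequence],
    fdr_cutoff: float = 0.10,
    ambiguity: Mapping[str, float] | None = None,
) -> list[TermResult]:
    """Collapse per-bootstrap row lists (ORA or MSEA) into :class:`TermResult`s.

    Rows expose ``term``, ``p``, ``q`` and either ``fold``/``intersection``
    (ORA) or ``es``/``leading_edge_size`` (MSEA).  Medians run over the
    bootstraps in which the term was tested; terms never tested are omitted.
    Deterministic given the inputs, and invariant to bootstrap order.
    """
    if not per_bootstrap_rows:
        raise ValueError("no bootstrap results to aggregate")
    n_boot = len(per_bootstrap_rows)
    ps: dict[str, list[float]] = {}
    qs: dict[str, list[float]] = {}
    effects: dict[str, list[float]] = {}
    sizes: dict[str, list[float]] = {}
    for rows in per_bootstrap_rows:
        for r in rows:
            eff = r.fold if isinstance(r, SingleOraRow) else r.es
            size = r.intersection if isinstance(r, SingleOraRow) else r.leading_edge_size
            ps.setdefault(r.term, []).append(r.p)
            qs.setdefault(r.term, []).append(r.q)
            effects.setdefault(r.term, []).append(eff)
            sizes.setdefault(r.term, []).append(size)
    out: list[TermResult] = []
    for term in ps:
        q = np.asarray(qs[term])
        eff = np.asarray(effects[term])
        out.append(TermResult(
            term=term,
            median_p=float(np.median(ps[term])),
            median_q=float(np.median(q)),
            fraction_significant=float(np.mean(q <= fdr_cutoff)),
            median_effect=float(np.median(eff)),
            effect_q25=float(np.quantile(eff, 0.25)),
            effect_q75=float(np.quantile(eff, 0.75)),
            median_size=float(np.median(sizes[term])),
            n_effective_bootstraps=len(q),
            n_bootstraps=n_boot,
            ambiguity_score=float((ambiguity or {}).get(term, float("nan"))),
        ))
    return out


@dataclass(frozen=True)
class DiscordantTerm:
    """A term called significant by standard ORA but unstable under bootstrapping."""

    term: str
    standard_q: float
    fraction_significant: float
    ambiguity_score: float


def compare_standard_vs_bootstrap(
    standard: Sequence[SingleOraRow],
    aggregated: Sequence[TermResult],
    fdr_cutoff: float = 0.10,
    fraction_threshold: float = 0.5,
) -> list[DiscordantTerm]:
    """Terms significant in the ambiguity-ignoring ORA whose bootstrap
    fraction_significant falls below *fraction_threshold* — candidate false
    positives driven by ambiguous annotations, each annotated with its
    ambiguity score."""
    agg = {t.term: t for t in aggregated}
    out: list[DiscordantTerm] = []
    for row in standard:
        if row.q > fdr_cutoff:
            continue
        res = agg.get(row.term)
        frac = res.fraction_significant if res is not None else 0.0
        score = res.ambiguity_score if res is not None else float("nan")
        if frac < fraction_threshold:
            out.append(DiscordantTerm(row.term, row.q, frac, score))
    return out


# ---------------------------------------------------------------------------
# Tabular serialisation (tab-separated, round-trippable with pandas)


def ora_results_frame(results: Sequence[TermResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "term": [r.term for r in results],
        "median_p": [r.median_p for r in results],
        "median_q": [r.median_q for r in results],
        "fraction_significant": [r.fraction_significant for r in results],
        "median_fold": [r.median_effect for r in results],
        "median_intersection": [r.median_size for r in results],
        "q25_fold": [r.effect_q25 for r in results],
        "q75_fold": [r.effect_q75 for r in results],
        "ambiguity_score": [r.ambiguity_score for r in results],
        "n_bootstraps": [r.n_bootstraps for r in results],
    })


def msea_results_frame(results: Sequence[TermResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "term": [r.term for r in results],
        "median_p": [r.median_p for r in results],
        "median_q": [r.median_q for r in results],
        "fraction_significant": [r.fraction_significant for r in results],
        "median_es": [r.median_effect for r in results],
        "q25_es": [r.effect_q25 for r in results],
        "q75_es": [r.effect_q75 for r in results],
        "median_leading_edge": [r.median_size for r in results],
        "ambiguity_score": [r.ambiguity_score for r in results],
        "n_effective_bootstraps": [r.n_effective_bootstraps for r in results],
        "n_bootstraps": [r.n_bootstraps for r in results],
    })


def discordance_frame(rows: Sequence[DiscordantTerm]) -> pd.DataFrame:
    return pd.DataFrame({
        "term": [r.term for r in rows],
        "standard_q": [r.standard_q for r in rows],
        "fraction_significant": [r.fraction_significant for r in rows],
        "ambiguity_score": [r.ambiguity_score for r in rows],
    })
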