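"""Rank-based metabolite set enrichment analysis (MSEA) for single-cell
intensity matrices, per bootstrap draw.

Metabolites (measured ions) are ranked by a two-condition contrast metric and
term concentration near the extremes of the ranking is scored with a weighted
Kolmogorov-Smirnov running sum: walking down the ranking, hits increment by
|metric|^alpha normalised over in-set metric mass, misses decrement by
1/(L - |S|); the enrichment score (ES) is the running-sum value of maximal
absolute magnitude.  Significance comes from a metabolite-label permutation
null, p = (1 + #{|ES_perm| >= |ES_obs|}) / (1 + n_perm).

Term membership operates at the ION level per bootstrap: a ranked ion belongs
to a term iff its sampled molecular candidate does, which is how candidate
ambiguity propagates into MSEA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import BootstrapDraw, SetCollection
from .ora import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityMatrix",
    "RankedList",
    "MseaRow",
    "RANK_METRICS",
    "rank_metric",
    "enrichment_score",
    "msea_permutation_p",
    "msea_single",
    "bootstrap_msea",
    "read_intensity_matrix",
    "read_conditions",
]

RANK_METRICS = ("log2fc", "tstat", "snr", "diff")


@dataclass(frozen=True)
class IntensityMatrix:
    """Metabolites x cells non-negative intensities with condition labels.

    Row labels are the measured ion IDs (matching an annotation table);
    ``conditions`` maps every cell ID to its condition/group label.
    """

    values: np.ndarray
    metabolite_ids: tuple[str, ...]
    cell_ids: tuple[str, ...]
    conditions: dict[str, str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        mids = tuple(str(m) for m in self.metabolite_ids)
        cids = tuple(str(c) for c in self.cell_ids)
        if v.shape != (len(mids), len(cids)):
            raise ValueError(f"matrix shape {v.shape} != ({len(mids)}, {len(cids)})")
        if len(set(mids)) != len(mids):
            raise ValueError("duplicate metabolite (row) labels")
        if len(set(cids)) != len(cids):
            raise ValueError("duplicate cell (column) labels")
        if np.any(v < 0) or np.any(~np.isfinite(v)):
            raise ValueError("intensities must be finite and non-negative")
        missing = [c for c in cids if c not in self.conditions]
        if missing:
            raise ValueError(f"cells without a condition label: {missing[:5]}...")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "metabolite_ids", mids)
        object.__setattr__(self, "cell_ids", cids)


@dataclass(frozen=True)
class RankedList:
    """Metabolites ordered by a contrast metric, descending."""

    ids: tuple[str, ...]
    metric: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.metric, dtype=float)
        ids = tuple(str(i) for i in self.ids)
        if m.shape != (len(ids),):
            raise ValueError("metric length must match ids")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate metabolite ids in ranking")
        if np.any(np.diff(m) > 0):
            raise ValueError("metric values must be non-increasing")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "metric", m)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class MseaRow:
    """One term's MSEA statistics from a single bootstrap draw."""

    term: str
    es: float
    p: float
    q: float
    leading_edge_size: int
    n_members: int


def rank_metric(
    matrix: IntensityMatrix,
    contrast: tuple[str, str],
    metric: str = "tstat",
    pseudocount: float | None = None,
) -> RankedList:
    """Rank all metabolites by a two-condition contrast statistic (A vs B).

    Positive values mean higher intensity in the first contrast label.
    Supported metrics: ``log2fc`` (log2 ratio of group means with a
    pseudo-count), ``tstat`` (Welch t), ``snr`` (mean difference over summed
    standard deviations), ``diff`` (difference of means).  Zero-variance
    metabolites under ``tstat``/``snr`` get metric 0 with a warning.  Ties
    are broken by metabolite ID so rankings are deterministic.
    """
    a_label, b_label = contrast
    labels = [matrix.conditions[c] for c in matrix.cell_ids]
    a_idx = np.array([l == a_label for l in labels])
    b_idx = np.array([l == b_label for l in labels])
    if not a_idx.any():
        raise ValueError(f"contrast label {a_label!r} absent from conditions")
    if not b_idx.any():
        raise ValueError(f"contrast label {b_label!r} absent from conditions")
    if metric not in RANK_METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {RANK_METRICS}")
    A = matrix.values[:, a_idx]
    B = matrix.values[:, b_idx]
    if metric in ("tstat", "snr") and (A.shape[1] < 2 or B.shape[1] < 2):
        raise ValueError(f"metric {metric!r} needs >= 2 cells per group")
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    if metric == "diff":
        vals = ma - mb
    elif metric == "log2fc":
        eps = pseudocount if pseudocount is not None else 1e-9 * max(matrix.values.max(), 1.0)
        vals = np.log2(ma + eps) - np.log2(mb + eps)
    else:
        sa = A.std(axis=1, ddof=1)
        sb = B.std(axis=1, ddof=1)
        if metric == "tstat":
            denom = np.sqrt(sa**2 / A.shape[1] + sb**2 / B.shape[1])
        else:  # snr
            denom = sa + sb
        zero = denom == 0
        if zero.any():
            logger.warning("%d zero-variance metabolite(s) under %s: metric set to 0",
                           int(zero.sum()), metric)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(zero, 0.0, (ma - mb) / np.where(zero, 1.0, denom))
    order = sorted(range(len(vals)), key=lambda i: (-vals[i], matrix.metabolite_ids[i]))
    return RankedList(
        ids=tuple(matrix.metabolite_ids[i] for i in order),
        metric=vals[np.array(order)],
    )


def _es_from_mask(metric: np.ndarray, mask: np.ndarray, weight_exponent: float) -> tuple[float, int]:
    """Running-sum ES and leading-edge size for one membership mask."""
    n_hit = int(mask.sum())
    L = mask.size
    w = np.where(mask, np.abs(metric) ** weight_exponent, 0.0)
    sw = w.sum()
    if sw == 0:  # all in-set metric values are 0; fall back to unweighted hits
        w = mask.astype(float)
        sw = float(n_hit)
    p_hit = np.cumsum(w) / sw
    p_miss = np.cumsum(~mask) / (L - n_hit)
    running = p_hit - p_miss
    i = int(np.argmax(np.abs(running)))
    es = float(running[i])
    if es >= 0:
        lead = int(mask[: i + 1].sum())
    else:
        lead = int(mask[i:].sum())
    return es, lead


def enrichment_score(
    ranked: RankedList,
    members: frozenset[str] | set[str],
    weight_exponent: float = 1.0,
) -> tuple[float, int]:
    """Weighted KS running-sum enrichment score of *members* on *ranked*.

    Returns ``(es, leading_edge_size)`` where ES is the signed running-sum
    extremum in [-1, 1], and the leading edge counts set members at or before
    the peak (positive ES) or at or after the trough (negative ES).
    The member set must intersect the ranking but not cover it entirely.
    """
    mask = np.array([i in members for i in ranked.ids])
    n_hit = int(mask.sum())
    if n_hit == 0:
        raise ValueError("member set does not intersect the ranked list")
    if n_hit == len(ranked):
        raise ValueError("member set covers the whole ranked list")
    return _es_from_mask(ranked.metric, mask, weight_exponent)


def _es_batch(metric: np.ndarray, masks: np.ndarray, weight_exponent: float) -> np.ndarray:
    """Vectorised ES over a (n_perm, L) boolean mask matrix (same set size per row)."""
    n_hit = int(masks[0].sum())
    L = masks.shape[1]
    absm = np.abs(metric) ** weight_exponent
    w = masks * absm
    sw = w.sum(axis=1, keepdims=True)
    degenerate = sw[:, 0] == 0
    if degenerate.any():
        w[degenerate] = masks[degenerate].astype(float)
        sw = w.sum(axis=1, keepdims=True)
    p_hit = np.cumsum(w, axis=1) / sw
    p_miss = np.cumsum(~masks, axis=1) / (L - n_hit)
    running = p_hit - p_miss
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(running.shape[0]), idx]


def msea_permutation_p(
    ranked: RankedList,
    members: frozenset[str] | set[str],
    n_perm: int,
    rng: np.random.Generator,
    weight_exponent: float = 1.0,
) -> float:
    """Two-sided metabolite-label permutation p-value for the ES of *members*.

    ES is recomputed on ``n_perm`` uniformly random same-size member sets;
    p = (1 + #{|ES_perm| >= |ES_obs|}) / (1 + n_perm), hence p >= 1/(1+n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable permutation null")
    es_obs, _ = enrichment_score(ranked, members, weight_exponent)
    L = len(ranked)
    size = len(set(members) & set(ranked.ids))
    # random same-size subsets via partial argsort of uniform noise
    keys = rng.random((n_perm, L))
    idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
    masks = np.zeros((n_perm, L), dtype=bool)
    np.put_along_axis(masks, idx, True, axis=1)
    es_perm = _es_batch(ranked.metric, masks, weight_exponent)
    exceed = int(np.sum(np.abs(es_perm) >= abs(es_obs)))
    return (1 + exceed) / (1 + n_perm)


def msea_single(
    draw: BootstrapDraw,
    ranked: RankedList,
    sets: SetCollection,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    weight_exponent: float = 1.0,
) -> list[MseaRow]:
    """MSEA of one bootstrap draw: term membership of each ranked ion is
    inherited from its sampled molecule; terms with fewer than
    ``sets.min_term_size`` sampled members on the list are skipped this draw.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    L = len(ranked)
    rows: list[tuple[str, float, float, int, int]] = []
    for term, molecules in sets.terms.items():
        member_ions = frozenset(
            ion for ion in ranked.ids
            if draw.assignment.get(ion) in molecules
        )
        size = len(member_ions)
        if size < sets.min_term_size or size >= L:
            continue
        es, lead = enrichment_score(ranked, member_ions, weight_exponent)
        p = msea_permutation_p(ranked, member_ions, n_perm, rng, weight_exponent)
        rows.append((term, es, p, lead, size))
    if not rows:
        logger.warning("no term passed the size filter in this bootstrap")
        return []
    qs = bh_adjust([r[2] for r in rows])
    return [
        MseaRow(term=t, es=es, p=p, q=float(q), leading_edge_size=lead, n_members=size)
        for (t, es, p, lead, size), q in zip(rows, qs)
    ]


def bootstrap_msea(
    table,
    matrix: IntensityMatrix,
    contrast: tuple[str, str],
    sets: SetCollection,
    cfg=None,
    metric: str = "tstat",
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
) -> tuple[RankedList, list[list[MseaRow]]]:
    """Full bootstrapped MSEA pipeline.

    The ranking is computed once (it does not depend on the draws).  The
    master seed is split into a bootstrap stream and a permutation stream so
    the two sources of randomness are independent.
    """
    from .sampler import SamplerConfig, draw_all

    cfg = cfg or SamplerConfig()
    ranked = rank_metric(matrix, contrast, metric)
    ss_boot, ss_perm = np.random.SeedSequence(cfg.master_seed).spawn(2)
    draws = draw_all(table, cfg, seed_sequence=ss_boot)
    perm_children = ss_perm.spawn(cfg.n_bootstraps)
    per_bootstrap = [
        msea_single(d, ranked, sets, n_perm=n_perm,
                    rng=np.random.default_rng(child), weight_exponent=weight_exponent)
        for d, child in zip(draws, perm_children)
    ]
    return ranked, per_bootstrap


# ---------------------------------------------------------------------------
# I/O


def read_intensity_matrix(
    path: str | Path,
    conditions: Mapping[str, str],
    row_labels: str | Path | None = None,
    col_labels: str | Path | None = None,
) -> IntensityMatrix:
    """Read a metabolites x cells matrix.

    Dense: delimited text with a header of cell IDs and metabolite IDs in the
    first column (comma vs tab by extension).  Sparse: MatrixMarket ``.mtx``
    plus separate one-per-line row/column label files.
    """
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        from scipy.io import mmread

        if row_labels is None or col_labels is None:
            raise ValueError("MTX input needs row_labels and col_labels files")
        m = mmread(path)
        values = np.asarray(m.toarray() if hasattr(m, "toarray") else m, dtype=float)
        mids = [l.strip() for l in Path(row_labels).read_text().splitlines() if l.strip()]
        cids = [l.strip() for l in Path(col_labels).read_text().splitlines() if l.strip()]
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        mids = [str(i) for i in df.index]
        cids = [str(c) for c in df.columns]
    return IntensityMatrix(values=values, metabolite_ids=tuple(mids),
                           cell_ids=tuple(cids), conditions=dict(conditions))


def read_conditions(path: str | Path) -> dict[str, str]:
    """Read a two-column (cell_id, condition) file; header optional."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty condition file")
    start = 1 if lines[0].split(sep)[0].strip().lower() in ("cell_id", "cell") else 0
    out: dict[str, str] = {}
    for lineno, ln in enumerate(lines[start:], start=start + 1):
        parts = ln.split(sep)
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected cell_id{sep!r}condition")
        out[parts[0].strip()] = parts[1].strip()
    return out
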