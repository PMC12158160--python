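"""Reproducible bootstrap resolution of annotation ambiguity.

Each bootstrap iteration draws one molecular candidate per ion, independently
across ions, with probability proportional to the candidate's weight.  A
master seed spawns one independent substream per iteration (NumPy
``SeedSequence.spawn``), so the draw sequence is bit-reproducible and
invariant to parallel execution order.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from itertools import accumulate

import numpy as np

from .annotations import AnnotationTable, BootstrapDraw, normalize_weights

__all__ = ["SamplerConfig", "draw_bootstrap", "draw_all"]


@dataclass(frozen=True)
class SamplerConfig:
    """Bootstrap settings.  At least 100 iterations are recommended for
    stable aggregate statistics; the default is that minimum."""

    n_bootstraps: int = 100
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstraps < 1:
            raise ValueError("n_bootstraps must be >= 1")


def _cumulative_weights(table: AnnotationTable) -> list[tuple[str, tuple[str, ...], list[float]]]:
    """Per-ion (ion_id, candidates, cumulative normalized weights)."""
    out = []
    for ion in table:
        ion = normalize_weights(ion)
        cum = list(accumulate(ion.weights))
        cum[-1] = 1.0  # guard against round-off at the top end
        out.append((ion.ion_id, ion.candidates, cum))
    return out


def draw_bootstrap(table: AnnotationTable, rng: np.random.Generator) -> BootstrapDraw:
    """Draw one bootstrap resolution: one candidate per ion, weight-proportional.

    Within-iteration molecule collisions across ions are collapsed in
    ``sampled_set`` (enrichment is set-based downstream by default).
    """
    return _draw_from_cum(_cumulative_weights(table), rng)


def _draw_from_cum(cum_table, rng: np.random.Generator) -> BootstrapDraw:
    u = rng.random(len(cum_table))
    assignment: dict[str, str] = {}
    for (ion_id, candidates, cum), x in zip(cum_table, u):
        assignment[ion_id] = candidates[bisect_left(cum, x)]
    return BootstrapDraw(assignment=assignment)


def draw_all(
    table: AnnotationTable,
    cfg: SamplerConfig,
    seed_sequence: np.random.SeedSequence | None = None,
) -> list[BootstrapDraw]:
    """Draw ``cfg.n_bootstraps`` independent resolutions of *table*.

    Deterministic given ``cfg.master_seed`` (or the explicit *seed_sequence*,
    which takes precedence and lets callers reserve separate substreams for
    other randomness, e.g. MSEA permutations).
    """
    ss = seed_sequence if seed_sequence is not None else np.random.SeedSequence(cfg.master_seed)
    cum_table = _cumulative_weights(table)
    return [
        _draw_from_cum(cum_table, np.random.default_rng(child))
        for child in ss.spawn(cfg.n_bootstraps)
    ]
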