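"""Iterative simultaneous imputation of several missing omics matrices.

All matrices are first completed by self-imputation.  Then, cyclically and
in order of increasing missing-feature count (so errors propagate from the
least to the most damaged matrix), each matrix is re-imputed by the
ensemble pipeline using the current filled state of the other matrices,
until the sum of squared changes at the missing locations between
consecutive iterations falls below the convergence threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MissingLocations, MultiOmicsSet, OmicsMatrix
from .cross import PriorKnowledgeGraph
from .ensemble import EnsembleConfig, multi_omics_impute
from .imputers import impute

__all__ = [
    "IterativeConfig",
    "IterationState",
    "order_by_missing",
    "delta",
    "iterative_impute",
]


@dataclass(frozen=True)
class IterativeConfig:
    """Convergence control for the multi-matrix loop.

    ``tau`` bounds the *relative* squared change per missing entry
    (raw delta divided by missing count times the pooled variance of the
    current imputed values), making the criterion scale-free.
    ``literal_printed_order`` restricts each matrix's cross sources to the
    matrices already refreshed in the current iteration (first matrix: all
    others at their previous state); by default every other matrix is used
    at its freshest available state.
    """

    tau: float = 1e-4
    max_iterations: int = 10
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    literal_printed_order: bool = False

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class IterationState:
    """Diagnostics of one run of the iterative algorithm."""

    n_iterations: int = 0
    delta_history: list[float] = field(default_factory=list)
    relative_delta_history: list[float] = field(default_factory=list)
    converged: bool = False
    weights_by_source: list[dict] = field(default_factory=list)


def order_by_missing(omics_set: MultiOmicsSet) -> list[int]:
    """Matrix indices sorted by the number of features containing at least
    one missing entry, ascending; ties keep input order (stable sort)."""
    counts = [int(m.missing_mask.any(axis=1).sum()) for m in omics_set]
    return sorted(range(len(counts)), key=lambda i: counts[i])


def delta(prev: MultiOmicsSet, curr: MultiOmicsSet,
          locations: MissingLocations) -> float:
    """Sum of squared differences at the true missing locations between two
    consecutive filled states."""
    total = 0.0
    for mi, r, c in locations:
        d = prev[mi].values[r, c] - curr[mi].values[r, c]
        total += d * d
    return float(total)


def _relative_delta(raw: float, curr: MultiOmicsSet,
                    locations: MissingLocations) -> float:
    if len(locations) == 0:
        return 0.0
    vals = np.array([curr[mi].values[r, c] for mi, r, c in locations])
    var = float(np.var(vals, ddof=1)) if vals.size > 1 else 0.0
    denom = len(locations) * max(var, 1e-12)
    return raw / denom


def iterative_impute(omics_set: MultiOmicsSet, cfg: IterativeConfig | None = None,
                     priors: dict[int, PriorKnowledgeGraph] | None = None
                     ) -> tuple[MultiOmicsSet, IterationState]:
    """Run the full iterative multi-omics imputation algorithm.

    Returns the completed set (observed entries untouched, original masks
    preserved) together with the iteration diagnostics.  Non-convergence
    within ``max_iterations`` is reported via ``state.converged``, not an
    exception.
    """
    cfg = cfg or IterativeConfig()
    priors = priors or {}
    locations = MissingLocations.from_masks(omics_set)
    state = IterationState()

    if len(locations) == 0:
        state.n_iterations = 1
        state.delta_history = [0.0]
        state.relative_delta_history = [0.0]
        state.converged = True
        return omics_set.copy(), state

    # Step A: initialize every matrix by self-imputation.
    current = []
    for m in omics_set:
        if m.n_missing == 0:
            current.append(m.copy())
        else:
            done = impute(m, cfg.ensemble.base)
            current.append(OmicsMatrix(done.values.copy(), m.missing_mask.copy(),
                                       list(m.feature_ids), list(m.sample_ids),
                                       m.omics_name))
    current = MultiOmicsSet(current)
    order = order_by_missing(omics_set)

    for h in range(1, cfg.max_iterations + 1):
        prev = current.copy()
        refreshed: list[int] = []
        iter_weights: dict[str, dict] = {}
        for pos, mi in enumerate(order):
            target_prev = current[mi]
            if target_prev.n_missing == 0:
                refreshed.append(mi)
                continue
            if cfg.literal_printed_order and pos > 0:
                other_idx = [j for j in refreshed if j != mi]
            else:
                other_idx = [j for j in range(len(current)) if j != mi]
            others = [current[j].with_values(current[j].values, clear_mask=True)
                      for j in other_idx]
            ens = EnsembleConfig(
                B=cfg.ensemble.B, subsample_fraction=cfg.ensemble.subsample_fraction,
                T=cfg.ensemble.T, faking_fraction=cfg.ensemble.faking_fraction,
                base=cfg.ensemble.base, alpha=cfg.ensemble.alpha,
                seed=int(np.random.SeedSequence(
                    [max(cfg.ensemble.seed, 0), h, mi]).generate_state(1)[0] % (2**31)))
            # warm start: previous estimates stay in place under the mask
            result = multi_omics_impute(target_prev, others, ens,
                                        priors.get(mi))
            current.matrices[mi] = result.matrix
            if result.weights is not None:
                iter_weights[current[mi].omics_name] = result.report["weights_by_source"]
            refreshed.append(mi)
        raw = delta(prev, current, locations)
        rel = _relative_delta(raw, current, locations)
        state.delta_history.append(raw)
        state.relative_delta_history.append(rel)
        state.weights_by_source.append(iter_weights)
        state.n_iterations = h
        if rel <= cfg.tau:
            state.converged = True
            break
    return current, state
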