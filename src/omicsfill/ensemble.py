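"""Ensemble combination of self- and cross-imputation basic models.

For one target omics matrix the pipeline is: hide a set of "faking missing"
entries (observed entries with known truth), generate m x B basic
imputations (each source omics x B feature subsamples), estimate one
simplex-constrained weight per basic model by regressing the truth at the
faking entries on the models' predictions there (T bootstrap rounds,
averaged), and fill the true missing entries with the weighted combination.
The non-negativity + sum-to-one constraint handles the strong collinearity
among models and implicitly prunes models that contribute nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .core import MissingLocations, OmicsMatrix
from .cross import PriorKnowledgeGraph, cross_impute
from .imputers import ImputerConfig, ImputationWarning, impute

__all__ = [
    "EnsembleConfig",
    "BasicModelOutput",
    "EnsembleWeights",
    "MultiOmicsResult",
    "make_faking_missing",
    "generate_basic_models",
    "estimate_weights",
    "solve_simplex_weights",
    "combine",
    "multi_omics_impute",
]

SIMPLEX_TOL = 1e-8


@dataclass(frozen=True)
class EnsembleConfig:
    """Ensemble hyper-parameters.

    B feature subsamples per source diversify the basic models;
    T bootstrap rounds stabilize the weight estimates (T = 30 by default).
    ``faking_fraction`` defaults to the target's true missing rate
    (floored at 1% of observed entries) so weights are fitted in the same
    error regime they will be applied to.
    """

    B: int = 5
    subsample_fraction: float = 0.7
    T: int = 30
    faking_fraction: float | None = None
    base: ImputerConfig = field(default_factory=ImputerConfig)
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.B < 1 or self.T < 1:
            raise ValueError("B and T must be >= 1")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.faking_fraction is not None and not 0 < self.faking_fraction <= 1:
            raise ValueError("faking_fraction must be in (0, 1]")


@dataclass
class BasicModelOutput:
    """One basic imputation: estimates at the requested locations.

    ``source_index`` 0 means self-imputation; 1.. index the cross sources.
    """

    source_index: int
    subsample_index: int
    source_name: str
    locations: MissingLocations
    estimates: np.ndarray              # aligned with locations.triples
    subsampled_features: list[str] | None = None

    def at(self, positions: np.ndarray) -> np.ndarray:
        return self.estimates[positions]


@dataclass
class EnsembleWeights:
    """Simplex weights over basic models: non-negative, summing to one."""

    weights: np.ndarray
    model_keys: list[str] = field(default_factory=list)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < -SIMPLEX_TOL):
            raise ValueError("negative ensemble weight")
        if abs(w.sum() - 1.0) > SIMPLEX_TOL:
            raise ValueError("ensemble weights do not sum to 1")
        self.weights = np.clip(w, 0.0, None)

    def by_source(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for key, w in zip(self.model_keys, self.weights):
            src = key.split(":", 1)[0]
            out[src] = out.get(src, 0.0) + float(w)
        return out


@dataclass
class MultiOmicsResult:
    matrix: OmicsMatrix
    weights: EnsembleWeights | None
    report: dict


# ---------------------------------------------------------------------------

def make_faking_missing(m: OmicsMatrix, fraction: float, seed: int) -> MissingLocations:
    """Plant fake missing locations at observed entries, disjoint from the
    true missing set; size = round(fraction x observed count)."""
    rng = np.random.default_rng(seed)
    obs_r, obs_c = np.nonzero(~m.missing_mask)
    n_obs = obs_r.size
    n_fake = int(np.floor(fraction * n_obs + 0.5))
    if n_fake > n_obs:
        raise ValueError(f"requested {n_fake} fakes but only {n_obs} observed entries")
    if n_fake == 0:
        return MissingLocations([])
    pick = rng.choice(n_obs, size=n_fake, replace=False)
    return MissingLocations([(0, int(obs_r[i]), int(obs_c[i])) for i in pick])


def _self_basic_estimates(m: OmicsMatrix, locations: MissingLocations,
                          fraction: float, rng: np.random.Generator,
                          base: ImputerConfig) -> np.ndarray:
    """One subsampled self-imputation: estimates aligned with ``locations``.

    A candidate pool of round(fraction x p) feature rows is drawn and
    imputed on its own; incomplete rows outside the pool are then imputed
    in a second pass stacked on the filled pool, so every requested
    location is covered while each basic model sees a different candidate
    pool (the source of ensemble diversity).
    """
    p, n = m.shape
    n_keep = max(2, min(p, int(np.ceil(fraction * p))))
    pool = np.sort(rng.choice(p, size=n_keep, replace=False))
    in_pool = np.zeros(p, dtype=bool)
    in_pool[pool] = True
    sub = OmicsMatrix(m.values[pool], m.missing_mask[pool],
                      [m.feature_ids[i] for i in pool], list(m.sample_ids),
                      m.omics_name)
    sub_done = impute(sub, base)
    filled = np.full((p, n), np.nan)
    filled[pool] = sub_done.values

    out_rows = np.nonzero(~in_pool & m.missing_mask.any(axis=1))[0]
    if out_rows.size:
        stack_vals = np.vstack([m.values[out_rows], sub_done.values])
        stack_mask = np.vstack([m.missing_mask[out_rows],
                                np.zeros_like(sub_done.missing_mask)])
        stack = OmicsMatrix(stack_vals, stack_mask,
                            [m.feature_ids[i] for i in out_rows]
                            + [f"__pool__{f}" for f in sub_done.feature_ids],
                            list(m.sample_ids), m.omics_name)
        stack_done = impute(stack, base)
        filled[out_rows] = stack_done.values[: out_rows.size]

    complete_out = np.nonzero(~in_pool & ~m.missing_mask.any(axis=1))[0]
    filled[complete_out] = m.values[complete_out]
    return np.array([filled[r, c] for _, r, c in locations])


def _subsample_source(src: OmicsMatrix, fraction: float,
                      rng: np.random.Generator) -> OmicsMatrix:
    p = src.shape[0]
    n_keep = max(1, int(np.ceil(fraction * p)))
    if n_keep >= p:
        return src
    rows = np.sort(rng.choice(p, size=n_keep, replace=False))
    return OmicsMatrix(src.values[rows], src.missing_mask[rows],
                       [src.feature_ids[i] for i in rows], list(src.sample_ids),
                       src.omics_name)


def generate_basic_models(target: OmicsMatrix, others: list[OmicsMatrix],
                          locations: MissingLocations, cfg: EnsembleConfig,
                          prior: PriorKnowledgeGraph | None = None
                          ) -> list[BasicModelOutput]:
    """Run self-imputation and every cross-imputation, B subsamples each.

    ``target`` must already carry the union mask (true missing plus faking
    locations) so each basic model produces estimates at all of them.  The
    per-model random streams derive from ``(seed, source, subsample)`` so
    results do not depend on execution order.
    """
    idx = np.asarray(locations.triples, dtype=int)
    if idx.size and (idx[:, 0] != 0).any():
        raise ValueError("locations must address the target matrix (index 0)")
    models: list[BasicModelOutput] = []
    sources: list[tuple[int, str, OmicsMatrix | None]] = [(0, "self", None)]
    sources += [(i + 1, o.omics_name, o) for i, o in enumerate(others)]
    for si, name, src in sources:
        for b in range(cfg.B):
            rng = np.random.default_rng(
                np.random.SeedSequence([max(cfg.seed, 0), si, b]))
            try:
                if src is None:
                    est = _self_basic_estimates(target, locations,
                                                cfg.subsample_fraction, rng,
                                                cfg.base)
                    record = None
                else:
                    src_sub = _subsample_source(src, cfg.subsample_fraction, rng)
                    done = cross_impute(target, src_sub, cfg.base, prior,
                                        alpha=cfg.alpha)
                    est = np.array([done.values[r, c] for _, r, c in locations])
                    record = list(src_sub.feature_ids)
            except Exception as exc:
                warnings.warn(f"basic model {name}:{b} failed ({exc}); dropped",
                              ImputationWarning, stacklevel=2)
                continue
            models.append(BasicModelOutput(si, b, name, locations, est, record))
    if not models:
        raise RuntimeError("every basic model failed")
    return models


def solve_simplex_weights(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """argmin ||y - X beta||^2 subject to beta >= 0 and sum(beta) = 1.

    Solved by non-negative least squares with a heavily weighted
    sum-to-one penalty row, then renormalized exactly.  Degenerate designs
    (all model predictions identical) make every simplex point optimal;
    uniform weights are returned in that case.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n_models = X.shape[1]
    if n_models == 1:
        return np.ones(1)
    if np.ptp(X, axis=1).max(initial=0.0) < 1e-12:
        return np.full(n_models, 1.0 / n_models)
    scale = max(1.0, float(np.abs(X).max()))
    lam = 1e6 * scale
    A = np.vstack([X, np.full((1, n_models), lam)])
    b = np.concatenate([y, [lam]])
    beta, _ = nnls(A, b)
    s = beta.sum()
    if s <= 0:
        return np.full(n_models, 1.0 / n_models)
    return beta / s


def estimate_weights(models: list[BasicModelOutput], truth_at_fakes: np.ndarray,
                     cfg: EnsembleConfig,
                     fake_positions: np.ndarray | None = None) -> EnsembleWeights:
    """Average simplex-constrained regression weights over T bootstrap rounds.

    Each round resamples the faking locations with replacement, regresses
    the true values on the models' predictions there under the simplex
    constraint, and the T solutions are averaged (the average of simplex
    points is itself a simplex point).
    """
    if not models:
        raise ValueError("no basic models")
    n_fakes = truth_at_fakes.size
    if n_fakes == 0:
        raise ValueError("no faking locations to fit weights on")
    if fake_positions is None:
        fake_positions = np.arange(n_fakes)
    X = np.column_stack([m.at(fake_positions) for m in models])
    y = np.asarray(truth_at_fakes, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([max(cfg.seed, 0), 997]))
    acc = np.zeros(len(models))
    for _ in range(cfg.T):
        boot = rng.integers(0, n_fakes, size=n_fakes)
        acc += solve_simplex_weights(X[boot], y[boot])
    w = acc / cfg.T
    w = w / w.sum()
    keys = [f"{m.source_name}:{m.subsample_index}" for m in models]
    return EnsembleWeights(w, keys)


def combine(models: list[BasicModelOutput], w: EnsembleWeights,
            target: OmicsMatrix, locations: MissingLocations) -> OmicsMatrix:
    """Fill the target's entries at ``locations`` with the weighted model
    average; every other entry is passed through untouched."""
    if len(models) != w.weights.size:
        raise ValueError("weights not aligned with models")
    pos_of = {trip: i for i, trip in enumerate(models[0].locations.triples)}
    out = target.values.copy()
    for trip in locations:
        j = pos_of[trip]
        _, r, c = trip
        out[r, c] = float(sum(wt * m.estimates[j]
                              for wt, m in zip(w.weights, models)))
    return target.with_values(out)


def multi_omics_impute(target: OmicsMatrix, others: list[OmicsMatrix],
                       cfg: EnsembleConfig | None = None,
                       prior: PriorKnowledgeGraph | None = None) -> MultiOmicsResult:
    """Full ensemble pipeline for one target matrix.

    Plants faking locations, generates the m x B basic models on the union
    mask, fits the simplex weights on the fakes, and combines the models at
    the true missing entries.  A target without missing entries is returned
    unchanged with a no-op notice.
    """
    cfg = cfg or EnsembleConfig()
    if target.n_missing == 0:
        return MultiOmicsResult(target.copy(), None, {"note": "no missing entries"})
    for o in others:
        if o.sample_ids != target.sample_ids:
            raise ValueError("all matrices must share the sample axis")

    frac = cfg.faking_fraction
    if frac is None:
        frac = max(target.n_missing / target.missing_mask.size, 0.01)
    fakes = make_faking_missing(target, frac,
                                int(np.random.SeedSequence([max(cfg.seed, 0), 131]
                                                           ).generate_state(1)[0] % (2**31)))
    if len(fakes) < 2:
        raise ValueError("too few faking locations; increase faking_fraction")

    # weight-fitting pass: fakes hidden on top of the true missing entries
    masked_vals = target.values.copy()
    union_mask = target.missing_mask.copy()
    for _, r, c in fakes:
        union_mask[r, c] = True
        masked_vals[r, c] = np.nan
    masked = OmicsMatrix(masked_vals, union_mask, list(target.feature_ids),
                         list(target.sample_ids), target.omics_name)
    fit_models = generate_basic_models(masked, others,
                                       MissingLocations(list(fakes.triples)),
                                       cfg, prior)
    truth = np.array([target.values[r, c] for _, r, c in fakes])
    weights = estimate_weights(fit_models, truth, cfg)

    # prediction pass: same subsample streams, true missing mask only
    true_locs = MissingLocations.from_masks([target])
    models = generate_basic_models(target, others, true_locs, cfg, prior)
    if [(m.source_index, m.subsample_index) for m in models] != \
            [(m.source_index, m.subsample_index) for m in fit_models]:
        raise RuntimeError("basic models of the two passes are misaligned "
                           "(a model failed in only one pass)")
    imputed = combine(models, weights, target, true_locs)

    fake_pred = np.column_stack([m.estimates for m in fit_models]) @ weights.weights
    report = {
        "n_missing": target.n_missing,
        "n_fakes": len(fakes),
        "B": cfg.B,
        "T": cfg.T,
        "method": cfg.base.method,
        "weights": {k: float(v) for k, v in zip(weights.model_keys, weights.weights)},
        "weights_by_source": weights.by_source(),
        "faking_rmse": float(np.sqrt(np.mean((fake_pred - truth) ** 2))),
    }
    return MultiOmicsResult(imputed, weights, report)
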