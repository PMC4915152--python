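"""Single-omics imputation engines.

Five classical algorithms are provided, spanning local neighbour methods
(KNN weighted averaging, local least squares and its iterative refinement)
and global low-rank methods (EM-style SVD completion, Bayesian PCA with an
automatic-relevance-determination prior).  All operate on
:class:`~omicsfill.core.OmicsMatrix` and share two contracts: observed
entries are never altered, and results are deterministic for a fixed
configuration and seed.

These engines double as the "basic model" generators of the multi-omics
ensemble (see :mod:`omicsfill.ensemble`), where they are run on augmented
cross-omics matrices as well as on the target matrix itself.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    DegenerateRowError,
    MissingLocations,
    OmicsMatrix,
    nrmse,
)

__all__ = [
    "ImputerConfig",
    "ImputationWarning",
    "knn_impute",
    "svd_impute",
    "bpca_impute",
    "lls_impute",
    "ills_impute",
    "select_param_by_faking",
    "impute",
    "METHODS",
]

METHODS = ("knn", "svd", "bpca", "lls", "ills")


class ImputationWarning(UserWarning):
    """Non-fatal degradation during imputation (fallbacks, non-convergence)."""


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class ImputerConfig:
    """Configuration shared by the five imputation engines.

    Parameters not applicable to the chosen method are ignored.  ``None``
    means "use the method's data-dependent default": 15 neighbours for KNN,
    20% of the sample count (rounded half up, minimum 1) eigenvectors for
    SVD, ``n - 1`` principal components for BPCA, and a faking-missing
    search over ``k_range`` / ``ratio_grid`` for LLS / iLLS.
    """

    method: str = "lls"
    k_neighbors: int = 15
    n_eigen: int | None = None
    n_pcs: int | None = None
    k_lls: int | None = None            # fixed LLS neighbour count; None -> search
    k_range: tuple[int, int] | None = None   # default (2, n-1)
    ratio: float | None = None          # fixed iLLS ratio; None -> search
    ratio_grid: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))
    faking_fraction: float | None = None     # None -> observed missing rate in [0.01, 0.10]
    convergence_tol: float = 1e-5
    max_iter: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    def replace(self, **kw) -> "ImputerConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _initial_fill(m: OmicsMatrix) -> np.ndarray:
    """Working copy with missing entries filled.

    Finite values already present under the mask (a warm start from a
    previous iteration) are kept; NaNs are replaced by row means.
    """
    vals = m.values.copy()
    miss = m.missing_mask
    warm = miss & np.isfinite(vals)
    cold = miss & ~np.isfinite(vals)
    if cold.any():
        obs = ~miss
        counts = obs.sum(axis=1)
        if np.any(counts == 0):
            bad = [m.feature_ids[i] for i in np.nonzero(counts == 0)[0][:5]]
            raise DegenerateRowError(
                f"feature rows with no observed values in {m.omics_name!r}: {bad}")
        row_means = np.where(obs, vals, 0.0).sum(axis=1) / counts
        vals[cold] = np.broadcast_to(row_means[:, None], vals.shape)[cold]
    return vals


def _pairwise_masked_sq_distances(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """All-pairs squared distances over mutual-observed overlaps, rescaled to n.

    Rows with no overlap get +inf.
    """
    n = values.shape[1]
    W = (~mask).astype(float)
    X = np.where(mask, 0.0, values)
    X2 = X * X
    overlap = W @ W.T
    sq = (X2 @ W.T) + (W @ X2.T) - 2.0 * (X @ X.T)
    np.maximum(sq, 0.0, out=sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(overlap > 0, n * sq / overlap, np.inf)
    return d2


def _distances_to_rows(target: np.ndarray, target_mask: np.ndarray,
                       candidates: np.ndarray) -> np.ndarray:
    """Rescaled distances from one partially observed row to complete rows."""
    obs = ~target_mask
    n = target.size
    k = int(obs.sum())
    diff = candidates[:, obs] - target[obs]
    return np.sqrt(n / k * np.einsum("ij,ij->i", diff, diff))


def _nonmissing_passthrough(m: OmicsMatrix, filled: np.ndarray) -> OmicsMatrix:
    out = np.where(m.missing_mask, filled, m.values)
    return m.with_values(out)


# ---------------------------------------------------------------------------
# KNN
# ---------------------------------------------------------------------------

def knn_impute(m: OmicsMatrix, cfg: ImputerConfig | None = None) -> OmicsMatrix:
    """KNN imputation: inverse-distance weighted average of neighbour rows.

    For each missing entry of a target row, the k nearest rows (by masked
    Euclidean distance on the target's observed part) that are observed at
    that column contribute ``value / d`` with total weight ``1/d``.  A
    zero-distance neighbour (exact duplicate on the overlap) is copied
    directly, averaging if several are tied at distance zero.
    """
    cfg = cfg or ImputerConfig(method="knn")
    if m.n_missing == 0:
        return m.copy()
    miss = m.missing_mask
    vals = m.values_with_nan()
    out = vals.copy()
    obs_counts = (~miss).sum(axis=1)
    if np.any(obs_counts == 0):
        bad = [m.feature_ids[i] for i in np.nonzero(obs_counts == 0)[0][:5]]
        raise DegenerateRowError(f"rows with no observed values: {bad}")
    row_means = np.nansum(np.where(miss, np.nan, vals), axis=1) / obs_counts
    k = cfg.k_neighbors
    n = vals.shape[1]
    W = (~miss).astype(float)
    X = np.where(miss, 0.0, vals)
    X2 = X * X
    for t in np.nonzero(miss.any(axis=1))[0]:
        # distances from row t only, over mutual-observed overlaps
        overlap = W @ W[t]
        sq = X2 @ W[t] + W @ X2[t] - 2.0 * (X @ X[t])
        np.maximum(sq, 0.0, out=sq)
        with np.errstate(divide="ignore", invalid="ignore"):
            d2_t = np.where(overlap > 0, n * sq / overlap, np.inf)
        d2_t[t] = np.inf
        order = np.argsort(d2_t, kind="stable")
        for col in np.nonzero(miss[t])[0]:
            eligible = order[~miss[order, col] & np.isfinite(d2_t[order])]
            if eligible.size == 0:
                out[t, col] = row_means[t]
                warnings.warn(
                    f"no neighbour observed at sample {m.sample_ids[col]!r} for "
                    f"feature {m.feature_ids[t]!r}; row-mean fallback",
                    ImputationWarning, stacklevel=2)
                continue
            if eligible.size < k:
                nbrs = eligible
            else:
                nbrs = eligible[:k]
            d = np.sqrt(d2_t[nbrs])
            zero = d < 1e-12
            if zero.any():
                out[t, col] = float(np.mean(vals[nbrs[zero], col]))
            else:
                w = 1.0 / d
                out[t, col] = float(np.dot(w, vals[nbrs, col]) / w.sum())
    return _nonmissing_passthrough(m, out)


# ---------------------------------------------------------------------------
# SVD (EM completion on eigengenes)
# ---------------------------------------------------------------------------

def svd_impute(m: OmicsMatrix, cfg: ImputerConfig | None = None) -> OmicsMatrix:
    """EM-style SVD completion.

    Missing entries are row-mean initialized, then the filled matrix is
    iteratively decomposed at rank ``n_eigen`` (default: 20% of the sample
    count, rounded half up); each incomplete row is regressed on the top
    right-singular vectors (eigengenes) using its observed entries and the
    fitted values replace the missing ones, until the change at missing
    entries drops below ``convergence_tol``.
    """
    cfg = cfg or ImputerConfig(method="svd")
    if m.n_missing == 0:
        return m.copy()
    p, n = m.shape
    q = cfg.n_eigen if cfg.n_eigen is not None else max(1, _round_half_up(0.2 * n))
    q = min(q, p, n)
    miss = m.missing_mask
    filled = _initial_fill(m)
    rows_to_fix = np.nonzero(miss.any(axis=1))[0]
    prev_delta = np.inf
    for it in range(cfg.max_iter):
        # right singular vectors via the n x n Gram matrix (p is often >> n)
        evals, evecs = np.linalg.eigh(filled.T @ filled)
        V = evecs[:, ::-1][:, :q]         # n x q eigengene basis
        new = filled.copy()
        for t in rows_to_fix:
            o = ~miss[t]
            coef, *_ = np.linalg.lstsq(V[o], filled[t, o], rcond=None)
            new[t, miss[t]] = V[miss[t]] @ coef
        delta = np.abs(new[miss] - filled[miss]).max(initial=0.0)
        scale = np.abs(filled[miss]).max(initial=1.0)
        filled = new
        if delta <= cfg.convergence_tol * max(1.0, scale):
            break
        # noise floor: once the update has nearly stagnated, further
        # sweeps only shuffle noise
        if it >= 2 and delta > 0.9 * prev_delta:
            break
        prev_delta = delta
    else:
        warnings.warn("SVD imputation did not converge; returning current estimate",
                      ImputationWarning, stacklevel=2)
    return _nonmissing_passthrough(m, filled)


# ---------------------------------------------------------------------------
# BPCA
# ---------------------------------------------------------------------------

def bpca_impute(m: OmicsMatrix, cfg: ImputerConfig | None = None) -> OmicsMatrix:
    """Bayesian PCA imputation with an automatic-relevance-determination prior.

    Feature rows are modelled as noisy linear images of low-dimensional
    latent scores, ``y_t = W x_t + mu + eps``.  The number of components
    starts at the safe value ``n - 1`` and the ARD prior on the columns of
    ``W`` shrinks irrelevant components away during fitting.  Crucially,
    the factor scores of an incomplete row are inferred from its observed
    entries only (ridge-regularized by the noise variance), so a missing
    entry never feeds back into its own reconstruction; missing entries
    are refilled with the posterior-mean reconstruction every sweep.
    """
    cfg = cfg or ImputerConfig(method="bpca")
    if m.n_missing == 0:
        return m.copy()
    p, n = m.shape
    if n < 3:
        raise ValueError("BPCA needs at least 3 samples")
    q = cfg.n_pcs if cfg.n_pcs is not None else n - 1
    # stability cap: with q close to n the point-estimate EM can interpolate
    # the complete rows, collapsing the noise variance and overfitting the
    # observed part of incomplete rows; at most n/2 axes are fitted and the
    # ARD prior prunes the surplus from there
    q = max(1, min(q, n - 1, max(1, n // 2)))
    miss = m.missing_mask
    incomplete = np.nonzero(miss.any(axis=1))[0]
    Y = _initial_fill(m)
    mu = Y.mean(axis=0)
    U, s, Vt = np.linalg.svd(Y - mu, full_matrices=False)
    q = min(q, s.size)
    W = (Vt[:q].T * (s[:q] / np.sqrt(p)))          # n x q loadings
    sigma2 = max(float(np.var(Y - mu) - np.sum(s[:q] ** 2) / (p * n)), 1e-8)
    alpha = np.full(q, 1.0)
    prev_fill = Y[miss].copy()
    prev_delta = np.inf
    converged = False
    for it in range(cfg.max_iter):
        E = Y - mu
        M = W.T @ W + sigma2 * np.eye(q)
        Minv = np.linalg.inv(M)
        X = E @ W @ Minv                            # p x q posterior means
        # observed-only posterior for incomplete rows: the filled entries
        # must not pull their own reconstruction back to the initial fill
        for t in incomplete:
            o = ~miss[t]
            Wo = W[o]
            Mo = Wo.T @ Wo + sigma2 * np.eye(q)
            X[t] = np.linalg.solve(Mo, Wo.T @ E[t, o])
        SumXX = X.T @ X + p * sigma2 * Minv
        W = E.T @ X @ np.linalg.inv(SumXX + sigma2 * np.diag(alpha))
        alpha = n / (np.einsum("ij,ij->j", W, W) + 1e-10)
        recon = X @ W.T + mu
        resid = Y - recon
        sigma2 = max(
            (float(np.einsum("ij,ij->", resid, resid))
             + p * sigma2 * float(np.trace(W.T @ W @ Minv))) / (p * n),
            1e-12)
        Y[miss] = recon[miss]
        mu = Y.mean(axis=0)
        delta = np.abs(Y[miss] - prev_fill).max(initial=0.0)
        scale = max(1.0, np.abs(prev_fill).max(initial=1.0))
        prev_fill = Y[miss].copy()
        if delta <= cfg.convergence_tol * scale:
            converged = True
            break
        if it >= 2 and delta > 0.9 * prev_delta:
            converged = True                        # stagnated at noise floor
            break
        prev_delta = delta
    if not converged:
        warnings.warn("BPCA did not converge; returning current estimate",
                      ImputationWarning, stacklevel=2)
    return _nonmissing_passthrough(m, Y)


# ---------------------------------------------------------------------------
# LLS / iLLS
# ---------------------------------------------------------------------------

def _lls_fill(values_filled: np.ndarray, miss: np.ndarray, k: int,
              keep: Sequence[int] | None,
              use_filled_distances: bool,
              raw_values: np.ndarray | None = None) -> np.ndarray:
    """One LLS pass: regress each incomplete row on its k nearest rows.

    ``values_filled`` must be complete; distances use either the target's
    observed part against filled candidates (classic LLS) or full filled
    vectors (iLLS refinement passes).  Forced-keep rows occupy the nearest
    neighbour slots.
    """
    p, n = values_filled.shape
    out = values_filled.copy()
    keep = [i for i in (keep or [])]
    for t in np.nonzero(miss.any(axis=1))[0]:
        o = ~miss[t]
        s = int(miss[t].sum())
        if use_filled_distances:
            diff = values_filled - values_filled[t]
            d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        else:
            d = _distances_to_rows(values_filled[t], miss[t], values_filled)
        d[t] = np.inf
        forced = [j for j in keep if j != t]
        order = np.argsort(d, kind="stable")
        rest = [j for j in order if j != t and j not in set(forced)]
        k_eff = max(1, min(k, p - 1))
        # forced predictors are always retained, even when k is smaller
        nbrs = forced + rest[: max(0, k_eff - len(forced))]
        if not nbrs:
            nbrs = rest[:1]
        Gk = values_filled[nbrs]
        if n - s < len(nbrs):
            warnings.warn(
                "fewer observed samples than neighbours; pseudo-inverse "
                "regression is underdetermined", ImputationWarning, stacklevel=3)
        beta, *_ = np.linalg.lstsq(Gk[:, o].T, values_filled[t, o], rcond=None)
        out[t, miss[t]] = Gk[:, miss[t]].T @ beta
    return out


def lls_impute(m: OmicsMatrix, cfg: ImputerConfig | None = None,
               keep: Sequence[int] | None = None) -> OmicsMatrix:
    """Local least squares imputation.

    Each incomplete row is regressed (via Moore-Penrose pseudo-inverse) on
    its k nearest candidate rows over its observed samples; the fitted
    combination predicts the missing samples.  ``keep`` lists row indices
    that must appear among the predictors regardless of distance (used by
    the prior-knowledge constraint of cross-imputation).  When ``k_lls`` is
    unset, k is chosen by the faking-missing search.
    """
    cfg = cfg or ImputerConfig(method="lls")
    if m.n_missing == 0:
        return m.copy()
    if cfg.k_lls is None:
        cfg = select_param_by_faking(m, cfg.replace(method="lls"))
    filled = _initial_fill(m)
    out = _lls_fill(filled, m.missing_mask, cfg.k_lls, keep,
                    use_filled_distances=False)
    return _nonmissing_passthrough(m, out)


def ills_impute(m: OmicsMatrix, cfg: ImputerConfig | None = None,
                keep: Sequence[int] | None = None) -> OmicsMatrix:
    """Iterative local least squares imputation.

    Repeated LLS passes in which previously imputed values of candidate
    rows are reused for both neighbour selection (full-vector distances)
    and regression.  The neighbour count is ``ratio x (p - 1)`` candidate
    rows; ``ratio`` is chosen by the faking-missing search when unset.
    """
    cfg = cfg or ImputerConfig(method="ills")
    if m.n_missing == 0:
        return m.copy()
    if cfg.ratio is None:
        cfg = select_param_by_faking(m, cfg.replace(method="ills"))
    p = m.shape[0]
    k = max(1, _round_half_up(cfg.ratio * (p - 1)))
    miss = m.missing_mask
    filled = _initial_fill(m)
    max_sweeps = min(cfg.max_iter, 50)
    prev_delta = np.inf
    for it in range(max_sweeps):
        new = _lls_fill(filled, miss, k, keep, use_filled_distances=True)
        delta = np.abs(new[miss] - filled[miss]).max(initial=0.0)
        scale = max(1.0, np.abs(filled[miss]).max(initial=1.0))
        filled = new
        if delta <= cfg.convergence_tol * scale:
            break
        if it >= 2 and delta > 0.9 * prev_delta:
            break
        prev_delta = delta
    else:
        warnings.warn("iLLS did not converge; returning current estimate",
                      ImputationWarning, stacklevel=2)
    return _nonmissing_passthrough(m, filled)


# ---------------------------------------------------------------------------
# parameter selection by faking missing values
# ---------------------------------------------------------------------------

def select_param_by_faking(m: OmicsMatrix, cfg: ImputerConfig) -> ImputerConfig:
    """Choose the LLS k (or iLLS ratio) minimizing error on planted fakes.

    Observed entries are hidden at random positions disjoint from the true
    missing set ("faking missing values"); every candidate parameter in the
    configured range is evaluated by NRMSE against the known truth at those
    positions and the minimizer (smallest value on ties) is returned in an
    updated config.  Deterministic given ``cfg.seed``.
    """
    if cfg.method not in ("lls", "ills"):
        raise ValueError("parameter search applies to lls/ills only")
    p, n = m.shape
    if cfg.method == "lls":
        lo, hi = cfg.k_range if cfg.k_range is not None else (2, n - 1)
        candidates = list(range(max(1, lo), max(1, min(hi, p - 1)) + 1))
    else:
        candidates = [r for r in cfg.ratio_grid if 0 < r <= 1]
    if not candidates:
        raise ValueError("empty parameter search range")
    if len(candidates) == 1:
        key = "k_lls" if cfg.method == "lls" else "ratio"
        return cfg.replace(**{key: candidates[0]})

    rng = np.random.default_rng(cfg.seed)
    obs_r, obs_c = np.nonzero(~m.missing_mask)
    n_obs = obs_r.size
    frac = cfg.faking_fraction
    if frac is None:
        frac = float(np.clip(m.n_missing / m.missing_mask.size, 0.01, 0.10))
    n_fake = max(2, _round_half_up(frac * n_obs))
    if n_fake >= n_obs:
        raise ValueError("not enough observed entries to host faking values")
    pick = rng.choice(n_obs, size=n_fake, replace=False)
    fr, fc = obs_r[pick], obs_c[pick]

    fake_mask = m.missing_mask.copy()
    fake_mask[fr, fc] = True
    hidden_vals = m.values.copy()
    hidden_vals[fr, fc] = np.nan
    # rows that end up with nothing observed cannot be initialized; un-fake one cell
    counts = (~fake_mask).sum(axis=1)
    for r in np.nonzero(counts == 0)[0]:
        j = np.nonzero(fake_mask[r] & ~m.missing_mask[r])[0][0]
        fake_mask[r, j] = False
        hidden_vals[r, j] = m.values[r, j]
    probe = OmicsMatrix(hidden_vals, fake_mask, list(m.feature_ids),
                        list(m.sample_ids), m.omics_name)
    fakes = np.nonzero(fake_mask & ~m.missing_mask)
    loc = MissingLocations([(0, int(r), int(c)) for r, c in zip(*fakes)])

    best_val, best_err = None, np.inf
    for cand in candidates:
        if cfg.method == "lls":
            trial = lls_impute(probe, cfg.replace(k_lls=int(cand)))
        else:
            trial = ills_impute(probe, cfg.replace(ratio=float(cand)))
        err = nrmse([m], [trial], loc)
        if err < best_err - 1e-15:
            best_val, best_err = cand, err
    key = "k_lls" if cfg.method == "lls" else "ratio"
    return cfg.replace(**{key: best_val})


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

_ENGINES = {
    "knn": knn_impute,
    "svd": svd_impute,
    "bpca": bpca_impute,
    "lls": lls_impute,
    "ills": ills_impute,
}


def impute(m: OmicsMatrix, cfg: ImputerConfig,
           keep: Sequence[int] | None = None) -> OmicsMatrix:
    """Run the configured imputation engine on one matrix.

    The prior-knowledge ``keep`` set only applies to the regression methods
    (LLS/iLLS); other engines ignore it.
    """
    engine = _ENGINES[cfg.method]
    if cfg.method in ("lls", "ills"):
        return engine(m, cfg, keep)
    return engine(m, cfg)
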