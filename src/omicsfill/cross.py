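"""Cross-omics imputation.

A target feature with missing samples in one omics layer is stacked on top
of correlated features from another layer to form an augmented matrix H,
which is then imputed by a single-omics engine; the estimate for the target
row is back-transformed to the original scale.  Optionally a prior-knowledge
edge list (e.g. STRING-style protein-protein interaction scores) forces
specific source features to stay in the LLS/iLLS regression model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import OmicsMatrix
from .imputers import ImputerConfig, ImputationWarning, _initial_fill, impute

__all__ = [
    "PriorKnowledgeGraph",
    "CrossMatrix",
    "select_correlated_features",
    "forced_keep_set",
    "build_cross_matrix",
    "cross_impute",
]

#: regression is kept over-determined: at most min(n-1, 50) source features
MAX_CROSS_FEATURES_CAP = 50


@dataclass
class PriorKnowledgeGraph:
    """Scored undirected feature-feature edges (e.g. STRING PPI scores).

    Edges are stored with a canonical (sorted) key so that (a, b) and
    (b, a) are the same edge; scores must lie in [0, 1].
    """

    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    score_threshold: float = 0.9

    @classmethod
    def from_edges(cls, triples, score_threshold: float = 0.9) -> "PriorKnowledgeGraph":
        g = cls(score_threshold=score_threshold)
        for a, b, score in triples:
            g.add_edge(str(a), str(b), float(score))
        return g

    @classmethod
    def from_file(cls, path, score_threshold: float = 0.9) -> "PriorKnowledgeGraph":
        """Read a headerless 3-column TSV (feature_a, feature_b, score)."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", header=None,
                         names=["a", "b", "score"], dtype={"a": str, "b": str})
        return cls.from_edges(df.itertuples(index=False))

    def add_edge(self, a: str, b: str, score: float) -> None:
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"edge score {score} outside [0, 1]")
        self.edges[tuple(sorted((a, b)))] = score

    def partners(self, feature_id: str, min_score: float | None = None) -> set[str]:
        thr = self.score_threshold if min_score is None else min_score
        out = set()
        for (a, b), score in self.edges.items():
            if score > thr:
                if a == feature_id:
                    out.add(b)
                elif b == feature_id:
                    out.add(a)
        return out

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class CrossMatrix:
    """The augmented matrix H: target row stacked above selected source rows.

    Every row is z-scored on its observed entries; ``row_means``/``row_sds``
    allow exact back-transformation.  Only row 0 (the target) may contain
    missing entries.
    """

    values: np.ndarray                 # (1 + k) x n, standardized
    target_mask: np.ndarray            # length-n missing mask of row 0
    row_means: np.ndarray
    row_sds: np.ndarray
    source_indices: list[int]          # source feature index per row 1..k

    def back_transform_target(self, standardized: np.ndarray) -> np.ndarray:
        return standardized * self.row_sds[0] + self.row_means[0]


def _pearson_with_pvalues(target: np.ndarray, target_mask: np.ndarray,
                          source_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided p (t-transform, n-2 df) of one partially
    observed row against every complete source row."""
    o = ~target_mask
    k = int(o.sum())
    x = target[o]
    Y = source_values[:, o]
    x_c = x - x.mean()
    Y_c = Y - Y.mean(axis=1, keepdims=True)
    x_ss = float(x_c @ x_c)
    y_ss = np.einsum("ij,ij->i", Y_c, Y_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Y_c @ x_c) / np.sqrt(y_ss * x_ss)
    r = np.where(np.isfinite(r), np.clip(r, -1.0, 1.0), 0.0)
    df = k - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0 - 1e-12, 0.0, p)
    return r, p


def select_correlated_features(target: np.ndarray, target_mask: np.ndarray,
                               source: OmicsMatrix, alpha: float = 0.05,
                               max_features: int | None = None,
                               _source_filled: np.ndarray | None = None) -> list[int]:
    """Source features significantly correlated with the target row.

    Pearson correlation on the target's observed samples against each
    (complete or filled) source row; features with two-sided p < alpha are
    returned ranked by \\|r\\| descending, ties broken by feature ID, and
    truncated to ``min(n - 1, 50)`` so the downstream regression stays
    over-determined.  Empty list signals "fall back to self-imputation".
    """
    target = np.asarray(target, dtype=float)
    target_mask = np.asarray(target_mask, dtype=bool)
    n = target.size
    if int((~target_mask).sum()) < 3:
        return []
    src_vals = _initial_fill(source) if _source_filled is None else _source_filled
    r, p = _pearson_with_pvalues(target, target_mask, src_vals)
    hits = np.nonzero(p < alpha)[0]
    if hits.size == 0:
        return []
    order = sorted(hits, key=lambda j: (-abs(r[j]), source.feature_ids[j]))
    cap = max_features if max_features is not None else min(n - 1, MAX_CROSS_FEATURES_CAP)
    return [int(j) for j in order[:cap]]


def forced_keep_set(target_id: str, target: np.ndarray, target_mask: np.ndarray,
                    source: OmicsMatrix, prior: PriorKnowledgeGraph | None,
                    alpha: float = 0.05,
                    _source_filled: np.ndarray | None = None) -> set[int]:
    """Source features that must stay in the LLS/iLLS regression model.

    The conjunction of (i) a prior-knowledge edge to the target scoring
    above the graph threshold and (ii) significant correlation (p < alpha)
    with the target on observed samples.
    """
    if prior is None or len(prior) == 0:
        return set()
    partner_ids = prior.partners(target_id)
    if not partner_ids:
        return set()
    if int((~np.asarray(target_mask, bool)).sum()) < 3:
        return set()
    src_vals = _initial_fill(source) if _source_filled is None else _source_filled
    _, p = _pearson_with_pvalues(np.asarray(target, float),
                                 np.asarray(target_mask, bool), src_vals)
    out = set()
    for j, fid in enumerate(source.feature_ids):
        if fid in partner_ids and p[j] < alpha:
            out.add(j)
    return out


def build_cross_matrix(target: np.ndarray, target_mask: np.ndarray,
                       source: OmicsMatrix, selected: list[int],
                       _source_filled: np.ndarray | None = None) -> CrossMatrix:
    """Stack the target row over selected source rows, z-scored per row.

    Standardization uses each row's observed entries only (the target's
    missing samples are excluded from its mean/sd).  Zero-variance rows
    cannot be standardized and are dropped with a warning.
    """
    if not selected:
        raise ValueError("no source features selected")
    target = np.asarray(target, dtype=float)
    target_mask = np.asarray(target_mask, dtype=bool)
    src_vals = _initial_fill(source) if _source_filled is None else _source_filled

    t_obs = target[~target_mask]
    t_mean, t_sd = float(t_obs.mean()), float(t_obs.std(ddof=0))
    if t_sd <= 0:
        raise ValueError("target row has zero variance; cannot standardize")
    t_std = (target - t_mean) / t_sd
    t_std[target_mask] = np.nan

    sel = np.asarray(selected, dtype=int)
    V = src_vals[sel]
    # source moments over the target's observed samples, so that a source
    # row duplicating the target standardizes to the identical vector
    obs = ~target_mask
    mus = V[:, obs].mean(axis=1)
    sds = V[:, obs].std(axis=1, ddof=0)
    good = sds > 0
    if not good.all():
        bad = [source.feature_ids[j] for j in sel[~good]]
        warnings.warn(f"zero-variance source feature(s) dropped from H: {bad[:5]}",
                      ImputationWarning, stacklevel=2)
    if not good.any():
        raise ValueError("all selected source rows had zero variance")
    sel, V, mus, sds = sel[good], V[good], mus[good], sds[good]
    rows = np.vstack([t_std, (V - mus[:, None]) / sds[:, None]])
    return CrossMatrix(rows, target_mask.copy(),
                       np.concatenate([[t_mean], mus]),
                       np.concatenate([[t_sd], sds]),
                       [int(j) for j in sel])


def cross_impute(target_matrix: OmicsMatrix, source_matrix: OmicsMatrix,
                 cfg: ImputerConfig | None = None,
                 prior: PriorKnowledgeGraph | None = None,
                 alpha: float = 0.05,
                 max_features: int | None = None,
                 diagnostics: dict | None = None) -> OmicsMatrix:
    """Impute a target omics matrix using a correlated source omics matrix.

    Every target feature with missing samples is imputed through its own
    augmented matrix H of significantly correlated source features; features
    for which no source feature passes the correlation screen (or whose H
    cannot be built) keep their self-imputed values instead.  The prior
    graph, when given, forces qualifying source features into the LLS/iLLS
    predictor set.
    """
    cfg = cfg or ImputerConfig()
    if target_matrix.sample_ids != source_matrix.sample_ids:
        raise ValueError("target and source must share the sample axis")
    if target_matrix.n_missing == 0:
        return target_matrix.copy()

    out = target_matrix.values.copy()
    miss = target_matrix.missing_mask
    self_imputed: OmicsMatrix | None = None
    if max_features is None and cfg.method not in ("lls", "ills"):
        # the min(n-1, 50) cap exists to keep the LLS/iLLS regression
        # over-determined; the global engines and KNN benefit from every
        # significantly correlated source feature
        max_features = source_matrix.shape[0]

    def self_fallback() -> OmicsMatrix:
        nonlocal self_imputed
        if self_imputed is None:
            self_imputed = impute(target_matrix, cfg)
        return self_imputed

    src_filled = _initial_fill(source_matrix)
    target_nan = target_matrix.values_with_nan()
    for t in np.nonzero(miss.any(axis=1))[0]:
        row = target_nan[t]
        row_mask = miss[t]
        fid = target_matrix.feature_ids[t]
        selected = select_correlated_features(row, row_mask, source_matrix,
                                              alpha=alpha, max_features=max_features,
                                              _source_filled=src_filled)
        forced = (forced_keep_set(fid, row, row_mask, source_matrix, prior, alpha,
                                  _source_filled=src_filled)
                  if cfg.method in ("lls", "ills") else set())
        # forced features join the selection even past the |r| cap
        sel = list(dict.fromkeys(list(selected) + sorted(forced)))
        if not sel:
            out[t, row_mask] = self_fallback().values[t, row_mask]
            continue
        try:
            H = build_cross_matrix(row, row_mask, source_matrix, sel,
                                   _source_filled=src_filled)
        except ValueError:
            out[t, row_mask] = self_fallback().values[t, row_mask]
            continue
        keep_rows = [1 + H.source_indices.index(j) for j in sorted(forced)
                     if j in H.source_indices]
        if diagnostics is not None:
            diagnostics.setdefault("predictors", {})[fid] = {
                "selected": [source_matrix.feature_ids[j] for j in H.source_indices],
                "forced": [source_matrix.feature_ids[j] for j in sorted(forced)
                           if j in H.source_indices],
            }
        h_mask = np.zeros_like(H.values, dtype=bool)
        h_mask[0] = H.target_mask
        h_mat = OmicsMatrix(np.where(h_mask, np.nan, H.values), h_mask,
                            [f"__target__{fid}"]
                            + [source_matrix.feature_ids[j] for j in H.source_indices],
                            list(target_matrix.sample_ids), "H")
        try:
            h_cfg = cfg if cfg.method not in ("svd", "bpca") else cfg.replace(
                n_eigen=min(cfg.n_eigen, h_mat.shape[0]) if cfg.n_eigen else None,
                n_pcs=min(cfg.n_pcs, h_mat.shape[0] - 1) if cfg.n_pcs else None)
            h_done = impute(h_mat, h_cfg, keep=keep_rows or None)
        except Exception as exc:  # degrade, never abort the whole matrix
            warnings.warn(f"cross-imputation of feature {fid!r} failed "
                          f"({exc}); self-imputation fallback",
                          ImputationWarning, stacklevel=2)
            out[t, row_mask] = self_fallback().values[t, row_mask]
            continue
        est = H.back_transform_target(h_done.values[0])
        out[t, row_mask] = est[row_mask]
    return target_matrix.with_values(np.where(miss, out, target_matrix.values))
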