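"""Core domain types and numeric primitives shared by all imputation modules.

An omics layer is a features x samples real matrix with an explicit boolean
missing mask.  Several layers measured on the same subjects form a
:class:`MultiOmicsSet`.  Missing entries are tracked positionally through
:class:`MissingLocations` so that evaluation (NRMSE) and the iterative
multi-matrix algorithm can address them without re-deriving masks.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "MultiOmicsSet",
    "MissingLocations",
    "DegenerateRowError",
    "IdentifierError",
    "NoOverlapError",
    "read_matrix",
    "write_matrix",
    "read_locations",
    "write_locations",
    "row_mean_initialize",
    "masked_distance",
    "nrmse",
]

#: tokens interpreted as missing on read; "NA" is always written.
MISSING_TOKENS = ("NA", "NaN", "nan", "")


class IdentifierError(ValueError):
    """Duplicate or invalid feature/sample identifiers."""


class DegenerateRowError(ValueError):
    """A feature row has no observed values, so nothing can be estimated."""


class NoOverlapError(ValueError):
    """Two partially observed vectors share no mutually observed position."""


@dataclass
class OmicsMatrix:
    """One omics layer: a ``p x n`` value matrix plus a missing mask.

    Parameters
    ----------
    values
        Real matrix, features in rows and samples in columns.  Entries under
        the mask may hold any value (typically NaN, or a working estimate).
    missing_mask
        Boolean matrix of the same shape; ``True`` marks a missing entry.
    feature_ids, sample_ids
        Unique string identifiers for rows and columns.
    omics_name
        Label for the layer, e.g. ``"miRNA"``.
    """

    values: np.ndarray
    missing_mask: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    omics_name: str = "omics"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        p, n = self.values.shape
        if self.missing_mask.shape != (p, n):
            raise ValueError("mask shape must equal values shape")
        if n < 2:
            raise ValueError("need at least 2 samples")
        if p < 1:
            raise ValueError("need at least 1 feature")
        if len(self.feature_ids) != p or len(self.sample_ids) != n:
            raise IdentifierError("identifier lengths do not match matrix shape")
        if len(set(self.feature_ids)) != p:
            raise IdentifierError(f"duplicate feature IDs in {self.omics_name!r}")
        if len(set(self.sample_ids)) != n:
            raise IdentifierError(f"duplicate sample IDs in {self.omics_name!r}")
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise ValueError("non-finite value at an observed position")

    # -- convenience -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def observed_values(self) -> np.ndarray:
        return self.values[~self.missing_mask]

    def values_with_nan(self) -> np.ndarray:
        """Values with NaN written at every missing position."""
        out = self.values.copy()
        out[self.missing_mask] = np.nan
        return out

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(
            self.values.copy(),
            self.missing_mask.copy(),
            list(self.feature_ids),
            list(self.sample_ids),
            self.omics_name,
        )

    def with_values(self, values: np.ndarray, *, clear_mask: bool = False) -> "OmicsMatrix":
        mask = np.zeros_like(self.missing_mask) if clear_mask else self.missing_mask.copy()
        return OmicsMatrix(np.asarray(values, dtype=float), mask,
                           list(self.feature_ids), list(self.sample_ids), self.omics_name)


@dataclass
class MultiOmicsSet:
    """Ordered collection of omics layers sharing one sample axis."""

    matrices: list[OmicsMatrix]

    def __post_init__(self) -> None:
        if not self.matrices:
            raise ValueError("empty multi-omics set")
        ref = self.matrices[0].sample_ids
        for m in self.matrices[1:]:
            if m.sample_ids != ref:
                raise ValueError(
                    f"sample IDs of {m.omics_name!r} do not match the first matrix")
        names = [m.omics_name for m in self.matrices]
        if len(set(names)) != len(names):
            raise ValueError("omics_name values must be unique")

    @property
    def sample_ids(self) -> list[str]:
        return self.matrices[0].sample_ids

    def __len__(self) -> int:
        return len(self.matrices)

    def __iter__(self):
        return iter(self.matrices)

    def __getitem__(self, i: int) -> OmicsMatrix:
        return self.matrices[i]

    def copy(self) -> "MultiOmicsSet":
        return MultiOmicsSet([m.copy() for m in self.matrices])


@dataclass
class MissingLocations:
    """Missing entries addressed as (matrix_index, feature_index, sample_index)."""

    triples: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.triples)) != len(self.triples):
            raise ValueError("duplicate missing-location triples")

    def __len__(self) -> int:
        return len(self.triples)

    def __iter__(self):
        return iter(self.triples)

    def for_matrix(self, matrix_index: int) -> np.ndarray:
        """(k, 2) array of (feature, sample) indices belonging to one matrix."""
        rc = [(f, s) for mi, f, s in self.triples if mi == matrix_index]
        return np.asarray(rc, dtype=int).reshape(-1, 2)

    @classmethod
    def from_masks(cls, omics_set: MultiOmicsSet | Sequence[OmicsMatrix]) -> "MissingLocations":
        mats = omics_set.matrices if isinstance(omics_set, MultiOmicsSet) else list(omics_set)
        triples = []
        for mi, m in enumerate(mats):
            rows, cols = np.nonzero(m.missing_mask)
            triples.extend((mi, int(r), int(c)) for r, c in zip(rows, cols))
        return cls(triples)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sep_for(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_matrix(path, omics_name: str = "omics") -> OmicsMatrix:
    """Read a feature x sample table (TSV, or CSV by extension).

    First column holds feature IDs, header row holds sample IDs; empty cells
    and the tokens ``NA``/``NaN`` denote missing values.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str,
                     keep_default_na=False)
    feature_ids = [str(f) for f in df.index]
    sample_ids = [str(s) for s in df.columns]
    if len(set(feature_ids)) != len(feature_ids):
        raise IdentifierError(f"duplicate feature ID in {path}")
    if len(set(sample_ids)) != len(sample_ids):
        raise IdentifierError(f"duplicate sample ID in {path}")
    raw = df.to_numpy(dtype=object)
    values = np.zeros(raw.shape, dtype=float)
    mask = np.zeros(raw.shape, dtype=bool)
    for (r, c), cell in np.ndenumerate(raw):
        cell = cell.strip() if isinstance(cell, str) else cell
        if cell in MISSING_TOKENS:
            mask[r, c] = True
            values[r, c] = np.nan
        else:
            try:
                values[r, c] = float(cell)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"non-numeric cell {cell!r} at feature {feature_ids[r]!r}, "
                    f"sample {sample_ids[c]!r} in {path}") from exc
    return OmicsMatrix(values, mask, feature_ids, sample_ids, omics_name)


def write_matrix(m: OmicsMatrix, path) -> None:
    """Write a matrix in the format :func:`read_matrix` reads; missing = "NA"."""
    out = m.values.astype(object)
    out[m.missing_mask] = "NA"
    df = pd.DataFrame(out, index=pd.Index(m.feature_ids, name="feature_id"),
                      columns=m.sample_ids)
    df.to_csv(path, sep=_sep_for(path), float_format="%.17g")


def write_locations(loc: MissingLocations, omics_set: MultiOmicsSet, path) -> None:
    rows = []
    for mi, f, s in loc:
        m = omics_set[mi]
        rows.append((m.omics_name, m.feature_ids[f], m.sample_ids[s]))
    pd.DataFrame(rows, columns=["omics_name", "feature_id", "sample_id"]).to_csv(
        path, sep="\t", index=False)


def read_locations(path, omics_set: MultiOmicsSet) -> MissingLocations:
    df = pd.read_csv(path, sep="\t", dtype=str)
    name_to_idx = {m.omics_name: i for i, m in enumerate(omics_set.matrices)}
    triples = []
    for _, row in df.iterrows():
        mi = name_to_idx[row["omics_name"]]
        m = omics_set[mi]
        triples.append((mi, m.feature_ids.index(row["feature_id"]),
                        m.sample_ids.index(row["sample_id"])))
    return MissingLocations(triples)


# ---------------------------------------------------------------------------
# Numeric primitives
# ---------------------------------------------------------------------------

def row_mean_initialize(m: OmicsMatrix, *, allow_drop: bool = False) -> OmicsMatrix:
    """Replace every missing entry by the mean of its row's observed entries.

    The mask is preserved on the returned matrix so downstream code can still
    tell estimated entries from observed ones.  A row with no observed value
    raises :class:`DegenerateRowError` unless ``allow_drop`` is set, in which
    case such rows are removed.
    """
    obs = ~m.missing_mask
    counts = obs.sum(axis=1)
    if np.any(counts == 0):
        if not allow_drop:
            bad = [m.feature_ids[i] for i in np.nonzero(counts == 0)[0][:5]]
            raise DegenerateRowError(
                f"feature rows with no observed values in {m.omics_name!r}: {bad}")
        keep = counts > 0
        m = OmicsMatrix(m.values[keep], m.missing_mask[keep],
                        [f for f, k in zip(m.feature_ids, keep) if k],
                        list(m.sample_ids), m.omics_name)
        obs = ~m.missing_mask
        counts = obs.sum(axis=1)
    vals = np.where(obs, m.values, 0.0)
    row_means = vals.sum(axis=1) / counts
    filled = np.where(m.missing_mask, row_means[:, None], m.values)
    return m.with_values(filled)


def masked_distance(a: np.ndarray, b: np.ndarray,
                    a_mask: np.ndarray | None = None,
                    b_mask: np.ndarray | None = None) -> float:
    """Euclidean distance over the mutually observed overlap, rescaled to n.

    ``sqrt((n/|O|) * sum_{j in O} (a_j - b_j)^2)`` where O is the set of
    positions observed in both vectors.  Missing entries may be given either
    as NaN or through explicit masks.  Rescaling makes distances comparable
    between candidate rows with different overlap sizes.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    miss_a = np.isnan(a) if a_mask is None else (np.asarray(a_mask, bool) | np.isnan(a))
    miss_b = np.isnan(b) if b_mask is None else (np.asarray(b_mask, bool) | np.isnan(b))
    overlap = ~(miss_a | miss_b)
    n_overlap = int(overlap.sum())
    if n_overlap == 0:
        raise NoOverlapError("vectors share no mutually observed position")
    diff = a[overlap] - b[overlap]
    return math.sqrt(len(a) / n_overlap * float(diff @ diff))


def nrmse(truth: Sequence[OmicsMatrix] | MultiOmicsSet,
          imputed: Sequence[OmicsMatrix] | MultiOmicsSet,
          locations: MissingLocations) -> float:
    """Normalized root mean squared imputation error at the given locations.

    ``sqrt(mean((true - imputed)^2) / var(true))`` with the squared residual
    averaged over all locations and ``var`` the sample variance (ddof=1) of
    the true values pooled over every location across matrices.  0 means
    perfect recovery; values near 1 mean the imputation is no better than
    predicting the pooled mean.
    """
    t_mats = truth.matrices if isinstance(truth, MultiOmicsSet) else list(truth)
    i_mats = imputed.matrices if isinstance(imputed, MultiOmicsSet) else list(imputed)
    if len(locations) == 0:
        raise ValueError("no missing locations to evaluate")
    idx = np.asarray(locations.triples, dtype=int)
    true_vals = np.empty(len(idx))
    imp_vals = np.empty(len(idx))
    for mi in np.unique(idx[:, 0]):
        sel = idx[:, 0] == mi
        r, c = idx[sel, 1], idx[sel, 2]
        true_vals[sel] = t_mats[mi].values[r, c]
        imp_vals[sel] = i_mats[mi].values[r, c]
    var = float(np.var(true_vals, ddof=1)) if len(idx) > 1 else 0.0
    if var <= 0.0:
        raise ValueError("pooled variance of true values at locations is zero")
    mse = float(np.mean((true_vals - imp_vals) ** 2))
    return math.sqrt(mse / var)
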