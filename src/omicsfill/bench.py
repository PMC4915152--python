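"""Synthetic multi-omics generation and the evaluation harness.

The generator emulates TCGA-style correlated omics layers with a shared
latent factor model: every layer is ``G_i = L_i F + E_i`` where the factor
matrix F is common to all layers (this is what makes cross-omics
imputation informative) and E_i is i.i.d. Gaussian noise.  Missingness is
injected as MCAR (uniform entries) or MAR (contiguous blocks of
neighbouring feature rows, emulating slide contamination).  Evaluation
covers NRMSE sweeps with paired t-tests and recovery of the cross-layer
Pearson correlation network as a ROC/AUC classification task.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

from .core import MissingLocations, MultiOmicsSet, OmicsMatrix, nrmse
from .ensemble import EnsembleConfig, multi_omics_impute
from .imputers import ImputerConfig, impute

__all__ = [
    "SimulationConfig",
    "EvaluationReport",
    "generate_multiomics",
    "inject_mcar",
    "inject_mar",
    "add_noise",
    "subsample_samples",
    "paired_t_test",
    "correlation_network",
    "network_recovery_roc",
    "run_benchmark",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Shared-latent-factor synthetic multi-omics generator settings.

    Defaults emulate the shape ratios of a TCGA-style study (a small miRNA
    layer next to large mRNA and methylation layers) at desk scale:
    300/60/250 features on 50 samples, rank-3 shared structure, noise sd
    0.3, 5% MCAR.
    """

    n_samples: int = 50
    n_features: tuple[int, ...] = (300, 60, 250)
    omics_names: tuple[str, ...] = ("mRNA", "miRNA", "methylation")
    latent_rank: int = 3
    loading_scale: float = 1.0
    noise_sd: float = 0.3
    missing_rate: float = 0.05
    mechanism: str = "MCAR"
    mar_block_size: int = 5
    n_replicates: int = 50
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.latent_rank >= self.n_samples:
            raise ValueError("latent_rank must be < n_samples")
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError("mechanism must be MCAR or MAR")
        if len(self.n_features) != len(self.omics_names):
            raise ValueError("n_features and omics_names lengths differ")


def generate_multiomics(cfg: SimulationConfig) -> MultiOmicsSet:
    """Draw a complete, correlated multi-omics ground-truth set.

    ``G_i = L_i F + E_i`` with F ~ N(0,1) of shape (rank x n) shared across
    layers, loadings L_i ~ N(0, loading_scale^2), noise E_i ~ N(0, sd^2).
    """
    rng = np.random.default_rng(cfg.seed)
    F = rng.standard_normal((cfg.latent_rank, cfg.n_samples))
    sample_ids = [f"S{j:03d}" for j in range(cfg.n_samples)]
    mats = []
    for name, p in zip(cfg.omics_names, cfg.n_features):
        L = cfg.loading_scale * rng.standard_normal((p, cfg.latent_rank))
        G = L @ F + cfg.noise_sd * rng.standard_normal((p, cfg.n_samples))
        mats.append(OmicsMatrix(G, np.zeros_like(G, dtype=bool),
                                [f"{name}_{i:04d}" for i in range(p)],
                                sample_ids, name))
    return MultiOmicsSet(mats)


def inject_mcar(m: OmicsMatrix, rate: float, seed: int
                ) -> tuple[OmicsMatrix, MissingLocations]:
    """Mask exactly round(rate x p x n) uniformly random entries."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    p, n = m.shape
    n_mask = int(np.floor(rate * p * n + 0.5))
    out = m.copy()
    if n_mask == 0:
        return out, MissingLocations([])
    flat = rng.choice(p * n, size=n_mask, replace=False)
    rows, cols = np.unravel_index(flat, (p, n))
    out.missing_mask[rows, cols] = True
    out.values[out.missing_mask] = np.nan
    return out, MissingLocations([(0, int(r), int(c)) for r, c in zip(rows, cols)])


def inject_mar(m: OmicsMatrix, rate: float, block_size: int, seed: int
               ) -> tuple[OmicsMatrix, MissingLocations]:
    """Mask contiguous runs of ``block_size`` adjacent feature rows.

    Random (anchor row, sample) pairs are drawn and the block of rows
    anchored there is masked at that sample, until the target count
    round(rate x p x n) is reached or exceeded — neighbouring features
    share missingness, as with contaminated array regions.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    rng = np.random.default_rng(seed)
    p, n = m.shape
    target_count = int(np.floor(rate * p * n + 0.5))
    mask = m.missing_mask.copy()
    base_missing = int(mask.sum())
    guard = 0
    while int(mask.sum()) - base_missing < target_count and guard < 100 * p * n:
        guard += 1
        anchor = int(rng.integers(0, max(1, p - block_size + 1)))
        col = int(rng.integers(0, n))
        mask[anchor:anchor + block_size, col] = True
    out = m.copy()
    new = mask & ~m.missing_mask
    out.missing_mask |= new
    out.values[out.missing_mask] = np.nan
    rows, cols = np.nonzero(new)
    return out, MissingLocations([(0, int(r), int(c)) for r, c in zip(rows, cols)])


def add_noise(m: OmicsMatrix, sd: float, seed: int) -> OmicsMatrix:
    """Add i.i.d. N(0, sd^2) noise to every entry; mask untouched."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return m.copy()
    rng = np.random.default_rng(seed)
    out = m.copy()
    out.values = out.values + sd * rng.standard_normal(out.shape)
    out.values[out.missing_mask] = np.nan
    return out


def subsample_samples(omics_set: MultiOmicsSet, n_keep: int, seed: int) -> MultiOmicsSet:
    """Keep the same random sample subset in every matrix, order preserved."""
    n = len(omics_set.sample_ids)
    if not 2 <= n_keep <= n:
        raise ValueError(f"n_keep must be in [2, {n}]")
    if n_keep == n:
        return omics_set.copy()
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=n_keep, replace=False))
    mats = []
    for m in omics_set:
        mats.append(OmicsMatrix(m.values[:, keep], m.missing_mask[:, keep],
                                list(m.feature_ids),
                                [m.sample_ids[j] for j in keep], m.omics_name))
    return MultiOmicsSet(mats)


def paired_t_test(a, b) -> float:
    """Two-sided paired t-test p-value on per-replicate score differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.allclose(a, b):
        return 1.0
    return float(stats.ttest_rel(a, b).pvalue)


def correlation_network(a: OmicsMatrix, b: OmicsMatrix) -> np.ndarray:
    """p_a x p_b matrix of Pearson correlations across shared samples.

    Zero-variance features get zero correlations (with a warning) rather
    than NaN, so downstream thresholding stays well defined.
    """
    if a.sample_ids != b.sample_ids:
        raise ValueError("matrices must share the sample axis")
    if len(a.sample_ids) < 3:
        raise ValueError("need at least 3 samples")
    if a.n_missing or b.n_missing:
        raise ValueError("matrices must be complete (impute first)")
    A = a.values - a.values.mean(axis=1, keepdims=True)
    B = b.values - b.values.mean(axis=1, keepdims=True)
    sa = np.sqrt(np.einsum("ij,ij->i", A, A))
    sb = np.sqrt(np.einsum("ij,ij->i", B, B))
    bad_a, bad_b = sa <= 0, sb <= 0
    if bad_a.any() or bad_b.any():
        import warnings

        warnings.warn("zero-variance feature(s); their correlations set to 0")
    sa[bad_a] = 1.0
    sb[bad_b] = 1.0
    r = (A @ B.T) / np.outer(sa, sb)
    r[bad_a, :] = 0.0
    r[:, bad_b] = 0.0
    return np.clip(r, -1.0, 1.0)


def network_recovery_roc(truth_corr: np.ndarray, imputed_corr: np.ndarray,
                         truth_threshold: float
                         ) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC of re-detecting complete-data correlation edges from imputed data.

    Positives are pairs whose true correlation lies beyond the threshold in
    its own direction (r < thr for a negative thr such as -0.55, r > thr
    for a positive one); the classifier score is the imputed correlation,
    oriented the same way.  Returns (fpr, tpr, auc).
    """
    truth_corr = np.asarray(truth_corr, dtype=float)
    imputed_corr = np.asarray(imputed_corr, dtype=float)
    if truth_corr.shape != imputed_corr.shape:
        raise ValueError("correlation matrices must have the same shape")
    if truth_threshold < 0:
        labels = (truth_corr < truth_threshold).ravel()
        scores = -imputed_corr.ravel()
    else:
        labels = (truth_corr > truth_threshold).ravel()
        scores = imputed_corr.ravel()
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("ROC undefined: need both positive and negative pairs")
    fpr, tpr, _ = _roc_curve(labels.astype(int), scores)
    return fpr, tpr, float(_auc(fpr, tpr))


# ---------------------------------------------------------------------------
# sweep harness
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Long-form NRMSE table plus paired-test summaries of one sweep."""

    nrmse_long: pd.DataFrame
    ttests: pd.DataFrame
    config: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        keys = [c for c in ("missing_rate", "sample_size", "noise_sd", "mechanism")
                if c in self.nrmse_long.columns]
        return (self.nrmse_long
                .groupby(keys + ["method", "arm"], sort=True)["nrmse"]
                .agg(["mean", "std", "count"]).reset_index())

    def to_files(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.nrmse_long.to_csv(outdir / "nrmse_long.tsv", sep="\t", index=False)
        self.ttests.to_csv(outdir / "ttests.tsv", sep="\t", index=False)
        report = {"config": self.config,
                  "summary": self.summary().to_dict(orient="records")}
        (outdir / "report.json").write_text(json.dumps(report, indent=2))


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def run_benchmark(cfg: SimulationConfig, methods: list[str],
                  sweep: dict | None = None,
                  arms: tuple[str, ...] = ("single", "multi"),
                  ensemble: EnsembleConfig | None = None,
                  target_index: int = 1,
                  imputer_kwargs: dict | None = None) -> EvaluationReport:
    """Factorial NRMSE sweep comparing single- and multi-omics imputation.

    ``sweep`` maps any of {"missing_rate", "sample_size", "noise_sd"} to a
    grid; omitted factors stay at their ``cfg`` value.  Within a replicate
    all methods and arms see bit-identical data and masks (paired design,
    required for the paired t-test).  The matrix at ``target_index``
    (default: the small miRNA-like layer) receives the missingness.
    """
    sweep = sweep or {}
    rates = sweep.get("missing_rate", [cfg.missing_rate])
    sizes = sweep.get("sample_size", [cfg.n_samples])
    noises = sweep.get("noise_sd", [None])   # None -> noise already in generator
    imputer_kwargs = imputer_kwargs or {}
    rows = []
    for rate in rates:
        for size in sizes:
            for extra_sd in noises:
                for rep in range(cfg.n_replicates):
                    truth = generate_multiomics(
                        SimulationConfig(**{**cfg.__dict__,
                                            "seed": _derive_seed(cfg.seed, rep)}))
                    if size != cfg.n_samples:
                        truth = subsample_samples(truth, size,
                                                  _derive_seed(cfg.seed, rep, 7))
                    work = truth.copy()
                    if extra_sd:
                        work = MultiOmicsSet([
                            add_noise(m, extra_sd, _derive_seed(cfg.seed, rep, 11, i))
                            for i, m in enumerate(work)])
                    target_truth = work[target_index]
                    if cfg.mechanism == "MCAR":
                        masked, loc = inject_mcar(target_truth, rate,
                                                  _derive_seed(cfg.seed, rep, 13))
                    else:
                        masked, loc = inject_mar(target_truth, rate,
                                                 cfg.mar_block_size,
                                                 _derive_seed(cfg.seed, rep, 13))
                    others = [m for i, m in enumerate(work) if i != target_index]
                    for method in methods:
                        base = ImputerConfig(method=method,
                                             seed=_derive_seed(cfg.seed, rep, 17),
                                             **imputer_kwargs.get(method, {}))
                        cell = {"missing_rate": rate, "sample_size": size,
                                "noise_sd": extra_sd if extra_sd else cfg.noise_sd,
                                "mechanism": cfg.mechanism,
                                "method": method, "replicate": rep}
                        try:
                            if "single" in arms:
                                single = impute(masked, base)
                                rows.append({**cell, "arm": "single",
                                             "nrmse": nrmse([target_truth], [single], loc)})
                            if "multi" in arms:
                                ens = ensemble or EnsembleConfig()
                                ens = EnsembleConfig(
                                    B=ens.B, subsample_fraction=ens.subsample_fraction,
                                    T=ens.T, faking_fraction=ens.faking_fraction,
                                    base=base, alpha=ens.alpha,
                                    seed=_derive_seed(cfg.seed, rep, 19))
                                multi = multi_omics_impute(masked, others, ens).matrix
                                rows.append({**cell, "arm": "multi",
                                             "nrmse": nrmse([target_truth], [multi], loc)})
                        except Exception as exc:
                            rows.append({**cell, "arm": "failed", "nrmse": np.nan,
                                         "error": str(exc)})
    df = pd.DataFrame(rows)
    tt = _pairwise_ttests(df)
    return EvaluationReport(df, tt, config={"methods": methods,
                                            "mechanism": cfg.mechanism,
                                            "n_replicates": cfg.n_replicates})


def _pairwise_ttests(df: pd.DataFrame) -> pd.DataFrame:
    """Paired t-test single vs multi per (cell, method)."""
    out = []
    keys = [c for c in ("missing_rate", "sample_size", "noise_sd", "mechanism", "method")
            if c in df.columns]
    if "arm" not in df.columns:
        return pd.DataFrame(out)
    for key_vals, grp in df[df["arm"].isin(["single", "multi"])].groupby(keys):
        wide = grp.pivot_table(index="replicate", columns="arm", values="nrmse")
        if {"single", "multi"} <= set(wide.columns) and len(wide.dropna()) >= 2:
            wide = wide.dropna()
            rec = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
            rec["mean_single"] = float(wide["single"].mean())
            rec["mean_multi"] = float(wide["multi"].mean())
            rec["p_value"] = paired_t_test(wide["single"], wide["multi"])
            out.append(rec)
    return pd.DataFrame(out)
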