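"""Data-preparation rules for the strain-by-feature phenotype matrices.

Standardization (per-feature z-scores with the n-1 standard deviation),
metabolite missing-value filtering, case-wise kNN imputation, averaging of
multiple peptides per gene, centered PCA with per-component top-contributor
export, and small correlation helpers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TraitMatrix",
    "PCAResult",
    "standardize",
    "filter_metabolites",
    "knn_impute",
    "aggregate_peptides",
    "run_pca",
    "top_contributors",
    "correlate",
]


@dataclass
class TraitMatrix:
    """Strains x features matrix with NaN as the missing-value marker."""

    data: pd.DataFrame  # rows = strains, columns = features
    standardized: bool = False
    log: list[str] = field(default_factory=list)  # processing notes (drops, warnings)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate strain ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate feature ids")
        self.data = self.data.astype(float)

    @property
    def strain_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def missing_mask(self) -> np.ndarray:
        return self.data.isna().to_numpy()

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "TraitMatrix":
        """Read a TSV/CSV with strain ids in the first column."""
        sep = "," if str(path).endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        return cls(df, **kwargs)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="strain")


@dataclass(frozen=True)
class PCAResult:
    """Centered PCA of a complete standardized matrix.

    ``loadings`` columns are orthonormal; ``scores @ loadings.T`` rebuilds
    the centered data exactly when all ``min(n - 1, F)`` components are kept.
    """

    feature_ids: tuple[str, ...]
    strain_ids: tuple[str, ...]
    loadings: np.ndarray  # features x components
    scores: np.ndarray  # strains x components
    variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def standardize(m: TraitMatrix) -> TraitMatrix:
    """Z-score each feature: mean 0, sample (n-1) s.d. 1, over observed entries.

    Constant features (zero s.d.) are dropped with a warning.  Missing
    entries stay missing.  Idempotent on complete data.
    """
    df = m.data
    counts = df.notna().sum(axis=0)
    too_few = counts[counts < 2].index.tolist()
    if too_few:
        raise ValueError(f"features with < 2 observed values: {too_few[:10]}")
    mu = df.mean(axis=0, skipna=True)
    sd = df.std(axis=0, ddof=1, skipna=True)
    constant = sd[sd == 0].index.tolist()
    log = list(m.log)
    if constant:
        warnings.warn(f"dropping {len(constant)} constant feature(s): {constant[:10]}")
        log.append(f"standardize: dropped {len(constant)} constant feature(s)")
        df = df.drop(columns=constant)
        mu = mu.drop(constant)
        sd = sd.drop(constant)
    out = (df - mu) / sd
    return TraitMatrix(out, standardized=True, log=log)


def filter_metabolites(m: TraitMatrix, excluded_strain: str | None = None) -> TraitMatrix:
    """Drop features missing in more than one strain, ignoring one strain's row.

    ``excluded_strain`` (if present in the matrix) does not count toward the
    missing-strain tally; features missing in >= 2 other strains are
    discarded, the rest kept for imputation.
    """
    df = m.data
    if excluded_strain is not None and excluded_strain in df.index:
        tally = df.drop(index=excluded_strain).isna().sum(axis=0)
    else:
        tally = df.isna().sum(axis=0)
    keep = tally[tally <= 1].index
    dropped = len(df.columns) - len(keep)
    log = list(m.log)
    log.append(f"filter_metabolites: dropped {dropped} feature(s) missing in >1 strain")
    return TraitMatrix(df[keep].copy(), standardized=m.standardized, log=log)


def knn_impute(m: TraitMatrix, k: int = 10) -> TraitMatrix:
    """Fill missing entries from the k nearest complete strain-rows.

    Distance is Euclidean over the features observed in the incomplete row;
    donors are rows with no missing values; each missing entry becomes the
    exp(-distance)-weighted mean of the donors' values.  Observed entries
    are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = m.data.copy()
    complete = df.index[df.notna().all(axis=1)]
    log = list(m.log)
    n_imputed = 0
    for strain in df.index:
        row = df.loc[strain]
        miss = row.isna()
        if not miss.any():
            continue
        donors = complete.drop(strain, errors="ignore")
        if len(donors) == 0:
            raise ValueError(f"no complete neighbor strain available to impute {strain!r}")
        kk = k
        if kk > len(donors):
            warnings.warn(
                f"k={k} exceeds {len(donors)} available neighbors for {strain!r}; using all"
            )
            kk = len(donors)
        obs_cols = row.index[~miss]
        diffs = df.loc[donors, obs_cols].to_numpy() - row[obs_cols].to_numpy()
        dist = np.sqrt((diffs**2).sum(axis=1))
        nearest = np.argsort(dist, kind="stable")[:kk]
        w = np.exp(-dist[nearest])
        if w.sum() == 0:
            w = np.ones_like(w)
        w = w / w.sum()
        fill = df.loc[donors[nearest], row.index[miss]].to_numpy()
        df.loc[strain, row.index[miss]] = w @ fill
        n_imputed += int(miss.sum())
    log.append(f"knn_impute: imputed {n_imputed} value(s) with k={k}")
    return TraitMatrix(df, standardized=m.standardized, log=log)


def aggregate_peptides(m: TraitMatrix, gene_map: Mapping[str, str]) -> TraitMatrix:
    """Average standardized peptide profiles per gene.

    Peptides absent from ``gene_map`` are excluded with a warning; genes
    represented by a single peptide pass through unchanged.
    """
    if not m.standardized:
        raise ValueError("aggregate_peptides expects a standardized matrix")
    unmapped = [p for p in m.feature_ids if p not in gene_map]
    if unmapped:
        warnings.warn(f"{len(unmapped)} peptide(s) missing from gene map; excluded")
    mapped = [p for p in m.feature_ids if p in gene_map]
    groups = pd.Series({p: gene_map[p] for p in mapped})
    out = m.data[mapped].T.groupby(groups).mean().T
    out = out.sort_index(axis=1)
    log = list(m.log)
    log.append(
        f"aggregate_peptides: {len(mapped)} peptide(s) -> {out.shape[1]} gene(s); "
        f"{len(unmapped)} unmapped"
    )
    return TraitMatrix(out, standardized=True, log=log)


def run_pca(m: TraitMatrix) -> PCAResult:
    """Centered PCA by SVD, keeping ``min(n_strains - 1, n_features)`` components."""
    if m.data.isna().to_numpy().any():
        raise ValueError("matrix has missing values; impute before PCA")
    X = m.values
    n, f = X.shape
    Xc = X - X.mean(axis=0, keepdims=True)
    k = min(n - 1, f)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # Deterministic sign: largest-magnitude loading positive per component.
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    var = s**2
    return PCAResult(
        feature_ids=tuple(m.feature_ids),
        strain_ids=tuple(m.strain_ids),
        loadings=Vt.T.copy(),
        scores=U * s,
        variance_fraction=var / var.sum(),
    )


def top_contributors(
    p: PCAResult, component: int, fraction: float = 0.10
) -> list[str]:
    """Features with the largest absolute loading on one component.

    Returns the top ``floor(fraction * n_features)`` feature ids, ranked by
    |loading| descending, ties at the cutoff broken by feature id.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if not (0 <= component < p.n_components):
        raise IndexError(f"component {component} out of range [0, {p.n_components})")
    contrib = np.abs(p.loadings[:, component])
    order = sorted(range(len(contrib)), key=lambda i: (-contrib[i], p.feature_ids[i]))
    n_top = int(np.floor(fraction * len(contrib)))
    return [p.feature_ids[i] for i in order[:n_top]]


def combine_blocks(
    blocks: Mapping[str, TraitMatrix], require_complete: bool = True
) -> TraitMatrix:
    """Concatenate standardized blocks column-wise over their shared strains.

    Feature ids are prefixed with the block name.  With
    ``require_complete`` (the default), blocks lacking strains present in
    the others are excluded with a warning rather than shrinking the strain
    set — e.g. a metabolite block missing one strain stays out of the
    combined matrix.
    """
    if not blocks:
        raise ValueError("no blocks to combine")
    for name, m in blocks.items():
        if not m.standardized:
            raise ValueError(f"block {name!r} is not standardized")
    all_strains = set().union(*(set(m.strain_ids) for m in blocks.values()))
    kept = dict(blocks)
    if require_complete:
        partial = [n for n, m in blocks.items() if set(m.strain_ids) != all_strains]
        if partial and len(partial) < len(blocks):
            warnings.warn(f"excluding block(s) lacking strains: {partial}")
            kept = {n: m for n, m in blocks.items() if n not in partial}
    strains = sorted(set.intersection(*(set(m.strain_ids) for m in kept.values())))
    frames = [
        m.data.loc[strains].add_prefix(f"{name}:") for name, m in kept.items()
    ]
    out = pd.concat(frames, axis=1)
    log = [note for m in kept.values() for note in m.log]
    log.append(f"combine_blocks: {list(kept)} over {len(strains)} strains")
    return TraitMatrix(out, standardized=True, log=log)


def correlate(x: Iterable[float], y: Iterable[float], method: str = "pearson") -> float:
    """Pearson or Spearman correlation coefficient."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")
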