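"""Generators for every input the pipeline consumes, plus the bundled strain table.

Everything is deterministic given a seed: pure-birth trees, traits drawn
from the multivariate normal implied by an evolution model, feature matrices
with planted linear effects on a lifespan-like trait, and Poisson per-base
depth profiles with an optional rDNA-like coverage spike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import DepthProfile, Region
from .pgls import EvolutionModel, covariance_matrix
from .phylo import PhyloTree, TreeGeometry, parse_newick
from .preprocess import TraitMatrix

__all__ = [
    "REFERENCE_STRAIN",
    "METABOLITE_EXCLUDED_STRAIN",
    "table1_fixture",
    "natural_isolates",
    "simulate_tree",
    "simulate_trait",
    "simulate_feature_set",
    "simulate_depth",
    "SimulationConfig",
]

REFERENCE_STRAIN = "BY4743"
#: strain lacking metabolite data, ignored by the metabolite missing-value filter
METABOLITE_EXCLUDED_STRAIN = "378604X"

_NUMERIC_COLS = [
    "max_rls",
    "mean_rls",
    "rls_se",
    "doubling_glucose_mean",
    "doubling_glucose_se",
    "doubling_glycerol_mean",
    "doubling_glycerol_se",
    "mtdna_relative_coverage",
    "cell_size",
]


def table1_fixture() -> pd.DataFrame:
    """The bundled per-strain phenotype table (22 natural isolates + BY4743).

    Columns: strain, strain_type, source, max_rls, mean_rls, rls_se,
    doubling_glucose_mean/se, doubling_glycerol_mean/se,
    mtdna_relative_coverage, cell_size.  Lifespans are cell divisions,
    doubling times minutes, cell size micrometers.
    """
    path = resources.files("pglscan").joinpath("data/table1.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    df[_NUMERIC_COLS] = df[_NUMERIC_COLS].astype(float)
    bad = df[df["mean_rls"] > df["max_rls"]]
    if not bad.empty:
        raise AssertionError(f"fixture violates mean <= max RLS: {bad['strain'].tolist()}")
    return df


def natural_isolates(table: pd.DataFrame) -> pd.DataFrame:
    """Rows for the 22 isolates, excluding the laboratory reference strain."""
    return table[table["strain"] != REFERENCE_STRAIN].reset_index(drop=True)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for :func:`simulate_feature_set`."""

    n_features: int
    n_planted: int = 0
    beta: float = 1.0
    noise_model: str = "BM"  # "BM", "Lambda", "OU" (phylogenetic) or "iid"
    noise_sigma2: float = 1.0
    lambda_: float | None = None
    alpha: float | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1 or not (0 <= self.n_planted <= self.n_features):
            raise ValueError("need n_features >= 1 and 0 <= n_planted <= n_features")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be in [0, 1]")
        if self.noise_model not in ("BM", "Lambda", "OU", "iid", "Null"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def simulate_tree(n_tips: int, seed: int) -> PhyloTree:
    """Pure-birth (Yule) tree with exponential waiting times, tips t1..tN."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)

    # Grow a list of active lineages; each split picks one uniformly.
    class _Node:
        __slots__ = ("children", "length", "label")

        def __init__(self):
            self.children = []
            self.length = 0.0
            self.label = None

    root = _Node()
    active = [root]
    while len(active) < n_tips:
        wait = rng.exponential(1.0 / len(active))
        for node in active:
            node.length += wait
        parent = active.pop(rng.integers(len(active)))
        for _ in range(2):
            child = _Node()
            parent.children.append(child)
            active.append(child)
    wait = rng.exponential(1.0 / len(active))
    for node in active:
        node.length += wait
    for i, node in enumerate(active):
        node.label = f"t{i + 1}"

    def newick(node: _Node) -> str:
        if not node.children:
            return f"{node.label}:{node.length:.12g}"
        inner = ",".join(newick(c) for c in node.children)
        return f"({inner}):{node.length:.12g}"

    text = "(" + ",".join(newick(c) for c in root.children) + ");"
    return parse_newick(text)


def simulate_trait(
    tree_or_geom: PhyloTree | TreeGeometry,
    model: EvolutionModel,
    seed: int,
    size: int = 1,
) -> np.ndarray:
    """Draw trait vectors from N(0, sigma^2 V(model)) over the tips.

    Returns shape (n_tips,) when ``size == 1``, else (size, n_tips), tip
    order matching the geometry.
    """
    geom = tree_or_geom if isinstance(tree_or_geom, TreeGeometry) else tree_or_geom.geometry()
    rng = np.random.default_rng(seed)
    V = model.sigma2 * covariance_matrix(geom, model)
    # jitter-free: V from covariance_matrix is already PD-checked
    L = np.linalg.cholesky(V)
    z = rng.standard_normal((size, geom.n))
    draws = z @ L.T
    return draws[0] if size == 1 else draws


def simulate_feature_set(
    tree_or_geom: PhyloTree | TreeGeometry,
    y: np.ndarray,
    config: SimulationConfig,
) -> tuple[TraitMatrix, pd.DataFrame]:
    """Feature matrix ``x_j = beta_j * y + eps_j`` plus its truth table.

    The first ``n_planted`` features carry slope ``beta``; the rest are
    null.  Noise is drawn per feature under the configured model
    (phylogenetic on the same tree, or iid).  Optional missingness is
    sprinkled uniformly to exercise the filter/impute stages; a
    configuration under which the missing-value filter would drop every
    feature is rejected.
    """
    geom = tree_or_geom if isinstance(tree_or_geom, TreeGeometry) else tree_or_geom.geometry()
    y = np.asarray(y, dtype=float)
    if y.shape != (geom.n,):
        raise ValueError("y must be one value per tip")
    rng = np.random.default_rng(config.seed)

    if config.noise_model in ("iid", "Null"):
        eps = rng.standard_normal((config.n_features, geom.n)) * np.sqrt(config.noise_sigma2)
    else:
        model = EvolutionModel(
            kind=config.noise_model,
            sigma2=config.noise_sigma2,
            lambda_=config.lambda_,
            alpha=config.alpha,
        )
        V = model.sigma2 * covariance_matrix(geom, model)
        L = np.linalg.cholesky(V)
        eps = rng.standard_normal((config.n_features, geom.n)) @ L.T

    betas = np.zeros(config.n_features)
    betas[: config.n_planted] = config.beta
    X = betas[:, None] * y[None, :] + eps

    if config.missing_rate > 0:
        holes = rng.random(X.shape) < config.missing_rate
        holes[:, 0] = False  # keep one strain fully observed (imputation donor pool)
        X[holes] = np.nan
        per_feature_missing = np.isnan(X).sum(axis=1)
        if (per_feature_missing > 1).all():
            raise ValueError(
                "missing_rate leaves no feature passing the missing-value filter"
            )

    feature_ids = [f"f{j + 1}" for j in range(config.n_features)]
    df = pd.DataFrame(X.T, index=list(geom.tip_order), columns=feature_ids)
    truth = pd.DataFrame({"feature": feature_ids, "beta": betas})
    return TraitMatrix(df), truth


def _roman(n: int) -> str:
    vals = [1000, 900, 500, 400, 100, 90, 50, 40, 10, 9, 5, 4, 1]
    syms = ["M", "CM", "D", "CD", "C", "XC", "L", "XL", "X", "IX", "V", "IV", "I"]
    out = []
    for v, s in zip(vals, syms):
        while n >= v:
            out.append(s)
            n -= v
    return "".join(out)


def simulate_depth(
    n_chroms: int,
    lengths: list[int] | int,
    nuclear_mean: float,
    mito_factor: float,
    seed: int,
    mito_length: int = 2_000,
    spike_region: Region | None = None,
    spike_depth: float | None = None,
) -> DepthProfile:
    """Poisson per-base depths: nuclear chrI..chrN (roman) plus mitochondrial chrM.

    The mitochondrial mean is ``mito_factor * nuclear_mean``.  If
    ``spike_region`` is given, that window's nuclear mean is raised to
    ``spike_depth`` (default 25x the nuclear mean), mimicking the rDNA
    repeat pile-up.
    """
    if n_chroms < 1:
        raise ValueError("need at least one nuclear chromosome")
    if nuclear_mean <= 0 or mito_factor <= 0:
        raise ValueError("means must be positive")
    if isinstance(lengths, int):
        lengths = [lengths] * n_chroms
    if len(lengths) != n_chroms or any(l <= 0 for l in lengths):
        raise ValueError("need one positive length per chromosome")
    rng = np.random.default_rng(seed)
    depths: dict[str, np.ndarray] = {}
    for i, length in enumerate(lengths):
        mean = np.full(length, nuclear_mean)
        name = f"chr{_roman(i + 1)}"
        if spike_region is not None and spike_region.chrom == name:
            if spike_region.end > length:
                raise ValueError(
                    f"spike region exceeds {name} length {length}"
                )
            mean[spike_region.start - 1 : spike_region.end] = (
                spike_depth if spike_depth is not None else 25.0 * nuclear_mean
            )
        depths[name] = rng.poisson(mean).astype(float)
    if spike_region is not None and spike_region.chrom not in depths:
        raise ValueError(f"spike region names absent chromosome {spike_region.chrom!r}")
    depths["chrM"] = rng.poisson(
        mito_factor * nuclear_mean, size=mito_length
    ).astype(float)
    return DepthProfile(depths, mito="chrM")
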