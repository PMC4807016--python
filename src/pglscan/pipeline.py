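"""End-to-end orchestration: measures, the association scan, and top-hit calling.

The scan regresses every feature (response) on each of four lifespan
measures (predictor) under all four evolution models, keeps the ML-selected
model, and optionally reruns each fit with every strain left out.  A feature
is a top hit when its slope is significant under at least two distinct
measures; the leave-one-out filter additionally demands that each counted
measure stays significant with any single strain removed.
"""

from __future__ import annotations

import json
import platform
import sys
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .pgls import (
    FitError,
    fit_all_models,
    loo_pvalues,
    select_best_model,
)
from .phylo import PhyloTree, TreeGeometry, parse_newick
from .preprocess import (
    TraitMatrix,
    correlate,
    filter_metabolites,
    knn_impute,
    run_pca,
    standardize,
    top_contributors,
)

__all__ = [
    "RLS_MEASURES",
    "build_rls_measures",
    "association_scan",
    "call_top_hits",
    "run_analysis",
]

RLS_MEASURES = ("mean_rls", "max_rls", "log_mean_rls", "log_max_rls")

RECORD_COLUMNS = [
    "feature_id",
    "data_layer",
    "rls_measure",
    "model",
    "parameter",
    "slope",
    "p_slope",
    "max_loo_p",
    "converged",
]


def build_rls_measures(table: pd.DataFrame, log_base: float | None = None) -> pd.DataFrame:
    """Four lifespan measures per strain: mean, max, and their (natural) logs.

    ``table`` needs columns ``strain``, ``mean_rls``, ``max_rls`` with
    strictly positive lifespans.  ``log_base`` overrides the natural log;
    slope-test p-values do not depend on the base.
    """
    for col in ("mean_rls", "max_rls"):
        if (table[col] <= 0).any():
            bad = table.loc[table[col] <= 0, "strain"].tolist()
            raise ValueError(f"nonpositive {col} for strains {bad}")
    out = pd.DataFrame(
        {
            "mean_rls": table["mean_rls"].to_numpy(float),
            "max_rls": table["max_rls"].to_numpy(float),
        },
        index=pd.Index(table["strain"].astype(str), name="strain"),
    )
    log = np.log if log_base is None else (lambda v: np.log(v) / np.log(log_base))
    out["log_mean_rls"] = log(out["mean_rls"])
    out["log_max_rls"] = log(out["max_rls"])
    return out


def _align(block: TraitMatrix, measures: pd.DataFrame, geom: TreeGeometry):
    strains = [
        s for s in geom.tip_order if s in set(block.strain_ids) & set(measures.index)
    ]
    dropped = sorted(
        (set(block.strain_ids) | set(measures.index) | set(geom.tip_order))
        - set(strains)
    )
    if len(strains) < 4:
        raise ValueError(
            f"only {len(strains)} strains shared by block, measures and tree "
            f"(dropped: {dropped})"
        )
    return strains, dropped


def association_scan(
    blocks: dict[str, TraitMatrix],
    measures: pd.DataFrame,
    tree: PhyloTree | TreeGeometry,
    loo: bool = True,
    progress: bool = False,
) -> pd.DataFrame:
    """PGLS of every feature against every lifespan measure.

    Strains are inner-joined across each block, the measure table and the
    tree tips; dropped strains are reported via a warning.  Each (feature,
    measure) cell carries the ML-selected model, its parameter, the slope
    and its p-value, and (if ``loo``) the worst leave-one-out p-value.
    """
    geom = tree if isinstance(tree, TreeGeometry) else tree.geometry()
    rows: list[dict] = []
    for layer, block in blocks.items():
        strains, dropped = _align(block, measures, geom)
        if dropped:
            warnings.warn(f"layer {layer!r}: strains dropped from scan: {dropped}")
        sub_geom = geom.subset(strains)
        data = block.data.loc[strains]
        meas = measures.loc[strains]
        for feature in data.columns:
            y = data[feature].to_numpy(float)
            if np.isnan(y).any():
                raise ValueError(
                    f"feature {feature!r} in layer {layer!r} has missing values; "
                    "impute before scanning"
                )
            for measure in meas.columns:
                x = meas[measure].to_numpy(float)
                try:
                    best = select_best_model(fit_all_models(y, x, sub_geom))
                except FitError:
                    rows.append(
                        dict(
                            feature_id=feature, data_layer=layer, rls_measure=measure,
                            model=None, parameter=np.nan, slope=np.nan,
                            p_slope=np.nan, max_loo_p=np.nan, converged=False,
                        )
                    )
                    continue
                max_loo_p = np.nan
                if loo:
                    max_loo_p = loo_pvalues(y, x, sub_geom, best.model.kind).max_p
                rows.append(
                    dict(
                        feature_id=feature,
                        data_layer=layer,
                        rls_measure=measure,
                        model=best.model.kind,
                        parameter=(
                            np.nan if best.model.parameter is None else best.model.parameter
                        ),
                        slope=best.fit.slope,
                        p_slope=best.p_slope,
                        max_loo_p=max_loo_p,
                        converged=best.converged,
                    )
                )
        if progress:
            print(f"scanned layer {layer}: {data.shape[1]} features", file=sys.stderr)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def call_top_hits(
    records: pd.DataFrame,
    alpha: float = 0.05,
    min_measures: int = 2,
    require_robust: bool = False,
) -> pd.DataFrame:
    """Features with slope p < alpha under at least ``min_measures`` measures.

    With ``require_robust``, a measure only counts when its worst
    leave-one-out p-value is also below alpha, so hits driven by a single
    strain are excluded.  Returns one row per hit with per-measure p-values
    and a robustness flag (all counted measures LOO-stable).
    """
    hits = []
    for (feature, layer), grp in records.groupby(
        ["feature_id", "data_layer"], sort=False
    ):
        sig = grp["p_slope"] < alpha
        if require_robust:
            sig &= grp["max_loo_p"] < alpha
        n_sig = int(sig.sum())
        if n_sig < min_measures:
            continue
        row = {
            "feature_id": feature,
            "data_layer": layer,
            "n_significant_measures": n_sig,
            "robust": bool((grp.loc[sig, "max_loo_p"] < alpha).all()),
        }
        for _, r in grp.iterrows():
            row[f"p_{r['rls_measure']}"] = r["p_slope"]
        hits.append(row)
    cols = ["feature_id", "data_layer", "n_significant_measures", "robust"] + [
        f"p_{m}" for m in RLS_MEASURES
    ]
    out = pd.DataFrame(hits)
    if out.empty:
        return pd.DataFrame(columns=cols)
    return out.reindex(columns=cols).sort_values(
        ["data_layer", "feature_id"], kind="stable"
    ).reset_index(drop=True)


def two_group_design(
    long_lived: list[str], short_lived: list[str]
) -> pd.DataFrame:
    """Design table for an external differential-expression contrast.

    Two columns (strain, group with levels ``long``/``short``); the
    group-wise model fit itself is left to external tools.
    """
    overlap = set(long_lived) & set(short_lived)
    if overlap:
        raise ValueError(f"strains in both groups: {sorted(overlap)}")
    return pd.DataFrame(
        {
            "strain": list(long_lived) + list(short_lived),
            "group": ["long"] * len(long_lived) + ["short"] * len(short_lived),
        }
    )


# ---------------------------------------------------------------------------
# Config-driven runner


@dataclass
class _Stage:
    name: str

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") from exc


def run_analysis(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Run the configured analysis and write a report directory.

    The config (a dict or a path to JSON) either points at real inputs
    (``tree``, ``lifespan_table``, ``blocks`` mapping layer names to TSV
    matrices), requests a synthetic dataset (``synthetic`` with a seed), or
    sets ``fixture_only`` to true to compute just the summary statistics of
    the bundled strain table.  Reruns with the same config produce identical
    tables.
    """
    from . import synthetic as syn

    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"pglscan {__version__} on python {platform.python_version()}",
        f"config: {json.dumps(config, sort_keys=True)}",
    ]
    alpha = float(config.get("alpha", 0.05))
    min_measures = int(config.get("min_measures", 2))
    require_robust = bool(config.get("require_robust", True))

    # --- lifespan table and summary correlations
    with _Stage("lifespan"):
        if "lifespan_table" in config:
            table = pd.read_csv(config["lifespan_table"], sep="\t")
        elif config.get("fixture_only") or "synthetic" not in config:
            table = syn.table1_fixture()
        else:
            table = None

    if table is not None:
        with _Stage("summary"):
            nat = (
                syn.natural_isolates(table)
                if syn.REFERENCE_STRAIN in set(table["strain"])
                else table
            )
            summary = {
                "pearson_mean_vs_max_rls": correlate(nat["mean_rls"], nat["max_rls"]),
                "pearson_doubling_glucose_vs_mean_rls": correlate(
                    nat["doubling_glucose_mean"], nat["mean_rls"]
                ),
            }
            if "mtdna_relative_coverage" in nat:
                summary["pearson_mtdna_coverage_vs_mean_rls"] = correlate(
                    nat["mtdna_relative_coverage"], nat["mean_rls"]
                )
                summary["pearson_mtdna_coverage_vs_max_rls"] = correlate(
                    nat["mtdna_relative_coverage"], nat["max_rls"]
                )
            pd.Series(summary, name="value").rename_axis("statistic").to_csv(
                out / "summary.tsv", sep="\t"
            )
            log_lines.append(f"summary: {len(summary)} correlations written")

    # --- inputs for the scan
    tree = None
    blocks: dict[str, TraitMatrix] = {}
    truth = None
    with _Stage("inputs"):
        if "synthetic" in config:
            s = dict(config["synthetic"])
            seed = int(s.get("seed", config.get("seed", 0)))
            rng = np.random.default_rng(seed)
            n_tips = int(s.get("n_tips", 30))
            tree = syn.simulate_tree(n_tips, seed=int(rng.integers(2**31)))
            geom = tree.geometry()
            from .pgls import EvolutionModel

            z = syn.simulate_trait(
                geom, EvolutionModel(kind="BM"), seed=int(rng.integers(2**31))
            )
            z = (z - z.mean()) / max(z.std(), 1e-9)
            u = np.abs(rng.standard_normal(n_tips)) * 0.5
            table = pd.DataFrame(
                {
                    "strain": list(geom.tip_order),
                    "mean_rls": np.exp(z),
                    "max_rls": np.exp(z + 0.2 + u),
                }
            )
            cfg = syn.SimulationConfig(
                n_features=int(s.get("n_features", 200)),
                n_planted=int(s.get("n_planted", 10)),
                beta=float(s.get("beta", 1.0)),
                noise_model=s.get("noise_model", "iid"),
                noise_sigma2=float(s.get("noise_sigma2", 1.0)),
                missing_rate=float(s.get("missing_rate", 0.0)),
                seed=int(rng.integers(2**31)),
            )
            block, truth = syn.simulate_feature_set(geom, z, cfg)
            blocks = {"synthetic": block}
            table.to_csv(out / "lifespan.tsv", sep="\t", index=False)
            (out / "tree.nwk").write_text(tree.to_newick() + "\n")
            truth.to_csv(out / "truth.tsv", sep="\t", index=False)
            log_lines.append(f"synthetic inputs: seed={seed}, {cfg}")
        elif "tree" in config:
            tree = parse_newick(Path(config["tree"]).read_text())
            for layer, path in config.get("blocks", {}).items():
                blocks[layer] = TraitMatrix.from_tsv(path)

    # --- preprocessing
    processed: dict[str, TraitMatrix] = {}
    with _Stage("preprocess"):
        for layer, block in blocks.items():
            m = block
            if layer == "metabolite" or m.n_missing:
                m = filter_metabolites(m, excluded_strain=syn.METABOLITE_EXCLUDED_STRAIN)
            if not m.standardized:
                m = standardize(m)
            if m.n_missing:
                m = knn_impute(m, k=int(config.get("knn_k", 10)))
            processed[layer] = m
            m.to_tsv(out / f"standardized_{layer}.tsv")
            for note in m.log:
                log_lines.append(f"{layer}: {note}")

    # --- PCA top contributors
    with _Stage("pca"):
        for layer, m in processed.items():
            pca = run_pca(m)
            frac = float(config.get("pca_top_fraction", 0.10))
            for comp in range(min(3, pca.n_components)):
                top = top_contributors(pca, comp, fraction=frac)
                (out / f"pca_{layer}_pc{comp + 1}_top.txt").write_text(
                    "\n".join(top) + ("\n" if top else "")
                )
            log_lines.append(
                f"{layer}: PCA variance fractions "
                f"{np.round(pca.variance_fraction[:3], 4).tolist()}"
            )

    # --- association scan and top hits
    if tree is not None and processed and table is not None:
        with _Stage("scan"):
            measures = build_rls_measures(table)
            records = association_scan(processed, measures, tree, loo=True)
            records.to_csv(out / "associations.tsv", sep="\t", index=False)
            hits = call_top_hits(
                records,
                alpha=alpha,
                min_measures=min_measures,
                require_robust=require_robust,
            )
            hits.to_csv(out / "tophits.tsv", sep="\t", index=False)
            log_lines.append(
                f"scan: {len(records)} records, {len(hits)} top hits "
                f"(alpha={alpha}, min_measures={min_measures}, "
                f"require_robust={require_robust})"
            )
    else:
        log_lines.append("scan: skipped (no tree and feature blocks configured)")

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out
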