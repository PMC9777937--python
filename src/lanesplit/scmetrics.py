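"""Single-cell concordance metrics: QC, embedding, marker and cluster stability.

The clustering itself is not reimplemented; labels come from the synthetic
truth, from the built-in k-means baseline, or from imported files.  The
metrics quantify how far two analyses of the same cells agree:

* marker-set similarity restricted to the smaller set (overlap coefficient),
  with the convention that an empty set scores 0;
* per-cell co-membership similarity — the Jaccard index between a cell's
  cluster-mate sets under the two clusterings — a fully specified per-element
  stand-in for element-centric clustering similarity;
* the within-island nearest-neighbour fraction, probing whether a small
  subpopulation remains discrete in the embedding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind
from sklearn.cluster import KMeans

__all__ = [
    "qc_filter_cells",
    "knn_graph",
    "cluster_marker_jsi",
    "per_cell_marker_jsi",
    "per_cell_comembership_similarity",
    "comembership_summary",
    "island_nn_fraction",
    "pca_embed",
    "normalize_counts",
    "rank_markers",
    "marker_sets",
    "kmeans_clusters",
]


def qc_filter_cells(
    cm: pd.DataFrame,
    mt_genes: Optional[list[str]] = None,
    rp_genes: Optional[list[str]] = None,
    mode: str = "10x",
    min_genes: int = 1000,
    max_mt_fraction: float = 0.10,
    min_rp_fraction: float = 0.20,
    min_cells_per_feature: int = 3,
    min_features: int = 50,
) -> tuple[pd.DataFrame, dict]:
    """Cell/feature QC filters.

    ``mode="10x"``: keep cells with more than ``min_genes`` detected genes,
    mitochondrial fraction below ``max_mt_fraction`` and ribosomal-protein
    fraction above ``min_rp_fraction`` (all thresholds strict), then drop the
    MT/RP genes from the matrix.  ``mode="smartseq"``: keep features expressed
    in more than ``min_cells_per_feature`` cells and cells with more than
    ``min_features`` features.  Returns the filtered matrix and a report of
    cells removed per criterion.
    """
    if mode == "10x":
        mt_genes = mt_genes or []
        rp_genes = rp_genes or []
        missing = (set(mt_genes) | set(rp_genes)) - set(cm.index)
        if missing:
            raise ValueError(f"MT/RP genes not in matrix: {sorted(missing)[:5]}")
        detected = (cm > 0).sum(axis=0)
        totals = cm.sum(axis=0).astype(float)
        mt_frac = cm.loc[mt_genes].sum(axis=0) / totals.replace(0, np.nan) if mt_genes else pd.Series(0.0, index=cm.columns)
        rp_frac = cm.loc[rp_genes].sum(axis=0) / totals.replace(0, np.nan) if rp_genes else pd.Series(1.0, index=cm.columns)
        fail_genes = detected <= min_genes
        fail_mt = mt_frac.fillna(1.0) >= max_mt_fraction
        fail_rp = rp_frac.fillna(0.0) <= min_rp_fraction
        keep = ~(fail_genes | fail_mt | fail_rp)
        report = {
            "mode": mode,
            "removed_low_genes": int(fail_genes.sum()),
            "removed_high_mt": int(fail_mt.sum()),
            "removed_low_rp": int(fail_rp.sum()),
            "cells_removed": int((~keep).sum()),
            "cells_kept": int(keep.sum()),
        }
        if keep.sum() == 0:
            raise ValueError(f"all cells removed by QC: {report}")
        keep_genes = [g for g in cm.index if g not in set(mt_genes) | set(rp_genes)]
        return cm.loc[keep_genes, keep[keep].index], report
    if mode == "smartseq":
        feat_ok = (cm > 0).sum(axis=1) > min_cells_per_feature
        sub = cm.loc[feat_ok]
        cell_ok = (sub > 0).sum(axis=0) > min_features
        report = {
            "mode": mode,
            "features_removed": int((~feat_ok).sum()),
            "cells_removed": int((~cell_ok).sum()),
            "cells_kept": int(cell_ok.sum()),
        }
        if cell_ok.sum() == 0:
            raise ValueError(f"all cells removed by QC: {report}")
        return sub.loc[:, cell_ok[cell_ok].index], report
    raise ValueError("mode must be '10x' or 'smartseq'")


def normalize_counts(cm: pd.DataFrame, target: float = 1e4) -> pd.DataFrame:
    """Depth-normalise to ``target`` counts per cell and log1p-transform."""
    totals = cm.sum(axis=0).replace(0, np.nan)
    return np.log1p(cm / totals * target).fillna(0.0)


def pca_embed(cm: pd.DataFrame, d: int = 30, n_top_genes: int = 3000) -> pd.DataFrame:
    """PCA scores of cells on the most abundant genes.

    Selects the ``n_top_genes`` genes with the highest total (normalised)
    abundance, centres them and takes SVD-based principal components.  Sign
    convention: the largest-magnitude loading of each component is positive.
    Returns a cells x d frame (fewer columns with a warning if the rank is
    deficient).
    """
    totals = cm.sum(axis=1)
    top = totals.sort_values(ascending=False, kind="stable").index[:n_top_genes]
    x = cm.loc[top].to_numpy(dtype=float).T  # cells x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    d_eff = min(d, rank)
    if d_eff < d:
        import warnings

        warnings.warn(f"rank {rank} < requested {d} components", stacklevel=2)
    u, s, vt = u[:, :d_eff], s[:d_eff], vt[:d_eff]
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(d_eff):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u * s
    return pd.DataFrame(scores, index=cm.columns, columns=[f"PC{i + 1}" for i in range(d_eff)])


def knn_graph(emb: pd.DataFrame, k: int = 20) -> dict[str, list[str]]:
    """Euclidean k-nearest neighbours, self excluded, deterministic ties.

    Ties in distance are broken by cell order in the embedding index, so the
    neighbour lists are reproducible bit-for-bit.
    """
    n = emb.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    x = emb.to_numpy(dtype=float)
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    cells = list(emb.index)
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), d2), axis=1)
    return {cells[i]: [cells[j] for j in order[i, :k]] for i in range(n)}


def cluster_marker_jsi(ma: set | list, mb: set | list, method: str = "overlap") -> float:
    """Marker-set similarity; 0 when at least one set is empty.

    ``method="overlap"`` (default): |A∩B| / min(|A|,|B|) — the similarity
    restricted to the smaller set.  ``method="jaccard"``: classical
    |A∩B| / |A∪B|.
    """
    a, b = set(ma), set(mb)
    if not a or not b:
        return 0.0
    inter = len(a & b)
    if method == "overlap":
        return inter / min(len(a), len(b))
    if method == "jaccard":
        return inter / len(a | b)
    raise ValueError("method must be 'overlap' or 'jaccard'")


def marker_sets(mt: pd.DataFrame, top: int = 25) -> dict[str, list[str]]:
    """Top-``top`` marker genes per cluster from a ranked marker table."""
    out: dict[str, list[str]] = {}
    if mt.empty:
        return out
    for cl, sub in mt.groupby("cluster", sort=False):
        out[str(cl)] = sub["gene"].head(top).tolist()
    return out


def per_cell_marker_jsi(
    ca: pd.Series,
    cb: pd.Series,
    ma: pd.DataFrame,
    mb: pd.DataFrame,
    top: int = 25,
    method: str = "overlap",
) -> pd.Series:
    """Per-cell similarity between the marker sets of the cell's clusters.

    For each cell present in both clusterings, the marker-set similarity
    between the top-``top`` markers of its cluster in A and in B; cells
    absent from either clustering are skipped.
    """
    sets_a = marker_sets(ma, top)
    sets_b = marker_sets(mb, top)
    common = ca.index.intersection(cb.index)
    vals = {
        cell: cluster_marker_jsi(
            sets_a.get(str(ca[cell]), []), sets_b.get(str(cb[cell]), []), method=method
        )
        for cell in common
    }
    return pd.Series(vals, name="marker_jsi")


def per_cell_comembership_similarity(ca: pd.Series, cb: pd.Series) -> pd.Series:
    """Per-cell Jaccard index between cluster-mate sets under two clusterings.

    For cell i, the sets are {cells sharing i's cluster in A} and {cells
    sharing i's cluster in B}, both restricted to the common cells and
    including i itself.  1 everywhere iff the partitions coincide on the
    common cells; symmetric in its arguments.
    """
    common = ca.index.intersection(cb.index)
    if len(common) == 0:
        raise ValueError("no common cells between the two clusterings")
    a = ca[common]
    b = cb[common]
    # contingency of (label_a, label_b) pair sizes
    pair_sizes = pd.crosstab(a, b)
    size_a = a.map(a.value_counts())
    size_b = b.map(b.value_counts())
    inter = pd.Series(
        [pair_sizes.loc[a[c], b[c]] for c in common], index=common, dtype=float
    )
    sim = inter / (size_a + size_b - inter)
    return sim.rename("comembership")


def comembership_summary(sim: pd.Series, high: float = 0.6, low: float = 0.2) -> dict:
    """Fractions of cells above/below the high/low similarity thresholds."""
    return {
        "fraction_high": float((sim > high).mean()),
        "fraction_low": float((sim < low).mean()),
        "fraction_intermediate": float(((sim >= low) & (sim <= high)).mean()),
        "mean": float(sim.mean()),
    }


def island_nn_fraction(
    graph: dict[str, list[str]], island: set | list
) -> tuple[pd.Series, float]:
    """Per-island-cell fraction of neighbours inside the island, plus mean."""
    island = set(island)
    if not island:
        raise ValueError("island must be non-empty")
    missing = island - set(graph)
    if missing:
        raise ValueError(f"island cells missing from the graph: {sorted(missing)[:5]}")
    fracs = {
        c: sum(1 for nb in graph[c] if nb in island) / len(graph[c]) for c in island
    }
    series = pd.Series(fracs, name="within_island_fraction")
    return series, float(series.mean())


def rank_markers(
    cm_norm: pd.DataFrame,
    clustering: pd.Series,
    min_log2fc: float = 0.0,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Per-cluster marker table ranked by discriminative power.

    For every cluster, Welch t-tests of each gene in-cluster vs rest on the
    normalised matrix; effect size is the log2 fold change of the mean
    (de-logged) expression.  Markers are positive (effect > ``min_log2fc``),
    ranked by descending effect with adjusted-p tie-break.
    """
    rows = []
    x = cm_norm.to_numpy(dtype=float)
    cells = list(cm_norm.columns)
    lab = clustering[cells]
    for cl in pd.unique(lab):
        mask = (lab == cl).to_numpy()
        if mask.sum() < 2 or (~mask).sum() < 2:
            continue
        inside = x[:, mask]
        outside = x[:, ~mask]
        t, p = ttest_ind(inside, outside, axis=1, equal_var=False)
        mean_in = np.expm1(inside).mean(axis=1)
        mean_out = np.expm1(outside).mean(axis=1)
        effect = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        p = np.nan_to_num(p, nan=1.0)
        if correction == "bonferroni":
            padj = np.minimum(p * len(p), 1.0)
        else:
            from statsmodels.stats.multitest import multipletests

            _, padj, _, _ = multipletests(p, method="fdr_bh")
        for g, e, q in zip(cm_norm.index, effect, padj):
            if e > min_log2fc:
                rows.append({"cluster": str(cl), "gene": g, "effect_size": float(e), "padj": float(q)})
    df = pd.DataFrame(rows, columns=["cluster", "gene", "effect_size", "padj"])
    return df.sort_values(
        ["cluster", "effect_size", "padj"], ascending=[True, False, True], kind="stable"
    ).reset_index(drop=True)


def kmeans_clusters(emb: pd.DataFrame, n_clusters: int, seed: int = 0) -> pd.Series:
    """Built-in k-means baseline clustering on an embedding."""
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(emb.to_numpy(dtype=float))
    return pd.Series([f"K{l}" for l in labels], index=emb.index, name="cluster")
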