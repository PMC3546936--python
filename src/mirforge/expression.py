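"""Relative expression from stem-loop RT-PCR Ct values, and clustering.

Expression is quantified as 2^-ΔCt with ΔCt = Ct(miRNA) - Ct(5S rRNA),
normalised per tissue and replicate; replicates are averaged on the linear
scale.  Both matrix axes can be clustered by average-linkage agglomeration
on 1 - Pearson correlation of log2 expression, mirroring common
heatmap-viewer defaults.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

REFERENCE_GENE = "5S_rRNA"


def load_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = {"mirna", "tissue", "replicate", "ct"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def relative_expression(
    ct: pd.DataFrame,
    reference: str = REFERENCE_GENE,
    replicate_agg: str = "mean_linear",
) -> pd.DataFrame:
    """miRNA x tissue matrix of 2^-ΔCt values.

    Each replicate is normalised against the same tissue/replicate Ct of
    the reference gene; ``mean_linear`` (default) averages the per-replicate
    2^-ΔCt values, ``mean_ct`` averages ΔCt before exponentiation.
    """
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    ref = ct[ct["mirna"] == reference].set_index(["tissue", "replicate"])["ct"]
    targets = ct[ct["mirna"] != reference]
    if targets.empty:
        raise ValueError("Ct table contains no miRNA rows")
    rows = {}
    for (mirna, tissue), grp in targets.groupby(["mirna", "tissue"], sort=False):
        vals = []
        for _, r in grp.iterrows():
            key = (tissue, r["replicate"])
            if key not in ref.index:
                raise ValueError(
                    f"no {reference} Ct for tissue {tissue!r} replicate {r['replicate']}"
                )
            vals.append(r["ct"] - ref.loc[key])
        dcts = np.asarray(vals, dtype=float)
        if replicate_agg == "mean_linear":
            value = float(np.mean(2.0 ** (-dcts)))
        elif replicate_agg == "mean_ct":
            value = float(2.0 ** (-np.mean(dcts)))
        else:
            raise ValueError(f"unknown replicate_agg {replicate_agg!r}")
        rows.setdefault(mirna, {})[tissue] = value
    matrix = pd.DataFrame(rows).T
    matrix = matrix.loc[targets["mirna"].unique(), targets["tissue"].unique()]
    return matrix


def _correlation_distance(values: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance over rows; constant rows -> distance 1."""
    sd = values.std(axis=1)
    if (sd == 0).any():
        warnings.warn("constant profile(s): correlation undefined, distance set to 1")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    dist = 1.0 - corr
    dist[np.isnan(dist)] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return squareform(dist, checks=False)


def hierarchical_cluster(
    matrix: pd.DataFrame,
    axis: str = "mirna",
    method: str = "average",
    metric: str = "correlation",
):
    """Cluster one axis of the expression matrix.

    Returns ``(linkage, leaf_labels, newick)``.  ``metric='correlation'``
    uses 1 - Pearson on log2 expression; ``'euclidean'`` uses log2
    Euclidean distance.
    """
    if axis not in ("mirna", "tissue"):
        raise ValueError("axis must be 'mirna' or 'tissue'")
    data = matrix if axis == "mirna" else matrix.T
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    log2 = np.log2(data.to_numpy(dtype=float))
    if metric == "correlation":
        condensed = _correlation_distance(log2)
    elif metric == "euclidean":
        from scipy.spatial.distance import pdist

        condensed = pdist(log2)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    Z = hierarchy.linkage(condensed, method=method)
    order = hierarchy.leaves_list(Z)
    labels = [data.index[i] for i in order]
    newick = _to_newick(hierarchy.to_tree(Z), list(data.index))
    return Z, labels, newick


def _to_newick(node, labels: list[str]) -> str:
    def rec(n) -> str:
        if n.is_leaf():
            return f"{labels[n.id]}:{n.dist:.6g}"
        return f"({rec(n.left)},{rec(n.right)}):{n.dist:.6g}"

    return f"({rec(node.left)},{rec(node.right)});"


def tissue_specificity(matrix: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Per-miRNA dominant tissue and expression fraction.

    A miRNA is flagged tissue-specific when its top tissue carries at least
    ``threshold`` of its summed expression across tissues.
    """
    if matrix.shape[1] < 2:
        raise ValueError("tissue specificity needs at least 2 tissues")
    totals = matrix.sum(axis=1)
    top = matrix.idxmax(axis=1)
    frac = matrix.max(axis=1) / totals
    return pd.DataFrame(
        {
            "top_tissue": top,
            "fraction": frac,
            "tissue_specific": frac >= threshold,
        }
    )


def plot_heatmap(matrix: pd.DataFrame, path=None):
    """Row-z-scored log2 heatmap with clustered axes (display only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    log2 = np.log2(matrix.to_numpy(dtype=float))
    z = (log2 - log2.mean(axis=1, keepdims=True)) / (log2.std(axis=1, keepdims=True) + 1e-12)
    _, row_order, _ = hierarchical_cluster(matrix, axis="mirna")
    _, col_order, _ = hierarchical_cluster(matrix, axis="tissue")
    zdf = pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    zdf = zdf.loc[row_order, col_order]
    fig, ax = plt.subplots(figsize=(0.5 * len(col_order) + 2, 0.2 * len(row_order) + 2))
    im = ax.imshow(zdf.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(col_order)), col_order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(row_order)), row_order, fontsize=6)
    fig.colorbar(im, ax=ax, label="row z-score of log2 expression")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
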