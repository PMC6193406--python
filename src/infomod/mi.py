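"""Mutual-information network inference.

The estimator is rank-based: both vectors are rank-transformed, cut into
``B = max(2, floor(n**(1/3)))`` equal-frequency bins, and MI is the plug-in
estimate from the joint histogram plus the Miller-Madow bias correction,
clamped at 0.  Rank transformation makes the estimate exactly invariant to
strictly monotone transforms of either input.  Values are in nats.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from infomod.dataset import ExpressionDataset

__all__ = [
    "estimate_mi",
    "build_mi_table",
    "dpi_prune",
    "prune_top_edges",
    "write_edge_list",
    "read_edge_list",
    "write_sif",
]

#: Network size used in the source analysis: the top 10,000 MI pairs.
DEFAULT_TOP_EDGES = 10_000

GeneNetwork = nx.Graph


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin labels in ``[0, n_bins)`` with (near-)equal occupancy, via ranks."""
    ranks = rankdata(x, method="ordinal") - 1  # 0 .. n-1, ties broken by order
    return (ranks * n_bins // len(x)).astype(np.int64)


def _mi_from_joint(joint: np.ndarray, n: int) -> float:
    """Plug-in MI (nats) from a joint count table, Miller-Madow corrected."""
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    mi = float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))
    # Miller-Madow on each entropy: H_mm = H + (K-1)/2n; Hxy enters MI with a
    # minus sign, so the net correction is (Kx + Ky - Kxy - 1)/2n
    correction = ((px > 0).sum() + (py > 0).sum() - nz.sum() - 1) / (2.0 * n)
    return max(mi + correction, 0.0)


def estimate_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Mutual information between two sample vectors, in nats.

    Symmetric in its arguments and invariant to strictly monotone
    transforms.  Constant vectors are degenerate and yield 0 with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 20:
        raise ValueError(f"need at least 20 samples, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: MI is degenerate, returning 0", stacklevel=2)
        return 0.0
    n_bins = max(2, int(np.floor(n ** (1.0 / 3.0))))
    bx = _equal_frequency_bins(x, n_bins)
    by = _equal_frequency_bins(y, n_bins)
    joint = np.zeros((n_bins, n_bins), dtype=np.int64)
    np.add.at(joint, (bx, by), 1)
    return _mi_from_joint(joint, n)


def build_mi_table(data: ExpressionDataset, subset: list[str] | None = None) -> pd.DataFrame:
    """MI for every unordered gene pair: columns gene_a, gene_b, mi.

    gene_a < gene_b lexicographically; rows sorted by (gene_a, gene_b).
    Pairwise joint histograms are accumulated with one-hot matrix products
    so the all-pairs sweep stays vectorized.
    """
    genes = list(data.gene_ids) if subset is None else list(subset)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids")
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    mat = np.stack([data.gene_row(g) for g in genes])
    n = mat.shape[1]
    if n < 20:
        raise ValueError(f"need at least 20 samples, got {n}")
    n_bins = max(2, int(np.floor(n ** (1.0 / 3.0))))

    n_genes = len(genes)
    constant = np.ptp(mat, axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s): their MI is set to 0", stacklevel=2
        )
    bins = np.empty((n_genes, n), dtype=np.int64)
    for i in range(n_genes):
        bins[i] = _equal_frequency_bins(mat[i], n_bins)

    # one-hot encode bins: onehot[g] is (n, B); joint(g, h) = onehot[g].T @ onehot[h]
    onehot = np.zeros((n_genes, n, n_bins))
    grid = np.arange(n)
    for i in range(n_genes):
        onehot[i, grid, bins[i]] = 1.0
    flat = onehot.transpose(1, 0, 2).reshape(n, n_genes * n_bins)

    records: list[tuple[str, str, float]] = []
    for i in range(n_genes - 1):
        joints = (onehot[i].T @ flat).reshape(n_bins, n_genes, n_bins)
        for j in range(i + 1, n_genes):
            if constant[i] or constant[j]:
                mi = 0.0
            else:
                mi = _mi_from_joint(joints[:, j, :], n)
            a, b = sorted((genes[i], genes[j]))
            records.append((a, b, mi))
    table = pd.DataFrame(records, columns=["gene_a", "gene_b", "mi"])
    return table.sort_values(["gene_a", "gene_b"], ignore_index=True)


def dpi_prune(table: pd.DataFrame, epsilon: float = 0.0) -> pd.DataFrame:
    """Data-processing-inequality pruning of an MI table.

    For every triangle (i, j, k), edge (i, j) is marked for removal when
    ``mi(i,j) < min(mi(i,k), mi(j,k)) * (1 - epsilon)``; all marked edges
    are removed simultaneously after scanning every triangle, so the
    strongest edge of a triangle is never removed.
    """
    if not (0.0 <= epsilon <= 1.0):
        raise ValueError("epsilon must lie in [0, 1]")
    weights: dict[tuple[str, str], float] = {
        (a, b): float(m) for a, b, m in table[["gene_a", "gene_b", "mi"]].itertuples(index=False)
    }
    neighbors: dict[str, set[str]] = {}
    for a, b in weights:
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)

    def w(u: str, v: str) -> float:
        return weights[(u, v)] if (u, v) in weights else weights[(v, u)]

    doomed: set[tuple[str, str]] = set()
    for (a, b), m_ab in weights.items():
        for c in neighbors[a] & neighbors[b]:
            if m_ab < min(w(a, c), w(b, c)) * (1.0 - epsilon):
                doomed.add((a, b))
                break
    keep = [pair not in doomed for pair in weights]
    return table.loc[keep].reset_index(drop=True)


def prune_top_edges(table: pd.DataFrame, k: int = DEFAULT_TOP_EDGES) -> GeneNetwork:
    """Keep the k highest-MI pairs as an undirected weighted network.

    Ties at the cutoff break by lexicographic (gene_a, gene_b).  Pairs with
    MI 0 carry no dependence and never become edges (network weights must be
    positive); genes with no surviving edge do not appear as nodes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(table) == 0:
        raise ValueError("empty MI table")
    table = table[table["mi"] > 0.0]
    ranked = table.sort_values(
        ["mi", "gene_a", "gene_b"], ascending=[False, True, True], ignore_index=True
    ).head(k)
    net = nx.Graph()
    for a, b, m in ranked[["gene_a", "gene_b", "mi"]].itertuples(index=False):
        net.add_edge(a, b, weight=float(m))
    return net


# -- interchange -----------------------------------------------------------


def write_edge_list(table_or_net: pd.DataFrame | GeneNetwork, path: str | Path) -> None:
    """Edge list TSV ``gene_a<TAB>gene_b<TAB>mi`` (6 decimals), one header line."""
    if isinstance(table_or_net, nx.Graph):
        rows = sorted(
            (min(a, b), max(a, b), d["weight"]) for a, b, d in table_or_net.edges(data=True)
        )
        table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "mi"])
    else:
        table = table_or_net
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_edge_list(path: str | Path) -> GeneNetwork:
    table = pd.read_csv(path, sep="\t")
    net = nx.Graph()
    for a, b, m in table[["gene_a", "gene_b", "mi"]].itertuples(index=False):
        net.add_edge(str(a), str(b), weight=float(m))
    return net


def write_sif(net: GeneNetwork, path: str | Path) -> None:
    """SIF lines ``gene_a mi gene_b`` for graph viewers."""
    with open(path, "w") as fh:
        for a, b in sorted((min(a, b), max(a, b)) for a, b in net.edges()):
            fh.write(f"{a}\tmi\t{b}\n")
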