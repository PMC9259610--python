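"""Denitrifier community statistics.

Abundance tables are pandas DataFrames with samples as rows and taxa as
columns (counts or relative abundances); a taxon -> marker mapping
(bnirS / bnirK / fnirK) rides along as a Series where needed.

Covers Levins' niche breadth B_i = 1/sum_j P_ij^2 (P_ij = taxon i's
proportional use of resource state j, here the samples), the asymmetric
niche overlap alpha_ij = sum_a P_ia P_ja / sum_a P_ia^2, alpha-diversity
indices (Shannon, Gini-Simpson, Chao1, ACE), Bray-Curtis distances, PCoA,
a seeded permutation ANOSIM, and correlation-threshold co-occurrence
networks (edges require r^2 > 0.90 and p < 0.05 by default) with
degree-ranked keystone extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio.diversity.alpha import ace as _skbio_ace
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

__all__ = [
    "niche_breadth",
    "niche_overlap",
    "niche_metrics",
    "diversity_indices",
    "bray_curtis",
    "pcoa",
    "anosim",
    "build_network",
    "keystone_taxa",
    "CooccurrenceNetwork",
]


def _use_profile(table: pd.DataFrame, taxon: str) -> np.ndarray:
    """Taxon's proportional use of each sample (resource state)."""
    if taxon not in table.columns:
        raise KeyError(f"taxon {taxon!r} not in table")
    x = table[taxon].to_numpy(dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError(f"taxon {taxon!r} has zero total abundance")
    return x / total


def niche_breadth(table: pd.DataFrame, taxon: str) -> float:
    """Levins breadth B = 1/sum P^2, between 1 and the number of states."""
    p = _use_profile(table, taxon)
    return 1.0 / float(np.sum(p**2))


def niche_overlap(table: pd.DataFrame, taxon_i: str, taxon_j: str) -> float:
    """Asymmetric overlap alpha_ij of taxon j's use onto taxon i's.

    alpha_ij = sum_a P_ia P_ja / sum_a P_ia^2; generally != alpha_ji.
    """
    pi = _use_profile(table, taxon_i)
    pj = _use_profile(table, taxon_j)
    denom = float(np.sum(pi**2))
    if denom == 0:
        raise ZeroDivisionError("taxon_i has no resource use")
    return float(np.sum(pi * pj)) / denom


def niche_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon breadth plus its abundance weight in the community.

    The community-level breadth is the abundance-weighted mean of the
    per-taxon values: (df['breadth'] * df['weight']).sum().
    """
    totals = table.sum(axis=0)
    totals = totals[totals > 0]
    rows = {
        t: {"breadth": niche_breadth(table, t), "weight": totals[t] / totals.sum()}
        for t in totals.index
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def _chao1(counts: np.ndarray) -> float:
    s_obs = int(np.sum(counts > 0))
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def diversity_indices(table: pd.DataFrame, sample: str) -> dict[str, float]:
    """Shannon (natural log), Gini-Simpson, Chao1 and ACE for one sample.

    Chao1 uses S_obs + F1^2/(2 F2), falling back to the bias-corrected
    F1(F1-1)/2 form when no doubletons exist; ACE uses the standard
    estimator with rare-taxon threshold 10.  Both require integer counts.
    """
    if sample not in table.index:
        raise KeyError(f"sample {sample!r} not in table")
    x = table.loc[sample].to_numpy(dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError(f"sample {sample!r} is empty")
    p = x / x.sum()
    shannon = float(-np.sum(p * np.log(p)))
    simpson = float(1.0 - np.sum(p**2))
    if not np.allclose(x, np.round(x)):
        raise ValueError("Chao1/ACE require integer counts")
    counts = np.round(x).astype(int)
    return {
        "shannon": shannon,
        "simpson": simpson,
        "chao1": float(_chao1(counts)),
        "ace": float(_skbio_ace(counts, rare_threshold=10)),
    }


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Sample-by-sample Bray-Curtis distance matrix."""
    if table.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    m = table.to_numpy(dtype=float)
    empty = m.sum(axis=1) == 0
    if empty.any():
        warnings.warn(
            f"all-zero samples (undefined pairs): {list(table.index[empty])}"
        )
    d = squareform(pdist(m, metric="braycurtis"))
    return pd.DataFrame(d, index=table.index, columns=table.index)


def pcoa(dist: pd.DataFrame, k: int = 2) -> dict:
    """Classical scaling (PCoA) of a distance matrix.

    Returns coordinates for the first ``k`` axes, per-axis explained
    proportions, and the full eigenvalue spectrum (negative eigenvalues
    from non-Euclidean input are reported, not dropped).
    """
    a = np.asarray(dist, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    ids = [str(i) for i in dist.index]
    res = _skbio_pcoa(DistanceMatrix(a, ids=ids), method="eigh")
    coords = res.samples.iloc[:, :k]
    coords.index = dist.index
    return {
        "coordinates": coords,
        "proportion_explained": res.proportion_explained.iloc[:k].to_numpy(),
        "eigenvalues": res.eigvals.to_numpy(),
    }


def anosim(
    dist: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Analysis of similarities with a seeded permutation test.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairwise distances; p is the one-sided permutation
    p-value (1 + #{R_perm >= R}) / (n_perm + 1).
    """
    labels = np.asarray(groups)
    n = len(labels)
    if dist.shape != (n, n):
        raise ValueError("groups length must match distance matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    condensed = squareform(np.asarray(dist, dtype=float), checks=False)
    ranks = rankdata(condensed)
    iu, ju = np.triu_indices(n, k=1)

    def _r(lab: np.ndarray) -> float:
        within = lab[iu] == lab[ju]
        m = ranks.size
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    r_obs = _r(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _r(rng.permutation(labels)) >= r_obs:
            hits += 1
    return {"R": float(r_obs), "p": (hits + 1) / (n_perm + 1), "n_perm": n_perm}


@dataclass
class CooccurrenceNetwork:
    """Thresholded correlation network over taxa.

    Every retained edge satisfies correlation^2 > r2_min and p < p_max.
    """

    graph: nx.Graph
    r2_min: float
    p_max: float
    method: str
    excluded: list[str] = field(default_factory=list)

    @property
    def summary(self) -> dict:
        markers = nx.get_node_attributes(self.graph, "marker")
        comp: dict[str, int] = {}
        for m in markers.values():
            comp[m] = comp.get(m, 0) + 1
        return {
            "n_nodes": self.graph.number_of_nodes(),
            "n_edges": self.graph.number_of_edges(),
            "marker_composition": comp,
        }


def _correlation_matrix(x: np.ndarray) -> np.ndarray:
    z = (x - x.mean(axis=0)) / x.std(axis=0)
    return (z.T @ z) / x.shape[0]


def build_network(
    table: pd.DataFrame,
    r2_min: float = 0.90,
    p_max: float = 0.05,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int | None = None,
    markers: pd.Series | None = None,
    min_prevalence: float = 0.5,
) -> CooccurrenceNetwork:
    """Pairwise-correlation co-occurrence network across samples.

    Correlations (Spearman by default, Pearson optional) are computed for
    every taxon pair over samples; two-sided p-values come from ``n_perm``
    seeded sample-label permutations.  Edges require correlation^2 > r2_min
    and p < p_max.  Constant taxa, and taxa present in fewer than
    ``min_prevalence`` of the samples (rank correlations of mostly-zero
    vectors are spurious), are excluded with a warning.  No
    multiple-testing correction is applied (matching the stated
    thresholds); apply one upstream if desired.
    """
    if table.shape[0] < 4:
        raise ValueError("need >= 4 samples for correlation p-values")
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    x = table.to_numpy(dtype=float)
    rare = (x > 0).mean(axis=0) < min_prevalence
    const = (x.std(axis=0) == 0) | rare
    excluded = list(table.columns[const])
    if excluded:
        warnings.warn(f"excluding constant or low-prevalence taxa: {excluded}")
    taxa = list(table.columns[~const])
    x = x[:, ~const]
    if method == "spearman":
        x = np.apply_along_axis(rankdata, 0, x)
    r = _correlation_matrix(x)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(r)
    z = (x - x.mean(axis=0)) / x.std(axis=0)
    for _ in range(n_perm):
        zp = z[rng.permutation(x.shape[0])]
        r_null = (z.T @ zp) / x.shape[0]
        # each (i, j) pair's null: x_i against permuted x_j
        exceed += np.abs(r_null) >= np.abs(r) - 1e-12
    pvals = (exceed + 1.0) / (n_perm + 1.0)
    g = nx.Graph()
    for t in taxa:
        g.add_node(t, marker=(markers.get(t, "unknown") if markers is not None else "unknown"))
    k = len(taxa)
    for i in range(k):
        for j in range(i + 1, k):
            if r[i, j] ** 2 > r2_min and pvals[i, j] < p_max:
                g.add_edge(taxa[i], taxa[j], correlation=float(r[i, j]), p=float(pvals[i, j]))
    return CooccurrenceNetwork(g, r2_min, p_max, method, excluded)


def keystone_taxa(net: CooccurrenceNetwork, top_k: int = 5) -> pd.DataFrame:
    """Taxa ranked by degree (ties: betweenness, then label).

    Returns the top_k rows with degree, betweenness and marker columns;
    empty frame for an empty network.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=["taxon", "degree", "betweenness", "marker"])
    bet = nx.betweenness_centrality(g)
    rows = [
        {
            "taxon": t,
            "degree": g.degree(t),
            "betweenness": bet[t],
            "marker": g.nodes[t].get("marker", "unknown"),
        }
        for t in g.nodes
    ]
    df = pd.DataFrame(rows).sort_values(
        ["degree", "betweenness", "taxon"], ascending=[False, False, True]
    )
    return df.head(top_k).reset_index(drop=True)
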