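"""Co-expression / co-translation networks and expression conservation (EC).

Both levels' cell-type profiles define a fully connected weighted network:
nodes are genes, the weight of edge (i, j) is the PCC between the two
genes' profiles.  A gene's *expression conservation* score is the PCC
between its edge-weight row in the co-expression (transcriptome) adjacency
matrix and the same row in the co-translation (translatome) matrix —
similar neighbourhoods mean conserved co-regulation, dissimilar ones
suggest rewiring.  A network-level summary, the full matrix correlation,
correlates the off-diagonal entries of the two adjacency matrices.

Significance mirrors the coupling stage: bootstrap networks are built from
random equal-sized unit subsets of each level's pool, yielding per-gene EC
null moments (for Z-score classification into conserved / rewired /
neutral) and an empirical null of the full matrix correlation (one-sided
lower-tail p with +1 smoothing, since the question is whether the observed
network similarity is *lower* than chance).

Thresholding the adjacency at t gives an unweighted relevance network on
which standard node properties are computed (degree, betweenness,
harmonic closeness, eigenvector centrality, alpha centrality, clustering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import (
    ExpressionMatrix,
    PipelineConfig,
    SampleMap,
    aggregate_to_cell_types,
)
from .coupling import bootstrap_units, pearson_correlation

EC_CLASSES = ("conserved", "rewired", "neutral", "degenerate")


def network_bootstrap_plan(scenario: str, n_cell_types: int,
                           cfg: PipelineConfig) -> tuple[str, int]:
    """Bootstrap unit and draw size for the network (EC) null.

    Networks are rebuilt from random *promoter* subsets: adjacency matrices
    are invariant to the order of their profile columns, so permuting the
    observed cell-type aggregates (the pool==k case) would reproduce the
    observed networks exactly and collapse the null.  The draw size matches
    the number of cell-type columns of the observed networks (4 identical /
    5 common), keeping the null networks' column count — and hence the
    sampling noise of their edge weights — exchangeable with the observed
    ones; ``cfg.common_bootstrap="promoters"`` draws 8 instead, and
    ``cfg.bootstrap_k`` overrides.
    """
    if scenario == "identical":
        k = 4
    elif cfg.common_bootstrap == "cell_types":
        k = n_cell_types
    else:
        k = 8
    if cfg.bootstrap_k is not None:
        k = cfg.bootstrap_k
    return "promoter", k


@dataclass
class AdjacencyMatrix:
    """Symmetric gene x gene PCC edge-weight matrix, diagonal fixed at 1.

    Entries incident to a zero-variance (constant-profile) gene are NaN.
    """

    gene_ids: np.ndarray
    W: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.gene_ids)
        if self.W.shape != (n, n):
            raise ValueError("adjacency must be square over gene_ids")
        finite = np.isfinite(self.W)
        if not np.array_equal(finite, finite.T) or np.nanmax(
                np.abs(self.W - self.W.T), initial=0.0,
                where=finite & finite.T) > 1e-12:
            raise ValueError("adjacency must be symmetric within 1e-12")
        with np.errstate(invalid="ignore"):
            if np.any(np.abs(self.W[finite]) > 1 + 1e-12):
                raise ValueError("edge weights must lie in [-1, 1]")

    def index_of(self, gene: str) -> int:
        hits = np.flatnonzero(self.gene_ids == gene)
        if hits.size != 1:
            raise KeyError(f"gene {gene!r} not in adjacency")
        return int(hits[0])


def coexpression_adjacency(X: np.ndarray, gene_ids) -> AdjacencyMatrix:
    """All-pairs PCC of gene profiles (rows of a genes x cell-types matrix)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a matrix with >= 2 gene rows")
    if X.shape[1] < 3:
        raise ValueError("need >= 3 cell-type columns")
    with warnings.catch_warnings(), np.errstate(divide="ignore", invalid="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        W = np.corrcoef(X)
    W = np.clip(W, -1.0, 1.0)
    # constant rows have no defined correlation; np.corrcoef can emit NaN or,
    # through 1-ulp mean residues, a spurious +/-1, so mask them explicitly
    constant = np.ptp(X, axis=1) == 0
    if constant.any():
        W[constant, :] = np.nan
        W[:, constant] = np.nan
    np.fill_diagonal(W, 1.0)
    return AdjacencyMatrix(np.asarray(gene_ids, dtype=object), W)


def _row_ec(W_tr: np.ndarray, W_tl: np.ndarray) -> np.ndarray:
    """Per-gene PCC of off-diagonal adjacency rows with pairwise NaN exclusion."""
    n = W_tr.shape[0]
    ec = np.full(n, np.nan)
    mask_all = np.isfinite(W_tr) & np.isfinite(W_tl)
    np.fill_diagonal(mask_all, False)
    if n >= 4 and mask_all.sum() == n * (n - 1):
        # no undefined entries: vectorized row correlation excluding the diagonal
        A = W_tr.copy()
        B = W_tl.copy()
        np.fill_diagonal(A, 0.0)
        np.fill_diagonal(B, 0.0)
        m = n - 1
        sa, sb = A.sum(1), B.sum(1)
        saa, sbb = (A * A).sum(1), (B * B).sum(1)
        sab = (A * B).sum(1)
        cov = sab - sa * sb / m
        va = saa - sa * sa / m
        vb = sbb - sb * sb / m
        with np.errstate(divide="ignore", invalid="ignore"):
            r = cov / np.sqrt(va * vb)
        r = np.where((va > 0) & (vb > 0), r, np.nan)
        return np.clip(r, -1.0, 1.0)
    for g in range(n):
        m = mask_all[g]
        if m.sum() < 3:
            continue
        a = W_tr[g, m]
        b = W_tl[g, m]
        ac = a - a.mean()
        bc = b - b.mean()
        denom = np.sqrt((ac @ ac) * (bc @ bc))
        if denom > 0:
            ec[g] = np.clip((ac @ bc) / denom, -1.0, 1.0)
    return ec


def ec_score(A_tr: AdjacencyMatrix, A_tl: AdjacencyMatrix, gene: str) -> float:
    """EC of one gene: PCC of its two adjacency rows, diagonal excluded.

    Undefined entries are pairwise-excluded; fewer than 3 usable entries
    gives NaN.
    """
    if not np.array_equal(A_tr.gene_ids, A_tl.gene_ids):
        raise ValueError("adjacency matrices must share gene list and order")
    g = A_tr.index_of(gene)
    keep = np.ones(len(A_tr.gene_ids), dtype=bool)
    keep[g] = False
    a = A_tr.W[g, keep]
    b = A_tl.W[g, keep]
    m = np.isfinite(a) & np.isfinite(b)
    if m.sum() < 3:
        return float("nan")
    return pearson_correlation(a[m], b[m])


def ec_scores(A_tr: AdjacencyMatrix, A_tl: AdjacencyMatrix) -> np.ndarray:
    """Vectorized EC for every gene (same conventions as :func:`ec_score`)."""
    if not np.array_equal(A_tr.gene_ids, A_tl.gene_ids):
        raise ValueError("adjacency matrices must share gene list and order")
    return _row_ec(A_tr.W, A_tl.W)


def full_matrix_correlation(A_tr: AdjacencyMatrix, A_tl: AdjacencyMatrix) -> float:
    """PCC over the vectorized strict upper triangles of both matrices."""
    if A_tr.W.shape != A_tl.W.shape or not np.array_equal(
            A_tr.gene_ids, A_tl.gene_ids):
        raise ValueError("adjacency matrices must share shape and gene order")
    iu = np.triu_indices(A_tr.W.shape[0], k=1)
    a = A_tr.W[iu]
    b = A_tl.W[iu]
    m = np.isfinite(a) & np.isfinite(b)
    if m.sum() < 3:
        return float("nan")
    return pearson_correlation(a[m], b[m])


def bootstrap_ec_null(
    X_tr_full: ExpressionMatrix,
    X_tl_full: ExpressionMatrix,
    smap: SampleMap,
    k: int,
    cfg: PipelineConfig,
    unit: str = "promoter",
    genes: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Bootstrap null of per-gene EC and of the full matrix correlation.

    Per iteration both levels' adjacency matrices are rebuilt from ``k``
    units drawn without replacement from each level's pool; per-gene EC and
    the full matrix correlation are recorded.  ``genes`` optionally
    restricts/subsamples the gene set (the statistic's definition is
    unchanged; only the network size is).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    U_tr, U_tl, all_genes = bootstrap_units(X_tr_full, X_tl_full, smap, unit)
    if genes is not None:
        pos = {g: i for i, g in enumerate(all_genes)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes not present on both levels: {missing[:10]}")
        sel = np.array([pos[g] for g in genes])
        U_tr, U_tl, all_genes = U_tr[sel], U_tl[sel], list(genes)
    for name, U in (("transcriptome", U_tr), ("translatome", U_tl)):
        if U.shape[1] < k:
            raise ValueError(
                f"{name} {unit} pool has {U.shape[1]} units, fewer than k={k}")
    G = len(all_genes)
    ec_null = np.empty((cfg.n_boot, G))
    fullmat_null = np.empty(cfg.n_boot)
    iu = np.triu_indices(G, k=1)
    for b in range(cfg.n_boot):
        i = rng.choice(U_tr.shape[1], size=k, replace=False)
        j = rng.choice(U_tl.shape[1], size=k, replace=False)
        with warnings.catch_warnings(), np.errstate(divide="ignore", invalid="ignore"):
            warnings.simplefilter("ignore", RuntimeWarning)
            W_tr = np.clip(np.corrcoef(U_tr[:, i]), -1.0, 1.0)
            W_tl = np.clip(np.corrcoef(U_tl[:, j]), -1.0, 1.0)
        np.fill_diagonal(W_tr, 1.0)
        np.fill_diagonal(W_tl, 1.0)
        ec_null[b] = _row_ec(W_tr, W_tl)
        a, bb = W_tr[iu], W_tl[iu]
        m = np.isfinite(a) & np.isfinite(bb)
        fullmat_null[b] = (pearson_correlation(a[m], bb[m])
                           if m.sum() >= 3 else np.nan)
    n_used = np.isfinite(ec_null).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(ec_null, axis=0)
        sd = np.nanstd(ec_null, axis=0, ddof=1)
    mean = np.where(n_used >= 2, mean, np.nan)
    sd = np.where(n_used >= 2, sd, np.nan)
    per_gene = pd.DataFrame(
        {"null_mean": mean, "null_sd": sd, "n_null_used": n_used},
        index=pd.Index(all_genes, name="gene_id"))
    return per_gene, fullmat_null


def classify_ec(
    ec: np.ndarray, null_mean: np.ndarray, null_sd: np.ndarray, z_crit: float,
) -> tuple[np.ndarray, np.ndarray]:
    """EC Z-scores and classes.

    conserved: Z >= z_crit and EC > 0; rewired: Z <= -z_crit; otherwise
    neutral; degenerate when EC or the null sd is undefined.
    """
    ec = np.asarray(ec, dtype=float)
    null_mean = np.asarray(null_mean, dtype=float)
    null_sd = np.asarray(null_sd, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (ec - null_mean) / null_sd
    z = np.where(np.isfinite(ec) & (null_sd > 0), z, np.nan)
    classes = np.full(ec.shape, "neutral", dtype=object)
    classes[np.isnan(z)] = "degenerate"
    zf = np.nan_to_num(z, nan=0.0)
    classes[(zf >= z_crit) & (ec > 0)] = "conserved"
    classes[zf <= -z_crit] = "rewired"
    return z, classes


def empirical_p_lower(observed: float, null: np.ndarray) -> float:
    """One-sided lower-tail empirical p with +1 smoothing."""
    null = np.asarray(null, dtype=float)
    null = null[np.isfinite(null)]
    return float((1.0 + np.sum(null <= observed)) / (null.size + 1.0))


def run_netcons(
    X_tr_full: ExpressionMatrix,
    X_tl_full: ExpressionMatrix,
    smap: SampleMap,
    scenario: str,
    cfg: PipelineConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Observed EC table with classification, plus a network-level summary."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    paired = aggregate_to_cell_types(X_tr_full, X_tl_full, smap,
                                     scenario=scenario, pooling=cfg.pooling)
    genes = list(paired.gene_ids)
    if cfg.ec_gene_subsample is not None and cfg.ec_gene_subsample < len(genes):
        sel = np.sort(rng.choice(len(genes), size=cfg.ec_gene_subsample,
                                 replace=False))
        genes = [genes[i] for i in sel]
        X_sub_tr = paired.X_tr[sel]
        X_sub_tl = paired.X_tl[sel]
    else:
        X_sub_tr, X_sub_tl = paired.X_tr, paired.X_tl
    A_tr = coexpression_adjacency(X_sub_tr, genes)
    A_tl = coexpression_adjacency(X_sub_tl, genes)
    ec = ec_scores(A_tr, A_tl)
    fullmat = full_matrix_correlation(A_tr, A_tl)
    unit, k = network_bootstrap_plan(scenario, len(paired.cell_types), cfg)
    null, fullmat_null = bootstrap_ec_null(
        X_tr_full, X_tl_full, smap, k, cfg, unit=unit, genes=genes, rng=rng)
    z, classes = classify_ec(ec, null["null_mean"].to_numpy(),
                             null["null_sd"].to_numpy(), cfg.z_crit)
    table = pd.DataFrame({
        "ec": ec,
        "null_mean": null["null_mean"].to_numpy(),
        "null_sd": null["null_sd"].to_numpy(),
        "zscore": z,
        "ec_class": classes,
        "n_null_used": null["n_null_used"].to_numpy(),
    }, index=pd.Index(genes, name="gene_id"))
    summary = {
        "scenario": scenario,
        "n_genes": len(genes),
        "full_matrix_correlation": fullmat,
        "empirical_p_lower": empirical_p_lower(fullmat, fullmat_null),
        "n_boot": cfg.n_boot,
        "null_mean": float(np.nanmean(fullmat_null)),
        "null_sd": float(np.nanstd(fullmat_null, ddof=1)),
    }
    return table, summary


def threshold_graph(A: AdjacencyMatrix, t: float) -> nx.Graph:
    """Unweighted relevance network: edge iff W[i, j] >= t (NaN: no edge)."""
    if not 0 < t <= 1:
        raise ValueError("threshold t must lie in (0, 1]")
    G = nx.Graph()
    G.add_nodes_from(A.gene_ids)
    n = len(A.gene_ids)
    with np.errstate(invalid="ignore"):
        ii, jj = np.nonzero(np.triu(A.W >= t, k=1))
    G.add_edges_from((A.gene_ids[i], A.gene_ids[j]) for i, j in zip(ii, jj))
    return G


def node_properties(G: nx.Graph, alpha_scale: float = 0.5
                    ) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Standard relevance-network node properties.

    Per node: degree, betweenness, harmonic closeness (normalized by n-1),
    eigenvector centrality (principal eigenvector of the adjacency,
    max-normalized), alpha centrality (solve of (I - alpha*A) x = 1 with
    alpha = alpha_scale / lambda_max), and the local clustering
    coefficient.  Isolated nodes receive 0 for closeness and centralities.
    Also returns the per-edge betweenness table and the graph-level
    transitivity.
    """
    if G.number_of_nodes() < 1:
        raise ValueError("graph must have at least one node")
    nodes = list(G.nodes)
    n = len(nodes)
    degree = dict(G.degree)
    betweenness = nx.betweenness_centrality(G)
    harm = nx.harmonic_centrality(G)
    closeness = {v: (harm[v] / (n - 1) if n > 1 else 0.0) for v in nodes}
    clustering = nx.clustering(G)
    A = nx.to_numpy_array(G, nodelist=nodes)
    if G.number_of_edges() > 0:
        evals, evecs = np.linalg.eigh(A)
        lead = evecs[:, -1]
        lead = np.abs(lead)
        eig = lead / lead.max()
        lam = float(evals[-1])
        alpha = alpha_scale / lam
        x = np.linalg.solve(np.eye(n) - alpha * A, np.ones(n))
        alpha_c = dict(zip(nodes, x))
        eig_c = dict(zip(nodes, eig))
    else:
        alpha_c = {v: 0.0 for v in nodes}
        eig_c = {v: 0.0 for v in nodes}
    isolated = set(nx.isolates(G))
    rows = []
    for v in nodes:
        iso = v in isolated
        rows.append({
            "node": v,
            "degree": degree[v],
            "betweenness": betweenness[v],
            "closeness": 0.0 if iso else closeness[v],
            "eigenvector": 0.0 if iso else eig_c[v],
            "alpha_centrality": 0.0 if iso else alpha_c[v],
            "clustering": clustering[v],
        })
    node_table = pd.DataFrame(rows).set_index("node")
    eb = nx.edge_betweenness_centrality(G)
    edge_table = pd.DataFrame(
        [{"gene_a": a, "gene_b": b, "edge_betweenness": v}
         for (a, b), v in eb.items()])
    transitivity = nx.transitivity(G)
    return node_table, edge_table, float(transitivity)


def write_edge_list(A: AdjacencyMatrix, path, t: float | None = None) -> None:
    """Undirected weighted edge list TSV (optionally thresholded at t)."""
    iu = np.triu_indices(len(A.gene_ids), k=1)
    w = A.W[iu]
    keep = np.isfinite(w)
    if t is not None:
        keep &= w >= t
    df = pd.DataFrame({
        "gene_a": A.gene_ids[iu[0][keep]],
        "gene_b": A.gene_ids[iu[1][keep]],
        "weight": w[keep],
    })
    df.to_csv(path, sep="\t", index=False)
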