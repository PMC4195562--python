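"""Cell-type similarity network motifs and their permutation significance.

For ``n`` cell types there are ``m = n(n-1)/2`` unordered pairs; a gene's
Tukey-HSD outcomes define a binary difference vector over those pairs
(1 = significant pairwise mean difference).  The complementary *similarity*
bits (1 = no significant difference = an edge between the two cell types)
define a labelled graph on the cell types — one of ``2^m`` possible
configurations, called a motif.  Motifs are labelled, i.e. cell-type
identities matter and isomorphic graphs with different isolated cell types
are distinct motifs.

Motif ids are the integer encoding of the similarity bits: bit position
``p`` (value ``2^p``) corresponds to the ``p``-th pair of the canonical
lexicographic pair order.  Id 0 is the empty graph (all cell types
pairwise different); id ``2^m - 1`` is the complete graph.

Over-represented motifs are found by a within-gene permutation test:
each permutation independently shuffles every gene's difference bits
(preserving its number of significant pairs), re-encodes, and re-counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import PipelineConfig


def pair_ordering(n: int) -> list[tuple[int, int]]:
    """Canonical lexicographic pair list [(0,1), (0,2), ..., (n-2,n-1)].

    Indices are 0-based positions into the cell-type order; length n(n-1)/2.
    """
    if n < 2:
        raise ValueError("need at least 2 cell types")
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def motif_count_space(n: int) -> int:
    """Number of possible labelled motifs on n cell types: 2^(n(n-1)/2)."""
    if n < 2:
        raise ValueError("need at least 2 cell types")
    return 2 ** (n * (n - 1) // 2)


@dataclass(frozen=True)
class MotifSpace:
    """The motif universe for a fixed number of cell types."""

    n: int

    @property
    def m(self) -> int:
        return self.n * (self.n - 1) // 2

    @property
    def pair_order(self) -> list[tuple[int, int]]:
        return pair_ordering(self.n)

    @property
    def size(self) -> int:
        return motif_count_space(self.n)


def encode_motif(diff_bits) -> int:
    """Difference bits -> motif id via the complementary similarity bits."""
    bits = np.asarray(diff_bits)
    if bits.ndim != 1 or not np.isin(bits, (0, 1)).all():
        raise ValueError("diff_bits must be a flat 0/1 vector")
    sim = 1 - bits.astype(int)
    return int((sim << np.arange(bits.size)).sum())


def encode_motifs(diff_matrix: np.ndarray) -> np.ndarray:
    """Row-wise :func:`encode_motif` of a genes x pairs 0/1 matrix."""
    bits = np.asarray(diff_matrix)
    if bits.ndim != 2 or not np.isin(bits, (0, 1)).all():
        raise ValueError("diff_matrix must be a genes x pairs 0/1 matrix")
    sim = 1 - bits.astype(np.int64)
    return sim @ (1 << np.arange(bits.shape[1], dtype=np.int64))


def similarity_bits(motif_id: int, space: MotifSpace) -> np.ndarray:
    """Motif id -> similarity bit vector in canonical pair order."""
    if not 0 <= motif_id < space.size:
        raise ValueError(f"motif id {motif_id} outside [0, {space.size})")
    return (motif_id >> np.arange(space.m)) & 1


@dataclass
class MotifStructure:
    """Decoded topology of one labelled motif."""

    motif_id: int
    graph: nx.Graph
    isolated: list[int]
    components: list[set[int]]
    is_clique_plus_isolate: bool


def motif_structure(motif_id: int, space: MotifSpace) -> MotifStructure:
    """Decode a motif id into its similarity graph and summary structure.

    ``is_clique_plus_isolate`` is true iff exactly one cell type is isolated
    and the remaining cell types form a complete subgraph — the shape of a
    single deviant cell type.
    """
    sim = similarity_bits(motif_id, space)
    G = nx.Graph()
    G.add_nodes_from(range(space.n))
    for bit, (i, j) in zip(sim, space.pair_order):
        if bit:
            G.add_edge(i, j)
    isolated = sorted(nx.isolates(G))
    components = [set(c) for c in nx.connected_components(G)]
    flag = False
    if len(isolated) == 1 and space.n >= 3:
        rest = [v for v in G if v not in isolated]
        k = len(rest)
        flag = G.subgraph(rest).number_of_edges() == k * (k - 1) // 2
    return MotifStructure(motif_id, G, isolated, components, flag)


def count_motifs(diff_matrix: np.ndarray, space: MotifSpace) -> np.ndarray:
    """Occurrence count per motif id (length ``space.size``)."""
    ids = encode_motifs(diff_matrix)
    return np.bincount(ids, minlength=space.size)


def shuffle_bits(diff_matrix: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each row's bits (row sums preserved)."""
    return rng.permuted(diff_matrix, axis=1)


def permutation_motif_test(
    vectors: pd.DataFrame,
    space: MotifSpace,
    cfg: PipelineConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Observed motif counts per level with permutation significance.

    ``vectors`` has columns gene_id, level, diff_bits (a 0/1 string in
    canonical pair order, as produced by the cell-type DE stage).  Per
    permutation every gene's bits are shuffled uniformly at random
    (within-gene, so each gene keeps its number of significant pairs) and
    motifs are re-counted.  The one-sided upper-tail empirical p uses +1
    smoothing: p = (1 + #{count_perm >= count_obs}) / (n_perm + 1).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    out: dict[str, dict[str, np.ndarray]] = {}
    for level, sub in vectors.groupby("level", sort=True):
        bits = np.array([[int(c) for c in s] for s in sub["diff_bits"]],
                        dtype=np.int8)
        if bits.size and bits.shape[1] != space.m:
            raise ValueError(
                f"diff_bits length {bits.shape[1]} does not match m={space.m}")
        observed = count_motifs(bits, space)
        exceed = np.zeros(space.size, dtype=np.int64)
        null_sum = np.zeros(space.size)
        null_sumsq = np.zeros(space.size)
        for _ in range(cfg.n_perm):
            counts = count_motifs(shuffle_bits(bits, rng), space)
            exceed += counts >= observed
            null_sum += counts
            null_sumsq += counts.astype(float) ** 2
        null_mean = null_sum / cfg.n_perm
        null_var = (null_sumsq - cfg.n_perm * null_mean**2) / (cfg.n_perm - 1)
        null_sd = np.sqrt(np.clip(null_var, 0.0, None))
        emp_p = (1.0 + exceed) / (cfg.n_perm + 1.0)
        out[level] = {"observed": observed, "null_mean": null_mean,
                      "null_sd": null_sd, "empirical_p": emp_p}
    ids = np.arange(space.size)
    table = pd.DataFrame({
        "motif_id": ids,
        "similarity_bits": ["".join(str(b) for b in similarity_bits(i, space))
                            for i in ids],
        "is_clique_plus_isolate": [motif_structure(i, space).is_clique_plus_isolate
                                   for i in ids],
        "n_isolated": [len(motif_structure(i, space).isolated) for i in ids],
    })
    for level, res in out.items():
        table[f"count_{level}"] = res["observed"]
        table[f"null_mean_{level}"] = res["null_mean"]
        table[f"null_sd_{level}"] = res["null_sd"]
        table[f"empirical_p_{level}"] = res["empirical_p"]
        table[f"significant_{level}"] = res["empirical_p"] < cfg.alpha
    return table
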