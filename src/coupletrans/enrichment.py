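"""Hypergeometric over-representation of annotation terms in a gene set.

For each term with at least one study gene, the probability of drawing at
least the observed number of term-annotated genes when sampling the study
set from the population without replacement is computed from the
hypergeometric distribution (upper tail).  The annotation is consumed as a
flat, pre-propagated gene -> term table; ontology-graph propagation is
upstream of this package.  Raw p-values are reported alongside a
Benjamini-Hochberg adjustment across the tested terms.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from scipy import stats

from .celltype_de import bh_fdr


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(
            f"invalid hypergeometric parameters k={k}, K={K}, n={n}, N={N}")
    # sf is exclusive, so P(X >= k) = sf(k - 1); scipy evaluates the tail
    # sum with log-gamma terms, stable for large N
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    study: Iterable[str],
    annotation: pd.DataFrame,
    population: Iterable[str],
    q: float = 0.05,
) -> pd.DataFrame:
    """Term over-representation table for a study set within a population.

    ``annotation`` has columns gene_id, term_id and is restricted to the
    population.  One test per term with >= 1 study gene; the result is
    sorted by raw p.  Columns: term, K (population genes with the term),
    n (study size), k (study genes with the term), N (population size),
    p, p_adj, significant (p_adj < q).
    """
    study_set = set(study)
    pop_set = set(population)
    outside = sorted(study_set - pop_set)
    if outside:
        raise ValueError(f"study genes outside the population: {outside[:10]}")
    if not {"gene_id", "term_id"}.issubset(annotation.columns):
        raise ValueError("annotation needs columns gene_id and term_id")
    ann = annotation[annotation["gene_id"].isin(pop_set)].drop_duplicates()
    N = len(pop_set)
    n = len(study_set)
    rows = []
    for term, sub in ann.groupby("term_id", sort=True):
        genes_with_term = set(sub["gene_id"])
        k = len(genes_with_term & study_set)
        if k == 0:
            continue
        K = len(genes_with_term)
        rows.append({"term": term, "K": K, "n": n, "k": k, "N": N,
                     "p": hypergeom_upper_tail(k, K, n, N)})
    if not rows:
        return pd.DataFrame(
            columns=["term", "K", "n", "k", "N", "p", "p_adj", "significant"])
    table = pd.DataFrame(rows)
    p_adj, reject = bh_fdr(table["p"].to_numpy(), q)
    table["p_adj"] = p_adj
    table["significant"] = reject
    return table.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
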