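"""Per-gene cell-type differential expression and pairwise similarity calls.

Each gene is tested per system level with a fixed-effects one-way ANOVA
across cell types (replicate samples as observations), followed by
Benjamini-Hochberg FDR selection across genes within a level.  Genes
differentially expressed on *both* levels then receive Tukey HSD post-hoc
tests, whose pairwise outcomes are encoded as a binary difference vector
over the canonical cell-type pair order (1 = significant pairwise mean
difference) — the input of the motif stage.

The Tukey test is the Tukey-Kramer form: the studentized-range statistic
q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)) with the pooled
within-group mean square, exact for balanced designs and mildly
conservative for the 2-3-replicate unbalance typical of this design.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix, PipelineConfig, SampleMap, LEVELS, intersect_genes
from .motifs import pair_ordering


def oneway_anova(groups) -> tuple[float, float]:
    """Classic one-way fixed-effects ANOVA F and upper-tail p.

    ``groups`` is a list of >= 2 replicate-value vectors.  If both the
    between- and within-group variances are zero the gene is degenerate and
    (NaN, NaN) is returned.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 1 for g in groups):
        raise ValueError("every group needs at least one value")
    N = sum(g.size for g in groups)
    if N - len(groups) < 1:
        raise ValueError("no residual degrees of freedom")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, p = stats.f_oneway(*groups)
    return float(F), float(p)


def oneway_anova_matrix(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ANOVA over genes: each group is a genes x n_i matrix."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, p = stats.f_oneway(*groups, axis=1)
    # constant genes: scipy returns NaN with a warning; keep NaN as the
    # degenerate marker
    return np.asarray(F, dtype=float), np.asarray(p, dtype=float)


def bh_fdr(pvalues, q: float) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment and rejection flags.

    Returns monotone adjusted p-values; reject iff adjusted < q.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj, p_adj < q


def tukey_hsd(groups, alpha: float) -> pd.DataFrame:
    """Tukey(-Kramer) HSD pairwise comparisons.

    Returns one row per canonical ordered pair (i, j), i < j, with columns
    ``pair_i, pair_j, difference, p, significant, degenerate``.  When the
    pooled within-group variance is zero every pair is reported
    non-significant with the degenerate flag set.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.array([g.size for g in groups])
    if np.any(sizes < 2):
        raise ValueError("every group needs >= 2 values for Tukey HSD")
    N = int(sizes.sum())
    df = N - k
    means = np.array([g.mean() for g in groups])
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msw = ssw / df
    rows = []
    for i, j in pair_ordering(k):
        diff = means[i] - means[j]
        if msw == 0:
            rows.append((i, j, diff, float("nan"), False, True))
            continue
        se = np.sqrt(msw / 2.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, df))
        rows.append((i, j, diff, p, p < alpha, False))
    return pd.DataFrame(rows, columns=["pair_i", "pair_j", "difference",
                                       "p", "significant", "degenerate"])


def tukey_bits_matrix(groups: list[np.ndarray], alpha: float) -> np.ndarray:
    """Vectorized Tukey-Kramer significance bits over genes.

    ``groups[c]`` is a genes x n_c replicate matrix for cell type c.
    Returns a genes x pairs 0/1 matrix in canonical pair order.  Equivalent
    to thresholding :func:`tukey_hsd` p-values at alpha, but compares the q
    statistic against a single critical value per (k, df), which avoids one
    studentized-range tail evaluation per gene and pair.  Genes with zero
    pooled within-group variance get all-zero rows (degenerate: no pair
    called significant).
    """
    k = len(groups)
    sizes = np.array([g.shape[1] for g in groups])
    N = int(sizes.sum())
    df = N - k
    means = np.column_stack([g.mean(axis=1) for g in groups])
    ssw = sum(((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
              for g in groups)
    msw = ssw / df
    q_crit = float(stats.studentized_range.ppf(1.0 - alpha, k, df))
    pairs = pair_ordering(k)
    bits = np.zeros((means.shape[0], len(pairs)), dtype=np.int8)
    ok = msw > 0
    for p, (i, j) in enumerate(pairs):
        se = np.sqrt(msw / 2.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.abs(means[:, i] - means[:, j]) / se
        bits[:, p] = ok & (q > q_crit)
    return bits


def _level_groups(
    em: ExpressionMatrix, smap: SampleMap, level: str, cell_types: list[str],
    promoters: list[str],
) -> list[np.ndarray]:
    """Per cell type, a genes x replicates value matrix (scenario promoters)."""
    groups = []
    for ct in cell_types:
        samples = [s for p in promoters
                   for s in smap.samples_for(level, promoter=p, cell_type=ct)]
        if len(samples) < 2:
            raise ValueError(f"cell type {ct!r} has < 2 samples on level {level}")
        groups.append(em.columns(samples))
    return groups


def run_celltype_de(
    X_tr_full: ExpressionMatrix,
    X_tl_full: ExpressionMatrix,
    smap: SampleMap,
    scenario: str,
    cfg: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """ANOVA/FDR per level, Tukey HSD on doubly-DE genes, similarity vectors.

    Returns ``(de_table, similarity_table, cell_types)``:

    * ``de_table`` — one row per gene per level: F, p, p_adj, de_flag
      (BH applied per level across all testable genes);
    * ``similarity_table`` — one row per gene per level for genes DE on
      *both* levels: ``diff_bits`` as a compact 0/1 string over the
      canonical cell-type pair order.
    """
    genes = intersect_genes(X_tr_full, X_tl_full)
    ems = {"transcriptome": X_tr_full.subset_genes(genes),
           "translatome": X_tl_full.subset_genes(genes)}
    proms = smap.scenario_promoters(scenario)
    cell_types = smap.scenario_cell_types(scenario)
    de_rows = []
    de_flags: dict[str, np.ndarray] = {}
    groups_by_level: dict[str, list[np.ndarray]] = {}
    for lv in LEVELS:
        groups = _level_groups(ems[lv], smap, lv, cell_types, proms[lv])
        groups_by_level[lv] = groups
        F, p = oneway_anova_matrix(groups)
        testable = np.isfinite(p)
        p_adj = np.full_like(p, np.nan)
        flag = np.zeros(p.size, dtype=bool)
        if testable.any():
            adj, rej = bh_fdr(p[testable], cfg.fdr_q)
            p_adj[testable] = adj
            flag[testable] = rej
        de_flags[lv] = flag
        de_rows.append(pd.DataFrame({
            "gene_id": genes, "level": lv, "F": F, "p": p,
            "p_adj": p_adj, "de_flag": flag}))
    de_table = pd.concat(de_rows, ignore_index=True)

    both = de_flags["transcriptome"] & de_flags["translatome"]
    idx = np.flatnonzero(both)
    sim_rows = []
    for lv in LEVELS:
        bits = tukey_bits_matrix([grp[idx] for grp in groups_by_level[lv]],
                                 cfg.alpha)
        for row, g in enumerate(idx):
            sim_rows.append((genes[g], lv,
                             "".join(str(b) for b in bits[row])))
    similarity = pd.DataFrame(sim_rows, columns=["gene_id", "level", "diff_bits"])
    return de_table, similarity, cell_types
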