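"""Per-gene transcriptome/translatome coupling statistics.

For every gene the similarity of its expression (total mRNA) and
translation (polysome-associated mRNA) profiles across cell types is
measured by Pearson's correlation coefficient (PCC).  Observed PCCs are
compared to a bootstrap null built by repeatedly drawing equal-sized
promoter (or cell-type) subsets *without replacement* from each level's
full pool, averaging replicates per unit, and pairing the two draws in
sampled order — a random mixture of cell types, so null variation reflects
cell-type-specific expression rather than level differences.

Z-scores are formed on the Fisher-transformed (atanh) correlation scale by
default: with only 4-5 cell types the raw PCC null is a bounded, strongly
non-normal distribution (uniform at n=4), whereas atanh(r) is close to
normal, which is what makes a +/-1.96 critical value meaningful.  A gene is
called *coupled* when Z >= z_crit, *uncoupled* when Z <= -z_crit, *neutral*
otherwise, and *degenerate* when its PCC or null sd is undefined.

Profile variability is summarized by the coefficient of variation
(CV = sd/mean across cell types), computed per level.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    ExpressionMatrix,
    PipelineConfig,
    SampleMap,
    aggregate_to_cell_types,
    intersect_genes,
    unit_mean_matrix,
)

COUPLING_CLASSES = ("coupled", "uncoupled", "neutral", "degenerate")

_CLIP = 1.0 - 1e-15


def coefficient_of_variation(profile) -> float:
    """Sample sd (n-1 denominator) over mean; NaN if the mean is <= 0.

    A non-positive mean makes the CV meaningless on an intensity scale, so
    such genes carry a degenerate (NaN) marker and are excluded from CV
    summaries rather than silently dropped.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("profile must be a vector of length >= 2")
    m = x.mean()
    if m <= 0:
        return float("nan")
    return float(x.std(ddof=1) / m)


def cv_matrix(X: np.ndarray) -> np.ndarray:
    """Row-wise CV of a genes x cell-types matrix (NaN where mean <= 0)."""
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=1)
    sds = X.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means > 0, sds / means, np.nan)
    return cv


def pearson_correlation(x, y) -> float:
    """Product-moment correlation; NaN if either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need vectors of length >= 2")
    if x.size == 2:
        warnings.warn("correlation of length-2 vectors is always +/-1",
                      stacklevel=2)
    # exact constancy check: mean subtraction alone can leave a constant
    # 1-ulp residue that would masquerade as variance
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def row_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise correlation of two equally shaped matrices (NaN on zero var)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("matrices must have identical shapes")
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    denom = np.sqrt((Ac * Ac).sum(axis=1) * (Bc * Bc).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Ac * Bc).sum(axis=1) / denom
    constant = (np.ptp(A, axis=1) == 0) | (np.ptp(B, axis=1) == 0)
    r = np.where(constant, np.nan, r)
    return np.clip(r, -1.0, 1.0)


def fisher_z(r):
    """Fisher transform atanh(r), with |r| clipped to 1 - 1e-15.

    The clip keeps perfectly correlated profiles finite instead of raising;
    |r| > 1 is a hard error.  NaN propagates.
    """
    r = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(np.abs(r[np.isfinite(r)]) > 1):
            raise ValueError("correlation magnitude exceeds 1")
    out = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    return float(out) if out.ndim == 0 else out


def two_sided_z_critical(alpha: float) -> float:
    """Standard-normal critical value of a two-sided test at level alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(stats.norm.ppf(1.0 - alpha / 2.0))


def bootstrap_units(
    X_tr_full: ExpressionMatrix,
    X_tl_full: ExpressionMatrix,
    smap: SampleMap,
    unit: str,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-level genes x units replicate-mean matrices over the shared genes."""
    genes = intersect_genes(X_tr_full, X_tl_full)
    U_tr, _ = unit_mean_matrix(X_tr_full.subset_genes(genes), smap,
                               "transcriptome", unit)
    U_tl, _ = unit_mean_matrix(X_tl_full.subset_genes(genes), smap,
                               "translatome", unit)
    return U_tr, U_tl, genes


def bootstrap_pcc_null(
    X_tr_full: ExpressionMatrix,
    X_tl_full: ExpressionMatrix,
    smap: SampleMap,
    k: int,
    cfg: PipelineConfig,
    unit: str = "promoter",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-gene null moments of the (transformed) bootstrap PCC.

    Each of ``cfg.n_boot`` iterations draws ``k`` units without replacement,
    independently per level, and correlates the paired unit means in sampled
    order.  Moments are taken on the scale selected by ``cfg.z_scale``.
    Iterations where a gene's PCC is undefined are dropped from that gene's
    null; the count of retained iterations is reported per gene.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    U_tr, U_tl, genes = bootstrap_units(X_tr_full, X_tl_full, smap, unit)
    for name, U in (("transcriptome", U_tr), ("translatome", U_tl)):
        if U.shape[1] < k:
            raise ValueError(
                f"{name} {unit} pool has {U.shape[1]} units, fewer than k={k}")
    null = np.empty((cfg.n_boot, len(genes)))
    for b in range(cfg.n_boot):
        i = rng.choice(U_tr.shape[1], size=k, replace=False)
        j = rng.choice(U_tl.shape[1], size=k, replace=False)
        null[b] = row_pearson(U_tr[:, i], U_tl[:, j])
    if cfg.z_scale == "fisher":
        null = fisher_z(null)
    n_used = np.isfinite(null).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(null, axis=0)
        sd = np.nanstd(null, axis=0, ddof=1)
    mean = np.where(n_used >= 2, mean, np.nan)
    sd = np.where(n_used >= 2, sd, np.nan)
    return pd.DataFrame({"null_mean": mean, "null_sd": sd, "n_null_used": n_used},
                        index=pd.Index(genes, name="gene_id"))


def classify_coupling(
    stat: np.ndarray,
    null_mean: np.ndarray,
    null_sd: np.ndarray,
    z_crit: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Z-scores and classes from observed statistics and null moments.

    ``stat`` must already be on the same scale as the null moments (raw PCC
    or Fisher-z).  Degenerate (NaN statistic, NaN or zero null sd) is a
    value, not an error.
    """
    stat = np.asarray(stat, dtype=float)
    null_mean = np.asarray(null_mean, dtype=float)
    null_sd = np.asarray(null_sd, dtype=float)
    if np.any(null_sd[np.isfinite(null_sd)] < 0):
        raise ValueError("null_sd must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (stat - null_mean) / null_sd
    z = np.where(null_sd > 0, z, np.nan)
    classes = np.full(stat.shape, "neutral", dtype=object)
    classes[np.isnan(z)] = "degenerate"
    classes[np.nan_to_num(z, nan=0.0) >= z_crit] = "coupled"
    classes[np.nan_to_num(z, nan=0.0) <= -z_crit] = "uncoupled"
    return z, classes


def bootstrap_plan(scenario: str, n_cell_types: int, cfg: PipelineConfig) -> tuple[str, int]:
    """Bootstrap unit and draw size k for a scenario.

    ``identical``: k=4 promoters from each level's full promoter pool.
    ``common``: by default k = n_cell_types cell-type aggregates
    (order-randomized pairing); ``cfg.common_bootstrap="promoters"`` draws 8
    raw promoters instead.  ``cfg.bootstrap_k`` overrides k.
    """
    if scenario == "identical":
        unit, k = "promoter", 4
    elif cfg.common_bootstrap == "cell_types":
        unit, k = "cell_type", n_cell_types
    else:
        unit, k = "promoter", 8
    if cfg.bootstrap_k is not None:
        k = cfg.bootstrap_k
    return unit, k


def run_coupling(
    X_tr_full: ExpressionMatrix,
    X_tl_full: ExpressionMatrix,
    smap: SampleMap,
    scenario: str,
    cfg: PipelineConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Full per-gene coupling table for one scenario.

    Columns: cv_tr, cv_tl, pcc, fisher_z, null_mean, null_sd, zscore,
    coupling_class, n_null_used.  ``null_mean``/``null_sd`` are on the
    classification scale (``cfg.z_scale``).
    """
    paired = aggregate_to_cell_types(X_tr_full, X_tl_full, smap,
                                     scenario=scenario, pooling=cfg.pooling)
    if len(paired.cell_types) < 3:
        raise ValueError("need >= 3 cell types for correlation stages")
    pcc = row_pearson(paired.X_tr, paired.X_tl)
    fz = fisher_z(pcc)
    unit, k = bootstrap_plan(scenario, len(paired.cell_types), cfg)
    null = bootstrap_pcc_null(X_tr_full, X_tl_full, smap, k, cfg,
                              unit=unit, rng=rng)
    null = null.loc[list(paired.gene_ids)]
    stat = fz if cfg.z_scale == "fisher" else pcc
    z, classes = classify_coupling(stat, null["null_mean"].to_numpy(),
                                   null["null_sd"].to_numpy(), cfg.z_crit)
    return pd.DataFrame({
        "cv_tr": cv_matrix(paired.X_tr),
        "cv_tl": cv_matrix(paired.X_tl),
        "pcc": pcc,
        "fisher_z": fz,
        "null_mean": null["null_mean"].to_numpy(),
        "null_sd": null["null_sd"].to_numpy(),
        "zscore": z,
        "coupling_class": classes,
        "n_null_used": null["n_null_used"].to_numpy(),
    }, index=pd.Index(paired.gene_ids, name="gene_id"))
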