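"""Data model and I/O for paired transcriptome/translatome expression data.

The package operates on already-normalized, log2-scale expression matrices
(genes x samples) together with a sample metadata table mapping each sample
(microarray hybridization) to a system level (``transcriptome`` or
``translatome``), the promoter used to isolate the cell population, the
targeted cell type, and a replicate number.  Upstream array pre-processing
(background correction, quantile normalization, probe summarization) is out
of scope: values are consumed as-is and assumed to be on the log2 scale.

Samples are aggregated into paired genes x cell-types matrices under two
scenarios mirroring the two promoter platforms of cell-sorted root data:

``identical``
    only promoters used verbatim on *both* system levels;
``common``
    all promoters, including level-specific ones that target the same cell
    type on the two levels.

The cell types of a scenario are those covered on both levels after the
promoter restriction; with the bundled synthetic generator's defaults the
identical scenario yields 4 cell types and the common scenario 5.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

LEVELS = ("transcriptome", "translatome")

SCENARIOS = ("identical", "common")

SAMPLE_MAP_COLUMNS = ("sample_id", "level", "promoter", "cell_type", "replicate")


def _duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of finite, log2-scale intensities.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, duplicate-free identifier lists.
    values
        Real matrix with ``len(gene_ids)`` rows and ``len(sample_ids)``
        columns; every entry must be finite.
    """

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dups = _duplicates(ids)
            if dups:
                raise ValueError(f"duplicate {name} ids: {dups}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.index.to_numpy(object), df.columns.to_numpy(object), df.to_numpy(float))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"),
                          columns=list(self.sample_ids))
        return df

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset (and reorder) to ``genes``; unknown ids are an error."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:10]}")
        idx = np.array([pos[g] for g in genes], dtype=int)
        return ExpressionMatrix(np.asarray(genes, dtype=object),
                                self.sample_ids.copy(), self.values[idx])

    def columns(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Values restricted to the given sample columns (gene order kept)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:10]}")
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return self.values[:, idx]


def load_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    Layout: header row ``gene_id<TAB><sample ids...>``, one row per gene.
    Duplicated gene/sample ids and non-numeric cells are hard errors that
    name the offending identifier or coordinate.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dup_g = _duplicates(list(df.index))
    if dup_g:
        raise ValueError(f"{path}: duplicate gene ids: {dup_g}")
    dup_s = _duplicates(list(df.columns))
    if dup_s:
        raise ValueError(f"{path}: duplicate sample ids: {dup_s}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing value at gene {df.index[r]!r}, "
                         f"sample {df.columns[c]!r}")
    return ExpressionMatrix.from_dataframe(numeric)


def write_expression_matrix(em: ExpressionMatrix, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    em.to_dataframe().to_csv(path, sep="\t")


@dataclass
class SampleMap:
    """Sample metadata: one record per sample id.

    ``table`` has columns sample_id, level, promoter, cell_type, replicate;
    levels are restricted to :data:`LEVELS` and every (level, promoter)
    group must contain at least one replicate.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in SAMPLE_MAP_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"sample map missing columns: {missing}")
        t = t.loc[:, list(SAMPLE_MAP_COLUMNS)].copy()
        t["replicate"] = t["replicate"].astype(int)
        dups = _duplicates(list(t["sample_id"]))
        if dups:
            raise ValueError(f"duplicate sample ids in sample map: {dups}")
        bad_levels = sorted(set(t["level"]) - set(LEVELS))
        if bad_levels:
            raise ValueError(f"unknown system levels: {bad_levels}")
        if (t["replicate"] < 1).any():
            raise ValueError("replicate numbers must be positive integers")
        self.table = t.reset_index(drop=True)

    def for_level(self, level: str) -> pd.DataFrame:
        if level not in LEVELS:
            raise ValueError(f"unknown level {level!r}")
        return self.table[self.table["level"] == level]

    def promoters(self, level: str) -> list[str]:
        """Promoters of a level, in order of first appearance."""
        return list(dict.fromkeys(self.for_level(level)["promoter"]))

    def cell_types(self, level: str) -> list[str]:
        return list(dict.fromkeys(self.for_level(level)["cell_type"]))

    def samples_for(self, level: str, promoter: str | None = None,
                    cell_type: str | None = None) -> list[str]:
        t = self.for_level(level)
        if promoter is not None:
            t = t[t["promoter"] == promoter]
        if cell_type is not None:
            t = t[t["cell_type"] == cell_type]
        return list(t["sample_id"])

    def require_covers(self, em: ExpressionMatrix, level: str) -> None:
        """Check every matrix sample resolves to exactly one record of `level`."""
        t = self.for_level(level)
        known = set(t["sample_id"])
        missing = [s for s in em.sample_ids if s not in known]
        if missing:
            raise ValueError(
                f"samples without a {level} metadata record: {missing[:10]}")

    def scenario_promoters(self, scenario: str) -> dict[str, list[str]]:
        """Promoters per level entering a scenario.

        ``identical`` keeps only promoter labels present on both levels;
        ``common`` keeps all promoters.
        """
        if scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
        per_level = {lv: self.promoters(lv) for lv in LEVELS}
        if scenario == "common":
            return per_level
        shared = set(per_level[LEVELS[0]]) & set(per_level[LEVELS[1]])
        return {lv: [p for p in per_level[lv] if p in shared] for lv in LEVELS}

    def scenario_cell_types(self, scenario: str) -> list[str]:
        """Cell types covered on both levels under the scenario's promoters.

        A cell type covered on exactly one level is a hard error: the paired
        analysis cannot silently drop half of a profile.
        """
        proms = self.scenario_promoters(scenario)
        per_level: dict[str, list[str]] = {}
        for lv in LEVELS:
            t = self.for_level(lv)
            t = t[t["promoter"].isin(proms[lv])]
            per_level[lv] = list(dict.fromkeys(t["cell_type"]))
        all_cts = list(dict.fromkeys(per_level[LEVELS[0]] + per_level[LEVELS[1]]))
        covered = [ct for ct in all_cts
                   if ct in per_level[LEVELS[0]] and ct in per_level[LEVELS[1]]]
        one_sided = [ct for ct in all_cts if ct not in covered]
        if scenario == "common" and one_sided:
            raise ValueError(
                f"cell types present on only one level: {one_sided}")
        # under "identical" the promoter restriction symmetrically removes
        # cell types lacking a shared promoter from both levels, so any
        # remaining one-sided coverage is likewise an inconsistency
        if scenario == "identical" and one_sided:
            raise ValueError(
                f"cell types covered on only one level after restricting to "
                f"identical promoters: {one_sided}")
        return covered


def load_sample_map(path: str | Path) -> SampleMap:
    return SampleMap(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def write_sample_map(smap: SampleMap, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    smap.table.to_csv(path, sep="\t", index=False)


@dataclass
class PairedCellTypeData:
    """Two genes x cell-types matrices with shared gene and cell-type order."""

    gene_ids: np.ndarray
    cell_types: list[str]
    X_tr: np.ndarray
    X_tl: np.ndarray
    scenario: str

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.X_tr = np.asarray(self.X_tr, dtype=float)
        self.X_tl = np.asarray(self.X_tl, dtype=float)
        shape = (len(self.gene_ids), len(self.cell_types))
        if self.X_tr.shape != shape or self.X_tl.shape != shape:
            raise ValueError("paired matrices must both be genes x cell_types")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")


@dataclass
class PipelineConfig:
    """Tunable statistical parameters shared across stages.

    Defaults follow the analysis conventions of cell-type-resolved
    two-level array studies: 1000 bootstrap datasets and permutations, the
    two-sided 5% normal critical value 1.96, a relevance-network edge
    threshold of 0.9, and 5% significance/FDR levels.
    """

    n_boot: int = 1000
    n_perm: int = 1000
    z_crit: float = 1.96
    t_edge: float = 0.9
    alpha: float = 0.05
    fdr_q: float = 0.05
    seed: int = 0
    # z_scale: scale on which bootstrap Z-scores are formed. "fisher"
    # (atanh-transformed correlations, approximately normal at small n)
    # or "raw".
    z_scale: str = "fisher"
    # pooling of multiple promoters targeting one cell type: grand mean over
    # all replicate samples ("replicate") or mean of promoter means ("promoter")
    pooling: str = "replicate"
    # common-scenario bootstrap unit: "cell_types" draws k = n_cell_types
    # cell-type aggregates; "promoters" draws 8 raw promoters
    common_bootstrap: str = "cell_types"
    # explicit override of the number of units drawn per bootstrap iteration
    bootstrap_k: int | None = None
    # optional gene subsample size for the network (EC) bootstrap
    ec_gene_subsample: int | None = None
    # alpha-centrality attenuation as a fraction of the 1/lambda_max bound
    alpha_centrality_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.n_boot < 2 or self.n_perm < 2:
            raise ValueError("n_boot and n_perm must be >= 2")
        if self.z_crit <= 0:
            raise ValueError("z_crit must be positive")
        if not 0 < self.t_edge <= 1:
            raise ValueError("t_edge must be in (0, 1]")
        for name in ("alpha", "fdr_q"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.z_scale not in ("fisher", "raw"):
            raise ValueError("z_scale must be 'fisher' or 'raw'")
        if self.pooling not in ("replicate", "promoter"):
            raise ValueError("pooling must be 'replicate' or 'promoter'")
        if self.common_bootstrap not in ("cell_types", "promoters"):
            raise ValueError("common_bootstrap must be 'cell_types' or 'promoters'")
        if not 0 < self.alpha_centrality_scale < 1:
            raise ValueError("alpha_centrality_scale must be in (0, 1)")

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


def intersect_genes(X_tr: ExpressionMatrix, X_tl: ExpressionMatrix) -> list[str]:
    """Shared gene universe, in transcriptome row order."""
    in_tl = set(X_tl.gene_ids)
    genes = [g for g in X_tr.gene_ids if g in in_tl]
    if not genes:
        raise ValueError("no genes shared between the two matrices")
    return genes


def aggregate_to_cell_types(
    X_tr: ExpressionMatrix,
    X_tl: ExpressionMatrix,
    smap: SampleMap,
    scenario: str = "common",
    pooling: str = "replicate",
) -> PairedCellTypeData:
    """Collapse replicate/promoter samples into paired cell-type profiles.

    Genes are restricted to the intersection of the two matrices' gene lists
    (transcriptome order preserved).  Per level, a cell-type column is the
    mean over all replicate samples of all scenario promoters mapped to that
    cell type (``pooling="replicate"``, unweighted grand mean) or the mean
    of promoter-wise replicate means (``pooling="promoter"``).
    """
    if pooling not in ("replicate", "promoter"):
        raise ValueError("pooling must be 'replicate' or 'promoter'")
    smap.require_covers(X_tr, "transcriptome")
    smap.require_covers(X_tl, "translatome")
    genes = intersect_genes(X_tr, X_tl)
    ems = {"transcriptome": X_tr.subset_genes(genes),
           "translatome": X_tl.subset_genes(genes)}
    proms = smap.scenario_promoters(scenario)
    cell_types = smap.scenario_cell_types(scenario)
    if not cell_types:
        raise ValueError(f"no cell types covered on both levels for scenario {scenario!r}")
    out = {}
    for lv in LEVELS:
        cols = np.empty((len(genes), len(cell_types)))
        for j, ct in enumerate(cell_types):
            ct_proms = [p for p in proms[lv]
                        if smap.samples_for(lv, promoter=p, cell_type=ct)]
            if not ct_proms:
                raise ValueError(f"cell type {ct!r} has no promoter on level {lv}")
            if pooling == "replicate":
                samples = [s for p in ct_proms
                           for s in smap.samples_for(lv, promoter=p, cell_type=ct)]
                cols[:, j] = ems[lv].columns(samples).mean(axis=1)
            else:
                per_prom = [ems[lv].columns(
                    smap.samples_for(lv, promoter=p, cell_type=ct)).mean(axis=1)
                    for p in ct_proms]
                cols[:, j] = np.mean(per_prom, axis=0)
        out[lv] = cols
    return PairedCellTypeData(
        gene_ids=np.asarray(genes, dtype=object),
        cell_types=cell_types,
        X_tr=out["transcriptome"],
        X_tl=out["translatome"],
        scenario=scenario,
    )


def unit_mean_matrix(
    em: ExpressionMatrix, smap: SampleMap, level: str, unit: str
) -> tuple[np.ndarray, list[str]]:
    """Genes x units matrix of replicate means, unit = "promoter"|"cell_type".

    The full promoter (or cell-type) pool of a level serves as the background
    population that bootstrap stages draw from.
    """
    if unit == "promoter":
        labels = smap.promoters(level)
        cols = [em.columns(smap.samples_for(level, promoter=p)).mean(axis=1)
                for p in labels]
    elif unit == "cell_type":
        labels = smap.cell_types(level)
        cols = [em.columns(smap.samples_for(level, cell_type=ct)).mean(axis=1)
                for ct in labels]
    else:
        raise ValueError("unit must be 'promoter' or 'cell_type'")
    return np.column_stack(cols), labels
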