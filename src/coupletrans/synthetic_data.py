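"""Paired synthetic transcriptome/translatome data with planted ground truth.

The generator emulates the sampling design of cell-sorted root microarray
studies: a handful of cell types, each targeted by one promoter shared
between the two system levels plus optional level-specific promoters, 2-3
replicate hybridizations per promoter, and log2-scale intensities.  Gene
profiles carry planted structure that every downstream stage can be scored
against:

coupled
    the same cell-type effect vector on both levels (positive cross-level
    correlation);
uncoupled
    the sign-flipped (or, optionally, an independent) effect vector on the
    translatome (negative correlation / no correlation);
null
    no cell-type effect on either level.

A configurable slice of the coupled class consists of *motif genes*: their
only effect is a shift in exactly one cell type, identical on both levels,
which plants a one-isolated-node similarity-network pattern for the
ANOVA/Tukey/motif stages.  Replicate noise is level-specific; the default
translatome noise is smaller than the transcriptome noise, mirroring the
lower variability of ribosome-associated mRNA profiles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    ExpressionMatrix,
    SampleMap,
    write_expression_matrix,
    write_sample_map,
)

DEFAULT_CELL_TYPES = (
    "companion_cell",
    "vasculature",
    "quiescent_centre",
    "cortex",
    "epidermis",
)

COUPLING_CLASSES = ("coupled", "uncoupled", "null")


@dataclass
class SyntheticConfig:
    """Study-design and effect-size parameters of the generator.

    Effect and noise scales are in log2-intensity units.  ``effect_sd`` is
    the standard deviation of a gene's per-cell-type effect; the
    ``noise_sd_*`` values are per-replicate noise standard deviations, with
    the translatome default below the transcriptome default.  Cell types in
    ``unshared_cell_types`` are targeted by different promoters on the two
    levels (no identical promoter), so they drop out of the "identical"
    scenario but stay in "common".
    """

    n_genes: int = 1000
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    unshared_cell_types: tuple[str, ...] = ("cortex",)
    extra_promoters_tr: int = 1
    extra_promoters_tl: int = 1
    replicates: tuple[int, int] = (2, 3)
    frac_coupled: float = 0.15
    frac_uncoupled: float = 0.10
    frac_null: float = 0.75
    effect_sd: float = 1.0
    noise_sd_tr: float = 0.3
    noise_sd_tl: float = 0.2
    frac_motif_genes: float = 0.05
    motif_shift: float = 2.0
    uncoupled_mode: str = "sign_flip"
    baseline_range: tuple[float, float] = (4.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.frac_coupled, self.frac_uncoupled, self.frac_null)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("class fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {sum(fracs)}")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if min(self.effect_sd, self.noise_sd_tr, self.noise_sd_tl) < 0:
            raise ValueError("effect and noise standard deviations must be >= 0")
        if not 0 <= self.frac_motif_genes <= self.frac_coupled + 1e-9:
            raise ValueError(
                "frac_motif_genes must lie in [0, frac_coupled]: motif genes "
                "are coupled by construction (one identical shift on both levels)")
        if self.uncoupled_mode not in ("sign_flip", "independent"):
            raise ValueError("uncoupled_mode must be 'sign_flip' or 'independent'")
        lo, hi = self.replicates
        if not 1 <= lo <= hi:
            raise ValueError("replicates must be an increasing range of positives")
        if len(self.cell_types) < 3:
            raise ValueError("need >= 3 cell types for correlation stages")
        unknown = set(self.unshared_cell_types) - set(self.cell_types)
        if unknown:
            raise ValueError(f"unshared cell types not in cell_types: {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    """Planted per-gene ground truth of a generated dataset."""

    gene_ids: np.ndarray
    cell_types: tuple[str, ...]
    coupling_class: np.ndarray          # per gene, in COUPLING_CLASSES
    deviant_cell_type: np.ndarray       # per gene, label or None
    effects_tr: np.ndarray              # genes x cell_types
    effects_tl: np.ndarray
    baseline: np.ndarray
    planted_terms: tuple[str, ...] = field(default_factory=tuple)

    def genes_in_class(self, cls: str) -> np.ndarray:
        return self.gene_ids[self.coupling_class == cls]

    def motif_genes(self) -> np.ndarray:
        return self.gene_ids[np.array([d is not None for d in self.deviant_cell_type])]


def largest_remainder_counts(total: int, fractions: list[float]) -> list[int]:
    """Integer class counts summing exactly to ``total``.

    Floors each quota, then distributes leftover units to the largest
    fractional remainders (ties broken by position) — deterministic.
    """
    quotas = [total * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    leftover = total - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:leftover]:
        counts[i] += 1
    return counts


def _promoter_plan(cfg: SyntheticConfig) -> dict[str, list[tuple[str, str]]]:
    """Per level: list of (promoter, cell_type), emulating a promoter table."""
    plan: dict[str, list[tuple[str, str]]] = {"transcriptome": [], "translatome": []}
    for ct in cfg.cell_types:
        if ct not in cfg.unshared_cell_types:
            plan["transcriptome"].append((f"p_{ct}", ct))
            plan["translatome"].append((f"p_{ct}", ct))
        else:
            plan["transcriptome"].append((f"p_{ct}_tr", ct))
            plan["translatome"].append((f"p_{ct}_tl", ct))
        for j in range(cfg.extra_promoters_tr):
            plan["transcriptome"].append((f"p_{ct}_trx{j + 1}", ct))
        for j in range(cfg.extra_promoters_tl):
            plan["translatome"].append((f"p_{ct}_tlx{j + 1}", ct))
    return plan


def generate_paired_dataset(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SampleMap, SyntheticTruth]:
    """Generate paired expression matrices, sample metadata and ground truth.

    Replicate sample value = baseline + cell-type effect + N(0, noise_sd^2).
    Fixed config + seed gives bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genes
    cts = list(cfg.cell_types)
    C = len(cts)
    gene_ids = np.array([f"G{i:05d}" for i in range(G)], dtype=object)

    n_coupled, n_uncoupled, n_null = largest_remainder_counts(
        G, [cfg.frac_coupled, cfg.frac_uncoupled, cfg.frac_null])
    classes = np.array(
        ["coupled"] * n_coupled + ["uncoupled"] * n_uncoupled + ["null"] * n_null,
        dtype=object)
    n_motif = min(
        largest_remainder_counts(
            G, [cfg.frac_motif_genes, 1.0 - cfg.frac_motif_genes])[0],
        n_coupled)

    baseline = rng.uniform(*cfg.baseline_range, size=G)
    effects_tr = np.zeros((G, C))
    effects_tl = np.zeros((G, C))
    deviant = np.full(G, None, dtype=object)

    # motif genes: first n_motif of the coupled block; a single-cell-type
    # shift (random sign) identical on both levels
    if n_motif:
        dev_idx = rng.integers(0, C, size=n_motif)
        signs = rng.choice([-1.0, 1.0], size=n_motif)
        for g in range(n_motif):
            effects_tr[g, dev_idx[g]] = signs[g] * cfg.motif_shift
            effects_tl[g, dev_idx[g]] = signs[g] * cfg.motif_shift
            deviant[g] = cts[dev_idx[g]]
    # remaining coupled genes: shared random effect vector
    n_plain = n_coupled - n_motif
    if n_plain:
        e = rng.normal(0.0, cfg.effect_sd, size=(n_plain, C))
        effects_tr[n_motif:n_coupled] = e
        effects_tl[n_motif:n_coupled] = e
    # uncoupled genes: sign-flipped (or independent) translatome effects
    if n_uncoupled:
        e = rng.normal(0.0, cfg.effect_sd, size=(n_uncoupled, C))
        effects_tr[n_coupled:n_coupled + n_uncoupled] = e
        if cfg.uncoupled_mode == "sign_flip":
            effects_tl[n_coupled:n_coupled + n_uncoupled] = -e
        else:
            effects_tl[n_coupled:n_coupled + n_uncoupled] = rng.normal(
                0.0, cfg.effect_sd, size=(n_uncoupled, C))

    plan = _promoter_plan(cfg)
    lo, hi = cfg.replicates
    noise_sd = {"transcriptome": cfg.noise_sd_tr, "translatome": cfg.noise_sd_tl}
    effects = {"transcriptome": effects_tr, "translatome": effects_tl}
    matrices: dict[str, ExpressionMatrix] = {}
    rows = []
    prefix = {"transcriptome": "tx", "translatome": "tl"}
    for level in ("transcriptome", "translatome"):
        cols = []
        sample_ids = []
        for promoter, ct in plan[level]:
            n_rep = int(rng.integers(lo, hi + 1))
            ct_idx = cts.index(ct)
            for r in range(1, n_rep + 1):
                sid = f"{prefix[level]}_{promoter}_r{r}"
                sample_ids.append(sid)
                rows.append({"sample_id": sid, "level": level,
                             "promoter": promoter, "cell_type": ct,
                             "replicate": r})
                cols.append(baseline + effects[level][:, ct_idx]
                            + rng.normal(0.0, noise_sd[level], size=G))
        matrices[level] = ExpressionMatrix(
            gene_ids.copy(), np.array(sample_ids, dtype=object),
            np.column_stack(cols))
    smap = SampleMap(pd.DataFrame(rows))
    truth = SyntheticTruth(
        gene_ids=gene_ids, cell_types=cfg.cell_types,
        coupling_class=classes, deviant_cell_type=deviant,
        effects_tr=effects_tr, effects_tl=effects_tl, baseline=baseline)
    return matrices["transcriptome"], matrices["translatome"], smap, truth


PLANTED_TERM = "T_COUPLED"


def generate_annotation(
    truth: SyntheticTruth,
    n_terms: int,
    background_prob: float,
    planted_prob: float,
    seed: int,
) -> pd.DataFrame:
    """Gene -> term table with one term enriched in the coupled gene set.

    Each gene receives each of ``n_terms`` background terms independently
    with ``background_prob``.  If the coupled set is non-empty, a designated
    planted term (:data:`PLANTED_TERM`) annotates coupled genes with
    ``planted_prob`` and all other genes with ``background_prob``.
    """
    if not 0 <= background_prob < planted_prob <= 1:
        raise ValueError("need 0 <= background_prob < planted_prob <= 1")
    rng = np.random.default_rng(seed)
    genes = truth.gene_ids
    coupled = truth.coupling_class == "coupled"
    records: list[tuple[str, str]] = []
    for t in range(n_terms):
        term = f"T{t:04d}"
        hit = rng.random(len(genes)) < background_prob
        records.extend((g, term) for g in genes[hit])
    if coupled.any():
        p = np.where(coupled, planted_prob, background_prob)
        hit = rng.random(len(genes)) < p
        records.extend((g, PLANTED_TERM) for g in genes[hit])
        truth.planted_terms = tuple(sorted(set(truth.planted_terms) | {PLANTED_TERM}))
    return pd.DataFrame(records, columns=["gene_id", "term_id"])


def write_dataset(
    outdir: str | Path,
    cfg: SyntheticConfig,
    em_tr: ExpressionMatrix,
    em_tl: ExpressionMatrix,
    smap: SampleMap,
    truth: SyntheticTruth,
    annotation: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Write TSV inputs plus a JSON manifest recording config and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcriptome": str(outdir / "transcriptome.tsv"),
        "translatome": str(outdir / "translatome.tsv"),
        "metadata": str(outdir / "metadata.tsv"),
        "truth": str(outdir / "truth.tsv"),
    }
    write_expression_matrix(em_tr, paths["transcriptome"])
    write_expression_matrix(em_tl, paths["translatome"])
    write_sample_map(smap, paths["metadata"])
    pd.DataFrame({
        "gene_id": truth.gene_ids,
        "coupling_class": truth.coupling_class,
        "deviant_cell_type": [d if d is not None else "" for d in truth.deviant_cell_type],
    }).to_csv(paths["truth"], sep="\t", index=False)
    if annotation is not None:
        paths["annotation"] = str(outdir / "annotation.tsv")
        annotation.to_csv(paths["annotation"], sep="\t", index=False)
    manifest = {"config": asdict(cfg), "files": paths}
    with open(outdir / "synthetic_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    return paths
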