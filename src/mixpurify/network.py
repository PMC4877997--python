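"""Expression calling, tiering, selectivity and ligand-receptor networks.

Operates on contamination-adjusted TPM matrices of two cell populations
(tumor cells and tumor-associated macrophages in the motivating setting)
and applies the expression-filter rules behind the common and
patient-specific signaling networks:

* a gene is *expressed* in a cell type if TPM >= 3 in at least 65 % of
  that cell type's samples;
* expressed genes are tiered low (TPM 3-20), moderate (20-100) or high
  (>100) by their median TPM;
* a gene is *cell-type selective* if the median ratio between the two cell
  types is at least threefold and the per-sample values overlap by at most
  one outlier;
* a ligand's *source class* (tumor / tam / both) follows a tenfold rule on
  the median ratio;
* *subset* (patient-specific) genes clear TPM > 3 in at least two samples
  while failing the 65 % criterion;
* network edges pair expressed (common or subset) ligands with receptors
  expressed in at least one cell type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: TPM at or above which a single sample counts as expressing the gene
EXPRESSION_THRESHOLD = 3.0
#: minimum fraction of samples that must express the gene
SAMPLE_FRACTION = 0.65
#: pseudocount stabilising median ratios against zero medians
RATIO_EPS = 0.01


def call_expressed(
    values: Sequence[float] | pd.Series | np.ndarray,
    threshold: float = EXPRESSION_THRESHOLD,
    sample_fraction: float = SAMPLE_FRACTION,
) -> bool:
    """True iff >= ``sample_fraction`` of samples have TPM >= ``threshold``.

    The comparison is inclusive on both sides: a TPM of exactly 3 counts as
    expressed, and 13 of 20 samples (= 0.65) meets the default fraction.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot call expression on an empty sample vector")
    return bool((arr >= threshold).sum() / arr.size >= sample_fraction)


def classify_tier(median_tpm: float) -> str:
    """Expression tier from the median TPM.

    ``none`` below 3, ``low`` in [3, 20), ``moderate`` in [20, 100],
    ``high`` above 100.  The published tier bands overlap at 20 and 100;
    the boundary at 20 goes to the higher class while exactly 100 stays
    moderate (high is strictly ">100").
    """
    if median_tpm < 0:
        raise ValueError("median TPM must be non-negative")
    if median_tpm < 3:
        return "none"
    if median_tpm < 20:
        return "low"
    if median_tpm <= 100:
        return "moderate"
    return "high"


def classify_selectivity(
    tumor_values: Sequence[float] | pd.Series,
    tam_values: Sequence[float] | pd.Series,
    fold: float = 3.0,
    max_outliers: int = 1,
    eps: float = RATIO_EPS,
    n_boot: int = 2000,
    seed: int = 1,
) -> tuple[str, float, tuple[float, float]]:
    """Cell-type selectivity call with a bootstrap CI on the median ratio.

    The ratio is ``(median_tumor + eps) / (median_tam + eps)``.  A gene is
    selective toward the higher-expressing cell type iff the ratio clears
    ``fold`` (or its reciprocal) *and* at most ``max_outliers`` values from
    the higher side fall at or below the lower side's maximum.  The CI is a
    seeded percentile bootstrap (``n_boot`` resamples) of the ratio.
    """
    t = np.asarray(tumor_values, dtype=float)
    m = np.asarray(tam_values, dtype=float)
    if t.size < 2 or m.size < 2:
        raise ValueError("need at least 2 samples per cell type")
    ratio = (np.median(t) + eps) / (np.median(m) + eps)
    if ratio >= fold:
        overlap = int((t <= m.max()).sum())
        selectivity = "tumor" if overlap <= max_outliers else "shared"
    elif ratio <= 1.0 / fold:
        overlap = int((m <= t.max()).sum())
        selectivity = "tam" if overlap <= max_outliers else "shared"
    else:
        selectivity = "shared"
    rng = np.random.default_rng(seed)
    bt = rng.choice(t, size=(n_boot, t.size), replace=True)
    bm = rng.choice(m, size=(n_boot, m.size), replace=True)
    boots = (np.median(bt, axis=1) + eps) / (np.median(bm, axis=1) + eps)
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return selectivity, float(ratio), ci


def classify_ligand_source(
    tumor_median: float, tam_median: float,
    fold: float = 10.0, eps: float = RATIO_EPS,
) -> str:
    """Ligand source class by the tenfold rule on the median ratio:
    ``tumor`` (ratio >= fold), ``tam`` (<= 1/fold), else ``both``."""
    ratio = (tumor_median + eps) / (tam_median + eps)
    if ratio >= fold:
        return "tumor"
    if ratio <= 1.0 / fold:
        return "tam"
    return "both"


@dataclass
class SubsetGene:
    """A gene expressed only in a patient subset (TPM > 3 in >= 2 samples
    but failing the 65 % common-network criterion)."""

    gene_id: str
    n_samples_above: int
    min_tpm: float
    max_tpm: float


def find_subset_genes(
    tpm_matrix: pd.DataFrame,
    common_calls: Mapping[str, bool] | pd.Series,
    min_samples: int = 2,
    threshold: float = EXPRESSION_THRESHOLD,
) -> list[SubsetGene]:
    """Patient-subset genes: strictly above ``threshold`` in at least
    ``min_samples`` samples while not commonly expressed.

    ``tpm_matrix`` is genes x samples; ``common_calls`` maps each gene to
    its common-network expression call in the same cell type.  Reported
    min/max TPM are taken across all samples.
    """
    calls = pd.Series(common_calls)
    missing = tpm_matrix.index.difference(calls.index)
    if len(missing) > 0:
        raise ValueError(f"no common-network call for gene(s): {list(missing)}")
    out = []
    arr = tpm_matrix.to_numpy(dtype=float)
    n_above = (arr > threshold).sum(axis=1)
    for i, gene in enumerate(tpm_matrix.index):
        if n_above[i] >= min_samples and not calls[gene]:
            out.append(
                SubsetGene(
                    gene_id=gene,
                    n_samples_above=int(n_above[i]),
                    min_tpm=float(arr[i].min()),
                    max_tpm=float(arr[i].max()),
                )
            )
    return out


def classify_genes(
    tumor_tpm: pd.DataFrame,
    tam_tpm: pd.DataFrame,
    ligand_genes: Sequence[str] | None = None,
    seed: int = 1,
    n_boot: int = 2000,
) -> pd.DataFrame:
    """Per-gene classification table over two cell populations.

    For every gene shared by both matrices: expression calls per cell type
    (65 % rule, evaluated per cell type), median TPM and tier per cell
    type, the tumor/TAM median ratio with a bootstrap 95 % CI, the
    selectivity class, and — for genes listed in ``ligand_genes`` — the
    ligand source class by the tenfold rule.
    """
    genes = tumor_tpm.index.intersection(tam_tpm.index)
    ligset = set(ligand_genes) if ligand_genes is not None else None
    rows = []
    for gene in genes:
        tv = tumor_tpm.loc[gene]
        mv = tam_tpm.loc[gene]
        expr_t = call_expressed(tv)
        expr_m = call_expressed(mv)
        med_t = float(np.median(tv))
        med_m = float(np.median(mv))
        sel, ratio, ci = classify_selectivity(
            tv, mv, seed=seed, n_boot=n_boot
        )
        row = {
            "gene_id": gene,
            "expressed_tumor": expr_t,
            "expressed_tam": expr_m,
            "median_tpm_tumor": med_t,
            "median_tpm_tam": med_m,
            "tier_tumor": classify_tier(med_t) if expr_t else "none",
            "tier_tam": classify_tier(med_m) if expr_m else "none",
            "tumor_tam_ratio": ratio,
            "ratio_ci_lo": ci[0],
            "ratio_ci_hi": ci[1],
            "selectivity": sel,
            "source_class": (
                classify_ligand_source(med_t, med_m)
                if ligset is None or gene in ligset
                else None
            ),
        }
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass
class NetworkEdge:
    """One ligand-receptor interaction admitted by the filter rules."""

    ligand_gene: str
    receptor_gene: str
    ligand_source_class: str
    receptor_expressed_in: frozenset[str]
    ligand_tier_tumor: str
    ligand_tier_tam: str
    receptor_tier_tumor: str
    receptor_tier_tam: str
    patient_specific: bool


def build_edges(
    classifications: pd.DataFrame,
    lr_map: pd.DataFrame,
    subset_genes: Sequence[SubsetGene] = (),
) -> list[NetworkEdge]:
    """Assemble network edges from a curated ligand -> receptor map.

    One edge is emitted per map pair whose ligand passes the common
    criterion in either cell type (or the subset criterion, marking the
    edge ``patient_specific``) and whose receptor is commonly expressed in
    at least one cell type.  Pairs naming genes absent from the
    classification table are skipped with a warning.
    """
    required = {"ligand_gene", "receptor_gene"}
    if not required.issubset(lr_map.columns):
        raise ValueError(f"lr_map must have columns {sorted(required)}")
    subset_ids = {s.gene_id for s in subset_genes}
    edges = []
    for _, pair in lr_map.iterrows():
        lig, rec = pair["ligand_gene"], pair["receptor_gene"]
        missing = [g for g in (lig, rec) if g not in classifications.index]
        if missing:
            warnings.warn(
                f"gene(s) {missing} absent from classification table; "
                f"skipping pair ({lig}, {rec})",
                UserWarning,
                stacklevel=2,
            )
            continue
        lrow = classifications.loc[lig]
        rrow = classifications.loc[rec]
        lig_common = bool(lrow["expressed_tumor"] or lrow["expressed_tam"])
        lig_subset = lig in subset_ids
        if not (lig_common or lig_subset):
            continue
        rec_in = frozenset(
            ct for ct, flag in
            (("tumor", rrow["expressed_tumor"]), ("tam", rrow["expressed_tam"]))
            if flag
        )
        if not rec_in:
            continue
        source = lrow["source_class"]
        edges.append(
            NetworkEdge(
                ligand_gene=lig,
                receptor_gene=rec,
                ligand_source_class=(
                    source if source is not None
                    else classify_ligand_source(
                        lrow["median_tpm_tumor"], lrow["median_tpm_tam"]
                    )
                ),
                receptor_expressed_in=rec_in,
                ligand_tier_tumor=lrow["tier_tumor"],
                ligand_tier_tam=lrow["tier_tam"],
                receptor_tier_tumor=rrow["tier_tumor"],
                receptor_tier_tam=rrow["tier_tam"],
                patient_specific=not lig_common,
            )
        )
    return edges


def edges_to_frame(edges: Sequence[NetworkEdge]) -> pd.DataFrame:
    """Tabular view of an edge list (for TSV export)."""
    return pd.DataFrame(
        [
            {
                "ligand_gene": e.ligand_gene,
                "receptor_gene": e.receptor_gene,
                "ligand_source_class": e.ligand_source_class,
                "receptor_expressed_in": ",".join(sorted(e.receptor_expressed_in)),
                "ligand_tier_tumor": e.ligand_tier_tumor,
                "ligand_tier_tam": e.ligand_tier_tam,
                "receptor_tier_tumor": e.receptor_tier_tumor,
                "receptor_tier_tam": e.receptor_tier_tam,
                "patient_specific": e.patient_specific,
            }
            for e in edges
        ]
    )
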