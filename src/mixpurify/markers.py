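"""Automatic contamination-marker selection from pure reference profiles.

A contamination marker for a (target, contaminant) cell-type pair is a gene
strongly expressed in the contaminating cell type and essentially silent in
the target — and, so that each panel reads out one contaminant specifically
in three-population settings, silent in every other reference cell type as
well.  Markers then behave as near-binary indicators: in a mixed sample the
ratio of a marker's TPM to its contaminant-reference TPM estimates the
mixing fraction directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class MarkerParams:
    """Thresholds for marker eligibility and ranking.

    min_contam_tpm : minimum TPM in the contaminant reference (default 30).
    max_target_tpm : maximum TPM in the target reference and in every other
        reference profile (default 1).
    pseudocount : stabiliser added to both sides of the ranking ratio.
    panel_size : number of top-ranked markers kept (default 17).
    """

    min_contam_tpm: float = 30.0
    max_target_tpm: float = 1.0
    pseudocount: float = 1.0
    panel_size: int = 17

    def __post_init__(self) -> None:
        if self.min_contam_tpm <= 0 or self.pseudocount <= 0:
            raise ValueError("thresholds and pseudocount must be positive")
        if self.max_target_tpm < 0:
            raise ValueError("max_target_tpm must be non-negative")
        if self.panel_size < 1:
            raise ValueError("panel_size must be >= 1")


@dataclass
class ReferenceProfile:
    """A pure cell type's TPM vector; purity is an input assumption."""

    cell_type: str
    tpm: pd.Series

    def __post_init__(self) -> None:
        vals = self.tpm.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError(f"negative TPM in reference {self.cell_type!r}")
        if not np.isclose(vals.sum(), 1e6, rtol=1e-6):
            raise ValueError(
                f"reference {self.cell_type!r} TPM sums to {vals.sum():.6g}, "
                "expected 1e6"
            )
        if self.tpm.index.has_duplicates:
            raise ValueError("duplicate gene ids in reference profile")


@dataclass
class MarkerPanel:
    """Ranked contamination markers for one (target, contaminant) pair.

    ``markers`` holds one row per marker gene (index = gene id) with
    columns ``contaminant_ref_tpm``, ``target_ref_tpm`` and ``ratio``,
    ordered by decreasing ratio.
    """

    target_type: str
    contaminant_type: str
    markers: pd.DataFrame
    params: MarkerParams = field(default_factory=MarkerParams)

    @property
    def gene_ids(self) -> pd.Index:
        return self.markers.index

    @property
    def contaminant_ref_tpm(self) -> pd.Series:
        return self.markers["contaminant_ref_tpm"]

    def to_tsv(self, path: str | Path) -> None:
        out = self.markers.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(
        cls, path: str | Path, target_type: str = "target",
        contaminant_type: str = "contaminant",
    ) -> "MarkerPanel":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(target_type, contaminant_type, df)


def select_markers(
    target_ref: ReferenceProfile,
    contaminant_ref: ReferenceProfile,
    other_refs: Sequence[ReferenceProfile] = (),
    params: MarkerParams | None = None,
) -> MarkerPanel:
    """Select contamination markers for a (target, contaminant) pair.

    Eligible genes have contaminant-reference TPM >= ``min_contam_tpm`` and
    TPM <= ``max_target_tpm`` in the target reference *and* in every profile
    in ``other_refs``.  Eligible genes are ranked by
    ``(contaminant + pseudocount) / (target + pseudocount)`` (descending,
    ties broken by gene id) and the top ``panel_size`` kept.

    Raises
    ------
    ValueError
        If the profiles do not share a gene universe or no gene is eligible.

    Warns
    -----
    UserWarning
        If fewer than ``panel_size`` genes are eligible (all are returned).
    """
    params = params or MarkerParams()
    genes = target_ref.tpm.index
    for ref in (contaminant_ref, *other_refs):
        if not genes.sort_values().equals(ref.tpm.index.sort_values()):
            raise ValueError(
                f"reference {ref.cell_type!r} does not share the gene "
                "universe of the target reference"
            )
    t = target_ref.tpm
    c = contaminant_ref.tpm.reindex(genes)
    eligible = (c >= params.min_contam_tpm) & (t <= params.max_target_tpm)
    for ref in other_refs:
        eligible &= ref.tpm.reindex(genes) <= params.max_target_tpm
    if not eligible.any():
        raise ValueError(
            "zero eligible marker genes for "
            f"({target_ref.cell_type}, {contaminant_ref.cell_type}); "
            "consider relaxing min_contam_tpm/max_target_tpm"
        )
    df = pd.DataFrame(
        {
            "contaminant_ref_tpm": c[eligible],
            "target_ref_tpm": t[eligible],
            "ratio": (c[eligible] + params.pseudocount)
            / (t[eligible] + params.pseudocount),
        }
    )
    df = _sort_by_ratio_then_id(df)
    if len(df) < params.panel_size:
        warnings.warn(
            f"only {len(df)} eligible markers for panel_size="
            f"{params.panel_size} ({target_ref.cell_type} vs "
            f"{contaminant_ref.cell_type}); returning all",
            UserWarning,
            stacklevel=2,
        )
    return MarkerPanel(
        target_type=target_ref.cell_type,
        contaminant_type=contaminant_ref.cell_type,
        markers=df.head(params.panel_size),
        params=params,
    )


def _sort_by_ratio_then_id(df: pd.DataFrame) -> pd.DataFrame:
    # descending ratio, lexicographic gene id on ties (reproducibility)
    tmp = df.reset_index(names="gene_id")
    tmp = tmp.sort_values(["ratio", "gene_id"], ascending=[False, True])
    return tmp.set_index("gene_id")


def select_panel_set(
    refs: Iterable[ReferenceProfile],
    target_type: str,
    params: MarkerParams | None = None,
) -> list[MarkerPanel]:
    """One panel per non-target reference, each specific against the rest."""
    refs = list(refs)
    target = next(r for r in refs if r.cell_type == target_type)
    panels = []
    for contaminant in refs:
        if contaminant.cell_type == target_type:
            continue
        others = [
            r for r in refs
            if r.cell_type not in (target_type, contaminant.cell_type)
        ]
        panels.append(select_markers(target, contaminant, others, params))
    return panels
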