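"""Linear mixture model for contamination estimation and TPM adjustment.

A bulk profile of a sorted cell population is modelled as a convex mixture
of the target cell type and one or more contaminating cell types,

    sample = (1 - sum_c alpha_c) * target + sum_c alpha_c * ref_c ,

on the TPM scale.  Because contamination markers are (near-)silent in the
target, each marker gene's observed TPM divided by its contaminant-reference
TPM estimates alpha_c directly; the per-contaminant estimate is the median
of these per-marker ratios, robust to the occasional marker the target does
express.  Adjustment subtracts the estimated contaminant signal gene-wise,
clips at zero and renormalises to one million, which redistributes the
removed transcript mass from contaminant-derived to target-derived genes.

The statsmodels-style entry point is :class:`ContaminationModel`, whose
``fit`` returns a :class:`ContaminationResults` carrying per-sample
estimates, exclusion flags, the adjusted matrix and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import TPM_SUM, ExpressionMatrix
from .markers import MarkerPanel, MarkerParams, ReferenceProfile, select_panel_set

#: per-marker ratios above this cap are truncated before taking the median
DEFAULT_CAP = 0.6
#: samples whose total estimated contamination exceeds this are flagged
DEFAULT_EXCLUSION_THRESHOLD = 0.20


@dataclass
class ContaminationEstimate:
    """Per-sample contamination fractions with per-marker diagnostics."""

    sample_id: str
    alpha: dict[str, float]  # contaminant cell type -> fraction
    marker_ratios: dict[str, pd.Series]  # contaminant -> raw per-marker ratios
    excluded: bool

    @property
    def total(self) -> float:
        return float(sum(self.alpha.values()))


def estimate_contamination(
    sample: pd.Series,
    panels: Sequence[MarkerPanel],
    cap: float = DEFAULT_CAP,
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
    sample_id: str | None = None,
) -> ContaminationEstimate:
    """Estimate the contamination fraction(s) of one TPM column.

    For each panel the fraction is the median over marker genes of
    ``clip(sample[g] / contaminant_ref_tpm[g], 0, cap)``.  The sample is
    flagged ``excluded`` when the summed fractions exceed
    ``exclusion_threshold``.
    """
    alpha: dict[str, float] = {}
    ratios: dict[str, pd.Series] = {}
    for panel in panels:
        if len(panel.markers) == 0:
            raise ValueError(
                f"empty marker panel for contaminant {panel.contaminant_type!r}"
            )
        missing = panel.gene_ids.difference(sample.index)
        if len(missing) > 0:
            raise ValueError(
                f"marker gene(s) absent from sample: {list(missing)}"
            )
        ref = panel.contaminant_ref_tpm
        if (ref <= 0).any():
            raise ValueError(
                "contaminant reference TPM must be positive at every marker"
            )
        r = sample.loc[panel.gene_ids] / ref
        ratios[panel.contaminant_type] = r
        alpha[panel.contaminant_type] = float(np.median(np.clip(r, 0.0, cap)))
    total = sum(alpha.values())
    return ContaminationEstimate(
        sample_id=sample_id if sample_id is not None else str(sample.name),
        alpha=alpha,
        marker_ratios=ratios,
        excluded=total > exclusion_threshold,
    )


def adjust(
    sample: pd.Series,
    estimate: ContaminationEstimate,
    contaminant_refs: Mapping[str, ReferenceProfile],
) -> pd.Series:
    """Remove estimated contaminant signal from one TPM column.

    Subtracts all contaminants jointly (``sample - sum_c alpha_c * ref_c``),
    clips negative values at zero — TPM is non-negative by definition — and
    renormalises the column to one million.

    Raises
    ------
    ValueError
        If the summed fractions reach 1, or nothing survives the subtraction.
    """
    total = estimate.total
    if total >= 1.0:
        raise ValueError(
            f"summed contamination fraction {total:.3f} >= 1 for sample "
            f"{estimate.sample_id!r}; cannot adjust"
        )
    raw = sample.astype(float).copy()
    for cell_type, a in estimate.alpha.items():
        ref = contaminant_refs[cell_type].tpm.reindex(sample.index)
        if ref.isna().any():
            raise ValueError(
                f"reference {cell_type!r} does not cover the gene universe"
            )
        raw = raw - a * ref
    raw = raw.clip(lower=0.0)
    mass = raw.sum()
    if mass == 0:
        raise ValueError(
            f"all adjusted values are zero for sample {estimate.sample_id!r}"
        )
    return raw / mass * TPM_SUM


def adjust_matrix(
    matrix: ExpressionMatrix,
    panels: Sequence[MarkerPanel],
    contaminant_refs: Mapping[str, ReferenceProfile],
    cap: float = DEFAULT_CAP,
    exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Estimate and adjust every column of a TPM matrix.

    Returns the adjusted matrix plus a per-sample report (alpha per
    contaminant, total, excluded flag).  Samples above the exclusion
    threshold are adjusted and retained in the output — dropping them is a
    downstream decision — but carry ``excluded=True`` in the report.
    """
    if matrix.unit != "tpm":
        raise ValueError("adjust_matrix expects a TPM matrix")
    adjusted = {}
    rows = []
    for sample_id in matrix.sample_ids:
        col = matrix.values[sample_id]
        try:
            est = estimate_contamination(
                col, panels, cap=cap, exclusion_threshold=exclusion_threshold
            )
            adjusted[sample_id] = adjust(col, est, contaminant_refs)
        except ValueError as err:
            raise ValueError(f"sample {sample_id!r}: {err}") from err
        row = {"sample_id": sample_id}
        row.update({f"alpha_{c}": a for c, a in est.alpha.items()})
        row["alpha_total"] = est.total
        row["excluded"] = est.excluded
        rows.append(row)
    out = ExpressionMatrix(
        pd.DataFrame(adjusted, index=matrix.gene_ids)[list(matrix.sample_ids)],
        unit="tpm",
    )
    report = pd.DataFrame(rows).set_index("sample_id")
    return out, report


class ContaminationModel:
    """Contamination mixture model for a TPM matrix of one cell population.

    Parameters
    ----------
    matrix : ExpressionMatrix
        TPM matrix of the target population's samples.
    panels : sequence of MarkerPanel
        One panel per contaminating cell type.
    contaminant_refs : mapping of cell type -> ReferenceProfile
        Pure contaminant profiles used for the subtraction step.
    cap, exclusion_threshold : float
        Per-marker ratio cap and the summed-fraction threshold above which
        a sample is flagged as too heavily contaminated to trust.

    Examples
    --------
    >>> model = ContaminationModel.from_references(tpm, refs, target_type="tumor")
    >>> res = model.fit()
    >>> res.alpha          # doctest: +SKIP
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        panels: Sequence[MarkerPanel],
        contaminant_refs: Mapping[str, ReferenceProfile],
        cap: float = DEFAULT_CAP,
        exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
    ) -> None:
        self.matrix = matrix
        self.panels = list(panels)
        self.contaminant_refs = dict(contaminant_refs)
        self.cap = cap
        self.exclusion_threshold = exclusion_threshold

    @classmethod
    def from_references(
        cls,
        matrix: ExpressionMatrix,
        refs: Sequence[ReferenceProfile],
        target_type: str,
        marker_params: MarkerParams | None = None,
        cap: float = DEFAULT_CAP,
        exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
    ) -> "ContaminationModel":
        """Build the model from pure reference profiles, selecting marker
        panels automatically for every non-target reference."""
        panels = select_panel_set(refs, target_type, marker_params)
        contaminant_refs = {
            r.cell_type: r for r in refs if r.cell_type != target_type
        }
        return cls(matrix, panels, contaminant_refs, cap, exclusion_threshold)

    def fit(self) -> "ContaminationResults":
        adjusted, report = adjust_matrix(
            self.matrix,
            self.panels,
            self.contaminant_refs,
            cap=self.cap,
            exclusion_threshold=self.exclusion_threshold,
        )
        estimates = [
            estimate_contamination(
                self.matrix.values[s],
                self.panels,
                cap=self.cap,
                exclusion_threshold=self.exclusion_threshold,
            )
            for s in self.matrix.sample_ids
        ]
        return ContaminationResults(self, estimates, adjusted, report)


@dataclass
class ContaminationResults:
    """Fitted contamination estimates and the adjusted matrix."""

    model: ContaminationModel
    estimates: list[ContaminationEstimate]
    adjusted: ExpressionMatrix
    report: pd.DataFrame = field(repr=False)

    @property
    def alpha(self) -> pd.DataFrame:
        """Sample x contaminant table of estimated fractions."""
        cols = [c for c in self.report.columns if c.startswith("alpha_")
                and c != "alpha_total"]
        return self.report[cols].rename(
            columns=lambda c: c.removeprefix("alpha_")
        )

    @property
    def excluded(self) -> pd.Series:
        return self.report["excluded"]

    def summary(self) -> str:
        """Plain-text per-sample summary table."""
        lines = ["Contamination mixture model", "=" * 60]
        contaminants = ", ".join(
            p.contaminant_type for p in self.model.panels
        )
        lines.append(f"samples: {len(self.report)}    contaminants: {contaminants}")
        lines.append(
            f"cap: {self.model.cap}    exclusion threshold: "
            f"{self.model.exclusion_threshold}"
        )
        lines.append("-" * 60)
        tbl = self.report.copy()
        for c in tbl.columns:
            if c != "excluded":
                tbl[c] = tbl[c].map(lambda v: f"{100 * v:.1f}%")
        lines.append(tbl.to_string())
        n_excl = int(self.report["excluded"].sum())
        lines.append("-" * 60)
        lines.append(f"flagged as heavily contaminated: {n_excl}")
        return "\n".join(lines)
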