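"""End-to-end orchestration of the subtyping pipeline on one cohort.

Chains the stages in their canonical order: marker selection on labeled
reference samples, signature construction, fraction deconvolution of
the mixed cohort, dominant-subtype calling, genomic-lesion association
(SNV and CNV dual selection with OPLS modeling of the MetB fraction),
and survival analysis.  Used by the command-line interface and by the
integration tests; each stage remains independently callable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from metac import deconvolution, genomics, signature, survival
from metac.core.types import (
    ExpressionMatrix,
    SampleAnnotation,
    SignatureMatrix,
    SubtypeLabeling,
    fractions_frame,
)
from metac.deconvolution import DeconvolutionConfig
from metac.genomics import OplsModel

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    markers: signature.MarkerSelection
    signature: SignatureMatrix
    fractions: pd.DataFrame
    snv_associations: pd.DataFrame
    cnv_dual: pd.DataFrame
    selected_cnv_genes: list[str]
    opls: OplsModel | None
    survival_report: dict


def run_pipeline(
    reference_expr: ExpressionMatrix,
    reference_labels: SubtypeLabeling,
    cohort_expr: ExpressionMatrix,
    annotation: SampleAnnotation,
    variants: pd.DataFrame | None = None,
    cnv_records: pd.DataFrame | None = None,
    top_n_markers: int = 60,
    min_fold_change: float = 1.5,
    replicates_per_subtype: int = 3,
    deconv_config: DeconvolutionConfig | None = None,
    snv_min_frequency: float = 0.02,
    association_alpha: float = 0.05,
    n_orthogonal: int = 1,
) -> PipelineResult:
    """Run signature -> fractions -> genomics -> survival on one cohort."""
    markers = signature.select_markers(
        reference_expr.to_log2(), reference_labels,
        top_n=top_n_markers, min_fc=min_fold_change,
    )
    sig = signature.build_reference(
        reference_expr, reference_labels, markers.genes,
        replicates_per_subtype=replicates_per_subtype,
    )
    estimates = deconvolution.estimate_cohort(cohort_expr, sig, deconv_config)
    fractions = fractions_frame(estimates)

    snv_assoc = pd.DataFrame()
    cnv_dual = pd.DataFrame()
    selected: list[str] = []
    opls_model = None
    samples = list(cohort_expr.sample_ids)
    metb = fractions["MetB"]

    retained = None
    if variants is not None and len(variants):
        retained, _ = genomics.filter_snvs(variants)
        if len(retained):
            lesions, _ = genomics.snv_gene_matrix(
                retained, samples, min_freq=snv_min_frequency
            )
            snv_assoc = genomics.lesion_fraction_association(lesions, metb)

    if cnv_records is not None and len(cnv_records):
        calls = genomics.cnv_call_matrix(cnv_records, samples)
        linear = cohort_expr.to_linear()
        kept = genomics.cnv_gene_filters(calls, linear)
        if kept:
            cnv_dual = genomics.cnv_dual_association(
                calls.loc[kept], linear, metb, alpha=association_alpha
            )
            selected = genomics.selected_genes(cnv_dual)
        if selected:
            X = linear.values.loc[selected].T
            opls_model = genomics.opls_fit(X, metb, n_orth=n_orthogonal)

    # binary lesion status for the multivariate model, mirroring
    # "SNVs and/or CNV loss" of the top-associated gene(s)
    lesion_status = None
    if len(snv_assoc) or selected:
        carrier = pd.Series(False, index=pd.Index(samples))
        if len(snv_assoc) and retained is not None:
            top_gene = snv_assoc["p_value"].idxmin()
            hit = set(retained.loc[retained["gene"] == top_gene, "sample_id"])
            carrier |= carrier.index.isin(hit)
        if selected and cnv_records is not None:
            loss = set(
                cnv_records.loc[
                    cnv_records["gene"].isin(selected)
                    & (cnv_records["copy_number"] <= 1),
                    "sample_id",
                ]
            )
            carrier |= carrier.index.isin(loss)
        lesion_status = carrier

    report = survival.subtype_survival_report(fractions, annotation, lesion_status)
    return PipelineResult(
        markers=markers,
        signature=sig,
        fractions=fractions,
        snv_associations=snv_assoc,
        cnv_dual=cnv_dual,
        selected_cnv_genes=selected,
        opls=opls_model,
        survival_report=report,
    )
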