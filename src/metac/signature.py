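"""Subtype marker selection and signature-matrix construction.

Markers are chosen one-vs-rest per subtype by Mann-Whitney p-value with
a median fold-change floor (fold change computed from log2 medians as
``2^(median_subtype - median_rest)``, up-regulation only).  An optional
cross-cohort consistency filter retains only markers whose expression
tracks their own subtype's marker-set mean in every external cohort.
The reference (signature) matrix is built from the most representative
samples per subtype - the ones nearest their subtype centroid over the
signature genes - averaged per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from metac.core.stats import spearman_corr
from metac.core.types import SUBTYPES, ExpressionMatrix, SignatureMatrix, SubtypeLabeling

log = logging.getLogger(__name__)


@dataclass
class MarkerSelection:
    """Per-gene marker records with per-subtype ranked lists.

    ``table`` has one row per selected gene with columns ``subtype``,
    ``p_value`` and ``fold_change``, ordered by ascending p within each
    subtype.
    """

    table: pd.DataFrame

    def genes_of(self, subtype: str) -> list[str]:
        sub = self.table[self.table["subtype"] == subtype]
        return list(sub.index)

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def _one_vs_rest_mw(values: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Vectorised per-gene two-sided Mann-Whitney p (genes x samples input)."""
    x = values[:, in_group]
    y = values[:, ~in_group]
    method = "exact" if (
        x.shape[1] <= 8 and y.shape[1] <= 8
        and np.unique(values, axis=None).size == values.size
    ) else "asymptotic"
    res = _sps.mannwhitneyu(x, y, alternative="two-sided", method=method, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    p[np.isnan(p)] = 1.0
    return p


def select_markers(
    expr: ExpressionMatrix,
    labels: SubtypeLabeling,
    top_n: int = 60,
    min_fc: float = 1.5,
) -> MarkerSelection:
    """Select up to ``top_n`` up-regulated marker genes per subtype.

    A gene qualifying for two subtypes is assigned to the subtype with
    the smaller p-value (ties broken by larger fold change).
    """
    if expr.scale != "log2":
        raise ValueError("marker selection requires log2-scale expression")
    labels.check_for_signature(expr)
    for s in SUBTYPES:
        if len(labels.samples_of(s)) < 2:
            raise ValueError(f"subtype {s} has fewer than 2 labeled samples")
    labeled = [s for s in expr.sample_ids if s in labels.labels]
    sub = expr.subset(samples=labeled)
    values = sub.values.to_numpy()
    genes = np.array(sub.gene_ids)
    log.info("selecting markers: top_n=%d, min_fc=%.3g", top_n, min_fc)

    candidates: dict[str, pd.DataFrame] = {}
    for subtype in SUBTYPES:
        in_group = np.array([labels.labels[s] == subtype for s in sub.sample_ids])
        p = _one_vs_rest_mw(values, in_group)
        med_in = np.median(values[:, in_group], axis=1)
        med_out = np.median(values[:, ~in_group], axis=1)
        fc = 2.0 ** (med_in - med_out)
        keep = fc >= min_fc
        candidates[subtype] = pd.DataFrame(
            {"p_value": p[keep], "fold_change": fc[keep]}, index=genes[keep]
        )

    # resolve genes qualifying for several subtypes: smaller p wins, then larger fc
    best: dict[str, tuple[float, float, str]] = {}
    for subtype, tab in candidates.items():
        for gene, row in tab.iterrows():
            prev = best.get(gene)
            if prev is None or (row["p_value"], -row["fold_change"]) < (prev[0], -prev[1]):
                best[gene] = (row["p_value"], row["fold_change"], subtype)

    rows = []
    for subtype in SUBTYPES:
        assigned = [
            (g, p, fc) for g, (p, fc, s) in best.items() if s == subtype
        ]
        assigned.sort(key=lambda t: (t[1], -t[2], t[0]))
        for g, p, fc in assigned[:top_n]:
            rows.append({"gene": g, "subtype": subtype, "p_value": p, "fold_change": fc})
    table = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["subtype", "p_value", "fold_change"]
    )
    return MarkerSelection(table)


def consistency_filter(
    markers: MarkerSelection,
    cohorts: list[ExpressionMatrix],
    min_own_corr: float = 0.3,
) -> tuple[MarkerSelection, pd.DataFrame]:
    """Retain markers whose expression tracks their own subtype set in every cohort.

    A marker is kept iff, in each cohort, its Spearman correlation with
    the mean expression of its own subtype's marker set is strictly
    larger than with either other subtype's marker-set mean *and* at
    least ``min_own_corr``.  The floor makes the filter decisive for
    genes carrying no signal at all, whose three correlations would
    otherwise hover around zero and win the comparison by chance.
    Returns the filtered selection and a per-gene retention report.
    """
    if not cohorts:
        raise ValueError("at least one external cohort is required")
    marker_genes = markers.genes
    retained = {g: True for g in marker_genes}
    report_rows = []
    for ci, cohort in enumerate(cohorts):
        present = [g for g in marker_genes if g in cohort.values.index]
        absent = set(marker_genes) - set(present)
        if len(present) < 0.5 * len(marker_genes):
            raise ValueError(
                f"cohort {ci} is missing more than 50% of markers "
                f"({len(absent)}/{len(marker_genes)})"
            )
        if absent:
            log.warning("cohort %d missing %d markers; dropped", ci, len(absent))
            for g in absent:
                retained[g] = False
        sub = cohort.values.loc[present]
        set_means = {
            s: sub.loc[[g for g in markers.genes_of(s) if g in sub.index]].mean(axis=0)
            for s in SUBTYPES
        }
        for g in present:
            own = markers.table.loc[g, "subtype"]
            corrs = {
                s: spearman_corr(sub.loc[g], set_means[s]).statistic for s in SUBTYPES
            }
            ok = corrs[own] >= min_own_corr and all(
                corrs[own] > corrs[s] for s in SUBTYPES if s != own
            )
            if not ok:
                retained[g] = False
            report_rows.append(
                {"gene": g, "cohort": ci, "subtype": own, **{
                    f"corr_{s}": corrs[s] for s in SUBTYPES
                }, "consistent": ok}
            )
    report = pd.DataFrame(report_rows)
    kept = markers.table.loc[[g for g in marker_genes if retained[g]]]
    log.info("consistency filter retained %d/%d markers", len(kept), len(marker_genes))
    return MarkerSelection(kept), report


def build_reference(
    expr: ExpressionMatrix,
    labels: SubtypeLabeling,
    signature_genes: list[str],
    replicates_per_subtype: int = 3,
) -> SignatureMatrix:
    """Build the subtype reference profile matrix from representative samples.

    Representatives are the ``replicates_per_subtype`` samples nearest
    (Euclidean distance over the signature genes) to their subtype
    centroid; each reference column is the per-gene mean of its
    representatives.
    """
    labels.check_for_signature(expr)
    present = [g for g in signature_genes if g in expr.values.index]
    dropped = set(signature_genes) - set(present)
    if dropped:
        log.warning("%d signature genes absent from expression; dropped", len(dropped))
    if not present:
        raise ValueError("no signature genes present in expression matrix")
    sub = expr.subset(genes=present)
    columns = {}
    for subtype in SUBTYPES:
        samples = labels.samples_of(subtype)
        if len(samples) < replicates_per_subtype:
            raise ValueError(
                f"subtype {subtype}: {len(samples)} samples < "
                f"{replicates_per_subtype} required replicates"
            )
        block = sub.values[samples]
        centroid = block.mean(axis=1)
        dist = np.sqrt(((block.sub(centroid, axis=0)) ** 2).sum(axis=0))
        reps = dist.nsmallest(replicates_per_subtype).index
        columns[subtype] = block[list(reps)].mean(axis=1)
    ref = pd.DataFrame(columns)[list(SUBTYPES)]
    return SignatureMatrix(ref, expr.scale)


def write_markers(markers: MarkerSelection, path) -> None:
    markers.table.to_csv(path, sep="\t", index_label="gene")


def read_markers(path) -> MarkerSelection:
    return MarkerSelection(pd.read_csv(path, sep="\t", index_col="gene"))
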