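"""Phenotype scores from the first principal component of a gene set.

Each sample's AR-activity / proliferation / NEPC-like score is its PC1
coordinate from a PCA of the gene-set submatrix (genes mean-centered
across samples, no per-gene scaling).  Because a principal component is
defined only up to sign, the score is oriented so that it correlates
positively with the per-sample mean expression of the gene set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from metac.core.stats import spearman_corr
from metac.core.types import SUBTYPES, ExpressionMatrix, GeneSet, ScoreVector

log = logging.getLogger(__name__)


def pc1_score(
    expr: ExpressionMatrix, gene_set: GeneSet, score_name: str
) -> ScoreVector:
    """First-principal-component sample scores over a gene set.

    Requires log2-scale expression, at least 3 samples and at least 2
    gene-set genes present (absent genes dropped with a log message).
    A zero-variance submatrix yields all-zero scores with a flag.
    """
    if expr.scale != "log2":
        raise ValueError("pc1_score expects log2-scale expression")
    if len(expr.sample_ids) < 3:
        raise ValueError("need at least 3 samples")
    present = [g for g in expr.gene_ids if g in gene_set.genes]
    absent = gene_set.genes - set(present)
    if absent:
        log.info("%s: %d gene-set genes absent from matrix", score_name, len(absent))
    if len(present) < 2:
        raise ValueError(
            f"fewer than 2 genes of set {gene_set.name!r} present in matrix"
        )
    sub = expr.values.loc[present]  # genes x samples
    centered = sub.sub(sub.mean(axis=1), axis=0).to_numpy()
    if np.allclose(centered, 0.0):
        scores = pd.Series(0.0, index=expr.sample_ids)
        return ScoreVector(score_name, scores, "zero-variance", 0.0, zero_variance=True)
    # samples are observations: PC1 sample scores from the SVD of X^T (samples x genes)
    u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
    t1 = u[:, 0] * s[0]
    evf = float(s[0] ** 2 / np.sum(s**2))
    mean_expr = sub.mean(axis=0).to_numpy()
    anchor = "positive correlation with gene-set mean expression"
    c = np.corrcoef(t1, mean_expr)[0, 1] if np.std(mean_expr) > 0 else 0.0
    if np.isnan(c):
        c = 0.0
    if c < 0:
        t1 = -t1
    elif c == 0:
        # degenerate anchor: orient by the first gene's loading
        anchor = "sign of first gene loading"
        if vt[0, 0] < 0:
            t1 = -t1
    scores = pd.Series(t1, index=expr.sample_ids)
    return ScoreVector(score_name, scores, anchor, evf)


def score_table(
    expr: ExpressionMatrix,
    gene_sets: dict[str, GeneSet],
    fractions: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman association of each phenotype score with each subtype fraction.

    ``fractions`` is a samples x {MetA, MetB, MetC} frame.  Returns a
    long-format table with one row per (score, subtype) pair carrying
    Rs and p, mirroring the layout used to report score/fraction
    correlations.
    """
    shared = [s for s in expr.sample_ids if s in fractions.index]
    if len(shared) < 3:
        raise ValueError("fewer than 3 samples shared between expression and fractions")
    sub = expr.subset(samples=shared)
    rows = []
    for name, gs in gene_sets.items():
        sv = pc1_score(sub, gs, name)
        for subtype in SUBTYPES:
            res = spearman_corr(sv.scores.loc[shared], fractions.loc[shared, subtype])
            rows.append(
                {
                    "score": name,
                    "subtype": subtype,
                    "rs": res.statistic,
                    "p_value": res.p_value,
                    "n": len(shared),
                }
            )
    return pd.DataFrame(rows)
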