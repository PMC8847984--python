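"""SNV/CNV retention rules, lesion-fraction association, and OPLS modeling.

Variant retention keeps truncating and splice classes unconditionally
and nonsynonymous SNVs only when both SIFT and PolyPhen call them
damaging (configurable to OR).  Copy-number calls use gain at copy
number >= 4 and loss at <= 1.  Genes surviving the expression/CNV
frequency filters are tested for association of lesion status with both
subtype fraction and expression (dual Mann-Whitney selection), and the
selected transcripts feed an orthogonal-projections-to-latent-structures
(OPLS) model of the MetB fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from metac.core.stats import bh_fdr, mann_whitney_u
from metac.core.types import ExpressionMatrix

log = logging.getLogger(__name__)

TRUNCATING_CLASSES = frozenset(
    {
        "frameshift_indel",
        "nonframeshift_indel",
        "startloss",
        "stopgain",
        "stoploss",
        "splice",
    }
)
EFFECT_CLASSES = TRUNCATING_CLASSES | {"nonsynonymous_snv", "other"}


def filter_snvs(records: pd.DataFrame, rule: str = "and") -> tuple[pd.DataFrame, dict]:
    """Retain deleterious variants.

    Truncating/splice classes are kept unconditionally; nonsynonymous
    SNVs are kept iff SIFT and PolyPhen both call them damaging
    (``rule='or'`` relaxes to either).  ``'other'`` records and
    nonsynonymous records lacking predictions are dropped and counted
    in the report.
    """
    if rule not in ("and", "or"):
        raise ValueError("rule must be 'and' or 'or'")
    bad = set(records["effect_class"]) - EFFECT_CLASSES
    if bad:
        raise ValueError(f"unknown effect classes: {sorted(bad)}")
    keep = np.zeros(len(records), dtype=bool)
    n_missing_pred = 0
    for i, (_, rec) in enumerate(records.iterrows()):
        cls = rec["effect_class"]
        if cls in TRUNCATING_CLASSES:
            keep[i] = True
        elif cls == "nonsynonymous_snv":
            sift = rec["sift_deleterious"]
            poly = rec["polyphen_damaging"]
            if pd.isna(sift) and pd.isna(poly):
                n_missing_pred += 1
                continue
            sift = bool(sift) if not pd.isna(sift) else False
            poly = bool(poly) if not pd.isna(poly) else False
            keep[i] = (sift and poly) if rule == "and" else (sift or poly)
    report = {
        "n_input": len(records),
        "n_retained": int(keep.sum()),
        "n_missing_predictions": n_missing_pred,
        "rule": rule,
    }
    log.info("filter_snvs: %s", report)
    return records.loc[keep].copy(), report


def snv_gene_matrix(
    records: pd.DataFrame, samples: list[str], min_freq: float = 0.02
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene x sample boolean mutation matrix, filtered by mutation frequency.

    Frequency is mutated samples over *all* supplied samples; the
    boundary (frequency exactly ``min_freq``) is retained.  Multiple
    records for one gene/sample count once.
    """
    if not samples:
        raise ValueError("empty sample universe")
    pairs = records[["gene", "sample_id"]].drop_duplicates()
    pairs = pairs[pairs["sample_id"].isin(samples)]
    genes = sorted(pairs["gene"].unique())
    mat = pd.DataFrame(False, index=genes, columns=samples)
    for _, row in pairs.iterrows():
        mat.loc[row["gene"], row["sample_id"]] = True
    freq = mat.sum(axis=1) / len(samples)
    retained = freq[freq >= min_freq].index
    log.info(
        "snv_gene_matrix: %d/%d genes at frequency >= %g", len(retained), len(genes), min_freq
    )
    return mat.loc[retained], freq.loc[retained]


def lesion_fraction_association(
    lesion_matrix: pd.DataFrame,
    fractions: pd.Series,
    subtype: str = "MetB",
) -> pd.DataFrame:
    """Mann-Whitney association of per-gene lesion status with a subtype fraction.

    ``lesion_matrix`` is genes x samples boolean; ``fractions`` maps the
    same samples to the tested subtype's fraction.  Genes with fewer
    than 2 samples in either status are skipped (logged).  The returned
    table also serves binary annotations such as ETS fusion status (one
    row, gene = annotation name).
    """
    shared = [s for s in lesion_matrix.columns if s in fractions.index]
    rows = []
    for gene in lesion_matrix.index:
        carrier = lesion_matrix.loc[gene, shared].to_numpy(bool)
        f = fractions.loc[shared].to_numpy(float)
        n1, n0 = int(carrier.sum()), int((~carrier).sum())
        if n1 < 2 or n0 < 2:
            log.debug("skipping %s: %d carriers vs %d non-carriers", gene, n1, n0)
            continue
        res = mann_whitney_u(f[carrier], f[~carrier])
        rows.append(
            {
                "gene": gene,
                "subtype": subtype,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n_carrier": n1,
                "n_noncarrier": n0,
                "median_carrier": float(np.median(f[carrier])),
                "median_noncarrier": float(np.median(f[~carrier])),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["direction"] = np.sign(table["median_carrier"] - table["median_noncarrier"])
        table["q_value"] = bh_fdr(table["p_value"].to_numpy())
        table = table.set_index("gene")
    return table


def call_cnv(copy_number) -> "str | np.ndarray":
    """Copy-number call: <=1 loss, >=4 gain, otherwise neutral."""
    cn = np.asarray(copy_number)
    if (cn < 0).any():
        raise ValueError("copy numbers must be >= 0")
    calls = np.where(cn <= 1, "loss", np.where(cn >= 4, "gain", "neutral"))
    if np.isscalar(copy_number) or np.ndim(copy_number) == 0:
        return str(calls)
    return calls


def cnv_call_matrix(cnv_records: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Genes x samples matrix of CNV calls (missing records are neutral)."""
    genes = sorted(cnv_records["gene"].unique())
    mat = pd.DataFrame("neutral", index=genes, columns=samples)
    sub = cnv_records[cnv_records["sample_id"].isin(samples)]
    for _, row in sub.iterrows():
        mat.loc[row["gene"], row["sample_id"]] = call_cnv(int(row["copy_number"]))
    return mat


def cnv_gene_filters(
    calls: pd.DataFrame,
    expr: ExpressionMatrix,
    rna_nonzero_fraction: float = 0.97,
    cnv_min_fraction: float = 0.03,
) -> list[str]:
    """Genes expressed in >97% of samples and CNV-altered in >=3%.

    The expression proportion is strict (> threshold), the CNV
    proportion inclusive (>= threshold); both follow the stated rules.
    """
    shared = [s for s in calls.columns if s in expr.values.columns]
    if not shared:
        raise ValueError("no shared samples between calls and expression")
    retained = []
    for gene in calls.index:
        if gene not in expr.values.index:
            continue
        nonzero = float((expr.values.loc[gene, shared] != 0).mean())
        altered = float((calls.loc[gene, shared] != "neutral").mean())
        if nonzero > rna_nonzero_fraction and altered >= cnv_min_fraction:
            retained.append(gene)
    log.info(
        "cnv_gene_filters: %d/%d genes (nonzero > %g, CNV >= %g)",
        len(retained), len(calls.index), rna_nonzero_fraction, cnv_min_fraction,
    )
    return retained


def cnv_dual_association(
    calls: pd.DataFrame,
    expr: ExpressionMatrix,
    fractions: pd.Series,
    subtype: str = "MetB",
    alpha: float = 0.05,
    pool_lesions: bool = False,
) -> pd.DataFrame:
    """Dual Mann-Whitney selection of CNV genes.

    A gene/lesion-type combination is selected iff the subtype fraction
    *and* the gene's expression both differ (p < alpha, unadjusted, as
    per the selection rule; BH q-values are reported alongside) between
    lesion carriers and neutral samples.  Losses and gains are tested
    separately unless ``pool_lesions``.
    """
    shared = [s for s in calls.columns if s in expr.values.columns and s in fractions.index]
    rows = []
    for gene in calls.index:
        if gene not in expr.values.index:
            continue
        gene_calls = calls.loc[gene, shared]
        lesion_kinds = (
            [("any", gene_calls != "neutral")]
            if pool_lesions
            else [(kind, gene_calls == kind) for kind in ("loss", "gain")]
        )
        for kind, carrier in lesion_kinds:
            carrier = carrier.to_numpy(bool)
            n1, n0 = int(carrier.sum()), int((~carrier).sum())
            if n1 < 2 or n0 < 2:
                continue
            f = fractions.loc[shared].to_numpy(float)
            e = expr.values.loc[gene, shared].to_numpy(float)
            res_f = mann_whitney_u(f[carrier], f[~carrier])
            res_e = mann_whitney_u(e[carrier], e[~carrier])
            rows.append(
                {
                    "gene": gene,
                    "lesion": kind,
                    "n_carrier": n1,
                    "p_fraction": res_f.p_value,
                    "p_expression": res_e.p_value,
                    "fraction_direction": float(
                        np.sign(np.median(f[carrier]) - np.median(f[~carrier]))
                    ),
                    "expression_direction": float(
                        np.sign(np.median(e[carrier]) - np.median(e[~carrier]))
                    ),
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["q_fraction"] = bh_fdr(table["p_fraction"].to_numpy())
        table["q_expression"] = bh_fdr(table["p_expression"].to_numpy())
        table["selected"] = (table["p_fraction"] < alpha) & (table["p_expression"] < alpha)
    log.info(
        "cnv_dual_association: %d/%d combinations selected at p < %g",
        int(table["selected"].sum()) if len(table) else 0, len(table), alpha,
    )
    return table


def selected_genes(dual_table: pd.DataFrame) -> list[str]:
    if not len(dual_table):
        return []
    return sorted(dual_table.loc[dual_table["selected"], "gene"].unique())


# ---------------------------------------------------------------------------
# OPLS


@dataclass
class OplsModel:
    """Single-response OPLS model (1 predictive + n_orth orthogonal components)."""

    feature_names: list[str]
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    pred_weights: np.ndarray
    pred_loadings: np.ndarray
    pred_scores: np.ndarray
    y_loading: float
    orth_weights: list[np.ndarray] = field(default_factory=list)
    orth_loadings: list[np.ndarray] = field(default_factory=list)
    orth_scores: list[np.ndarray] = field(default_factory=list)
    r2y: float = np.nan
    q2: float = np.nan

    @property
    def n_orth(self) -> int:
        return len(self.orth_weights)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xc = (np.asarray(X, dtype=float) - self.x_mean) / self.x_std
        for w_o, p_o in zip(self.orth_weights, self.orth_loadings):
            t_o = Xc @ w_o
            Xc = Xc - np.outer(t_o, p_o)
        return Xc @ self.pred_weights * self.y_loading + self.y_mean

    def fitted(self) -> np.ndarray:
        return self.pred_scores * self.y_loading + self.y_mean


def _opls_core(Xc: np.ndarray, yc: np.ndarray, n_orth: int):
    """NIPALS extraction of y-orthogonal components then one predictive one."""
    orth = []
    X = Xc.copy()
    for _ in range(n_orth):
        w = X.T @ yc
        w = w / np.linalg.norm(w)
        t = X @ w
        p = X.T @ t / (t @ t)
        w_orth = p - (w @ p) * w
        norm = np.linalg.norm(w_orth)
        if norm < 1e-12:
            # no y-orthogonal variation left: keep a zero component
            orth.append((np.zeros_like(w), np.zeros_like(w), np.zeros(X.shape[0])))
            continue
        w_orth = w_orth / norm
        t_orth = X @ w_orth
        p_orth = X.T @ t_orth / (t_orth @ t_orth)
        X = X - np.outer(t_orth, p_orth)
        orth.append((w_orth, p_orth, t_orth))
    w = X.T @ yc
    w = w / np.linalg.norm(w)
    t = X @ w
    p = X.T @ t / (t @ t)
    q = (yc @ t) / (t @ t)
    return orth, w, p, t, q


def opls_fit(
    X: pd.DataFrame,
    y: pd.Series,
    n_orth: int = 1,
    n_folds: int = 7,
) -> OplsModel:
    """Fit an OPLS model of a continuous response on transcript levels.

    Columns are centered and unit-variance scaled (zero-variance columns
    dropped with a log message).  R2Y is computed on the training data
    and Q2 by venetian-blinds ``n_folds``-fold cross-validation.
    """
    X = X.astype(float)
    yv = y.loc[X.index].to_numpy(dtype=float)
    n, m = X.shape
    if n < 5:
        raise ValueError("need at least 5 samples")
    std = X.std(axis=0, ddof=1)
    dead = std[std == 0].index
    if len(dead):
        log.warning("opls_fit: dropping %d zero-variance columns", len(dead))
        X = X.drop(columns=dead)
        std = std.drop(dead)
    rank = np.linalg.matrix_rank(X.to_numpy() - X.to_numpy().mean(axis=0))
    if n_orth >= rank:
        raise ValueError(f"n_orth={n_orth} >= rank(X)={rank}")
    x_mean = X.mean(axis=0).to_numpy()
    x_std = std.to_numpy()
    Xc = (X.to_numpy() - x_mean) / x_std
    y_mean = float(yv.mean())
    yc = yv - y_mean

    orth, w, p, t, q = _opls_core(Xc, yc, n_orth)
    yhat = t * q
    ss_y = float(yc @ yc)
    r2y = 1.0 - float((yc - yhat) @ (yc - yhat)) / ss_y if ss_y > 0 else np.nan

    # venetian-blinds cross-validation
    press = 0.0
    for fold in range(n_folds):
        test = np.arange(n) % n_folds == fold
        if test.sum() == 0 or (~test).sum() < 3:
            continue
        Xtr, ytr = Xc[~test], yc[~test]
        orth_cv, w_cv, _, t_cv, q_cv = _opls_core(Xtr, ytr, n_orth)
        Xte = Xc[test].copy()
        for w_o, p_o, _ in orth_cv:
            t_o = Xte @ w_o
            Xte = Xte - np.outer(t_o, p_o)
        press += float(np.sum((yc[test] - Xte @ w_cv * q_cv) ** 2))
    q2 = 1.0 - press / ss_y if ss_y > 0 else np.nan

    return OplsModel(
        feature_names=list(X.columns),
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        pred_weights=w,
        pred_loadings=p,
        pred_scores=t,
        y_loading=float(q),
        orth_weights=[o[0] for o in orth],
        orth_loadings=[o[1] for o in orth],
        orth_scores=[o[2] for o in orth],
        r2y=float(r2y),
        q2=float(q2),
    )
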