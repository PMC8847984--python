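"""Moderated-t ranking and preranked gene-set enrichment.

Gene ranking uses an empirical-Bayes moderated two-group t-statistic:
per-gene pooled residual variances are shrunk toward a common prior
whose variance and degrees of freedom are estimated by moment matching
on the distribution of log sample variances.  Enrichment of a gene set
in the ranked list is quantified with the weighted Kolmogorov-Smirnov
running statistic; the enrichment score (ES) is normalized against a
gene-label permutation null to give the NES, a nominal permutation p,
and an FDR q computed with the standard positive/negative-pool
procedure across all sets of a run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma

from metac.core.types import ExpressionMatrix, GeneSet

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# moderated t ranking


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of the prior variance s0^2 and prior df d0.

    Works on z = log(s^2): E[z] and Var[z] are matched to the scaled-F
    sampling model of the pooled variances, giving d0 from the excess of
    Var[z] over trigamma(df/2) and s0^2 from the mean.  Returns
    ``(s0_squared, d0)`` where d0 may be ``inf`` (no excess variation).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return float(np.mean(s2[ok])) if ok.any() else 0.0, np.inf
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    excess = float(np.var(e, ddof=1) - _trigamma(df / 2.0))
    if excess <= 0:
        return float(np.exp(np.mean(e))), np.inf
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(np.mean(e) + digamma(half_d0) - np.log(half_d0)))
    return s0_sq, d0


def moderated_t_rank(
    expr: ExpressionMatrix,
    group_samples,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.Series:
    """Rank genes by a moderated one-vs-rest t-statistic (descending).

    ``group_samples`` lists the sample ids of the focal group; all other
    samples form the rest.  ``prior_df``/``prior_var`` override the
    moment-matched prior (``prior_df=0`` gives the ordinary pooled t,
    ``prior_df=inf`` fully trusts the prior variance).  Ties in the
    statistic are broken by gene id for determinism.
    """
    if expr.scale != "log2":
        raise ValueError("moderated_t_rank expects log2-scale expression")
    group = [s for s in expr.sample_ids if s in set(group_samples)]
    rest = [s for s in expr.sample_ids if s not in set(group_samples)]
    n1, n2 = len(group), len(rest)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 samples per side, got {n1} vs {n2}")
    x = expr.values[group].to_numpy()
    y = expr.values[rest].to_numpy()
    delta = x.mean(axis=1) - y.mean(axis=1)
    df = n1 + n2 - 2
    s2 = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 += ((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 /= df
    if prior_df is None or prior_var is None:
        s0_sq, d0 = estimate_variance_prior(s2, df)
        if prior_df is not None:
            d0 = prior_df
        if prior_var is not None:
            s0_sq = prior_var
    else:
        s0_sq, d0 = prior_var, prior_df
    if np.isinf(d0):
        s2_mod = np.full_like(s2, s0_sq)
    elif d0 == 0:
        s2_mod = s2
    else:
        s2_mod = (d0 * s0_sq + df * s2) / (d0 + df)
    denom = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / denom
    t[(denom == 0) & (delta == 0)] = 0.0
    finite = np.isfinite(t)
    if not finite.all():
        # zero residual variance with nonzero effect: stronger than any
        # finite statistic, placed just beyond the finite range
        cap = np.abs(t[finite]).max() + 1.0 if finite.any() else 1.0
        t[~finite] = np.sign(delta[~finite]) * cap
    ranked = pd.Series(t, index=expr.values.index, name="moderated_t")
    order = sorted(ranked.index, key=lambda g: (-ranked[g], g))
    return ranked.loc[order]


# ---------------------------------------------------------------------------
# preranked GSEA


@dataclass
class EnrichmentResult:
    """Enrichment of one gene set in one ranked list."""

    gene_set: str
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    n_permutations: int
    leading_edge: list[str]
    p_is_upper_bound: bool = False


def _observed_es(stats: np.ndarray, hit_mask: np.ndarray, weight: float
                 ) -> tuple[float, int]:
    """ES and extremum index from the full running statistic."""
    n = stats.size
    n_hit = int(hit_mask.sum())
    absw = np.abs(stats) ** weight
    norm = absw[hit_mask].sum()
    if norm == 0:
        # degenerate: all hit statistics are zero; weight hits uniformly
        inc = np.where(hit_mask, 1.0 / n_hit, -1.0 / (n - n_hit))
    else:
        inc = np.where(hit_mask, absw / norm, -1.0 / (n - n_hit))
    running = np.cumsum(inc)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), idx


def _permutation_es(
    stats: np.ndarray, set_size: int, weight: float, n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized ES of gene-label permutations (random hit positions)."""
    n = stats.size
    k = set_size
    absw = np.abs(stats) ** weight
    pos = np.argpartition(rng.random((n_perm, n)), k - 1, axis=1)[:, :k]
    pos.sort(axis=1)
    w = absw[pos]
    cumw = np.cumsum(w, axis=1)
    norm = cumw[:, -1].copy()
    degenerate = norm == 0
    norm[degenerate] = 1.0
    cumw /= norm[:, None]
    if degenerate.any():
        cumw[degenerate] = (np.arange(1, k + 1) / k)[None, :]
    j = np.arange(k)
    drop = (pos - j) / (n - k)
    after = cumw - drop            # running value just after each hit
    before = cumw - w / norm[:, None] - drop  # value just before each hit
    if degenerate.any():
        before[degenerate] = after[degenerate] - 1.0 / k
    es_pos = after.max(axis=1)
    es_neg = before.min(axis=1)
    return np.where(es_pos >= -es_neg, es_pos, es_neg)


def gsea_preranked(
    ranked: pd.Series,
    gene_set: GeneSet,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Preranked GSEA of a single gene set (FDR q over this one set)."""
    results = gsea_batch(ranked, [gene_set], weight=weight, n_perm=n_perm, seed=seed)
    return results[0]


def gsea_batch(
    ranked: pd.Series,
    gene_sets,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Preranked GSEA of several gene sets against one ranked list.

    NES normalizes the ES by the mean magnitude of same-sign permutation
    ESs; the nominal p is the same-sign permutation tail probability
    ``(r+1)/(m+1)``; FDR q pools sign-matched permutation NES values
    across all sets.
    """
    stats = ranked.to_numpy(dtype=float)
    if not np.all(np.isfinite(stats)):
        raise ValueError("ranking statistics must be finite")
    genes = np.array(ranked.index)
    n = genes.size
    rng = np.random.default_rng(seed)

    per_set = []
    for gs in gene_sets:
        hit_mask = np.isin(genes, list(gs.genes))
        k = int(hit_mask.sum())
        if k == 0:
            raise ValueError(f"no members of set {gs.name!r} in the ranked list")
        if k >= n:
            raise ValueError(f"set {gs.name!r} covers the whole ranked list")
        es, idx = _observed_es(stats, hit_mask, weight)
        if es >= 0:
            le = [g for g, h in zip(genes[: idx + 1], hit_mask[: idx + 1]) if h]
        else:
            le = [g for g, h in zip(genes[idx:], hit_mask[idx:]) if h]
        perm = _permutation_es(stats, k, weight, n_perm, rng)
        pos = perm[perm >= 0]
        neg = perm[perm < 0]
        if es >= 0:
            same = pos
            mean_same = pos.mean() if pos.size else np.nan
        else:
            same = neg
            mean_same = -neg.mean() if neg.size else np.nan
        nes = es / mean_same if mean_same and np.isfinite(mean_same) else 0.0
        r = int(np.sum(np.abs(same) >= abs(es))) if same.size else 0
        nominal_p = (r + 1) / (same.size + 1)
        per_set.append((gs.name, es, nes, nominal_p, same.size == 0, perm, le, k))

    # FDR: normalize permutation ES per set, pool across sets by sign
    perm_nes_all = []
    for name, es, nes, p, ub, perm, le, k in per_set:
        pos = perm[perm >= 0]
        neg = perm[perm < 0]
        pn = np.empty_like(perm)
        pn[perm >= 0] = perm[perm >= 0] / pos.mean() if pos.size else 0.0
        pn[perm < 0] = perm[perm < 0] / -neg.mean() if neg.size else 0.0
        perm_nes_all.append(pn)
    pool = np.concatenate(perm_nes_all) if perm_nes_all else np.array([])
    obs_nes = np.array([r[2] for r in per_set])

    results = []
    for name, es, nes, p, ub, perm, le, k in per_set:
        if nes >= 0:
            denom_pool = pool[pool >= 0]
            tail = np.mean(denom_pool >= nes) if denom_pool.size else 0.0
            obs_tail = np.mean(obs_nes[obs_nes >= 0] >= nes)
        else:
            denom_pool = pool[pool < 0]
            tail = np.mean(denom_pool <= nes) if denom_pool.size else 0.0
            obs_tail = np.mean(obs_nes[obs_nes < 0] <= nes)
        q = min(1.0, tail / obs_tail) if obs_tail > 0 else 1.0
        results.append(
            EnrichmentResult(
                gene_set=name,
                es=es,
                nes=float(nes),
                nominal_p=float(nominal_p := p),
                fdr_q=float(q),
                n_permutations=n_perm,
                leading_edge=le,
                p_is_upper_bound=ub,
            )
        )
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_set": r.gene_set,
                "es": r.es,
                "nes": r.nes,
                "nominal_p": r.nominal_p,
                "fdr_q": r.fdr_q,
                "n_permutations": r.n_permutations,
                "leading_edge_size": len(r.leading_edge),
            }
            for r in results
        ]
    ).set_index("gene_set")


def hallmark_consistency(
    results: dict[str, dict[str, pd.DataFrame]],
    q_threshold: float = 0.05,
) -> dict[str, list[str]]:
    """Gene sets consistently positively enriched for a subtype across cohorts.

    ``results[cohort][subtype]`` is a frame indexed by gene-set name
    with ``nes`` and ``fdr_q`` columns.  A set is retained for a
    subtype iff NES > 0 and q < threshold in *every* cohort; a cohort
    missing the set counts as non-significant.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 cohorts")
    log.info("hallmark consistency at q < %g over %d cohorts", q_threshold, len(results))
    subtypes = sorted({s for per_cohort in results.values() for s in per_cohort})
    out: dict[str, list[str]] = {}
    for subtype in subtypes:
        tables = [
            per_cohort[subtype] for per_cohort in results.values() if subtype in per_cohort
        ]
        if len(tables) != len(results):
            out[subtype] = []
            continue
        names = set(tables[0].index)
        for t in tables[1:]:
            names &= set(t.index)
        kept = [
            name
            for name in sorted(names)
            if all(
                (t.loc[name, "nes"] > 0) and (t.loc[name, "fdr_q"] < q_threshold)
                for t in tables
            )
        ]
        out[subtype] = kept
    return out


def write_rnk(ranked: pd.Series, path) -> None:
    ranked.to_csv(path, sep="\t", header=False)


def read_rnk(path) -> pd.Series:
    s = pd.read_csv(path, sep="\t", header=None, index_col=0).iloc[:, 0]
    s.index.name = None
    return s.sort_values(ascending=False)
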