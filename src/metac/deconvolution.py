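"""Estimation of per-sample MetA/MetB/MetC fractions from bulk expression.

The primary solver regresses each (standardized) mixture on the
(standardized) signature columns with linear nu-support-vector
regression over a small nu grid, keeping the fit with the smallest
reconstruction RMSE; negative coefficients are clipped to zero and the
rest renormalized to sum to one.  A deterministic nonnegative
least-squares solver serves as reference.

Standardization is per gene, using the signature matrix's own row mean
and standard deviation.  Because per-gene centering makes the three
signature columns sum to zero in every row, the coefficient vector is
only identified up to an additive constant; the constant is pinned by
the biological sum-to-one constraint (coefficients are shifted by
``(1 - sum(w)) / 3`` before clipping).  Deconvolution always operates
on the linear scale; log2 inputs are unlogged first.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _nnls
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import NuSVR

from metac.core.types import (
    SUBTYPES,
    ExpressionMatrix,
    FractionEstimate,
    SampleAnnotation,
    SignatureMatrix,
)

log = logging.getLogger(__name__)

_SD_FLOOR = 1e-12


@dataclass
class DeconvolutionConfig:
    """Solver settings for fraction estimation."""

    nu_grid: tuple[float, ...] = (0.25, 0.5, 0.75)
    quantile_normalize: bool = True
    standardize: bool = True
    svr_c: float = 1.0
    svr_tol: float = 1e-6
    svr_max_iter: int = 100_000

    def __post_init__(self) -> None:
        if not all(0.0 < nu < 1.0 for nu in self.nu_grid):
            raise ValueError("nu values must lie in (0, 1)")


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Map every sample onto the mean empirical quantile distribution.

    Tied values receive the average of their tied target quantiles
    (mid-rank interpolation).  A single-sample matrix is returned
    unchanged with a warning.
    """
    mat = expr.values.to_numpy()
    n_genes, n_samples = mat.shape
    if n_samples < 2:
        log.warning("quantile_normalize: single-sample matrix returned unchanged")
        return expr
    reference = np.sort(mat, axis=0).mean(axis=1)
    positions = np.arange(1, n_genes + 1, dtype=float)
    out = np.empty_like(mat)
    for j in range(n_samples):
        ranks = rankdata(mat[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns),
        expr.scale,
    )


def _align(mixture: pd.Series, signature: SignatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    common = signature.values.index.intersection(mixture.index)
    if len(common) < 0.5 * len(signature.values.index):
        raise ValueError(
            f"mixture shares only {len(common)}/{len(signature.values.index)} "
            "signature genes (<50%)"
        )
    return mixture.loc[common].to_numpy(float), signature.values.loc[common].to_numpy(float)


def _standardize(m: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = S.mean(axis=1)
    sd = S.std(axis=1, ddof=0)
    keep = sd > _SD_FLOOR * np.maximum(np.abs(mu), 1.0)
    if keep.sum() < 3:
        raise ValueError("signature has fewer than 3 subtype-differentiating genes")
    if (~keep).any():
        log.debug("dropping %d non-differentiating signature rows", int((~keep).sum()))
    return (m[keep] - mu[keep]) / sd[keep], (S[keep] - mu[keep, None]) / sd[keep, None]


def _finalize(w: np.ndarray, m: np.ndarray, S: np.ndarray, sample_id: str,
              rmse: float | None = None) -> FractionEstimate:
    w = np.clip(w, 0.0, None)
    degenerate = w.sum() <= 0.0
    fractions = np.full(3, 1.0 / 3) if degenerate else w / w.sum()
    recon = S @ w
    if rmse is None:
        rmse = float(np.sqrt(np.mean((recon - m) ** 2)))
    if degenerate or np.std(recon) == 0 or np.std(m) == 0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(recon, m)[0, 1])
    dominant, tie_flag = call_dominant(fractions)
    return FractionEstimate(
        sample_id=sample_id,
        fractions=fractions,
        rmse=float(rmse),
        correlation=corr,
        dominant=dominant,
        tie_flag=tie_flag,
        degenerate=degenerate,
    )


def solve_fractions_svr(
    mixture: pd.Series,
    signature: SignatureMatrix,
    config: DeconvolutionConfig | None = None,
    sample_id: str = "",
) -> FractionEstimate:
    """nu-SVR deconvolution of one mixture profile against the signature.

    The nu minimizing the reconstruction RMSE wins (ties favour the
    smaller nu).  An all-nonpositive coefficient vector yields uniform
    fractions with the degenerate flag set.
    """
    config = config or DeconvolutionConfig()
    m, S = _align(mixture, signature)
    if config.standardize:
        mz, Sz = _standardize(m, S)
    else:
        mz, Sz = m, S
    best: tuple[float, np.ndarray] | None = None
    for nu in config.nu_grid:
        model = NuSVR(
            kernel="linear",
            nu=nu,
            C=config.svr_c,
            tol=config.svr_tol,
            max_iter=config.svr_max_iter,
        )
        with warnings.catch_warnings():
            # the iteration cap is a deliberate guard against libsvm
            # cycling; a capped fit loses the RMSE model selection anyway
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(Sz, mz)
        w = model.coef_.ravel().astype(float).copy()
        if config.standardize:
            # pin the additive null direction with the sum-to-one constraint
            w += (1.0 - w.sum()) / 3.0
        wc = np.clip(w, 0.0, None)
        rmse = float(np.sqrt(np.mean((Sz @ wc - mz) ** 2)))
        if best is None or rmse < best[0] - 1e-12:
            best = (rmse, w)
    rmse, w = best
    return _finalize(w, mz, Sz, sample_id, rmse=rmse)


def solve_fractions_nnls(
    mixture: pd.Series, signature: SignatureMatrix, sample_id: str = ""
) -> FractionEstimate:
    """Deterministic nonnegative least-squares reference solver."""
    m, S = _align(mixture, signature)
    w, _ = _nnls(S, m)
    return _finalize(w, m, S, sample_id)


def estimate_cohort(
    expr: ExpressionMatrix,
    signature: SignatureMatrix,
    config: DeconvolutionConfig | None = None,
    solver: str = "svr",
) -> list[FractionEstimate]:
    """Estimate fractions for every sample of a cohort.

    Both signature and mixtures are taken to the linear scale; quantile
    normalization of the mixture matrix is applied when configured (it
    should be disabled for RNA-seq-scale cohorts).
    """
    config = config or DeconvolutionConfig()
    expr = expr.to_linear()
    signature = signature.to_linear()
    if config.quantile_normalize:
        log.info("estimate_cohort: quantile normalization enabled")
        expr = quantile_normalize(expr)
    else:
        log.info("estimate_cohort: quantile normalization disabled")
    estimates = []
    for sample in expr.sample_ids:
        mixture = expr.values[sample]
        if solver == "svr":
            est = solve_fractions_svr(mixture, signature, config, sample_id=sample)
        elif solver == "nnls":
            est = solve_fractions_nnls(mixture, signature, sample_id=sample)
        else:
            raise ValueError(f"unknown solver {solver!r}")
        estimates.append(est)
    return estimates


def aggregate_replicates(
    estimates: list[FractionEstimate], annotation: SampleAnnotation
) -> list[FractionEstimate]:
    """Average replicate samples of one patient/timepoint into one entry.

    Replicate groups are defined by (patient_id, timepoint_id); distinct
    timepoints of one patient stay separate.  Fractions are arithmetic
    means, renormalized; rmse/correlation are averaged.
    """
    by_sample = {e.sample_id: e for e in estimates}
    groups: dict[tuple, list[FractionEstimate]] = {}
    for sample_id, row in annotation.table.iterrows():
        if sample_id not in by_sample:
            continue
        key = (row["patient_id"], row["timepoint_id"])
        groups.setdefault(key, []).append(by_sample[sample_id])
    out = []
    for (patient, timepoint), members in groups.items():
        sites = {
            annotation.table.loc[e.sample_id, "metastatic_site"] for e in members
        }
        if len(sites) > 1:
            log.warning(
                "replicate group (%s, %s) spans metastatic sites %s; aggregated anyway",
                patient, timepoint, sorted(sites),
            )
        if len(members) == 1:
            out.append(members[0])
            continue
        fractions = np.mean([e.fractions for e in members], axis=0)
        fractions = fractions / fractions.sum()
        dominant, tie_flag = call_dominant(fractions)
        out.append(
            FractionEstimate(
                sample_id=f"{patient}:{timepoint}",
                fractions=fractions,
                rmse=float(np.mean([e.rmse for e in members])),
                correlation=float(np.mean([e.correlation for e in members])),
                dominant=dominant,
                tie_flag=tie_flag,
                degenerate=any(e.degenerate for e in members),
            )
        )
    return out


def call_dominant(fractions: np.ndarray) -> tuple[str, bool]:
    """Dominant subtype = argmax fraction; exact ties resolve in MetA<MetB<MetC order."""
    fractions = np.asarray(fractions, dtype=float)
    top = fractions.max()
    winners = [s for s, f in zip(SUBTYPES, fractions) if f == top]
    return winners[0], len(winners) > 1
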