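"""Synthetic cohorts with the statistical structure the pipeline assumes.

A cohort is generated from three latent subtype expression profiles
(lognormal baseline; subtype markers up-shifted by a known log2 fold
change).  Each sample's bulk profile is the fraction-weighted sum of
the profiles (fractions ~ Dirichlet) under multiplicative lognormal
noise.  On top of the expression structure the generator plants the
genomic and clinical features the analysis is designed to detect: a
deleterious-SNV gene and a 21-gene deletion block whose carrier
probability is logistic in the true MetB fraction (with expression
knockdown of the block in carriers), and exponential survival whose
log-hazard is linear in the MetB fraction.  Everything is reproducible
from the config seed and the full ground truth is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from metac.core.types import (
    SUBTYPES,
    TREATMENT_STATES,
    ExpressionMatrix,
    SampleAnnotation,
    SubtypeLabeling,
)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-cohort generator.

    Defaults mirror the cohorts the analysis targets: ~2000 measured
    transcripts with 60 markers per subtype at fold change 4,
    MetA-skewed Dirichlet(2,1,1) mixing, array-like multiplicative
    noise (sigma 0.5 on log2), lesion carrier probability ~0.6 at MetB
    fraction 0.6, and a MetB log-hazard slope of ln(16) ~ 2.77 per unit
    fraction with baseline hazard 0.1 per year.
    """

    n_genes: int = 2000
    n_marker_per_subtype: int = 60
    marker_log2fc: float = 2.0
    n_samples: int = 100
    dirichlet_alpha: tuple[float, float, float] = (2.0, 1.0, 1.0)
    noise_sigma_log2: float = 0.5
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    # planted deleterious SNV (carrier probability logistic in MetB fraction)
    snv_logit_slope: float = 5.0
    snv_logit_intercept: float = -2.5
    # planted deletion block (copy number 1, expression knockdown in carriers)
    deletion_block_size: int = 21
    knockdown_log2fc: float = -1.5
    block_logit_slope: float = 5.0
    block_logit_intercept: float = -2.5
    # background passenger SNVs
    n_passenger_genes: int = 30
    passenger_snv_rate: float = 0.01
    # survival model
    baseline_hazard: float = 0.1
    log_hazard_slope: float = 2.77
    censoring_rate: float = 0.2
    n_replicate_samples: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_genes, self.n_marker_per_subtype, self.n_samples,
            self.deletion_block_size,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ValueError("dirichlet_alpha must be positive")
        for rate in (self.censoring_rate, self.passenger_snv_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        needed = (
            3 * self.n_marker_per_subtype + self.deletion_block_size
            + 1 + self.n_passenger_genes
        )
        if needed > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {needed} special genes"
            )


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    fractions: pd.DataFrame  # samples x SUBTYPES
    profiles: pd.DataFrame  # genes x SUBTYPES, linear scale
    marker_genes: dict[str, list[str]]
    snv_gene: str
    snv_carriers: list[str]
    block_genes: list[str]
    block_carriers: list[str]
    passenger_genes: list[str]
    survival_params: dict = field(default_factory=dict)

    @property
    def all_markers(self) -> list[str]:
        return [g for s in SUBTYPES for g in self.marker_genes[s]]

    def dominant(self) -> pd.Series:
        idx = self.fractions[list(SUBTYPES)].to_numpy().argmax(axis=1)
        return pd.Series([SUBTYPES[i] for i in idx], index=self.fractions.index)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def generate_profiles(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Three subtype profiles (linear scale) with planted marker genes.

    Marker, deletion-block, SNV and passenger genes are allocated to
    disjoint id ranges, so planted structures never overlap.
    """
    rng = rng or np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    baseline = 2.0 ** rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes
    )
    profiles = pd.DataFrame(
        np.tile(baseline[:, None], (1, 3)), index=genes, columns=list(SUBTYPES)
    )
    m = config.n_marker_per_subtype
    marker_genes = {}
    for k, subtype in enumerate(SUBTYPES):
        ids = genes[k * m : (k + 1) * m]
        profiles.loc[ids, subtype] *= 2.0 ** config.marker_log2fc
        marker_genes[subtype] = ids
    cursor = 3 * m
    block_genes = genes[cursor : cursor + config.deletion_block_size]
    cursor += config.deletion_block_size
    snv_gene = genes[cursor]
    cursor += 1
    passenger_genes = genes[cursor : cursor + config.n_passenger_genes]
    assert not set(block_genes) & set(g for ids in marker_genes.values() for g in ids)
    truth = SyntheticTruth(
        fractions=pd.DataFrame(columns=list(SUBTYPES)),
        profiles=profiles,
        marker_genes=marker_genes,
        snv_gene=snv_gene,
        snv_carriers=[],
        block_genes=block_genes,
        block_carriers=[],
        passenger_genes=passenger_genes,
    )
    return profiles, truth


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[ExpressionMatrix, SampleAnnotation, SyntheticTruth]:
    """Generate a mixed cohort with expression, clinical data, and truth.

    Bulk expression is the fraction-weighted sum of the subtype
    profiles with deletion-block knockdown applied to lesion carriers,
    then multiplied by lognormal noise.  Optional replicate samples
    share their patient's true fractions but receive fresh noise.
    """
    rng = np.random.default_rng(config.seed)
    profiles, truth = generate_profiles(config, rng)

    n = config.n_samples
    patient_ids = [f"P{i:03d}" for i in range(n)]
    fractions = rng.dirichlet(config.dirichlet_alpha, size=n)

    # lesion carriers, logistic in the true MetB fraction
    f_b = fractions[:, 1]
    snv_carrier = rng.random(n) < _sigmoid(
        config.snv_logit_slope * f_b + config.snv_logit_intercept
    )
    block_carrier = rng.random(n) < _sigmoid(
        config.block_logit_slope * f_b + config.block_logit_intercept
    )

    sample_ids: list[str] = []
    sample_patient: list[int] = []
    for i in range(n):
        sample_ids.append(f"S{i:03d}")
        sample_patient.append(i)
    for j in range(min(config.n_replicate_samples, n)):
        sample_ids.append(f"S{j:03d}R")
        sample_patient.append(j)

    P = profiles.to_numpy()
    cols = []
    for sample_idx in sample_patient:
        bulk = P @ fractions[sample_idx]
        cols.append(bulk)
    mat = np.column_stack(cols)
    block_rows = profiles.index.get_indexer(truth.block_genes)
    for col, sample_idx in enumerate(sample_patient):
        if block_carrier[sample_idx]:
            mat[block_rows, col] *= 2.0 ** config.knockdown_log2fc
    noise = 2.0 ** rng.normal(0.0, config.noise_sigma_log2, mat.shape)
    expr = ExpressionMatrix(
        pd.DataFrame(mat * noise, index=profiles.index, columns=sample_ids), "linear"
    )

    truth.fractions = pd.DataFrame(
        fractions[sample_patient], index=sample_ids, columns=list(SUBTYPES)
    )
    truth.snv_carriers = [
        s for s, i in zip(sample_ids, sample_patient) if snv_carrier[i]
    ]
    truth.block_carriers = [
        s for s, i in zip(sample_ids, sample_patient) if block_carrier[i]
    ]

    times, events = generate_survival(config, truth, rng)
    state = rng.choice(list(TREATMENT_STATES), size=len(sample_ids), p=(0.2, 0.15, 0.65))
    site = rng.choice(["bone", "lymph_node", "liver"], size=len(sample_ids), p=(0.7, 0.2, 0.1))
    annotation = SampleAnnotation(
        pd.DataFrame(
            {
                "patient_id": [patient_ids[i] for i in sample_patient],
                "timepoint_id": "T0",
                "treatment_state": state,
                "metastatic_site": site,
                "survival_time": times,
                "event": events,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth.survival_params = {
        "baseline_hazard": config.baseline_hazard,
        "log_hazard_slope": config.log_hazard_slope,
        "censoring_rate": config.censoring_rate,
    }
    return expr, annotation, truth


def generate_survival(
    config: GeneratorConfig, truth: SyntheticTruth, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with log-hazard linear in the MetB fraction.

    Censoring is independent uniform on (0, tau) with tau calibrated by
    bisection so the expected censored proportion matches the
    configured rate; rate 0 disables censoring.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    f_b = truth.fractions["MetB"].to_numpy(float)
    hazard = config.baseline_hazard * np.exp(config.log_hazard_slope * f_b)
    t_event = rng.exponential(1.0 / hazard)
    if config.censoring_rate <= 0:
        return t_event, np.ones(t_event.size, dtype=bool)

    def censored_fraction(tau: float) -> float:
        # P(C < T) for C ~ U(0, tau): E[min(T, tau)] / tau
        return float(np.mean(np.minimum(t_event, tau) / tau))

    lo, hi = 1e-6, 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if censored_fraction(mid) > config.censoring_rate:
            lo = mid
        else:
            hi = mid
    tau = np.sqrt(lo * hi)
    c = rng.uniform(0.0, tau, size=t_event.size)
    events = t_event <= c
    times = np.minimum(t_event, c)
    return times, events


def generate_genomics(
    config: GeneratorConfig, truth: SyntheticTruth, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Materialize variant and copy-number tables from the planted truth.

    The planted SNV gene carries a deleterious nonsynonymous variant in
    its carrier samples; passenger genes mutate independently of the
    fractions at a fixed low rate; the deletion block has copy number 1
    in block carriers and 2 otherwise.
    """
    if set(truth.block_genes) & set(truth.all_markers):
        raise ValueError("deletion block overlaps marker genes")
    rng = rng or np.random.default_rng(config.seed + 2)
    samples = list(truth.fractions.index)
    variant_rows = []
    for s in truth.snv_carriers:
        variant_rows.append(
            {
                "sample_id": s,
                "gene": truth.snv_gene,
                "effect_class": "nonsynonymous_snv",
                "sift_deleterious": True,
                "polyphen_damaging": True,
            }
        )
    classes = ["stopgain", "nonsynonymous_snv", "other"]
    for gene in truth.passenger_genes:
        hit = rng.random(len(samples)) < config.passenger_snv_rate
        for s, h in zip(samples, hit):
            if not h:
                continue
            cls = classes[rng.integers(len(classes))]
            variant_rows.append(
                {
                    "sample_id": s,
                    "gene": gene,
                    "effect_class": cls,
                    "sift_deleterious": True if cls == "nonsynonymous_snv" else None,
                    "polyphen_damaging": True if cls == "nonsynonymous_snv" else None,
                }
            )
    variants = pd.DataFrame(
        variant_rows,
        columns=["sample_id", "gene", "effect_class", "sift_deleterious", "polyphen_damaging"],
    )
    carriers = set(truth.block_carriers)
    cnv_rows = [
        {"sample_id": s, "gene": g, "copy_number": 1 if s in carriers else 2}
        for g in truth.block_genes
        for s in samples
    ]
    cnv = pd.DataFrame(cnv_rows, columns=["sample_id", "gene", "copy_number"])
    return variants, cnv


def generate_reference_cohort(
    config: GeneratorConfig,
    truth: SyntheticTruth,
    n_per_subtype: int = 10,
    seed_offset: int = 10_000,
) -> tuple[ExpressionMatrix, SubtypeLabeling]:
    """Labeled pure-subtype samples for signature construction.

    Emulates the labeled discovery samples from which markers and the
    reference profiles are derived: each sample is one subtype's pure
    profile under the generator's multiplicative noise.
    """
    rng = np.random.default_rng(config.seed + seed_offset)
    P = truth.profiles.to_numpy()
    cols, ids, labels = [], [], {}
    for k, subtype in enumerate(SUBTYPES):
        for r in range(n_per_subtype):
            noise = 2.0 ** rng.normal(0.0, config.noise_sigma_log2, P.shape[0])
            sid = f"REF_{subtype}_{r:02d}"
            cols.append(P[:, k] * noise)
            ids.append(sid)
            labels[sid] = subtype
    expr = ExpressionMatrix(
        pd.DataFrame(np.column_stack(cols), index=truth.profiles.index, columns=ids),
        "linear",
    )
    return expr, SubtypeLabeling(labels)
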