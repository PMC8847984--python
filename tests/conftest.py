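"""Shared fixtures: small synthetic cohorts and reusable oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from metac.core.types import ExpressionMatrix, SignatureMatrix
from metac.synthetic_data import (
    GeneratorConfig,
    generate_cohort,
    generate_genomics,
    generate_reference_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-parameter cohort with genomics and labeled reference samples."""
    cfg = GeneratorConfig(seed=1)
    expr, annotation, truth = generate_cohort(cfg)
    variants, cnv = generate_genomics(cfg, truth)
    reference, labels = generate_reference_cohort(cfg, truth)
    return {
        "config": cfg,
        "expr": expr,
        "annotation": annotation,
        "truth": truth,
        "variants": variants,
        "cnv": cnv,
        "reference": reference,
        "labels": labels,
    }


@pytest.fixture()
def tiny_expr():
    """3 genes x 4 samples log2 matrix with visible structure."""
    df = pd.DataFrame(
        [[5.0, 5.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0], [7.0, 7.0, 7.0, 7.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(df, "log2")


def make_signature(n_per_subtype: int = 5, seed: int = 0, fc: float = 4.0) -> SignatureMatrix:
    """Small linear-scale signature with n_per_subtype markers per subtype."""
    rng = np.random.default_rng(seed)
    g = 3 * n_per_subtype
    base = 2.0 ** rng.normal(7, 1.5, g)
    vals = np.tile(base[:, None], (1, 3))
    for k in range(3):
        vals[k * n_per_subtype : (k + 1) * n_per_subtype, k] *= fc
    df = pd.DataFrame(
        vals, index=[f"g{i}" for i in range(g)], columns=["MetA", "MetB", "MetC"]
    )
    return SignatureMatrix(df, "linear")
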