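"""Domain types shared across the pipeline.

Expression data are held as a genes x samples :class:`pandas.DataFrame`
with an explicit scale declaration (``log2`` for RMA-style array values,
``linear`` for normalized counts / FPKM), because the two scales must
never be mixed silently: marker selection operates on log2 values while
deconvolution operates on linear values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The three metastasis subtypes, in canonical (tie-break) order.
SUBTYPES: tuple[str, str, str] = ("MetA", "MetB", "MetC")

#: Treatment states recognised in sample annotations.
TREATMENT_STATES = ("hormone_naive", "short_term_castrated", "castration_resistant")

_SCALES = ("log2", "linear")


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise ValueError(f"duplicated {what} identifiers: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with a declared scale."""

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "sample")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if self.scale == "linear" and (arr < 0).any():
            raise ValueError("linear-scale expression values must be >= 0")
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == "linear":
            return self
        return ExpressionMatrix(2.0 ** self.values, "linear")

    def to_log2(self, pseudocount: float = 0.0) -> "ExpressionMatrix":
        if self.scale == "log2":
            return self
        shifted = self.values + pseudocount
        if (shifted.to_numpy() <= 0).any():
            raise ValueError(
                "cannot log2-transform non-positive values; supply a pseudocount"
            )
        return ExpressionMatrix(np.log2(shifted), "log2")

    def subset(
        self,
        genes: Iterable[str] | None = None,
        samples: Iterable[str] | None = None,
    ) -> "ExpressionMatrix":
        df = self.values
        if genes is not None:
            df = df.loc[[g for g in genes if g in df.index]]
        if samples is not None:
            df = df[[s for s in samples if s in df.columns]]
        return ExpressionMatrix(df, self.scale)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (one GMT line)."""

    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class SampleAnnotation:
    """Per-sample clinical annotation table.

    Wraps a DataFrame indexed by ``sample_id`` with at least the columns
    ``patient_id``, ``timepoint_id``, ``treatment_state``,
    ``metastatic_site``, ``survival_time`` (years) and ``event``
    (boolean).  Extra covariate columns pass through untouched.
    """

    table: pd.DataFrame

    REQUIRED = (
        "patient_id",
        "timepoint_id",
        "treatment_state",
        "metastatic_site",
        "survival_time",
        "event",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation table missing columns: {missing}")
        _check_unique(list(self.table.index), "sample")
        t = pd.to_numeric(self.table["survival_time"], errors="coerce")
        if (t.dropna() <= 0).any():
            raise ValueError("survival_time must be > 0 when present")
        states = self.table["treatment_state"].dropna()
        bad = set(states) - set(TREATMENT_STATES)
        if bad:
            raise ValueError(f"unknown treatment states: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def check_matches(self, expr: ExpressionMatrix) -> None:
        missing = set(self.sample_ids) - set(expr.sample_ids)
        if missing:
            raise ValueError(
                f"annotation samples absent from expression matrix: {sorted(missing)[:5]}"
            )


@dataclass
class TestResult:
    """Outcome of a two-sample or correlation test."""

    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]
    undefined: bool = False

    def __post_init__(self) -> None:
        if not self.undefined and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass
class SignatureMatrix:
    """Signature-gene x subtype reference-profile matrix (deconvolution basis)."""

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        if list(self.values.columns) != list(SUBTYPES):
            raise ValueError(f"signature columns must be exactly {SUBTYPES}")
        _check_unique(list(self.values.index), "gene")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("signature values must be finite")
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def to_linear(self) -> "SignatureMatrix":
        if self.scale == "linear":
            return self
        return SignatureMatrix(2.0 ** self.values, "linear")


@dataclass
class FractionEstimate:
    """Per-sample MetA/MetB/MetC fraction estimate."""

    sample_id: str
    fractions: np.ndarray  # length 3, order SUBTYPES
    rmse: float
    correlation: float
    dominant: str
    tie_flag: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (3,):
            raise ValueError("fractions must have length 3")
        if (self.fractions < -1e-12).any():
            raise ValueError("fractions must be nonnegative")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def fractions_frame(estimates: Sequence[FractionEstimate]) -> pd.DataFrame:
    """Assemble fraction estimates into a tidy DataFrame (samples x columns)."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "sample_id": e.sample_id,
                **dict(zip(SUBTYPES, e.fractions)),
                "rmse": e.rmse,
                "correlation": e.correlation,
                "dominant": e.dominant,
                "tie_flag": e.tie_flag,
                "degenerate": e.degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class ScoreVector:
    """Per-sample scalar phenotype score (PC1 of a gene-set submatrix)."""

    score_name: str
    scores: pd.Series
    orientation_anchor: str
    explained_variance_fraction: float
    zero_variance: bool = False


@dataclass
class SubtypeLabeling:
    """sample_id -> subtype label mapping used for signature building."""

    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - set(SUBTYPES)
        if bad:
            raise ValueError(f"unknown subtype labels: {sorted(bad)}")

    def samples_of(self, subtype: str) -> list[str]:
        return [s for s, l in self.labels.items() if l == subtype]

    def check_for_signature(self, expr: ExpressionMatrix) -> None:
        missing = set(self.labels) - set(expr.sample_ids)
        if missing:
            raise ValueError(
                f"labeled samples absent from expression matrix: {sorted(missing)[:5]}"
            )
        absent = [s for s in SUBTYPES if not self.samples_of(s)]
        if absent:
            raise ValueError(f"subtypes without labeled samples: {absent}")
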