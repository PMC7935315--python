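"""Domain containers for the multi-omic screen.

Three matrix kinds circulate through the pipeline: gene expression
(non-negative normalized units such as RSEM or cRPKM), promoter methylation
(beta values in [0, 1]) and exon inclusion (PSI on the 0-100 scale, the only
kind where missing cells are legal).  Everything is features x samples.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MatrixKind",
    "OmicsMatrix",
    "SampleTable",
    "ExonAnnotation",
    "TargetMap",
    "FoldChange",
    "RandomizationResult",
    "AgreementResult",
    "TUMOR",
    "NORMAL",
]

TUMOR = "tumor"
NORMAL = "normal"


class MatrixKind(str, enum.Enum):
    expression = "expression"
    methylation = "methylation"
    psi = "psi"


@dataclass
class OmicsMatrix:
    """A validated features x samples matrix of one omics kind.

    ``values`` is a float DataFrame indexed by feature id with sample ids as
    columns.  NaN encodes a missing measurement and is allowed only for
    ``kind=psi``.  Range violations raise at construction: values are never
    silently clamped.
    """

    kind: MatrixKind
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.kind = MatrixKind(self.kind)
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = self.values.to_numpy()
        if np.isinf(arr).any():
            raise ValueError("non-finite value in matrix")
        nan = np.isnan(arr)
        if self.kind is MatrixKind.psi:
            ok = nan | ((arr >= 0.0) & (arr <= 100.0))
            if not ok.all():
                raise ValueError("PSI out of range [0, 100]")
        elif self.kind is MatrixKind.methylation:
            if nan.any():
                raise ValueError("missing value not allowed for methylation")
            if ((arr < 0.0) | (arr > 1.0)).any():
                raise ValueError("beta out of range [0, 1]")
        else:
            if nan.any():
                raise ValueError("missing value not allowed for expression")
            if (arr < 0.0).any():
                raise ValueError("negative expression value")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.kind, self.values.loc[:, list(sample_ids)])


@dataclass
class SampleTable:
    """Per-sample tissue and tumor/normal condition labels.

    ``frame`` has columns ``tissue`` and ``condition`` (plus optional
    covariates such as purity) indexed by unique sample id.  Condition is
    exactly ``tumor`` or ``normal``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        for col in ("tissue", "condition"):
            if col not in self.frame.columns:
                raise ValueError(f"sample table missing column {col!r}")
        cond = self.frame["condition"].astype(str).str.strip().str.lower()
        bad = sorted(set(cond) - {TUMOR, NORMAL})
        if bad:
            raise ValueError(
                f"unknown condition label(s) {bad}; allowed: ['normal', 'tumor']"
            )
        self.frame = self.frame.assign(condition=cond)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def tissues(self) -> list[str]:
        return sorted(self.frame["tissue"].unique())

    def group(self, tissue: str, condition: str) -> list[str]:
        f = self.frame
        m = (f["tissue"] == tissue) & (f["condition"] == condition)
        return list(f.index[m])

    def group_sizes(self, tissue: str) -> tuple[int, int]:
        return len(self.group(tissue, TUMOR)), len(self.group(tissue, NORMAL))


@dataclass
class ExonAnnotation:
    """Exon id -> host gene and length (nt).  Coordinates are opaque text."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise ValueError("duplicate exon ids")
        for col in ("gene_id", "length_nt"):
            if col not in self.frame.columns:
                raise ValueError(f"exon annotation missing column {col!r}")
        lengths = self.frame["length_nt"]
        if (lengths < 1).any() or not np.equal(lengths, lengths.astype(int)).all():
            raise ValueError("length_nt must be a positive integer")
        self.frame = self.frame.assign(length_nt=lengths.astype(int))

    @property
    def exon_ids(self) -> list[str]:
        return list(self.frame.index)

    def length(self, exon_id: str) -> int:
        return int(self.frame.at[exon_id, "length_nt"])


@dataclass
class TargetMap:
    """Map from splicing-factor gene id to its set of regulated exon ids."""

    mapping: dict[str, set[str]] = field(default_factory=dict)

    def validate_against(self, annotation: ExonAnnotation) -> None:
        known = set(annotation.exon_ids)
        for sf, exons in self.mapping.items():
            missing = exons - known
            if missing:
                raise ValueError(
                    f"targets of {sf} absent from annotation: {sorted(missing)[:5]}"
                )

    def targets(self, sf_id: str) -> set[str]:
        return set(self.mapping.get(sf_id, set()))


@dataclass(frozen=True)
class FoldChange:
    """Tumor/normal ratio of group medians with zero-handling sentinels."""

    ratio: float | None
    status: str  # "ok" | "undefined-both-zero" | "undefined-zero-denominator"

    @property
    def defined(self) -> bool:
        return self.status == "ok" and self.ratio is not None and self.ratio > 0

    @property
    def magnitude(self) -> float | None:
        """max(r, 1/r); None for sentinels and non-positive ratios."""
        if not self.defined:
            return None
        return max(self.ratio, 1.0 / self.ratio)


@dataclass
class RandomizationResult:
    """Outcome of the median-coupling randomization test."""

    observed_median_rho: float
    background_medians: list[float]
    p_one_tailed: float
    tail: str  # "greater" | "less"
    background_kind: str = "random"

    @property
    def n_background(self) -> int:
        return len(self.background_medians)


@dataclass
class AgreementResult:
    """Sign-agreement count between two datasets with a binomial p-value."""

    n: int
    k: int
    p_two_sided: float

    @property
    def fraction(self) -> float:
        return self.k / self.n if self.n else float("nan")
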