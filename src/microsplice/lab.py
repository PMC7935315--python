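"""Closed-form wet-lab calculations.

Relative qPCR quantification by the ddCt rule (fold change = 2^-ddCt with a
reference gene per sample), the caliper xenograft tumor-volume formula
(length x width^2 / 2), and reference-point normalization used in growth
and competition assays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["CtRecord", "ddct_fold_change", "tumor_volume", "normalize_to_reference"]


@dataclass(frozen=True)
class CtRecord:
    """Mean technical-replicate Ct values for one sample.

    Averaging of in-plate technical replicates happens before construction;
    the record stores the means.
    """

    sample_id: str
    target_ct: float
    reference_ct: float
    condition: str = "treated"

    def __post_init__(self) -> None:
        for name in ("target_ct", "reference_ct"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0")

    @property
    def dct(self) -> float:
        return self.target_ct - self.reference_ct


def ddct_fold_change(treated: CtRecord, control: CtRecord) -> float:
    """Fold change 2^-ddCt, where ddCt = dCt(treated) - dCt(control)."""
    ddct = treated.dct - control.dct
    return float(2.0 ** (-ddct))


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumor volume in mm^3: (length x width^2) / 2."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("tumor dimensions must be positive")
    if width_mm > length_mm:
        warnings.warn(
            "width exceeds length; by convention length is the longer axis",
            stacklevel=2,
        )
    return float(length_mm * width_mm**2 / 2.0)


def normalize_to_reference(series, reference_value: float) -> list[float]:
    """Element-wise division by a positive reference value."""
    if reference_value <= 0:
        raise ValueError("reference value must be positive")
    return [float(v) / reference_value for v in series]
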