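"""Differential exon inclusion between tumor and normal samples.

PSI (percent spliced in, 0-100) is compared per exon and tissue by a
two-tailed Mann-Whitney test after a coverage filter requiring the exon to
be quantified in at least ``min_n`` tumor AND ``min_n`` normal samples.
BH correction is applied within each tissue across the exons surviving the
filter.  An exon is called significant when q < 0.01 and |dPSI| >= 5
(defaults; both thresholds and the inclusive boundary are configurable).

Microexons are cassette exons of 3-27 nt; their inclusion depends on a
dedicated splicing machinery, which is why direction summaries are split by
the microexon flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    NORMAL,
    TUMOR,
    ExonAnnotation,
    MatrixKind,
    OmicsMatrix,
    SampleTable,
)
from .stats import TWO, bh_adjust, fisher_exact, mann_whitney

__all__ = [
    "coverage_filter",
    "differential_psi",
    "classify_microexon",
    "direction_summary",
    "target_enrichment",
    "direction_bias_test",
]

MICROEXON_MIN_NT = 3
MICROEXON_MAX_NT = 27

DEFAULT_MIN_N = 20
DEFAULT_DPSI = 5.0
DEFAULT_Q = 0.01


def classify_microexon(length_nt: int) -> bool:
    """True iff the exon length falls in the 3-27 nt microexon band."""
    if length_nt < 1:
        raise ValueError("exon length must be a positive integer")
    return MICROEXON_MIN_NT <= length_nt <= MICROEXON_MAX_NT


def coverage_filter(
    psi: OmicsMatrix, samples: SampleTable, tissue: str, min_n: int = DEFAULT_MIN_N
) -> list[str]:
    """Exons with >= min_n non-missing PSI values in both groups of a tissue."""
    if psi.kind is not MatrixKind.psi:
        raise ValueError("coverage filter expects a PSI matrix")
    tumor_ids = samples.group(tissue, TUMOR)
    normal_ids = samples.group(tissue, NORMAL)
    n_t = psi.values[tumor_ids].notna().sum(axis=1)
    n_n = psi.values[normal_ids].notna().sum(axis=1)
    keep = (n_t >= min_n) & (n_n >= min_n)
    return list(psi.values.index[keep])


def differential_psi(
    psi: OmicsMatrix,
    samples: SampleTable,
    tissue: str,
    min_n: int = DEFAULT_MIN_N,
    dpsi_threshold: float = DEFAULT_DPSI,
    q_threshold: float = DEFAULT_Q,
    annotation: ExonAnnotation | None = None,
    targets=None,
    center: str = "median",
    strict_dpsi: bool = False,
) -> pd.DataFrame:
    """Exon-level tumor-vs-normal differential inclusion calls for a tissue.

    The coverage filter is applied internally; the BH family is the set of
    exons that survive it.  dPSI is the difference of group centers
    (medians by default) of the non-missing values.  ``strict_dpsi`` switches
    the |dPSI| boundary from >= to > .
    """
    if tissue not in set(samples.frame["tissue"]):
        raise KeyError(f"tissue {tissue!r} absent from sample table")
    exon_ids = coverage_filter(psi, samples, tissue, min_n)
    tumor_ids = samples.group(tissue, TUMOR)
    normal_ids = samples.group(tissue, NORMAL)
    centerf = np.median if center == "median" else np.mean

    rows = []
    pvals = []
    tmat = psi.values.loc[exon_ids, tumor_ids].to_numpy()
    nmat = psi.values.loc[exon_ids, normal_ids].to_numpy()
    for i, exon_id in enumerate(exon_ids):
        t = tmat[i][~np.isnan(tmat[i])]
        n = nmat[i][~np.isnan(nmat[i])]
        dpsi = float(centerf(t) - centerf(n))
        if np.ptp(t) == 0 and np.ptp(n) == 0 and t[0] == n[0]:
            p = 1.0
        else:
            p = mann_whitney(t, n, sided=TWO).p
        pvals.append(p)
        rows.append({"exon_id": exon_id, "tissue": tissue, "dpsi": dpsi, "p": p})
    calls = pd.DataFrame(rows, columns=["exon_id", "tissue", "dpsi", "p"])
    if calls.empty:
        calls["q"] = calls["significant"] = calls["direction"] = None
        return calls
    calls["q"] = bh_adjust(pvals)
    passes_dpsi = (
        calls["dpsi"].abs() > dpsi_threshold
        if strict_dpsi
        else calls["dpsi"].abs() >= dpsi_threshold
    )
    calls["significant"] = (calls["q"] < q_threshold) & passes_dpsi
    calls["direction"] = np.where(
        calls["significant"] & (calls["dpsi"] > 0),
        "up",
        np.where(calls["significant"] & (calls["dpsi"] < 0), "down", "none"),
    )
    if annotation is not None:
        calls["is_microexon"] = [
            classify_microexon(annotation.length(e)) for e in calls["exon_id"]
        ]
    if targets is not None:
        targets = set(targets)
        calls["is_target"] = calls["exon_id"].isin(targets)
    return calls


def direction_summary(calls: pd.DataFrame, targets) -> pd.DataFrame:
    """Per-tissue and pooled fractions of significant calls decreasing.

    Reports, among significant calls: the fraction of target exons with
    direction "down", the same split for microexons (when the calls carry an
    ``is_microexon`` column), and the microexon share among decreasing vs
    increasing targets.  Empty denominators yield NaN, never 0.
    """
    targets = set(targets)
    sig = calls[calls["significant"]].copy()
    sig["is_target"] = sig["exon_id"].isin(targets)

    def _frac(mask_down, mask_all) -> float:
        denom = int(mask_all.sum())
        return float(mask_down.sum() / denom) if denom else float("nan")

    def _summarize(group: pd.DataFrame, label: str) -> dict:
        tgt = group[group["is_target"]]
        down_t = tgt["direction"] == "down"
        row = {
            "tissue": label,
            "n_significant": len(group),
            "n_significant_targets": len(tgt),
            "frac_targets_down": _frac(down_t, tgt["direction"].notna()),
        }
        if "is_microexon" in group.columns:
            micro = group[group["is_microexon"]]
            row["frac_microexons_down"] = _frac(
                micro["direction"] == "down", micro["direction"].notna()
            )
            down_targets = tgt[tgt["direction"] == "down"]
            up_targets = tgt[tgt["direction"] == "up"]
            row["frac_down_targets_micro"] = _frac(
                down_targets.get("is_microexon", pd.Series(dtype=bool)),
                down_targets["direction"].notna(),
            )
            row["frac_up_targets_micro"] = _frac(
                up_targets.get("is_microexon", pd.Series(dtype=bool)),
                up_targets["direction"].notna(),
            )
        return row

    rows = [
        _summarize(group, tissue) for tissue, group in sig.groupby("tissue", sort=True)
    ]
    rows.append(_summarize(sig, "pooled"))
    return pd.DataFrame(rows)


def target_enrichment(calls: pd.DataFrame, targets, universe=None) -> pd.DataFrame:
    """One-sided Fisher p per tissue for targets among significant exons.

    The 2x2 table crosses (significant vs not) with (target vs not) over the
    coverage-filtered universe of that tissue.
    """
    targets = set(targets)
    rows = []
    for tissue, group in calls.groupby("tissue", sort=True):
        ids = set(group["exon_id"]) if universe is None else set(universe) & set(group["exon_id"])
        sub = group[group["exon_id"].isin(ids)]
        if sub.empty:
            raise ValueError(f"empty exon universe for tissue {tissue!r}")
        is_sig = sub["significant"].to_numpy()
        is_tgt = sub["exon_id"].isin(targets).to_numpy()
        a = int((is_sig & is_tgt).sum())
        b = int((is_sig & ~is_tgt).sum())
        c = int((~is_sig & is_tgt).sum())
        d = int((~is_sig & ~is_tgt).sum())
        rows.append(
            {
                "tissue": tissue,
                "n_sig_targets": a,
                "n_sig_other": b,
                "p": fisher_exact([[a, b], [c, d]], sided="greater"),
            }
        )
    return pd.DataFrame(rows)


def direction_bias_test(calls: pd.DataFrame, targets) -> pd.DataFrame:
    """Per-tissue one-sided Fisher test for excess "down" among targets.

    Restricted to significant calls; the reference background is all
    significantly changing exons of the tissue.  Tissues with an empty
    margin report NaN.
    """
    targets = set(targets)
    sig = calls[calls["significant"]]
    rows = []
    for tissue, group in sig.groupby("tissue", sort=True):
        is_tgt = group["exon_id"].isin(targets).to_numpy()
        is_down = (group["direction"] == "down").to_numpy()
        a = int((is_tgt & is_down).sum())
        b = int((is_tgt & ~is_down).sum())
        c = int((~is_tgt & is_down).sum())
        d = int((~is_tgt & ~is_down).sum())
        if (a + b) == 0 or (c + d) == 0:
            p = float("nan")
        else:
            p = fisher_exact([[a, b], [c, d]], sided="greater")
        rows.append(
            {"tissue": tissue, "n_targets_down": a, "n_targets_up": b, "p": p}
        )
    return pd.DataFrame(rows)
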