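"""Pan-cancer splicing-factor screen.

For each splicing factor and tissue, tumor and normal samples are compared
by a two-tailed Mann-Whitney test on expression (or promoter methylation),
with Benjamini-Hochberg correction within each (tissue, assay) family.
Cross-tissue consistency is then summarized per factor as the number of
tissues significantly up minus the number significantly down: a factor
silenced everywhere scores -n_tissues, one activated everywhere +n_tissues.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import NORMAL, TUMOR, FoldChange, OmicsMatrix, SampleTable
from .stats import TWO, bh_adjust, mann_whitney

__all__ = ["run_screen", "consistency_scores", "median_fold_change"]

log = logging.getLogger(__name__)

DEFAULT_MIN_GROUP_SIZE = 20
DEFAULT_Q_DIRECTION = 0.05


def median_fold_change(
    matrix: OmicsMatrix, samples: SampleTable, feature: str, tissue: str
) -> FoldChange:
    """Tumor/normal ratio of group medians for one feature in one tissue.

    Zero medians cannot form a ratio: both zero yields the
    ``undefined-both-zero`` sentinel, a zero normal (denominator) median with
    a positive tumor median yields ``undefined-zero-denominator``, and a zero
    tumor median over a positive normal one is reported as ratio 0.  Only
    strictly positive ratios contribute to fold magnitudes downstream.
    """
    row = matrix.values.loc[feature]
    med_t = float(row[samples.group(tissue, TUMOR)].median())
    med_n = float(row[samples.group(tissue, NORMAL)].median())
    if med_t == 0.0 and med_n == 0.0:
        return FoldChange(None, "undefined-both-zero")
    if med_n == 0.0:
        return FoldChange(None, "undefined-zero-denominator")
    return FoldChange(med_t / med_n, "ok")


def _direction(delta: float, q: float, q_threshold: float) -> str:
    if q < q_threshold and delta > 0:
        return "up"
    if q < q_threshold and delta < 0:
        return "down"
    return "none"


def run_screen(
    matrix: OmicsMatrix,
    samples: SampleTable,
    features=None,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
    q_threshold: float = DEFAULT_Q_DIRECTION,
) -> pd.DataFrame:
    """Per-feature, per-tissue tumor-vs-normal differential test.

    Returns one row per feature x tissue with group sizes, group medians,
    delta (tumor - normal median), Mann-Whitney p, BH q (adjusted across
    features within the tissue) and a direction call at ``q_threshold``.
    Tissues with fewer than ``min_group_size`` samples in either group are
    skipped with a warning.
    """
    if features is None:
        features = matrix.feature_ids
    features = list(features)
    missing = sorted(set(features) - set(matrix.feature_ids))
    if missing:
        raise KeyError(f"feature(s) absent from matrix: {missing[:5]}")

    values = matrix.values
    rows = []
    for tissue in samples.tissues:
        tumor_ids = samples.group(tissue, TUMOR)
        normal_ids = samples.group(tissue, NORMAL)
        if len(tumor_ids) < min_group_size or len(normal_ids) < min_group_size:
            log.warning(
                "skipping tissue %s: %d tumor / %d normal below min group size %d",
                tissue, len(tumor_ids), len(normal_ids), min_group_size,
            )
            continue
        tmat = values.loc[features, tumor_ids].to_numpy()
        nmat = values.loc[features, normal_ids].to_numpy()
        pvals = np.empty(len(features))
        for i in range(len(features)):
            t, n = tmat[i], nmat[i]
            if np.ptp(t) == 0 and np.ptp(n) == 0 and t[0] == n[0]:
                # constant and identical in both groups (e.g. all-zero):
                # keep the record with p = 1 so score denominators match
                pvals[i] = 1.0
                method = "exact"
            else:
                res = mann_whitney(t, n, sided=TWO)
                pvals[i] = res.p
                method = res.method
            rows.append(
                {
                    "feature_id": features[i],
                    "tissue": tissue,
                    "n_tumor": len(tumor_ids),
                    "n_normal": len(normal_ids),
                    "median_tumor": float(np.median(t)),
                    "median_normal": float(np.median(n)),
                    "p": pvals[i],
                    "method": method,
                }
            )
        qvals = bh_adjust(pvals)
        for i, q in enumerate(qvals):
            rows[-len(features) + i]["q"] = float(q)

    records = pd.DataFrame(rows)
    if records.empty:
        return pd.DataFrame(
            columns=[
                "feature_id", "tissue", "n_tumor", "n_normal", "median_tumor",
                "median_normal", "delta", "p", "q", "direction", "method",
            ]
        )
    records["delta"] = records["median_tumor"] - records["median_normal"]
    records["direction"] = [
        _direction(d, q, q_threshold) for d, q in zip(records["delta"], records["q"])
    ]
    return records[
        [
            "feature_id", "tissue", "n_tumor", "n_normal", "median_tumor",
            "median_normal", "delta", "p", "q", "direction", "method",
        ]
    ]


def consistency_scores(records: pd.DataFrame, q_threshold: float = DEFAULT_Q_DIRECTION) -> pd.DataFrame:
    """Cross-tissue consistency summary per feature.

    ``score = n_up - n_down`` where a tissue counts as up/down when its BH q
    is below ``q_threshold`` and the median delta has the matching sign.
    ``mean_fold_magnitude`` averages ``max(r, 1/r)`` of the tumor/normal
    median ratio over tissues where that ratio is defined and positive.
    Rows are ranked ascending by score (most consistently silenced first),
    ties broken by larger fold magnitude, then feature id.
    """
    out = []
    for sf_id, group in records.groupby("feature_id", sort=True):
        sig = group["q"] < q_threshold
        n_up = int((sig & (group["delta"] > 0)).sum())
        n_down = int((sig & (group["delta"] < 0)).sum())
        n_tested = len(group)
        mags = []
        for med_t, med_n in zip(group["median_tumor"], group["median_normal"]):
            if med_n > 0 and med_t > 0:
                r = med_t / med_n
                mags.append(max(r, 1.0 / r))
        out.append(
            {
                "sf_id": sf_id,
                "n_up": n_up,
                "n_down": n_down,
                "score": n_up - n_down,
                "n_tissues_tested": n_tested,
                "consistent_all_down": n_down == n_tested and n_tested > 0,
                "consistent_all_up": n_up == n_tested and n_tested > 0,
                "mean_fold_magnitude": float(np.mean(mags)) if mags else float("nan"),
            }
        )
    table = pd.DataFrame(out)
    table = table.sort_values(
        by=["score", "mean_fold_magnitude", "sf_id"],
        ascending=[True, False, True],
        na_position="last",
        kind="stable",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
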