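"""Overexpression-response analysis.

After inducing a splicing factor in cell lines, exons responding with
dPSI >= 25 in both biological replicates define the factor's target set;
exons passing the threshold in every line form the shared inclusion
program; genes changing >= 2-fold define the expression response.  The
cross-dataset agreement test asks whether changes in two independent
datasets share their sign more often than chance (two-sided binomial at
p0 = 0.5), restricted to features passing both datasets' cutoffs.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import AgreementResult
from .stats import binomial_test

__all__ = [
    "define_targets",
    "shared_inclusion_sets",
    "fold_change_calls",
    "cross_dataset_agreement",
]


def _as_series(changes) -> pd.Series:
    if isinstance(changes, pd.Series):
        return changes.astype(float)
    return pd.Series(changes, dtype=float)


def define_targets(dpsi_rep1, dpsi_rep2, threshold: float = 25.0) -> set[str]:
    """Exons with change >= threshold in BOTH replicates (inclusive bound)."""
    a, b = _as_series(dpsi_rep1), _as_series(dpsi_rep2)
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("replicates share no exons")
    passing = (a.loc[shared] >= threshold) & (b.loc[shared] >= threshold)
    return set(shared[passing])


def shared_inclusion_sets(per_line: dict, threshold: float = 25.0) -> dict:
    """Per-line passing sets and UpSet-style exclusive intersection counts.

    Returns per-line sets, the all-lines intersection, the union, and
    ``exclusive_counts``: for every non-empty line combination, the number
    of exons passing in exactly those lines.  Exclusive counts sum to the
    union size.
    """
    if len(per_line) < 2:
        raise ValueError("need at least 2 lines")
    sets = {
        line: set(_as_series(tbl).index[_as_series(tbl) >= threshold])
        for line, tbl in per_line.items()
    }
    lines = list(sets)
    union = set().union(*sets.values())
    all_shared = set.intersection(*sets.values())
    exclusive: dict[frozenset, int] = {}
    for r in range(1, len(lines) + 1):
        for combo in combinations(lines, r):
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set().union(*(sets[l] for l in lines if l not in combo), set())
            count = len(inside - outside)
            if count:
                exclusive[frozenset(combo)] = count
    return {
        "per_line": sets,
        "all_shared": all_shared,
        "union": union,
        "exclusive_counts": exclusive,
    }


def fold_change_calls(
    expr_case,
    expr_control,
    threshold: float = 2.0,
    pseudocount: float = 1.0,
) -> tuple[set[str], set[str]]:
    """Up/down feature sets from a pseudocounted linear-scale ratio.

    ``ratio = (case + pseudocount) / (control + pseudocount)``; up when the
    ratio >= threshold, down when <= 1/threshold.
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    case, control = _as_series(expr_case), _as_series(expr_control)
    if (case < 0).any() or (control < 0).any():
        raise ValueError("negative expression value")
    shared = case.index.intersection(control.index)
    ratio = (case.loc[shared] + pseudocount) / (control.loc[shared] + pseudocount)
    up = set(shared[ratio >= threshold])
    down = set(shared[ratio <= 1.0 / threshold])
    return up, down


def cross_dataset_agreement(
    changes_a,
    changes_b,
    threshold_a: float,
    threshold_b: float,
    kind: str = "psi",
    require_both: bool = True,
) -> AgreementResult:
    """Sign agreement of changes between two datasets.

    For ``kind="psi"`` the change is dPSI and thresholds apply as
    |change| >= cutoff; for ``kind="expression"`` the change is a fold
    ratio and a feature passes when ratio >= cutoff or <= 1/cutoff (its
    sign being the sign of log ratio).  Features must pass in both datasets
    (default) to enter the test; two-sided binomial at p0 = 0.5.
    """
    a, b = _as_series(changes_a), _as_series(changes_b)
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]
    if kind == "psi":
        sign_a, sign_b = np.sign(a), np.sign(b)
        pass_a, pass_b = a.abs() >= threshold_a, b.abs() >= threshold_b
    elif kind == "expression":
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("expression fold ratios must be positive")
        sign_a, sign_b = np.sign(np.log(a)), np.sign(np.log(b))
        pass_a = (a >= threshold_a) | (a <= 1.0 / threshold_a)
        pass_b = (b >= threshold_b) | (b <= 1.0 / threshold_b)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    entering = (pass_a & pass_b) if require_both else (pass_a | pass_b)
    entering &= (sign_a != 0) & (sign_b != 0)
    n = int(entering.sum())
    if n == 0:
        raise ValueError("no feature passes the cutoffs in both datasets")
    k = int((sign_a[entering] == sign_b[entering]).sum())
    return AgreementResult(n=n, k=k, p_two_sided=binomial_test(k, n, 0.5, sided="two"))
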