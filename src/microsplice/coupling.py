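"""Coupling between splicing-factor activity, target inclusion and proliferation.

Three analyses live here:

* the mitotic-index (MI) signature score — a per-sample proliferation proxy
  computed as the mean z-scored log2(x+1) expression of a signature gene
  list;
* the median Spearman correlation between a per-sample profile (SF
  expression or promoter methylation) and the PSI of the SF's target exons,
  with an add-one randomization test against background genes drawn from a
  supplied pool (random genes, splicing-GO genes or microexon regulators);
* per-exon MI correlations and the binomial sign-agreement test between the
  MI-correlation sign of each exon and the sign of its tumor-vs-normal dPSI.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats import t as _student_t

from .datatypes import (
    TUMOR,
    AgreementResult,
    OmicsMatrix,
    RandomizationResult,
    SampleTable,
)
from .stats import binomial_test, spearman_rho

__all__ = [
    "mi_score",
    "sf_target_coupling",
    "randomization_test",
    "per_exon_mi_correlation",
    "sign_agreement_test",
]

#: named background pools with the pool sizes used in the screen design
BACKGROUND_POOL_SIZES = {"random_expression": 5000, "random_methylation": 500}


def mi_score(expr: OmicsMatrix, signature_genes, min_fraction: float = 0.5) -> pd.Series:
    """Mitotic-index score per sample.

    Each signature gene's log2(x+1) expression is z-scored across the cohort
    (genes with zero variance are dropped); a sample's score is the mean
    over signature genes.  Samples quantified for fewer than
    ``min_fraction`` of the signature genes get NaN.  By construction the
    cohort mean of defined scores is ~0.
    """
    present = [g for g in signature_genes if g in set(expr.feature_ids)]
    if len(present) < 2:
        raise ValueError("fewer than 2 signature genes present in the matrix")
    block = np.log2(expr.values.loc[present].to_numpy() + 1.0)
    mu = np.nanmean(block, axis=1, keepdims=True)
    sd = np.nanstd(block, axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    z = (block[keep] - mu[keep]) / sd[keep]
    n_defined = (~np.isnan(z)).sum(axis=0)
    scores = np.nanmean(z, axis=0)
    scores[n_defined < min_fraction * len(present)] = np.nan
    return pd.Series(scores, index=expr.sample_ids, name="mi_score")


def sf_target_coupling(profile: pd.Series, psi: OmicsMatrix, targets) -> float:
    """Median Spearman rho between a per-sample profile and target exon PSI.

    Correlations are pairwise-complete per target; targets with an undefined
    correlation (fewer than 3 complete pairs or zero variance) are excluded
    from the median.  Raises when no target has a defined correlation.
    """
    common = [s for s in psi.sample_ids if s in profile.index]
    prof = profile.loc[common].to_numpy(dtype=float)
    rhos = []
    sub = psi.values.loc[[t for t in targets if t in psi.values.index], common]
    for row in sub.to_numpy():
        rho = spearman_rho(prof, row)
        if rho is not None:
            rhos.append(rho)
    if not rhos:
        raise ValueError("no target exon with a defined correlation")
    return float(np.median(rhos))


def _masked_ranks(profiles: np.ndarray, order: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Average ranks of each profile row restricted to ``mask`` columns.

    ``order`` is a stable per-row argsort of ``profiles`` computed once, so
    each subset ranking is a gather instead of a fresh sort; rows with ties
    inside the subset fall back to ``rankdata``.
    """
    n_profiles, n = profiles.shape
    k = int(mask.sum())
    keep = mask[order]
    sel = order[keep].reshape(n_profiles, k)
    vals = np.take_along_axis(profiles, sel, axis=1)
    pos = np.broadcast_to(np.arange(1, k + 1, dtype=float), (n_profiles, k)).copy()
    tied_rows = np.nonzero((vals[:, 1:] == vals[:, :-1]).any(axis=1))[0]
    for i in tied_rows:
        pos[i] = rankdata(vals[i])
    compact = np.empty(n, dtype=int)
    compact[np.nonzero(mask)[0]] = np.arange(k)
    out = np.empty((n_profiles, k))
    np.put_along_axis(out, compact[sel], pos, axis=1)
    return out


def _median_couplings(profiles: np.ndarray, psi_block: np.ndarray) -> np.ndarray:
    """Median over targets of Spearman rho for each of several profiles.

    ``profiles`` is (n_profiles, n_samples) with no missing values;
    ``psi_block`` is (n_targets, n_samples) with NaN for missing.  Each
    target is correlated over its own complete-sample subset.
    """
    n_profiles = profiles.shape[0]
    order = np.argsort(profiles, axis=1, kind="stable")
    rhos = np.full((n_profiles, psi_block.shape[0]), np.nan)
    for j, row in enumerate(psi_block):
        mask = ~np.isnan(row)
        n = int(mask.sum())
        if n < 3:
            continue
        y = rankdata(row[mask])
        sy = y.std()
        if sy == 0:
            continue
        x = _masked_ranks(profiles, order, mask)
        sx = x.std(axis=1)
        ok = sx > 0
        yc = y - y.mean()
        xc = x - x.mean(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc @ yc) / (n * sx * sy)
        rhos[ok, j] = np.clip(r[ok], -1.0, 1.0)
    with np.errstate(all="ignore"):
        return np.nanmedian(rhos, axis=1)


def randomization_test(
    psi: OmicsMatrix,
    targets,
    focal_profile: pd.Series,
    background_pool,
    background_matrix: OmicsMatrix,
    B: int = 500,
    tail: str = "greater",
    seed: int | np.random.Generator = 0,
    replace: bool = False,
    background_kind: str = "random",
    samples=None,
) -> RandomizationResult:
    """Add-one randomization test of the median target-coupling statistic.

    ``B`` background genes are drawn from ``background_pool`` (without
    replacement unless ``replace``); each background gene's per-sample
    profile from ``background_matrix`` is coupled to the same target exons,
    and the one-tailed p is ``(1 + #{background >= observed}) / (B + 1)``
    for ``tail="greater"`` (mirrored for ``"less"``), so p is never exactly
    0.  ``samples`` restricts the computation, e.g. to the tumor samples of
    one tissue or of the whole cohort.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    focal_name = focal_profile.name
    pool = [g for g in background_pool if g != focal_name]
    if not replace and len(pool) < B:
        raise ValueError(
            f"background pool of {len(pool)} cannot supply B={B} draws without replacement"
        )
    if tail not in ("greater", "less"):
        raise ValueError(f"unknown tail {tail!r}")

    if samples is None:
        common = [s for s in psi.sample_ids if s in focal_profile.index]
    else:
        common = [s for s in samples if s in set(psi.sample_ids)]
    common = [s for s in common if s in set(background_matrix.sample_ids)]

    target_ids = [t for t in targets if t in psi.values.index]
    psi_block = psi.values.loc[target_ids, common].to_numpy()
    focal = focal_profile.loc[common].to_numpy(dtype=float)[None, :]
    observed = float(_median_couplings(focal, psi_block)[0])
    if np.isnan(observed):
        raise ValueError("no target exon with a defined correlation")

    drawn = rng.choice(np.asarray(pool, dtype=object), size=B, replace=replace)
    bg = background_matrix.values.loc[list(drawn), common].to_numpy(dtype=float)
    bg_medians = _median_couplings(bg, psi_block)

    finite = bg_medians[~np.isnan(bg_medians)]
    if tail == "greater":
        extreme = int((finite >= observed).sum())
    else:
        extreme = int((finite <= observed).sum())
    p = (1 + extreme) / (B + 1)
    return RandomizationResult(
        observed_median_rho=observed,
        background_medians=[float(v) for v in bg_medians],
        p_one_tailed=float(p),
        tail=tail,
        background_kind=background_kind,
    )


def per_exon_mi_correlation(
    psi: OmicsMatrix,
    mi: pd.Series,
    samples: SampleTable,
    tissue: str,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Spearman rho (and p) of each exon's PSI against MI in tumor samples.

    Exons with fewer than 3 complete pairs or constant PSI report NaN.  The
    p-value uses the t approximation for the rank correlation; the
    significance flag applies ``p_threshold``.
    """
    tumor_ids = [s for s in samples.group(tissue, TUMOR) if s in set(psi.sample_ids)]
    mi_vals = mi.loc[tumor_ids].to_numpy(dtype=float)
    rows = []
    for exon_id, row in psi.values[tumor_ids].iterrows():
        rho = spearman_rho(mi_vals, row.to_numpy(dtype=float))
        if rho is None:
            rows.append(
                {"exon_id": exon_id, "tissue": tissue, "rho": np.nan, "p": np.nan,
                 "significant": False}
            )
            continue
        n = int((~(np.isnan(mi_vals) | row.isna().to_numpy())).sum())
        if abs(rho) >= 1.0 or n <= 2:
            p = 0.0 if n > 2 else np.nan
        else:
            tstat = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * _student_t.sf(abs(tstat), df=n - 2))
        rows.append(
            {"exon_id": exon_id, "tissue": tissue, "rho": rho, "p": p,
             "significant": bool(p < p_threshold)}
        )
    return pd.DataFrame(rows)


def sign_agreement_test(
    calls: pd.DataFrame, rhos: pd.DataFrame, association: str = "same"
) -> AgreementResult:
    """Binomial test of sign agreement between MI correlation and dPSI.

    Evaluated on (exon, tissue) pairs that are significant in ``calls`` and
    have a defined correlation in ``rhos``.  With ``association="same"``
    (default) a success is a pair whose correlation sign matches its dPSI
    sign — the expectation when exons negatively coupled to proliferation
    are the ones decreasing in tumors.  ``association="opposite"`` inverts
    the success definition.  Two-sided binomial p at p0 = 0.5.
    """
    sig = calls[calls["significant"]][["exon_id", "tissue", "dpsi"]]
    cor = rhos.dropna(subset=["rho"])[["exon_id", "tissue", "rho"]]
    merged = sig.merge(cor, on=["exon_id", "tissue"])
    merged = merged[(merged["dpsi"] != 0) & (merged["rho"] != 0)]
    n = len(merged)
    if n == 0:
        raise ValueError("no (exon, tissue) pair with both a call and a correlation")
    same = int((np.sign(merged["rho"]) == np.sign(merged["dpsi"])).sum())
    k = same if association == "same" else n - same
    return AgreementResult(n=n, k=k, p_two_sided=binomial_test(k, n, 0.5, sided="two"))
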