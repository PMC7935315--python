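"""Seeded multi-omic tumor/normal cohort generator with known ground truth.

The generator emulates the statistical structure the screen assumes, at
desk scale:

* several tissues, each with tumor and normal cohorts;
* a panel of splicing factors of which exactly one is planted as silenced —
  its tumor expression is divided by a silencing factor and its promoter
  methylation (beta) is shifted up on the logit scale — in every tissue;
* target exons whose PSI is monotonically coupled (log1p link) to the
  planted factor's expression, a configurable fraction of them with zero
  baseline inclusion outside the coupling term;
* a latent per-sample proliferation variable, higher in tumors, that drives
  a proliferation-signature gene block and enters the planted factor's
  expression with a negative coefficient (so factor expression anticorrelates
  with the mitotic index);
* uniformly random missing PSI cells.

Setting every effect parameter to its null value (see
:meth:`GeneratorConfig.null`) yields exchangeable tumor/normal cohorts for
calibration experiments.  A fixed seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import coupling as coupling_mod
from . import exons as exons_mod
from . import screen as screen_mod
from .datatypes import (
    ExonAnnotation,
    MatrixKind,
    OmicsMatrix,
    SampleTable,
    TargetMap,
)

__all__ = ["GeneratorConfig", "CohortBundle", "TruthBundle", "generate_cohorts",
           "evaluate_recovery", "run_recovery"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    ``expression_silencing_factor`` is the tumor-vs-normal median ratio
    divisor applied to the planted factor (>= 1; 1 = no effect);
    ``methylation_shift`` is the logit-scale promoter shift in tumors;
    ``coupling_slope`` multiplies log1p(factor expression) in target PSI;
    ``mi_anticorrelation`` (in [-1, 0]) couples the latent proliferation
    variable into the planted factor's expression.
    """

    seed: int = 0
    n_tissues: int = 9
    n_tumor_per_tissue: int = 40
    n_normal_per_tissue: int = 25
    n_sfs: int = 202
    n_exons: int = 500
    n_targets: int = 314
    n_background_genes: int = 1000
    n_signature_genes: int = 50
    fraction_microexon_targets: float = 0.66
    fraction_zero_baseline_targets: float = 0.66
    planted_sf_index: int = 0
    expression_silencing_factor: float = 3.67
    methylation_shift: float = 0.8
    coupling_slope: float = 12.0
    psi_noise_sd: float = 8.0
    mi_anticorrelation: float = -0.5
    proliferation_shift: float = 1.0
    missing_psi_rate: float = 0.10

    def __post_init__(self) -> None:
        if self.expression_silencing_factor < 1:
            raise ValueError("expression_silencing_factor must be >= 1")
        if not 0 <= self.methylation_shift <= 1:
            raise ValueError("methylation_shift must lie in [0, 1]")
        if not -1 <= self.mi_anticorrelation <= 0:
            raise ValueError("mi_anticorrelation must lie in [-1, 0]")
        if not 0 <= self.missing_psi_rate < 1:
            raise ValueError("missing_psi_rate must lie in [0, 1)")
        if self.psi_noise_sd < 0:
            raise ValueError("psi_noise_sd must be >= 0")
        if not 0 <= self.fraction_microexon_targets <= 1:
            raise ValueError("fraction_microexon_targets must lie in [0, 1]")
        if not 0 <= self.fraction_zero_baseline_targets <= 1:
            raise ValueError("fraction_zero_baseline_targets must lie in [0, 1]")
        if self.n_targets > self.n_exons:
            raise ValueError("n_targets cannot exceed n_exons")
        if not 0 <= self.planted_sf_index < self.n_sfs:
            raise ValueError("planted_sf_index out of range")

    def null(self) -> "GeneratorConfig":
        """The same cohort shape with every planted effect switched off."""
        return replace(
            self,
            expression_silencing_factor=1.0,
            methylation_shift=0.0,
            coupling_slope=0.0,
            mi_anticorrelation=0.0,
            proliferation_shift=0.0,
        )


@dataclass
class TruthBundle:
    """Ground truth of one generated cohort."""

    planted_sf_id: str
    target_exons: set[str]
    expression_ratio: float  # tumor/normal median divisor of the planted SF
    methylation_shift: float  # logit-scale tumor shift of the planted SF
    expected_dpsi: pd.Series  # per-tissue expected dPSI of coupled targets
    proliferation: pd.Series  # latent per-sample proliferation values


@dataclass
class CohortBundle:
    config: GeneratorConfig
    expression: OmicsMatrix
    methylation: OmicsMatrix
    psi: OmicsMatrix
    samples: SampleTable
    targets: TargetMap
    annotation: ExonAnnotation
    sf_ids: list[str] = field(default_factory=list)
    background_genes: list[str] = field(default_factory=list)
    signature_genes: list[str] = field(default_factory=list)
    truth: TruthBundle | None = None


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohorts(config: GeneratorConfig) -> CohortBundle:
    """Generate one fully seeded tumor/normal multi-omic cohort."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    tissues = [f"tissue{i + 1:02d}" for i in range(cfg.n_tissues)]
    sample_rows = []
    for tissue in tissues:
        for j in range(cfg.n_tumor_per_tissue):
            sample_rows.append((f"{tissue}_T{j + 1:03d}", tissue, "tumor"))
        for j in range(cfg.n_normal_per_tissue):
            sample_rows.append((f"{tissue}_N{j + 1:03d}", tissue, "normal"))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "tissue", "condition"]
    ).set_index("sample_id")
    n_samples = len(samples)
    is_tumor = (samples["condition"] == "tumor").to_numpy()
    tissue_idx = pd.Categorical(samples["tissue"], categories=tissues).codes

    # latent proliferation, higher in tumors
    pi = rng.normal(0.0, 1.0, n_samples) + cfg.proliferation_shift * is_tumor

    sf_ids = [f"SF{i + 1:03d}" for i in range(cfg.n_sfs)]
    planted = sf_ids[cfg.planted_sf_index]
    bg_ids = [f"BG{i + 1:04d}" for i in range(cfg.n_background_genes)]
    sig_ids = [f"PRG{i + 1:03d}" for i in range(cfg.n_signature_genes)]

    # --- expression -------------------------------------------------------
    def tissue_baselines(n_features):
        base = rng.uniform(1.0, 9.0, size=(n_features, 1))
        jitter = np.exp(rng.normal(0.0, 0.4, size=(n_features, cfg.n_tissues)))
        return base * jitter  # features x tissues

    sf_base = tissue_baselines(cfg.n_sfs)
    bg_base = tissue_baselines(cfg.n_background_genes)

    def expand(baselines):
        return baselines[:, tissue_idx]

    log_noise_sd = 0.5
    expr_sf = expand(sf_base) * np.exp(
        rng.normal(0.0, log_noise_sd, size=(cfg.n_sfs, n_samples))
    )
    # planted factor: silenced in tumors, anticorrelated with proliferation
    p = cfg.planted_sf_index
    planted_expr = expand(sf_base)[p] * np.exp(
        cfg.mi_anticorrelation * pi + rng.normal(0.0, 0.3, n_samples)
    )
    planted_expr = planted_expr / np.where(is_tumor, cfg.expression_silencing_factor, 1.0)
    expr_sf[p] = np.maximum(planted_expr, 0.0)

    expr_bg = expand(bg_base) * np.exp(
        rng.normal(0.0, log_noise_sd, size=(cfg.n_background_genes, n_samples))
    )
    sig_base = np.exp(rng.uniform(0.0, 3.0, size=(cfg.n_signature_genes, 1)))
    expr_sig = sig_base * np.exp(
        0.8 * pi[None, :] + rng.normal(0.0, 0.3, size=(cfg.n_signature_genes, n_samples))
    )

    expression = OmicsMatrix(
        MatrixKind.expression,
        pd.DataFrame(
            np.vstack([expr_sf, expr_bg, expr_sig]),
            index=sf_ids + bg_ids + sig_ids,
            columns=samples.index,
        ),
    )

    # --- promoter methylation --------------------------------------------
    meth_ids = sf_ids + bg_ids
    # base beta drawn uniformly, converted to logit
    base_beta = rng.uniform(0.1, 0.6, size=(len(meth_ids), 1))
    meth_base_logit = np.log(base_beta / (1.0 - base_beta))
    logits = meth_base_logit + rng.normal(0.0, 0.4, size=(len(meth_ids), n_samples))
    logits[p] += cfg.methylation_shift * is_tumor
    methylation = OmicsMatrix(
        MatrixKind.methylation,
        pd.DataFrame(_logistic(logits), index=meth_ids, columns=samples.index),
    )

    # --- exon annotation and target map ----------------------------------
    exon_ids = [f"EX{i + 1:04d}" for i in range(cfg.n_exons)]
    target_ids = exon_ids[: cfg.n_targets]
    is_target = np.zeros(cfg.n_exons, dtype=bool)
    is_target[: cfg.n_targets] = True

    lengths = np.empty(cfg.n_exons, dtype=int)
    micro_t = rng.random(cfg.n_targets) < cfg.fraction_microexon_targets
    lengths[: cfg.n_targets] = np.where(
        micro_t,
        rng.integers(3, 28, cfg.n_targets),
        rng.integers(28, 301, cfg.n_targets),
    )
    n_other = cfg.n_exons - cfg.n_targets
    micro_o = rng.random(n_other) < 0.10
    lengths[cfg.n_targets:] = np.where(
        micro_o, rng.integers(3, 28, n_other), rng.integers(28, 301, n_other)
    )
    host_genes = [f"HOST{i + 1:04d}" for i in range(cfg.n_exons)]
    annotation = ExonAnnotation(
        pd.DataFrame({"gene_id": host_genes, "length_nt": lengths}, index=exon_ids)
    )
    targets = TargetMap({planted: set(target_ids)})

    # --- PSI ---------------------------------------------------------------
    psi_vals = np.empty((cfg.n_exons, n_samples))
    zero_base = rng.random(cfg.n_targets) < cfg.fraction_zero_baseline_targets
    target_base = np.where(zero_base, 0.0, rng.uniform(20.0, 60.0, cfg.n_targets))
    sf_signal = cfg.coupling_slope * np.log1p(expr_sf[p])
    psi_vals[: cfg.n_targets] = (
        target_base[:, None]
        + sf_signal[None, :]
        + rng.normal(0.0, cfg.psi_noise_sd, size=(cfg.n_targets, n_samples))
    )
    other_base = rng.uniform(0.0, 100.0, size=(n_other, 1))
    psi_vals[cfg.n_targets:] = other_base + rng.normal(
        0.0, cfg.psi_noise_sd, size=(n_other, n_samples)
    )
    psi_vals = np.clip(psi_vals, 0.0, 100.0)
    if cfg.missing_psi_rate > 0:
        mask = rng.random(psi_vals.shape) < cfg.missing_psi_rate
        psi_vals[mask] = np.nan
    psi = OmicsMatrix(
        MatrixKind.psi,
        pd.DataFrame(psi_vals, index=exon_ids, columns=samples.index),
    )

    # expected dPSI of coupled targets per tissue, from the planted effect
    expected = {}
    for t_i, tissue in enumerate(tissues):
        base = sf_base[p, t_i]
        expected[tissue] = cfg.coupling_slope * (
            np.log1p(base / cfg.expression_silencing_factor) - np.log1p(base)
        )
    truth = TruthBundle(
        planted_sf_id=planted,
        target_exons=set(target_ids),
        expression_ratio=cfg.expression_silencing_factor,
        methylation_shift=cfg.methylation_shift,
        expected_dpsi=pd.Series(expected),
        proliferation=pd.Series(pi, index=samples.index, name="proliferation"),
    )
    return CohortBundle(
        config=cfg,
        expression=expression,
        methylation=methylation,
        psi=psi,
        samples=SampleTable(samples),
        targets=targets,
        annotation=annotation,
        sf_ids=sf_ids,
        background_genes=bg_ids,
        signature_genes=sig_ids,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# end-to-end recovery


def run_recovery(
    config: GeneratorConfig,
    B: int = 500,
    min_group_size: int = 20,
    q_direction: float = 0.05,
    randomization_seed: int | None = None,
) -> dict:
    """Generate a cohort, run the full pipeline, and score it against truth.

    Returns a report with the planted factor's consistency-score ranks, the
    pooled fraction of significant target exons called down, target-call
    sensitivity/specificity, the randomization p for the planted factor
    (expression profile vs target PSI, pooled tumor samples), and the
    Spearman correlation of the mitotic-index score with planted-factor
    expression in tumors.
    """
    bundle = generate_cohorts(config)
    return evaluate_recovery(bundle, B=B, min_group_size=min_group_size,
                             q_direction=q_direction,
                             randomization_seed=randomization_seed)


def evaluate_recovery(
    bundle: CohortBundle,
    B: int = 500,
    min_group_size: int = 20,
    q_direction: float = 0.05,
    randomization_seed: int | None = None,
) -> dict:
    cfg = bundle.config
    truth = bundle.truth
    sf_expr = OmicsMatrix(
        MatrixKind.expression, bundle.expression.values.loc[bundle.sf_ids]
    )
    sf_meth = OmicsMatrix(
        MatrixKind.methylation, bundle.methylation.values.loc[bundle.sf_ids]
    )
    expr_records = screen_mod.run_screen(
        sf_expr, bundle.samples, min_group_size=min_group_size,
        q_threshold=q_direction,
    )
    meth_records = screen_mod.run_screen(
        sf_meth, bundle.samples, min_group_size=min_group_size,
        q_threshold=q_direction,
    )
    expr_scores = screen_mod.consistency_scores(expr_records, q_direction)
    meth_scores = screen_mod.consistency_scores(meth_records, q_direction)

    planted = truth.planted_sf_id
    expr_rank = int(
        expr_scores.index[expr_scores["sf_id"] == planted][0] + 1
    )
    min_score = int(expr_scores["score"].min())
    planted_expr_score = int(
        expr_scores.loc[expr_scores["sf_id"] == planted, "score"].iloc[0]
    )
    max_meth_score = int(meth_scores["score"].max())
    planted_meth_score = int(
        meth_scores.loc[meth_scores["sf_id"] == planted, "score"].iloc[0]
    )

    # differential inclusion across tissues
    calls = pd.concat(
        [
            exons_mod.differential_psi(
                bundle.psi, bundle.samples, tissue,
                annotation=bundle.annotation,
                targets=truth.target_exons,
            )
            for tissue in bundle.samples.tissues
        ],
        ignore_index=True,
    )
    sig = calls[calls["significant"]]
    sig_targets = sig[sig["exon_id"].isin(truth.target_exons)]
    frac_down = (
        float((sig_targets["direction"] == "down").mean())
        if len(sig_targets)
        else float("nan")
    )
    called = set(sig["exon_id"])
    tp = len(called & truth.target_exons)
    fp = len(called - truth.target_exons)
    n_nontargets = cfg.n_exons - cfg.n_targets
    sensitivity = tp / cfg.n_targets
    specificity = 1.0 - fp / n_nontargets if n_nontargets else float("nan")

    # randomization test: planted-factor expression vs target PSI, tumors
    tumor_ids = [
        s for s in bundle.samples.sample_ids
        if bundle.samples.frame.at[s, "condition"] == "tumor"
    ]
    rand_seed = cfg.seed if randomization_seed is None else randomization_seed
    rand = coupling_mod.randomization_test(
        bundle.psi,
        truth.target_exons,
        bundle.expression.values.loc[planted].rename(planted),
        bundle.background_genes,
        bundle.expression,
        B=B,
        tail="greater",
        seed=rand_seed,
        samples=tumor_ids,
    )

    mi = coupling_mod.mi_score(bundle.expression, bundle.signature_genes)
    from .stats import spearman_rho

    mi_sf_rho = spearman_rho(
        mi.loc[tumor_ids].to_numpy(),
        bundle.expression.values.loc[planted, tumor_ids].to_numpy(),
    )
    mi_truth_rho = spearman_rho(
        mi.to_numpy(), truth.proliferation.loc[mi.index].to_numpy()
    )

    return {
        "planted_sf_id": planted,
        "expression_rank": expr_rank,
        "expression_score": planted_expr_score,
        "expression_is_minimum": planted_expr_score == min_score,
        "methylation_score": planted_meth_score,
        "methylation_is_maximum": planted_meth_score == max_meth_score,
        "n_significant_target_calls": int(len(sig_targets)),
        "frac_targets_down": frac_down,
        "target_sensitivity": float(sensitivity),
        "target_specificity": float(specificity),
        "randomization_p": rand.p_one_tailed,
        "observed_median_rho": rand.observed_median_rho,
        "mi_sf_spearman": mi_sf_rho,
        "mi_latent_spearman": mi_truth_rho,
        "expr_scores": expr_scores,
        "meth_scores": meth_scores,
        "calls": calls,
    }
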