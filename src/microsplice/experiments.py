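"""Calibration and recovery experiments over seeded synthetic cohorts.

These drive the package end to end: null-mode cohorts measure the false
positive rate of the differential-inclusion calls and the uniformity of the
randomization p-value; planted cohorts measure how reliably the silenced
factor is recovered as the top-ranked hit.  Problem sizes are chosen so a
whole experiment runs in minutes on one core; see docs/methods.md.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import coupling as coupling_mod
from . import exons as exons_mod
from .simulate import GeneratorConfig, generate_cohorts, run_recovery

__all__ = [
    "null_exon_fp_rate",
    "null_randomization_pvalues",
    "planted_recovery_summary",
    "NULL_EXON_CONFIG",
    "NULL_RANDOMIZATION_CONFIG",
]

#: cohort shape for the exon-call false-positive calibration (null mode)
NULL_EXON_CONFIG = GeneratorConfig(
    n_tissues=2,
    n_tumor_per_tissue=30,
    n_normal_per_tissue=30,
    n_sfs=10,
    n_exons=200,
    n_targets=50,
    n_background_genes=20,
    n_signature_genes=5,
).null()

#: cohort shape for the randomization-test calibration (null mode)
NULL_RANDOMIZATION_CONFIG = GeneratorConfig(
    n_tissues=1,
    n_tumor_per_tissue=40,
    n_normal_per_tissue=20,
    n_sfs=5,
    n_exons=30,
    n_targets=25,
    n_background_genes=250,
    n_signature_genes=5,
).null()


def null_exon_fp_rate(n_cohorts: int = 100, seed: int = 0) -> dict:
    """Fraction of exons called significant across null cohorts.

    With no planted effects the tumor and normal groups are exchangeable,
    so calls at q < 0.01 and |dPSI| >= 5 are false positives; BH keeps
    their pooled fraction at or below the q threshold.
    """
    n_sig = 0
    n_tests = 0
    for i in range(n_cohorts):
        cfg = dataclasses.replace(NULL_EXON_CONFIG, seed=seed + i)
        bundle = generate_cohorts(cfg)
        for tissue in bundle.samples.tissues:
            calls = exons_mod.differential_psi(bundle.psi, bundle.samples, tissue)
            n_sig += int(calls["significant"].sum())
            n_tests += len(calls)
    return {"fp_rate": n_sig / n_tests, "n_tests": n_tests, "n_cohorts": n_cohorts}


def null_randomization_pvalues(
    n_datasets: int = 200, B: int = 199, seed: int = 0
) -> np.ndarray:
    """Randomization p for the (effect-free) planted factor on null cohorts.

    Under the null the focal gene is exchangeable with the background pool,
    so the add-one p should be approximately Uniform(0, 1).
    """
    ps = np.empty(n_datasets)
    for i in range(n_datasets):
        cfg = dataclasses.replace(NULL_RANDOMIZATION_CONFIG, seed=seed + i)
        bundle = generate_cohorts(cfg)
        tumor_ids = [
            s for s in bundle.samples.sample_ids
            if bundle.samples.frame.at[s, "condition"] == "tumor"
        ]
        planted = bundle.truth.planted_sf_id
        res = coupling_mod.randomization_test(
            bundle.psi,
            bundle.truth.target_exons,
            bundle.expression.values.loc[planted].rename(planted),
            bundle.background_genes,
            bundle.expression,
            B=B,
            tail="greater",
            seed=seed + i + 1_000_000,
            samples=tumor_ids,
        )
        ps[i] = res.p_one_tailed
    return ps


def planted_recovery_summary(n_runs: int = 50, B: int = 500, seed: int = 0) -> dict:
    """Recovery rates of the planted factor over seeded default cohorts."""
    expr_min = meth_max = rand_hits = mi_neg = 0
    down_calls = 0
    total_sig_targets = 0
    frac_down_runs = []
    rand_ps = []
    mi_rhos = []
    rhos = []
    for i in range(n_runs):
        report = run_recovery(GeneratorConfig(seed=seed + i), B=B)
        expr_min += report["expression_is_minimum"]
        meth_max += report["methylation_is_maximum"]
        rand_hits += report["randomization_p"] < 0.05
        mi_neg += report["mi_sf_spearman"] < 0
        n_sig = report["n_significant_target_calls"]
        total_sig_targets += n_sig
        down_calls += int(round(report["frac_targets_down"] * n_sig))
        frac_down_runs.append(report["frac_targets_down"])
        rand_ps.append(report["randomization_p"])
        mi_rhos.append(report["mi_sf_spearman"])
        rhos.append(report["observed_median_rho"])
    return {
        "n_runs": n_runs,
        "expression_min_rate": expr_min / n_runs,
        "methylation_max_rate": meth_max / n_runs,
        "randomization_detection_rate": rand_hits / n_runs,
        "mi_negative_rate": mi_neg / n_runs,
        "pooled_frac_targets_down": down_calls / total_sig_targets,
        "frac_down_runs": frac_down_runs,
        "randomization_ps": rand_ps,
        "mi_sf_spearman_median": float(np.median(mi_rhos)),
        "observed_median_rho_median": float(np.median(rhos)),
    }
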