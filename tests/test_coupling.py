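import numpy as np
import pandas as pd
import pytest

from microsplice.coupling import (
    mi_score,
    per_exon_mi_correlation,
    randomization_test,
    sf_target_coupling,
    sign_agreement_test,
)
from microsplice.datatypes import MatrixKind, OmicsMatrix, SampleTable
from microsplice.stats import spearman_rho


def _expr(frame):
    return OmicsMatrix(MatrixKind.expression, frame)


def _psi(frame):
    return OmicsMatrix(MatrixKind.psi, frame)


class TestMiScore:
    def test_sample_at_cohort_mean_scores_zero(self):
        cols = [f"s{i}" for i in range(5)]
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 10, size=(4, 4))
        # 5th sample sits exactly at the geometric structure of the mean
        block = np.hstack([base, np.zeros((4, 1))])
        logged = np.log2(base + 1)
        target = (2 ** logged.mean(axis=1)) - 1
        block[:, 4] = target
        # re-center: the mean now shifts, so recompute the fixed point once
        for _ in range(200):
            logged = np.log2(block + 1)
            block[:, 4] = 2 ** logged.mean(axis=1) - 1
        expr = _expr(pd.DataFrame(block, index=list("abcd"), columns=cols))
        scores = mi_score(expr, list("abcd"))
        assert scores["s4"] == pytest.approx(0.0, abs=1e-8)

    def test_monotone_in_expression(self):
        cols = ["low", "mid", "high"]
        block = np.array([[1.0, 5.0, 50.0], [2.0, 6.0, 60.0]])
        expr = _expr(pd.DataFrame(block, index=["g1", "g2"], columns=cols))
        scores = mi_score(expr, ["g1", "g2"])
        assert scores["low"] < scores["mid"] < scores["high"]
        assert scores.mean() == pytest.approx(0.0, abs=1e-12)

    def test_requires_two_signature_genes(self):
        expr = _expr(pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["a", "b"]))
        with pytest.raises(ValueError, match="signature genes"):
            mi_score(expr, ["g1", "absent"])

    def test_recovers_latent_proliferation(self, small_bundle):
        scores = mi_score(small_bundle.expression, small_bundle.signature_genes)
        rho = spearman_rho(
            scores.to_numpy(), small_bundle.truth.proliferation.to_numpy()
        )
        assert rho > 0.8


class TestSfTargetCoupling:
    def test_profile_matching_target_ranks(self):
        cols = [f"s{i}" for i in range(8)]
        vals = np.linspace(0, 70, 8)
        psi = _psi(pd.DataFrame([vals, vals * 0.5 + 10], index=["E1", "E2"], columns=cols))
        profile = pd.Series(np.arange(8, dtype=float), index=cols)
        assert sf_target_coupling(profile, psi, ["E1", "E2"]) == pytest.approx(1.0)

    def test_no_defined_target_raises(self):
        cols = ["a", "b", "c", "d"]
        psi = _psi(pd.DataFrame([[50.0] * 4], index=["E1"], columns=cols))
        profile = pd.Series([1.0, 2.0, 3.0, 4.0], index=cols)
        with pytest.raises(ValueError, match="defined correlation"):
            sf_target_coupling(profile, psi, ["E1"])


def _random_setup(seed=0, n_samples=30, n_targets=8, n_pool=40, couple=True):
    rng = np.random.default_rng(seed)
    cols = [f"s{i}" for i in range(n_samples)]
    focal = rng.normal(size=n_samples) ** 2 + 0.5
    psi_rows = {}
    for j in range(n_targets):
        signal = 10 * np.log1p(focal) if couple else np.zeros(n_samples)
        psi_rows[f"E{j}"] = np.clip(
            30 + signal + rng.normal(0, 5, n_samples), 0, 100
        )
    psi = _psi(pd.DataFrame(psi_rows).T.set_axis(cols, axis=1))
    genes = {f"G{i}": rng.normal(size=n_samples) ** 2 for i in range(n_pool)}
    genes["FOCAL"] = focal
    expr = _expr(pd.DataFrame(genes).T.set_axis(cols, axis=1))
    profile = pd.Series(focal, index=cols, name="FOCAL")
    return psi, expr, profile, [f"G{i}" for i in range(n_pool)], [f"E{j}" for j in range(n_targets)]


class TestRandomization:
    def test_planted_coupling_detected_with_add_one_floor(self):
        psi, expr, profile, pool, targets = _random_setup(couple=True)
        res = randomization_test(psi, targets, profile, pool, expr, B=39, seed=1)
        assert res.p_one_tailed == pytest.approx(1 / 40)
        assert res.observed_median_rho > 0.4

    def test_observed_equal_to_background_gives_p_one(self):
        psi, expr, profile, pool, targets = _random_setup(couple=True)
        # every background gene IS the focal profile
        clones = pd.DataFrame(
            {g: profile.to_numpy() for g in pool}, index=profile.index
        ).T
        expr_clone = _expr(clones)
        res = randomization_test(psi, targets, profile, pool, expr_clone, B=20, seed=0)
        assert res.p_one_tailed == 1.0

    def test_pool_too_small_without_replacement(self):
        psi, expr, profile, pool, targets = _random_setup()
        with pytest.raises(ValueError, match="without replacement"):
            randomization_test(psi, targets, profile, pool[:5], expr, B=10, seed=0)

    def test_focal_excluded_from_pool(self):
        psi, expr, profile, pool, targets = _random_setup()
        res = randomization_test(
            psi, targets, profile, pool + ["FOCAL"], expr, B=len(pool), seed=2
        )
        assert res.n_background == len(pool)

    def test_invariant_to_monotone_transform(self):
        psi, expr, profile, pool, targets = _random_setup(seed=4)
        res1 = randomization_test(psi, targets, profile, pool, expr, B=30, seed=7)
        expr2 = _expr(np.exp(expr.values / expr.values.to_numpy().max() * 3))
        res2 = randomization_test(
            psi, targets, np.exp(profile / profile.max() * 3), pool, expr2, B=30, seed=7
        )
        assert res1.p_one_tailed == res2.p_one_tailed
        assert res1.observed_median_rho == pytest.approx(res2.observed_median_rho)

    def test_deterministic_under_seed(self):
        psi, expr, profile, pool, targets = _random_setup(seed=5)
        a = randomization_test(psi, targets, profile, pool, expr, B=25, seed=3)
        b = randomization_test(psi, targets, profile, pool, expr, B=25, seed=3)
        assert a.background_medians == b.background_medians
        assert a.p_one_tailed == b.p_one_tailed


def _mi_setup():
    cols = [f"t{i}" for i in range(10)]
    meta = pd.DataFrame(
        {"tissue": ["lung"] * 10, "condition": ["tumor"] * 10}, index=cols
    )
    mi = pd.Series(np.arange(10, dtype=float), index=cols)
    return SampleTable(meta), mi, cols


class TestPerExonMi:
    def test_reversed_ranks_give_minus_one(self):
        table, mi, cols = _mi_setup()
        psi = _psi(
            pd.DataFrame(
                [np.arange(10, dtype=float)[::-1] * 10, [50.0] * 10],
                index=["Erev", "Econst"],
                columns=cols,
            )
        )
        out = per_exon_mi_correlation(psi, mi, table, "lung")
        rev = out[out["exon_id"] == "Erev"].iloc[0]
        const = out[out["exon_id"] == "Econst"].iloc[0]
        assert rev["rho"] == pytest.approx(-1.0) and rev["significant"]
        assert np.isnan(const["rho"]) and not const["significant"]

    def test_planted_targets_anticorrelate_with_mi(self, small_bundle):
        mi = mi_score(small_bundle.expression, small_bundle.signature_genes)
        out = per_exon_mi_correlation(
            small_bundle.psi, mi, small_bundle.samples, "tissue01"
        )
        target_rho = out[out["exon_id"].isin(small_bundle.truth.target_exons)]["rho"]
        assert (target_rho.dropna() < 0).mean() > 0.7


class TestSignAgreement:
    def _frames(self, signs):
        calls = pd.DataFrame(
            {
                "exon_id": [f"E{i}" for i in range(len(signs))],
                "tissue": "lung",
                "dpsi": [10.0 * s for s, _ in signs],
                "significant": True,
            }
        )
        rhos = pd.DataFrame(
            {
                "exon_id": [f"E{i}" for i in range(len(signs))],
                "tissue": "lung",
                "rho": [0.5 * r for _, r in signs],
            }
        )
        return calls, rhos

    def test_nine_of_ten_agreements(self):
        signs = [(1, 1)] * 5 + [(-1, -1)] * 4 + [(1, -1)]
        result = sign_agreement_test(*self._frames(signs))
        assert (result.n, result.k) == (10, 9)
        assert result.p_two_sided == pytest.approx(0.021484375)

    def test_half_agreement_is_null(self):
        signs = [(1, 1)] * 5 + [(1, -1)] * 5
        result = sign_agreement_test(*self._frames(signs))
        assert result.p_two_sided == 1.0

    def test_empty_overlap_raises(self):
        calls, rhos = self._frames([(1, 1)])
        rhos["tissue"] = "breast"
        with pytest.raises(ValueError):
            sign_agreement_test(calls, rhos)
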