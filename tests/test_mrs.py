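import dataclasses

import numpy as np
import pandas as pd
import pytest
from helpers_oracles import elnet_global_oracle

from cordmrs.io import MrsModel, ValidationError
from cordmrs.mrs import (
    ReferencePanel,
    TuningGrid,
    elnet_objective,
    elnet_summary,
    lambda_path,
    prepare_b,
    reference_correlation,
    score_samples,
    soft_threshold,
    standardize,
    tune,
)
from cordmrs.qc import impute_mean
from cordmrs.simulate import simulate_discovery_sumstats


class TestStandardize:
    def test_two_point_probe(self):
        beta = pd.DataFrame([[0.0, 1.0]], index=["p"], columns=["a", "b"])
        z, means, sds = standardize(beta)
        np.testing.assert_allclose(z.to_numpy(), [[-np.sqrt(0.5), np.sqrt(0.5)]])
        assert means["p"] == 0.5 and sds["p"] == pytest.approx(np.sqrt(0.5))

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 50))
        x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
        df = pd.DataFrame(x)
        z, _, _ = standardize(df)
        np.testing.assert_allclose(z.to_numpy(), x, atol=1e-12)

    def test_output_means_are_zero(self, complete_bundle):
        z, _, _ = standardize(complete_bundle.beta)
        assert np.abs(z.mean(axis=1)).max() < 1e-12

    def test_zero_variance_probe_named(self):
        beta = pd.DataFrame([[0.5, 0.5]], index=["cgflat"], columns=["a", "b"])
        with pytest.raises(ValidationError, match="cgflat"):
            standardize(beta)


class TestReferenceCorrelation:
    def test_duplicated_probe_has_unit_correlation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1, 40))
        df = pd.DataFrame(np.vstack([x, x]), index=["a", "b"])
        z, _, _ = standardize(df)
        panel = reference_correlation(z)
        assert panel.R[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_and_unit_diagonal(self, complete_bundle):
        z, _, _ = standardize(complete_bundle.beta)
        panel = reference_correlation(z)
        np.testing.assert_allclose(panel.R, panel.R.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(panel.R), 1.0, atol=1e-12)

    def test_independent_probes_have_small_offdiagonals(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(12, 10_000)))
        z, _, _ = standardize(df)
        R = reference_correlation(z).R
        off = R[~np.eye(12, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]])
        z, _, _ = standardize(df)
        with pytest.raises(ValueError):
            reference_correlation(z)


class TestPrepareB:
    def _ss(self, effects, ses, n=1000):
        return pd.DataFrame({
            "probe_id": [f"cg{i}" for i in range(len(effects))],
            "effect": effects, "se": ses, "p": 0.5, "n": n,
        })

    def test_zero_effect_maps_to_zero(self):
        assert prepare_b(self._ss([0.0], [1.0]), ["cg0"])[0] == 0.0

    def test_worked_example(self):
        b = prepare_b(self._ss([3.0], [1.0], n=1000), ["cg0"])
        assert b[0] == pytest.approx(3 / np.sqrt(1009), abs=1e-10)
        assert b[0] == pytest.approx(0.0945, abs=5e-4)

    def test_bounded_below_one(self):
        rng = np.random.default_rng(4)
        eff = rng.normal(scale=50, size=100)
        b = prepare_b(self._ss(eff, np.full(100, 0.01), n=5), [f"cg{i}" for i in range(100)])
        assert np.all(np.abs(b) < 1)
        assert np.all(np.sign(b) == np.sign(eff))

    def test_missing_probe_rejected(self):
        with pytest.raises(ValidationError, match="absent"):
            prepare_b(self._ss([1.0], [1.0]), ["cg_missing"])


class TestElnetSolver:
    def test_orthonormal_soft_threshold_closed_form(self):
        gamma, conv = elnet_summary(np.array([0.5, -0.2]), np.eye(2), 0.1, 0.0)
        assert conv
        np.testing.assert_allclose(gamma, [0.4, -0.1], atol=1e-10)

    def test_full_shrinkage_at_lambda_max(self):
        b = np.array([0.3, -0.5, 0.1])
        gamma, _ = elnet_summary(b, np.eye(3), lambda1=0.5, lambda2=0.0)
        np.testing.assert_array_equal(gamma, 0.0)

    def test_unpenalized_equals_linear_solve(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(20, 5))
        R = np.corrcoef(A.T)
        b = rng.normal(scale=0.3, size=5)
        gamma, conv = elnet_summary(b, R, 0.0, 0.0, tol=1e-10)
        assert conv
        np.testing.assert_allclose(gamma, np.linalg.solve(R, b), atol=1e-6)

    @pytest.mark.parametrize("lam1,lam2", [(0.05, 0.0), (0.02, 0.1), (0.1, 0.3)])
    def test_matches_global_sign_pattern_oracle(self, lam1, lam2):
        rng = np.random.default_rng(6)
        for _ in range(5):
            A = rng.normal(size=(30, 4))
            R = np.corrcoef(A.T)
            b = rng.normal(scale=0.2, size=4)
            gamma, _ = elnet_summary(b, R, lam1, lam2, tol=1e-10)
            oracle_gamma, oracle_obj = elnet_global_oracle(b, R, lam1, lam2)
            np.testing.assert_allclose(gamma, oracle_gamma, atol=1e-6)
            assert elnet_objective(gamma, b, R, lam1, lam2) <= oracle_obj + 1e-9

    def test_local_optimality_against_random_perturbations(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(40, 8))
        R = np.corrcoef(A.T)
        b = rng.normal(scale=0.25, size=8)
        gamma, _ = elnet_summary(b, R, 0.05, 0.05, tol=1e-10)
        f0 = elnet_objective(gamma, b, R, 0.05, 0.05)
        for scale in (1e-4, 1e-2):
            pert = gamma + rng.normal(scale=scale, size=(1000, 8))
            objs = [elnet_objective(g, b, R, 0.05, 0.05) for g in pert]
            assert f0 <= min(objs) + 1e-12

    def test_nonzero_count_monotone_on_orthonormal_path(self):
        rng = np.random.default_rng(8)
        b = rng.normal(scale=0.3, size=20)
        path = lambda_path(b, 15)
        counts = []
        gamma = np.zeros(20)
        for lam in path:
            gamma, _ = elnet_summary(b, np.eye(20), lam, 0.0, warm_start=gamma)
            counts.append(int((gamma != 0).sum()))
        assert counts == sorted(counts)  # grows as λ1 falls

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            elnet_summary(np.zeros(3), np.eye(2), 0.1, 0.0)

    def test_warm_start_agrees_with_cold_start(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(50, 6))
        R = np.corrcoef(A.T)
        b = rng.normal(scale=0.2, size=6)
        cold, _ = elnet_summary(b, R, 0.03, 0.02, tol=1e-10)
        warm, _ = elnet_summary(b, R, 0.03, 0.02, tol=1e-10,
                                warm_start=rng.normal(scale=0.1, size=6))
        np.testing.assert_allclose(cold, warm, atol=1e-6)


class TestLambdaPath:
    def test_first_point_forces_all_zero(self):
        b = np.array([0.3, -0.2])
        path = lambda_path(b)
        gamma, _ = elnet_summary(b, np.eye(2), path[0], 0.0)
        np.testing.assert_array_equal(gamma, 0.0)

    def test_default_length_is_fifty(self):
        assert len(lambda_path(np.array([1.0]))) == 50

    def test_strictly_decreasing(self):
        path = lambda_path(np.array([0.5, 0.1]))
        assert np.all(np.diff(path) < 0)

    def test_all_zero_b_rejected(self):
        with pytest.raises(ValueError):
            lambda_path(np.zeros(4))


class TestTune:
    @pytest.fixture(scope="class")
    def tuned(self, complete_bundle):
        ss = simulate_discovery_sumstats(
            _cfg_of(complete_bundle), complete_bundle.truth, n_discovery=5000
        )
        z, _, _ = standardize(complete_bundle.beta)
        panel = reference_correlation(z)
        b = prepare_b(ss, panel.probe_ids)
        grid = TuningGrid.default(b, n_lambda=15, n_alpha=4)
        model, trace = tune(b, panel, complete_bundle, grid=grid)
        return model, trace, set(complete_bundle.truth["causal_probes"])

    def test_trace_covers_the_full_grid(self, tuned):
        _, trace, _ = tuned
        assert len(trace) == 15 * 4
        assert trace["selected"].sum() == 1

    def test_recovers_causal_set(self, tuned):
        model, _, causal = tuned
        hits = set(model.probe_ids) & causal
        jaccard = len(hits) / len(set(model.probe_ids) | causal)
        assert jaccard > 0.3

    def test_default_grid_is_50_by_10(self):
        grid = TuningGrid.default(np.array([0.5, 0.2]))
        assert len(grid.lambda1_values) == 50
        assert len(grid.alpha_values) == 10

    def test_permuted_phenotype_does_not_crash(self, complete_bundle):
        rng = np.random.default_rng(10)
        ss = simulate_discovery_sumstats(
            _cfg_of(complete_bundle), complete_bundle.truth, n_discovery=5000
        )
        z, _, _ = standardize(complete_bundle.beta)
        panel = reference_correlation(z)
        b = prepare_b(ss, panel.probe_ids)
        pheno = complete_bundle.phenotypes.copy()
        perm_cols = ["smoking_history", "current_smoker", "ever_smoker"]
        perm = rng.permutation(len(pheno))
        pheno[perm_cols] = pheno[perm_cols].to_numpy()[perm]
        shuffled = dataclasses.replace(complete_bundle, phenotypes=pheno)
        grid = TuningGrid.default(b, n_lambda=8, n_alpha=2)
        model, trace = tune(b, panel, shuffled, grid=grid)
        assert trace.loc[trace["selected"], "p"].iloc[0] >= 0.0


def _cfg_of(bundle):
    from cordmrs.simulate import SimConfig

    return SimConfig(
        n_samples=bundle.beta.shape[1], n_cpgs=bundle.beta.shape[0],
        n_causal=len(bundle.truth["causal_probes"]), missing_rate=0.0,
        seed=101, structure_seed=7,
    )


class TestScoreSamples:
    def _model(self, probes, weights):
        k = len(probes)
        return MrsModel(probe_ids=probes, weights=weights, lambda1=0.1,
                        lambda2=0.0, means=np.full(k, 0.5), sds=np.full(k, 0.1))

    def test_all_zero_weights_give_zero_scores(self, complete_bundle):
        probes = list(complete_bundle.beta.index[:5])
        model = self._model(probes, np.zeros(5))
        scores, n_used = score_samples(model, complete_bundle.beta)
        np.testing.assert_array_equal(scores.to_numpy(), 0.0)
        assert n_used == 5

    def test_single_cpg_unit_weight_is_standardized_probe(self, complete_bundle):
        probe = complete_bundle.beta.index[3]
        model = self._model([probe], np.array([1.0]))
        scores, _ = score_samples(model, complete_bundle.beta)
        z, _, _ = standardize(complete_bundle.beta.loc[[probe]])
        np.testing.assert_allclose(scores.to_numpy(), z.to_numpy()[0], atol=1e-12)

    def test_partial_overlap_uses_available_cpgs(self, complete_bundle):
        rng = np.random.default_rng(11)
        in_matrix = list(rng.choice(complete_bundle.beta.index, 26, replace=False))
        absent = [f"cgABSENT{i}" for i in range(143 - 26)]
        model = self._model(in_matrix + absent, rng.normal(size=143))
        scores, n_used = score_samples(model, complete_bundle.beta)
        assert n_used == 26
        assert len(scores) == complete_bundle.beta.shape[1]

    def test_zero_overlap_rejected(self, complete_bundle):
        model = self._model(["cgNOPE"], np.array([1.0]))
        with pytest.raises(ValidationError, match="no model CpGs"):
            score_samples(model, complete_bundle.beta)

    def test_frozen_standardization_mode(self, complete_bundle):
        probe = complete_bundle.beta.index[0]
        model = self._model([probe], np.array([2.0]))
        scores, _ = score_samples(model, complete_bundle.beta,
                                  frozen_standardization=True)
        expected = 2.0 * (complete_bundle.beta.loc[probe] - 0.5) / 0.1
        np.testing.assert_allclose(scores.to_numpy(), expected.to_numpy(), atol=1e-12)
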