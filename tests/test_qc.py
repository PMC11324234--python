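import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cordmrs.io import CELL_TYPES, ValidationError
from cordmrs.qc import (
    drop_masked,
    drop_noninformative,
    estimate_cell_proportions,
    filter_by_missingness,
    flag_sex_and_duplicates,
    impute_mean,
    run_qc,
    synthetic_cell_reference,
)


def _matrix(arr, probes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    probes = probes or [f"p{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=probes, columns=samples)


class TestMissingnessFilter:
    def test_sample_above_threshold_dropped(self):
        beta = _matrix(np.full((10, 3), 0.5))
        beta.iloc[0:2, 0] = np.nan  # sample s0: 20% missing
        out, rep = filter_by_missingness(beta)
        assert rep.samples_dropped == {"s0": "missingness"}

    def test_exactly_ten_percent_retained(self):
        beta = _matrix(np.full((10, 12), 0.5))
        beta.iloc[0, 0] = np.nan  # s0: exactly 10% of probes missing
        out, rep = filter_by_missingness(beta)
        assert rep.samples_dropped == {}
        assert out.shape == beta.shape

    def test_crafted_pattern_matches_hand_enumeration(self):
        # 12 samples × 10 probes; s0 misses p0,p1,p2 (30% → dropped);
        # s1/s2/s3 each miss exactly 1/10 probes (10% → kept); then p0
        # misses 2/11 (18% → dropped) and p1 misses 1/11 (9% → kept)
        beta = _matrix(np.full((10, 12), 0.5))
        beta.loc[["p0", "p1", "p2"], "s0"] = np.nan
        beta.loc["p0", ["s1", "s2"]] = np.nan
        beta.loc["p1", "s3"] = np.nan
        out, rep = filter_by_missingness(beta)
        assert rep.samples_dropped == {"s0": "missingness"}
        assert rep.probes_dropped == {"p0": "missingness"}
        assert out.shape == (9, 11)
        assert int(out.isna().sum().sum()) == 1  # p1/s1 left for imputation

    def test_all_samples_removed_is_an_error(self):
        beta = _matrix(np.full((4, 2), np.nan))
        with pytest.raises(ValidationError, match="every sample"):
            filter_by_missingness(beta)

    def test_conservation_of_dimensions(self, small_bundle):
        beta = small_bundle.beta
        out, rep = filter_by_missingness(beta)
        n_s_dropped = sum(1 for r in rep.samples_dropped.values() if r == "missingness")
        n_p_dropped = sum(1 for r in rep.probes_dropped.values() if r == "missingness")
        assert out.shape[0] + n_p_dropped == beta.shape[0]
        assert out.shape[1] + n_s_dropped == beta.shape[1]


class TestImputation:
    def test_direct_mean(self):
        beta = _matrix([[0.2, np.nan, 0.4]])
        out, n = impute_mean(beta)
        assert n == 1
        np.testing.assert_allclose(out.to_numpy(), [[0.2, 0.3, 0.4]])

    def test_no_missing_is_identity(self, tiny_beta):
        out, n = impute_mean(tiny_beta)
        assert n == 0
        pd.testing.assert_frame_equal(out, tiny_beta)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=3, max_size=8),
           st.integers(min_value=0, max_value=7))
    def test_imputed_value_within_observed_range(self, values, miss_at):
        miss_at = miss_at % len(values)
        row = list(values)
        row[miss_at] = np.nan
        observed = [v for i, v in enumerate(values) if i != miss_at]
        out, _ = impute_mean(_matrix([row]))
        v = out.iloc[0, miss_at]
        assert min(observed) - 1e-12 <= v <= max(observed) + 1e-12

    def test_fully_missing_probe_is_an_error(self):
        with pytest.raises(ValidationError, match="no observed"):
            impute_mean(_matrix([[np.nan, np.nan]]))


class TestMaskedAndNoninformative:
    def _manifest(self, probes, mask):
        return pd.DataFrame({
            "probe_id": probes, "chromosome": "1",
            "position": range(1, len(probes) + 1), "gene": "",
            "mask": mask,
        })

    def test_mixed_manifest_keeps_exactly_unmasked(self):
        beta = _matrix(np.full((4, 2), 0.5))
        man = self._manifest(list(beta.index), [True, False, True, False])
        out, rep = drop_masked(beta, man)
        assert list(out.index) == ["p1", "p3"]
        assert set(rep.probes_dropped) == {"p0", "p2"}

    def test_all_masked_is_an_error(self):
        beta = _matrix(np.full((2, 2), 0.5))
        man = self._manifest(list(beta.index), [True, True])
        with pytest.raises(ValidationError, match="every probe"):
            drop_masked(beta, man)

    def test_probe_absent_from_manifest_is_an_error(self):
        beta = _matrix(np.full((2, 2), 0.5))
        man = self._manifest(["p0"], [False])
        with pytest.raises(ValidationError, match="absent"):
            drop_masked(beta, man)

    def test_all_hypomethylated_probe_dropped(self):
        beta = _matrix([[0.05, 0.05], [0.5, 0.5]])
        out, rep = drop_noninformative(beta)
        assert rep.probes_dropped == {"p0": "hypomethylated"}

    def test_one_informative_value_retains_probe(self):
        beta = _matrix([[0.05, 0.5], [0.95, 0.95]])
        out, rep = drop_noninformative(beta)
        assert "p0" not in rep.probes_dropped
        assert rep.probes_dropped == {"p1": "hypermethylated"}

    def test_boundary_value_retained_under_strict_comparison(self):
        beta = _matrix([[0.1, 0.1], [0.5, 0.5]])
        out, _ = drop_noninformative(beta)
        assert "p0" in out.index


class TestSexAndDuplicates:
    def _sexed_cohort(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        female = np.arange(n) % 2 == 0
        auto = rng.uniform(0.2, 0.8, size=(20, n))
        x = np.clip(0.3 + 0.3 * female + rng.normal(0, 0.02, size=(10, n)), 0, 1)
        beta = _matrix(np.vstack([auto, x]))
        man = pd.DataFrame({
            "probe_id": beta.index,
            "chromosome": ["1"] * 20 + ["X"] * 10,
            "position": range(1, 31), "gene": "", "mask": False,
        })
        sex = pd.Series(female.astype(float), index=beta.columns)
        return beta, man, sex

    def test_concordant_cohort_has_zero_flags(self):
        beta, man, sex = self._sexed_cohort()
        rep = flag_sex_and_duplicates(beta, man, sex)
        assert rep.samples_dropped == {}

    def test_mismatched_sample_flagged(self):
        beta, man, sex = self._sexed_cohort()
        sex.iloc[0] = 1 - sex.iloc[0]
        rep = flag_sex_and_duplicates(beta, man, sex)
        assert rep.samples_dropped == {sex.index[0]: "sex_mismatch"}

    def test_single_cluster_abstains(self):
        beta, man, sex = self._sexed_cohort()
        all_female = pd.Series(1.0, index=beta.columns)
        # collapse the X signal to one cluster
        beta.iloc[20:] = 0.5
        rep = flag_sex_and_duplicates(beta, man, all_female)
        assert rep.samples_dropped == {}
        assert any("abstains" in w for w in rep.warnings)

    def test_no_x_probes_warns_not_errors(self):
        beta, man, sex = self._sexed_cohort()
        man["chromosome"] = "1"
        rep = flag_sex_and_duplicates(beta, man, sex)
        assert any("skipped" in w for w in rep.warnings)

    def test_verbatim_duplicate_flags_later_sample(self):
        beta, man, sex = self._sexed_cohort()
        beta["s1"] = beta["s0"]
        sex["s1"] = sex["s0"]
        rep = flag_sex_and_duplicates(beta, man, sex)
        assert rep.samples_dropped.get("s1") == "duplicate"
        assert "s0" not in rep.samples_dropped


class TestCascade:
    def test_rerun_on_own_output_is_identity(self, small_bundle):
        sex = small_bundle.phenotypes.set_index("sample_id")["newborn_sex"]
        clean, rep1 = run_qc(small_bundle.beta, small_bundle.manifest, sex)
        sex2 = sex.loc[clean.columns]
        again, rep2 = run_qc(clean, small_bundle.manifest, sex2)
        pd.testing.assert_frame_equal(again, clean)
        assert rep2.samples_dropped == {} and rep2.probes_dropped == {}
        assert rep2.n_imputed == 0

    def test_conservation(self, small_bundle):
        sex = small_bundle.phenotypes.set_index("sample_id")["newborn_sex"]
        clean, rep = run_qc(small_bundle.beta, small_bundle.manifest, sex)
        assert clean.shape[0] + len(rep.probes_dropped) == small_bundle.beta.shape[0]
        assert clean.shape[1] + len(rep.samples_dropped) == small_bundle.beta.shape[1]
        assert not clean.isna().any().any()


class TestDeconvolution:
    def test_pure_type_recovers_vertex(self):
        ref = synthetic_cell_reference()
        beta = _matrix(ref["CD4T"].to_numpy()[:, None], probes=list(ref["probe_id"]))
        props = estimate_cell_proportions(beta, ref)
        expected = np.zeros(len(CELL_TYPES))
        expected[list(CELL_TYPES).index("CD4T")] = 1.0
        np.testing.assert_allclose(
            props[list(CELL_TYPES)].to_numpy()[0], expected, atol=1e-6
        )

    def test_noiseless_half_half_mixture_exact(self):
        ref = synthetic_cell_reference()
        mix = 0.5 * ref["Gran"].to_numpy() + 0.5 * ref["nRBC"].to_numpy()
        beta = _matrix(mix[:, None], probes=list(ref["probe_id"]))
        props = estimate_cell_proportions(beta, ref)[list(CELL_TYPES)].to_numpy()[0]
        expected = {"Gran": 0.5, "nRBC": 0.5}
        for cell, want in zip(CELL_TYPES, props):
            assert want == pytest.approx(expected.get(cell, 0.0), abs=1e-6)

    def test_noisy_mixture_recovery(self):
        rng = np.random.default_rng(8)
        ref = synthetic_cell_reference()
        A = ref[list(CELL_TYPES)].to_numpy()
        truth = rng.dirichlet(np.ones(len(CELL_TYPES)), size=30)
        obs = np.clip(A @ truth.T + rng.normal(0, 0.02, (A.shape[0], 30)), 0, 1)
        beta = _matrix(obs, probes=list(ref["probe_id"]))
        props = estimate_cell_proportions(beta, ref)[list(CELL_TYPES)].to_numpy()
        assert np.max(np.abs(props - truth)) < 0.05

    def test_rank_deficient_reference_rejected(self):
        ref = synthetic_cell_reference()
        ref["CD8T"] = ref["CD4T"]
        beta = _matrix(ref["CD4T"].to_numpy()[:, None], probes=list(ref["probe_id"]))
        with pytest.raises(ValidationError, match="rank"):
            estimate_cell_proportions(beta, ref)

    def test_constrained_objective_vs_unconstrained(self):
        # the constrained residual can never beat unconstrained least squares
        rng = np.random.default_rng(3)
        ref = synthetic_cell_reference()
        A = ref[list(CELL_TYPES)].to_numpy()
        y = np.clip(rng.uniform(0, 1, A.shape[0]), 0, 1)
        beta = _matrix(y[:, None], probes=list(ref["probe_id"]))
        props = estimate_cell_proportions(beta, ref)
        x_unc, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert props["residual_norm"][0] >= np.linalg.norm(A @ x_unc - y) - 1e-9
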