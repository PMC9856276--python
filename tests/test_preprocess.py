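import numpy as np
import pandas as pd
import pytest

from protpanel import (
    ProteinMatrix,
    SampleMetadata,
    combat_adjust,
    log2_and_standardize,
    log2_transform,
    pc_confounder_scan,
    qc_filter_samples,
    residualize_covariates,
    small_config,
    standardize,
)
from protpanel.preprocess import PreprocessError
from protpanel.synth import BatchSpec, generate_cohort


def _matrix(arr, ids=None, proteins=None, state="log2"):
    arr = np.asarray(arr, dtype=float)
    ids = ids or [f"S{i}" for i in range(arr.shape[0])]
    proteins = proteins or [f"P{j}" for j in range(arr.shape[1])]
    return ProteinMatrix(pd.DataFrame(arr, index=ids, columns=proteins), state)


class TestQC:
    def test_acceptance_window_is_closed(self, tiny_matrix):
        factors = {"S1": 1.0, "S2": 0.4, "S3": 2.5}
        kept, report = qc_filter_samples(tiny_matrix, factors)
        assert kept.sample_ids == ["S1", "S2", "S3"]
        assert report.empty

    def test_out_of_range_samples_removed_with_reason(self, tiny_matrix):
        factors = {"S1": 1.0, "S2": 0.3, "S3": 2.6}
        kept, report = qc_filter_samples(tiny_matrix, factors)
        assert kept.sample_ids == ["S1"]
        assert sorted(report.sample_id) == ["S2", "S3"]
        assert report.reason.str.contains("0.4").all()

    def test_missing_factor_errors(self, tiny_matrix):
        with pytest.raises(PreprocessError, match="S3"):
            qc_filter_samples(tiny_matrix, {"S1": 1.0, "S2": 1.0})


class TestStandardize:
    def test_closed_form_column(self):
        m = _matrix([[1.0], [2.0], [4.0]], state="raw")
        out = log2_and_standardize(m)
        np.testing.assert_allclose(
            out.values.to_numpy().ravel(), [-1.0, 0.0, 1.0], atol=1e-12
        )
        assert out.transform_state == "standardized"

    def test_postconditions_on_random_input(self, rng):
        m = _matrix(rng.lognormal(3, 1, (40, 8)), state="raw")
        out = log2_and_standardize(m)
        assert np.abs(out.values.mean(axis=0)).max() < 1e-10
        assert np.abs(out.values.std(axis=0, ddof=1) - 1).max() < 1e-10

    def test_constant_column_errors_or_drops(self):
        m = _matrix([[1.0, 5.0], [2.0, 5.0], [4.0, 5.0]], state="raw")
        with pytest.raises(PreprocessError, match="P1"):
            log2_and_standardize(m)
        out = log2_and_standardize(m, on_zero_variance="drop")
        assert out.protein_ids == ["P0"]


class TestResidualize:
    def test_perfect_fit_leaves_zero_residuals(self):
        age = np.array([50.0, 60, 70, 80])
        m = _matrix((2 * age)[:, None])
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": m.sample_ids, "status": ["case"] * 4, "age": age,
        }))
        out, _ = residualize_covariates(m, meta, ["age"])
        assert np.abs(out.values.to_numpy()).max() < 1e-8
        assert out.transform_state == "residualized"

    def test_independent_protein_keeps_centered_signal(self, rng):
        n = 2000
        x = rng.normal(0, 1, n)
        age = rng.normal(65, 8, n)
        m = _matrix(x[:, None])
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": m.sample_ids, "status": ["case"] * n, "age": age,
        }))
        out, _ = residualize_covariates(m, meta, ["age"])
        r = np.corrcoef(out.values.to_numpy().ravel(), x - x.mean())[0, 1]
        assert r > 0.999

    def test_slope_recovered_and_residuals_decorrelated(self, rng):
        # protein = 1 + 0.5 age + noise: residuals orthogonal to age and
        # the implied coefficient within 3 SE of 0.5
        n = 200
        age = rng.normal(65, 8, n)
        eps = rng.normal(0, 1, n)
        m = _matrix((1 + 0.5 * age + eps)[:, None])
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": m.sample_ids, "status": ["case"] * n, "age": age,
        }))
        out, _ = residualize_covariates(m, meta, ["age"])
        resid = out.values.to_numpy().ravel()
        assert abs(np.corrcoef(resid, age)[0, 1]) < 1e-8
        # normal-equation oracle
        X = np.column_stack([np.ones(n), age])
        coef = np.linalg.solve(X.T @ X, X.T @ (1 + 0.5 * age + eps))
        se = np.sqrt(
            (eps.var(ddof=2) / ((age - age.mean()) ** 2).sum())
        )
        assert abs(coef[1] - 0.5) < 3 * se

    def test_missing_covariate_samples_dropped_with_report(self, rng):
        m = _matrix(rng.normal(0, 1, (5, 2)))
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": m.sample_ids, "status": ["case"] * 5,
            "age": [60.0, np.nan, 65, 70, np.nan],
        }))
        out, report = residualize_covariates(m, meta, ["age"])
        assert out.n_samples == 3
        assert len(report) == 2

    def test_constant_covariate_errors(self, rng):
        m = _matrix(rng.normal(0, 1, (4, 1)))
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": m.sample_ids, "status": ["case"] * 4,
            "cohort": ["X"] * 4,
        }))
        with pytest.raises(PreprocessError, match="cohort"):
            residualize_covariates(m, meta, ["cohort"])

    def test_date_covariate_encoded_as_days(self):
        dates = ["2019-01-01", "2019-01-11", "2019-01-21", "2019-01-31"]
        days = np.array([0.0, 10, 20, 30])
        m = _matrix((5 + 0.1 * days)[:, None])
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": m.sample_ids, "status": ["case"] * 4,
            "assay_date": dates,
        }))
        out, _ = residualize_covariates(m, meta, ["assay_date"])
        assert np.abs(out.values.to_numpy()).max() < 1e-8


class TestCombat:
    def test_single_batch_identity(self, rng):
        m = _matrix(rng.normal(8, 1, (20, 5)))
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": m.sample_ids, "status": ["case"] * 20,
            "batch": ["B1"] * 20,
        }))
        out = combat_adjust(m, meta)
        np.testing.assert_allclose(
            out.values.to_numpy(), m.values.to_numpy(), atol=1e-8
        )

    def test_pure_location_shift_equalized(self, rng):
        # two equal batches, identical variance, shift +/- delta:
        # without shrinkage the closed-form adjustment moves each batch
        # mean onto the grand mean
        n = 100
        base = rng.normal(8, 1, (n, 6))
        delta = 1.0
        base[: n // 2] += delta / 2
        base[n // 2:] -= delta / 2
        m = _matrix(base)
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": m.sample_ids, "status": ["case"] * n,
            "batch": ["A"] * (n // 2) + ["B"] * (n // 2),
        }))
        out = combat_adjust(m, meta, shrink=False)
        vals = out.values.to_numpy()
        mean_a = vals[: n // 2].mean(axis=0)
        mean_b = vals[n // 2:].mean(axis=0)
        np.testing.assert_allclose(mean_a, mean_b, atol=1e-10)
        # each batch moved by about delta/2 toward the middle
        # (up to the sampling noise of the per-batch means, sd ~ 1/sqrt(n/2))
        shift = base[: n // 2].mean(axis=0) - mean_a
        assert np.abs(shift - delta / 2).max() < 0.35

    def test_protected_status_effect_preserved(self):
        # planted status effect orthogonal to the batch shift survives
        # adjustment within 3 SE of the planted value
        cfg = small_config(
            n_samples=300, case_fraction=0.5, n_proteins=40, seed=21,
            informative_proteins=(("P00005", 0.8),),
            batch_spec=(BatchSpec("A", 0.8), BatchSpec("B", -0.8)),
        )
        m, md = generate_cohort(cfg, "serum")
        adj = combat_adjust(log2_transform(m), md, protect=["status"])
        x = adj.values["P00005"]
        case = (md.status == "case").to_numpy()
        diff = x[case].mean() - x[~case].mean()
        se = 0.5 * np.sqrt(1 / case.sum() + 1 / (~case).sum())
        assert abs(diff - 0.8) < 3 * se

    def test_single_sample_batch_rejected(self, rng):
        m = _matrix(rng.normal(8, 1, (5, 3)))
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": m.sample_ids, "status": ["case"] * 5,
            "batch": ["A", "A", "A", "A", "B"],
        }))
        with pytest.raises(PreprocessError, match="single sample"):
            combat_adjust(m, meta)

    def test_confounded_batch_rejected(self, rng):
        m = _matrix(rng.normal(8, 1, (8, 3)))
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": m.sample_ids,
            "status": ["case"] * 4 + ["control"] * 4,
            "batch": ["A"] * 4 + ["B"] * 4,
        }))
        with pytest.raises(PreprocessError, match="confounded"):
            combat_adjust(m, meta, protect=["status"])


class TestPCScan:
    def test_planted_batch_flagged_on_pc1(self):
        cfg = small_config(
            n_samples=200, case_fraction=0.5, n_proteins=60, seed=30,
            informative_proteins=(),
            batch_spec=(BatchSpec("A", 1.0), BatchSpec("B", -1.0)),
        )
        m, md = generate_cohort(cfg, "serum")
        report = pc_confounder_scan(
            log2_and_standardize(m), md, k=3, confounders=["batch"]
        )
        pc1 = report[report.pc == "PC1"].iloc[0]
        assert pc1.flagged and pc1.p < 1e-6

    def test_null_matrix_flag_rate_controlled(self):
        flags = 0
        tests = 0
        for seed in range(10):
            cfg = small_config(n_samples=80, case_fraction=0.5,
                               n_proteins=40, seed=100 + seed,
                               informative_proteins=())
            m, md = generate_cohort(cfg, "serum")
            report = pc_confounder_scan(
                log2_and_standardize(m), md, k=3,
                confounders=["sex", "batch", "age"], alpha=0.01,
            )
            flags += int(report.flagged.sum())
            tests += len(report)
        assert flags <= max(3, 3 * 0.01 * tests)

    def test_k_zero_gives_empty_report(self, small_cohort):
        m, md = small_cohort
        report = pc_confounder_scan(log2_and_standardize(m), md, k=0)
        assert report.empty


def test_chain_preserves_sample_order(small_cohort):
    m, md = small_cohort
    std = log2_and_standardize(m)
    out, _ = residualize_covariates(std, md, ["age", "sex"])
    assert out.sample_ids == m.sample_ids
    assert out.transform_state == "residualized"
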