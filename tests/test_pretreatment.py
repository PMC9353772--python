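"""Intensity-based pretreatment: imputation, normalization, glog, Pareto."""

import numpy as np
import pandas as pd
import pytest

from mdinet import AlignedMatrix
from mdinet.pretreatment import (
    PretreatmentConfig,
    glog_transform,
    idt_pipeline,
    impute_fifth_min,
    impute_random_forest,
    normalize_pqn,
    normalize_reference_feature,
    pareto_scale,
)


def _matrix(values: dict, masses=None, classes=None) -> AlignedMatrix:
    inten = pd.DataFrame(values, dtype=float)
    inten.index = [f"f{i + 1}" for i in range(len(inten))]
    m = masses if masses is not None else pd.Series(
        np.linspace(100, 900, len(inten)), index=inten.index
    )
    return AlignedMatrix(inten, m, classes)


class TestFifthMin:
    def test_per_sample_fifth_minimum(self):
        m = _matrix({"s1": [10.0, np.nan, 50.0], "s2": [5.0, 8.0, np.nan]})
        out = impute_fifth_min(m).intensities
        assert out.loc["f2", "s1"] == 2.0  # min(10, 50)/5
        assert out.loc["f3", "s2"] == 1.0  # min(5, 8)/5

    def test_no_missing_is_identity(self):
        m = _matrix({"s1": [10.0, 20.0], "s2": [5.0, 8.0]})
        pd.testing.assert_frame_equal(impute_fifth_min(m).intensities, m.intensities)


class TestRfImputation:
    def test_no_missing_is_identity(self):
        m = _matrix({"s1": [10.0, 20.0], "s2": [5.0, 8.0], "s3": [1.0, 2.0]})
        out = impute_random_forest(m, PretreatmentConfig(imputation="random_forest"))
        pd.testing.assert_frame_equal(out.intensities, m.intensities)

    def test_completes_and_respects_feature_range(self):
        rng = np.random.default_rng(5)
        base = rng.lognormal(3, 0.5, size=(12, 8))
        mask = rng.random(base.shape) < 0.15
        vals = np.where(mask, np.nan, base)
        vals[:, 0] = base[:, 0]  # keep one complete sample
        m = _matrix({f"s{j}": vals[:, j] for j in range(8)})
        cfg = PretreatmentConfig(imputation="random_forest", rf_trees=15, seed=0)
        out = impute_random_forest(m, cfg).intensities
        assert not out.isna().any().any()
        observed = m.intensities
        for f in m.feature_ids:
            lo, hi = observed.loc[f].min(), observed.loc[f].max()
            assert (out.loc[f] >= lo - 1e-9).all() and (out.loc[f] <= hi + 1e-9).all()

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(6)
        vals = rng.lognormal(3, 0.5, size=(10, 6))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        m = _matrix({f"s{j}": vals[:, j] for j in range(6)})
        cfg = PretreatmentConfig(imputation="random_forest", rf_trees=10, seed=42)
        a = impute_random_forest(m, cfg).intensities
        b = impute_random_forest(m, cfg).intensities
        pd.testing.assert_frame_equal(a, b)


class TestReferenceNormalization:
    def _m(self):
        masses = pd.Series([100.0, 554.262022, 300.0], index=["f1", "f2", "f3"])
        return _matrix(
            {"s1": [10.0, 2.0, 4.0], "s2": [9.0, 1.0, 3.0]}, masses=masses
        )

    def test_divides_and_removes_reference(self):
        out = normalize_reference_feature(self._m(), 554.262022, tol_ppm=1.0)
        assert "f2" not in out.feature_ids
        assert out.intensities.loc["f1", "s1"] == 5.0  # ref intensity 2
        assert out.intensities.loc["f1", "s2"] == 9.0  # ref intensity 1

    def test_no_match_and_ambiguity_errors(self):
        with pytest.raises(ValueError, match="no feature within"):
            normalize_reference_feature(self._m(), 700.0, tol_ppm=1.0)
        masses = pd.Series([554.262022, 554.262023], index=["f1", "f2"])
        dup = _matrix({"s1": [1.0, 2.0], "s2": [3.0, 4.0]}, masses=masses)
        with pytest.raises(ValueError, match="multiple features"):
            normalize_reference_feature(dup, 554.262022, tol_ppm=1.0)


class TestPqn:
    def test_identical_samples_unchanged(self):
        m = _matrix({"s1": [1.0, 4.0, 9.0], "s2": [1.0, 4.0, 9.0], "s3": [1.0, 4.0, 9.0]})
        pd.testing.assert_frame_equal(normalize_pqn(m).intensities, m.intensities)

    def test_sample_twice_reference_halved(self):
        ref = pd.Series([2.0, 4.0, 8.0], index=["f1", "f2", "f3"])
        m = _matrix({"s1": [4.0, 8.0, 16.0], "s2": [2.0, 4.0, 8.0]})
        out = normalize_pqn(m, reference=ref).intensities
        assert out["s1"].tolist() == [2.0, 4.0, 8.0]
        assert out["s2"].tolist() == [2.0, 4.0, 8.0]

    def test_fixed_reference_scale_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(2, 1, size=(20, 5))
        m = _matrix({f"s{j}": vals[:, j] for j in range(5)})
        ref = m.intensities.mean(axis=1)
        base = normalize_pqn(m, reference=ref).intensities
        scaled = m.intensities.copy()
        scaled["s2"] *= 7.3
        out = normalize_pqn(m.with_intensities(scaled), reference=ref).intensities
        pd.testing.assert_frame_equal(out, base)

    def test_requires_complete_matrix(self):
        m = _matrix({"s1": [1.0, np.nan], "s2": [2.0, 3.0]})
        with pytest.raises(ValueError, match="imputed"):
            normalize_pqn(m)


class TestGlog:
    def test_lambda_zero_is_log2(self):
        m = _matrix({"s1": [1.0, 2.0], "s2": [4.0, 1024.0]})
        out = glog_transform(m, 0.0).intensities
        assert np.allclose(out, np.log2(m.intensities))
        assert out.loc["f1", "s1"] == 0.0

    def test_monotone_in_x(self):
        xs = np.linspace(0.0, 50.0, 200)
        for lam in (0.5, 4.0, 100.0):
            g = np.log2((xs + np.sqrt(xs**2 + lam)) / 2)
            assert (np.diff(g) > 0).all()

    def test_nonpositive_with_zero_lambda_rejected(self):
        m = _matrix({"s1": [0.0, 2.0], "s2": [1.0, 3.0]})
        with pytest.raises(ValueError, match="lambda"):
            glog_transform(m, 0.0)


class TestPareto:
    def test_centering_and_variance(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(2, 1, size=(10, 6))
        m = _matrix({f"s{j}": vals[:, j] for j in range(6)})
        pre_sd = m.intensities.std(axis=1, ddof=1)
        out = pareto_scale(m).intensities
        assert np.allclose(out.mean(axis=1), 0.0)
        assert np.allclose(out.var(axis=1, ddof=1), pre_sd)

    def test_constant_feature_becomes_zero(self):
        m = _matrix({"s1": [5.0, 1.0], "s2": [5.0, 2.0], "s3": [5.0, 3.0]})
        out = pareto_scale(m).intensities
        assert (out.loc["f1"] == 0).all()


class TestPipeline:
    def _train_test(self):
        rng = np.random.default_rng(9)
        vals = rng.lognormal(4, 1, size=(15, 9))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        vals[0, :] = rng.lognormal(4, 1, 9)  # keep feature 1 complete
        m = _matrix({f"s{j}": vals[:, j] for j in range(9)})
        return m.select_samples([f"s{j}" for j in range(6)]), m.select_samples(
            [f"s{j}" for j in range(6, 9)]
        )

    def test_train_only_run_is_complete_and_centered(self):
        train, _ = self._train_test()
        res = idt_pipeline(train, cfg=PretreatmentConfig())
        assert not res.train.intensities.isna().any().any()
        assert np.allclose(res.train.intensities.mean(axis=1), 0.0, atol=1e-9)

    def test_absent_test_feature_filled_with_train_minimum(self):
        train, test = self._train_test()
        # make one train-retained feature entirely absent from the test set
        kept = idt_pipeline(train).train.feature_ids
        target = kept[0]
        blanked = test.intensities.copy()
        blanked.loc[target] = np.nan
        test2 = AlignedMatrix(blanked, test.neutral_mass, test.classes)
        res = idt_pipeline(train, test2, PretreatmentConfig())
        assert res.fitted["train_min"] == pytest.approx(
            float(np.nanmin(train.intensities.loc[kept].to_numpy())), rel=1e-6
        )
        assert target in res.test.feature_ids
        assert not res.test.intensities.isna().any().any()

    def test_test_side_uses_train_fitted_parameters(self):
        train, test = self._train_test()
        res = idt_pipeline(train, test, PretreatmentConfig())
        mu = res.fitted["pareto_mean"]
        # train rows are centered by construction; test rows generally not,
        # proving test was scaled with train parameters, not its own
        assert np.allclose(res.train.intensities.mean(axis=1), 0.0, atol=1e-9)
        assert not np.allclose(res.test.intensities.mean(axis=1), 0.0, atol=1e-6)
        assert set(res.test.feature_ids) == set(res.train.feature_ids)
        assert mu.index.equals(res.train.intensities.index)

    def test_disjoint_universes_rejected(self):
        train, test = self._train_test()
        renamed = test.intensities.copy()
        renamed.index = [f"g{i}" for i in range(len(renamed))]
        bad = AlignedMatrix(renamed, pd.Series(np.linspace(100, 900, len(renamed)),
                                               index=renamed.index))
        with pytest.raises(ValueError, match="share no features"):
            idt_pipeline(train, bad)
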