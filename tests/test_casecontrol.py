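"""Case-control models, PCA, quadrants and map correlations vs oracles."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import morphosim as ms
from morphosim.casecontrol import RankDeficientDesignError


@pytest.fixture(scope="module")
def null_fit(small_cohort):
    subjects, _ = small_cohort
    profiles = ms.cohort_profiles(subjects)
    meta = ms.metadata_frame(subjects)
    return subjects, profiles, meta, ms.fit_region_models(profiles, meta)


class TestRegionModels:
    def test_matches_statsmodels_ols(self, null_fit):
        """t and p for the group contrast equal an independent OLS oracle."""
        import statsmodels.api as sm

        subjects, profiles, meta, cc = null_fit
        group = (meta["group"] == "case").astype(float)
        X = sm.add_constant(pd.DataFrame({
            "group": group,
            "age": meta["age"],
            "sex": meta["sex"],
            "icv": meta["icv"],
        }))
        for j in [0, 7, 19]:
            y = np.array([p.regional_ms[j] for p in profiles])
            fit = sm.OLS(y, X).fit()
            assert cc.t_stat[j] == pytest.approx(fit.tvalues["group"],
                                                 abs=1e-10)
            assert cc.p[j] == pytest.approx(fit.pvalues["group"], abs=1e-10)

    def test_matches_normal_equations(self, null_fit):
        """Brute-force hat-matrix algebra reproduces t to 1e-10."""
        subjects, profiles, meta, cc = null_fit
        g = (meta["group"] == "case").to_numpy(float)
        X = np.column_stack([np.ones(len(meta)), g, meta["age"],
                             meta["sex"], meta["icv"]])
        j = 3
        y = np.array([p.regional_ms[j] for p in profiles])
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ X.T @ y
        resid = y - X @ beta
        dof = len(y) - X.shape[1]
        se = np.sqrt(resid @ resid / dof * xtx_inv[1, 1])
        assert cc.t_stat[j] == pytest.approx(beta[1] / se, abs=1e-10)

    def test_covariate_component_orthogonal_to_group_effect(self, null_fit):
        """Adding any covariate-linear component leaves the group t intact
        (Frisch-Waugh): the covariate part carries no group information."""
        subjects, profiles, meta, cc_plain = null_fit
        shifted = [
            dataclasses.replace(
                p,
                regional_ms=p.regional_ms
                + (0.1 * s.age - 0.2 * s.sex + 1e-6 * s.icv))
            for p, s in zip(profiles, subjects)
        ]
        cc = ms.fit_region_models(shifted, meta)
        np.testing.assert_allclose(cc.t_stat, cc_plain.t_stat, atol=1e-7)

    def test_cohen_d_conversion_and_z_monotone(self, null_fit):
        _, _, meta, cc = null_fit
        n1 = (meta["group"] == "case").sum()
        n2 = (meta["group"] == "control").sum()
        np.testing.assert_allclose(
            cc.cohen_d, cc.t_stat * np.sqrt(1 / n1 + 1 / n2))
        order = np.argsort(cc.t_stat)
        assert np.all(np.diff(cc.z_stat[order]) >= 0)
        assert np.all(np.sign(cc.z_stat) == np.sign(cc.t_stat))

    def test_fdr_monotone_and_above_p(self, null_fit):
        _, _, _, cc = null_fit
        assert np.all(cc.p_fdr >= cc.p - 1e-15)
        order = np.argsort(cc.p)
        assert np.all(np.diff(cc.p_fdr[order]) >= -1e-15)

    def test_rank_deficient_design_names_columns(self, null_fit):
        subjects, profiles, meta, _ = null_fit
        meta2 = meta.copy()
        meta2["icv"] = 2.0 * meta2["age"]  # collinear pair
        with pytest.raises(RankDeficientDesignError, match="age"):
            ms.fit_region_models(profiles, meta2)

    def test_missing_region_dropped_not_imputed(self, null_fit):
        subjects, profiles, meta, cc_full = null_fit
        profiles2 = [dataclasses.replace(
            p, regional_ms=p.regional_ms.copy()) for p in profiles]
        profiles2[0].regional_ms[4] = np.nan
        with pytest.warns(UserWarning, match="dropped"):
            cc = ms.fit_region_models(profiles2, meta)
        assert np.isfinite(cc.t_stat[4])
        untouched = np.delete(np.arange(20), 4)
        np.testing.assert_allclose(cc.t_stat[untouched],
                                   cc_full.t_stat[untouched])


class TestGlobal:
    def test_identical_groups_give_zero_t(self, null_fit):
        subjects, profiles, meta, _ = null_fit
        mirrored = []
        meta_rows = []
        for i, (p, s) in enumerate(zip(profiles, profiles)):
            for grp in ("case", "control"):
                mirrored.append(dataclasses.replace(
                    p, subject_id=f"{grp}_{i}"))
                meta_rows.append({"subject_id": f"{grp}_{i}", "group": grp,
                                  "age": 40 + i, "sex": i % 2,
                                  "icv": 1.5e6 + 1000 * (i % 7) ** 2})
        t, p, _ = ms.global_comparison(mirrored, pd.DataFrame(meta_rows))
        assert t == pytest.approx(0.0, abs=1e-10)

    def test_consistent_with_region_machinery(self, null_fit):
        subjects, profiles, meta, _ = null_fit
        as_regions = [
            dataclasses.replace(
                p, regional_ms=np.array([p.global_ms]), region_labels=["g"])
            for p in profiles
        ]
        cc = ms.fit_region_models(as_regions, meta)
        t, pval, _ = ms.global_comparison(profiles, meta)
        assert t == pytest.approx(cc.t_stat[0], abs=1e-12)
        assert pval == pytest.approx(cc.p[0], abs=1e-12)


class TestLeaveOneFeatureOut:
    def test_excluding_a_duplicated_feature_restores_original_map(
            self, small_cohort):
        """Dropping a duplicated column recovers the un-duplicated map
        exactly (the duplicate itself double-weights its source, so the
        six-feature map is not the reference — the five-feature one is)."""
        subjects, _ = small_cohort
        meta = ms.metadata_frame(subjects)
        original = ms.fit_region_models(ms.cohort_profiles(subjects), meta)
        dup = [
            dataclasses.replace(
                s,
                features=np.column_stack([s.features, s.features[:, 0]]),
                feature_names=tuple(s.feature_names) + ("dup",),
            )
            for s in subjects
        ]
        maps, rhos, weakest = ms.leave_one_feature_out(dup, meta)
        np.testing.assert_allclose(maps["dup"].t_stat, original.t_stat,
                                   atol=1e-10)
        assert ms.correlate_maps(maps["dup"].t_stat,
                                 original.t_stat) == pytest.approx(1.0)

    def test_full_map_self_correlation_is_one(self, null_fit):
        subjects, profiles, meta, cc = null_fit
        assert ms.correlate_maps(cc.t_stat, cc.t_stat) == pytest.approx(1.0)


class TestVonEconomo:
    def test_single_class_equals_global(self, null_fit):
        subjects, profiles, meta, _ = null_fit
        labels = list(profiles[0].region_labels)
        cc = ms.aggregate_von_economo(
            profiles, meta, {r: "all" for r in labels})
        t, p, _ = ms.global_comparison(profiles, meta)
        assert cc.t_stat[0] == pytest.approx(t, abs=1e-12)

    def test_relabelling_invariance(self, null_fit):
        subjects, profiles, meta, _ = null_fit
        labels = list(profiles[0].region_labels)
        class_map = {r: f"c{i % 4}" for i, r in enumerate(labels)}
        renamed = {r: class_map[r].replace("c", "klass")
                   for r in labels}
        a = ms.aggregate_von_economo(profiles, meta, class_map)
        b = ms.aggregate_von_economo(profiles, meta, renamed)
        assert sorted(a.t_stat) == pytest.approx(sorted(b.t_stat))

    def test_unmapped_region_is_an_error(self, null_fit):
        subjects, profiles, meta, _ = null_fit
        labels = list(profiles[0].region_labels)
        partial = {r: "x" for r in labels[:-1]}
        with pytest.raises(ValueError, match="not mapped"):
            ms.aggregate_von_economo(profiles, meta, partial)

    def test_shipped_manifest_covers_dk68(self):
        from morphosim.parcellation import DK68_LABELS, load_von_economo_classes

        classes = load_von_economo_classes()
        assert set(DK68_LABELS) <= set(classes.index)


class TestHubSusceptibility:
    def test_perfect_anti_alignment(self):
        control = np.array([0.4, 0.2, -0.1, -0.3, 0.1, -0.2])
        rho, quad = ms.hub_susceptibility(-control, control)
        assert rho == pytest.approx(-1.0)
        occupied = set(quad.labels.unique())
        assert occupied == {"dedifferentiation", "decoupling"}
        assert quad.percentages.sum() == pytest.approx(100.0)

    def test_hand_tallied_quadrants(self):
        control = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0])
        delta = np.array([1.0, -1.0, 1.0, -1.0, 1.0, 1.0])
        _, quad = ms.hub_susceptibility(delta, control)
        counts = quad.labels.value_counts()
        assert counts["hypercoupling"] == 2
        assert counts["decoupling"] == 1
        assert counts["dedifferentiation"] == 2
        assert counts["hyperdifferentiation"] == 1

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(1)
        control = rng.standard_normal(30)
        delta = rng.standard_normal(30)
        _, a = ms.hub_susceptibility(delta, control)
        _, b = ms.hub_susceptibility(5.0 * delta, 0.1 * control)
        assert (a.labels == b.labels).all()

    def test_constant_axis_rejected(self):
        with pytest.raises(ValueError, match="constant|undefined"):
            ms.hub_susceptibility(np.zeros(5), np.ones(5))


class TestCrossConditionPCA:
    @staticmethod
    def _map_from(z, ds):
        return ms.CaseControlMap(
            dataset_id=ds, region_labels=[f"r{i}" for i in range(len(z))],
            t_stat=z.copy(), z_stat=z, cohen_d=z * 0.2,
            p=np.full(len(z), 0.5), p_fdr=np.full(len(z), 0.5),
            df_resid=10.0)

    def test_three_identical_maps_are_rank_one(self):
        z = np.random.default_rng(2).standard_normal(68)
        maps = [self._map_from(z, d) for d in "abc"]
        pattern = ms.cross_condition_pca(maps)
        assert pattern.explained_variance_pct[0] == pytest.approx(100.0)
        assert pattern.eigenvalues[0] == pytest.approx(3.0)

    def test_variance_accounting(self):
        rng = np.random.default_rng(3)
        maps = [self._map_from(rng.standard_normal(68), d) for d in "abc"]
        pattern = ms.cross_condition_pca(maps)
        assert pattern.explained_variance_pct.sum() == pytest.approx(100.0)
        assert pattern.eigenvalues.sum() == pytest.approx(3.0)

    def test_uncorrelated_long_maps_split_variance(self):
        rng = np.random.default_rng(4)
        maps = [self._map_from(rng.standard_normal(5000), d) for d in "abc"]
        pattern = ms.cross_condition_pca(maps)
        assert np.all(np.abs(pattern.explained_variance_pct - 100 / 3) < 5)

    def test_pc1_sign_convention(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal(68)
        maps = [self._map_from(base + 0.3 * rng.standard_normal(68), d)
                for d in "abc"]
        pattern = ms.cross_condition_pca(maps)
        mean_map = np.mean([m.z_stat for m in maps], axis=0)
        assert np.corrcoef(pattern.pc_scores, mean_map)[0, 1] > 0

    def test_constant_column_rejected(self):
        z = np.random.default_rng(6).standard_normal(68)
        maps = [self._map_from(z, "a"), self._map_from(np.zeros(68), "b")]
        with pytest.raises(ValueError, match="constant"):
            ms.cross_condition_pca(maps)


class TestCorrelateMaps:
    def test_identity_and_reversal(self):
        v = np.arange(10.0)
        assert ms.correlate_maps(v, v) == pytest.approx(1.0)
        assert ms.correlate_maps(v, v[::-1]) == pytest.approx(-1.0)

    def test_matches_brute_force_rank_correlation(self):
        rng = np.random.default_rng(9)
        a, b = rng.standard_normal((2, 15))
        ranks_a = stats.rankdata(a)
        ranks_b = stats.rankdata(b)
        expected = np.corrcoef(ranks_a, ranks_b)[0, 1]
        assert ms.correlate_maps(a, b) == pytest.approx(expected, abs=1e-12)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ms.correlate_maps(np.ones(5), np.arange(5.0))


@settings(deadline=None, max_examples=30)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0),
                min_size=3, max_size=40))
def test_bh_fdr_properties(pvals):
    """BH adjustment is monotone in p and fixes an all-equal vector."""
    from statsmodels.stats.multitest import multipletests

    p = np.array(pvals)
    adj = multipletests(p, method="fdr_bh")[1]
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)
    same = multipletests(np.full(8, p[0]), method="fdr_bh")[1]
    np.testing.assert_allclose(same, p[0])
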